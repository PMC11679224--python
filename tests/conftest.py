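"""Shared fixtures: small synthetic cohorts and fused feature sets."""

import numpy as np
import pytest

from stanet.ica import extract_features
from stanet.stfa import ConvBankParams, fuse_subject
from stanet.synth import make_cohort, make_rsn_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """300 voxels x 20 networks."""
    return make_rsn_atlas(300, 20, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    """8 pos / 4 neg subjects, 40 timepoints, 4 sources, strong effect."""
    scans, truth = make_cohort(
        n_pos=8, n_neg=4, T=40, V=300, n_sources=4, effect_size=2.0,
        atlas=small_atlas, seed=5, snr=20.0,
    )
    return scans, truth


@pytest.fixture(scope="session")
def small_features(small_cohort, small_atlas):
    scans, _ = small_cohort
    feature_sets, decomp, sim = extract_features(
        scans, small_atlas, n_components=4, n_restarts=3, seed=3, discard=5,
    )
    return feature_sets, decomp, sim


@pytest.fixture(scope="session")
def tiny_conv_params():
    """Two small scales, 2 filters, pool 4: keeps classifier tests fast."""
    return ConvBankParams(kernel_sizes=(3, 5), n_filters=2, pool_size=4, seed=2)


@pytest.fixture(scope="session")
def small_fused(small_features, tiny_conv_params):
    feature_sets, _, _ = small_features
    return [fuse_subject(fs, tiny_conv_params) for fs in feature_sets]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
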