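"""End-to-end orchestration: simulate -> extract -> fuse -> cross-validate."""

from __future__ import annotations

import logging
import time
from pathlib import Path

from . import afgru, io
from .config import PipelineConfig
from .evaluate import MetricsReport, cross_validate
from .ica import extract_features
from .stfa import ConvBankParams, FusedFeature, fuse_subject
from .synth import RSNAtlas, SubjectScan, make_cohort, make_rsn_atlas

__all__ = ["full_run", "simulate", "fuse_cohort", "classifier_config"]

log = logging.getLogger("stanet")


def simulate(config: PipelineConfig) -> tuple[list[SubjectScan], RSNAtlas]:
    atlas = make_rsn_atlas(config.voxels, config.n_networks, config.seed)
    scans, _ = make_cohort(
        config.n_pos, config.n_neg, config.timepoints, config.voxels,
        config.n_sources, config.effect_size, atlas, config.seed, snr=config.snr,
    )
    return scans, atlas


def fuse_cohort(feature_sets, config: PipelineConfig) -> list[FusedFeature]:
    params = ConvBankParams(
        kernel_sizes=config.kernel_sizes, n_filters=config.n_filters,
        pool_size=config.pool, seed=config.seed,
    )
    return [fuse_subject(fs, params) for fs in feature_sets]


def classifier_config(config: PipelineConfig) -> afgru.AFGRUConfig:
    return afgru.AFGRUConfig(
        hidden=config.hidden, layers=config.layers, attn_dim=config.attn_dim,
        lr=config.lr, rounds=config.rounds, epochs=config.epochs,
        val_fraction=config.val_fraction, seed=config.seed,
    )


def full_run(
    config: PipelineConfig,
    in_dir: Path | str | None = None,
    atlas_path: Path | str | None = None,
    out_dir: Path | str | None = None,
) -> MetricsReport:
    """Run the whole pipeline and (optionally) write artifacts.

    Without ``in_dir`` a cohort is simulated from the config; otherwise
    NIfTI scans plus a labels table are read from ``in_dir`` (and the
    atlas from ``atlas_path`` when given, else generated).
    """
    t0 = time.time()
    log.info("config %s seed=%d", config.digest(), config.seed)
    if in_dir is None:
        scans, atlas = simulate(config)
        log.info("simulated %d scans (%d x %d)", len(scans),
                 config.timepoints, config.voxels)
    else:
        scans = io.load_cohort(in_dir)
        atlas = (io.load_atlas(atlas_path) if atlas_path
                 else make_rsn_atlas(scans[0].n_voxels, config.n_networks, config.seed))
        log.info("loaded %d scans from %s", len(scans), in_dir)

    t = time.time()
    feature_sets, decomp, _ = extract_features(
        scans, atlas, n_components=config.n_components,
        n_restarts=config.restarts, seed=config.seed, discard=config.discard,
    )
    log.info("group ICA: %d components, converged=%s (%.1fs)",
             decomp.n_components, decomp.converged, time.time() - t)

    t = time.time()
    fused = fuse_cohort(feature_sets, config)
    log.info("fused %d subjects into %d-d vectors (%.1fs)",
             len(fused), fused[0].vector.size, time.time() - t)

    t = time.time()
    report = cross_validate(
        fused, k=config.folds, sampler=config.sampler, smote_k=config.smote_k,
        seed=config.seed, classifier="afgru", config=classifier_config(config),
        stratify=config.stratify,
    )
    log.info("%d-fold CV: ACC=%.3f AUC=%.3f (%.1fs)",
             config.folds, report.ACC, report.AUC, time.time() - t)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.save_fused(fused, out / "fused.csv")
        io.save_json(
            {
                "config": config.to_dict(),
                "config_hash": config.digest(),
                "seed": config.seed,
                "metrics": report.as_dict(),
                "runtime_s": time.time() - t0,
            },
            out / "report.json",
        )
    return report
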