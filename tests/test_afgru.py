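"""AFGRU classifier: FFT front end, cell equations, attention, weighting,
gradient correctness and training behavior."""

import numpy as np
import pytest

from stanet import afgru
from stanet.afgru import (
    AFGRUConfig,
    AttentionParams,
    BranchWeights,
    FGRUParams,
    adaptive_weight_update,
    attention_pool,
    fft_real,
    fgru_cell_step,
    fgru_layer,
    init_branch_weights,
    to_sequences,
)
from _oracles import _cell_transliteration, _dft_oracle, _random_cell
from stanet.stfa import ConvBankParams, fuse_features




class TestFFT:
    def test_constant_input_concentrates_at_dc(self):
        out = fft_real(np.full(8, 3.5))
        expected = np.zeros(8)
        expected[0] = 8 * 3.5
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(fft_real(np.zeros(5)), np.zeros(5))

    def test_matches_direct_dft_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 65))
            x = rng.standard_normal(n)
            np.testing.assert_allclose(fft_real(x), _dft_oracle(x), atol=1e-8)

    def test_even_symmetric_input_is_purely_real(self, rng):
        half = rng.standard_normal(5)
        x = np.concatenate([[rng.standard_normal()], half, half[::-1]])
        assert np.abs(np.fft.fft(x).imag).max() < 1e-10
        np.testing.assert_allclose(fft_real(x), _dft_oracle(x), atol=1e-8)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fft_real(np.array([]))


class TestFGRUCell:
    def test_zero_weights_halve_previous_state(self, rng):
        H, d = 4, 3
        params = FGRUParams(*(np.zeros((H, H + d)) for _ in range(3)),
                            *(np.zeros(H) for _ in range(3)))
        v = rng.standard_normal(H)
        np.testing.assert_allclose(fgru_cell_step(params, v, np.zeros(d)),
                                   0.5 * v, atol=1e-12)

    def test_saturated_update_gate_passes_candidate(self, rng):
        # huge update-gate bias forces z ~ 1, so h ~ h_tilde
        H, d = 3, 2
        params = _random_cell(rng, H, d)
        params.b_z[:] = 40.0
        h_prev = rng.standard_normal(H)
        x_t = rng.standard_normal(d)
        h = fgru_cell_step(params, h_prev, x_t)
        xf = fft_real(x_t)
        r = 1.0 / (1.0 + np.exp(-(params.W_r @ np.concatenate([h_prev, xf]) + params.b_r)))
        h_til = np.tanh(params.W_h @ np.concatenate([r * h_prev, xf]) + params.b_h)
        np.testing.assert_allclose(h, h_til, atol=1e-10)

    def test_scalar_unit_case(self):
        params = FGRUParams(*(np.ones((1, 2)) for _ in range(3)),
                            *(np.zeros(1) for _ in range(3)))
        h = fgru_cell_step(params, np.zeros(1), np.zeros(1))
        np.testing.assert_allclose(h, [0.0], atol=1e-12)

    def test_matches_loop_transliteration(self, rng):
        for _ in range(100):
            H = int(rng.integers(1, 5))
            d = int(rng.integers(1, 7))
            params = _random_cell(rng, H, d)
            h_prev = rng.standard_normal(H)
            x_t = rng.standard_normal(d)
            got = fgru_cell_step(params, h_prev, x_t)
            want = _cell_transliteration(params, h_prev, x_t)
            assert np.abs(got - want).max() < 1e-10

    def test_gate_values_bounded(self, rng):
        params = _random_cell(rng, 3, 4, scale=5.0)
        h_prev = rng.standard_normal(3)
        xf = fft_real(rng.standard_normal(4))
        a = np.concatenate([h_prev, xf])
        z = 1.0 / (1.0 + np.exp(-(params.W_z @ a + params.b_z)))
        r = 1.0 / (1.0 + np.exp(-(params.W_r @ a + params.b_r)))
        assert np.all((z > 0) & (z < 1)) and np.all((r > 0) & (r < 1))

    def test_nan_input_rejected(self, rng):
        params = _random_cell(rng, 2, 2)
        with pytest.raises(ValueError):
            fgru_cell_step(params, np.array([np.nan, 0.0]), np.zeros(2))


class TestFGRULayer:
    def test_zero_weights_keep_state_at_zero(self, rng):
        H, d = 3, 2
        params = FGRUParams(*(np.zeros((H, H + d)) for _ in range(3)),
                            *(np.zeros(H) for _ in range(3)))
        out = fgru_layer(params, rng.standard_normal((6, d)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_single_step_equals_cell(self, rng):
        params = _random_cell(rng, 4, 3)
        x = rng.standard_normal((1, 3))
        np.testing.assert_allclose(
            fgru_layer(params, x)[0],
            fgru_cell_step(params, np.zeros(4), x[0]), atol=1e-12)

    def test_matches_stepwise_recomputation(self, rng):
        params = _random_cell(rng, 3, 4)
        seq = rng.standard_normal((7, 4))
        out = fgru_layer(params, seq)
        h = np.zeros(3)
        for t in range(7):
            h = fgru_cell_step(params, h, seq[t])
            np.testing.assert_allclose(out[t], h, atol=1e-12)

    def test_hidden_state_remains_bounded(self, rng):
        # convex combination of h_prev and tanh keeps |h| <= 1 from h0 = 0
        params = _random_cell(rng, 4, 3, scale=3.0)
        out = fgru_layer(params, 10.0 * rng.standard_normal((50, 3)))
        assert np.abs(out).max() <= 1.0

    def test_empty_sequence_rejected(self, rng):
        params = _random_cell(rng, 2, 2)
        with pytest.raises(ValueError):
            fgru_layer(params, np.empty((0, 2)))


class TestAttention:
    def _params(self, rng, H=4, Da=3):
        return AttentionParams(W_a=rng.standard_normal((Da, H)),
                               b_a=rng.standard_normal(Da),
                               v=rng.standard_normal(Da))

    def test_identical_states_return_that_state(self, rng):
        params = self._params(rng)
        v = rng.standard_normal(4)
        hidden = np.tile(v, (6, 1))
        np.testing.assert_allclose(attention_pool(hidden, params), v, atol=1e-10)

    def test_dominant_energy_approaches_hard_max(self, rng):
        params = self._params(rng)
        hidden = rng.standard_normal((5, 4))
        _, alpha = attention_pool(hidden, params, return_weights=True)
        sharp = AttentionParams(W_a=params.W_a, b_a=params.b_a, v=1e3 * params.v)
        ctx, alpha_sharp = attention_pool(hidden, sharp, return_weights=True)
        np.testing.assert_allclose(ctx, hidden[np.argmax(alpha)], atol=1e-8)
        assert alpha_sharp.max() > 1 - 1e-8

    def test_weights_match_softmax_oracle(self, rng):
        params = self._params(rng)
        hidden = rng.standard_normal((8, 4))
        ctx, alpha = attention_pool(hidden, params, return_weights=True)
        e = np.tanh(hidden @ params.W_a.T + params.b_a) @ params.v
        oracle = np.exp(e) / np.exp(e).sum()
        np.testing.assert_allclose(alpha, oracle, atol=1e-10)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(ctx, oracle @ hidden, atol=1e-10)


class TestAdaptiveWeighting:
    def test_initial_weights_on_simplex(self):
        for seed in range(10):
            bw = init_branch_weights(seed)
            assert np.all(bw.w > 0)
            assert bw.w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_learning_rate_is_identity(self, rng):
        bw = init_branch_weights(0)
        preds = rng.uniform(size=(6, 9))
        truths = rng.integers(0, 2, 9).astype(float)
        out = adaptive_weight_update(bw, preds, truths, lr=0.0)
        np.testing.assert_allclose(out.w, bw.w, atol=1e-15)

    def test_equal_errors_leave_weights_unchanged(self):
        bw = init_branch_weights(1)
        preds = np.tile(np.array([0.2, 0.9, 0.4, 0.4]), (6, 1))
        truths = np.array([0.0, 1.0, 1.0, 0.0])
        out = adaptive_weight_update(bw, preds, truths, lr=0.05)
        np.testing.assert_allclose(out.w, bw.w, atol=1e-12)

    def test_matches_hand_computed_exponential_ratios(self):
        w0 = np.full(6, 1 / 6)
        bw = BranchWeights(w=w0.copy(), lr=0.01)
        truths = np.array([1.0, 0.0])
        preds = np.vstack([
            [1.0, 0.0],  # perfect branch: error 0
            [0.0, 1.0],  # inverted branch: squared error 2
            [0.5, 0.5],  # neutral: squared error 0.5
            [1.0, 1.0],  # error 1
            [0.0, 0.0],  # error 1
            [0.5, 0.0],  # error 0.25
        ])
        sq = np.array([0.0, 2.0, 0.5, 1.0, 1.0, 0.25])
        expected = w0 * np.exp(-0.01 * sq)
        expected /= expected.sum()
        out = adaptive_weight_update(bw, preds, truths)
        np.testing.assert_allclose(out.w, expected, atol=1e-12)

    def test_simplex_preserved_over_many_rounds(self, rng):
        bw = init_branch_weights(3)
        truths = rng.integers(0, 2, 12).astype(float)
        for _ in range(500):
            preds = rng.uniform(size=(6, 12))
            bw = adaptive_weight_update(bw, preds, truths)
            assert np.all(bw.w > 0)
            assert abs(bw.w.sum() - 1.0) < 1e-12


@pytest.fixture(scope="module")
def tiny_fused(request):
    """Small separable fused dataset built through the real conv stage."""
    rng = np.random.default_rng(7)
    params = ConvBankParams(kernel_sizes=(3,), n_filters=2, pool_size=4, seed=0)
    vectors, labels = [], []
    for i in range(24):
        label = i % 2
        tc = rng.standard_normal((20, 6)) * (1.0 + 1.5 * label)
        sp = rng.standard_normal((12, 6)) + 0.8 * label
        f = fuse_features(tc, sp, params, subject_id=f"s{i}", label=label)
        vectors.append(f.vector)
        labels.append(label)
    return np.stack(vectors), np.array(labels), f.layout


@pytest.fixture(scope="module")
def tiny_config():
    return AFGRUConfig(hidden=12, layers=3, attn_dim=6, lr=0.01,
                       rounds=150, epochs=60, seed=0)


@pytest.fixture(scope="module")
def tiny_model(tiny_fused, tiny_config):
    vectors, labels, layout = tiny_fused
    return afgru.train(tiny_config, vectors, labels, layout)


class TestTraining:
    def test_gradients_match_numerical_differentiation(self, rng):
        cfg = AFGRUConfig(hidden=4, layers=3, attn_dim=3, rounds=5, seed=1)
        B, T, d, D = 3, 5, 6, 11
        X = rng.standard_normal((B, T, d))
        F = rng.standard_normal((B, D))
        y = np.array([1.0, 0.0, 1.0])
        w = np.abs(rng.standard_normal(6))
        w /= w.sum()
        params = afgru._init_params(cfg, (T, d), D)
        for i in range(6):  # perturb zero-init heads so all paths carry gradient
            params[f"U{i}"] = 0.3 * rng.standard_normal(cfg.hidden)
        _, grads, _ = afgru._loss_and_grads(params, X, F, y, w, cfg)
        eps = 1e-6
        for key in ("Wz0", "Wh2", "Win", "Wa", "va", "Wd", "U0", "U5", "c3", "bin"):
            v = params[key]
            flat_idx = np.unravel_index(0, v.shape)
            for idx in {flat_idx, np.unravel_index(v.size - 1, v.shape)}:
                old = v[idx]
                v[idx] = old + eps
                lp, _, _ = afgru._loss_and_grads(params, X, F, y, w, cfg)
                v[idx] = old - eps
                lm, _, _ = afgru._loss_and_grads(params, X, F, y, w, cfg)
                v[idx] = old
                num = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_fits_separable_data(self, tiny_fused, tiny_model):
        vectors, labels, _ = tiny_fused
        scores, preds = afgru.predict(tiny_model, vectors)
        assert np.mean(preds == labels) >= 0.95
        assert np.all((scores >= 0) & (scores <= 1))

    def test_constant_labels_fit_to_constant(self, tiny_fused):
        vectors, _, layout = tiny_fused
        cfg = AFGRUConfig(hidden=8, layers=2, attn_dim=4, rounds=60, seed=0)
        model = afgru.train(cfg, vectors[:10], np.ones(10), layout)
        scores, preds = afgru.predict(model, vectors[:10])
        assert model.loss_history[-1] < 0.05
        assert np.all(preds == 1)

    def test_training_is_deterministic(self, tiny_fused, tiny_config):
        vectors, labels, layout = tiny_fused
        m1 = afgru.train(tiny_config, vectors, labels, layout)
        m2 = afgru.train(tiny_config, vectors, labels, layout)
        np.testing.assert_array_equal(m1.branch_weights.w, m2.branch_weights.w)
        np.testing.assert_array_equal(m1.loss_history, m2.loss_history)

    def test_branch_weights_remain_on_simplex(self, tiny_model):
        w = tiny_model.branch_weights.w
        assert np.all(w > 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_labels_rejected(self, tiny_fused, tiny_config):
        vectors, _, layout = tiny_fused
        with pytest.raises(ValueError):
            afgru.train(tiny_config, vectors[:4], np.array([0, 1, 2, 1]), layout)


class TestForwardPredict:
    def test_forward_score_is_weighted_branch_sum(self, tiny_model, tiny_fused):
        vectors, _, _ = tiny_fused
        score, branch_scores = afgru.forward(tiny_model, vectors[0])
        assert branch_scores.shape == (6,)
        assert score == pytest.approx(float(np.dot(tiny_model.branch_weights.w,
                                                   branch_scores)), abs=1e-12)

    def test_one_hot_weights_select_single_branch(self, tiny_model, tiny_fused):
        vectors, _, _ = tiny_fused
        original = tiny_model.branch_weights.w.copy()
        try:
            for j in (0, 4):
                tiny_model.branch_weights.w = np.eye(6)[j]
                score, branch_scores = afgru.forward(tiny_model, vectors[1])
                assert score == pytest.approx(branch_scores[j], abs=1e-12)
        finally:
            tiny_model.branch_weights.w = original

    def test_threshold_rule_with_ties_positive(self, tiny_model, tiny_fused):
        vectors, _, _ = tiny_fused
        scores, preds = afgru.predict(tiny_model, vectors)
        np.testing.assert_array_equal(preds, (scores >= 0.5).astype(int))

    def test_batch_equals_per_sample_prediction(self, tiny_model, tiny_fused):
        vectors, _, _ = tiny_fused
        batch_scores, _ = afgru.predict(tiny_model, vectors[:5])
        singles = [afgru.predict(tiny_model, vectors[i:i + 1])[0][0]
                   for i in range(5)]
        np.testing.assert_allclose(batch_scores, singles, atol=1e-12)

    def test_untrained_model_rejected(self, tiny_fused, tiny_config):
        vectors, _, layout = tiny_fused
        model = afgru.AFGRUModel(
            config=tiny_config, params={}, branch_weights=init_branch_weights(0),
            seq_shape=(5, 6), layout=layout,
        )
        with pytest.raises(RuntimeError):
            afgru.predict(model, vectors[:1])


class TestSequenceView:
    def test_time_blocks_fold_back_and_spatial_broadcast(self, tiny_fused):
        vectors, _, layout = tiny_fused
        seq = to_sequences(vectors[:3], layout)
        time_dims = sum(r["shape"][0] * r["shape"][2]
                        for r in layout if r["branch"] == "time")
        spatial_dims = sum(r["stop"] - r["start"]
                           for r in layout if r["branch"] == "spatial")
        Tp = next(r["shape"][1] for r in layout if r["branch"] == "time")
        assert seq.shape == (3, Tp, time_dims + spatial_dims)
        # static covariates identical across timesteps
        np.testing.assert_array_equal(seq[:, 0, time_dims:], seq[:, -1, time_dims:])

    def test_inconsistent_layout_rejected(self, tiny_fused):
        vectors, _, layout = tiny_fused
        broken = [dict(r) for r in layout]
        for r in broken:
            if r["branch"] == "time":
                r["shape"] = [r["shape"][0], r["shape"][1] + 1, r["shape"][2]]
                break
        with pytest.raises(ValueError):
            to_sequences(vectors[:1], broken)
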