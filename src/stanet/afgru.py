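"""Attention-Fourier GRU (AFGRU) classifier.

The classifier consumes the fused STFA vector of each subject, viewed as
a short sequence: the pooled time-branch features are folded back to a
(pooled-time x channels) sequence and the spatial-branch features are
appended to every timestep as static covariates.

Architecture:

* an input-projection branch X1 that sees the full standardized fused
  vector (so the weighted ensemble always contains a near-linear model
  of the complete input);
* stacked FGRU layers (default 3).  An FGRU is a GRU whose gates see the
  real part of the DFT of the current input, ``x_fft = Real(FFT(x_t))``:

      z_t = sigmoid(W_z [h_{t-1}, x_fft] + b_z)
      r_t = sigmoid(W_r [h_{t-1}, x_fft] + b_r)
      h~  = tanh(W_h [r_t * h_{t-1}, x_fft] + b_h)
      h_t = (1 - z_t) * h_{t-1} + z_t * h~

* additive attention pooling over the last layer's hidden sequence;
* six branch taps X1..X6 (the input projection, the three stacked FGRU
  final states, the attention context, and a dense transform of the
  context), each mapped to a scalar score by an affine head;
* an adaptively weighted combination of the branches.  Training uses
  branch-level (deeply supervised) MSE: every branch prediction
  sigmoid(s_i) is regressed on the {0,1} label with weight w_i, so each
  branch is individually calibrated and a branch that carries no signal
  settles near the base rate instead of injecting arbitrary offsets
  into the ensemble.  The final prediction is the convex combination
  sum_i w_i sigmoid(s_i).

  The branch weights w live on the probability simplex and follow a
  multiplicative-weights (Hedge) rule: after every round,
  ``w_i <- w_i * exp(-lr * sum_j (p_ij - y_j)^2)`` over the samples of a
  small held-out slice of the training data, then renormalized.
  Held-out errors are used because once every branch interpolates the
  fitted samples, training errors carry no information about branch
  quality.  The number of weight-update rounds (default 500) is
  independent of the number of gradient epochs: when training stops
  early the remaining updates reuse the final model's held-out errors,
  so the weights still converge onto the branches that generalize.

Network parameters take full-batch Adam steps at the configured
learning rate.  Everything is plain numpy with hand-written
reverse-mode gradients (verified against numerical differentiation in
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "fft_real",
    "FGRUParams",
    "AttentionParams",
    "BranchWeights",
    "AFGRUConfig",
    "AFGRUModel",
    "fgru_cell_step",
    "fgru_layer",
    "attention_pool",
    "adaptive_weight_update",
    "init_branch_weights",
    "to_sequences",
    "train",
    "forward",
    "predict",
]

N_BRANCHES = 6
DEFAULT_HIDDEN = 200
DEFAULT_LAYERS = 3
DEFAULT_ATTN_DIM = 64
DEFAULT_LR = 0.01
DEFAULT_ROUNDS = 500


# ---------------------------------------------------------------------------
# FFT front end


def fft_real(x: np.ndarray) -> np.ndarray:
    """Real part of the DFT along the last axis (same length as input)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("fft_real: empty input")
    return np.fft.fft(x, axis=-1).real


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class FGRUParams:
    """One FGRU layer; each matrix maps [h_{t-1}, x_fft] to H values."""

    W_z: np.ndarray
    W_r: np.ndarray
    W_h: np.ndarray
    b_z: np.ndarray
    b_r: np.ndarray
    b_h: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_z.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_z.shape[1] - self.hidden_size


@dataclass
class AttentionParams:
    """Additive scoring: e_t = v . tanh(W_a h_t + b_a)."""

    W_a: np.ndarray
    b_a: np.ndarray
    v: np.ndarray


@dataclass
class BranchWeights:
    w: np.ndarray
    lr: float = DEFAULT_LR
    rounds: int = DEFAULT_ROUNDS


@dataclass
class AFGRUConfig:
    """Classifier configuration.

    ``rounds`` counts branch-weight updates (the adaptive-weighting
    loop); ``epochs`` counts full-batch gradient steps and defaults to
    ``rounds``.  ``val_fraction`` of each class is held out of gradient
    training to measure per-branch generalization errors for the weight
    updates (skipped for classes with fewer than 3 samples).
    """

    hidden: int = DEFAULT_HIDDEN
    layers: int = DEFAULT_LAYERS
    attn_dim: int = DEFAULT_ATTN_DIM
    lr: float = DEFAULT_LR
    rounds: int = DEFAULT_ROUNDS
    epochs: int | None = None
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs is None:
            self.epochs = self.rounds
        if min(self.hidden, self.layers, self.attn_dim, self.rounds, self.epochs) < 1:
            raise ValueError("hidden, layers, attn_dim, rounds and epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in [0, 0.5)")


@dataclass
class AFGRUModel:
    config: AFGRUConfig
    params: dict[str, np.ndarray]
    branch_weights: BranchWeights
    seq_shape: tuple[int, int]  # (T, d) after the sequence view
    layout: list[dict] | None = None
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reference single-sample operations (the contract the batch code follows)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fgru_cell_step(params: FGRUParams, h_prev: np.ndarray, x_t: np.ndarray) -> np.ndarray:
    """One FGRU step on a single sample."""
    h_prev = np.asarray(h_prev, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    if not (np.all(np.isfinite(h_prev)) and np.all(np.isfinite(x_t))):
        raise ValueError("non-finite input to fgru_cell_step")
    xf = fft_real(x_t)
    a = np.concatenate([h_prev, xf])
    z = _sigmoid(params.W_z @ a + params.b_z)
    r = _sigmoid(params.W_r @ a + params.b_r)
    ah = np.concatenate([r * h_prev, xf])
    h_til = np.tanh(params.W_h @ ah + params.b_h)
    return (1.0 - z) * h_prev + z * h_til


def fgru_layer(params: FGRUParams, sequence: np.ndarray) -> np.ndarray:
    """Run the cell over a (T, d) sequence from h_0 = 0; returns (T, H)."""
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim != 2 or sequence.shape[0] == 0:
        raise ValueError("sequence must be a non-empty T x d matrix")
    H = params.hidden_size
    h = np.zeros(H)
    out = np.empty((sequence.shape[0], H))
    for t in range(sequence.shape[0]):
        h = fgru_cell_step(params, h, sequence[t])
        out[t] = h
    return out


def attention_pool(
    hidden: np.ndarray, params: AttentionParams, return_weights: bool = False
):
    """Softmax-weighted convex combination of hidden states."""
    hidden = np.asarray(hidden, dtype=float)
    if hidden.ndim != 2 or hidden.shape[0] == 0:
        raise ValueError("hidden must be a non-empty T x H matrix")
    e = np.tanh(hidden @ params.W_a.T + params.b_a) @ params.v
    e = e - e.max()
    alpha = np.exp(e)
    alpha = alpha / alpha.sum()
    ctx = alpha @ hidden
    if return_weights:
        return ctx, alpha
    return ctx


# ---------------------------------------------------------------------------
# Adaptive branch weighting


def init_branch_weights(seed: int, lr: float = DEFAULT_LR, rounds: int = DEFAULT_ROUNDS) -> BranchWeights:
    """Gaussian draws, folded positive, normalized to the simplex."""
    rng = np.random.default_rng(seed)
    w = np.abs(rng.standard_normal(N_BRANCHES))
    w = np.where(w == 0, 1.0, w)
    return BranchWeights(w=w / w.sum(), lr=lr, rounds=rounds)


def adaptive_weight_update(
    weights: BranchWeights,
    branch_preds: np.ndarray,
    truths: np.ndarray,
    lr: float | None = None,
) -> BranchWeights:
    """One multiplicative-weights (Hedge) round on the branch weights.

    The per-sample updates ``w_i <- w_i * exp(-lr * (p_ij - y_j)^2)``
    accumulate over the evaluation samples, i.e. one round multiplies
    each weight by ``exp(-lr * sum_j (p_ij - y_j)^2)`` and renormalizes
    to the simplex.  Branches whose squared error is persistently above
    the others lose weight exponentially; equal errors (and lr = 0)
    leave the weights unchanged because the common factor cancels in
    the normalization.  Positivity is preserved by construction.
    """
    branch_preds = np.asarray(branch_preds, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if branch_preds.shape[0] != N_BRANCHES:
        raise ValueError(f"expected {N_BRANCHES} branch prediction rows")
    if not np.all(np.isfinite(branch_preds)):
        raise ValueError("branch predictions must be finite")
    if lr is None:
        lr = weights.lr
    err = np.sum((branch_preds - truths[None, :]) ** 2, axis=1)
    # subtract the common minimum before exponentiating (cancels in the
    # normalization, avoids underflow over many accumulated rounds)
    w = weights.w * np.exp(-lr * (err - err.min()))
    total = w.sum()
    if not (np.isfinite(total) and total > 0):
        raise RuntimeError("branch weights collapsed during update")
    return BranchWeights(w=w / total, lr=weights.lr, rounds=weights.rounds)


# ---------------------------------------------------------------------------
# Sequence view of the fused vector


def to_sequences(vectors: np.ndarray, layout: list[dict]) -> np.ndarray:
    """Fold fused vectors (n, D) into sequences (n, T, channels).

    Time-branch blocks (n_filters, pooled_T, pooled_N) become
    (pooled_T, n_filters * pooled_N) and are concatenated across scales;
    spatial-branch features are flattened and broadcast to every
    timestep as static covariates.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = vectors.shape[0]
    time_blocks, spatial_blocks = [], []
    Tp = None
    for rec in layout:
        block = vectors[:, rec["start"]:rec["stop"]]
        if rec["branch"] == "time":
            nf, ph, pw = rec["shape"]
            if Tp is None:
                Tp = ph
            elif ph != Tp:
                raise ValueError("time-branch blocks disagree on pooled length")
            time_blocks.append(
                block.reshape(n, nf, ph, pw).transpose(0, 2, 1, 3).reshape(n, ph, nf * pw)
            )
        else:
            spatial_blocks.append(block)
    if Tp is None:
        raise ValueError("layout has no time-branch blocks")
    seq = np.concatenate(time_blocks, axis=2)
    if spatial_blocks:
        stat = np.concatenate(spatial_blocks, axis=1)
        seq = np.concatenate([seq, np.repeat(stat[:, None, :], Tp, axis=1)], axis=2)
    return seq


# ---------------------------------------------------------------------------
# Parameter initialization

_GATES = ("z", "r", "h")


def _init_params(
    config: AFGRUConfig, seq_shape: tuple[int, int], input_dim: int
) -> dict[str, np.ndarray]:
    T, d = seq_shape
    H, Da = config.hidden, config.attn_dim
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    din = d
    for layer in range(config.layers):
        # column blocks scaled to the magnitude of their inputs: hidden
        # states are O(1); DFT coefficients of a standardized input have
        # variance ~ din/2, hence the 1/din scale on the fft block
        std_h = 1.0 / np.sqrt(2.0 * H)
        std_x = 1.0 / max(din, 1)
        for g in _GATES:
            Wh_block = std_h * rng.standard_normal((H, H))
            Wx_block = std_x * rng.standard_normal((H, din))
            params[f"W{g}{layer}"] = np.concatenate([Wh_block, Wx_block], axis=1)
            params[f"b{g}{layer}"] = np.zeros(H)
        din = H
    params["Win"] = rng.standard_normal((H, input_dim)) / np.sqrt(input_dim)
    params["bin"] = np.zeros(H)
    params["Wa"] = rng.standard_normal((Da, H)) / np.sqrt(H)
    params["ba"] = np.zeros(Da)
    params["va"] = rng.standard_normal(Da) / np.sqrt(Da)
    params["Wd"] = rng.standard_normal((H, H)) / np.sqrt(H)
    params["bd"] = np.zeros(H)
    for i in range(N_BRANCHES):
        # zero-initialized heads: every branch starts at the neutral
        # prediction 0.5 and grows only as its features earn it
        params[f"U{i}"] = np.zeros(H)
        params[f"c{i}"] = np.zeros(1)
    return params


def _layer_params(params: dict[str, np.ndarray], layer: int) -> FGRUParams:
    return FGRUParams(
        W_z=params[f"Wz{layer}"], W_r=params[f"Wr{layer}"], W_h=params[f"Wh{layer}"],
        b_z=params[f"bz{layer}"], b_r=params[f"br{layer}"], b_h=params[f"bh{layer}"],
    )


# ---------------------------------------------------------------------------
# Batched forward / backward


def _forward_batch(
    params: dict[str, np.ndarray], X: np.ndarray, F: np.ndarray, config: AFGRUConfig
) -> dict:
    """Vectorized forward pass over a batch; returns all caches.

    ``X`` is the (B, T, d) sequence view and ``F`` the (B, D) flat
    standardized fused vectors feeding the input-projection branch.
    """
    B, T, _ = X.shape
    H = config.hidden
    cache: dict = {"X": X, "layers": []}
    seq = X
    for layer in range(config.layers):
        lp = _layer_params(params, layer)
        xf = fft_real(seq)
        z_s = np.empty((B, T, H))
        r_s = np.empty((B, T, H))
        ht_s = np.empty((B, T, H))
        h_s = np.empty((B, T, H))
        h = np.zeros((B, H))
        for t in range(T):
            a = np.concatenate([h, xf[:, t]], axis=1)
            z = _sigmoid(a @ lp.W_z.T + lp.b_z)
            r = _sigmoid(a @ lp.W_r.T + lp.b_r)
            ah = np.concatenate([r * h, xf[:, t]], axis=1)
            h_til = np.tanh(ah @ lp.W_h.T + lp.b_h)
            h = (1.0 - z) * h + z * h_til
            z_s[:, t], r_s[:, t], ht_s[:, t], h_s[:, t] = z, r, h_til, h
        cache["layers"].append({"xf": xf, "z": z_s, "r": r_s, "htil": ht_s, "h": h_s})
        seq = h_s
    H3 = seq
    X1 = np.tanh(F @ params["Win"].T + params["bin"])
    E = np.tanh(np.einsum("bth,dh->btd", H3, params["Wa"]) + params["ba"])
    e = E @ params["va"]
    e = e - e.max(axis=1, keepdims=True)
    alpha = np.exp(e)
    alpha = alpha / alpha.sum(axis=1, keepdims=True)
    X5 = np.einsum("bt,bth->bh", alpha, H3)
    X6 = np.tanh(X5 @ params["Wd"].T + params["bd"])
    branches = [X1] + [cache["layers"][l]["h"][:, -1] for l in range(config.layers)]
    while len(branches) < N_BRANCHES - 2:  # pad if fewer than 3 layers
        branches.append(branches[-1])
    branches = branches[: N_BRANCHES - 2] + [X5, X6]
    scores = np.stack(
        [branches[i] @ params[f"U{i}"] + params[f"c{i}"][0] for i in range(N_BRANCHES)]
    )  # (6, B)
    cache.update(
        F=F, X1=X1, E=E, alpha=alpha, H3=H3, X5=X5, X6=X6,
        branches=branches, scores=scores,
    )
    return cache


def _loss_and_grads(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    F: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    config: AFGRUConfig,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Branch-supervised MSE loss, parameter gradients, branch predictions.

    The loss is ``sum_i w_i * mean_j (sigmoid(s_ij) - y_j)^2``: every
    branch is regressed on the label with its current ensemble weight,
    which keeps each branch individually calibrated.
    """
    B, T, d = X.shape
    H = config.hidden
    L = config.layers
    cache = _forward_batch(params, X, F, config)
    scores = cache["scores"]
    branch_preds = _sigmoid(scores)  # (6, B)
    loss = float(np.sum(w * np.mean((branch_preds - y) ** 2, axis=1)))

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    d_branch = []
    for i in range(N_BRANCHES):
        p_i = branch_preds[i]
        dsi = w[i] * (2.0 / B) * (p_i - y) * p_i * (1.0 - p_i)
        grads[f"U{i}"] += cache["branches"][i].T @ dsi
        grads[f"c{i}"] += np.array([dsi.sum()])
        d_branch.append(dsi[:, None] * params[f"U{i}"][None, :])

    dX = np.zeros_like(X)
    dH = [np.zeros((B, T, H)) for _ in range(L)]

    # X6 -> X5
    dX6 = d_branch[5]
    dpre6 = dX6 * (1.0 - cache["X6"] ** 2)
    grads["Wd"] += dpre6.T @ cache["X5"]
    grads["bd"] += dpre6.sum(axis=0)
    dX5 = d_branch[4] + dpre6 @ params["Wd"]

    # attention backward -> last layer hidden sequence
    alpha, H3, E = cache["alpha"], cache["H3"], cache["E"]
    dalpha = np.einsum("bh,bth->bt", dX5, H3)
    dH[L - 1] += alpha[:, :, None] * dX5[:, None, :]
    de = alpha * (dalpha - np.sum(dalpha * alpha, axis=1, keepdims=True))
    grads["va"] += np.einsum("btd,bt->d", E, de)
    dE = de[:, :, None] * params["va"][None, None, :]
    dpreE = dE * (1.0 - E**2)
    grads["Wa"] += np.einsum("btd,bth->dh", dpreE, H3)
    grads["ba"] += dpreE.sum(axis=(0, 1))
    dH[L - 1] += np.einsum("btd,dh->bth", dpreE, params["Wa"])

    # final-state branches X2..X4
    n_layer_taps = min(L, N_BRANCHES - 3)
    for i in range(1, n_layer_taps + 1):
        dH[i - 1][:, -1] += d_branch[i]
    # padded branches (fewer than 3 layers) tap the last layer again
    for i in range(n_layer_taps + 1, N_BRANCHES - 2):
        dH[L - 1][:, -1] += d_branch[i]

    # input projection branch X1 (full fused vector; no sequence gradient)
    dX1 = d_branch[0]
    dpre1 = dX1 * (1.0 - cache["X1"] ** 2)
    grads["Win"] += dpre1.T @ cache["F"]
    grads["bin"] += dpre1.sum(axis=0)

    # BPTT through the stacked layers, top down
    for layer in range(L - 1, -1, -1):
        lc = cache["layers"][layer]
        lp = _layer_params(params, layer)
        xf, z_s, r_s, ht_s, h_s = lc["xf"], lc["z"], lc["r"], lc["htil"], lc["h"]
        din = xf.shape[2]
        dxf = np.zeros((B, T, din))
        dh_carry = np.zeros((B, H))
        gWz, gWr, gWh = grads[f"Wz{layer}"], grads[f"Wr{layer}"], grads[f"Wh{layer}"]
        gbz, gbr, gbh = grads[f"bz{layer}"], grads[f"br{layer}"], grads[f"bh{layer}"]
        for t in range(T - 1, -1, -1):
            dh_t = dH[layer][:, t] + dh_carry
            h_prev = h_s[:, t - 1] if t > 0 else np.zeros((B, H))
            z, r, h_til = z_s[:, t], r_s[:, t], ht_s[:, t]
            a = np.concatenate([h_prev, xf[:, t]], axis=1)
            ah = np.concatenate([r * h_prev, xf[:, t]], axis=1)
            dz = dh_t * (h_til - h_prev)
            dh_til = dh_t * z
            dh_prev = dh_t * (1.0 - z)
            dph = dh_til * (1.0 - h_til**2)
            gWh += dph.T @ ah
            gbh += dph.sum(axis=0)
            dah = dph @ lp.W_h
            drh = dah[:, :H]
            dxf[:, t] += dah[:, H:]
            dr = drh * h_prev
            dh_prev += drh * r
            dpz = dz * z * (1.0 - z)
            gWz += dpz.T @ a
            gbz += dpz.sum(axis=0)
            da = dpz @ lp.W_z
            dpr = dr * r * (1.0 - r)
            gWr += dpr.T @ a
            gbr += dpr.sum(axis=0)
            da += dpr @ lp.W_r
            dh_prev += da[:, :H]
            dxf[:, t] += da[:, H:]
            dh_carry = dh_prev
        dseq = fft_real(dxf)  # DFT real-part matrix is symmetric
        if layer > 0:
            dH[layer - 1] += dseq
        else:
            dX += dseq
    return loss, grads, branch_preds


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training and inference


def _holdout_mask(labels: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Stratified held-out mask for branch-weight evaluation.

    Classes with fewer than 3 samples are never held out (the gradient
    set must retain every class).
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros(labels.shape[0], dtype=bool)
    # with a single class there is no discrimination to hold out for
    if fraction <= 0 or np.unique(labels).size < 2:
        return mask
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            continue
        n_val = max(1, int(round(fraction * idx.size)))
        mask[rng.choice(idx, size=n_val, replace=False)] = True
    return mask


def train(
    config: AFGRUConfig,
    vectors: np.ndarray,
    labels: np.ndarray,
    layout: list[dict],
) -> AFGRUModel:
    """Train the AFGRU on fused feature vectors.

    A stratified ``val_fraction`` slice of the data is held out for the
    adaptive branch weighting; the rest takes one full-batch Adam step
    per epoch on the branch-supervised MSE loss.  After every epoch one
    multiplicative weight update is applied with the held-out branch
    errors; if fewer epochs than ``rounds`` are run, the remaining
    weight updates reuse the final model's held-out errors.  Features
    are standardized with statistics of this training set (stored on
    the model and re-applied at prediction time).  Deterministic given
    the config seed.
    """
    vectors = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("labels must be in {0, 1}")
    mean = vectors.mean(axis=0)
    std = vectors.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    F = (vectors - mean) / std
    X = to_sequences(F, layout)
    seq_shape = (X.shape[1], X.shape[2])
    params = _init_params(config, seq_shape, F.shape[1])
    weights = init_branch_weights(config.seed, lr=config.lr, rounds=config.rounds)
    opt = _Adam(params, config.lr)
    model = AFGRUModel(
        config=config, params=params, branch_weights=weights,
        seq_shape=seq_shape, layout=layout, feature_mean=mean, feature_std=std,
    )
    val = _holdout_mask(labels, config.val_fraction, config.seed)
    X_fit, F_fit, y_fit = X[~val], F[~val], labels[~val]
    has_val = bool(val.any())
    val_preds, val_truth = None, labels[val]
    for _ in range(config.epochs):
        loss, grads, fit_preds = _loss_and_grads(params, X_fit, F_fit, y_fit, weights.w, config)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged (loss={loss})")
        opt.step(params, grads)
        if has_val:
            val_cache = _forward_batch(params, X[val], F[val], config)
            val_preds = _sigmoid(val_cache["scores"])
            weights = adaptive_weight_update(weights, val_preds, val_truth)
        else:
            weights = adaptive_weight_update(weights, fit_preds, y_fit)
        model.loss_history.append(loss)
    # remaining weight-update rounds with the final held-out errors
    if has_val and val_preds is not None:
        for _ in range(max(0, config.rounds - config.epochs)):
            weights = adaptive_weight_update(weights, val_preds, val_truth)
    model.branch_weights = weights
    model.trained = True
    return model


def forward(model: AFGRUModel, vector: np.ndarray) -> tuple[float, np.ndarray]:
    """Raw weighted score and the six branch scores for one fused vector."""
    vector = np.asarray(vector, dtype=float).ravel()
    if model.feature_mean is not None:
        vector = (vector - model.feature_mean) / model.feature_std
    F = vector[None, :]
    X = to_sequences(F, model.layout)
    if (X.shape[1], X.shape[2]) != model.seq_shape:
        raise ValueError("fused vector layout does not match the model")
    cache = _forward_batch(model.params, X, F, model.config)
    scores = cache["scores"][:, 0]
    return float(model.branch_weights.w @ scores), scores


def predict(model: AFGRUModel, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probability-like scores in [0, 1] and hard classes (ties -> 1).

    The score is the branch-weighted convex combination of the branch
    probabilities ``sum_i w_i sigmoid(s_i)``, which lies in [0, 1] by
    construction; class 1 is predicted for scores >= 0.5.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained")
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    F = (vectors - model.feature_mean) / model.feature_std
    X = to_sequences(F, model.layout)
    if (X.shape[1], X.shape[2]) != model.seq_shape:
        raise ValueError("fused vector layout does not match the model")
    cache = _forward_batch(model.params, X, F, model.config)
    p = model.branch_weights.w @ _sigmoid(cache["scores"])
    return p, (p >= 0.5).astype(int)
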