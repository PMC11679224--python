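"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from stanet.afgru import FGRUParams


def _dft_oracle(x):
    """Direct O(n^2) DFT, real part."""
    n = len(x)
    k = np.arange(n)
    return np.array([np.sum(x * np.cos(2 * np.pi * kk * k / n)) for kk in k])


def _random_cell(rng, H, d, scale=0.5):
    return FGRUParams(
        W_z=scale * rng.standard_normal((H, H + d)),
        W_r=scale * rng.standard_normal((H, H + d)),
        W_h=scale * rng.standard_normal((H, H + d)),
        b_z=scale * rng.standard_normal(H),
        b_r=scale * rng.standard_normal(H),
        b_h=scale * rng.standard_normal(H),
    )


def _cell_transliteration(params, h_prev, x_t):
    """Scalar-loop evaluation of the gate equations (independent oracle)."""
    H = params.hidden_size
    d = len(x_t)
    xf = np.zeros(d)
    for k in range(d):
        for n in range(d):
            xf[k] += x_t[n] * np.cos(2 * np.pi * k * n / d)
    a = np.concatenate([h_prev, xf])
    z = np.zeros(H)
    r = np.zeros(H)
    for i in range(H):
        sz = params.b_z[i]
        sr = params.b_r[i]
        for j in range(H + d):
            sz += params.W_z[i, j] * a[j]
            sr += params.W_r[i, j] * a[j]
        z[i] = 1.0 / (1.0 + np.exp(-sz))
        r[i] = 1.0 / (1.0 + np.exp(-sr))
    ah = np.concatenate([r * h_prev, xf])
    h_til = np.zeros(H)
    for i in range(H):
        sh = params.b_h[i]
        for j in range(H + d):
            sh += params.W_h[i, j] * ah[j]
        h_til[i] = np.tanh(sh)
    return (1.0 - z) * h_prev + z * h_til
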