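"""Numba kernel for the collapsed Gibbs sweep.

The full conditional for token i (word w in document d), with that token's
current assignment removed from all counts (the "exclude" counts n^-i), is

    P(z_i = k | z_-i, w)  propto  (n_dk^-i + alpha) * (n_kw^-i + beta) / (n_k^-i + V*beta).

Each sweep is seeded explicitly via numba's internal RNG so a sweep is a pure
function of (state, seed); callers derive per-sweep seeds deterministically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK64 = (1 << 64) - 1


def mix_seed(base_seed: int, step: int) -> int:
    """splitmix64-style mix of (base_seed, step) into a seed in [0, 2^31)."""
    x = (base_seed * 0x9E3779B97F4A7C15 + (step + 1) * 0xBF58476D1CE4E5B9) & _MASK64
    x ^= x >> 30
    x = (x * 0xBF58476D1CE4E5B9) & _MASK64
    x ^= x >> 27
    x = (x * 0x94D049BB133111EB) & _MASK64
    x ^= x >> 31
    return int(x % (1 << 31))


@njit(cache=True)
def gibbs_sweep_kernel(w, d, z, n_dk, n_kw, n_k, alpha, beta, seed):  # pragma: no cover
    np.random.seed(seed)
    n_topics = n_k.shape[0]
    vbeta = n_kw.shape[1] * beta
    p = np.empty(n_topics, dtype=np.float64)
    for i in range(w.shape[0]):
        wi = w[i]
        di = d[i]
        k = z[i]
        n_dk[di, k] -= 1
        n_kw[k, wi] -= 1
        n_k[k] -= 1
        total = 0.0
        for t in range(n_topics):
            total += (n_dk[di, t] + alpha) * (n_kw[t, wi] + beta) / (n_k[t] + vbeta)
            p[t] = total
        u = np.random.random() * total
        k_new = 0
        while p[k_new] < u:
            k_new += 1
        z[i] = k_new
        n_dk[di, k_new] += 1
        n_kw[k_new, wi] += 1
        n_k[k_new] += 1
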