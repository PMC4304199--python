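"""Independent oracles used by the tests.

Everything here is computed by brute force (explicit loops, exhaustive
enumeration, sequential Polya-urn products) without touching the package's
own inference code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import gammaln, logsumexp


def exact_log_joint(
    z: tuple[int, ...],
    w: np.ndarray,
    d: np.ndarray,
    T: int,
    V: int,
    alpha: float,
    beta: float,
    D: int,
) -> float:
    """log p(w, z) of collapsed LDA via explicit count accumulation."""
    n_dk = np.zeros((D, T))
    n_kw = np.zeros((T, V))
    n_k = np.zeros(T)
    n_d = np.zeros(D)
    for zi, wi, di in zip(z, w, d):
        n_dk[di, zi] += 1
        n_kw[zi, wi] += 1
        n_k[zi] += 1
        n_d[di] += 1
    val = 0.0
    for dd in range(D):
        val += gammaln(T * alpha) - gammaln(n_d[dd] + T * alpha)
        val += gammaln(n_dk[dd] + alpha).sum() - T * gammaln(alpha)
    for k in range(T):
        val += gammaln(V * beta) - gammaln(n_k[k] + V * beta)
        val += gammaln(n_kw[k] + beta).sum() - V * gammaln(beta)
    return float(val)


def enumerate_posterior(
    w: np.ndarray, d: np.ndarray, T: int, V: int, alpha: float, beta: float, D: int
) -> tuple[list[tuple[int, ...]], np.ndarray, float]:
    """All assignment configurations with exact posterior p(z | w) and the
    exact log marginal log p(w)."""
    configs = list(itertools.product(range(T), repeat=len(w)))
    lj = np.array([exact_log_joint(z, w, d, T, V, alpha, beta, D) for z in configs])
    log_marginal = float(logsumexp(lj))
    return configs, np.exp(lj - log_marginal), log_marginal


def sequential_log_p_words(
    z: np.ndarray, w: np.ndarray, T: int, V: int, beta: float
) -> float:
    """log p(w | z) as a sequential Polya-urn product: the i-th word's
    probability given all previous (word, topic) pairs."""
    n_kw = np.zeros((T, V))
    n_k = np.zeros(T)
    val = 0.0
    for zi, wi in zip(z, w):
        val += np.log((n_kw[zi, wi] + beta) / (n_k[zi] + V * beta))
        n_kw[zi, wi] += 1
        n_k[zi] += 1
    return float(val)
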