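"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The model: each document d draws a topic mixture theta_d ~ Dirichlet(alpha),
each topic k a word distribution phi_k ~ Dirichlet(beta); every token draws a
topic z ~ theta_d and a word w ~ phi_z. Inference integrates theta and phi out
and resamples each token's topic assignment from its full conditional
(collapsed Gibbs). Point estimates are the usual smoothed count ratios

    theta_dk = (n_dk + alpha) / (n_d + T*alpha)
    phi_kw   = (n_kw + beta)  / (n_k + V*beta)

and the marginal data likelihood is estimated by the harmonic mean of
p(w | z) over retained post-burn-in samples, where

    log p(w | z) = sum_k [ logG(V*beta) - V*logG(beta)
                           + sum_w logG(n_kw + beta) - logG(n_k + V*beta) ].

Model-order selection ranks candidate topic counts by the posterior-mean
joint log p(w, z) (the conditional above plus the document-side
Dirichlet-multinomial term), not by the harmonic-mean estimate: the harmonic
mean is a valid but high-variance estimator of p(w) whose overestimation
bias grows with model size, so its argmax degenerates to the largest T on
corpora with long documents over a small vocabulary. The joint score carries
the document-side Occam penalty and peaks at the supported model order.

Defaults follow the sparse-prior setting alpha = 0.1, beta = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from ._gibbs import gibbs_sweep_kernel, mix_seed
from .corpus import BowCorpus, Vocabulary

__all__ = [
    "Hyperparams",
    "LdaState",
    "TopicModel",
    "ModelSelectionResult",
    "init_assignments",
    "conditional_distribution",
    "gibbs_sweep",
    "estimate_theta",
    "estimate_phi",
    "log_p_words_given_z",
    "estimate_log_likelihood",
    "fit",
    "select_num_topics",
    "top_words",
]


@dataclass(frozen=True)
class Hyperparams:
    """Sampler configuration. ``n_topics`` is T; ``alpha`` and ``beta`` are the
    symmetric Dirichlet concentrations for document-topic and topic-word
    distributions; samples are retained every ``sample_lag`` sweeps after
    ``burn_in`` of ``n_iter`` total sweeps."""

    n_topics: int
    alpha: float = 0.1
    beta: float = 0.01
    n_iter: int = 1000
    burn_in: int = 500
    sample_lag: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0 < self.burn_in < self.n_iter:
            raise ValueError("require 0 < burn_in < n_iter")
        if self.sample_lag < 1:
            raise ValueError("sample_lag must be >= 1")


@dataclass
class LdaState:
    """Mutable Gibbs state: flattened token arrays, per-token assignments z,
    and the sufficient-statistic count matrices kept consistent with z."""

    w: np.ndarray          # token word indices, concatenated over documents
    d: np.ndarray          # token document indices, aligned with w
    doc_offsets: np.ndarray  # start offset of each document in w/d
    z: np.ndarray          # per-token topic assignment
    n_dk: np.ndarray       # D x T document-topic counts
    n_kw: np.ndarray       # T x V topic-word counts
    n_k: np.ndarray        # per-topic token totals
    n_d: np.ndarray        # per-document lengths
    n_words: int           # V
    base_seed: int
    sweeps_done: int = 0

    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Recompute (n_dk, n_kw, n_k) from z alone (consistency oracle)."""
        T = self.n_k.shape[0]
        n_dk = np.zeros_like(self.n_dk)
        n_kw = np.zeros_like(self.n_kw)
        np.add.at(n_dk, (self.d, self.z), 1)
        np.add.at(n_kw, (self.z, self.w), 1)
        return n_dk, n_kw, n_kw.sum(axis=1)

    def copy(self) -> "LdaState":
        return LdaState(
            self.w, self.d, self.doc_offsets, self.z.copy(),
            self.n_dk.copy(), self.n_kw.copy(), self.n_k.copy(), self.n_d,
            self.n_words, self.base_seed, self.sweeps_done,
        )


@dataclass
class TopicModel:
    """Fitted model: row-stochastic theta (D x T) and phi (T x V)."""

    theta: np.ndarray
    phi: np.ndarray
    hyper: Hyperparams
    vocab: Vocabulary
    doc_ids: list[str]
    log_likelihood: float = float("nan")   # harmonic-mean estimate of log p(w)
    joint_score: float = float("nan")      # posterior-mean joint log p(w, z)
    ll_samples: list[float] = field(default_factory=list)


@dataclass
class ModelSelectionResult:
    grid: list[int]
    log_likelihoods: list[float]
    chosen_T: int
    seeds: dict[int, int]
    models: dict[int, TopicModel] = field(default_factory=dict)


def init_assignments(corpus: BowCorpus, hyper: Hyperparams) -> LdaState:
    """Assign every token a uniform-random topic from the seeded RNG and build
    the count matrices."""
    if corpus.n_docs == 0:
        raise ValueError("corpus is empty")
    T = hyper.n_topics
    V = len(corpus.vocabulary)
    w = np.concatenate([d.astype(np.int32) for d in corpus.docs]) if corpus.total_tokens \
        else np.empty(0, dtype=np.int32)
    d = np.concatenate(
        [np.full(len(doc), i, dtype=np.int32) for i, doc in enumerate(corpus.docs)]
    ) if corpus.total_tokens else np.empty(0, dtype=np.int32)
    lengths = corpus.doc_lengths
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(np.int64)

    rng = np.random.default_rng(hyper.seed)
    z = rng.integers(0, T, size=len(w)).astype(np.int32)
    n_dk = np.zeros((corpus.n_docs, T), dtype=np.int64)
    n_kw = np.zeros((T, V), dtype=np.int64)
    np.add.at(n_dk, (d, z), 1)
    np.add.at(n_kw, (z, w), 1)
    return LdaState(w, d, offsets, z, n_dk, n_kw, n_kw.sum(axis=1), lengths, V,
                    base_seed=hyper.seed)


def conditional_distribution(
    state: LdaState, doc: int, token_pos: int, hyper: Hyperparams
) -> np.ndarray:
    """Full-conditional topic distribution for one token (counts are excluded
    and restored; the state is left unchanged)."""
    i = int(state.doc_offsets[doc]) + token_pos
    wi, di, k = int(state.w[i]), int(state.d[i]), int(state.z[i])
    state.n_dk[di, k] -= 1
    state.n_kw[k, wi] -= 1
    state.n_k[k] -= 1
    p = (
        (state.n_dk[di] + hyper.alpha)
        * (state.n_kw[:, wi] + hyper.beta)
        / (state.n_k + state.n_words * hyper.beta)
    )
    state.n_dk[di, k] += 1
    state.n_kw[k, wi] += 1
    state.n_k[k] += 1
    return p / p.sum()


def gibbs_sweep(state: LdaState, hyper: Hyperparams) -> LdaState:
    """Resample every token once from its full conditional (in place).

    The sweep's randomness is derived deterministically from the state's base
    seed and sweep counter, so trajectories are reproducible sweep by sweep.
    """
    if len(state.w):
        gibbs_sweep_kernel(
            state.w, state.d, state.z, state.n_dk, state.n_kw, state.n_k,
            hyper.alpha, hyper.beta, mix_seed(state.base_seed, state.sweeps_done),
        )
    state.sweeps_done += 1
    return state


def estimate_theta(state: LdaState, hyper: Hyperparams) -> np.ndarray:
    theta = (state.n_dk + hyper.alpha) / (
        state.n_d[:, None] + hyper.n_topics * hyper.alpha
    )
    return theta


def estimate_phi(state: LdaState, hyper: Hyperparams) -> np.ndarray:
    phi = (state.n_kw + hyper.beta) / (
        state.n_k[:, None] + state.n_words * hyper.beta
    )
    return phi


def log_p_words_given_z(state: LdaState, hyper: Hyperparams) -> float:
    """Closed-form log p(w | z) with phi integrated out (per-topic Dirichlet-
    multinomial), the quantity whose harmonic mean estimates the marginal."""
    V = state.n_words
    beta = hyper.beta
    val = hyper.n_topics * (gammaln(V * beta) - V * gammaln(beta))
    val += gammaln(state.n_kw + beta).sum()
    val -= gammaln(state.n_k + V * beta).sum()
    return float(val)


def log_p_z(state: LdaState, hyper: Hyperparams) -> float:
    """Closed-form log p(z) with theta integrated out (per-document
    Dirichlet-multinomial)."""
    a, T = hyper.alpha, hyper.n_topics
    val = state.n_d.shape[0] * gammaln(T * a) - gammaln(state.n_d + T * a).sum()
    val += gammaln(state.n_dk + a).sum() - state.n_dk.size * gammaln(a)
    return float(val)


def log_p_joint(state: LdaState, hyper: Hyperparams) -> float:
    """Full joint log p(w, z): the model-selection score."""
    return log_p_words_given_z(state, hyper) + log_p_z(state, hyper)


def estimate_log_likelihood(samples: Sequence[float]) -> float:
    """Harmonic-mean estimate of log p(w), computed in log space:
    log HM = log n - logsumexp(-samples)."""
    if len(samples) == 0:
        raise ValueError("need at least one post-burn-in sample")
    s = np.asarray(samples, dtype=np.float64)
    return float(np.log(len(s)) - logsumexp(-s))


def fit(corpus: BowCorpus, hyper: Hyperparams, average: bool = False) -> TopicModel:
    """Run the collapsed Gibbs sampler and return point estimates.

    theta/phi come from the final sweep by default; with ``average=True`` they
    are the mean over retained post-burn-in samples instead.
    """
    state = init_assignments(corpus, hyper)
    ll_samples: list[float] = []
    joint_samples: list[float] = []
    theta_acc = phi_acc = None
    n_ret = 0
    for sweep in range(hyper.n_iter):
        gibbs_sweep(state, hyper)
        if sweep + 1 > hyper.burn_in and (sweep + 1 - hyper.burn_in) % hyper.sample_lag == 0:
            ll_samples.append(log_p_words_given_z(state, hyper))
            joint_samples.append(ll_samples[-1] + log_p_z(state, hyper))
            if average:
                th, ph = estimate_theta(state, hyper), estimate_phi(state, hyper)
                theta_acc = th if theta_acc is None else theta_acc + th
                phi_acc = ph if phi_acc is None else phi_acc + ph
                n_ret += 1
    if average and n_ret:
        theta, phi = theta_acc / n_ret, phi_acc / n_ret
    else:
        theta, phi = estimate_theta(state, hyper), estimate_phi(state, hyper)
    ll = estimate_log_likelihood(ll_samples) if ll_samples else float("nan")
    joint = float(np.mean(joint_samples)) if joint_samples else float("nan")
    return TopicModel(theta, phi, hyper, corpus.vocabulary, list(corpus.doc_ids),
                      ll, joint, ll_samples)


def select_num_topics(
    corpus: BowCorpus,
    grid: Sequence[int],
    hyper_template: Hyperparams,
    keep_models: bool = False,
) -> ModelSelectionResult:
    """Fit one model per candidate T (fresh deterministic seed per value) and
    choose the T with the highest posterior-mean joint log-likelihood
    (ties: lowest T)."""
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    if any(t < 1 for t in grid):
        raise ValueError("all grid values must be >= 1")
    lls: list[float] = []
    seeds: dict[int, int] = {}
    models: dict[int, TopicModel] = {}
    for T in grid:
        seed_T = mix_seed(hyper_template.seed, T)
        seeds[T] = seed_T
        model = fit(corpus, replace(hyper_template, n_topics=T, seed=seed_T))
        lls.append(model.joint_score)
        if keep_models:
            models[T] = model
    chosen = int(grid[int(np.argmax(lls))])
    return ModelSelectionResult(list(grid), lls, chosen, seeds, models)


def top_words(model: TopicModel, n: int = 15) -> list[list[str]]:
    """Per topic, the n highest-probability words (ties broken by vocabulary
    order, i.e. lowest index first)."""
    V = model.phi.shape[1]
    if n > V:
        raise ValueError(f"n={n} exceeds vocabulary size {V}")
    out: list[list[str]] = []
    idx = np.arange(V)
    for row in model.phi:
        order = np.lexsort((idx, -row))
        out.append([model.vocab[i] for i in order[:n]])
    return out
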