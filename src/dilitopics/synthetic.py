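"""Synthetic corpus generation with a planted, seed-enriched topic.

Emulates the structure of a per-drug narrative corpus: each document is drawn
from an LDA generative process (symmetric Dirichlet topic-word and
document-topic priors), a designated subset of "seed" documents receives an
additive probability boost on one planted topic, and every document gets a
paired evidence section whose probability of containing an evidence-lexicon
phrase depends on whether the document is truly planted-positive.

Defaults mirror the target corpus regime: 100 documents of 200-400 content
words over a 200-word vocabulary, 5 topics, 26 seed documents, and a boost
putting the planted topic's mean probability near 0.5 in seed documents
against a 0.2 background. Ground truth (true theta, true phi, seed ids,
positive ids) is carried alongside the rendered text so every downstream
stage can be scored exactly.

Vocabulary words are synthetic letter strings ("waa", "wab", ...); the last few double as
the evidence lexicon so verification runs without English text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import RawDocument, load_stopwords

__all__ = [
    "SyntheticCorpusSpec",
    "SyntheticCorpus",
    "generate_topics",
    "generate_corpus",
    "truth_report",
    "write_truth",
]

N_LEXICON_WORDS = 6


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Generator configuration; a corpus is a pure function of (spec, seed)."""

    n_topics_true: int = 5
    vocab_size: int = 200
    n_docs: int = 100
    doc_len_range: tuple[int, int] = (200, 400)
    beta_true: float = 0.05     # topic-word concentration: sparse, distinct topics
    alpha_true: float = 0.1     # background document-topic concentration: sparse mixtures
    planted_topic: int = 0
    seed_doc_count: int = 26
    seed_boost: float = 0.5     # additive mass on the planted topic for seed docs
    positive_threshold: float = 0.3  # true theta above this => planted-positive
    evidence_p_pos: float = 0.9
    evidence_p_neg: float = 0.1
    evidence_len: int = 40      # filler words per evidence section
    stopword_rate: float = 0.0  # chance of injecting a stop-word after each token
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.doc_len_range
        if not (0 < lo <= hi):
            raise ValueError("doc_len_range must satisfy 0 < min <= max")
        if self.vocab_size < self.n_topics_true:
            raise ValueError("vocab_size must be >= n_topics_true")
        if self.vocab_size <= N_LEXICON_WORDS:
            raise ValueError("vocab_size too small to reserve lexicon words")
        if not 0 <= self.evidence_p_neg < self.evidence_p_pos <= 1:
            raise ValueError("require 0 <= evidence_p_neg < evidence_p_pos <= 1")
        if not 0 <= self.planted_topic < self.n_topics_true:
            raise ValueError("planted_topic out of range")
        if not 0 < self.seed_doc_count <= self.n_docs:
            raise ValueError("seed_doc_count out of range")
        if self.seed_boost < 0 or not 0 <= self.stopword_rate < 1:
            raise ValueError("seed_boost must be >= 0 and stopword_rate in [0, 1)")


@dataclass
class SyntheticCorpus:
    """Generated corpus plus full ground truth."""

    spec: SyntheticCorpusSpec
    raw_docs: list[RawDocument]       # section "hepatotoxicity"
    evidence_docs: list[RawDocument]  # section "outcome_and_management"
    true_phi: np.ndarray
    true_theta: np.ndarray
    seed_doc_ids: list[str]
    positive_doc_ids: list[str]
    lexicon_terms: list[str]
    evidence_has_term: dict[str, bool] = field(default_factory=dict)

    @property
    def doc_ids(self) -> list[str]:
        return [d.drug_id for d in self.raw_docs]


def _vocab_words(V: int) -> list[str]:
    # letter-only tokens (digit-bearing tokens would be dropped by tokenize)
    width = 1
    while 26 ** width < V:
        width += 1
    words = []
    for i in range(V):
        s, x = "", i
        for _ in range(width):
            s = chr(ord("a") + x % 26) + s
            x //= 26
        words.append("w" + s)
    return words


def generate_topics(spec: SyntheticCorpusSpec) -> np.ndarray:
    """True topic-word matrix: one symmetric-Dirichlet(beta_true) draw per topic."""
    rng = np.random.default_rng(spec.seed)
    return rng.dirichlet([spec.beta_true] * spec.vocab_size, size=spec.n_topics_true)


def generate_corpus(spec: SyntheticCorpusSpec) -> SyntheticCorpus:
    """Draw a full synthetic corpus (text + paired evidence sections + truth)."""
    rng = np.random.default_rng(spec.seed)
    T, V, D = spec.n_topics_true, spec.vocab_size, spec.n_docs
    words = _vocab_words(V)
    lexicon = words[V - N_LEXICON_WORDS:]
    # same stream order as generate_topics, so true_phi matches it exactly
    true_phi = rng.dirichlet([spec.beta_true] * V, size=T)

    doc_ids = [f"drug{i:04d}" for i in range(D)]
    seed_rows = np.sort(rng.choice(D, size=spec.seed_doc_count, replace=False))
    is_seed = np.zeros(D, dtype=bool)
    is_seed[seed_rows] = True

    true_theta = rng.dirichlet([spec.alpha_true] * T, size=D)
    true_theta[is_seed, spec.planted_topic] += spec.seed_boost
    true_theta /= true_theta.sum(axis=1, keepdims=True)

    lo, hi = spec.doc_len_range
    lengths = rng.integers(lo, hi + 1, size=D)
    stop_list = sorted(load_stopwords()) if spec.stopword_rate > 0 else []

    raw_docs: list[RawDocument] = []
    evidence_docs: list[RawDocument] = []
    has_term: dict[str, bool] = {}
    positives: list[str] = []
    filler_pool = V - N_LEXICON_WORDS  # evidence filler avoids lexicon words
    for i, drug in enumerate(doc_ids):
        z = rng.choice(T, size=lengths[i], p=true_theta[i])
        w = np.array(
            [rng.choice(V, p=true_phi[k]) for k in z]
        ) if lengths[i] else np.empty(0, dtype=int)
        toks = [words[j] for j in w]
        if spec.stopword_rate > 0:
            inject = rng.random(len(toks)) < spec.stopword_rate
            picks = rng.integers(0, len(stop_list), size=len(toks))
            merged: list[str] = []
            for t, inj, p in zip(toks, inject, picks):
                merged.append(t)
                if inj:
                    merged.append(stop_list[p])
            toks = merged
        raw_docs.append(RawDocument(drug, "hepatotoxicity", " ".join(toks)))

        positive = true_theta[i, spec.planted_topic] > spec.positive_threshold
        if positive:
            positives.append(drug)
        p_term = spec.evidence_p_pos if positive else spec.evidence_p_neg
        ev = [words[j] for j in rng.integers(0, filler_pool, size=spec.evidence_len)]
        emit = bool(rng.random() < p_term)
        if emit:
            term = lexicon[rng.integers(0, len(lexicon))]
            ev.insert(int(rng.integers(0, len(ev) + 1)), term)
        has_term[drug] = emit
        evidence_docs.append(RawDocument(drug, "outcome_and_management", " ".join(ev)))

    return SyntheticCorpus(
        spec, raw_docs, evidence_docs, true_phi, true_theta,
        [doc_ids[r] for r in seed_rows], positives, list(lexicon), has_term,
    )


def cosine_to_true_topics(fitted_phi: np.ndarray, corpus: SyntheticCorpus,
                          vocab_words: Sequence[str]) -> np.ndarray:
    """Cosine similarity between fitted and true topics on the shared vocabulary.

    ``vocab_words`` is the fitted model's vocabulary (a subset of the
    generator's words, e.g. after preprocessing); true phi is restricted to
    those columns. Returns a (fitted x true) similarity matrix.
    """
    pos = {w: i for i, w in enumerate(_vocab_words(corpus.spec.vocab_size))}
    cols = [pos[w] for w in vocab_words]
    tp = corpus.true_phi[:, cols]
    num = fitted_phi @ tp.T
    den = (
        np.linalg.norm(fitted_phi, axis=1)[:, None]
        * np.linalg.norm(tp, axis=1)[None, :]
    )
    return num / den


def truth_report(corpus: SyntheticCorpus) -> dict[str, pd.DataFrame]:
    """Ground-truth tables for test-harness consumption."""
    spec = corpus.spec
    topics = [f"topic_{k}" for k in range(spec.n_topics_true)]
    words = _vocab_words(spec.vocab_size)
    theta = pd.DataFrame(corpus.true_theta, index=corpus.doc_ids, columns=topics)
    theta.index.name = "drug_id"
    phi = pd.DataFrame(corpus.true_phi, index=topics, columns=words)
    phi.index.name = "topic"
    labels = pd.DataFrame(
        {
            "is_seed": [d in set(corpus.seed_doc_ids) for d in corpus.doc_ids],
            "is_positive": [d in set(corpus.positive_doc_ids) for d in corpus.doc_ids],
            "evidence_has_term": [corpus.evidence_has_term[d] for d in corpus.doc_ids],
        },
        index=pd.Index(corpus.doc_ids, name="drug_id"),
    )
    return {"true_theta": theta, "true_phi": phi, "labels": labels}


def write_truth(corpus: SyntheticCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write the truth tables as TSV and return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, frame in truth_report(corpus).items():
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t")
        paths[name] = p
    return paths
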