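"""Seed-guided topic labeling and drug flagging.

Given a fitted document-topic matrix theta and a seed set of drugs with
established causality for the outcome of interest (here: acute liver failure),
the seed topic is the topic j maximizing the mean of theta[:, j] over the seed
documents. Its enrichment over the baseline (the mean over the remaining
topics) is tested by permutation, and further drugs are flagged when the seed
topic ranks among their top k topics (k = 3 by default).

All argmax/ranking ties break toward the lowest topic index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SeedTopicResult",
    "TopicRanking",
    "check_seed_set",
    "mean_topic_distribution",
    "identify_seed_topic",
    "permutation_test_seed_topic",
    "rank_topics",
    "classify_top_k",
    "rank_distribution",
    "unique_top_words",
]


@dataclass
class SeedTopicResult:
    mean_theta: np.ndarray
    seed_topic: int
    seed_topic_mean: float
    baseline_mean: float
    p_value: float | None = None


@dataclass
class TopicRanking:
    """Descending ordering of one document's topics (rank 1 = most probable)."""

    drug_id: str
    order: np.ndarray        # topic indices, most probable first
    probabilities: np.ndarray  # aligned with order

    def rank_of(self, topic: int) -> int:
        return int(np.where(self.order == topic)[0][0]) + 1


def check_seed_set(doc_ids: Sequence[str], seeds: Sequence[str]) -> np.ndarray:
    """Validate a seed drug list against the corpus and return row indices."""
    if len(seeds) == 0:
        raise ValueError("seed set is empty")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seed set contains duplicates")
    pos = {d: i for i, d in enumerate(doc_ids)}
    missing = [s for s in seeds if s not in pos]
    if missing:
        raise KeyError(f"seed drug(s) not in corpus: {missing}")
    return np.array([pos[s] for s in seeds], dtype=np.int64)


def mean_topic_distribution(
    theta: np.ndarray, doc_ids: Sequence[str], seeds: Sequence[str]
) -> np.ndarray:
    """Arithmetic mean of the seed documents' theta rows."""
    rows = check_seed_set(doc_ids, seeds)
    return theta[rows].mean(axis=0)


def identify_seed_topic(
    theta: np.ndarray, doc_ids: Sequence[str], seeds: Sequence[str]
) -> SeedTopicResult:
    """Seed topic = argmax of the seed-mean topic distribution; baseline =
    mean of the remaining entries, equivalently (1 - max) / (T - 1) when the
    mean vector is normalized."""
    mean = mean_topic_distribution(theta, doc_ids, seeds)
    T = mean.shape[0]
    if T < 2:
        raise ValueError("need at least 2 topics to define a baseline")
    j = int(np.argmax(mean))  # np.argmax returns the lowest index on ties
    baseline = float(np.delete(mean, j).mean())
    return SeedTopicResult(mean, j, float(mean[j]), baseline)


def permutation_test_seed_topic(
    theta: np.ndarray,
    doc_ids: Sequence[str],
    seeds: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for seed-topic enrichment.

    Statistic: max over topics of the seed-mean. Null: topic labels carry no
    drug-specific information, emulated by independently permuting each seed
    document's theta row. p uses add-one smoothing, so p in (0, 1].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rows = check_seed_set(doc_ids, seeds)
    sub = theta[rows]
    observed = float(sub.mean(axis=0).max())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = np.stack([rng.permutation(row) for row in sub])
        if perm.mean(axis=0).max() >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def rank_topics(theta_row: np.ndarray, drug_id: str = "") -> TopicRanking:
    """Descending sort of one theta row (ties: lowest topic index first)."""
    row = np.asarray(theta_row, dtype=np.float64)
    idx = np.arange(row.shape[0])
    order = np.lexsort((idx, -row))
    return TopicRanking(drug_id, order, row[order])


def classify_top_k(
    theta: np.ndarray,
    doc_ids: Sequence[str],
    topic: int,
    k: int = 3,
    exclude: Sequence[str] = (),
) -> list[str]:
    """Drugs (minus ``exclude``) whose rank of ``topic`` is <= k, sorted by
    that topic's probability, descending."""
    T = theta.shape[1]
    if not 1 <= k <= T:
        raise ValueError(f"k={k} out of range [1, {T}]")
    excl = set(exclude)
    flagged: list[tuple[float, str]] = []
    for i, drug in enumerate(doc_ids):
        if drug in excl:
            continue
        if rank_topics(theta[i], drug).rank_of(topic) <= k:
            flagged.append((float(theta[i, topic]), drug))
    flagged.sort(key=lambda t: (-t[0], t[1]))
    return [drug for _, drug in flagged]


def rank_distribution(
    theta: np.ndarray, doc_ids: Sequence[str], topic: int, seeds: Sequence[str]
) -> dict[str, int]:
    """Counts of seed drugs whose rank of ``topic`` is 1, 2, 3, 4 or deeper."""
    rows = check_seed_set(doc_ids, seeds)
    counts = {"1": 0, "2": 0, "3": 0, "4": 0, ">4": 0}
    for i in rows:
        r = rank_topics(theta[i]).rank_of(topic)
        counts[str(r) if r <= 4 else ">4"] += 1
    return counts


def unique_top_words(
    top_lists: Sequence[Sequence[str]], topic: int
) -> set[str]:
    """Words in one topic's top-word list absent from every other topic's
    list (order within the list is not considered)."""
    others: set[str] = set()
    for j, words in enumerate(top_lists):
        if j != topic:
            others.update(words)
    return set(top_lists[topic]) - others
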