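"""Corpus ingestion and bag-of-words preprocessing.

Raw per-drug documents (one free-text record per drug and section) are
tokenized and reduced to a bag-of-words corpus in three filtering stages:

1. digit-bearing tokens are dropped during tokenization,
2. stop-words (a bundled, overridable English list) are removed,
3. words whose document frequency exceeds a cutoff (default: strictly
   greater than 0.8) are removed, together with an explicit extra-removal
   list for hand-picked ubiquitous words.

No stemming or lemmatization is applied. Documents that become empty after
filtering are retained (with zero length) so row alignment with external
tables is preserved; their ids are reported on the corpus object.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "RawDocument",
    "Vocabulary",
    "BowCorpus",
    "tokenize",
    "document_frequency",
    "preprocess",
    "read_corpus",
    "write_corpus",
    "load_stopwords",
    "select_section",
]

_WORD_UNIT = re.compile(r"\S+")
_ALPHA_RUN = re.compile(r"[a-z]+")
_HAS_DIGIT = re.compile(r"\d")


@dataclass(frozen=True)
class RawDocument:
    """A single free-text record: one drug, one named section."""

    drug_id: str
    section: str
    text: str

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")


class Vocabulary:
    """Ordered word list with a word -> integer index bijection."""

    def __init__(self, words: Iterable[str]):
        self.words: list[str] = list(words)
        self.index: dict[str, int] = {w: i for i, w in enumerate(self.words)}
        if len(self.index) != len(self.words):
            raise ValueError("vocabulary contains duplicate words")

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def __getitem__(self, i: int) -> str:
        return self.words[i]

    def __iter__(self) -> Iterator[str]:
        return iter(self.words)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Vocabulary) and self.words == other.words


@dataclass
class BowCorpus:
    """Bag-of-words corpus: token-index sequences over a shared vocabulary.

    ``docs[d]`` is the ordered sequence of vocabulary indices for document
    ``d`` (order within a document is preserved from the raw text).
    """

    vocabulary: Vocabulary
    docs: list[np.ndarray]
    doc_ids: list[str]
    empty_doc_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.docs) != len(self.doc_ids):
            raise ValueError("docs and doc_ids length mismatch")
        V = len(self.vocabulary)
        for d in self.docs:
            if len(d) and (d.min() < 0 or d.max() >= V):
                raise ValueError("token index outside [0, V)")

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    @property
    def doc_lengths(self) -> np.ndarray:
        return np.array([len(d) for d in self.docs], dtype=np.int64)

    @property
    def total_tokens(self) -> int:
        return int(self.doc_lengths.sum())

    def to_dense_counts(self) -> np.ndarray:
        """D x V matrix of per-document token counts."""
        out = np.zeros((self.n_docs, len(self.vocabulary)), dtype=np.int64)
        for i, d in enumerate(self.docs):
            np.add.at(out[i], d, 1)
        return out

    def render_texts(self) -> list[str]:
        """Rewrite each document as whitespace-joined words (for idempotence checks)."""
        return [" ".join(self.vocabulary[t] for t in doc) for doc in self.docs]


def tokenize(text: str) -> list[str]:
    """Lowercased alphabetic tokens; any whitespace-delimited unit containing
    a digit is discarded whole (so "5-fold" yields nothing, not "fold")."""
    tokens: list[str] = []
    for unit in _WORD_UNIT.findall(text.lower()):
        if _HAS_DIGIT.search(unit):
            continue
        tokens.extend(_ALPHA_RUN.findall(unit))
    return tokens


def document_frequency(docs: Sequence[Sequence[str]]) -> dict[str, float]:
    """Fraction of documents containing each word (a word repeated within one
    document counts once for that document)."""
    if len(docs) == 0:
        raise ValueError("document_frequency requires at least one document")
    counts: dict[str, int] = {}
    for doc in docs:
        for w in set(doc):
            counts[w] = counts.get(w, 0) + 1
    n = len(docs)
    return {w: c / n for w, c in counts.items()}


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list; defaults to the bundled English list."""
    if path is None:
        text = (resources.files("dilitopics.data") / "stopwords_en.txt").read_text()
    else:
        text = Path(path).read_text()
    words = [ln.strip() for ln in text.splitlines()]
    return frozenset(w for w in words if w and not w.startswith("#"))


def preprocess(
    docs: Sequence[RawDocument],
    stopwords: Iterable[str] | None = None,
    extra_removals: Iterable[str] = (),
    df_threshold: float = 0.8,
) -> BowCorpus:
    """Tokenize and filter raw documents into a :class:`BowCorpus`.

    The vocabulary excludes stop-words, the explicit ``extra_removals`` list,
    and any word whose document frequency is strictly greater than
    ``df_threshold``. Vocabulary order is alphabetical (deterministic).
    """
    if not 0 < df_threshold <= 1:
        raise ValueError("df_threshold must be in (0, 1]")
    if len(docs) == 0:
        raise ValueError("no documents supplied")
    stop = frozenset(load_stopwords()) if stopwords is None else frozenset(stopwords)
    extra = frozenset(extra_removals)

    tokenized = [tokenize(d.text) for d in docs]
    df = document_frequency(tokenized)
    removed_by_df = {w for w, f in df.items() if f > df_threshold}
    keep = set(df) - stop - extra - removed_by_df
    vocab = Vocabulary(sorted(keep))

    bow_docs: list[np.ndarray] = []
    empty: list[str] = []
    for raw, toks in zip(docs, tokenized):
        idx = np.array([vocab.index[t] for t in toks if t in vocab.index], dtype=np.int32)
        if len(idx) == 0:
            empty.append(raw.drug_id)
        bow_docs.append(idx)
    if len(empty) == len(docs):
        raise ValueError("all documents are empty after filtering")
    return BowCorpus(vocab, bow_docs, [d.drug_id for d in docs], empty)


def _check_duplicates(docs: Sequence[RawDocument]) -> None:
    seen: set[tuple[str, str]] = set()
    for d in docs:
        key = (d.drug_id, d.section)
        if key in seen:
            raise ValueError(f"duplicate (drug_id, section) record: {key}")
        seen.add(key)


def read_corpus(path: str | Path, format: str = "jsonl") -> list[RawDocument]:
    """Read raw documents from a JSON-lines file or a directory of
    ``<drug_id>__<section>.txt`` files."""
    path = Path(path)
    docs: list[RawDocument] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    docs.append(RawDocument(rec["drug_id"], rec["section"], rec["text"]))
                except (json.JSONDecodeError, KeyError, TypeError) as exc:
                    raise ValueError(f"malformed record at {path}:{lineno}: {exc}") from exc
    elif format == "textdir":
        for file in sorted(path.glob("*.txt")):
            stem = file.stem
            if "__" not in stem:
                raise ValueError(f"file name {file.name} lacks '<drug_id>__<section>.txt' form")
            drug_id, _, section = stem.partition("__")
            docs.append(RawDocument(drug_id, section, file.read_text(encoding="utf-8")))
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    _check_duplicates(docs)
    return docs


def write_corpus(docs: Sequence[RawDocument], path: str | Path) -> None:
    """Write raw documents as JSON-lines (the format ``read_corpus`` reads)."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {"drug_id": d.drug_id, "section": d.section, "text": d.text},
                    ensure_ascii=False,
                )
                + "\n"
            )


def select_section(docs: Sequence[RawDocument], section: str) -> Mapping[str, RawDocument]:
    """Restrict a multi-section corpus to one section, keyed by drug_id."""
    return {d.drug_id: d for d in docs if d.section == section}
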