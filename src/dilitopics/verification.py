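"""Lexicon-based evidence verification for flagged drugs.

A flagged drug is checked against a designated evidence section (for the
liver-failure use case, the drug's outcome-and-management narrative): the
section text is scanned for each phrase of an evidence lexicon by
case-insensitive substring matching after whitespace normalization. Matching
is substring by default ("fatal" also hits "fatality"); pass
``word_boundary=True`` for whole-word matching.

External evidence tiers (regulatory labels, spontaneous-report databases,
literature) are out of computational scope; a user-supplied annotation
mapping can be attached to the summary as a pass-through.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import RawDocument

__all__ = [
    "EvidenceLexicon",
    "EvidenceRecord",
    "VerificationSummary",
    "load_lexicon",
    "match_terms",
    "verify_drugs",
    "summarize",
]

_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class EvidenceLexicon:
    terms: tuple[str, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("lexicon must contain at least one phrase")
        cleaned = tuple(_WS.sub(" ", t.strip().lower()) for t in self.terms)
        if len(set(cleaned)) != len(cleaned):
            raise ValueError("lexicon contains duplicate phrases")
        object.__setattr__(self, "terms", cleaned)


@dataclass
class EvidenceRecord:
    drug_id: str
    matched_terms: frozenset[str]
    tier: str  # "section_evidence" | "no_section_evidence" | "section_missing"


@dataclass
class VerificationSummary:
    n_flagged: int
    n_with_evidence: int
    fraction_with_evidence: float
    tier_counts: dict[str, int]
    external_tiers: Mapping[str, str] = field(default_factory=dict)


def load_lexicon(path: str | Path | None = None, name: str | None = None) -> EvidenceLexicon:
    """Load a one-phrase-per-line lexicon; defaults to the bundled ALF list."""
    if path is None:
        text = (resources.files("dilitopics.data") / "alf_lexicon.txt").read_text()
        name = name or "ALF-default"
    else:
        text = Path(path).read_text()
        name = name or Path(path).stem
    terms = [ln.strip() for ln in text.splitlines()]
    return EvidenceLexicon(tuple(t for t in terms if t and not t.startswith("#")), name)


def match_terms(
    text: str, lexicon: EvidenceLexicon, word_boundary: bool = False
) -> frozenset[str]:
    """Lexicon phrases found in ``text`` (case-insensitive, whitespace-
    normalized; substring matching unless ``word_boundary``)."""
    hay = _WS.sub(" ", text.lower())
    if word_boundary:
        return frozenset(
            t for t in lexicon.terms if re.search(rf"\b{re.escape(t)}\b", hay)
        )
    return frozenset(t for t in lexicon.terms if t in hay)


def verify_drugs(
    flagged: Sequence[str],
    evidence_docs: Mapping[str, RawDocument] | Mapping[str, str],
    lexicon: EvidenceLexicon,
    word_boundary: bool = False,
) -> list[EvidenceRecord]:
    """One evidence record per flagged drug; drugs without an evidence
    section are tiered ``section_missing``."""
    records: list[EvidenceRecord] = []
    for drug in flagged:
        doc = evidence_docs.get(drug)
        if doc is None:
            records.append(EvidenceRecord(drug, frozenset(), "section_missing"))
            continue
        text = doc.text if isinstance(doc, RawDocument) else doc
        hits = match_terms(text, lexicon, word_boundary)
        tier = "section_evidence" if hits else "no_section_evidence"
        records.append(EvidenceRecord(drug, hits, tier))
    return records


def summarize(
    records: Sequence[EvidenceRecord],
    external_tiers: Mapping[str, str] | None = None,
) -> VerificationSummary:
    """Tier counts and the fraction of flagged drugs with section evidence."""
    if len(records) == 0:
        raise ValueError("no evidence records to summarize")
    tiers = {"section_evidence": 0, "no_section_evidence": 0, "section_missing": 0}
    for r in records:
        tiers[r.tier] += 1
    n = len(records)
    n_ev = tiers["section_evidence"]
    return VerificationSummary(n, n_ev, n_ev / n, tiers, external_tiers or {})
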