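"""End-to-end pipeline: preprocess -> (select T) -> fit -> seed topic ->
flag drugs -> verify evidence -> report.

Every stage writes a TSV/JSON artifact under the configured output directory,
each carrying a header comment with the run seed and a hash of the effective
configuration, so any report number can be regenerated from disk. A
"theta-only" entry point (``theta_path`` set) loads a precomputed
document-topic matrix and skips preprocessing and fitting entirely — this is
how published per-drug topic tables can be analyzed without the original
corpus.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import corpus as corpus_mod
from . import lda as lda_mod
from . import seed_topic as st_mod
from . import verification as ver_mod

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "load_theta_tsv"]

log = logging.getLogger("dilitopics")


@dataclass
class PipelineConfig:
    corpus_path: str | None = None
    corpus_format: str = "jsonl"
    analysis_section: str = "hepatotoxicity"
    evidence_section: str = "outcome_and_management"
    seed_path: str | None = None
    lexicon_path: str | None = None
    theta_path: str | None = None       # theta-only mode: skip preprocessing + fitting
    n_topics: int | None = None
    topic_grid: list[int] = field(default_factory=list)
    alpha: float = 0.1
    beta: float = 0.01
    n_iter: int = 1000
    burn_in: int = 500
    sample_lag: int = 10
    df_threshold: float = 0.8
    extra_removals: list[str] = field(default_factory=list)
    stopwords_path: str | None = None
    k: int = 3
    top_n_words: int = 15
    n_perm: int = 999
    word_boundary: bool = False
    outdir: str = "dilitopics_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.theta_path is None and self.corpus_path is None:
            raise ValueError("either corpus_path or theta_path is required")
        if self.seed_path is None:
            raise ValueError("seed_path (seed drug list) is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # outdir is excluded: the same analysis into two directories is the same run
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineReport:
    chosen_T: int
    topic_labels: list[str]
    seed_topic_label: str
    seed_topic_mean: float
    baseline_mean: float
    p_value: float
    rank_distribution: dict[str, int]
    top_words: list[str]
    unique_words: list[str]
    flagged_drugs: list[str]
    n_flagged: int
    verification: dict[str, Any]
    seed: int
    config_hash: str
    empty_doc_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _header(config: PipelineConfig) -> str:
    return f"# dilitopics seed={config.seed} config={config.config_hash()}\n"


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        frame.to_csv(fh, sep="\t", index=index)


def load_theta_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a document-topic TSV (rows: drug_id; columns: topic labels),
    ignoring '#' header comments. Returns (theta, doc_ids, topic_labels)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return frame.to_numpy(dtype=float), list(frame.index.astype(str)), list(frame.columns)


def _read_seed_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def _stage(name: str, t0: float, **info: Any) -> None:
    extra = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, extra)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full workflow and write all artifacts under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _read_seed_list(config.seed_path)
    raw_docs: list[corpus_mod.RawDocument] = []
    if config.corpus_path is not None:
        raw_docs = corpus_mod.read_corpus(config.corpus_path, config.corpus_format)

    empty_ids: list[str] = []
    top_lists: list[list[str]] = []
    if config.theta_path is not None:
        theta, doc_ids, topic_labels = load_theta_tsv(config.theta_path)
        chosen_T = theta.shape[1]
    else:
        t0 = time.perf_counter()
        analysis_docs = [d for d in raw_docs if d.section == config.analysis_section]
        stop = corpus_mod.load_stopwords(config.stopwords_path)
        bow = corpus_mod.preprocess(
            analysis_docs, stop, config.extra_removals, config.df_threshold
        )
        empty_ids = bow.empty_doc_ids
        _stage("preprocess", t0, docs=bow.n_docs, vocab=len(bow.vocabulary),
               tokens=bow.total_tokens)
        with open(outdir / "vocabulary.txt", "w") as fh:
            fh.write(_header(config))
            fh.write("\n".join(bow.vocabulary.words) + "\n")

        hyper = lda_mod.Hyperparams(
            n_topics=config.n_topics or 1, alpha=config.alpha, beta=config.beta,
            n_iter=config.n_iter, burn_in=config.burn_in,
            sample_lag=config.sample_lag, seed=config.seed,
        )
        if config.topic_grid:
            t0 = time.perf_counter()
            sel = lda_mod.select_num_topics(bow, config.topic_grid, hyper)
            chosen_T = sel.chosen_T
            curve = pd.DataFrame(
                {"n_topics": sel.grid, "log_likelihood": sel.log_likelihoods}
            )
            _write_tsv(curve, outdir / "selection_curve.tsv", config, index=False)
            _stage("select_num_topics", t0, grid=sel.grid, chosen=chosen_T)
            hyper = dataclasses.replace(
                hyper, n_topics=chosen_T, seed=sel.seeds[chosen_T]
            )
        elif config.n_topics:
            chosen_T = config.n_topics
            hyper = dataclasses.replace(hyper, n_topics=chosen_T)
        else:
            raise ValueError("set n_topics or topic_grid (or use theta_path)")

        t0 = time.perf_counter()
        model = lda_mod.fit(bow, hyper)
        _stage("fit", t0, T=hyper.n_topics, loglik=round(model.log_likelihood, 2))
        theta, doc_ids = model.theta, model.doc_ids
        topic_labels = [f"topic_{k}" for k in range(chosen_T)]
        theta_frame = pd.DataFrame(theta, index=pd.Index(doc_ids, name="drug_id"),
                                   columns=topic_labels)
        _write_tsv(theta_frame, outdir / "theta.tsv", config)
        phi_frame = pd.DataFrame(model.phi, index=pd.Index(topic_labels, name="topic"),
                                 columns=model.vocab.words)
        _write_tsv(phi_frame, outdir / "phi.tsv", config)
        top_lists = lda_mod.top_words(model, min(config.top_n_words, len(model.vocab)))

    t0 = time.perf_counter()
    result = st_mod.identify_seed_topic(theta, doc_ids, seeds)
    result.p_value = st_mod.permutation_test_seed_topic(
        theta, doc_ids, seeds, config.n_perm, config.seed
    )
    seed_label = topic_labels[result.seed_topic]
    ranks = st_mod.rank_distribution(theta, doc_ids, result.seed_topic, seeds)
    _stage("seed_topic", t0, topic=seed_label, mean=round(result.seed_topic_mean, 4))
    _write_tsv(
        pd.DataFrame(
            [{
                "seed_topic": seed_label,
                "seed_topic_mean": result.seed_topic_mean,
                "baseline_mean": result.baseline_mean,
                "p_value": result.p_value,
            }]
        ),
        outdir / "seed_topic.tsv", config, index=False,
    )

    top_k_words = top_lists[result.seed_topic] if top_lists else []
    uniq = sorted(st_mod.unique_top_words(top_lists, result.seed_topic)) if top_lists else []
    if top_lists:
        _write_tsv(
            pd.DataFrame(
                {"topic": [topic_labels[j] for j in range(len(top_lists))],
                 "top_words": [" ".join(ws) for ws in top_lists]}
            ),
            outdir / "top_words.tsv", config, index=False,
        )

    t0 = time.perf_counter()
    flagged = st_mod.classify_top_k(theta, doc_ids, result.seed_topic, config.k, seeds)
    rankings = pd.DataFrame(
        [
            {
                "drug_id": doc_ids[i],
                "rank_of_seed_topic": st_mod.rank_topics(theta[i]).rank_of(result.seed_topic),
                **{
                    f"top{r + 1}": f"{topic_labels[st_mod.rank_topics(theta[i]).order[r]]}"
                       f":{st_mod.rank_topics(theta[i]).probabilities[r]:.4g}"
                    for r in range(min(3, theta.shape[1]))
                },
            }
            for i in range(len(doc_ids))
        ]
    )
    _write_tsv(rankings, outdir / "rankings.tsv", config, index=False)
    _write_tsv(
        pd.DataFrame({"drug_id": flagged,
                      "seed_topic_prob": [theta[doc_ids.index(d), result.seed_topic]
                                          for d in flagged]}),
        outdir / "flagged.tsv", config, index=False,
    )
    _stage("classify", t0, k=config.k, flagged=len(flagged))

    verification: dict[str, Any] = {}
    if raw_docs:
        t0 = time.perf_counter()
        lex = ver_mod.load_lexicon(config.lexicon_path)
        evidence = corpus_mod.select_section(raw_docs, config.evidence_section)
        records = ver_mod.verify_drugs(flagged, evidence, lex, config.word_boundary)
        if records:
            summary = ver_mod.summarize(records)
            _write_tsv(
                pd.DataFrame(
                    [{"drug_id": r.drug_id, "tier": r.tier,
                      "matched_terms": ";".join(sorted(r.matched_terms))}
                     for r in records]
                ),
                outdir / "evidence.tsv", config, index=False,
            )
            _write_tsv(
                pd.DataFrame([{**summary.tier_counts,
                               "n_flagged": summary.n_flagged,
                               "fraction_with_evidence": summary.fraction_with_evidence}]),
                outdir / "summary.tsv", config, index=False,
            )
            verification = {
                "n_flagged": summary.n_flagged,
                "n_with_evidence": summary.n_with_evidence,
                "fraction_with_evidence": summary.fraction_with_evidence,
                "tier_counts": summary.tier_counts,
            }
            _stage("verify", t0, with_evidence=summary.n_with_evidence)

    report = PipelineReport(
        chosen_T=chosen_T,
        topic_labels=topic_labels,
        seed_topic_label=seed_label,
        seed_topic_mean=result.seed_topic_mean,
        baseline_mean=result.baseline_mean,
        p_value=result.p_value,
        rank_distribution=ranks,
        top_words=top_k_words,
        unique_words=uniq,
        flagged_drugs=flagged,
        n_flagged=len(flagged),
        verification=verification,
        seed=config.seed,
        config_hash=config.config_hash(),
        empty_doc_ids=empty_ids,
    )
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
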