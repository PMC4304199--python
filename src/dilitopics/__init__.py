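"""dilitopics: seed-guided LDA topic modeling for drug-safety narratives.

Fits latent Dirichlet allocation by collapsed Gibbs sampling to per-drug
free-text documents, identifies the topic most associated with a seed set of
drugs with established causality for an adverse outcome (the motivating use
case is drug-induced acute liver failure), flags further drugs whose
documents rank that topic highly, and verifies flags against a second text
section with an evidence-term lexicon.
"""

from importlib import resources

from . import corpus, lda, pipeline, seed_topic, synthetic, verification

__version__ = "0.1.0"

__all__ = [
    "corpus",
    "lda",
    "seed_topic",
    "verification",
    "synthetic",
    "pipeline",
    "table1_theta_path",
    "table1_seed_path",
]


def table1_theta_path() -> str:
    """Path of the packaged 26-drug published document-topic worked example."""
    return str(resources.files("dilitopics.data") / "table1_theta.tsv")


def table1_seed_path() -> str:
    """Path of the packaged 26-drug seed list matching the worked example."""
    return str(resources.files("dilitopics.data") / "table1_seed_drugs.txt")
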