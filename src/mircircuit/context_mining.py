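"""Cancer-context attachment by gene-MeSH literature co-occurrence.

Eight of the Hanahan-Weinberg hallmarks of cancer are represented by nine
MeSH terms (immunosuppression is excluded: immune cells are absent from the
in vitro cell-culture system). A gene is linked to a term when the two
co-occur in more documents than expected by chance, assessed with a
one-sided (upper-tail) hypergeometric test over exact per-document
membership counts — a local, reproducible stand-in for a co-citation
service.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Iterable, Sequence
from pathlib import Path
from typing import Union

import pandas as pd
from scipy import stats

__all__ = [
    "MESH_TERMS",
    "HALLMARK_MESH",
    "Document",
    "Corpus",
    "CooccurrenceResult",
    "cooccurrence",
    "build_context_edges",
]

logger = logging.getLogger(__name__)

#: The nine MeSH terms standing for the inspected cancer hallmarks.
MESH_TERMS: tuple[str, ...] = (
    "mutation",
    "cyclin dependent kinase inhibitor proteins",
    "cell death",
    "receptors cytokine",
    "drug resistance neoplasm",
    "angiogenesis inducing agents",
    "glycolysis",
    "epithelial-mesenchymal transition",
    "genomic instability",
)

#: (hallmark label, MeSH term) pairs. Two terms map to the genome
#: instability hallmark; immunosuppression is deliberately absent.
HALLMARK_MESH: tuple[tuple[str, str], ...] = (
    ("genome instability and mutation", "mutation"),
    ("evading growth suppressors", "cyclin dependent kinase inhibitor proteins"),
    ("resisting cell death", "cell death"),
    ("sustaining proliferative signaling", "receptors cytokine"),
    ("acquired therapy resistance", "drug resistance neoplasm"),
    ("inducing angiogenesis", "angiogenesis inducing agents"),
    ("deregulating cellular energetics", "glycolysis"),
    ("activating invasion and metastasis", "epithelial-mesenchymal transition"),
    ("genome instability and mutation", "genomic instability"),
)

assert tuple(t for _, t in HALLMARK_MESH) == MESH_TERMS


@dataclasses.dataclass(frozen=True)
class Document:
    """One corpus document: the gene symbols and context terms it mentions."""

    id: str
    genes: frozenset[str]
    terms: frozenset[str]


@dataclasses.dataclass
class Corpus:
    """A document collection with exact membership counting."""

    documents: list[Document]

    @property
    def n_docs(self) -> int:
        return len(self.documents)

    def gene_docs(self, gene: str) -> set[int]:
        return {i for i, d in enumerate(self.documents) if gene in d.genes}

    def term_docs(self, term: str) -> set[int]:
        return {i for i, d in enumerate(self.documents) if term in d.terms}

    @classmethod
    def from_jsonl(cls, path: Union[str, Path]) -> "Corpus":
        docs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                docs.append(Document(str(obj["id"]), frozenset(obj["genes"]), frozenset(obj["terms"])))
        return cls(docs)

    def to_jsonl(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for d in self.documents:
                fh.write(
                    json.dumps(
                        {"id": d.id, "genes": sorted(d.genes), "terms": sorted(d.terms)},
                        sort_keys=True,
                    )
                    + "\n"
                )


@dataclasses.dataclass(frozen=True)
class CooccurrenceResult:
    """Co-occurrence counts and upper-tail hypergeometric p for one pair."""

    gene: str
    term: str
    n_gene: int
    n_term: int
    n_both: int
    n_total: int
    p_value: float


def cooccurrence(corpus: Corpus, gene: str, term: str) -> CooccurrenceResult:
    """Count documents mentioning the gene, the term, and both; test
    over-representation.

    ``p_value = P(X >= n_both)`` for X hypergeometric with population
    ``n_total``, ``n_gene`` successes and ``n_term`` draws. A gene or term
    absent from the corpus yields ``n_both = 0`` and ``p_value = 1`` (an
    outcome, not an error).
    """
    if corpus.n_docs == 0:
        raise ValueError("empty corpus")
    g_docs = corpus.gene_docs(gene)
    t_docs = corpus.term_docs(term)
    n_both = len(g_docs & t_docs)
    p = float(stats.hypergeom.sf(n_both - 1, corpus.n_docs, len(g_docs), len(t_docs)))
    return CooccurrenceResult(gene, term, len(g_docs), len(t_docs), n_both, corpus.n_docs, min(p, 1.0))


def build_context_edges(
    corpus: Corpus,
    genes: Iterable[str],
    mesh_map: Sequence[tuple[str, str]] = HALLMARK_MESH,
    min_count: int = 1,
    max_p: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Gene-term association edges by co-occurrence over-representation.

    An undirected association edge (gene, term) is emitted iff
    ``n_both >= min_count`` and the (optionally Benjamini-Hochberg adjusted)
    hypergeometric p is ``<= max_p``. Returns a TSV-ready DataFrame with
    columns ``gene, term, n_both, p`` (plus ``p_adj`` when correcting).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not (0 < max_p <= 1):
        raise ValueError("max_p must be in (0, 1]")
    terms = sorted({t for _, t in mesh_map})
    rows = []
    for gene in sorted(set(genes)):
        for term in terms:
            res = cooccurrence(corpus, gene, term)
            rows.append((res.gene, res.term, res.n_both, res.p_value))
    df = pd.DataFrame(rows, columns=["gene", "term", "n_both", "p"])
    if bh_correct:
        df["p_adj"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
        keep = (df["n_both"] >= min_count) & (df["p_adj"] <= max_p)
    else:
        keep = (df["n_both"] >= min_count) & (df["p"] <= max_p)
    out = df[keep].reset_index(drop=True)
    logger.info("build_context_edges: %d/%d pairs kept", len(out), len(df))
    return out
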