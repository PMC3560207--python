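"""Network validation by mean edge correlation under node-label permutation.

The statistic is the mean, over all inhibition and regulation edges, of the
expected-sign-weighted Pearson correlation between the two endpoints'
expression profiles across the six samples (3 cell lines x 2 replicates).
The expected sign is -1 for inhibition edges and for repressive regulation,
+1 for activating or unknown-direction regulation, so a biologically
coherent network scores high; context (association) edges are not scored.

The null model permutes which expression profile each node label carries,
within feature class (miRNA profiles among miRNA nodes, gene profiles among
gene nodes), keeping the topology fixed; the one-sided upper-tail empirical
p is reported both raw (``#(null >= observed)/n_perm``, which can print
0.000 when no permutation reaches the observed statistic) and with the
add-one correction ``(#+1)/(n_perm+1)``, which is never exactly zero.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
from scipy import stats

from .expression import ExpressionMatrix
from .network import (
    EDGE_INHIBITION,
    EDGE_REGULATION,
    NODE_GENE,
    NODE_MIRNA,
    IntegrativeNetwork,
)

__all__ = ["ValidationResult", "edge_score", "network_statistic", "permutation_test"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ValidationResult:
    """Observed statistic, permutation null sample and empirical p-values."""

    observed_stat: float
    null_stats: np.ndarray
    p_raw: float
    p_corrected: float
    n_perm: int
    n_edges_scored: int
    seed: int
    method: str = "pearson"

    def __post_init__(self) -> None:
        assert len(self.null_stats) == self.n_perm
        assert 0.0 <= self.p_raw <= 1.0
        assert 0.0 < self.p_corrected <= 1.0
        assert self.p_corrected >= self.p_raw

    def to_dict(self) -> dict:
        return {
            "observed_stat": float(self.observed_stat),
            "p_raw": float(self.p_raw),
            "p_corrected": float(self.p_corrected),
            "n_perm": int(self.n_perm),
            "n_edges_scored": int(self.n_edges_scored),
            "seed": int(self.seed),
            "method": self.method,
        }

    def save_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    def save_null_tsv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, self.null_stats, fmt="%.10g", header="null_stat", comments="")


def _edge_sign(edge_type: str, direction: str = "unknown") -> int:
    if edge_type == EDGE_INHIBITION:
        return -1
    if edge_type == EDGE_REGULATION:
        return -1 if direction == "repression" else +1
    raise ValueError(f"edge type {edge_type!r} is not scored")


def _prepare(profile: np.ndarray, method: str) -> np.ndarray:
    x = np.asarray(profile, dtype=float)
    if method == "spearman":
        x = stats.rankdata(x)
    return x


def edge_score(
    profile_u: np.ndarray,
    profile_v: np.ndarray,
    edge_type: str,
    direction: str = "unknown",
    method: str = "pearson",
) -> float | None:
    """Expected-sign-weighted correlation of one edge's endpoint profiles.

    Returns ``sign * r`` with r the Pearson (or Spearman) correlation across
    samples, or ``None`` when either profile has zero variance (the edge is
    then excluded from the network mean and counted).
    """
    u = _prepare(profile_u, method)
    v = _prepare(profile_v, method)
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        return None
    return _edge_sign(edge_type, direction) * float(uc @ vc / (nu * nv))


def _aligned_profiles(
    network: IntegrativeNetwork,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
):
    """Profile matrix (log2, common sample order) for scored nodes.

    Returns (Z, ok, index, n_mirna_nodes): rows of Z are unit-normalized
    centered profiles (so a dot product is a Pearson r), ok flags nonzero
    variance, index maps node id -> row.
    """
    mi = mirna_expr.to_log2().values
    mr = mrna_expr.to_log2().values
    if set(mi.columns) != set(mr.columns):
        raise ValueError("miRNA and mRNA matrices must share the same sample set")
    order = sorted(mi.columns)
    if len(order) < 3:
        raise ValueError("need at least 3 shared samples to correlate profiles")
    mi_nodes = network.nodes_of_type(NODE_MIRNA)
    gene_nodes = network.nodes_of_type(NODE_GENE)
    for n in mi_nodes:
        if n not in mi.index:
            raise ValueError(f"miRNA node {n!r} has no expression profile")
    for n in gene_nodes:
        if n not in mr.index:
            raise ValueError(f"gene node {n!r} has no expression profile")
    P = np.vstack(
        [mi.loc[mi_nodes, order].to_numpy(dtype=float), mr.loc[gene_nodes, order].to_numpy(dtype=float)]
    ) if (mi_nodes or gene_nodes) else np.empty((0, len(order)))
    index = {n: i for i, n in enumerate(mi_nodes + gene_nodes)}
    return P, index, len(mi_nodes), len(gene_nodes)


def _standardize(P: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    if method == "spearman":
        P = np.apply_along_axis(stats.rankdata, 1, P) if len(P) else P
    Pc = P - P.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Pc, axis=1)
    ok = norms > 0
    Z = np.zeros_like(Pc)
    Z[ok] = Pc[ok] / norms[ok, None]
    return Z, ok


def _scored_edges(network: IntegrativeNetwork, index: dict[str, int]):
    edges = []
    for u, v, d in sorted(network.graph.edges(data=True), key=lambda e: (e[0], e[1])):
        et = d.get("edge_type")
        if et in (EDGE_INHIBITION, EDGE_REGULATION):
            edges.append((index[u], index[v], _edge_sign(et, d.get("direction", "unknown"))))
    return edges


def network_statistic(
    network: IntegrativeNetwork,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    method: str = "pearson",
) -> tuple[float, int]:
    """Mean signed edge correlation over all scorable inhibition/regulation
    edges; association edges are excluded. Returns (stat, n_edges_scored)."""
    P, index, _, _ = _aligned_profiles(network, mirna_expr, mrna_expr)
    Z, ok = _standardize(P, method)
    scores = []
    for iu, iv, sign in _scored_edges(network, index):
        if ok[iu] and ok[iv]:
            scores.append(sign * float(Z[iu] @ Z[iv]))
    if not scores:
        raise ValueError("no scorable inhibition/regulation edges in the network")
    return float(np.mean(scores)), len(scores)


def permutation_test(
    network: IntegrativeNetwork,
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    n_perm: int = 5000,
    seed: int = 0,
    method: str = "pearson",
) -> ValidationResult:
    """One-sided upper-tail node-label permutation test of the network
    statistic.

    Each permutation reshuffles the assignment of expression profiles to
    node labels within feature class, keeps the topology fixed, and
    recomputes the statistic. Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    P, index, n_mi, n_ge = _aligned_profiles(network, mirna_expr, mrna_expr)
    Z, ok = _standardize(P, method)
    edges = _scored_edges(network, index)
    if not edges:
        raise ValueError("no scorable inhibition/regulation edges in the network")
    iu = np.array([e[0] for e in edges])
    iv = np.array([e[1] for e in edges])
    sign = np.array([e[2] for e in edges], dtype=float)

    obs_mask = ok[iu] & ok[iv]
    if not obs_mask.any():
        raise ValueError("all edges have a zero-variance endpoint")
    observed = float((sign * np.einsum("es,es->e", Z[iu], Z[iv]))[obs_mask].mean())
    n_scored = int(obs_mask.sum())

    rng = np.random.default_rng(seed)
    perm = np.tile(np.arange(n_mi + n_ge), (n_perm, 1))
    if n_mi > 1:
        perm[:, :n_mi] = rng.permuted(perm[:, :n_mi], axis=1)
    if n_ge > 1:
        perm[:, n_mi:] = rng.permuted(perm[:, n_mi:], axis=1)

    pu = perm[:, iu]  # (n_perm, E) profile row carried by each edge source
    pv = perm[:, iv]
    dots = np.einsum("pes,pes->pe", Z[pu], Z[pv])
    mask = ok[pu] & ok[pv]
    null = (dots * sign * mask).sum(axis=1) / mask.sum(axis=1)

    exceed = int((null >= observed).sum())
    p_raw = exceed / n_perm
    p_corrected = (exceed + 1) / (n_perm + 1)
    logger.info(
        "permutation test: observed=%.4f p_raw=%.3f p_corrected=%.4g (n_perm=%d, edges=%d)",
        observed, p_raw, p_corrected, n_perm, n_scored,
    )
    return ValidationResult(observed, null, p_raw, p_corrected, n_perm, n_scored, seed, method)
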