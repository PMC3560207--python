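"""Markov clustering (MCL) of the integrative network and the cluster
selection rules.

The network is treated as undirected with unit edge weights and self-loops;
MCL alternates random-walk expansion (matrix power) and inflation
(entrywise power followed by column re-normalization) on the
column-stochastic adjacency matrix until the flow matrix stabilizes, then
reads clusters off the attractor rows. Downstream selection mirrors the
original study's rules: drop orphan (singleton) clusters, then keep the top
k largest clusters with at least ``min_size`` elements (defaults k=10,
min_size=5).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Sequence
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np

from .network import IntegrativeNetwork

__all__ = ["ClusterSet", "mcl", "non_orphan", "select_top", "recovery_score"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ClusterSet:
    """A partition of the network's nodes with the MCL parameters used."""

    clusters: list[list[str]]
    parameters: dict
    converged: bool
    n_iter: int

    def validate(self, nodes: Sequence[str]) -> None:
        flat = [n for c in self.clusters for n in c]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters are not pairwise disjoint")
        if set(flat) != set(nodes):
            raise ValueError("clusters do not cover the node set")
        if any(len(c) == 0 for c in self.clusters):
            raise ValueError("empty cluster")

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def save_json(self, path: Union[str, Path]) -> None:
        payload = {
            "parameters": self.parameters,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "clusters": [
                {"cluster_id": i, "size": len(c), "members": list(c)}
                for i, c in enumerate(self.clusters)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _as_undirected(network) -> nx.Graph:
    if isinstance(network, IntegrativeNetwork):
        g = network.graph
    else:
        g = network
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    und.add_edges_from((u, v) for u, v in g.edges() if u != v)
    return und


def mcl(
    network,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ClusterSet:
    """Markov clustering of an :class:`IntegrativeNetwork` or networkx graph.

    Edges are undirected with unit weight; self-loops are added before
    column-stochastic normalization. Iterates expansion (matrix power),
    inflation (entrywise power, renormalize) and pruning of entries below
    ``prune_threshold`` until the maximum entrywise change falls below
    ``tol`` or ``max_iter`` is reached (the latter returns the current
    clustering with ``converged=False``). Each node joins the cluster of its
    lowest-indexed attractor, which resolves overlapping attractor systems
    deterministically.
    """
    und = _as_undirected(network)
    if und.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(und.nodes)
    A = nx.to_numpy_array(und, nodelist=nodes, weight=None)
    A = (A > 0).astype(float)
    np.fill_diagonal(A, 1.0)
    M = A / A.sum(axis=0)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Mp = np.linalg.matrix_power(M, expansion)
        Mp = Mp**inflation
        Mp[Mp < prune_threshold] = 0.0
        colsum = Mp.sum(axis=0)
        dead = colsum == 0  # fully pruned column: park the walker on itself
        if dead.any():
            Mp[np.where(dead), np.where(dead)] = 1.0
            colsum = Mp.sum(axis=0)
        Mp = Mp / colsum
        diff = float(np.abs(Mp - M).max())
        M = Mp
        if diff < tol:
            converged = True
            break
    if not converged:
        logger.warning("mcl: no convergence after %d iterations (last change %.3g)", max_iter, diff)

    attractors = [i for i in range(len(nodes)) if M[i, i] > 0]
    attractor_set = set(attractors)
    assignment: dict[int, int] = {}
    for j in range(len(nodes)):
        support = [i for i in attractors if M[i, j] > 0]
        assignment[j] = min(support) if support else (j if j in attractor_set else -1)
    # a node with no attractor support (non-converged edge case) stands alone
    clusters_by_attractor: dict[int, list[str]] = {}
    for j, a in sorted(assignment.items()):
        key = a if a >= 0 else -(j + 1)
        clusters_by_attractor.setdefault(key, []).append(nodes[j])

    clusters = [sorted(members) for _, members in sorted(clusters_by_attractor.items(), key=lambda kv: min(kv[1]))]
    cs = ClusterSet(
        clusters=clusters,
        parameters={
            "inflation": inflation,
            "expansion": expansion,
            "prune_threshold": prune_threshold,
            "max_iter": max_iter,
            "tol": tol,
        },
        converged=converged,
        n_iter=n_iter,
    )
    cs.validate(nodes)
    return cs


def non_orphan(clusters: ClusterSet | Sequence[Sequence[str]]) -> list[list[str]]:
    """Clusters with at least two members, order preserved."""
    items = clusters.clusters if isinstance(clusters, ClusterSet) else clusters
    return [list(c) for c in items if len(c) >= 2]


def select_top(
    clusters: ClusterSet | Sequence[Sequence[str]],
    k: int = 10,
    min_size: int = 5,
) -> list[list[str]]:
    """Top ``k`` largest clusters with at least ``min_size`` elements,
    sorted by size descending; ties broken by the lexicographically smallest
    member id."""
    items = clusters.clusters if isinstance(clusters, ClusterSet) else clusters
    qualifying = [sorted(c) for c in items if len(c) >= min_size]
    qualifying.sort(key=lambda c: (-len(c), c[0]))
    return qualifying[:k]


def recovery_score(found: Sequence[Sequence[str]], truth: Sequence[Sequence[str]]) -> float:
    """Mean over truth clusters of the best Jaccard index against any found
    cluster; in [0, 1], with 1 meaning exact recovery."""
    truth_sets = [set(c) for c in truth]
    if not truth_sets:
        raise ValueError("empty truth clustering")
    found_sets = [set(c) for c in found]
    best = []
    for t in truth_sets:
        if not found_sets:
            best.append(0.0)
            continue
        best.append(max(len(t & f) / len(t | f) for f in found_sets))
    return float(np.mean(best))
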