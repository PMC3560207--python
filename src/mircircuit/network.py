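"""Circuit assembly, inverse-expression refinement, and the typed
integrative network.

A *circuit* is the integrated relation upstream-regulator -> miRNA ->
target: a TF or signaling protein controlling a miRNA's transcription,
joined with a validated target of that miRNA, where the target itself is
restricted to TF- or signaling-protein-encoding genes. Circuits are refined
by the inverse-expression condition (miRNA and target fold changes of
opposite sign in at least one resistant-vs-parent contrast), then merged
with gene-context association edges into one typed graph:

* inhibition edges: miRNA -> gene (blunt-ended blue in the figures);
* regulation edges: gene -> miRNA (circle-ended dashed black), carrying the
  regulation direction;
* association edges: gene/miRNA -> context term (grey).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path
from typing import Union

import networkx as nx
import numpy as np
import pandas as pd

from .expression import inverse_signs
from .knowledge_base import RegulatorInteraction, TargetInteraction

__all__ = [
    "NODE_MIRNA",
    "NODE_GENE",
    "NODE_CONTEXT",
    "EDGE_INHIBITION",
    "EDGE_REGULATION",
    "EDGE_ASSOCIATION",
    "SIF_TOKENS",
    "Circuit",
    "IntegrativeNetwork",
    "assemble_circuits",
    "refine_circuits",
    "build_network",
    "node_color",
    "export_network",
    "read_graphml",
]

logger = logging.getLogger(__name__)

NODE_MIRNA = "miRNA"
NODE_GENE = "gene"
NODE_CONTEXT = "context"

EDGE_INHIBITION = "inhibition"
EDGE_REGULATION = "regulation"
EDGE_ASSOCIATION = "association"

SIF_TOKENS = {
    EDGE_INHIBITION: "inhibits",
    EDGE_REGULATION: "regulates",
    EDGE_ASSOCIATION: "associated",
}


@dataclasses.dataclass
class Circuit:
    """One upstream-regulator -> miRNA -> target triple."""

    regulator: str
    role: str
    direction: str
    mirna: str
    target: str
    inverse_flags: dict[str, bool] = dataclasses.field(default_factory=dict)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.regulator, self.mirna, self.target)


class IntegrativeNetwork:
    """Typed directed graph of miRNA, gene and context nodes.

    Node attributes: ``node_type`` plus ``log2fc_<contrast>`` floats on
    expression-bearing nodes. Edge attributes: ``edge_type`` plus
    ``direction`` on regulation edges.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- views -------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_type(self, node_type: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("node_type") == node_type)

    def edges_of_type(self, edge_type: str) -> list[tuple[str, str, dict]]:
        return [
            (u, v, d)
            for u, v, d in sorted(self.graph.edges(data=True), key=lambda e: (e[0], e[1]))
            if d.get("edge_type") == edge_type
        ]

    # -- invariants --------------------------------------------------------

    _ALLOWED = {
        EDGE_INHIBITION: (NODE_MIRNA, NODE_GENE),
        EDGE_REGULATION: (NODE_GENE, NODE_MIRNA),
        EDGE_ASSOCIATION: ((NODE_GENE, NODE_MIRNA), NODE_CONTEXT),
    }

    def validate(self) -> None:
        """Raise on any violated type invariant."""
        for n, d in self.graph.nodes(data=True):
            nt = d.get("node_type")
            if nt not in (NODE_MIRNA, NODE_GENE, NODE_CONTEXT):
                raise ValueError(f"node {n!r} has invalid node_type {nt!r}")
            if nt == NODE_CONTEXT and any(k.startswith("log2fc") for k in d):
                raise ValueError(f"context node {n!r} carries expression attributes")
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            et = d.get("edge_type")
            if et not in self._ALLOWED:
                raise ValueError(f"edge ({u!r}, {v!r}) has invalid edge_type {et!r}")
            src_req, dst_req = self._ALLOWED[et]
            ut = self.graph.nodes[u].get("node_type")
            vt = self.graph.nodes[v].get("node_type")
            src_ok = ut == src_req if isinstance(src_req, str) else ut in src_req
            dst_ok = vt == dst_req if isinstance(dst_req, str) else vt in dst_req
            if not (src_ok and dst_ok):
                raise ValueError(f"{et} edge ({u!r}:{ut} -> {v!r}:{vt}) violates type rule")


def assemble_circuits(
    regulator_records: Sequence[RegulatorInteraction],
    target_records: Sequence[TargetInteraction],
    tf_signaling_universe: Iterable[str],
) -> list[Circuit]:
    """Triple join of the two evidence tables, with target restriction.

    Output set = { (r, m, t) : r->m in the regulator table, m->t in the
    target table, t in the TF/signaling universe }, deduplicated on the
    (regulator, miRNA, target) triple and sorted. Records must already be
    identifier-mapped and miRNA-canonicalized.
    """
    universe = frozenset(tf_signaling_universe)
    if not universe:
        raise ValueError("empty TF/signaling universe: target restriction would erase all circuits")
    targets_by_mirna: dict[str, list[TargetInteraction]] = {}
    for t in target_records:
        targets_by_mirna.setdefault(t.mirna, []).append(t)
    circuits: dict[tuple[str, str, str], Circuit] = {}
    for reg in regulator_records:
        for tgt in targets_by_mirna.get(reg.mirna, ()):
            if tgt.target not in universe:
                continue
            key = (reg.regulator, reg.mirna, tgt.target)
            if key not in circuits:
                circuits[key] = Circuit(reg.regulator, reg.role, reg.direction, reg.mirna, tgt.target)
    return [circuits[k] for k in sorted(circuits)]


def refine_circuits(
    circuits: Sequence[Circuit],
    fc_mirna: pd.DataFrame,
    fc_mrna: pd.DataFrame,
    min_abs_log2fc: float = 0.0,
) -> list[Circuit]:
    """Keep circuits whose miRNA and target are inversely expressed in at
    least one contrast; per-contrast flags are recorded on retained
    circuits. Circuits referencing a feature with no fold-change row are
    dropped with a logged count.
    """
    mi = fc_mirna.set_index(["feature_id", "contrast_id"])["log2fc"]
    mr = fc_mrna.set_index(["feature_id", "contrast_id"])["log2fc"]
    contrasts = sorted(set(fc_mirna["contrast_id"]) & set(fc_mrna["contrast_id"]))
    if not contrasts:
        raise ValueError("fold-change tables share no contrast")
    retained: list[Circuit] = []
    n_missing = 0
    for c in circuits:
        try:
            flags = {
                cid: inverse_signs(mi[(c.mirna, cid)], mr[(c.target, cid)], min_abs_log2fc)
                for cid in contrasts
            }
        except KeyError:
            n_missing += 1
            continue
        if any(flags.values()):
            retained.append(dataclasses.replace(c, inverse_flags=flags))
    if n_missing:
        logger.info("refine_circuits: dropped %d circuit(s) lacking fold-change rows", n_missing)
    return retained


def _fc_lookup(fc: pd.DataFrame | None) -> Mapping[tuple[str, str], float]:
    if fc is None:
        return {}
    return fc.set_index(["feature_id", "contrast_id"])["log2fc"].to_dict()


def build_network(
    circuits: Sequence[Circuit],
    association_edges: pd.DataFrame | Sequence[tuple[str, str]] | None = None,
    fc_mirna: pd.DataFrame | None = None,
    fc_mrna: pd.DataFrame | None = None,
) -> IntegrativeNetwork:
    """Merge circuits and gene-context associations into one typed graph.

    Nodes are the distinct regulators, miRNAs, targets and context terms;
    edges are deduplicated. log2 fold changes are attached per contrast as
    ``log2fc_<contrast>`` (miRNA nodes from the miRNA table, gene nodes from
    the mRNA table). Association edges naming a gene absent from all
    circuits are dropped with a logged count (recorded in
    ``graph.graph["n_associations_dropped"]``).
    """
    g = nx.DiGraph()
    mi_fc = _fc_lookup(fc_mirna)
    mr_fc = _fc_lookup(fc_mrna)

    genes = sorted({c.regulator for c in circuits} | {c.target for c in circuits})
    mirnas = sorted({c.mirna for c in circuits})
    for name in genes:
        attrs = {f"log2fc_{cid}": float(v) for (f, cid), v in mr_fc.items() if f == name} if mr_fc else {}
        g.add_node(name, node_type=NODE_GENE, **attrs)
    for name in mirnas:
        attrs = {f"log2fc_{cid}": float(v) for (f, cid), v in mi_fc.items() if f == name} if mi_fc else {}
        g.add_node(name, node_type=NODE_MIRNA, **attrs)

    for c in sorted(circuits, key=lambda c: c.triple):
        g.add_edge(c.regulator, c.mirna, edge_type=EDGE_REGULATION, direction=c.direction)
        g.add_edge(c.mirna, c.target, edge_type=EDGE_INHIBITION)

    dropped = 0
    if association_edges is not None:
        if isinstance(association_edges, pd.DataFrame):
            pairs = list(zip(association_edges["gene"], association_edges["term"]))
        else:
            pairs = list(association_edges)
        for gene, term in sorted(set(pairs)):
            if gene not in g:
                dropped += 1
                continue
            if term not in g:
                g.add_node(term, node_type=NODE_CONTEXT)
            g.add_edge(gene, term, edge_type=EDGE_ASSOCIATION)
    if dropped:
        logger.info("build_network: dropped %d association edge(s) on genes absent from circuits", dropped)
    g.graph["n_associations_dropped"] = dropped

    net = IntegrativeNetwork(g)
    net.validate()
    return net


#: Green (down in the resistant subline) through black to red (up).
_COLOR_DOWN = (0, 176, 80)
_COLOR_MID = (0, 0, 0)
_COLOR_UP = (255, 0, 0)


def node_color(log2fc: float, lo: float, hi: float) -> str:
    """Hex color for a log2 fold change on a diverging gradient.

    ``lo``/``hi`` are the linear-ratio extremes of the color scale (e.g.
    0.039 and 12.4); interpolation is linear in log2 space on each side of
    the neutral anchor at ratio 1 (so ratio 1 is exactly the midpoint color
    even on an asymmetric range), and values beyond the range are clipped.
    """
    if lo <= 0 or hi <= 0:
        raise ValueError("color-scale extremes must be positive linear ratios")
    llo, lhi = math.log2(lo), math.log2(hi)
    if not (llo < 0.0 < lhi):
        raise ValueError("color scale must straddle ratio 1 (lo < 1 < hi)")
    x = float(np.clip(log2fc, llo, lhi))
    if x <= 0:
        w = x / llo  # 1 at the low extreme, 0 at ratio 1
        a, b = _COLOR_DOWN, _COLOR_MID
        w = 1.0 - w
    else:
        w = x / lhi
        a, b = _COLOR_MID, _COLOR_UP
    rgb = tuple(round(ai + (bi - ai) * w) for ai, bi in zip(a, b))
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def export_network(
    network: IntegrativeNetwork,
    path: Union[str, Path],
    fmt: str,
    contrast: str | None = None,
    color_range: tuple[float, float] | None = None,
) -> None:
    """Write the network for Cytoscape-style consumption.

    ``fmt="SIF"``: one line per edge, relation tokens ``inhibits`` /
    ``regulates`` / ``associated``. ``fmt="GraphML"``: full node/edge
    attributes; when ``contrast`` is given, the node's ``log2fc`` for that
    contrast is exported, plus a ``color`` (if ``color_range=(lo, hi)``).
    GraphML round-trips through :func:`read_graphml`.
    """
    token = fmt.strip().lower()
    if token == "sif":
        lines = []
        for u, v, d in sorted(network.graph.edges(data=True), key=lambda e: (e[0], e[1])):
            lines.append(f"{u}\t{SIF_TOKENS[d['edge_type']]}\t{v}")
        Path(path).write_text("\n".join(lines) + "\n")
    elif token == "graphml":
        h = nx.DiGraph()
        for n in sorted(network.graph.nodes):
            d = dict(network.graph.nodes[n])
            if contrast is not None:
                key = f"log2fc_{contrast}"
                if key in d:
                    d["log2fc"] = float(d[key])
                    if color_range is not None:
                        d["color"] = node_color(d[key], *color_range)
            h.add_node(n, **d)
        for u, v, d in sorted(network.graph.edges(data=True), key=lambda e: (e[0], e[1])):
            h.add_edge(u, v, **d)
        nx.write_graphml(h, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; expected 'SIF' or 'GraphML'")


def read_graphml(path: Union[str, Path]) -> IntegrativeNetwork:
    """Read a network written by :func:`export_network` back into memory."""
    net = IntegrativeNetwork(nx.read_graphml(path, force_multigraph=False))
    net.validate()
    return net


def write_node_table(
    network: IntegrativeNetwork,
    path: Union[str, Path],
    contrasts: Sequence[str] = (),
    color_range: tuple[float, float] | None = None,
    color_contrast: str | None = None,
) -> None:
    """Node attribute TSV (id, type, log2fc per contrast, optional color)."""
    rows = []
    for n in sorted(network.graph.nodes):
        d = network.graph.nodes[n]
        row: dict[str, object] = {"id": n, "node_type": d["node_type"]}
        for cid in contrasts:
            row[f"log2fc_{cid}"] = d.get(f"log2fc_{cid}", "")
        if color_range is not None and color_contrast is not None:
            fc = d.get(f"log2fc_{color_contrast}")
            row["color"] = node_color(fc, *color_range) if fc is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
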