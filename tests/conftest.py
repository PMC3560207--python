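"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive results through a different code
path than the package (nested-loop joins, exhaustive enumeration,
plain-Python MCL) so the tests compare two independent routes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mircircuit.expression import ExpressionMatrix

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """A 4-feature, 6-sample linear-scale matrix with the standard design."""
    rng = np.random.default_rng(11)
    cols = [f"{line}.{rep}" for line in ("parent", "T", "F") for rep in (1, 2)]
    values = pd.DataFrame(
        2.0 ** rng.uniform(4, 10, size=(4, 6)), index=["f1", "f2", "f3", "f4"], columns=cols
    )
    return ExpressionMatrix(values, "mRNA", "linear")


# ---------------------------------------------------------------------------
# oracle: brute-force circuit join

def bruteforce_triple_join(regulators, targets, universe):
    """Nested-loop reference for circuit assembly; returns the triple set."""
    out = set()
    for reg in regulators:
        for tgt in targets:
            if reg.mirna == tgt.mirna and tgt.target in set(universe):
                out.add((reg.regulator, reg.mirna, tgt.target))
    return out


# ---------------------------------------------------------------------------
# oracle: exhaustive hypergeometric tail

def enumeration_pvalue(n_total: int, n_gene: int, n_term: int, n_both: int) -> float:
    """P(|gene-docs ∩ term-docs| >= n_both) by enumerating every placement
    of the term set against a fixed gene set (valid by symmetry)."""
    gene_docs = set(range(n_gene))
    hits = 0
    total = 0
    for term_docs in itertools.combinations(range(n_total), n_term):
        total += 1
        if len(gene_docs & set(term_docs)) >= n_both:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# oracle: plain-Python MCL (independent of the package's numpy loop)

def reference_mcl_partition(graph, inflation=2.0, expansion=2, max_iter=200, tol=1e-8):
    """Markov clustering via explicit Python loops on dict adjacency.

    Column-normalize with self-loops, then alternate expansion (matrix
    power) and inflation (entrywise power + renormalize) until stable;
    clusters are the connected components of the limit matrix's nonzero
    pattern. Returns a set of frozensets of node ids.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = [[0.0] * n for _ in range(n)]
    for u, v in graph.edges():
        if u == v:
            continue
        M[idx[u]][idx[v]] = 1.0
        M[idx[v]][idx[u]] = 1.0
    for i in range(n):
        M[i][i] = 1.0

    def normalize(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            for i in range(n):
                mat[i][j] /= s
        return mat

    def matmul(a, b):
        return [[sum(a[i][k] * b[k][j] for k in range(n)) for j in range(n)] for i in range(n)]

    M = normalize(M)
    for _ in range(max_iter):
        expanded = M
        for _ in range(expansion - 1):
            expanded = matmul(expanded, M)
        inflated = normalize([[expanded[i][j] ** inflation for j in range(n)] for i in range(n)])
        diff = max(abs(inflated[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = inflated
        if diff < tol:
            break

    # connected components of the nonzero pattern (ignoring numerically dead mass)
    eps = 1e-6
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(n):
            if M[i][j] > eps:
                adj[i].add(j)
                adj[j].add(i)
    seen: set[int] = set()
    clusters = set()
    for start in range(n):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            cur = frontier.pop()
            for nxt in adj[cur]:
                if nxt not in comp:
                    comp.add(nxt)
                    frontier.append(nxt)
        seen |= comp
        clusters.add(frozenset(nodes[i] for i in comp))
    return clusters


def pearson_sum_formula(x, y) -> float:
    """Textbook sum-formula Pearson correlation."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(a * a for a in x), sum(b * b for b in y), sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den
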