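"""Synthetic pipeline inputs with known planted structure.

Every downstream stage is exercised against a ground truth this module
plants:

* *circuits* — regulator -> miRNA -> target triples written into
  TransmiR-/miRTarBase-style tables, alongside decoy rows that the pipeline
  must discard (regulators of miRNAs absent from the arrays, targets
  outside the TF/signaling universe) and rows written under foreign
  identifiers that must survive identifier mapping;
* *inverse-expression pairs* — planted opposite-sign log2 fold changes of a
  miRNA and its target between a resistant subline and the parent line,
  with tunable across-sample anti-correlation;
* *graph modules* — the circuits are laid out in disjoint modules so the
  network has planted clusters;
* *gene-term associations* — co-injected into corpus documents that
  otherwise draw genes and terms independently (giving an exact null for
  the hypergeometric test).

Expression is generated on log2 scale (baseline + planted shift + noise)
and exponentiated to linear intensities, matching microarray convention;
anti-correlation is induced by a shared latent per-sample factor loaded
with opposite signs on a miRNA and its targets.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from ._rng import rng_for
from .context_mining import MESH_TERMS, Corpus, Document
from .expression import ExpressionMatrix

__all__ = [
    "CONTRAST_SUBLINE",
    "SimulationConfig",
    "SyntheticTruth",
    "mirna_names",
    "gene_names",
    "plant_truth",
    "generate_expression",
    "generate_knowledge_base",
    "generate_corpus",
    "tf_signaling_annotation",
]

#: Which cell line each standard contrast compares against the parent.
CONTRAST_SUBLINE = {"T_vs_P": "T", "F_vs_P": "F"}


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the synthetic experiment.

    Defaults mirror the real design (three cell lines, two array replicates
    each) at desk scale; ``noise_sd`` and ``effect_size`` are on log2 scale,
    and ``anticorrelation_strength`` is the expected magnitude of the
    across-sample Pearson anti-correlation of a planted miRNA-target pair.
    """

    n_mirna: int = 30
    n_mrna: int = 60
    n_samples_per_line: int = 2
    cell_lines: tuple[str, ...] = ("parent", "T", "F")
    noise_sd: float = 0.3
    effect_size: float = 1.0
    anticorrelation_strength: float = 0.8
    n_docs: int = 200
    doc_gene_prob: float = 0.03
    doc_term_prob: float = 0.08
    min_cooccurrence: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_mrna", "n_samples_per_line", "n_docs", "min_cooccurrence"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.cell_lines) < 1:
            raise ValueError("need at least one cell line")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.anticorrelation_strength <= 1.0):
            raise ValueError("anticorrelation_strength must be in [0, 1]")

    @property
    def sample_columns(self) -> list[str]:
        return [f"{line}.{rep + 1}" for line in self.cell_lines for rep in range(self.n_samples_per_line)]


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of everything planted into the generated inputs."""

    planted_circuits: list[tuple[str, str, str, str, str]]  # (regulator, role, direction, mirna, target)
    planted_inverse_pairs: list[tuple[str, str, str]]  # (mirna, target, contrast_id)
    planted_clusters: list[set[str]]
    planted_associations: list[tuple[str, str]]
    decoy_counts: dict[str, int]
    seed: int

    def validate(self) -> None:
        circuit_pairs = {(m, t) for _, _, _, m, t in self.planted_circuits}
        for m, t, _cid in self.planted_inverse_pairs:
            if (m, t) not in circuit_pairs:
                raise ValueError(f"planted inverse pair ({m}, {t}) is not a circuit miRNA-target pair")
        flat = [n for c in self.planted_clusters for n in c]
        if len(flat) != len(set(flat)):
            raise ValueError("planted clusters are not pairwise disjoint")
        if len(set(self.planted_circuits)) != len(self.planted_circuits):
            raise ValueError("duplicate planted circuits")

    @property
    def circuit_triples(self) -> set[tuple[str, str, str]]:
        return {(r, m, t) for r, _, _, m, t in self.planted_circuits}

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "planted_circuits": [list(c) for c in self.planted_circuits],
            "planted_inverse_pairs": [list(p) for p in self.planted_inverse_pairs],
            "planted_clusters": [sorted(c) for c in self.planted_clusters],
            "planted_associations": [list(a) for a in self.planted_associations],
            "decoy_counts": self.decoy_counts,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SyntheticTruth":
        obj = json.loads(Path(path).read_text())
        truth = cls(
            planted_circuits=[tuple(c) for c in obj["planted_circuits"]],
            planted_inverse_pairs=[tuple(p) for p in obj["planted_inverse_pairs"]],
            planted_clusters=[set(c) for c in obj["planted_clusters"]],
            planted_associations=[tuple(a) for a in obj["planted_associations"]],
            decoy_counts=dict(obj["decoy_counts"]),
            seed=int(obj["seed"]),
        )
        truth.validate()
        return truth


def mirna_names(n: int) -> list[str]:
    return [f"hsa-mir-{i + 1}" for i in range(n)]


def gene_names(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


_DEFAULT_DECOYS = {"absent_mirna_regulators": 5, "non_universe_targets": 5, "foreign_id_targets": 3}


def plant_truth(
    config: SimulationConfig,
    n_modules: int = 3,
    regulators_per_module: int = 2,
    mirnas_per_module: int = 3,
    targets_per_module: int = 3,
    terms_per_module: int = 2,
    decoy_counts: dict[str, int] | None = None,
    coherent: bool = True,
) -> SyntheticTruth:
    """Lay out planted circuits in disjoint modules.

    Module ``k`` owns its own regulators, miRNAs, targets and context
    terms; circuits are all (regulator, miRNA, target) combinations within
    a module, so the network decomposes into ``n_modules`` planted
    clusters. With ``coherent=True`` every circuit's miRNA-target pair is
    planted as inversely expressed in both contrasts; with
    ``coherent=False`` nothing is planted in expression (a null dataset
    with unchanged topology).
    """
    n_mi_needed = n_modules * mirnas_per_module
    n_ge_needed = n_modules * (regulators_per_module + targets_per_module)
    if n_mi_needed > config.n_mirna:
        raise ValueError(f"need {n_mi_needed} miRNAs but config.n_mirna={config.n_mirna}")
    if n_ge_needed > config.n_mrna:
        raise ValueError(f"need {n_ge_needed} genes but config.n_mrna={config.n_mrna}")
    if n_modules * terms_per_module > len(MESH_TERMS):
        raise ValueError("not enough MeSH terms for disjoint module contexts")

    mirnas = mirna_names(config.n_mirna)
    genes = gene_names(config.n_mrna)
    contrasts = [cid for cid, line in CONTRAST_SUBLINE.items() if line in config.cell_lines]

    circuits: list[tuple[str, str, str, str, str]] = []
    inverse_pairs: list[tuple[str, str, str]] = []
    clusters: list[set[str]] = []
    associations: list[tuple[str, str]] = []
    directions = ("activation", "repression", "unknown")

    gi = 0
    for k in range(n_modules):
        regs = genes[gi : gi + regulators_per_module]
        gi += regulators_per_module
        tgts = genes[gi : gi + targets_per_module]
        gi += targets_per_module
        mis = mirnas[k * mirnas_per_module : (k + 1) * mirnas_per_module]
        terms = list(MESH_TERMS[k * terms_per_module : (k + 1) * terms_per_module])

        for ri, reg in enumerate(regs):
            role = "TF" if ri % 2 == 0 else "signaling"
            for mi_i, m in enumerate(mis):
                direction = directions[(ri + mi_i) % 3]
                for t in tgts:
                    circuits.append((reg, role, direction, m, t))
        if coherent:
            for m in mis:
                for t in tgts:
                    for cid in sorted(contrasts):
                        inverse_pairs.append((m, t, cid))
        for ti, t in enumerate(tgts):
            associations.append((t, terms[ti % len(terms)]))
        clusters.append(set(regs) | set(mis) | set(tgts) | set(terms))

    truth = SyntheticTruth(
        planted_circuits=circuits,
        planted_inverse_pairs=inverse_pairs,
        planted_clusters=clusters,
        planted_associations=associations,
        decoy_counts=dict(decoy_counts if decoy_counts is not None else _DEFAULT_DECOYS),
        seed=config.seed,
    )
    truth.validate()
    return truth


def _check_names(truth: SyntheticTruth, mirnas: list[str], genes: list[str]) -> None:
    mi_set, ge_set = set(mirnas), set(genes)
    for r, _, _, m, t in truth.planted_circuits:
        for name, pool in ((m, mi_set), (r, ge_set), (t, ge_set)):
            if name not in pool:
                raise ValueError(f"truth references unknown feature {name!r}")
    for m, t, cid in truth.planted_inverse_pairs:
        if m not in mi_set:
            raise ValueError(f"truth references unknown feature {m!r}")
        if t not in ge_set:
            raise ValueError(f"truth references unknown feature {t!r}")
        if cid not in CONTRAST_SUBLINE:
            raise ValueError(f"unknown contrast id {cid!r}")


def generate_expression(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Linear-intensity miRNA and mRNA matrices with the planted signal.

    For each planted inverse pair and contrast, the miRNA's expected log2
    fold change is ``-effect_size`` and the target's ``+effect_size``;
    non-planted features have expected log2 fold change 0. Pairs connected
    through planted inverse pairs share a latent per-sample factor loaded
    with opposite signs, so their across-sample Pearson correlation has
    expectation ``-anticorrelation_strength``. Deterministic under
    (config, truth, seed).
    """
    mirnas = mirna_names(config.n_mirna)
    genes = gene_names(config.n_mrna)
    _check_names(truth, mirnas, genes)
    cols = config.sample_columns
    lines = [c.rsplit(".", 1)[0] for c in cols]
    n_s = len(cols)

    rng = rng_for(config.seed, "expression")
    base_mi = rng.uniform(6.0, 12.0, size=config.n_mirna)
    base_ge = rng.uniform(6.0, 12.0, size=config.n_mrna)

    shift_mi = np.zeros((config.n_mirna, n_s))
    shift_ge = np.zeros((config.n_mrna, n_s))
    mi_index = {m: i for i, m in enumerate(mirnas)}
    ge_index = {g: i for i, g in enumerate(genes)}
    for m, t, cid in truth.planted_inverse_pairs:
        subline = CONTRAST_SUBLINE[cid]
        sel = [j for j, line in enumerate(lines) if line == subline]
        shift_mi[mi_index[m], sel] = -config.effect_size
        shift_ge[ge_index[t], sel] = +config.effect_size

    # shared latent factors: one per connected component of the planted
    # miRNA-target pairing, loaded -1 on miRNAs and +1 on targets
    factor_mi = np.zeros((config.n_mirna, n_s))
    factor_ge = np.zeros((config.n_mrna, n_s))
    loaded_mi = np.zeros(config.n_mirna, dtype=bool)
    loaded_ge = np.zeros(config.n_mrna, dtype=bool)
    strength = config.anticorrelation_strength
    a = np.sqrt(strength) * config.noise_sd
    components = _pair_components(truth.planted_inverse_pairs)
    for comp in components:
        z = rng.normal(0.0, 1.0, size=n_s)
        for kind, name in comp:
            if kind == "mirna":
                factor_mi[mi_index[name]] = -a * z
                loaded_mi[mi_index[name]] = True
            else:
                factor_ge[ge_index[name]] = +a * z
                loaded_ge[ge_index[name]] = True

    resid_loaded = np.sqrt(max(1.0 - strength, 0.0)) * config.noise_sd
    noise_mi = rng.normal(0.0, 1.0, size=(config.n_mirna, n_s))
    noise_ge = rng.normal(0.0, 1.0, size=(config.n_mrna, n_s))
    sd_mi = np.where(loaded_mi, resid_loaded, config.noise_sd)[:, None]
    sd_ge = np.where(loaded_ge, resid_loaded, config.noise_sd)[:, None]

    log_mi = base_mi[:, None] + shift_mi + factor_mi + noise_mi * sd_mi
    log_ge = base_ge[:, None] + shift_ge + factor_ge + noise_ge * sd_ge

    mi = ExpressionMatrix(pd.DataFrame(2.0**log_mi, index=mirnas, columns=cols), "miRNA", "linear")
    ge = ExpressionMatrix(pd.DataFrame(2.0**log_ge, index=genes, columns=cols), "mRNA", "linear")
    return mi, ge


def _pair_components(pairs) -> list[list[tuple[str, str]]]:
    """Connected components of the planted miRNA-target pairing (union-find)."""
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for m, t, _cid in pairs:
        union(("mirna", m), ("gene", t))
    comps: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in parent:
        comps.setdefault(find(node), []).append(node)
    return [sorted(members) for _, members in sorted(comps.items())]


def generate_knowledge_base(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Evidence tables and identifier map with planted circuits and decoys.

    Returns (target table, regulator table, identifier map) as TSV-ready
    DataFrames. Every planted circuit contributes one regulator row and one
    target row; decoy rows are added per ``truth.decoy_counts``:

    * ``absent_mirna_regulators`` — regulator rows for miRNAs that exist in
      no expression array (never assemble into circuits);
    * ``non_universe_targets`` — target rows for genes outside the
      TF/signaling universe (dropped by the target restriction);
    * ``foreign_id_targets`` — that many planted target rows are rewritten
      under RefSeq-style foreign IDs, so circuit recovery depends on the
      identifier-mapping step.

    The identifier map covers every foreign ID emitted, plus identity rows
    for all symbols so already-symbolic genes resolve.
    """
    reg_rows: list[tuple[str, str, str, str]] = []
    seen_reg: set[tuple[str, str, str, str]] = set()
    for r, role, direction, m, _t in truth.planted_circuits:
        row = (r, role, direction, m)
        if row not in seen_reg:
            seen_reg.add(row)
            reg_rows.append(row)

    tgt_rows: list[tuple[str, str, str]] = []
    seen_tgt: set[tuple[str, str]] = set()
    for _r, _role, _direction, m, t in truth.planted_circuits:
        if (m, t) not in seen_tgt:
            seen_tgt.add((m, t))
            tgt_rows.append((m, t, "reporter assay"))

    decoys = truth.decoy_counts
    planted_mirnas = sorted({m for _, _, _, m, _ in truth.planted_circuits})
    for k in range(decoys.get("absent_mirna_regulators", 0)):
        reg_rows.append((f"DREG{k + 1}", "signaling", "unknown", f"hsa-mir-absent-{k + 1}"))
    for k in range(decoys.get("non_universe_targets", 0)):
        m = planted_mirnas[k % len(planted_mirnas)] if planted_mirnas else f"hsa-mir-absent-{k + 1}"
        tgt_rows.append((m, f"DTGT{k + 1}", "weak evidence"))

    idmap_pairs: list[tuple[str, str]] = []
    n_foreign = min(decoys.get("foreign_id_targets", 0), len(seen_tgt))
    for k in range(n_foreign):
        m, t, ev = tgt_rows[k]
        foreign = f"NM_{100000 + k}"
        tgt_rows[k] = (m, foreign, ev)
        idmap_pairs.append((foreign, t))

    symbols = {r for r, _, _, _ in reg_rows} | {t for _, t, _ in tgt_rows if not t.startswith("NM_")}
    symbols |= {t for _, t in idmap_pairs}
    idmap_pairs.extend((s, s) for s in sorted(symbols))

    targets = pd.DataFrame(tgt_rows, columns=["mirna", "target", "evidence"])
    regulators = pd.DataFrame(reg_rows, columns=["regulator", "role", "direction", "mirna"])
    idmap = pd.DataFrame(sorted(set(idmap_pairs)), columns=["foreign_id", "gene_symbol"])
    return targets, regulators, idmap


def tf_signaling_annotation(truth: SyntheticTruth) -> list[str]:
    """The TF/signaling gene annotation list accompanying the synthetic
    knowledge base: planted targets are TF-/signaling-encoding genes by
    construction (decoy targets deliberately are not)."""
    return sorted({t for _, _, _, _, t in truth.planted_circuits})


def generate_corpus(truth: SyntheticTruth, config: SimulationConfig) -> Corpus:
    """Document corpus with planted gene-term co-occurrence.

    Each document includes every gene independently with probability
    ``doc_gene_prob`` and every MeSH term with probability
    ``doc_term_prob``; each planted (gene, term) association is then
    co-injected into ``min_cooccurrence`` randomly chosen documents.
    Deterministic under the config seed.
    """
    if config.n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    rng = rng_for(config.seed, "corpus")
    genes = gene_names(config.n_mrna)
    terms = list(MESH_TERMS)
    gene_hits = rng.random((config.n_docs, len(genes))) < config.doc_gene_prob
    term_hits = rng.random((config.n_docs, len(terms))) < config.doc_term_prob
    doc_genes = [set(np.array(genes)[row]) for row in gene_hits]
    doc_terms = [set(np.array(terms)[row]) for row in term_hits]
    n_inject = min(config.min_cooccurrence, config.n_docs)
    for gene, term in sorted(set(truth.planted_associations)):
        chosen = rng.choice(config.n_docs, size=n_inject, replace=False)
        for d in chosen:
            doc_genes[d].add(gene)
            doc_terms[d].add(term)
    docs = [
        Document(f"doc{i + 1:04d}", frozenset(doc_genes[i]), frozenset(doc_terms[i]))
        for i in range(config.n_docs)
    ]
    return Corpus(docs)
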