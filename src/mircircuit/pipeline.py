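"""End-to-end orchestration: simulate/load inputs, normalize, fold changes,
assemble and refine circuits, attach contexts, validate, cluster, export.

Every stage's counts land in a machine-readable JSON run report; a fixed
(config, seed) pair reproduces the report and all exports byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Union

import yaml

from . import clustering as cl
from . import context_mining as cm
from . import expression as ex
from . import knowledge_base as kb
from . import network as nw
from . import synthetic as syn
from . import validation as vd
from ._rng import child_seed

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_simulated_inputs"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one run.

    Defaults follow the reference analysis: 5000 node-label permutations,
    top 10 clusters of size >= 5, inflation 2.0, sign-only inverse
    condition.
    """

    outdir: str = "mircircuit_run"
    simulate: bool = True
    # input paths (required when simulate is False; filled in by simulation otherwise)
    mirna_expression: str | None = None
    mrna_expression: str | None = None
    target_table: str | None = None
    regulator_table: str | None = None
    identifier_map: str | None = None
    corpus: str | None = None
    tf_signaling_list: str | None = None
    # analysis parameters
    contrasts: dict[str, tuple[str, str]] = dataclasses.field(
        default_factory=lambda: dict(ex.CONTRASTS)
    )
    min_abs_log2fc: float = 0.0
    min_count: int = 1
    max_p: float = 0.05
    bh_correct: bool = False
    n_perm: int = 5000
    inflation: float = 2.0
    top_k: int = 10
    min_cluster_size: int = 5
    seed: int = 0
    simulation: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        if "contrasts" in obj:
            obj["contrasts"] = {cid: tuple(pair) for cid, pair in obj["contrasts"].items()}
        return cls(**obj)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = {cid: list(pair) for cid, pair in self.contrasts.items()}
        return d


def write_simulated_inputs(config: PipelineConfig) -> tuple[PipelineConfig, syn.SyntheticTruth]:
    """Generate all inputs with planted structure and write them under
    ``<outdir>/inputs``; returns the config updated with the input paths."""
    sim_kwargs = dict(config.simulation)
    plant_kwargs = sim_kwargs.pop("plant", {})
    sim_kwargs.setdefault("seed", child_seed(config.seed, "simulation"))
    sim = syn.SimulationConfig(**sim_kwargs)
    truth = syn.plant_truth(sim, **plant_kwargs)

    indir = Path(config.outdir) / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    mi, ge = syn.generate_expression(sim, truth)
    mi.to_tsv(indir / "mirna_expression.tsv")
    ge.to_tsv(indir / "mrna_expression.tsv")
    targets, regulators, idmap = syn.generate_knowledge_base(truth, sim)
    targets.to_csv(indir / "targets.tsv", sep="\t", index=False)
    regulators.to_csv(indir / "regulators.tsv", sep="\t", index=False)
    idmap.to_csv(indir / "identifier_map.tsv", sep="\t", index=False)
    (indir / "tf_signaling.txt").write_text("\n".join(syn.tf_signaling_annotation(truth)) + "\n")
    syn.generate_corpus(truth, sim).to_jsonl(indir / "corpus.jsonl")
    truth.to_json(indir / "truth.json")

    updated = dataclasses.replace(
        config,
        mirna_expression=str(indir / "mirna_expression.tsv"),
        mrna_expression=str(indir / "mrna_expression.tsv"),
        target_table=str(indir / "targets.tsv"),
        regulator_table=str(indir / "regulators.tsv"),
        identifier_map=str(indir / "identifier_map.tsv"),
        corpus=str(indir / "corpus.jsonl"),
        tf_signaling_list=str(indir / "tf_signaling.txt"),
    )
    return updated, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    stages = report["stages"]
    truth: syn.SyntheticTruth | None = None

    stage = "simulate"
    try:
        if config.simulate:
            config, truth = write_simulated_inputs(config)
            stages["simulate"] = {
                "planted_circuits": len(truth.planted_circuits),
                "planted_inverse_pairs": len(truth.planted_inverse_pairs),
                "planted_clusters": len(truth.planted_clusters),
                "planted_associations": len(truth.planted_associations),
            }
        report["config"] = config.to_dict()

        stage = "normalize"
        mi = ex.quantile_normalize(ex.ExpressionMatrix.from_tsv(config.mirna_expression, "miRNA"))
        ge = ex.quantile_normalize(ex.ExpressionMatrix.from_tsv(config.mrna_expression, "mRNA"))
        stages["normalize"] = {"n_mirna": len(mi.values), "n_mrna": len(ge.values)}

        stage = "fold_change"
        fc_mi = ex.fold_change_table(mi, config.contrasts)
        fc_ge = ex.fold_change_table(ge, config.contrasts)
        stages["fold_change"] = {"contrasts": sorted(config.contrasts)}

        stage = "knowledge_base"
        targets = kb.canonicalize_records(kb.read_target_table(config.target_table))
        regulators = kb.canonicalize_records(kb.read_regulator_table(config.regulator_table))
        idmap = kb.IdentifierMap.from_tsv(config.identifier_map)
        targets, unmapped_t = kb.map_identifiers(targets, idmap, "target")
        regulators, unmapped_r = kb.map_identifiers(regulators, idmap, "regulator")
        extra = []
        if config.tf_signaling_list:
            extra = [
                line.strip()
                for line in Path(config.tf_signaling_list).read_text().splitlines()
                if line.strip()
            ]
        universe = kb.tf_signaling_universe(regulators, extra)
        stages["knowledge_base"] = {
            "target_records": len(targets),
            "regulator_records": len(regulators),
            "unmapped": len(unmapped_t) + len(unmapped_r),
            "universe_size": len(universe),
        }

        stage = "circuit_assembly"
        circuits = nw.assemble_circuits(regulators, targets, universe)
        if not circuits:
            raise ValueError("no circuits could be assembled from the evidence tables")
        stages["circuit_assembly"] = {"assembled_circuits": len(circuits)}

        stage = "inverse_refinement"
        retained = nw.refine_circuits(circuits, fc_mi, fc_ge, config.min_abs_log2fc)
        stages["inverse_refinement"] = {
            "retained_circuits": len(retained),
            "retained_triples": sorted(["|".join(c.triple) for c in retained]),
        }
        if truth is not None:
            planted = truth.circuit_triples
            found = {c.triple for c in retained}
            stages["inverse_refinement"]["recall_vs_planted"] = (
                len(planted & found) / len(planted) if planted else None
            )
            stages["inverse_refinement"]["precision_vs_planted"] = (
                len(planted & found) / len(found) if found else None
            )

        stage = "context_edges"
        corpus = cm.Corpus.from_jsonl(config.corpus)
        circuit_genes = sorted({c.regulator for c in retained} | {c.target for c in retained})
        assoc = cm.build_context_edges(
            corpus,
            circuit_genes,
            min_count=config.min_count,
            max_p=config.max_p,
            bh_correct=config.bh_correct,
        )
        assoc.to_csv(outdir / "context_edges.tsv", sep="\t", index=False)
        stages["context_edges"] = {"n_edges": len(assoc), "n_docs": corpus.n_docs}

        stage = "network_build"
        net = nw.build_network(retained, assoc, fc_mi, fc_ge)
        stages["network_build"] = {
            "nodes": net.n_nodes,
            "edges": net.n_edges,
            "mirna_nodes": len(net.nodes_of_type(nw.NODE_MIRNA)),
            "gene_nodes": len(net.nodes_of_type(nw.NODE_GENE)),
            "context_nodes": len(net.nodes_of_type(nw.NODE_CONTEXT)),
            "associations_dropped": net.graph.graph["n_associations_dropped"],
        }

        stage = "validation"
        result = vd.permutation_test(
            net, mi, ge, n_perm=config.n_perm, seed=child_seed(config.seed, "permutation")
        )
        result.save_json(outdir / "validation.json")
        stages["validation"] = result.to_dict()

        stage = "clustering"
        clusters = cl.mcl(net, inflation=config.inflation)
        orphansless = cl.non_orphan(clusters)
        selected = cl.select_top(clusters, k=config.top_k, min_size=config.min_cluster_size)
        clusters.save_json(outdir / "clusters.json")
        stages["clustering"] = {
            "total_clusters": len(clusters.clusters),
            "non_orphan_clusters": len(orphansless),
            "selected_clusters": len(selected),
            "selected_sizes": [len(c) for c in selected],
            "converged": clusters.converged,
        }
        if truth is not None and truth.planted_clusters:
            stages["clustering"]["recovery_vs_planted"] = cl.recovery_score(
                clusters.clusters, [sorted(c) for c in truth.planted_clusters]
            )

        stage = "export"
        nw.export_network(net, outdir / "network.sif", "SIF")
        for cid in sorted(config.contrasts):
            nw.export_network(net, outdir / f"network_{cid}.graphml", "GraphML", contrast=cid)
        stages["export"] = {
            "files": sorted(
                ["network.sif"] + [f"network_{cid}.graphml" for cid in sorted(config.contrasts)]
            )
        }
    except Exception as err:  # noqa: BLE001 - annotate failures with the stage name
        raise PipelineError(stage, err) from err

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: report at %s", outdir / "report.json")
    return report
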