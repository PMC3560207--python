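"""The synthetic-data generator: planted signal, decoys, determinism."""

import numpy as np
import pandas as pd
import pytest

from conftest import bruteforce_triple_join
from mircircuit.context_mining import MESH_TERMS, cooccurrence
from mircircuit.expression import fold_change
from mircircuit.knowledge_base import (
    IdentifierMap,
    RegulatorInteraction,
    TargetInteraction,
    map_identifiers,
    tf_signaling_universe,
)
from mircircuit.network import assemble_circuits
from mircircuit.synthetic import (
    SimulationConfig,
    SyntheticTruth,
    generate_corpus,
    generate_expression,
    generate_knowledge_base,
    gene_names,
    mirna_names,
    plant_truth,
    tf_signaling_annotation,
)


def small_config(**kw):
    base = dict(n_mirna=8, n_mrna=16, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


def small_truth(config, **kw):
    base = dict(n_modules=1, regulators_per_module=1, mirnas_per_module=2, targets_per_module=2)
    base.update(kw)
    return plant_truth(config, **base)


def _kb_records(targets_df, regulators_df):
    targets = [TargetInteraction(r.mirna, r.target, r.evidence) for r in targets_df.itertuples()]
    regulators = [
        RegulatorInteraction(r.regulator, r.role, r.direction, r.mirna)
        for r in regulators_df.itertuples()
    ]
    return targets, regulators


class TestTruth:
    def test_inverse_pairs_subset_of_circuit_pairs(self):
        truth = plant_truth(SimulationConfig())
        truth.validate()

    def test_clusters_disjoint(self):
        truth = plant_truth(SimulationConfig())
        flat = [n for c in truth.planted_clusters for n in c]
        assert len(flat) == len(set(flat))

    def test_json_roundtrip(self, tmp_path):
        truth = plant_truth(SimulationConfig())
        truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.planted_circuits == truth.planted_circuits
        assert back.planted_clusters == truth.planted_clusters

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError, match="miRNA"):
            plant_truth(small_config(), n_modules=5, mirnas_per_module=10)


class TestGenerateExpression:
    def test_planted_fold_change_signs_and_magnitude(self):
        cfg = small_config(noise_sd=0.0, effect_size=1.0)
        truth = small_truth(cfg)
        mi, ge = generate_expression(cfg, truth)
        fc_mi = fold_change(mi, ("T", "parent"), "T_vs_P").set_index("feature_id")
        fc_ge = fold_change(ge, ("T", "parent"), "T_vs_P").set_index("feature_id")
        for m, t, cid in truth.planted_inverse_pairs:
            if cid != "T_vs_P":
                continue
            assert fc_mi.loc[m, "log2fc"] == pytest.approx(-1.0, abs=1e-9)
            assert fc_ge.loc[t, "log2fc"] == pytest.approx(+1.0, abs=1e-9)

    def test_zero_noise_null_features_have_zero_fold_change(self):
        cfg = small_config(noise_sd=0.0)
        truth = small_truth(cfg)
        mi, ge = generate_expression(cfg, truth)
        planted_genes = {t for _, t, _ in truth.planted_inverse_pairs}
        fc_ge = fold_change(ge, ("T", "parent")).set_index("feature_id")
        for g in gene_names(cfg.n_mrna):
            if g not in planted_genes:
                assert fc_ge.loc[g, "log2fc"] == pytest.approx(0.0, abs=1e-9)

    def test_null_fold_changes_within_clt_bound(self):
        """200 unplanted features, noise_sd=0.5: the mean log2fc stays
        within 3 sigma/sqrt(200) of zero (sigma of one feature's log2fc is
        noise_sd*sqrt(1/2 + 1/2) with two replicates per group)."""
        cfg = SimulationConfig(n_mirna=4, n_mrna=200, noise_sd=0.5, seed=13)
        truth = plant_truth(cfg, n_modules=1, regulators_per_module=1,
                            mirnas_per_module=1, targets_per_module=1, coherent=False)
        _, ge = generate_expression(cfg, truth)
        fc = fold_change(ge, ("T", "parent"))["log2fc"].to_numpy()
        sigma = 0.5 * np.sqrt(0.5 + 0.5)
        assert abs(fc.mean()) <= 3 * sigma / np.sqrt(200)

    def test_anticorrelation_strength_controls_pearson(self):
        cfg = SimulationConfig(n_mirna=8, n_mrna=16, n_samples_per_line=40,
                               anticorrelation_strength=0.8, noise_sd=0.5, seed=2)
        truth = small_truth(cfg)
        mi, ge = generate_expression(cfg, truth)
        m, t, _ = truth.planted_inverse_pairs[0]
        x = np.log2(mi.values.loc[m]).to_numpy()
        y = np.log2(ge.values.loc[t]).to_numpy()
        # remove planted group shifts before correlating (many samples/line)
        lines = [c.rsplit(".", 1)[0] for c in mi.values.columns]
        for arr in (x, y):
            for line in set(lines):
                sel = [i for i, l in enumerate(lines) if l == line]
                arr[sel] -= arr[sel].mean()
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(-0.8, abs=0.1)

    def test_unknown_feature_name_rejected_with_name(self):
        cfg = small_config()
        truth = small_truth(cfg)
        truth.planted_inverse_pairs.append(("hsa-mir-999", gene_names(cfg.n_mrna)[0], "T_vs_P"))
        with pytest.raises(ValueError, match="hsa-mir-999"):
            generate_expression(cfg, truth)

    def test_bit_identical_under_same_seed(self):
        cfg = small_config(seed=5)
        truth = small_truth(cfg)
        a = generate_expression(cfg, truth)
        b = generate_expression(cfg, truth)
        pd.testing.assert_frame_equal(a[0].values, b[0].values)
        pd.testing.assert_frame_equal(a[1].values, b[1].values)

    def test_planted_signal_monotone_in_effect_size(self):
        """With common random numbers, raising effect_size shifts each
        planted feature's fold change by exactly the effect difference in
        the planted direction."""
        truths = {}
        fcs = {}
        for effect in (0.5, 1.0, 2.0):
            cfg = small_config(effect_size=effect, seed=3)
            truth = small_truth(cfg)
            truths[effect] = truth
            _, ge = generate_expression(cfg, truth)
            fcs[effect] = fold_change(ge, ("T", "parent")).set_index("feature_id")["log2fc"]
        t0 = {t for _, t, _ in truths[1.0].planted_inverse_pairs}
        for t in t0:
            assert fcs[1.0][t] - fcs[0.5][t] == pytest.approx(0.5, abs=1e-9)
            assert fcs[2.0][t] - fcs[1.0][t] == pytest.approx(1.0, abs=1e-9)


class TestGenerateKnowledgeBase:
    def test_one_circuit_no_decoys_gives_one_row_each(self):
        cfg = small_config()
        truth = plant_truth(cfg, n_modules=1, regulators_per_module=1,
                            mirnas_per_module=1, targets_per_module=1,
                            decoy_counts={})
        targets, regulators, idmap = generate_knowledge_base(truth, cfg)
        assert len(targets) == 1 and len(regulators) == 1

    def test_planted_circuits_recovered_exactly_through_assembly(self):
        """Planted circuits + decoys in, exactly the planted circuits out
        (precision = recall = 1), including the foreign-id mapping step."""
        cfg = small_config()
        truth = small_truth(
            cfg,
            decoy_counts={"absent_mirna_regulators": 8, "non_universe_targets": 8,
                          "foreign_id_targets": 2},
        )
        targets_df, regulators_df, idmap_df = generate_knowledge_base(truth, cfg)
        targets, regulators = _kb_records(targets_df, regulators_df)
        idmap = IdentifierMap.from_pairs(zip(idmap_df.foreign_id, idmap_df.gene_symbol))
        targets, unmapped = map_identifiers(targets, idmap, "target")
        assert not unmapped
        universe = tf_signaling_universe(regulators, tf_signaling_annotation(truth))
        got = {c.triple for c in assemble_circuits(regulators, targets, universe)}
        assert got == truth.circuit_triples
        assert got == bruteforce_triple_join(regulators, targets, universe)

    def test_foreign_ids_require_mapping(self):
        cfg = small_config()
        truth = small_truth(cfg, decoy_counts={"foreign_id_targets": 2})
        targets_df, _, idmap_df = generate_knowledge_base(truth, cfg)
        foreign = [t for t in targets_df.target if t.startswith("NM_")]
        assert len(foreign) == 2
        assert set(foreign) <= set(idmap_df.foreign_id)

    def test_decoy_targets_outside_universe(self):
        cfg = small_config()
        truth = small_truth(cfg, decoy_counts={"non_universe_targets": 4})
        targets_df, regulators_df, _ = generate_knowledge_base(truth, cfg)
        targets, regulators = _kb_records(targets_df, regulators_df)
        universe = tf_signaling_universe(regulators, tf_signaling_annotation(truth))
        decoys = {t.target for t in targets if t.target.startswith("DTGT")}
        assert len(decoys) == 4 and not (decoys & universe)


class TestGenerateCorpus:
    def test_planted_pair_cooccurs_at_least_min_times(self):
        cfg = small_config(n_docs=50, min_cooccurrence=3)
        truth = small_truth(cfg)
        corpus = generate_corpus(truth, cfg)
        for g, t in truth.planted_associations:
            assert cooccurrence(corpus, g, t).n_both >= 3

    def test_deterministic_under_seed(self):
        cfg = small_config(n_docs=30)
        truth = small_truth(cfg)
        c1 = generate_corpus(truth, cfg)
        c2 = generate_corpus(truth, cfg)
        assert c1.documents == c2.documents

    def test_null_pairs_cooccur_only_by_chance(self):
        """With no planted associations, the observed mean co-occurrence
        matches the independence expectation p_gene*p_term*n_docs."""
        cfg = SimulationConfig(n_mirna=4, n_mrna=40, n_docs=400,
                               doc_gene_prob=0.1, doc_term_prob=0.1, seed=21)
        truth = plant_truth(cfg, n_modules=1, regulators_per_module=1,
                            mirnas_per_module=1, targets_per_module=1)
        truth.planted_associations = []
        corpus = generate_corpus(truth, cfg)
        counts = [
            cooccurrence(corpus, g, t).n_both
            for g in gene_names(cfg.n_mrna)
            for t in MESH_TERMS
        ]
        expected = 0.1 * 0.1 * 400
        assert np.mean(counts) == pytest.approx(expected, rel=0.15)

    def test_planted_pairs_rank_above_decoys_across_seeds(self):
        """The planted pair's hypergeometric p beats every decoy pair in at
        least 95 of 100 seeded corpora (at generator defaults)."""
        wins = 0
        for seed in range(100):
            cfg = SimulationConfig(seed=seed)
            truth = plant_truth(cfg)
            corpus = generate_corpus(truth, cfg)
            planted = set(truth.planted_associations)
            p_planted = max(cooccurrence(corpus, g, t).p_value for g, t in planted)
            p_decoy = min(
                cooccurrence(corpus, g, t).p_value
                for g in gene_names(cfg.n_mrna)
                for t in MESH_TERMS
                if (g, t) not in planted
            )
            wins += p_planted < p_decoy
        assert wins >= 95
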