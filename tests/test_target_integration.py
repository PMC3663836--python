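"""Diametric set construction and target over-representation nulls."""

import numpy as np
import pandas as pd
import pytest

import mirgist as mg
from mirgist.io_formats import TargetPair
from mirgist.target_integration import (
    DiametricSets,
    TargetTable,
    exhaustive_gene_set_pvalue,
)


def table(pairs, mirnas, genes):
    return TargetTable(
        frozenset(TargetPair(m, g) for m, g in pairs), frozenset(mirnas), frozenset(genes)
    )


def sets(mirnas, genes, name="all_wt_vs_all_mutant"):
    return DiametricSets(name, frozenset(mirnas), frozenset(genes))


class TestBuildDiametricSets:
    def make_tables(self):
        mirna_de = pd.DataFrame(
            {
                "comparison": ["all_wt_vs_all_mutant"] * 4,
                "feature_id": ["m1", "m2", "m3", "m4"],
                "direction": ["higher_in_b", "higher_in_b", "higher_in_a", "higher_in_b"],
                "significant": [True, True, True, False],
            }
        )
        gene_de = pd.DataFrame(
            {
                "comparison": ["all_wt_vs_all_mutant"] * 5,
                "gene_id": ["g1", "g2", "g3", "g4", "g5"],
                "direction": ["higher_in_a"] * 3 + ["higher_in_b", "higher_in_a"],
                "significant": [True, True, True, True, False],
            }
        )
        return mirna_de, gene_de

    def test_hand_selection(self):
        mirna_de, gene_de = self.make_tables()
        # genes up in WT (side a) pair with miRNAs down in WT (higher in mutant, side b)
        s = mg.build_diametric_sets(mirna_de, gene_de, "genes_up_in_wt__mirs_down_in_wt")
        assert s.mirnas_down == {"m1", "m2"}
        assert s.genes_up == {"g1", "g2", "g3"}

    def test_no_significant_features_empty_sets(self):
        mirna_de, gene_de = self.make_tables()
        mirna_de["significant"] = False
        gene_de["significant"] = False
        s = mg.build_diametric_sets(mirna_de, gene_de, "genes_up_in_wt__mirs_down_in_wt")
        assert s.mirnas_down == frozenset() and s.genes_up == frozenset()

    def test_missing_comparison_is_error(self):
        mirna_de, gene_de = self.make_tables()
        with pytest.raises(ValueError, match="adult_mutant_vs_pediatric"):
            mg.build_diametric_sets(
                mirna_de, gene_de, "genes_up_in_pediatric__mirs_down_in_pediatric"
            )


class TestCounting:
    def test_enumeration_by_hand(self):
        t = table([("m1", "g1"), ("m2", "g3")], ["m1", "m2"], ["g1", "g2", "g3"])
        assert mg.count_predicted_interactions(sets(["m1", "m2"], ["g1", "g2"]), t) == 1

    def test_empty_and_total(self):
        t = table([("m1", "g1"), ("m2", "g2")], ["m1", "m2"], ["g1", "g2"])
        assert mg.count_predicted_interactions(sets([], ["g1"]), t) == 0
        assert mg.count_predicted_interactions(sets(["m1", "m2"], ["g1", "g2"]), t) == 2

    def test_id_outside_universe(self):
        t = table([("m1", "g1")], ["m1"], ["g1"])
        with pytest.raises(ValueError, match="outside"):
            mg.count_predicted_interactions(sets(["mX"], ["g1"]), t)

    def test_count_symmetric_in_sets(self):
        rng = np.random.default_rng(0)
        mirnas = [f"m{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(12)]
        pairs = [(m, g) for m in mirnas for g in genes if rng.random() < 0.3]
        t = table(pairs, mirnas, genes)
        s = sets(mirnas[:4], genes[:5])
        via_genes = sum(
            1 for p in t.pairs if p.gene_id in s.genes_up and p.mirna_id in s.mirnas_down
        )
        assert mg.count_predicted_interactions(s, t) == via_genes


class TestEnrichment:
    def test_symmetric_toy_not_enriched(self):
        # every gene targeted by exactly one set-miRNA: any same-size gene
        # draw yields the same count, so p = 1
        t = table([("m1", "g1"), ("m1", "g2"), ("m1", "g3"), ("m1", "g4")],
                  ["m1"], ["g1", "g2", "g3", "g4"])
        r = mg.interaction_enrichment(sets(["m1"], ["g1", "g2"]), t, seed=0, n_permutations=200)
        assert r.p_value >= 0.5

    def test_permutation_matches_exhaustive_on_tiny_universe(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(5)]
        mirnas = ["m1", "m2"]
        pairs = [(m, g) for m in mirnas for g in genes if rng.random() < 0.5]
        t = table(pairs, mirnas, genes)
        s = sets(mirnas, genes[:2])
        exact = exhaustive_gene_set_pvalue(s, t)
        r = mg.interaction_enrichment(s, t, n_permutations=10_000, seed=11)
        # Monte-Carlo error at B = 10000 over C(5,2) = 10 exhaustive subsets
        assert r.p_value == pytest.approx(exact, abs=0.02)

    def test_hypergeometric_expectation_formula(self):
        t = table([("m1", "g1"), ("m1", "g2"), ("m2", "g1")],
                  ["m1", "m2"], ["g1", "g2", "g3", "g4"])
        s = sets(["m1", "m2"], ["g1", "g2"])
        r = mg.interaction_enrichment(s, t, null_kind="hypergeometric")
        # sum_m deg(m) * |genes_up| / |G| = 3 * 2 / 4
        assert r.expected == pytest.approx(1.5)
        assert 0 < r.p_value <= 1

    def test_seeded_determinism(self, cohort):
        s = DiametricSets(
            "all_wt_vs_all_mutant", cohort.truth.enriched_mirnas, cohort.truth.enriched_genes
        )
        r1 = mg.interaction_enrichment(s, cohort.targets, seed=5, n_permutations=2000)
        r2 = mg.interaction_enrichment(s, cohort.targets, seed=5, n_permutations=2000)
        assert r1 == r2

    def test_gene_relabelling_invariance(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(20)]
        pairs = [("m1", g) for g in genes if rng.random() < 0.4] + [("m2", genes[0])]
        t1 = table(pairs, ["m1", "m2"], genes)
        relabel = {g: f"X{g}" for g in genes}
        t2 = table([(m, relabel[g]) for m, g in pairs], ["m1", "m2"],
                   [relabel[g] for g in genes])
        s1 = sets(["m1", "m2"], genes[:5])
        s2 = sets(["m1", "m2"], [relabel[g] for g in genes[:5]])
        r1 = mg.interaction_enrichment(s1, t1, seed=2, n_permutations=5000)
        r2 = mg.interaction_enrichment(s2, t2, seed=2, n_permutations=5000)
        assert r1.observed == r2.observed
        assert r1.p_value == pytest.approx(r2.p_value, abs=0.02)

    def test_too_few_permutations_rejected(self, cohort):
        s = DiametricSets("x", cohort.truth.enriched_mirnas, cohort.truth.enriched_genes)
        with pytest.raises(ValueError, match="n_permutations"):
            mg.interaction_enrichment(s, cohort.targets, n_permutations=50)

    def test_planted_enrichment_detected(self):
        """Planted 5x target density inside the diametric sets is detected
        (p < 0.05) in >= 95% of replicates at default sizes."""
        detected = 0
        reps = 40
        for seed in range(reps):
            cohort = mg.simulate_cohort(mg.SimConfig(seed=1000 + seed))
            s = DiametricSets(
                "all_wt_vs_all_mutant",
                cohort.truth.enriched_mirnas,
                cohort.truth.enriched_genes,
            )
            r = mg.interaction_enrichment(s, cohort.targets, seed=seed, n_permutations=1000)
            detected += r.p_value < 0.05
        assert detected / reps >= 0.95

    def test_type_one_error_at_background_density(self):
        """With planted density equal to background the test is calibrated:
        rejection rate <= 6%."""
        rejected = 0
        reps = 100
        cfg_kwargs = dict(target_density_planted=0.02)
        for seed in range(reps):
            cohort = mg.simulate_cohort(mg.SimConfig(seed=2000 + seed, **cfg_kwargs))
            s = DiametricSets(
                "all_wt_vs_all_mutant",
                cohort.truth.enriched_mirnas,
                cohort.truth.enriched_genes,
            )
            r = mg.interaction_enrichment(s, cohort.targets, seed=seed, n_permutations=1000)
            rejected += r.p_value < 0.05
        assert rejected / reps <= 0.06 + 2.5 * np.sqrt(0.06 * 0.94 / reps)
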