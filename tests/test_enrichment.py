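"""Gene statistics, ranking, running-sum ES and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathgwas.containers import UntestableSetError
from pathgwas.enrichment import (
    GeneSet,
    enrichment_score,
    gene_statistics,
    permutation_test,
    rank_genes,
    run_pathway_analysis,
)
from pathgwas.enrichment import _summarise, EnrichmentScore, RunningSumProfile
from pathgwas.simulate import (
    SimulationConfig,
    plant_effects,
    simulate_annotation,
    simulate_cohort,
)

from conftest import es_oracle, random_ranked_instance


def _results_frame(rows):
    """Minimal association-scan frame: (snp_id, p, flagged)."""
    df = pd.DataFrame(rows, columns=["snp_id", "p", "flagged"])
    df["flag_reason"] = np.where(df["flagged"], "separation", "")
    return df


class TestGeneStatistics:
    def test_min_p_and_neglog10(self):
        res = _results_frame(
            [("a1", 0.5, False), ("a2", 0.01, False), ("a3", 0.2, False)]
        )
        out = gene_statistics(res, {"a1": "G", "a2": "G", "a3": "G"})
        assert len(out) == 1
        assert out.loc[0, "best_snp_id"] == "a2"
        assert out.loc[0, "p_min"] == 0.01
        assert out.loc[0, "r"] == pytest.approx(2.0)

    def test_tied_p_breaks_to_smaller_snp_id(self):
        res = _results_frame([("z9", 0.05, False), ("a1", 0.05, False)])
        out = gene_statistics(res, {"z9": "G", "a1": "G"})
        assert out.loc[0, "best_snp_id"] == "a1"

    def test_uncovered_and_discarded_genes_are_omitted(self):
        """38-gene set: 4 genes unannotated, 2 lose every SNP → 32 genes enter."""
        genes = [f"G{i:02d}" for i in range(38)]
        mapped = genes[:34]  # 4 genes never had array coverage
        rows, mapping = [], {}
        for i, g in enumerate(mapped):
            snp = f"s{i:02d}"
            mapping[snp] = g
            rows.append((snp, 0.01 * (i + 1), g in mapped[:2]))  # first 2 genes flagged out
        out = gene_statistics(_results_frame(rows), mapping)
        assert len(out) == 32
        assert set(out["gene_id"]) == set(mapped[2:])
        assert GeneSet("path", tuple(genes)).effective_size(out["gene_id"]) == 32

    def test_flagged_snps_never_represent_a_gene(self):
        res = _results_frame([("s1", 1e-9, True), ("s2", 0.3, False)])
        out = gene_statistics(res, {"s1": "G", "s2": "G"})
        assert out.loc[0, "best_snp_id"] == "s2"

    def test_empty_results(self):
        assert gene_statistics(_results_frame([]), {}).empty


class TestRankGenes:
    def test_orders_descending(self):
        stats = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "best_snp_id": ["x"] * 3, "p_min": [0.1] * 3,
             "r": [1.0, 3.0, 2.0]}
        )
        assert list(rank_genes(stats)["gene_id"]) == ["b", "c", "a"]

    def test_ties_break_lexicographically(self):
        stats = pd.DataFrame(
            {"gene_id": ["c", "a", "b"], "best_snp_id": ["x"] * 3, "p_min": [0.1] * 3,
             "r": [1.0, 1.0, 1.0]}
        )
        assert list(rank_genes(stats)["gene_id"]) == ["a", "b", "c"]

    def test_duplicates_error_and_empty_passes(self):
        stats = pd.DataFrame({"gene_id": ["a", "a"], "r": [1.0, 2.0]})
        with pytest.raises(ValueError):
            rank_genes(stats)
        assert rank_genes(pd.DataFrame(columns=["gene_id", "r"])).empty


class TestEnrichmentScore:
    def test_single_member_at_top(self):
        ranked = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "r": [3.0, 2.0, 1.0]})
        out = enrichment_score(ranked, GeneSet("s", ("g1",)))
        assert out.es == pytest.approx(1.0, abs=1e-12)  # +3/3 then -1/2, -1/2
        assert out.leading_edge == ("g1",)

    def test_two_member_walk(self):
        ranked = pd.DataFrame({"gene_id": ["g1", "g2", "g3", "g4"], "r": [4.0, 3.0, 2.0, 1.0]})
        out = enrichment_score(ranked, GeneSet("s", ("g1", "g3")))
        # +4/6, -1/2, +2/6, -1/2 → peak 2/3 at position 1
        assert out.es == pytest.approx(2 / 3, abs=1e-12)
        assert out.leading_edge == ("g1",)
        np.testing.assert_allclose(
            out.profile.values, [4 / 6, 4 / 6 - 1 / 2, 4 / 6 - 1 / 2 + 2 / 6, 0.0], atol=1e-12
        )

    def test_unweighted_ks(self):
        ranked = pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "r": [3.0, 2.0, 1.0]})
        out = enrichment_score(ranked, GeneSet("s", ("g2",)), weight_p=0.0)
        assert out.es == pytest.approx(0.5, abs=1e-12)  # -1/2, +1, -1/2

    def test_untestable_and_saturated_sets(self):
        ranked = pd.DataFrame({"gene_id": ["g1", "g2"], "r": [2.0, 1.0]})
        with pytest.raises(UntestableSetError):
            enrichment_score(ranked, GeneSet("s", ("zz",)))
        with pytest.raises(ValueError):
            enrichment_score(ranked, GeneSet("s", ("g1", "g2")))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            ranked, members = random_ranked_instance(rng)
            out = enrichment_score(ranked, GeneSet("s", tuple(members)))
            es, values = es_oracle(
                list(ranked["gene_id"]), list(ranked["r"]), members
            )
            assert out.es == pytest.approx(es, abs=1e-12)
            np.testing.assert_allclose(out.profile.values, values, atol=1e-12)

    @given(
        n=st.integers(3, 30),
        n_s=st.integers(1, 10),
        scale=st.floats(0.01, 100.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_invariance_and_closure(self, n, n_s, scale, seed):
        """ES depends on r only through relative magnitudes; the walk closes at 0."""
        rng = np.random.default_rng(seed)
        n_s = min(n_s, n - 1)
        r = np.sort(rng.exponential(1.0, size=n))[::-1] + 1e-6
        genes = [f"g{j}" for j in range(n)]
        members = tuple(rng.choice(genes, size=n_s, replace=False))
        ranked = pd.DataFrame({"gene_id": genes, "r": r})
        scaled = pd.DataFrame({"gene_id": genes, "r": r * scale})
        a = enrichment_score(ranked, GeneSet("s", members))
        b = enrichment_score(scaled, GeneSet("s", members))
        assert a.es == pytest.approx(b.es, rel=1e-9)
        assert abs(a.profile.values[-1]) < 1e-10
        assert 0.0 <= a.es <= 1.0 + 1e-12

    def test_es_is_one_iff_members_fill_the_top(self):
        genes = [f"g{j}" for j in range(6)]
        r = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        ranked = pd.DataFrame({"gene_id": genes, "r": r})
        top = enrichment_score(ranked, GeneSet("s", tuple(genes[:3])))
        assert top.es == pytest.approx(1.0, abs=1e-12)
        assert top.leading_edge == tuple(genes[:3])
        split = enrichment_score(ranked, GeneSet("s", (genes[0], genes[4])))
        assert split.es < 1.0


def _null_cohort(n_subjects=260, n_genes=40, snps_per_gene=2, seed=0):
    truth = simulate_annotation(n_genes, snps_per_gene, [10, 10], seed=seed)
    cfg = SimulationConfig(
        n_subjects=n_subjects, snp_mafs=[0.3] * (n_genes * snps_per_gene),
        missing_rate=0.02, seed=seed + 1,
    )
    geno, pheno = simulate_cohort(cfg)
    return truth, geno, pheno


class TestPermutation:
    def test_nominal_p_counts_ties_as_extreme(self):
        score = EnrichmentScore(
            es=0.5,
            profile=RunningSumProfile(("a",), np.array([0.5]), 1.0),
            leading_edge=("a",),
        )
        perm = np.array([0.5, 0.6, 0.4, 0.7])
        res = _summarise(score, perm, "s", 1, 4, 0)
        assert res.nominal_p == pytest.approx(3 / 4)
        low = _summarise(score, np.array([0.6, 0.7, 0.8]), "s", 1, 3, 0)
        assert low.nominal_p == 1.0  # observed below every permuted score

    def test_nes_normalisation(self):
        c = 0.25
        score = EnrichmentScore(
            es=1.76 * c,
            profile=RunningSumProfile(("a",), np.array([1.76 * c]), 1.0),
            leading_edge=("a",),
        )
        res = _summarise(score, np.full(100, c), "s", 1, 100, 0)
        assert res.nes == pytest.approx(1.76, rel=1e-12)

    def test_permutation_test_is_deterministic(self):
        truth, geno, pheno = _null_cohort()
        gs = GeneSet("SET1", truth.gene_sets["SET1"])
        kwargs = dict(
            snp_gene_map=truth.snp_gene_map, gene_set=gs, k_permutations=25, seed=42
        )
        a = permutation_test(geno, pheno["status"].to_numpy(), pheno[["age", "sex"]], **kwargs)
        b = permutation_test(geno, pheno["status"].to_numpy(), pheno[["age", "sex"]], **kwargs)
        assert a.es == b.es and a.nominal_p == b.nominal_p and a.nes == b.nes
        np.testing.assert_array_equal(a.perm_es, b.perm_es)
        assert len(a.perm_es) == 25
        assert a.nominal_p == (a.perm_es >= a.es).mean()

    def test_multi_set_driver_matches_single_set(self):
        truth, geno, pheno = _null_cohort(seed=3)
        gs = GeneSet("SET1", truth.gene_sets["SET1"])
        single = permutation_test(
            geno, pheno["status"].to_numpy(), pheno[["age", "sex"]],
            truth.snp_gene_map, gs, k_permutations=20, seed=7,
        )
        table, results = run_pathway_analysis(
            geno, pheno["status"].to_numpy(), pheno[["age", "sex"]],
            truth.snp_gene_map, [gs], k_permutations=20, seed=7,
        )
        assert len(table) == 1
        assert table.loc[0, "es"] == single.es
        assert table.loc[0, "nominal_p"] == single.nominal_p
        assert table.loc[0, "nes"] == single.nes
        np.testing.assert_array_equal(results[0].perm_es, single.perm_es)

    def test_two_sets_share_one_permutation_stream(self):
        truth, geno, pheno = _null_cohort(seed=5)
        sets = [GeneSet(n, truth.gene_sets[n]) for n in ("SET1", "SET2")]
        table, results = run_pathway_analysis(
            geno, pheno["status"].to_numpy(), pheno[["age", "sex"]],
            truth.snp_gene_map, sets, k_permutations=30, seed=9,
        )
        assert list(table["set"]) == ["SET1", "SET2"]
        for res in results:
            assert 0.0 <= res.nominal_p <= 1.0
            assert len(res.perm_es) == 30

    def test_empty_set_list_and_zero_permutations_error(self):
        truth, geno, pheno = _null_cohort(seed=6)
        with pytest.raises(ValueError):
            run_pathway_analysis(
                geno, pheno["status"].to_numpy(), pheno[["age", "sex"]],
                truth.snp_gene_map, [], k_permutations=10, seed=0,
            )
        with pytest.raises(ValueError):
            permutation_test(
                geno, pheno["status"].to_numpy(), pheno[["age", "sex"]],
                truth.snp_gene_map, GeneSet("SET1", truth.gene_sets["SET1"]),
                k_permutations=0, seed=0,
            )

    def test_gene_label_mode_is_fast_approximation(self):
        truth, geno, pheno = _null_cohort(seed=8)
        res = permutation_test(
            geno, pheno["status"].to_numpy(), pheno[["age", "sex"]],
            truth.snp_gene_map, GeneSet("SET1", truth.gene_sets["SET1"]),
            k_permutations=500, seed=10, mode="gene",
        )
        assert 0.0 <= res.nominal_p <= 1.0
        assert len(res.perm_es) == 500

    def test_planted_pathway_is_detected(self):
        """Strong planted effects in the truth set give small p and the causal
        genes in the leading edge."""
        truth = simulate_annotation(60, 2, [15], seed=21)
        effects = plant_effects(truth, 5, np.log(2.2), seed=22)
        cfg = SimulationConfig(
            n_subjects=900, snp_mafs=[0.3] * 120, effect_map=effects, seed=23
        )
        geno, pheno = simulate_cohort(cfg)
        res = permutation_test(
            geno, pheno["status"].to_numpy(), pheno[["age", "sex"]],
            truth.snp_gene_map, GeneSet("SET1", truth.gene_sets["SET1"]),
            k_permutations=99, seed=24,
        )
        causal_genes = {truth.snp_gene_map[s] for s in effects}
        assert res.nominal_p <= 0.05
        assert len(causal_genes & set(res.leading_edge)) >= 3
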