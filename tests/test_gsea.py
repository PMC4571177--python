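import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xsmono import gsea
from xsmono.io_formats import GeneSetCollection, RankedList

import oracles


def _random_instance(rng, n_max=50, set_max=10):
    n = int(rng.integers(3, n_max + 1))
    genes = [f"g{i:03d}" for i in range(n)]
    scores = np.round(rng.normal(size=n), 3)
    if rng.random() < 0.3:  # inject ties and zeros to stress tie handling
        scores[rng.integers(0, n, size=max(1, n // 4))] = 0.0
    ranked = RankedList.from_scores(genes, scores)
    m = int(rng.integers(1, min(set_max, n - 1) + 1))
    members = list(rng.choice(ranked.genes, size=m, replace=False))
    return ranked, members


class TestEnrichmentScore:
    def test_single_top_hit_saturates(self, three_gene_ranked):
        prof = gsea.enrichment_score(three_gene_ranked, ["g1"])
        assert prof.es == 1.0
        np.testing.assert_allclose(prof.running_sum, [1.0, 0.5, 0.0])
        assert prof.peak_index == 1

    def test_single_bottom_hit(self, three_gene_ranked):
        prof = gsea.enrichment_score(three_gene_ranked, ["g3"])
        assert prof.es == -1.0
        np.testing.assert_allclose(prof.running_sum, [-0.5, -1.0, 0.0])
        assert prof.peak_index == 2

    @pytest.mark.parametrize("exponent", [0.0, 1.0])
    def test_matches_brute_force(self, exponent):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ranked, members = _random_instance(rng)
            prof = gsea.enrichment_score(ranked, members, exponent)
            hits = set(members)
            es, peak = oracles.brute_es(
                ranked.scores, [g in hits for g in ranked.genes], exponent
            )
            assert prof.es == pytest.approx(es, abs=1e-12)
            # peak must carry the ES value (indices may differ on exact-tie
            # plateaus where summation order perturbs the last ulp)
            assert prof.running_sum[prof.peak_index - 1] == pytest.approx(es, abs=1e-12)

    def test_matches_external_reference(self):
        # independently cross-checked against a widely used enrichment tool
        gseapy = pytest.importorskip("gseapy")
        import pandas as pd

        rng = np.random.default_rng(5)
        genes = [f"g{i:03d}" for i in range(200)]
        ranked = RankedList.from_scores(genes, np.sort(rng.normal(size=200))[::-1])
        members = list(rng.choice(ranked.genes, size=20, replace=False))
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": ranked.genes, "score": ranked.scores}),
            gene_sets={"S": members}, permutation_num=4, min_size=1, max_size=500,
            seed=1, outdir=None, no_plot=True, weight=1.0,
        ).res2d
        assert gsea.enrichment_score(ranked, members).es == pytest.approx(
            float(res["ES"].iloc[0]), abs=1e-9
        )

    def test_unweighted_telescopes_to_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ranked, members = _random_instance(rng)
            prof = gsea.enrichment_score(ranked, members, exponent=0.0)
            assert prof.running_sum[-1] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_unweighted(self):
        # needs tie-free scores: reversal is only exact when the flipped
        # list is the exact mirror of the original order
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            ranked = RankedList.from_scores(
                [f"g{i:03d}" for i in range(n)], rng.normal(size=n)
            )
            members = list(rng.choice(ranked.genes, size=int(rng.integers(1, n // 2)), replace=False))
            flipped = RankedList.from_scores(ranked.genes, -ranked.scores)
            prof = gsea.enrichment_score(ranked, members, 0.0)
            prof_f = gsea.enrichment_score(flipped, members, 0.0)
            # mirror property: the flipped running sum is the negated
            # reversal of the original (up to the final telescoped zero)
            np.testing.assert_allclose(
                prof_f.running_sum[:-1], -prof.running_sum[-2::-1], atol=1e-12
            )
            assert abs(prof_f.es) == pytest.approx(abs(prof.es), abs=1e-12)
            # the sign flips whenever the extremum is untied
            if not np.isclose(prof.running_sum.max(), -prof.running_sum.min(), atol=1e-12):
                assert prof_f.es == pytest.approx(-prof.es, abs=1e-12)

    def test_absent_set_rejected(self, three_gene_ranked):
        with pytest.raises(ValueError, match="not represented"):
            gsea.enrichment_score(three_gene_ranked, ["zz"])

    def test_full_cover_rejected(self, three_gene_ranked):
        with pytest.raises(ValueError, match="whole ranked list"):
            gsea.enrichment_score(three_gene_ranked, ["g1", "g2", "g3"])

    def test_all_zero_scores_fall_back_to_uniform(self):
        ranked = RankedList.from_scores(list("abcd"), [1.0, 0.0, 0.0, -1.0])
        prof = gsea.enrichment_score(ranked, ["b", "c"], exponent=1.0)
        # both hits carry weight 0^1: increments fall back to 1/N_H
        np.testing.assert_allclose(prof.running_sum, [-0.5, 0.0, 0.5, 0.0])


class TestLeadingEdge:
    def test_positive_peak(self, three_gene_ranked):
        prof = gsea.enrichment_score(three_gene_ranked, ["g1"])
        assert gsea.leading_edge(prof, three_gene_ranked, ["g1"]) == ["g1"]

    def test_negative_peak(self, three_gene_ranked):
        prof = gsea.enrichment_score(three_gene_ranked, ["g3"])
        assert gsea.leading_edge(prof, three_gene_ranked, ["g3"]) == ["g3"]

    def test_strict_subset_when_peak_precedes_last_member(self):
        ranked = RankedList.from_scores([f"g{i}" for i in range(10)], np.arange(10.0, 0.0, -1))
        members = ["g0", "g1", "g9"]
        prof = gsea.enrichment_score(ranked, members)
        edge = gsea.leading_edge(prof, ranked, members)
        assert set(edge) < set(members)
        assert edge == ["g0", "g1"]


class TestGseaTest:
    def test_add_one_convention(self):
        perm = np.full(100, 0.1)
        assert gsea._permutation_p(perm, 0.9) == pytest.approx(1.0 / 101.0)

    def test_deterministic_under_seed(self, random_matrix_factory, small_collection):
        m = random_matrix_factory(n_genes=50, seed=2)
        coll = GeneSetCollection.from_dict(
            {"S1": [f"g{i:05d}" for i in range(5)], "S2": [f"g{i:05d}" for i in range(10, 25)]}
        )
        a = gsea.gsea_test(m, coll, scheme="gene_set", n_perm=150, seed=9)
        b = gsea.gsea_test(m, coll, scheme="gene_set", n_perm=150, seed=9)
        assert [(r.set_name, r.es, r.nes, r.p_value, r.fdr_q, r.leading_edge) for r in a] == [
            (r.set_name, r.es, r.nes, r.p_value, r.fdr_q, r.leading_edge) for r in b
        ]

    def test_phenotype_scheme_runs_for_large_groups(self, random_matrix_factory):
        m = random_matrix_factory(n_genes=80, n_per_group=(7, 7), seed=4)
        coll = GeneSetCollection.from_dict({"S": [f"g{i:05d}" for i in range(8)]})
        (res,) = gsea.gsea_test(m, coll, n_perm=120, seed=3)  # scheme auto-picked
        assert res.scheme == "phenotype"
        assert 0 < res.p_value <= 1

    def test_small_groups_fall_back_with_warning(self, random_matrix_factory):
        m = random_matrix_factory(n_genes=60, n_per_group=(4, 4), seed=4)
        coll = GeneSetCollection.from_dict({"S": [f"g{i:05d}" for i in range(6)]})
        with pytest.warns(UserWarning, match="gene-set permutation"):
            (res,) = gsea.gsea_test(m, coll, n_perm=120, seed=3)
        assert res.scheme == "gene_set"

    def test_absent_members_dropped_and_counted(self, random_matrix_factory):
        m = random_matrix_factory(n_genes=40, seed=6)
        coll = GeneSetCollection.from_dict({"S": ["g00001", "g00002", "nope1", "nope2"]})
        (res,) = gsea.gsea_test(m, coll, scheme="gene_set", n_perm=100, seed=0)
        assert res.size == 2 and res.n_dropped == 2

    def test_nperm_floor(self, random_matrix_factory, small_collection):
        m = random_matrix_factory(n_genes=30, seed=1)
        with pytest.raises(ValueError, match="at least 100"):
            gsea.gsea_test(m, small_collection, n_perm=50, seed=0)

    def test_null_p_superuniform(self):
        # random sets against a random list: P(p <= a) <= a + 1/(n_perm+1)
        rng = np.random.default_rng(13)
        genes = [f"g{i:03d}" for i in range(300)]
        ranked = RankedList.from_scores(genes, rng.normal(size=300))
        pvals = []
        for k in range(60):
            members = list(rng.choice(genes, size=20, replace=False))
            (res,) = gsea.gsea_test(
                ranked, GeneSetCollection.from_dict({"S": members}),
                scheme="gene_set", n_perm=100, seed=1000 + k,
            )
            pvals.append(res.p_value)
        for alpha in (0.05, 0.1, 0.25):
            frac = np.mean(np.asarray(pvals) <= alpha)
            # 60 replicates: allow three binomial sd of slack
            slack = 3 * np.sqrt(alpha * (1 - alpha) / 60)
            assert frac <= alpha + 1.0 / 101.0 + slack

    def test_bh_fdr_flag(self, random_matrix_factory):
        m = random_matrix_factory(n_genes=60, seed=21)
        coll = GeneSetCollection.from_dict(
            {f"S{j}": [f"g{i:05d}" for i in range(j * 5, j * 5 + 5)] for j in range(4)}
        )
        res = gsea.gsea_test(m, coll, scheme="gene_set", n_perm=100, seed=2, fdr_method="bh")
        ps = [r.p_value for r in res]
        qs = [r.fdr_q for r in res]
        assert qs == pytest.approx(oracles.brute_bh(ps))

    def test_significance_flag_at_study_threshold(self, random_matrix_factory):
        # a set made of the top-ranked genes must clear the FDR < 0.25 screen
        m = random_matrix_factory(n_genes=100, seed=30)
        import xsmono.diffexp as de

        ranked = de.rank_genes(m)
        coll = GeneSetCollection.from_dict(
            {"TOP": ranked.genes[:10], "RAND": ranked.genes[40:80:4]}
        )
        res = {r.set_name: r for r in gsea.gsea_test(
            ranked, coll, scheme="gene_set", n_perm=500, seed=3
        )}
        assert res["TOP"].fdr_q < 0.25 and res["TOP"].es > 0


class TestSsgsea:
    def test_rank_invariance(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        vals = rng.normal(size=30)
        members = genes[3:8]
        s1 = gsea.ssgsea_score(genes, vals, members)
        s2 = gsea.ssgsea_score(genes, vals**3, members)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_matches_hand_enumeration(self):
        genes = list("abcdef")
        vals = [4.0, 6.0, 1.0, 3.0, 5.0, 2.0]
        members = ["b", "d"]
        expected = oracles.brute_ssgsea(dict(zip(genes, vals)), members, alpha=0.25)
        assert gsea.ssgsea_score(genes, vals, members, alpha=0.25) == pytest.approx(
            expected, abs=1e-12
        )

    def test_ties_resolve_deterministically(self):
        genes = [f"g{i}" for i in range(8)]
        vals = [1.0] * 8
        members = ["g2", "g5"]
        s1 = gsea.ssgsea_score(genes, vals, members)
        s2 = gsea.ssgsea_score(list(reversed(genes)), vals, members)
        assert s1 == s2

    def test_modes(self, tiny_matrix):
        genes, absolute = gsea.single_sample_profile(tiny_matrix, "t1", "absolute")
        np.testing.assert_array_equal(absolute, tiny_matrix.values[:, 2])
        _, rel = gsea.single_sample_profile(tiny_matrix, "t1", "relative_to_baseline")
        np.testing.assert_allclose(rel, tiny_matrix.values[:, 2] - tiny_matrix.values[:, :2].mean(axis=1))

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="not represented"):
            gsea.ssgsea_score(["a", "b", "c"], [1.0, 2.0, 3.0], ["zz"])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), exponent=st.sampled_from([0.0, 1.0]))
def test_es_oracle_property(seed, exponent):
    """ES equals the definitional running-sum enumeration on random instances."""
    rng = np.random.default_rng(seed)
    ranked, members = _random_instance(rng, n_max=30, set_max=8)
    prof = gsea.enrichment_score(ranked, members, exponent)
    hits = set(members)
    es, peak = oracles.brute_es(ranked.scores, [g in hits for g in ranked.genes], exponent)
    assert prof.es == pytest.approx(es, abs=1e-12)
    assert prof.running_sum[prof.peak_index - 1] == pytest.approx(es, abs=1e-12)
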