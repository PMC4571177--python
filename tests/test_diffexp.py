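import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from xsmono import diffexp
from xsmono.io_formats import ExpressionMatrix, RankedList

import oracles


def _matrix(control_rows, treated_rows, genes=None):
    """Build a two-group matrix from per-gene (control tuple, treated tuple)."""
    n_c = len(control_rows[0])
    values = np.array([list(c) + list(t) for c, t in zip(control_rows, treated_rows)])
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"c{i}" for i in range(n_c)] + [f"t{i}" for i in range(values.shape[1] - n_c)]
    groups = {s: ("control" if s.startswith("c") else "ami") for s in samples}
    return ExpressionMatrix(genes, samples, values, groups, treatment="ami")


class TestDeTest:
    def test_pooled_t_closed_form(self):
        # group1=(1,2), group2=(3,4): diff=2, pooled var 0.5,
        # se=sqrt(0.5*(1/2+1/2)), t=2*sqrt(2)=2.8284..., df=2
        m = _matrix([(1.0, 2.0)], [(3.0, 4.0)])
        row = diffexp.de_test(m).iloc[0]
        t_expected = 2.0 / np.sqrt(0.5)
        # survival of t with 2 df has the closed form (1 - t/sqrt(2+t^2))/2
        p_expected = 1.0 - t_expected / np.sqrt(2.0 + t_expected**2)
        assert row["log2fc"] == pytest.approx(2.0)
        assert row["fold_change"] == pytest.approx(4.0)
        assert row["t_stat"] == pytest.approx(t_expected, abs=1e-12)
        assert row["p_value"] == pytest.approx(p_expected, abs=1e-12)

    def test_identical_values_are_null(self):
        m = _matrix([(5.0, 5.0)], [(5.0, 5.0)])
        row = diffexp.de_test(m).iloc[0]
        assert (row["log2fc"], row["t_stat"], row["p_value"]) == (0.0, 0.0, 1.0)
        assert row["zero_variance"]

    def test_zero_variance_unequal_means_flagged(self):
        m = _matrix([(1.0, 1.0)], [(2.0, 2.0)])
        row = diffexp.de_test(m).iloc[0]
        assert row["p_value"] == 0.0
        assert row["zero_variance"]

    def test_single_sample_group_rejected(self):
        values = np.array([[1.0, 2.0, 3.0]])
        # matrix construction itself enforces >=2 per group
        with pytest.raises(ValueError, match="at least 2"):
            ExpressionMatrix(
                ["g0"], ["c0", "c1", "t0"], values,
                {"c0": "control", "c1": "control", "t0": "ami"}, treatment="ami",
            )

    def test_sign_agreement(self, random_matrix_factory):
        table = diffexp.de_test(random_matrix_factory(n_genes=300, seed=3))
        ok = ~table["zero_variance"]
        assert np.all(np.sign(table.loc[ok, "t_stat"]) == np.sign(table.loc[ok, "log2fc"]))

    def test_null_pvalues_uniform(self, random_matrix_factory):
        m = random_matrix_factory(n_genes=5000, n_per_group=(6, 6), seed=11)
        p = diffexp.de_test(m)["p_value"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestDeFilter:
    @pytest.fixture
    def table(self):
        m = _matrix(
            [(1.0, 1.1, 0.9)] * 4,
            [
                (2.3, 2.4, 2.2),   # fc ~2.5, strongly up
                (2.0, 2.0, 2.001),  # fc ~2 boundary
                (1.0, 1.05, 0.95),  # flat
                (-0.4, -0.3, -0.35),  # down
            ],
        )
        return diffexp.de_test(m)

    def test_figure_thresholds_select_up_and_down(self, table):
        up, down = diffexp.de_filter(table, fc_min=2.0, p_max=0.01)
        assert "g0" in up and "g3" in down and "g2" not in up + down

    def test_boundary_fold_change_excluded(self):
        m = _matrix([(0.0, 0.001, -0.001)], [(1.0, 1.001, 0.999)])
        table = diffexp.de_test(m)
        assert table.iloc[0]["fold_change"] == pytest.approx(2.0, abs=1e-3)
        table.loc["g0", "fold_change"] = 2.0  # pin the exact boundary
        up, _ = diffexp.de_filter(table, fc_min=2.0, p_max=0.01)
        assert up == []

    def test_monotone_in_p(self, random_matrix_factory):
        table = diffexp.de_test(random_matrix_factory(n_genes=2000, seed=5))
        up_loose, down_loose = diffexp.de_filter(table, 1.2, 0.2)
        up_tight, down_tight = diffexp.de_filter(table, 1.2, 0.02)
        assert set(up_tight) <= set(up_loose)
        assert set(down_tight) <= set(down_loose)
        assert not set(up_loose) & set(down_loose)

    def test_bad_thresholds(self, table):
        pytest.raises(ValueError, diffexp.de_filter, table, 0.9, 0.05)
        pytest.raises(ValueError, diffexp.de_filter, table, 2.0, 0.0)


class TestRankGenes:
    def test_snr_direct_substitution(self):
        # two samples per group with sample sd exactly 0.5 and mean shift 1
        d = 0.5 * np.sqrt(2.0)
        m = _matrix([(0.0, d)], [(1.0, 1.0 + d)])
        ranked = diffexp.rank_genes(m, "signal_to_noise")
        assert ranked.scores[0] == pytest.approx(1.0)

    def test_monotone_across_metrics(self):
        m = _matrix([(1.0, 1.2, 0.8), (5.0, 5.2, 4.8)], [(3.0, 3.2, 2.8), (5.1, 4.9, 5.2)])
        for metric in diffexp.RANK_METRICS:
            ranked = diffexp.rank_genes(m, metric)
            assert ranked.genes[0] == "g0", metric

    def test_constant_gene_finite(self):
        m = _matrix([(2.0, 2.0), (1.0, 1.5)], [(2.0, 2.0), (1.2, 1.4)])
        ranked = diffexp.rank_genes(m, "signal_to_noise")
        assert np.all(np.isfinite(ranked.scores))

    def test_log2fc_order_matches_de_table(self, random_matrix_factory):
        m = random_matrix_factory(n_genes=200, seed=7)
        ranked = diffexp.rank_genes(m, "log2fc")
        table = diffexp.de_test(m)
        expected = table["log2fc"].sort_values(ascending=False, kind="stable")
        np.testing.assert_allclose(ranked.scores, expected.to_numpy())

    def test_unknown_metric(self, tiny_matrix):
        pytest.raises(ValueError, diffexp.rank_genes, tiny_matrix, "fold")


class TestSignature:
    def test_prefix_preserved(self):
        ranked = RankedList.from_scores(["A", "B", "C"], [1.0, 3.0, 2.0])
        assert diffexp.select_signature(ranked, 2).genes == ["B", "C"]

    def test_default_size(self, random_matrix_factory):
        ranked = diffexp.rank_genes(random_matrix_factory(n_genes=1000, seed=1))
        assert len(diffexp.select_signature(ranked, 200)) == 200

    def test_bad_sizes(self, three_gene_ranked):
        pytest.raises(ValueError, diffexp.select_signature, three_gene_ranked, 0)
        pytest.raises(ValueError, diffexp.select_signature, three_gene_ranked, 4)


class TestSpearman:
    def test_monotone_transform_gives_unity(self):
        x = np.arange(1.0, 13.0)
        rho, r2, p = diffexp.spearman_r2(x, x**3)
        assert (rho, r2) == (1.0, 1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        rho, _, _ = diffexp.spearman_r2(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_small_n_matches_enumeration(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.8])
        rho, _, p = diffexp.spearman_r2(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)
        rx = stats.rankdata(x).tolist()
        ry = stats.rankdata(y).tolist()
        assert p == pytest.approx(oracles.brute_spearman_perm_p(rx, ry))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            diffexp.spearman_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=30, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(-100, 100), st.integers(-100, 100)), min_size=10, max_size=20
        )
    )
    def test_monotone_invariance_property(self, data):
        # integer-valued inputs keep the monotone transforms tie-exact
        x = np.array([float(a) for a, _ in data])
        y = np.array([float(b) for _, b in data])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        rho1, _, p1 = diffexp.spearman_r2(x, y)
        rho2, _, p2 = diffexp.spearman_r2(np.exp(x / 100.0), 5.0 * y + 2.0)
        assert rho1 == pytest.approx(rho2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)
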