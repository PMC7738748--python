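import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntsr_f2map.diffexpr import (
    bh_adjust,
    call_degs,
    classify_samples,
    delta_delta_ct,
    regress_expression_on_rating,
    segregation_independence_test,
)
from ntsr_f2map.diffexpr import test_differential_expression as welch_de
from ntsr_f2map.io_formats import CountMatrix


def _design(ratings):
    return pd.DataFrame(
        {"rating_24D": ratings}, index=[f"p{i}" for i in range(len(ratings))]
    )


class TestClassify:
    @pytest.mark.parametrize("rating,label", [(10, "R"), (1, "S"), (3, "S"), (4, "R")])
    def test_boundaries(self, rating, label):
        assert classify_samples(_design([rating]), "24D").iloc[0] == label

    def test_cutoff_configurable(self):
        assert classify_samples(_design([3]), "24D", cutoff=2).iloc[0] == "R"

    def test_out_of_range_rating_rejected(self):
        with pytest.raises(ValueError):
            classify_samples(_design([11]), "24D")


class TestSegregation:
    def test_diagonal_table(self):
        # joint counts [[2,0],[0,2]]: enumeration over margins (2,2)x(2,2)
        # gives three tables with probabilities 1/6, 4/6, 1/6 -> p = 1/3
        table, p = segregation_independence_test(list("RRSS"), list("RRSS"))
        assert table.tolist() == [[2, 0], [0, 2]]
        assert p == pytest.approx(1 / 3)

    def test_modal_table_p_one(self):
        a = ["R"] * 10 + ["S"] * 10
        b = (["R", "S"] * 10)[:20]
        table, p = segregation_independence_test(a, b)
        assert table.tolist() == [[5, 5], [5, 5]]
        assert p == pytest.approx(1.0)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning):
            _, p = segregation_independence_test(["R", "R"], ["R", "S"])
        assert p == 1.0

    def test_type_one_error_rate_under_independence(self, rng):
        """Independent traits are rejected at about the nominal rate."""
        n_rep, n = 400, 60
        rejections = 0
        for _ in range(n_rep):
            a = np.where(rng.random(n) < 0.75, "R", "S")
            b = np.where(rng.random(n) < 0.75, "R", "S")
            _, p = segregation_independence_test(a, b)
            rejections += p <= 0.05
        # Fisher is conservative on discrete tables: rate at or below ~alpha
        assert rejections / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


def _bh_oracle(p):
    """Literal step-up: q_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        cands = [min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_pos, m)]
        q[idx] = min(cands)
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_singleton(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_oracle_and_bounds(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, _bh_oracle(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15) and np.all(q <= 1)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestDifferentialExpression:
    def _labels(self, samples):
        half = len(samples) // 2
        return pd.Series(["R"] * half + ["S"] * (len(samples) - half), index=samples)

    def test_all_zero_gene_p_one(self, rng):
        counts = pd.DataFrame(
            rng.poisson(50, size=(5, 8)), index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        counts.iloc[2] = 0
        cm = CountMatrix(counts.astype(float))
        res = welch_de(cm, self._labels(cm.samples))
        assert res.loc["g2", "p"] == 1.0 and res.loc["g2", "effect"] == 0.0

    def test_effect_sign_positive_means_higher_in_r(self, rng):
        counts = pd.DataFrame(
            np.vstack([
                np.r_[rng.poisson(400, 4), rng.poisson(100, 4)],
                rng.poisson(5000, 8),
            ]),
            index=["g0", "stable"], columns=[f"s{i}" for i in range(8)],
        )
        res = welch_de(CountMatrix(counts.astype(float)), self._labels(list(counts.columns)))
        assert res.loc["g0", "effect"] > 0

    def test_requires_two_per_group(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(3, 3)).astype(float),
                              index=list("abc"), columns=["x", "y", "z"])
        labels = pd.Series(["R", "S", "S"], index=["x", "y", "z"])
        with pytest.raises(ValueError):
            welch_de(CountMatrix(counts), labels)

    def test_external_table_passthrough(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(3, 4)).astype(float),
                              index=list("abc"), columns=list("wxyz"))
        ext = pd.DataFrame({"effect": [1.0, 0.0, -1.0], "p": [0.001, 0.9, 0.04]}, index=list("abc"))
        res = welch_de(CountMatrix(counts), None, method="external", external_p=ext)
        pd.testing.assert_frame_equal(res, ext)

    def test_planted_cis_gene_power(self, rng):
        """A 3-fold cis gene at n=8 vs 8 is detected with small p."""
        ps = []
        for _ in range(20):
            r = rng.poisson(rng.gamma(50, 6.0, size=8))  # 2x overexpressed het-like mix
            s = rng.poisson(rng.gamma(50, 3.0, size=8))
            counts = pd.DataFrame(
                np.vstack([np.r_[r, s], rng.poisson(300, 16)]).astype(float),
                index=["cis", "null"], columns=[f"s{i}" for i in range(16)],
            )
            labels = pd.Series(["R"] * 8 + ["S"] * 8, index=counts.columns)
            res = welch_de(CountMatrix(counts), labels)
            ps.append(res.loc["cis", "p"])
        assert np.median(ps) < 0.01

    def test_null_pvalues_roughly_uniform(self, rng):
        n_genes = 400
        counts = pd.DataFrame(
            rng.negative_binomial(50, 50 / (50 + 200.0), size=(n_genes, 16)).astype(float),
            index=[f"g{i}" for i in range(n_genes)], columns=[f"s{i}" for i in range(16)],
        )
        labels = pd.Series(["R"] * 8 + ["S"] * 8, index=counts.columns)
        res = welch_de(CountMatrix(counts), labels)
        from scipy.stats import kstest

        assert kstest(res["p"], "uniform").pvalue > 0.01


class TestCallDegs:
    def test_boundary_q_is_deg(self):
        res = pd.DataFrame({"effect": [1.0], "p": [0.1]}, index=["g"])
        (d,) = call_degs(res, fdr=0.1)
        assert d.q == pytest.approx(0.1) and d.is_deg

    def test_all_p_one_no_degs(self):
        res = pd.DataFrame({"effect": [0.0] * 5, "p": [1.0] * 5}, index=list("abcde"))
        assert not any(d.is_deg for d in call_degs(res))


class TestQpcr:
    def _table(self):
        return pd.DataFrame(
            {
                "T": [20.0, 18.0, 19.0],
                "h1": [18.0, 17.0, 18.0],
                "h2": [18.0, 17.0, 18.0],
                "h3": [18.0, 17.0, 18.0],
            },
            index=["a", "b", "ref"],
        )

    def test_reference_rel_expr_one(self):
        results = delta_delta_ct(self._table(), "T", ["h1", "h2", "h3"], "ref")
        byid = {r.sample_id: r for r in results}
        assert byid["ref"].rel_expr == pytest.approx(1.0)

    def test_worked_example(self):
        # sample a: dCt = 20 - 18 = 2; reference dCt = 1 -> ddCt = 1 -> 2^-1
        results = delta_delta_ct(self._table(), "T", ["h1", "h2", "h3"], "ref")
        byid = {r.sample_id: r for r in results}
        assert byid["a"].delta_ct == pytest.approx(2.0)
        assert byid["a"].delta_delta_ct == pytest.approx(1.0)
        assert byid["a"].rel_expr == pytest.approx(0.5)
        # ddCt = -2 gives a 4-fold relative expression
        assert byid["b"].delta_delta_ct == pytest.approx(0.0)

    def test_negative_ddct_quadruples(self):
        t = self._table()
        t.loc["a", "T"] = 17.0  # dCt = -1, ddCt = -2
        byid = {r.sample_id: r for r in delta_delta_ct(t, "T", ["h1", "h2", "h3"], "ref")}
        assert byid["a"].rel_expr == pytest.approx(4.0)

    def test_missing_ct_skipped_with_warning(self):
        t = self._table()
        t.loc["a", "h2"] = np.nan
        with pytest.warns(UserWarning):
            results = delta_delta_ct(t, "T", ["h1", "h2", "h3"], "ref")
        assert [r.sample_id for r in results] == ["b", "ref"]


class TestRegression:
    def test_perfect_line(self):
        ratings = pd.Series([1.0, 4, 7, 10], index=list("abcd"))
        rel = pd.Series([2.0, 8, 14, 20], index=list("abcd"))
        slope, p = regress_expression_on_rating(rel, ratings)
        assert slope == pytest.approx(2.0)
        assert p < 1e-10

    def test_constant_rating_rejected(self):
        ratings = pd.Series([5.0, 5, 5], index=list("abc"))
        rel = pd.Series([1.0, 2, 3], index=list("abc"))
        with pytest.raises(ValueError):
            regress_expression_on_rating(rel, ratings)

    def test_null_slope_pvalues_uniformish(self, rng):
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            ratings = pd.Series(rng.integers(1, 11, 14).astype(float), index=range(14))
            rel = pd.Series(rng.lognormal(0, 0.5, 14), index=range(14))
            if ratings.nunique() == 1:
                continue
            _, p = regress_expression_on_rating(rel, ratings)
            hits += p <= 0.05
        assert abs(hits / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)
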