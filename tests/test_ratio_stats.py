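"""IsomiR ratios and the statistical battery (ANOVA, Wilcoxon, BH, OLS)."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isomirshift.ratio_stats import (
    RatioTable,
    bh_fdr,
    cohort_ratio_correlation,
    diff_expression_test,
    diff_ratio_test,
    isomir_ratio,
    mean_ratio,
    minmax_ols,
    rank_isomirs,
    regress_isomir_abundance,
    relative_expression_qpcr,
)

KEY_NAMES = ["locus_id", "arm", "mature_name", "offset"]


def make_expr(rows, columns):
    idx = pd.MultiIndex.from_tuples(list(rows), names=KEY_NAMES)
    return pd.DataFrame(list(rows.values()), index=idx, columns=columns, dtype=float)


class TestRatio:
    def test_arm_total_denominator(self):
        expr = make_expr(
            {
                ("l", "5p", "m", 0): [80.0],
                ("l", "5p", "m", 1): [15.0],
                ("l", "5p", "m", -1): [5.0],
            },
            ["s1"],
        )
        table = isomir_ratio(expr)
        assert table.ratios.loc[("l", "5p", "m", 1), "s1"] == pytest.approx(0.15)
        assert table.ratios.loc[("l", "5p", "m", -1), "s1"] == pytest.approx(0.05)

    def test_canonical_denominator_flag(self):
        expr = make_expr(
            {("l", "5p", "m", 0): [80.0], ("l", "5p", "m", 1): [20.0]}, ["s1"]
        )
        table = isomir_ratio(expr, denominator="canonical")
        assert table.ratios.loc[("l", "5p", "m", 1), "s1"] == pytest.approx(0.25)

    def test_canonical_only_arm_has_no_rows(self):
        expr = make_expr({("l", "5p", "m", 0): [80.0]}, ["s1"])
        assert isomir_ratio(expr).ratios.empty

    def test_zero_arm_total_gives_missing(self):
        expr = make_expr(
            {("l", "5p", "m", 0): [80.0, 0.0], ("l", "5p", "m", 1): [20.0, 0.0]},
            ["s1", "s2"],
        )
        table = isomir_ratio(expr)
        assert table.ratios.loc[("l", "5p", "m", 1), "s1"] == pytest.approx(0.2)
        assert np.isnan(table.ratios.loc[("l", "5p", "m", 1), "s2"])

    def test_ratios_sum_with_canonical_fraction_to_one(self, rng):
        """Normalization invariant on random matrices."""
        for _ in range(20):
            n_iso = int(rng.integers(1, 5))
            vals = rng.random((n_iso + 1, 4)) * 100
            rows = {("l", "5p", "m", 0): vals[0]}
            for i in range(n_iso):
                rows[("l", "5p", "m", i + 1)] = vals[i + 1]
            table = isomir_ratio(make_expr(rows, list("abcd")))
            canonical_frac = vals[0] / vals.sum(axis=0)
            np.testing.assert_allclose(
                canonical_frac + table.ratios.sum(axis=0), 1.0, atol=1e-9
            )


class TestMeanAndRank:
    def test_mean_ignores_missing(self):
        idx = pd.MultiIndex.from_tuples([("l", "5p", "m", 1)], names=KEY_NAMES)
        ratios = pd.DataFrame([[0.2, np.nan, 0.4]], index=idx, columns=list("abc"))
        table = RatioTable(ratios=ratios, arm_total=pd.DataFrame())
        assert mean_ratio(table).iloc[0] == pytest.approx(0.3)
        with pytest.raises(ValueError, match="empty"):
            mean_ratio(table, [])

    def test_rank_tiebreaks(self):
        expr = make_expr(
            {
                ("l", "5p", "m", 0): [100.0, 100.0],
                ("l", "5p", "m", 1): [30.0, 30.0],
                ("l", "5p", "m", -1): [10.0, 10.0],
                ("l", "5p", "m", 2): [10.0, 10.0],
            },
            ["a", "b"],
        )
        ranked = rank_isomirs(expr, k=2)[("l", "5p")]
        assert [k[3] for k in ranked] == [1, -1]

    def test_rank_shorter_than_k(self):
        expr = make_expr(
            {("l", "5p", "m", 0): [10.0], ("l", "5p", "m", 1): [5.0]}, ["a"]
        )
        assert len(rank_isomirs(expr, k=2)[("l", "5p")]) == 1

    def test_rank_agrees_with_bruteforce_sort(self, rng):
        for _ in range(20):
            offsets = [-2, -1, 1, 2]
            vals = {o: rng.random(5) * 50 for o in offsets}
            rows = {("l", "5p", "m", 0): rng.random(5) * 100}
            rows.update({("l", "5p", "m", o): v for o, v in vals.items()})
            expr = make_expr(rows, list("abcde"))
            ranked = [k[3] for k in rank_isomirs(expr, k=4)[("l", "5p")]]
            expected = sorted(
                offsets, key=lambda o: (-np.median(vals[o]), abs(o), o)
            )
            assert ranked == expected


def _ratio_table(rows, columns):
    return RatioTable(ratios=make_expr(rows, columns), arm_total=pd.DataFrame())


class TestDiffRatio:
    def _groups(self, n1, n2):
        cols = [f"n{i}" for i in range(n1)] + [f"t{i}" for i in range(n2)]
        return cols, pd.Series(["non_tumor"] * n1 + ["tumor"] * n2, index=cols)

    def test_identical_values_give_f0_p1(self):
        cols, groups = self._groups(3, 3)
        table = _ratio_table({("l", "5p", "m", 1): [0.3] * 6}, cols)
        res = diff_ratio_test(table, groups)
        assert res["statistic"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_zero_within_variance_separated_groups(self):
        cols, groups = self._groups(3, 3)
        table = _ratio_table({("l", "5p", "m", 1): [0.1] * 3 + [0.5] * 3}, cols)
        res = diff_ratio_test(table, groups)
        assert res["p"].iloc[0] < 0.01
        # cross-check the epsilon policy against a barely-perturbed ANOVA
        vals = np.array([0.1, 0.1, 0.1 + 1e-9, 0.5, 0.5, 0.5 - 1e-9])
        ref = stats.f_oneway(vals[:3], vals[3:])
        assert ref.pvalue < 0.01

    def test_matches_scipy_on_noisy_data(self, rng):
        cols, groups = self._groups(8, 8)
        vals = rng.random(16)
        table = _ratio_table({("l", "5p", "m", 1): vals}, cols)
        res = diff_ratio_test(table, groups)
        ref = stats.f_oneway(vals[:8], vals[8:])
        assert res["statistic"].iloc[0] == pytest.approx(ref.statistic)
        assert res["p"].iloc[0] == pytest.approx(ref.pvalue)

    def test_single_group_rejected(self):
        cols = ["a", "b", "c"]
        table = _ratio_table({("l", "5p", "m", 1): [0.1, 0.2, 0.3]}, cols)
        with pytest.raises(ValueError, match="two groups"):
            diff_ratio_test(table, pd.Series(["g"] * 3, index=cols))

    def test_underpowered_keys_reported_untested(self):
        cols, groups = self._groups(3, 3)
        table = _ratio_table(
            {("l", "5p", "m", 1): [0.1, np.nan, np.nan, 0.5, 0.4, 0.3]}, cols
        )
        res = diff_ratio_test(table, groups)
        assert not res["tested"].iloc[0]
        assert np.isnan(res["q"].iloc[0])

    def test_planted_shift_detected_with_high_power(self, rng):
        """Simulation oracle: delta = 0.15, sd = 0.05, n = 20+20."""
        cols, groups = self._groups(20, 20)
        detected = 0
        reps = 100
        for _ in range(reps):
            base = rng.normal(0.2, 0.05, 20).clip(0, 1)
            shifted = rng.normal(0.35, 0.05, 20).clip(0, 1)
            table = _ratio_table({("l", "5p", "m", 1): np.r_[base, shifted]}, cols)
            res = diff_ratio_test(table, groups)
            if res["q"].iloc[0] <= 0.05:
                detected += 1
        assert detected >= 95


class TestDiffExpression:
    def test_complete_separation_exact_p(self):
        """All tumor > all non-tumor at n=5/5: one-tailed p = 1/C(10,5)."""
        cols = [f"n{i}" for i in range(5)] + [f"t{i}" for i in range(5)]
        groups = pd.Series(["non_tumor"] * 5 + ["tumor"] * 5, index=cols)
        expr = make_expr(
            {("l", "5p", "m", 1): [1.0, 2, 3, 4, 5, 10, 11, 12, 13, 14]}, cols
        )
        res = diff_expression_test(expr, groups, alternative="greater")
        assert res["p"].iloc[0] == pytest.approx(1 / 252)

    def test_null_p_uniform(self, rng):
        """KS uniformity of p under identical distributions (1000 reps)."""
        cols = [f"n{i}" for i in range(12)] + [f"t{i}" for i in range(12)]
        groups = pd.Series(["non_tumor"] * 12 + ["tumor"] * 12, index=cols)
        ps = []
        for _ in range(1000):
            expr = make_expr({("l", "5p", "m", 1): rng.normal(size=24)}, cols)
            ps.append(diff_expression_test(expr, groups)["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_paired_signed_rank_drops_zero_differences(self):
        cols = ["n0", "n1", "n2", "n3", "n4", "t0", "t1", "t2", "t3", "t4"]
        groups = pd.Series(["non_tumor"] * 5 + ["tumor"] * 5, index=cols)
        pairs = pd.Series([0, 1, 2, 3, 4, 0, 1, 2, 3, 4], index=cols)
        expr = make_expr(
            {("l", "5p", "m", 1): [1.0, 2, 3, 4, 5, 1.0, 4, 6, 9, 11]}, cols
        )
        res = diff_expression_test(expr, groups, paired=True, pairs=pairs)
        diffs = np.array([4 - 2, 6 - 3, 9 - 4, 11 - 5])  # zero pair removed
        ref = stats.wilcoxon(diffs, alternative="greater")
        assert res["p"].iloc[0] == pytest.approx(ref.pvalue)

    def test_paired_unmatched_samples_listed(self):
        cols = ["n0", "n1", "t0", "t1"]
        groups = pd.Series(["non_tumor"] * 2 + ["tumor"] * 2, index=cols)
        pairs = pd.Series([0, 1, 0, 9], index=cols)
        expr = make_expr({("l", "5p", "m", 1): [1.0, 2, 3, 4]}, cols)
        with pytest.raises(ValueError, match="1.*9|9.*1"):
            diff_expression_test(expr, groups, paired=True, pairs=pairs)


class TestBH:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_tied_inputs(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_fdr([0.05] * 10), [0.05] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 30)))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_fdr(p), q_ref, atol=1e-12)

    def test_q_never_below_p(self, rng):
        p = rng.random(50)
        assert (bh_fdr(p) >= p - 1e-12).all()


class TestRegression:
    def test_exact_linear_recovery(self):
        n = 40
        x1 = pd.Series(np.linspace(0, 1, n))
        x2 = pd.Series(np.sin(np.arange(n)) * 0.5 + 0.5)
        y = 0.5 * x1 + 0.3 * x2
        res = minmax_ols(y, pd.DataFrame({"x1": x1, "x2": x2}))
        # variables are rescaled to [0,1]; undo the spans to recover the
        # original-scale coefficients exactly
        span_y = y.max() - y.min()
        spans = np.array([x1.max() - x1.min(), x2.max() - x2.min()])
        np.testing.assert_allclose(
            res.coefficients * span_y / spans, [0.5, 0.3], atol=1e-8
        )

    def test_constant_predictor_named_in_error(self):
        y = pd.Series(np.arange(10.0))
        X = pd.DataFrame({"x1": np.arange(10.0), "x2": np.ones(10)})
        with pytest.raises(ValueError, match="x2"):
            minmax_ols(y, X)

    def test_planted_ratio_effect_recovered(self, rng):
        n = 100
        canonical = pd.Series(rng.lognormal(5, 1, n))
        ratio = pd.Series(rng.random(n) * 0.4)
        isomir = canonical * ratio * rng.lognormal(0, 0.05, n)
        res = regress_isomir_abundance(isomir, canonical, ratio)
        i = res.predictors.index("isomir_ratio")
        assert res.coefficients[i] > 0
        assert res.pvalues[i] < 0.01

    def test_reduces_to_simple_regression_slope(self, rng):
        """Dropping one predictor reproduces the simple OLS slope."""
        x = pd.Series(rng.random(30))
        y = 2.0 * x + rng.normal(0, 0.01, 30)
        multi = minmax_ols(y, pd.DataFrame({"x": x}))
        xs = (x - x.min()) / (x.max() - x.min())
        ys = (y - y.min()) / (y.max() - y.min())
        slope = np.polyfit(xs, ys, 1)[0]
        assert multi.coefficients[0] == pytest.approx(slope, rel=1e-6)


class TestCorrelationAndQpcr:
    def test_identical_and_reversed_vectors(self):
        a = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("wxyz"))
        rev = pd.Series(a.to_numpy()[::-1], index=a.index)  # same keys, anti-ordered
        r = cohort_ratio_correlation({"c1": a, "c2": a, "c3": rev})
        assert r.loc["c1", "c2"] == pytest.approx(1.0)
        assert r.loc["c1", "c3"] == pytest.approx(-1.0)

    def test_too_few_shared_keys_rejected(self):
        a = pd.Series([0.1, 0.2], index=["k1", "k2"])
        with pytest.raises(ValueError, match="shared"):
            cohort_ratio_correlation({"c1": a, "c2": a})

    def test_independent_vectors_near_zero(self, rng):
        ok = 0
        for _ in range(100):
            a = pd.Series(rng.random(1000))
            b = pd.Series(rng.random(1000))
            r = cohort_ratio_correlation({"c1": a, "c2": b}).loc["c1", "c2"]
            ok += abs(r) < 0.1
        assert ok >= 99

    @pytest.mark.parametrize(
        "ct_t,ct_c,expected", [(25, 25, 1.0), (26, 25, 0.5), (24, 25, 2.0)]
    )
    def test_qpcr_two_to_minus_delta_ct(self, ct_t, ct_c, expected):
        assert relative_expression_qpcr(ct_t, ct_c) == expected

    def test_qpcr_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            relative_expression_qpcr(np.nan, 25)
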