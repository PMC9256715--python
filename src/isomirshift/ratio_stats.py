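"""IsomiR ratios and the differential / association statistics battery.

The isomiR ratio expresses an isoform's abundance relative to the total
output of its hairpin arm: ratio(i, s) = RPM_i(s) / (RPM_canonical(s) +
sum_j RPM_j(s)) over all isoforms j of the same (locus, arm).  The
alternative canonical-only denominator is available via
``denominator="canonical"``.

Statistics: one-way ANOVA on ratios between groups, one-tailed Wilcoxon
rank-sum (unpaired) / signed-rank (paired) on expression, BH step-up FDR,
multivariate OLS on min-max-scaled variables, cross-cohort Pearson
correlation and the qPCR 2^-dCt normalization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

TINY_P = 1e-300  # F-limit p when within-group variance is exactly zero


@dataclass
class RatioTable:
    """Per-isomiR, per-sample ratios in [0, 1] plus arm-total RPM.

    ``ratios`` is indexed like the expression matrix but restricted to
    non-canonical keys; a ratio is missing (NaN) where the arm-total RPM
    is zero.  ``arm_total`` is indexed by (locus_id, arm).
    """

    ratios: pd.DataFrame
    arm_total: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.ratios.columns)


def isomir_ratio(expr: pd.DataFrame, denominator: str = "arm_total") -> RatioTable:
    """Compute the isomiR ratio table from an RPM expression matrix.

    Arms with only a canonical key contribute no ratio rows.  Missing
    where the denominator is zero.
    """
    if denominator not in ("arm_total", "canonical"):
        raise ValueError(f"unknown denominator {denominator!r}")
    offsets = expr.index.get_level_values("offset")
    arm_groups = expr.groupby(level=["locus_id", "arm"])
    arm_sum = arm_groups.sum()
    if denominator == "arm_total":
        denom = arm_sum
    else:
        denom = expr[offsets == 0].droplevel(["mature_name", "offset"])
    non_canonical = expr[offsets != 0]
    pairs = pd.MultiIndex.from_arrays(
        [
            non_canonical.index.get_level_values("locus_id"),
            non_canonical.index.get_level_values("arm"),
        ]
    )
    denom_rows = denom.reindex(pairs)
    denom_values = denom_rows.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom_values > 0, non_canonical.to_numpy() / denom_values, np.nan)
    ratios = pd.DataFrame(values, index=non_canonical.index, columns=expr.columns)
    return RatioTable(ratios=ratios, arm_total=arm_sum)


def mean_ratio(table: RatioTable, samples: list[str] | None = None) -> pd.Series:
    """Per-key mean ratio over a sample subset, ignoring missing values."""
    sub = table.ratios if samples is None else table.ratios[list(samples)]
    if sub.shape[1] == 0:
        raise ValueError("empty sample subset")
    return sub.mean(axis=1, skipna=True)


def rank_isomirs(expr: pd.DataFrame, k: int = 1) -> dict[tuple[str, str], list[tuple]]:
    """Top-k non-canonical isoforms per (locus, arm) by median RPM.

    Ties break toward smaller |offset|, then negative before positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    offsets = expr.index.get_level_values("offset")
    medians = expr[offsets != 0].median(axis=1)
    out: dict[tuple[str, str], list[tuple]] = {}
    for (locus_id, arm), sub in medians.groupby(level=["locus_id", "arm"]):
        ranked = sorted(
            sub.items(),
            key=lambda kv: (-kv[1], abs(kv[0][3]), kv[0][3]),
        )
        out[(locus_id, arm)] = [key for key, _ in ranked[:k]]
    return out


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA with an explicit zero-within-variance policy."""
    pooled = np.concatenate(groups)
    grand = pooled.mean()
    between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(pooled) - len(groups)
    if within <= 1e-30:
        if between <= 1e-30:
            return 0.0, 1.0
        return np.inf, TINY_P
    f = (between / df_b) / (within / df_w)
    p = stats.f.sf(f, df_b, df_w)
    return float(f), float(max(p, TINY_P))


def diff_ratio_test(
    table: RatioTable,
    groups: pd.Series,
    *,
    alpha: float = 0.05,
    tumor_label: str = "tumor",
) -> pd.DataFrame:
    """One-way ANOVA on per-sample ratios between condition groups.

    Keys lacking >=2 non-missing values in >=2 groups are reported
    untested (NaN statistics, excluded from the FDR family).
    """
    groups = groups.reindex(table.samples)
    labels = [g for g in pd.unique(groups.dropna())]
    if len(labels) < 2:
        raise ValueError("diff_ratio_test requires at least two groups")
    rows = []
    for key, row in table.ratios.iterrows():
        vals = [row[groups == g].dropna().to_numpy() for g in labels]
        usable = [v for v in vals if len(v) >= 2]
        if len(usable) < 2 or any(len(v) < 2 for v in vals):
            rows.append({"key": key, "statistic": np.nan, "p": np.nan, "tested": False,
                         "direction": None})
            continue
        f, p = _anova_oneway(vals)
        direction = None
        if tumor_label in labels:
            tumor_mean = row[groups == tumor_label].mean()
            other_mean = row[groups != tumor_label].mean()
            direction = "up_in_tumor" if tumor_mean > other_mean else "down_in_tumor"
        rows.append({"key": key, "statistic": f, "p": p, "tested": True,
                     "direction": direction})
    out = pd.DataFrame(rows).set_index("key")
    out.index = pd.MultiIndex.from_tuples(out.index, names=table.ratios.index.names)
    out["q"] = np.nan
    tested = out["tested"]
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    return out


def diff_expression_test(
    expr: pd.DataFrame,
    groups: pd.Series,
    *,
    paired: bool = False,
    pairs: pd.Series | None = None,
    alternative: str = "greater",
    tumor_label: str = "tumor",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-tailed Wilcoxon test of expression, tumor vs non-tumor.

    Unpaired: rank-sum (Mann-Whitney U); paired: signed-rank on per-pair
    differences with zero differences removed (standard convention).
    ``alternative="greater"`` tests for higher expression in tumor.
    """
    groups = groups.reindex(expr.columns)
    tumor_cols = list(groups[groups == tumor_label].index)
    other_cols = list(groups[(groups != tumor_label) & groups.notna()].index)
    if not tumor_cols or not other_cols:
        raise ValueError("both tumor and non-tumor samples are required")
    if paired:
        if pairs is None:
            raise ValueError("paired test requires a pairing series")
        pairs = pairs.reindex(expr.columns)
        t_by_pair = {pairs[c]: c for c in tumor_cols}
        o_by_pair = {pairs[c]: c for c in other_cols}
        shared = sorted(set(t_by_pair) & set(o_by_pair))
        unmatched = sorted(set(t_by_pair) ^ set(o_by_pair))
        if unmatched:
            raise ValueError(f"unmatched pair ids: {unmatched}")
        tumor_cols = [t_by_pair[p] for p in shared]
        other_cols = [o_by_pair[p] for p in shared]
    rows = []
    for key, row in expr.iterrows():
        x = row[tumor_cols].to_numpy(dtype=float)
        y = row[other_cols].to_numpy(dtype=float)
        if paired:
            diffs = x - y
            nonzero = diffs[diffs != 0]
            if len(nonzero) == 0:
                stat, p = 0.0, 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = stats.wilcoxon(
                        nonzero, alternative=alternative, zero_method="wilcox"
                    )
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = stats.mannwhitneyu(x, y, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
        direction = "up_in_tumor" if np.median(x) > np.median(y) else "down_in_tumor"
        rows.append({"key": key, "statistic": stat, "p": p, "direction": direction})
    out = pd.DataFrame(rows).set_index("key")
    out.index = pd.MultiIndex.from_tuples(out.index, names=expr.index.names)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    return out


@dataclass
class RegressionResult:
    response: str
    predictors: list[str]
    coefficients: np.ndarray
    pvalues: np.ndarray
    intercept: float
    r_squared: float


def minmax_scale(x: pd.Series, name: str | None = None) -> pd.Series:
    rng = x.max() - x.min()
    if not np.isfinite(rng) or rng == 0:
        raise ValueError(f"zero-variance predictor after scaling: {name or x.name}")
    return (x - x.min()) / rng


def minmax_ols(y: pd.Series, X: pd.DataFrame, response_name: str = "y") -> RegressionResult:
    """OLS after min-max scaling of response and all predictors to [0, 1]."""
    data = pd.concat([y.rename("_y"), X], axis=1).dropna()
    if len(data) < len(X.columns) + 2:
        raise ValueError("too few complete observations for regression")
    ys = minmax_scale(data["_y"], response_name)
    Xs = pd.DataFrame(
        {c: minmax_scale(data[c], c) for c in X.columns}, index=data.index
    )
    model = sm.OLS(ys, sm.add_constant(Xs)).fit()
    return RegressionResult(
        response=response_name,
        predictors=list(X.columns),
        coefficients=model.params[X.columns].to_numpy(),
        pvalues=model.pvalues[X.columns].to_numpy(),
        intercept=float(model.params["const"]),
        r_squared=float(model.rsquared),
    )


def regress_isomir_abundance(
    isomir_rpm: pd.Series,
    canonical_rpm: pd.Series,
    ratio: pd.Series,
) -> RegressionResult:
    """Regress isomiR RPM on canonical-miRNA RPM and the isomiR ratio.

    All three variables are min-max scaled first so the coefficients are
    comparable across cohorts.
    """
    X = pd.DataFrame({"canonical_rpm": canonical_rpm, "isomir_ratio": ratio})
    return minmax_ols(isomir_rpm, X, response_name="isomir_rpm")


def cohort_ratio_correlation(mean_ratios: dict[str, pd.Series]) -> pd.DataFrame:
    """Pearson r between cohorts' per-key mean ratios (shared keys only)."""
    cohorts = list(mean_ratios)
    r = pd.DataFrame(np.eye(len(cohorts)), index=cohorts, columns=cohorts)
    for i, a in enumerate(cohorts):
        for b in cohorts[i + 1 :]:
            merged = pd.concat(
                [mean_ratios[a].rename("a"), mean_ratios[b].rename("b")], axis=1
            ).dropna()
            if len(merged) < 3:
                raise ValueError(f"fewer than 3 shared keys between {a} and {b}")
            rv = stats.pearsonr(merged["a"], merged["b"]).statistic
            r.loc[a, b] = r.loc[b, a] = rv
    return r


def relative_expression_qpcr(ct_target: float, ct_control: float) -> float:
    """qPCR relative expression normalized to a control: 2^-(Ct_t - Ct_c)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_control)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** (-(ct_target - ct_control)))
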