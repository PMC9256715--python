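"""Survival stratification and association: median split, KM, Cox + Wald.

Patients are split at the median of a marker (expression or isomiR
ratio); overall survival is summarized by the Kaplan-Meier product-limit
estimator and tested with Cox proportional hazards (Efron ties, matching
the R ``coxph`` default), with Wald z = log-HR / SE and a two-sided p.
Prioritization: an isomiR is "clinically relevant" iff its ratio is
differential in all cohorts and its Cox Wald p <= 0.05 in at least one
dataset.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

logger = logging.getLogger(__name__)


def median_stratify(values: pd.Series) -> pd.Series:
    """Label samples 'high' (strictly above the median) or 'low'.

    Ties at the median go to 'low' (deterministic rule).  Requires >=4
    samples; an all-constant marker yields all-'low' with a warning.
    """
    values = values.dropna()
    if len(values) < 4:
        raise ValueError("median stratification requires >= 4 samples")
    med = values.median()
    labels = pd.Series(np.where(values > med, "high", "low"), index=values.index)
    if (labels == "low").all():
        logger.warning("constant marker: all samples stratified 'low'")
    return labels


def km_estimate(
    time: pd.Series, event: pd.Series, groups: pd.Series | None = None
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier survival step functions, per group.

    Returns {group: DataFrame(time, survival)}; a single 'all' group when
    ``groups`` is None.
    """
    if event.sum() < 1:
        logger.warning("no events observed; survival is flat at 1.0")
    if groups is None:
        groups = pd.Series("all", index=time.index)
    out = {}
    for label in pd.unique(groups.dropna()):
        mask = groups == label
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        sf = kmf.survival_function_
        out[str(label)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


@dataclass
class CoxResult:
    covariate: str
    hazard_ratio: float
    log_hr: float
    se: float
    wald_z: float
    p: float
    converged: bool = True

    @property
    def flagged(self) -> bool:
        return not self.converged


def cox_wald(
    records: pd.DataFrame,
    covariates: list[str] | str,
    *,
    time_col: str = "time",
    event_col: str = "event",
) -> list[CoxResult]:
    """Cox proportional-hazards fit with Wald tests per covariate.

    Monotone likelihood (perfect separation) or non-convergence is
    flagged rather than estimated.  Requires >=2 events and non-constant
    covariates.
    """
    if isinstance(covariates, str):
        covariates = [covariates]
    df = records[[time_col, event_col] + covariates].dropna()
    if df[event_col].sum() < 2:
        raise ValueError("Cox regression requires at least 2 events")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"constant covariate {c!r}")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=time_col, event_col=event_col)
    except ConvergenceError:
        return [
            CoxResult(c, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False)
            for c in covariates
        ]
    results = []
    for c in covariates:
        log_hr = float(cph.params_[c])
        se = float(cph.standard_errors_[c])
        ok = np.isfinite(se) and se < 50 and np.isfinite(log_hr)
        z = log_hr / se if ok else np.nan
        results.append(
            CoxResult(
                covariate=c,
                hazard_ratio=float(np.exp(log_hr)) if ok else np.nan,
                log_hr=log_hr if ok else np.nan,
                se=se if ok else np.nan,
                wald_z=z,
                p=float(cph.summary.loc[c, "p"]) if ok else np.nan,
                converged=ok,
            )
        )
    return results


def prioritize(
    differential_all_cohorts: pd.Series,
    cox_p_by_dataset: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Clinically relevant = differential in all cohorts AND Wald p <= alpha
    in at least one dataset.

    ``differential_all_cohorts`` is a boolean series per key;
    ``cox_p_by_dataset`` has keys as rows and datasets as columns.
    """
    min_p = cox_p_by_dataset.min(axis=1)
    keys = differential_all_cohorts.index
    out = pd.DataFrame(
        {
            "differential_all_cohorts": differential_all_cohorts,
            "min_cox_p": min_p.reindex(keys),
        }
    )
    out["clinically_relevant"] = out["differential_all_cohorts"] & (
        out["min_cox_p"] <= alpha
    )
    return out
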