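"""Descriptive and nonparametric analyses of a cohort.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
this module adds the cohort-aware surfaces: frequency tables with recovery
percentages, restricted-mean and median survival, visit-aligned profile
summaries, and the model-implied marginal correlation between the two
outcomes over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import Cohort

__all__ = [
    "KMCurve",
    "LogRankResult",
    "kaplan_meier",
    "median_survival",
    "restricted_mean_survival",
    "logrank_test",
    "descriptive_table",
    "profiles",
    "marginal_correlation_profile",
    "empirical_correlation_profile",
]


@dataclass
class KMCurve:
    """Product-limit estimate on the observed event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    variance: np.ndarray  # Greenwood

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def kaplan_meier(times, status) -> KMCurve:
    """Kaplan-Meier product-limit estimator (ties grouped; censored
    subjects at a tied time stay at risk for the events at that time)."""
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    km = KaplanMeierFitter().fit(times, status)
    tab = km.event_table.iloc[1:] if km.event_table.index[0] == 0 else km.event_table
    grid = tab.index.to_numpy(dtype=float)
    surv = km.survival_function_at_times(grid).to_numpy()
    # Greenwood variance: S(t)^2 * cumsum(d / (n (n - d)))
    d = tab["observed"].to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n > d, d / (n * (n - d)), np.nan)
    gw = surv**2 * np.cumsum(np.nan_to_num(inc))
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=n,
        events=d,
        censored=tab["censored"].to_numpy(dtype=float),
        variance=gw,
    )


def median_survival(curve: KMCurve):
    """Smallest t with S(t) <= 0.5, or None when the curve never crosses."""
    below = curve.survival <= 0.5 + 1e-12
    if not below.any():
        return None
    return float(curve.times[np.argmax(below)])


def restricted_mean_survival(curve: KMCurve) -> float:
    """Area under the KM step function up to the largest observed time."""
    t = np.concatenate([[0.0], curve.times])
    s = np.concatenate([[1.0], curve.survival])
    return float(np.sum(np.diff(t) * s[:-1]))


def logrank_test(times, status, groups) -> LogRankResult:
    """k-sample log-rank test (chi-square with k-1 df)."""
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    res = multivariate_logrank_test(times, groups, status)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=int(labels.size - 1),
        p_value=float(res.p_value),
    )


def descriptive_table(cohort: Cohort) -> pd.DataFrame:
    """Per covariate level: n (%), recovered n (%), not-recovered n (%),
    plus the contingency chi-square and the log-rank statistic.

    The two test statistics answer different questions (association of the
    level with recovery status vs. with the full survival experience) and
    are labelled explicitly.
    """
    surv = cohort.surv
    total = len(surv)
    rows = []
    for cov in cohort.design.covariates:
        obs = surv[cov.name].astype(str)
        rec = surv["status"].astype(int)
        counts = pd.crosstab(obs, rec).reindex(
            index=list(cov.levels), columns=[0, 1], fill_value=0
        )
        if (counts.sum(axis=1) > 0).sum() >= 2 and counts.sum(axis=0).gt(0).sum() >= 2:
            nonzero = counts.loc[counts.sum(axis=1) > 0]
            chi2, chi2_p = stats.chi2_contingency(nonzero)[:2]
        else:
            chi2, chi2_p = np.nan, np.nan
        if obs.nunique() >= 2:
            lr = logrank_test(surv["event_time_h"], rec, obs)
            lr_stat, lr_p = lr.statistic, lr.p_value
        else:
            lr_stat, lr_p = np.nan, np.nan
        for level in cov.levels:
            n_level = int(counts.loc[level].sum())
            n_rec = int(counts.loc[level, 1])
            n_not = int(counts.loc[level, 0])
            rows.append(
                {
                    "covariate": cov.name,
                    "level": level,
                    "n": n_level,
                    "pct_of_total": 100.0 * n_level / total if total else 0.0,
                    "recovered_n": n_rec,
                    "recovered_pct": 100.0 * n_rec / n_level if n_level else 0.0,
                    "not_recovered_n": n_not,
                    "not_recovered_pct": 100.0 * n_not / n_level if n_level else 0.0,
                    "contingency_chi2": chi2,
                    "contingency_p": chi2_p,
                    "logrank_chi2": lr_stat,
                    "logrank_p": lr_p,
                }
            )
    rows.append(
        {
            "covariate": "overall",
            "level": "recovered",
            "n": int(surv["status"].sum()),
            "pct_of_total": 100.0 * surv["status"].mean() if total else 0.0,
            "recovered_n": int(surv["status"].sum()),
            "recovered_pct": 100.0,
            "not_recovered_n": 0,
            "not_recovered_pct": 0.0,
            "contingency_chi2": np.nan,
            "contingency_p": np.nan,
            "logrank_chi2": np.nan,
            "logrank_p": np.nan,
        }
    )
    return pd.DataFrame(rows)


def profiles(cohort: Cohort, outcome: str):
    """Per-subject trajectories plus the visit-aligned mean trajectory.

    Returns (individual, mean) where ``individual`` is the long table for
    the outcome and ``mean`` has one row per visit time with the mean value
    and the number of subjects still under observation; visits with no
    contributing subject are omitted.
    """
    sub = cohort.longitudinal(outcome)
    if sub.empty:
        raise ValueError(f"no longitudinal records for outcome {outcome!r}")
    mean = (
        sub.groupby("time_h")["value"]
        .agg(mean="mean", n="count")
        .reset_index()
        .sort_values("time_h", ignore_index=True)
    )
    return sub.copy(), mean


def marginal_correlation_profile(lmm_fit, time_grid) -> pd.DataFrame:
    """Model-implied correlation between the two outcomes at each time.

        rho(t) = z' D12 z / sqrt((z' D11 z + s1^2)(z' D22 z + s2^2)),

    with z = (1, t), D the fitted 4x4 random-effects covariance (blocks
    ordered PR intercept/slope then BT intercept/slope) and s_k the
    residual SDs.
    """
    D = np.asarray(lmm_fit.D, dtype=float)
    if np.linalg.eigvalsh(0.5 * (D + D.T)).min() < -1e-8:
        raise ValueError("fitted random-effects covariance is not PSD")
    s1, s2 = lmm_fit.sigma
    t = np.asarray(time_grid, dtype=float)
    z = np.column_stack([np.ones_like(t), t])
    D11, D22, D12 = D[:2, :2], D[2:, 2:], D[:2, 2:]
    v1 = np.einsum("ti,ij,tj->t", z, D11, z) + s1**2
    v2 = np.einsum("ti,ij,tj->t", z, D22, z) + s2**2
    cov = np.einsum("ti,ij,tj->t", z, D12, z)
    rho = cov / np.sqrt(v1 * v2)
    return pd.DataFrame({"time_h": t, "correlation": rho})


def empirical_correlation_profile(cohort: Cohort) -> pd.DataFrame:
    """Per-visit sample correlation between the two outcomes (subjects with
    both measurements at that visit)."""
    k1, k2 = cohort.design.outcomes
    wide = cohort.long.pivot_table(
        index=["subject_id", "time_h"], columns="outcome", values="value"
    ).dropna()
    rows = []
    for t, grp in wide.groupby(level="time_h"):
        if len(grp) >= 3:
            r = np.corrcoef(grp[k1], grp[k2])[0, 1]
            rows.append({"time_h": float(t), "correlation": float(r), "n": len(grp)})
    return pd.DataFrame(rows)
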