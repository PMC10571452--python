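"""Separate-analysis survival models for time to recovery.

``fit_cox`` is the semiparametric Cox proportional-hazards model on the
baseline covariates (partial likelihood via lifelines, Efron ties by
default since the 6-hourly grid produces many ties; Breslow selectable),
together with the hazard-ratio transform used throughout the reporting.
``fit_piecewise_ph`` is the fully parametric analogue with a
piecewise-constant baseline hazard; it shares its baseline-hazard family
with the joint model, which uses it both for initial values and for
separability checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceWarning
from scipy import optimize, stats

from .hazard import PiecewiseConstantHazard

__all__ = [
    "CoxFit",
    "PiecewisePHFit",
    "fit_cox",
    "fit_piecewise_ph",
    "hazard_ratio",
    "percent_change",
]

Z975 = 1.959963984540054


@dataclass
class CoxFit:
    columns: tuple
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    partial_loglik: float
    baseline_cumhaz: pd.Series  # Breslow estimate on the event-time grid
    params: pd.DataFrame
    converged: bool
    message: str


@dataclass
class PiecewisePHFit:
    columns: tuple
    coef: np.ndarray
    se: np.ndarray
    hazard: PiecewiseConstantHazard
    loglik: float
    converged: bool


def hazard_ratio(coef: float) -> float:
    """HR = exp(coef)."""
    coef = float(coef)
    if not np.isfinite(coef):
        raise ValueError("coefficient must be finite")
    return float(np.exp(coef))


def percent_change(coef: float) -> float:
    """Percent change in hazard: 100(1 - e^c) for c < 0, 100(e^c - 1) else."""
    hr = hazard_ratio(coef)
    return 100.0 * (1.0 - hr) if coef < 0 else 100.0 * (hr - 1.0)


def fit_cox(times, status, W, columns=(), ties: str = "efron") -> CoxFit:
    """Cox PH fit on baseline covariates.

    W may have zero columns, in which case only the Breslow baseline
    cumulative hazard (Nelson-Aalen-type) is estimated.  Monotone
    likelihood / separation is flagged on the fit rather than raised.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if status.sum() < 1:
        raise ValueError("need at least one event")
    columns = tuple(columns) if len(columns) else tuple(
        f"w{j}" for j in range(W.shape[1])
    )
    df = pd.DataFrame(W, columns=list(columns))
    df["time"] = times
    df["status"] = status

    cph = CoxPHFitter()
    converged, message = True, ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        try:
            cph.fit(
                df,
                duration_col="time",
                event_col="status",
                fit_options={"step_size": 0.5},
            )
        except Exception as exc:
            # monotone likelihood / separation: retry with a small ridge and
            # flag the fit instead of raising
            converged = False
            message = f"unpenalised fit failed ({exc}); ridge-penalised retry"
            cph = CoxPHFitter(penalizer=0.01)
            cph.fit(df, duration_col="time", event_col="status",
                    fit_options={"step_size": 0.25})
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                converged = False
                message = message or str(w.message)

    if W.shape[1]:
        coef = cph.params_.to_numpy()
        se = cph.standard_errors_.to_numpy()
        pll = float(cph.log_likelihood_)
    else:
        coef = np.zeros(0)
        se = np.zeros(0)
        pll = float(cph.log_likelihood_)
    ch = cph.baseline_cumulative_hazard_.iloc[:, 0]

    rows = []
    with np.errstate(over="ignore"):
        for name, c, s in zip(columns, coef, se):
            z = c / s if s > 0 else np.nan
            rows.append(
                {
                    "parameter": f"surv:{name}",
                    "estimate": c,
                    "se": s,
                    "ci_low": c - Z975 * s,
                    "ci_high": c + Z975 * s,
                    "hr": np.exp(c),
                    "hr_ci_low": np.exp(c - Z975 * s),
                    "hr_ci_high": np.exp(c + Z975 * s),
                    "p_value": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                }
            )
    return CoxFit(
        columns=columns if W.shape[1] else (),
        coef=coef,
        se=se,
        hr=np.exp(coef),
        partial_loglik=pll,
        baseline_cumhaz=ch,
        params=pd.DataFrame(rows),
        converged=converged,
        message=message,
    )


def default_cuts(times, status, n_pieces: int = 5) -> tuple:
    """Interior cutpoints at event-time quantiles (quintiles by default)."""
    ev = np.asarray(times, dtype=float)[np.asarray(status, dtype=int) == 1]
    if ev.size == 0:
        raise ValueError("need at least one event to place cutpoints")
    qs = np.quantile(ev, np.linspace(0, 1, n_pieces + 1)[1:-1])
    cuts = sorted(set(float(q) for q in qs if q > 0))
    return tuple(cuts)


def _exposures(times, cuts):
    """Exposure time of each subject in each piece, (n, P)."""
    times = np.asarray(times, dtype=float)
    starts = np.concatenate([[0.0], np.asarray(cuts, dtype=float)])
    ends = np.concatenate([np.asarray(cuts, dtype=float), [np.inf]])
    return np.clip(np.minimum(times[:, None], ends[None]) - starts[None], 0.0, None)


def fit_piecewise_ph(times, status, W, columns=(), cuts=None, n_pieces: int = 5):
    """ML fit of the piecewise-exponential proportional-hazards model.

    The piece rates are profiled out in closed form (occurrence/exposure
    weighted by exp(gamma'w)), leaving a low-dimensional search over gamma.
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status, dtype=int)
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    q = W.shape[1]
    columns = tuple(columns) if len(columns) else tuple(f"w{j}" for j in range(q))
    if cuts is None:
        cuts = default_cuts(times, status, n_pieces)
    cuts = tuple(cuts)
    E = _exposures(times, cuts)  # (n, P)
    piece_of_event = np.searchsorted(np.asarray(cuts), times, side="right")
    P = len(cuts) + 1
    d_p = np.array([((status == 1) & (piece_of_event == p)).sum() for p in range(P)])
    if d_p.sum() == 0:
        raise ValueError("need at least one event")

    def profile(gamma):
        eta = W @ gamma if q else np.zeros(len(times))
        w = np.exp(eta)
        denom = E.T @ w  # (P,)
        lam = np.where(denom > 0, d_p / np.maximum(denom, 1e-300), 1e-12)
        lam = np.maximum(lam, 1e-12)
        ll = float(
            np.sum(status * (np.log(lam[piece_of_event]) + eta))
            - np.sum((E * lam[None]) @ np.ones(P) * w)
        )
        return lam, ll

    if q:
        res = optimize.minimize(
            lambda g: -profile(g)[1],
            np.zeros(q),
            method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )
        gamma = res.x
        converged = bool(res.success)
        cov = res.hess_inv
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    else:
        gamma = np.zeros(0)
        se = np.zeros(0)
        converged = True
    lam, ll = profile(gamma)
    return PiecewisePHFit(
        columns=columns if q else (),
        coef=gamma,
        se=se,
        hazard=PiecewiseConstantHazard(cuts, tuple(lam)),
        loglik=ll,
        converged=converged,
    )
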