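"""Maximum-likelihood estimation of the bivariate linear mixed model.

The model for outcome k in {PR, BT} of subject i is

    y_ik(t) = x_ik(t)' beta_k + b_ik0 + b_ik1 t + eps_ik(t),

with (b_i10, b_i11, b_i20, b_i21) ~ N(0, D) shared across outcomes and
independent N(0, sigma_k^2) measurement noise.  Estimation is ML (not
REML): the same likelihood is a building block of the joint model, and
separate-versus-joint comparisons need one coherent objective.  D is
parameterised by its log-Cholesky factor (always PSD); beta is profiled
out by generalised least squares during optimisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._core import (
    StackedData,
    chol_pack,
    chol_unpack,
    fd_hessian,
    long_loglik,
    stack_cohort,
)
from .cohort import Cohort
from .params import flatten_D

__all__ = ["LmmSpec", "LmmFit", "lmm_loglik", "fit_lmm", "blup"]


@dataclass
class LmmSpec:
    """Fixed-effect columns per outcome plus the random-effect structure.

    ``x_columns`` maps outcome -> ordered column names (None: all design
    columns); ``random`` is "intercept_slope" (default) or "none" (plain
    independent-errors regression, mostly a degenerate reference point).
    """

    x_columns: dict | None = None
    random: str = "intercept_slope"
    method: str = "ML"

    def __post_init__(self) -> None:
        if self.random not in ("intercept_slope", "none"):
            raise ValueError("random must be 'intercept_slope' or 'none'")
        if self.method != "ML":
            raise ValueError("only ML estimation is supported")


@dataclass
class LmmFit:
    spec: LmmSpec
    data: StackedData
    beta: dict
    D: np.ndarray
    sigma: tuple
    loglik: float
    n_params: int
    aic: float
    bic: float
    converged: bool
    n_iter: int
    message: str
    params: pd.DataFrame
    theta_var: np.ndarray = field(repr=False, default=None)

    def parameter_values(self) -> dict:
        """Flattened estimates under the canonical naming."""
        out = {}
        for k in self.data.outcomes:
            for name, v in zip(self.data.x_columns[k], self.beta[k]):
                out[f"{k}:{name}"] = float(v)
        if self.D.size:
            out.update(flatten_D(self.D))
        for k, s in zip(self.data.outcomes, self.sigma):
            out[f"sigma_{k}"] = float(s)
        return out


def _as_stack(cohort_or_data, spec: LmmSpec | None = None) -> StackedData:
    if isinstance(cohort_or_data, StackedData):
        return cohort_or_data
    if isinstance(cohort_or_data, Cohort):
        x_cols = spec.x_columns if spec is not None else None
        return stack_cohort(cohort_or_data, x_cols)
    raise TypeError("expected a Cohort or StackedData")


def lmm_loglik(beta, D, sigma, cohort_or_data) -> float:
    """Marginal log-likelihood at natural-scale parameters.

    ``beta`` is either the stacked (p,) vector or a dict outcome -> vector;
    D is the r x r random-effects covariance (r = 4, or 0 x 0 for the
    no-random-effects model); sigma the pair of residual SDs.
    """
    data = _as_stack(cohort_or_data)
    if isinstance(beta, dict):
        beta = np.concatenate([np.asarray(beta[k], float) for k in data.outcomes])
    D = np.asarray(D, dtype=float)
    if D.size and data.r and D.shape != (data.r, data.r):
        raise ValueError(f"D must be {data.r}x{data.r}")
    ll = long_loglik(
        np.asarray(beta, float)[None],
        D[None] if D.size else np.zeros((1, data.r, data.r)),
        np.asarray(sigma, float)[None],
        data,
    )
    return float(ll.sum())


def _profile_beta(D, sigma, data: StackedData) -> np.ndarray:
    """GLS estimate of the stacked fixed effects at given (D, sigma).

    Uses the Woodbury identity so only r-dimensional systems are solved.
    """
    sig2 = np.asarray(sigma) ** 2
    Rdiag = np.where(data.mask, sig2[data.kofrow], 1.0)
    y = np.where(data.mask, data.Y, 0.0)
    Xw = data.X / Rdiag[..., None]
    if data.r:
        Zw = data.Z / Rdiag[..., None]
        try:
            Dinv = np.linalg.inv(D)
        except np.linalg.LinAlgError:
            Dinv = np.linalg.pinv(D)
        prec = np.matmul(np.swapaxes(Zw, -1, -2), data.Z) + Dinv
        ZtX = np.matmul(np.swapaxes(Zw, -1, -2), data.X)
        Zty = np.matmul(np.swapaxes(Zw, -1, -2), y[..., None])
        sol_X = np.linalg.solve(prec, ZtX)
        sol_y = np.linalg.solve(prec, Zty)
        A = np.einsum("nmp,nmq->pq", data.X, Xw) - np.einsum(
            "nrp,nrq->pq", ZtX, sol_X
        )
        rhs = np.einsum("nmp,nm->p", Xw, y) - np.einsum(
            "nrp,nr->p", ZtX, sol_y[..., 0]
        )
    else:
        A = np.einsum("nmp,nmq->pq", data.X, Xw)
        rhs = np.einsum("nmp,nm->p", Xw, y)
    return np.linalg.solve(A, rhs)


def _var_bounds(r):
    """Box bounds keeping log-scale parameters in a numerically safe range
    (log Cholesky diagonals and log residual SDs in [-8, 12])."""
    bounds = []
    for i in range(r):
        for j in range(i + 1):
            bounds.append((-8.0, 12.0) if i == j else (None, None))
    bounds += [(-8.0, 8.0)] * 2
    return bounds


def _unpack_var(theta, r):
    """(B, nvar) -> D (B, r, r), sigma (B, 2)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    ntri = r * (r + 1) // 2
    D = chol_unpack(theta[:, :ntri], r) if r else np.zeros((theta.shape[0], 0, 0))
    sigma = np.exp(theta[:, ntri : ntri + 2])
    return D, sigma


def _initial_theta(data: StackedData, r: int) -> np.ndarray:
    """Moment-based starting values: OLS residual spread split between a
    random intercept and the residual, small slope variance, zero
    cross-correlations."""
    sig0 = []
    int_var = []
    for j, k in enumerate(data.outcomes):
        rows = data.mask & (data.kofrow == j)
        y = data.Y[rows]
        X = data.X[rows][:, data.beta_slices[k]]
        if len(y) > X.shape[1]:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            v = float(np.var(resid)) or 1.0
        else:
            v = 1.0
        sig0.append(np.sqrt(0.5 * v))
        int_var.append(0.5 * v)
    if r == 0:
        return np.log(np.asarray(sig0))
    D0 = np.diag([int_var[0], 1e-2 * int_var[0] + 1e-4,
                  int_var[1], 1e-2 * int_var[1] + 1e-4])
    return np.concatenate([chol_pack(D0), np.log(sig0)])


def fit_lmm(spec: LmmSpec | None, cohort_or_data) -> LmmFit:
    """Fit the bivariate LMM by quasi-Newton ML.

    beta is profiled out by GLS inside the variance-parameter search;
    standard errors come from the inverse observed information of the full
    (beta, variance) likelihood.  Non-convergence is flagged on the fit,
    not raised.
    """
    spec = spec or LmmSpec()
    data = _as_stack(cohort_or_data, spec)
    r = data.r if spec.random == "intercept_slope" else 0
    if spec.random == "none":
        data = _drop_random(data)

    theta0 = _initial_theta(data, r)

    def nll_var(theta):
        try:
            D, sigma = _unpack_var(theta, r)
            beta = _profile_beta(D[0], sigma[0], data)
            val = -float(long_loglik(beta[None], D, sigma, data).sum())
        except np.linalg.LinAlgError:
            return 1e12
        return val if np.isfinite(val) else 1e12

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = optimize.minimize(
            nll_var,
            theta0,
            method="L-BFGS-B",
            bounds=_var_bounds(r),
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-6},
        )
    D, sigma = _unpack_var(res.x, r)
    D, sigma = D[0], sigma[0]
    beta = _profile_beta(D, sigma, data)
    ll = float(long_loglik(beta[None], D[None], sigma[None], data).sum())

    # observed information over the full (beta, variance) parameter vector
    def nll_full_batch(phis):
        phis = np.atleast_2d(phis)
        betas = phis[:, : data.p]
        Ds, sigmas = _unpack_var(phis[:, data.p :], r)
        return -long_loglik(betas, Ds, sigmas, data).sum(axis=1)

    phi = np.concatenate([beta, res.x])
    with np.errstate(over="ignore", invalid="ignore"):
        H = fd_hessian(nll_full_batch, phi, h_scale=1e-4, guard=True)
    beta_se = np.full(data.p, np.nan)
    try:
        cov = np.linalg.inv(H)
        dcov = np.diag(cov)
        if np.all(dcov[: data.p] > 0):
            beta_se = np.sqrt(dcov[: data.p])
        else:
            warnings.warn("observed information not PD; beta SEs unreliable")
    except np.linalg.LinAlgError:
        warnings.warn("singular observed information; beta SEs unavailable")

    n_params = data.p + r * (r + 1) // 2 + 2
    n_subj = data.n_subjects
    aic = -2.0 * ll + 2.0 * n_params
    bic = -2.0 * ll + n_params * np.log(max(n_subj, 1))

    rows = []
    for k in data.outcomes:
        sl = data.beta_slices[k]
        for name, est, se in zip(data.x_columns[k], beta[sl], beta_se[sl]):
            z = est / se if se and np.isfinite(se) and se > 0 else np.nan
            rows.append(
                {
                    "parameter": f"{k}:{name}",
                    "estimate": est,
                    "se": se,
                    "ci_low": est - 1.959963984540054 * se,
                    "ci_high": est + 1.959963984540054 * se,
                    "p_value": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                }
            )
    table = pd.DataFrame(rows)

    return LmmFit(
        spec=spec,
        data=data,
        beta={k: beta[data.beta_slices[k]].copy() for k in data.outcomes},
        D=D,
        sigma=tuple(sigma),
        loglik=ll,
        n_params=n_params,
        aic=aic,
        bic=bic,
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
        params=table,
        theta_var=res.x,
    )


def _drop_random(data: StackedData) -> StackedData:
    from dataclasses import replace

    return replace(data, Z=np.zeros(data.Z.shape[:2] + (0,)))


def blup(fit: LmmFit, subject_id: str):
    """Posterior mean and covariance of a subject's random effects.

    A subject with no longitudinal observations gets the prior (0, D).
    """
    data = fit.data
    if subject_id not in data.subjects:
        raise KeyError(f"unknown subject {subject_id!r}")
    i = data.subjects.index(subject_id)
    beta = np.concatenate([fit.beta[k] for k in data.outcomes])
    _, mu, Sig = long_loglik(
        beta[None], fit.D[None], np.asarray(fit.sigma)[None], data, want_posterior=True
    )
    return mu[0, i], Sig[0, i]
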