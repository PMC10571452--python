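"""Joint maximum-likelihood estimation of the bivariate longitudinal and
survival sub-models.

The subject-level likelihood is

    L_i = int prod_kj N(y_ikj | x'b_k + z'b_ik, s_k^2)
              h_i(T_i | b)^d_i exp(-Lam_i(T_i | b)) N(b | 0, D) db ,

with log h_i(t|b) = log h0(t) + gamma'w_i + (association term).  Because
the Gaussian longitudinal factor times the prior equals the marginal
longitudinal density times the Gaussian posterior of b, the integral is
evaluated as  (marginal) x E_posterior[survival term]  with a pruned
product Gauss-Hermite rule centred at each subject's posterior -- an
adaptive quadrature that is exact when the association vanishes.  True
trajectories are affine in time, so the piecewise-constant baseline
hazard gives a closed-form cumulative hazard on every node.

Association structures: "current_value" (hazard shifts with the noise-free
biomarker level m_k(t)), "current_value_and_slope" (adds the subject
slope m'_k), "shared_random_effects" (the two random slopes enter the
hazard directly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._core import (
    StackedData,
    chol_pack,
    chol_unpack,
    eval_chunked,
    fd_hessian,
    gh_nodes,
    long_loglik,
    logsumexp,
    stack_cohort,
)
from .cox import default_cuts, fit_piecewise_ph
from .hazard import PiecewiseConstantHazard, _expm1_div
from .lmm import LmmSpec, fit_lmm
from .params import association_param_names, flatten_D

__all__ = [
    "JointSpec",
    "JointFit",
    "joint_loglik",
    "fit_joint",
    "association_summary",
    "information_criteria",
    "conditional_survival",
]

Z975 = 1.959963984540054


@dataclass
class JointSpec:
    """Model structure for the joint fit.

    ``association`` selects the linkage; ``fix_alpha_zero`` constrains all
    association coefficients to zero (the separate-models special case).
    The baseline hazard is piecewise-constant with ``n_pieces`` pieces at
    event-time quantiles (or explicit ``cuts``); ``n_nodes`` is the
    Gauss-Hermite order per active random-effect dimension.
    """

    lmm: LmmSpec = field(default_factory=LmmSpec)
    w_columns: tuple | None = None
    association: str = "shared_random_effects"
    n_pieces: int = 5
    cuts: tuple | None = None
    n_nodes: int = 7
    prune: float = 1e-10
    fix_alpha_zero: bool = False
    #: centring of the biomarker inside the current-value association terms;
    #: None centres at the observed outcome means so the baseline hazard
    #: refers to an average biomarker level (the association coefficients
    #: are unaffected by this reparameterisation).
    assoc_center: tuple | None = None

    def __post_init__(self) -> None:
        if self.association not in (
            "current_value",
            "current_value_and_slope",
            "shared_random_effects",
        ):
            raise ValueError(f"unknown association {self.association!r}")
        if self.n_nodes < 3:
            raise ValueError("need at least 3 quadrature nodes per dimension")
        if self.n_pieces < 1:
            raise ValueError("need at least one baseline-hazard piece")


@dataclass
class JointFit:
    spec: JointSpec
    data: StackedData
    beta: dict
    D: np.ndarray
    sigma: tuple
    gamma: np.ndarray
    alpha: np.ndarray
    hazard: PiecewiseConstantHazard
    loglik: float
    n_params: int
    converged: bool
    se_reliable: bool
    n_iter: int
    message: str
    params: pd.DataFrame
    theta: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)

    @property
    def assoc_names(self) -> tuple:
        return association_param_names(
            None if self.spec.fix_alpha_zero else self.spec.association,
            self.data.outcomes,
        )

    def parameter_values(self) -> dict:
        out = {}
        for k in self.data.outcomes:
            for name, v in zip(self.data.x_columns[k], self.beta[k]):
                out[f"{k}:{name}"] = float(v)
        out.update(flatten_D(self.D))
        for k, s in zip(self.data.outcomes, self.sigma):
            out[f"sigma_{k}"] = float(s)
        for name, v in zip(self.data.w_columns, self.gamma):
            out[f"surv:{name}"] = float(v)
        for name, v in zip(self.assoc_names, self.alpha):
            out[name] = float(v)
        for p, r in enumerate(self.hazard.rates):
            out[f"h0:rate_{p + 1}"] = float(r)
        return out


# ---------------------------------------------------------------------------
# parameter packing


class _Layout:
    """Index layout of the internal unconstrained parameter vector."""

    def __init__(self, data: StackedData, spec: JointSpec, n_pieces: int):
        self.p = data.p
        self.ntri = data.r * (data.r + 1) // 2
        self.q = data.W.shape[1]
        if spec.fix_alpha_zero:
            self.na = 0
        else:
            self.na = len(association_param_names(spec.association, data.outcomes))
        self.npieces = n_pieces
        o = 0
        self.sl_beta = slice(o, o + self.p); o += self.p
        self.sl_chol = slice(o, o + self.ntri); o += self.ntri
        self.sl_lsig = slice(o, o + 2); o += 2
        self.sl_gamma = slice(o, o + self.q); o += self.q
        self.sl_alpha = slice(o, o + self.na); o += self.na
        self.sl_lrate = slice(o, o + n_pieces); o += n_pieces
        self.size = o

    def pack(self, beta, D, sigma, gamma, alpha, rates) -> np.ndarray:
        th = np.empty(self.size)
        th[self.sl_beta] = beta
        th[self.sl_chol] = chol_pack(D)
        th[self.sl_lsig] = np.log(sigma)
        th[self.sl_gamma] = gamma
        th[self.sl_alpha] = alpha
        th[self.sl_lrate] = np.log(rates)
        return th


def _assoc_vectors(spec: JointSpec, layout: _Layout, thetas, data, beta):
    """Per-batch association geometry: log h = log h0 + g + p'b + (r + q'b) t.

    Returns g (B, n), rbase (B,), p_vec (B, 4), q_vec (B, 4) and the active
    random-effect dimensions.
    """
    B = thetas.shape[0]
    gamma = thetas[:, layout.sl_gamma]
    eta_w = (
        np.einsum("nq,bq->bn", data.W, gamma)
        if layout.q
        else np.zeros((B, data.n_subjects))
    )
    p_vec = np.zeros((B, 4))
    q_vec = np.zeros((B, 4))
    rbase = np.zeros(B)
    g = eta_w
    if layout.na == 0:
        return g, rbase, p_vec, q_vec, (1, 3)

    alpha = thetas[:, layout.sl_alpha]
    if spec.association in ("current_value", "current_value_and_slope"):
        centers = (
            spec.assoc_center
            if spec.assoc_center is not None
            else tuple(data.ybar[k] for k in data.outcomes)
        )
        al = alpha[:, :2]
        xb = []
        bt = []
        for k, ctr in zip(data.outcomes, centers):
            sl = data.beta_slices[k]
            bk = beta[:, sl]
            xb.append(np.einsum("np,bp->bn", data.Xbase[k], bk[:, :-1]) - ctr)
            bt.append(bk[:, -1])
        g = g + al[:, 0:1] * xb[0] + al[:, 1:2] * xb[1]
        rbase = al[:, 0] * bt[0] + al[:, 1] * bt[1]
        p_vec[:, 0] = al[:, 0]
        p_vec[:, 2] = al[:, 1]
        q_vec[:, 1] = al[:, 0]
        q_vec[:, 3] = al[:, 1]
        if spec.association == "current_value_and_slope":
            als = alpha[:, 2:4]
            g = g + als[:, 0:1] * bt[0][:, None] + als[:, 1:2] * bt[1][:, None]
            p_vec[:, 1] += als[:, 0]
            p_vec[:, 3] += als[:, 1]
        active = (0, 1, 2, 3)
    else:  # shared_random_effects
        p_vec[:, 1] = alpha[:, 0]
        p_vec[:, 3] = alpha[:, 1]
        active = (1, 3)
    return g, rbase, p_vec, q_vec, active


def _pc_cumulative_batch(cuts, rates, T, A, C):
    """Closed-form Lambda(T) with per-batch rates.

    rates: (B, P); T: (n,); A, C: (B, n, K).  Broadcasts to (B, n, K).
    """
    starts = np.concatenate([[0.0], np.asarray(cuts, dtype=float)])
    ends = np.concatenate([np.asarray(cuts, dtype=float), [np.inf]])
    total = np.zeros(np.broadcast_shapes(A.shape, C.shape))
    with np.errstate(over="ignore"):
        for p in range(rates.shape[1]):
            dt = np.clip(np.minimum(T, ends[p]) - starts[p], 0.0, None)
            lam = rates[:, p][:, None, None]
            total = total + lam * np.exp(A + C * starts[p]) * _expm1_div(
                C, dt[None, :, None]
            )
    return total


def _make_nll(data: StackedData, spec: JointSpec, cuts: tuple):
    """Batched negative joint log-likelihood over the internal vector."""
    layout = _Layout(data, spec, len(cuts) + 1)
    T = data.T
    delta = data.delta.astype(float)
    piece_of_T = np.searchsorted(np.asarray(cuts), T, side="right")

    def nll(thetas: np.ndarray) -> np.ndarray:
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        beta = thetas[:, layout.sl_beta]
        D = chol_unpack(thetas[:, layout.sl_chol], data.r)
        sigma = np.exp(thetas[:, layout.sl_lsig])
        rates = np.exp(thetas[:, layout.sl_lrate])

        ll_long, mu, Sig = long_loglik(beta, D, sigma, data, want_posterior=True)
        g, rbase, p_vec, q_vec, active = _assoc_vectors(
            spec, layout, thetas, data, beta
        )
        act = list(active)
        mua = mu[:, :, act]
        Siga = Sig[:, :, act][:, :, :, act]
        da = len(act)
        jitter = 1e-10 * np.eye(da)
        La = np.linalg.cholesky(Siga + jitter)
        z, logw = gh_nodes(spec.n_nodes, da, spec.prune)
        # (K, da) @ La' -> (B, n, K, da), BLAS-backed
        b_nodes = mua[:, :, None, :] + np.matmul(z, np.swapaxes(La, -1, -2))
        A = g[:, :, None] + np.matmul(b_nodes, p_vec[:, act][:, None, :, None])[..., 0]
        C = (
            rbase[:, None, None]
            + np.matmul(b_nodes, q_vec[:, act][:, None, :, None])[..., 0]
        )
        Lam = _pc_cumulative_batch(cuts, rates, T, A, C)
        log_h = (
            np.log(rates[:, piece_of_T])[:, :, None] + A + C * T[None, :, None]
        )
        logS = delta[None, :, None] * log_h - Lam
        ll_surv = logsumexp(logw[None, None, :] + logS, axis=-1)
        return -(ll_long + ll_surv).sum(axis=1)

    return nll, layout


def _resolve(cohort_or_data, spec: JointSpec) -> StackedData:
    data = (
        cohort_or_data
        if isinstance(cohort_or_data, StackedData)
        else stack_cohort(cohort_or_data, spec.lmm.x_columns)
    )
    if spec.w_columns is not None:
        idx = [data.w_columns.index(c) for c in spec.w_columns]
        data = replace(data, W=data.W[:, idx], w_columns=tuple(spec.w_columns))
    return data


def _spec_cuts(spec: JointSpec, data: StackedData) -> tuple:
    if spec.cuts is not None:
        return tuple(spec.cuts)
    return default_cuts(data.T, data.delta, spec.n_pieces)


def joint_loglik(values, cohort_or_data, spec: JointSpec) -> float:
    """Joint log-likelihood at natural-scale parameters.

    ``values`` maps the canonical parameter names (as in
    ``TrueParameterReport``/``JointFit.parameter_values``) to numbers; the
    baseline-hazard cutpoints come from ``spec.cuts`` (required here so the
    rate parameters are well-defined).
    """
    data = _resolve(cohort_or_data, spec)
    if spec.cuts is None:
        raise ValueError("joint_loglik needs explicit spec.cuts")
    cuts = tuple(spec.cuts)
    nll, layout = _make_nll(data, spec, cuts)
    beta = np.concatenate(
        [
            [values[f"{k}:{c}"] for c in data.x_columns[k]]
            for k in data.outcomes
        ]
    )
    D = np.zeros((4, 4))
    from .params import RE_LABELS

    for i in range(4):
        for j in range(i + 1):
            D[i, j] = D[j, i] = values[f"D[{RE_LABELS[i]},{RE_LABELS[j]}]"]
    sigma = np.array([values[f"sigma_{k}"] for k in data.outcomes])
    gamma = np.array([values[f"surv:{c}"] for c in data.w_columns])
    alpha = np.array(
        [values[n] for n in association_param_names(spec.association, data.outcomes)]
        if not spec.fix_alpha_zero
        else []
    )
    rates = np.array([values[f"h0:rate_{p + 1}"] for p in range(len(cuts) + 1)])
    theta = layout.pack(beta, D, sigma, gamma, alpha, rates)
    val = -float(nll(theta[None])[0])
    if not np.isfinite(val):
        raise FloatingPointError("non-finite joint log-likelihood")
    return val


def fit_joint(spec: JointSpec | None, cohort_or_data, verbose: bool = False) -> JointFit:
    """Fit the joint model by quasi-Newton on the quadrature likelihood.

    Initial values come from the separate fits (bivariate LMM; piecewise
    proportional-hazards) with the association started at zero; the fit is
    deterministic given data and spec.  Standard errors come from the
    inverse observed information; a non-PD Hessian flags them unreliable.
    """
    spec = spec or JointSpec()
    data = _resolve(cohort_or_data, spec)
    if data.n_subjects < 20:
        warnings.warn("fewer than 20 subjects: joint fit may be unstable")
    cuts = _spec_cuts(spec, data)
    nll, layout = _make_nll(data, spec, cuts)

    lfit = fit_lmm(spec.lmm, data)
    sfit = fit_piecewise_ph(
        data.T, data.delta, data.W, data.w_columns, cuts=cuts
    )
    beta0 = np.concatenate([lfit.beta[k] for k in data.outcomes])
    D0 = _regularize(lfit.D)
    theta0 = layout.pack(
        beta0,
        D0,
        np.asarray(lfit.sigma),
        sfit.coef,
        np.zeros(layout.na),
        np.asarray(sfit.hazard.rates),
    )

    trace: list[tuple] = []

    def value_and_grad(theta):
        P = theta.size
        h = 1e-6 * (1.0 + np.abs(theta))
        pts = np.empty((2 * P + 1, P))
        pts[0] = theta
        for j in range(P):
            pts[2 * j + 1] = theta
            pts[2 * j + 1, j] += h[j]
            pts[2 * j + 2] = theta
            pts[2 * j + 2, j] -= h[j]
        vals = eval_chunked(nll, pts, chunk=32, guard=True)
        f = vals[0]
        grad = (vals[1::2] - vals[2::2]) / (2.0 * h)
        trace.append((f, float(np.linalg.norm(grad))))
        if verbose:
            print(f"iter {len(trace):4d}  -2ll {2 * f:.6f}  |grad| {trace[-1][1]:.3e}")
        return f, grad

    with np.errstate(over="ignore", invalid="ignore"):
        res = optimize.minimize(
            value_and_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-11, "gtol": 1e-5},
        )
    theta = res.x
    ll = -float(res.fun)

    se = np.full(layout.size, np.nan)
    se_reliable = True
    cov = None
    with np.errstate(over="ignore", invalid="ignore"):
        H = fd_hessian(nll, theta, h_scale=1e-4, chunk=32, guard=True)
    try:
        evals = np.linalg.eigvalsh(0.5 * (H + H.T))
        if evals.min() <= 0:
            se_reliable = False
            warnings.warn("observed information not positive definite at optimum")
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        if np.any(d <= 0):
            se_reliable = False
    except np.linalg.LinAlgError:
        se_reliable = False
        warnings.warn("singular observed information; SEs unavailable")

    beta = theta[layout.sl_beta]
    D = chol_unpack(theta[layout.sl_chol][None], data.r)[0]
    sigma = np.exp(theta[layout.sl_lsig])
    gamma = theta[layout.sl_gamma]
    alpha = theta[layout.sl_alpha]
    rates = np.exp(theta[layout.sl_lrate])

    rows = []

    def add_row(name, est, s, hr=False):
        z = est / s if np.isfinite(s) and s > 0 else np.nan
        row = {
            "parameter": name,
            "estimate": est,
            "se": s,
            "ci_low": est - Z975 * s,
            "ci_high": est + Z975 * s,
            "p_value": 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
        }
        if hr:
            row["hr"] = np.exp(est)
            row["hr_ci_low"] = np.exp(est - Z975 * s)
            row["hr_ci_high"] = np.exp(est + Z975 * s)
        rows.append(row)

    for k in data.outcomes:
        sl = data.beta_slices[k]
        for name, est, s in zip(
            data.x_columns[k], beta[sl], se[layout.sl_beta][sl]
        ):
            add_row(f"{k}:{name}", est, s)
    for name, est, s in zip(data.w_columns, gamma, se[layout.sl_gamma]):
        add_row(f"surv:{name}", est, s, hr=True)
    assoc_names = association_param_names(
        None if spec.fix_alpha_zero else spec.association, data.outcomes
    )
    for name, est, s in zip(assoc_names, alpha, se[layout.sl_alpha]):
        add_row(name, est, s, hr=True)
    for p_i, (r, ls) in enumerate(zip(rates, se[layout.sl_lrate])):
        add_row(f"h0:rate_{p_i + 1}", r, r * ls if np.isfinite(ls) else np.nan)

    fit = JointFit(
        spec=spec,
        data=data,
        beta={k: beta[data.beta_slices[k]].copy() for k in data.outcomes},
        D=D,
        sigma=tuple(sigma),
        gamma=gamma.copy(),
        alpha=alpha.copy(),
        hazard=PiecewiseConstantHazard(cuts, tuple(rates)),
        loglik=ll,
        n_params=layout.size,
        converged=bool(res.success),
        se_reliable=se_reliable,
        n_iter=int(res.nit),
        message=str(res.message),
        params=pd.DataFrame(rows),
        theta=theta,
        cov=cov,
    )
    return fit


def _regularize(D: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Lift tiny/negative eigenvalues so chol_pack is defined."""
    w, v = np.linalg.eigh(0.5 * (D + D.T))
    scale = max(np.max(w), 1.0)
    return (v * np.clip(w, floor * scale, None)) @ v.T


def association_summary(fit: JointFit) -> pd.DataFrame:
    """Hazard ratios and percent hazard change per association coefficient
    (delta-method CIs on the exp scale)."""
    rows = []
    tab = fit.params.set_index("parameter")
    for name in fit.assoc_names:
        est = float(tab.loc[name, "estimate"])
        s = float(tab.loc[name, "se"])
        hr = float(np.exp(est))
        rows.append(
            {
                "parameter": name,
                "estimate": est,
                "se": s,
                "hr": hr,
                "hr_ci_low": float(np.exp(est - Z975 * s)),
                "hr_ci_high": float(np.exp(est + Z975 * s)),
                "percent_change": 100.0 * (1.0 - hr) if est < 0 else 100.0 * (hr - 1.0),
                "p_value": float(tab.loc[name, "p_value"]),
            }
        )
    return pd.DataFrame(rows)


def _blup_all(fit: JointFit):
    """Posterior means of b given each subject's longitudinal data."""
    data = fit.data
    beta = np.concatenate([fit.beta[k] for k in data.outcomes])
    _, mu, _ = long_loglik(
        beta[None], fit.D[None], np.asarray(fit.sigma)[None], data,
        want_posterior=True,
    )
    return mu[0]


def _subject_AC(fit: JointFit, b: np.ndarray):
    """(A, C) of log h = log h0 + A + C t for given random effects (n, 4)."""
    data = fit.data
    spec = fit.spec
    gamma = fit.gamma
    eta_w = data.W @ gamma if data.W.shape[1] else np.zeros(data.n_subjects)
    if spec.fix_alpha_zero or fit.alpha.size == 0:
        return eta_w, np.zeros(data.n_subjects)
    k1, k2 = data.outcomes
    centers = (
        spec.assoc_center
        if spec.assoc_center is not None
        else tuple(data.ybar[k] for k in data.outcomes)
    )
    a = {}
    c = {}
    for j, (k, ctr) in enumerate(zip(data.outcomes, centers)):
        bk = fit.beta[k]
        a[k] = data.Xbase[k] @ bk[:-1] + b[:, 2 * j] - ctr
        c[k] = bk[-1] + b[:, 2 * j + 1]
    al = fit.alpha
    if spec.association == "current_value":
        A = eta_w + al[0] * a[k1] + al[1] * a[k2]
        C = al[0] * c[k1] + al[1] * c[k2]
    elif spec.association == "current_value_and_slope":
        A = eta_w + al[0] * a[k1] + al[1] * a[k2] + al[2] * c[k1] + al[3] * c[k2]
        C = al[0] * c[k1] + al[1] * c[k2]
    else:
        A = eta_w + al[0] * b[:, 1] + al[1] * b[:, 3]
        C = np.zeros(data.n_subjects)
    return A, C


def information_criteria(fit: JointFit) -> dict:
    """AIC/BIC with a conditional longitudinal/survival decomposition.

    The survival part is the conditional survival log-likelihood evaluated
    at the empirical-Bayes random effects, with the survival-side parameter
    count (gamma, association, baseline rates); the longitudinal part is
    the remainder, so the parts sum to the total criterion exactly.
    """
    n = fit.data.n_subjects
    p = fit.n_params
    aic = -2.0 * fit.loglik + 2.0 * p
    bic = -2.0 * fit.loglik + p * np.log(max(n, 1))

    b = _blup_all(fit)
    A, C = _subject_AC(fit, b)
    T = fit.data.T
    delta = fit.data.delta.astype(float)
    Lam = fit.hazard.cumulative(T, A, C)
    ll_surv = float(np.sum(delta * fit.hazard.log_hazard(T, A, C) - Lam))
    p_surv = len(fit.gamma) + len(fit.alpha) + fit.hazard.n_pieces
    aic_surv = -2.0 * ll_surv + 2.0 * p_surv
    bic_surv = -2.0 * ll_surv + p_surv * np.log(max(n, 1))
    return {
        "loglik": fit.loglik,
        "n_params": p,
        "aic": aic,
        "bic": bic,
        "aic_survival": aic_surv,
        "aic_longitudinal": aic - aic_surv,
        "bic_survival": bic_surv,
        "bic_longitudinal": bic - bic_surv,
        "conditional_surv_loglik": ll_surv,
    }


def conditional_survival(
    fit: JointFit, subject_id: str, t: float, horizon: float
) -> float:
    """P(T >= t + horizon | T >= t, longitudinal history up to t).

    Empirical-Bayes plug-in: the posterior mean of the subject's random
    effects given measurements up to t, then the ratio of plug-in survival
    functions.  Nonincreasing in the horizon; equals 1 at horizon 0.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    data = fit.data
    if subject_id not in data.subjects:
        raise KeyError(f"unknown subject {subject_id!r}")
    i = data.subjects.index(subject_id)

    # rows of this subject's history observed no later than t
    obs = data.mask[i] & ((data.Z[i, :, 1] + data.Z[i, :, 3]) <= t)
    beta = np.concatenate([fit.beta[k] for k in data.outcomes])
    y = data.Y[i][obs]
    X = data.X[i][obs]
    Z = data.Z[i][obs]
    sig2 = np.asarray(fit.sigma) ** 2
    Rinv = 1.0 / sig2[data.kofrow[i][obs]]
    Dinv = np.linalg.inv(fit.D)
    prec = (Z * Rinv[:, None]).T @ Z + Dinv
    Sigma = np.linalg.inv(prec)
    bhat = Sigma @ ((Z * Rinv[:, None]).T @ (y - X @ beta))

    A, C = _subject_AC(fit, np.tile(bhat, (data.n_subjects, 1)))
    Ai, Ci = A[i], C[i]
    lam_t = fit.hazard.cumulative(t, Ai, Ci)
    lam_h = fit.hazard.cumulative(t + horizon, Ai, Ci)
    return float(np.exp(-(lam_h - lam_t)))
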