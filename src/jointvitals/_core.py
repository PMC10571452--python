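"""Internal likelihood engine: per-subject stacked arrays and batched
Gaussian computations.

Subjects are padded to a common visit count M; padded rows have zero design
rows, zero residuals and unit residual variance so they contribute nothing
to any likelihood.  Every function broadcasts over an optional leading
parameter-batch axis B, which lets finite-difference gradients and Hessians
be computed as a single vectorised evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, build_design

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class StackedData:
    """Cohort flattened to padded per-subject arrays.

    Longitudinal: Y/mask/kofrow are (n, M); X is (n, M, p) with the two
    outcomes' fixed-effect columns side by side (PR block then BT block);
    Z is (n, M, r) with random intercept+slope per outcome.  Survival:
    T/delta are (n,), W is (n, q); Xbase[k] is the time-free part of the
    longitudinal design row (intercept + dummies) per subject.
    """

    subjects: list
    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    mask: np.ndarray
    kofrow: np.ndarray
    n_obs: np.ndarray
    x_columns: dict
    beta_slices: dict
    outcomes: tuple
    T: np.ndarray
    delta: np.ndarray
    W: np.ndarray
    w_columns: tuple
    Xbase: dict
    time_index: dict
    ybar: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def p(self) -> int:
        return self.X.shape[2]

    @property
    def r(self) -> int:
        return self.Z.shape[2]

    @property
    def total_obs(self) -> int:
        return int(self.n_obs.sum())


def stack_cohort(cohort: Cohort, x_columns: dict | None = None) -> StackedData:
    """Build padded stacks from a validated cohort.

    ``x_columns`` optionally restricts the fixed-effect columns per outcome
    (default: all design columns).  The visit-time column must be present
    and last so trajectories stay affine in time.
    """
    dm = build_design(cohort)
    design = cohort.design
    outcomes = design.outcomes
    tcol = design.time_column
    all_cols = dm.x_columns
    if x_columns is None:
        x_columns = {k: tuple(all_cols) for k in outcomes}
    for k in outcomes:
        cols = tuple(x_columns[k])
        if cols[-1] != tcol or tcol not in cols:
            raise ValueError(f"x columns for {k!r} must end with {tcol!r}")
        missing = [c for c in cols if c not in all_cols]
        if missing:
            raise ValueError(f"unknown design columns for {k!r}: {missing}")

    subjects = list(cohort.surv["subject_id"].astype(str))
    sidx = {s: i for i, s in enumerate(subjects)}
    n = len(subjects)
    colidx = {k: [all_cols.index(c) for c in x_columns[k]] for k in outcomes}
    p_k = {k: len(colidx[k]) for k in outcomes}
    p = sum(p_k.values())
    beta_slices = {}
    off = 0
    for k in outcomes:
        beta_slices[k] = slice(off, off + p_k[k])
        off += p_k[k]
    r = 2 * len(outcomes)

    per_subject: list[list[tuple]] = [[] for _ in range(n)]
    for j, k in enumerate(outcomes):
        Xk_full = dm.X[k]
        sub = cohort.longitudinal(k)
        vals = sub["value"].to_numpy(dtype=float)
        times = sub["time_h"].to_numpy(dtype=float)
        subs = sub["subject_id"].astype(str).to_numpy()
        for row in range(len(sub)):
            per_subject[sidx[subs[row]]].append(
                (j, times[row], vals[row], Xk_full[row, colidx[k]])
            )

    M = max((len(rows) for rows in per_subject), default=0)
    M = max(M, 1)
    Y = np.zeros((n, M))
    X = np.zeros((n, M, p))
    Z = np.zeros((n, M, r))
    mask = np.zeros((n, M), dtype=bool)
    kofrow = np.zeros((n, M), dtype=int)
    for i, rows in enumerate(per_subject):
        rows.sort(key=lambda t: (t[0], t[1]))
        for m, (j, t, v, xr) in enumerate(rows):
            Y[i, m] = v
            k = outcomes[j]
            X[i, m, beta_slices[k]] = xr
            Z[i, m, 2 * j] = 1.0
            Z[i, m, 2 * j + 1] = t
            mask[i, m] = True
            kofrow[i, m] = j
    n_obs = mask.sum(axis=1)

    surv = cohort.surv
    T = surv["event_time_h"].to_numpy(dtype=float)
    delta = surv["status"].to_numpy(dtype=int)
    W = dm.W
    # time-free part of the longitudinal design per subject and outcome
    Xbase = {}
    time_index = {}
    base_full = np.column_stack([np.ones(n), W])  # (intercept, dummies)
    base_cols = ("intercept",) + dm.w_columns
    for k in outcomes:
        cols = tuple(x_columns[k])[:-1]
        idx = [base_cols.index(c) for c in cols]
        Xbase[k] = base_full[:, idx]
        time_index[k] = len(cols)  # position of time coef inside beta_k
    return StackedData(
        subjects=subjects,
        Y=Y,
        X=X,
        Z=Z,
        mask=mask,
        kofrow=kofrow,
        n_obs=n_obs,
        x_columns={k: tuple(x_columns[k]) for k in outcomes},
        beta_slices=beta_slices,
        outcomes=outcomes,
        T=T,
        delta=delta,
        W=W,
        w_columns=dm.w_columns,
        Xbase=Xbase,
        time_index=time_index,
        ybar={
            k: (
                float(cohort.longitudinal(k)["value"].mean())
                if len(cohort.longitudinal(k))
                else 0.0
            )
            for k in outcomes
        },
    )


def _ensure_batch(a: np.ndarray, nd: int) -> tuple[np.ndarray, bool]:
    a = np.asarray(a, dtype=float)
    if a.ndim == nd:
        return a[None, ...], False
    return a, True


def residual_variances(sigma: np.ndarray, data: StackedData) -> np.ndarray:
    """Per-row residual variances (B, n, M); padded rows get variance 1."""
    sig2 = sigma**2  # (B, 2)
    out = sig2[:, data.kofrow]  # (B, n, M)
    return np.where(data.mask[None, :, :], out, 1.0)


def long_loglik(beta, D, sigma, data: StackedData, want_posterior: bool = False):
    """Marginal Gaussian log-likelihood of the longitudinal data.

    beta: (B, p) stacked fixed effects; D: (B, r, r); sigma: (B, 2).
    Returns (B, n) per-subject log-likelihoods, and optionally the
    posterior mean (B, n, r) and covariance (B, n, r, r) of the random
    effects given the longitudinal data.
    """
    beta, _ = _ensure_batch(beta, 1)
    D, _ = _ensure_batch(D, 2)
    sigma, _ = _ensure_batch(sigma, 1)
    B = beta.shape[0]
    n, M, r = data.Z.shape[0], data.Z.shape[1], data.r

    resid = np.where(
        data.mask[None],
        data.Y[None] - np.matmul(data.X, beta.T).transpose(2, 0, 1),
        0.0,
    )
    Rdiag = residual_variances(sigma, data)  # (B, n, M)

    # V = R + Z D Z'; Woodbury keeps everything r-dimensional:
    #   logdet V = logdet R + logdet D + logdet(Z'R^-1 Z + D^-1)
    #   resid'V^-1 resid = resid'R^-1 resid - m' prec^-1 m,  m = Z'R^-1 resid
    # The dense fallback covers singular D (e.g. D = 0).
    singular_D = r > 0 and bool(
        np.any(np.linalg.eigvalsh(D).min(axis=-1) <= 1e-12 * np.abs(D).max())
    )
    quad_R = np.sum(resid**2 / Rdiag, axis=-1)
    logdet_R = np.sum(np.where(data.mask[None], np.log(Rdiag), 0.0), axis=-1)

    if r == 0:
        ll = -0.5 * (quad_R + logdet_R + data.n_obs[None] * LOG2PI)
        if not want_posterior:
            return ll
        return ll, np.zeros((B, n, 0)), np.zeros((B, n, 0, 0))

    Zw = data.Z[None] / Rdiag[..., None]  # R^-1 Z, (B, n, M, r)
    ZtRZ = np.matmul(np.swapaxes(Zw, -1, -2), data.Z[None])  # (B, n, r, r)
    m = np.matmul(np.swapaxes(Zw, -1, -2), resid[..., None])[..., 0]  # (B, n, r)

    if not singular_D:
        Dinv = np.linalg.inv(D)
        sign_D, logdet_D = np.linalg.slogdet(D)
        prec = ZtRZ + Dinv[:, None]
        Lp = np.linalg.cholesky(prec)
        logdet_prec = 2.0 * np.sum(
            np.log(np.diagonal(Lp, axis1=-2, axis2=-1)), axis=-1
        )
        Sig = np.linalg.inv(prec)
        mu = np.matmul(Sig, m[..., None])[..., 0]
        quad = quad_R - np.sum(m * mu, axis=-1)
        logdet = logdet_R + logdet_D[:, None] + logdet_prec
        ll = -0.5 * (quad + logdet + data.n_obs[None] * LOG2PI)
        if not want_posterior:
            return ll
        return ll, mu, Sig

    # dense path (singular D): V built explicitly
    ZD = np.einsum("nmr,brs->bnms", data.Z, D)
    V = np.matmul(ZD, np.swapaxes(data.Z, -1, -2)[None])
    idx = np.arange(M)
    V[..., idx, idx] += Rdiag
    L = np.linalg.cholesky(V)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
    sol = np.linalg.solve(V, resid[..., None])[..., 0]
    quad = np.sum(resid * sol, axis=-1)
    ll = -0.5 * (quad + logdet + data.n_obs[None] * LOG2PI)
    if not want_posterior:
        return ll
    # posterior via D m - D Z' V^-1 Z D m (valid for singular D)
    DZt = np.swapaxes(ZD, -1, -2)  # (B, n, r, M)
    VinvZD = np.linalg.solve(V, ZD)
    Sig = np.matmul(D[:, None], np.eye(r)) - np.matmul(DZt, VinvZD)
    mu = np.matmul(DZt, sol[..., None])[..., 0]
    return ll, mu, Sig


def gh_nodes(n_nodes: int, dim: int, prune: float = 1e-10):
    """Pruned product Gauss-Hermite rule for Gaussian expectations.

    Returns (z, logw): standard-normal-scaled nodes (K, dim) and log
    weights with sum(exp(logw)) == 1 exactly after pruning, so constants
    integrate exactly.
    """
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    z1 = x * np.sqrt(2.0)
    lw1 = np.log(w) - 0.5 * np.log(np.pi)
    grids = np.meshgrid(*([z1] * dim), indexing="ij")
    z = np.column_stack([g.ravel() for g in grids])
    lw = sum(np.meshgrid(*([lw1] * dim), indexing="ij")).ravel()
    if prune > 0 and dim > 1:
        keep = lw >= (lw.max() + np.log(prune))
        z, lw = z[keep], lw[keep]
    lw = lw - _logsumexp(lw)
    return z, lw


def _logsumexp(a: np.ndarray, axis=None):
    amax = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.sum(np.exp(a - amax), axis=axis, keepdims=True)) + amax
    return out if axis is None else np.squeeze(out, axis=axis)


logsumexp = _logsumexp


def fd_grad(f_batch, theta: np.ndarray, h_scale: float = 1e-6, chunk: int = 64,
            guard: bool = False):
    """Central-difference gradient using one batched evaluation."""
    theta = np.asarray(theta, dtype=float)
    P = theta.size
    h = h_scale * (1.0 + np.abs(theta))
    pts = np.empty((2 * P, P))
    for j in range(P):
        pts[2 * j] = theta
        pts[2 * j, j] += h[j]
        pts[2 * j + 1] = theta
        pts[2 * j + 1, j] -= h[j]
    vals = eval_chunked(f_batch, pts, chunk, guard=guard)
    return (vals[0::2] - vals[1::2]) / (2.0 * h)


def fd_hessian(f_batch, theta: np.ndarray, h_scale: float = 1e-4, chunk: int = 16,
               guard: bool = False):
    """Central-difference Hessian using batched evaluations."""
    theta = np.asarray(theta, dtype=float)
    P = theta.size
    h = h_scale * (1.0 + np.abs(theta))
    pts = []
    pairs = []
    for i in range(P):
        for j in range(i, P):
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                t = theta.copy()
                t[i] += si * h[i]
                t[j] += sj * h[j]
                pts.append(t)
            pairs.append((i, j))
    vals = eval_chunked(f_batch, np.asarray(pts), chunk, guard=guard)
    H = np.zeros((P, P))
    for m, (i, j) in enumerate(pairs):
        fpp, fpm, fmp, fmm = vals[4 * m : 4 * m + 4]
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def eval_chunked(
    f_batch, thetas: np.ndarray, chunk: int = 16, guard: bool = False
) -> np.ndarray:
    """Evaluate a batched objective in chunks.

    With ``guard``, numerically invalid points (LinAlgError / non-finite)
    are replaced by a large penalty instead of aborting, which keeps
    quasi-Newton line searches alive near parameter boundaries.
    """
    out = np.empty(len(thetas))
    for s in range(0, len(thetas), chunk):
        block = thetas[s : s + chunk]
        if not guard:
            out[s : s + chunk] = f_batch(block)
            continue
        try:
            vals = np.asarray(f_batch(block), dtype=float)
        except np.linalg.LinAlgError:
            vals = np.empty(len(block))
            for j, point in enumerate(block):
                try:
                    vals[j] = float(f_batch(point[None])[0])
                except np.linalg.LinAlgError:
                    vals[j] = np.inf
        out[s : s + chunk] = np.where(np.isfinite(vals), vals, 1e12)
    return out


def chol_pack(D: np.ndarray) -> np.ndarray:
    """Log-Cholesky parameterisation: lower triangle of chol(D), log diag.

    A PSD-but-singular D gets a relative jitter so the factor exists.
    """
    D = np.asarray(D, dtype=float)
    try:
        L = np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        scale = max(float(np.max(np.abs(D))), 1.0)
        L = np.linalg.cholesky(D + 1e-10 * scale * np.eye(D.shape[0]))
    r = D.shape[0]
    out = []
    for i in range(r):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.asarray(out)


def chol_unpack(theta: np.ndarray, r: int) -> np.ndarray:
    """Batched inverse of :func:`chol_pack`; returns D = L L' of shape
    (B, r, r) for theta of shape (B, r(r+1)/2)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    B = theta.shape[0]
    L = np.zeros((B, r, r))
    m = 0
    for i in range(r):
        for j in range(i + 1):
            L[:, i, j] = np.exp(theta[:, m]) if i == j else theta[:, m]
            m += 1
    return L @ np.swapaxes(L, 1, 2)
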