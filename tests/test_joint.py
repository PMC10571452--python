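"""Joint model: quadrature correctness, separability, fitting, prediction."""

import numpy as np
import pytest

from jointvitals._core import stack_cohort
from jointvitals.cox import fit_piecewise_ph
from jointvitals.joint import (
    JointSpec,
    association_summary,
    conditional_survival,
    fit_joint,
    information_criteria,
    joint_loglik,
)
from jointvitals.lmm import LmmSpec, fit_lmm, lmm_loglik
from jointvitals.simulate import simulate_cohort

from conftest import RECOVERY_D, recovery_config


def mc_joint_loglik(cohort, values, spec, n_draws, seed, assoc_center):
    """Monte-Carlo integration oracle for the joint likelihood.

    Importance-samples b from an inflated Gaussian proposal centred at a
    posterior mean computed with test-local dense linear algebra (plain
    prior sampling has vanishing effective sample size once a subject has
    many visits).  Returns (loglik, se) combining the per-subject MC
    errors of the log integrals by the delta method.
    """
    rng = np.random.default_rng(seed)
    data = stack_cohort(cohort)
    k1, k2 = data.outcomes
    beta = {
        k: np.array([values[f"{k}:{c}"] for c in data.x_columns[k]])
        for k in data.outcomes
    }
    from jointvitals.params import RE_LABELS

    D = np.zeros((4, 4))
    for i in range(4):
        for j in range(i + 1):
            D[i, j] = D[j, i] = values[f"D[{RE_LABELS[i]},{RE_LABELS[j]}]"]
    sigma = np.array([values[f"sigma_{k}"] for k in data.outcomes])
    gamma = np.array([values[f"surv:{c}"] for c in data.w_columns])
    from jointvitals.params import association_param_names

    alpha = np.array(
        [values[n] for n in association_param_names(spec.association)]
    )
    rates = np.array(
        [values[f"h0:rate_{p + 1}"] for p in range(len(spec.cuts) + 1)]
    )
    from jointvitals.hazard import PiecewiseConstantHazard

    h = PiecewiseConstantHazard(tuple(spec.cuts), tuple(rates))
    Dj = D + 1e-10 * np.eye(4)
    Dinv = np.linalg.inv(Dj)
    _, logdet_D = np.linalg.slogdet(Dj)
    total = 0.0
    var = 0.0
    inflate = 2.0
    for i in range(data.n_subjects):
        m = data.mask[i]
        y, X, Z, kof = data.Y[i][m], data.X[i][m], data.Z[i][m], data.kofrow[i][m]
        bvec = np.concatenate([beta[k1], beta[k2]])
        sig = sigma[kof]
        # dense posterior of b given this subject's longitudinal data
        Rinv = 1.0 / sig**2
        prec = (Z * Rinv[:, None]).T @ Z + Dinv
        Sig_post = np.linalg.inv(prec)
        mu_post = Sig_post @ ((Z * Rinv[:, None]).T @ (y - X @ bvec))
        Q = inflate * Sig_post
        Lq = np.linalg.cholesky(Q)
        _, logdet_Q = np.linalg.slogdet(Q)
        zdraw = rng.standard_normal((n_draws, 4))
        b = mu_post + zdraw @ Lq.T
        # log densities: prior N(0, D) minus proposal N(mu_post, Q)
        log_prior = -0.5 * (
            np.einsum("si,ij,sj->s", b, Dinv, b) + logdet_D + 4 * np.log(2 * np.pi)
        )
        log_prop = -0.5 * (
            np.sum(zdraw**2, axis=1) + logdet_Q + 4 * np.log(2 * np.pi)
        )
        mean = X @ bvec + b @ Z.T
        ll_long = -0.5 * np.sum(
            ((y - mean) / sig) ** 2 + np.log(2 * np.pi * sig**2), axis=1
        )
        a1 = data.Xbase[k1][i] @ beta[k1][:-1] + b[:, 0] - assoc_center[0]
        c1 = beta[k1][-1] + b[:, 1]
        a2 = data.Xbase[k2][i] @ beta[k2][:-1] + b[:, 2] - assoc_center[1]
        c2 = beta[k2][-1] + b[:, 3]
        eta_w = data.W[i] @ gamma if data.W.shape[1] else 0.0
        if spec.association == "current_value":
            A = eta_w + alpha[0] * a1 + alpha[1] * a2
            C = alpha[0] * c1 + alpha[1] * c2
        elif spec.association == "shared_random_effects":
            A = eta_w + alpha[0] * b[:, 1] + alpha[1] * b[:, 3]
            C = np.zeros(n_draws)
        else:
            A = (
                eta_w + alpha[0] * a1 + alpha[1] * a2
                + alpha[2] * c1 + alpha[3] * c2
            )
            C = alpha[0] * c1 + alpha[1] * c2
        T, d = data.T[i], data.delta[i]
        logS = d * h.log_hazard(T, A, C) - h.cumulative(T, A, C)
        li = ll_long + logS + log_prior - log_prop
        mx = li.max()
        vals = np.exp(li - mx)
        mean_v = vals.mean()
        se_v = vals.std(ddof=1) / np.sqrt(n_draws)
        total += mx + np.log(mean_v)
        var += (se_v / mean_v) ** 2
    return total, np.sqrt(var)


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = recovery_config(seed=3, n=5)
    return simulate_cohort(cfg)


def test_quadrature_matches_monte_carlo_oracle(tiny_cohort):
    cohort, truth = tiny_cohort
    spec = JointSpec(
        association="current_value", cuts=(48.0,), n_nodes=9,
        assoc_center=(110.0, 38.0),
    )
    gh = joint_loglik(dict(truth.values), cohort, spec)
    mc, se = mc_joint_loglik(
        cohort, dict(truth.values), spec, n_draws=400_000, seed=1,
        assoc_center=(110.0, 38.0),
    )
    assert abs(gh - mc) < 3 * se


def test_quadrature_refinement_converges(tiny_cohort):
    cohort, truth = tiny_cohort
    vals = []
    for nodes in (5, 9, 15):
        spec = JointSpec(
            association="current_value", cuts=(48.0,), n_nodes=nodes,
            prune=0.0, assoc_center=(110.0, 38.0),
        )
        vals.append(joint_loglik(dict(truth.values), cohort, spec))
    assert abs(vals[2] - vals[1]) <= abs(vals[1] - vals[0]) + 1e-9
    assert abs(vals[2] - vals[1]) < 1e-4


def test_zero_association_loglik_separates(null_assoc_cohort):
    cohort, truth = null_assoc_cohort
    spec = JointSpec(association="current_value", cuts=(48.0,), n_nodes=7,
                     assoc_center=(110.0, 38.0))
    jl = joint_loglik(dict(truth.values), cohort, spec)
    data = stack_cohort(cohort)
    beta = {"PR": np.array([110.0, 2.0, -0.4]), "BT": np.array([38.0, 0.3, -0.012])}
    ll_long = lmm_loglik(beta, RECOVERY_D, (3.0, 0.5), data)
    from jointvitals.hazard import PiecewiseConstantHazard

    h = PiecewiseConstantHazard((48.0,), (0.012, 0.015))
    A = data.W @ np.array([0.3])
    C = np.zeros(len(A))
    ll_surv = float(
        np.sum(data.delta * h.log_hazard(data.T, A, C) - h.cumulative(data.T, A, C))
    )
    assert jl == pytest.approx(ll_long + ll_surv, abs=1e-6)


def test_fit_with_alpha_fixed_zero_matches_separate_fits(null_assoc_cohort):
    cohort, _ = null_assoc_cohort
    lfit = fit_lmm(LmmSpec(), cohort)
    data = stack_cohort(cohort)
    spec = JointSpec(association="current_value", n_pieces=2, n_nodes=3,
                     fix_alpha_zero=True)
    jfit = fit_joint(spec, cohort)
    sfit = fit_piecewise_ph(
        data.T, data.delta, data.W, data.w_columns, cuts=jfit.hazard.cuts
    )
    assert jfit.loglik == pytest.approx(lfit.loglik + sfit.loglik, abs=1e-4)
    for k in ("PR", "BT"):
        assert jfit.beta[k] == pytest.approx(lfit.beta[k], abs=1e-3)
    assert jfit.gamma == pytest.approx(sfit.coef, abs=1e-3)


def test_joint_fit_recovers_association(joint_fit_cv):
    fit = joint_fit_cv
    assert fit.converged
    tab = fit.params.set_index("parameter")
    for name, truth in (("assoc_value_PR", -0.05), ("assoc_value_BT", -0.5)):
        est = tab.loc[name, "estimate"]
        se = tab.loc[name, "se"]
        assert abs(est - truth) < 3 * se
    # freeing the association never lowers the maximised log-likelihood
    fixed = fit_joint(
        JointSpec(association="current_value", cuts=fit.hazard.cuts,
                  n_nodes=3, fix_alpha_zero=True),
        fit.data,
    )
    assert fit.loglik >= fixed.loglik - 1e-6


def test_association_summary_hr_transform(joint_fit_cv):
    summ = association_summary(joint_fit_cv).set_index("parameter")
    for name in ("assoc_value_PR", "assoc_value_BT"):
        est = summ.loc[name, "estimate"]
        assert summ.loc[name, "hr"] == pytest.approx(np.exp(est), rel=1e-12)
        expected_pct = 100 * (1 - np.exp(est)) if est < 0 else 100 * (np.exp(est) - 1)
        assert summ.loc[name, "percent_change"] == pytest.approx(expected_pct)


def test_information_criteria_decomposition_sums(joint_fit_cv):
    ic = information_criteria(joint_fit_cv)
    assert ic["aic_longitudinal"] + ic["aic_survival"] == pytest.approx(
        ic["aic"], abs=1e-8
    )
    assert ic["bic_longitudinal"] + ic["bic_survival"] == pytest.approx(
        ic["bic"], abs=1e-8
    )
    assert ic["aic"] == pytest.approx(-2 * ic["loglik"] + 2 * ic["n_params"])


def test_conditional_survival_properties(joint_fit_cv):
    fit = joint_fit_cv
    sid = next(
        s for s in fit.data.subjects
        if fit.data.n_obs[fit.data.subjects.index(s)] >= 4
    )
    p0 = conditional_survival(fit, sid, 24.0, 0.0)
    assert p0 == pytest.approx(1.0)
    probs = [conditional_survival(fit, sid, 24.0, d) for d in (0.0, 6.0, 12.0, 48.0)]
    assert np.all(np.diff(probs) <= 1e-12)
    with pytest.raises(ValueError):
        conditional_survival(fit, sid, 24.0, -1.0)


def test_conditional_survival_alpha_zero_equals_marginal(null_assoc_cohort):
    cohort, _ = null_assoc_cohort
    spec = JointSpec(association="current_value", n_pieces=2, n_nodes=3,
                     fix_alpha_zero=True)
    fit = fit_joint(spec, cohort)
    sid = fit.data.subjects[0]
    i = 0
    W = fit.data.W
    A = float(W[i] @ fit.gamma)
    t, dt = 18.0, 24.0
    marg = np.exp(
        -(fit.hazard.cumulative(t + dt, A, 0.0) - fit.hazard.cumulative(t, A, 0.0))
    )
    assert conditional_survival(fit, sid, t, dt) == pytest.approx(
        float(marg), abs=1e-6
    )


def test_identifiability_guard_and_spec_validation():
    with pytest.raises(ValueError, match="association"):
        JointSpec(association="both_structures")
    with pytest.raises(ValueError, match="nodes"):
        JointSpec(n_nodes=2)
    with pytest.raises(ValueError, match="piece"):
        JointSpec(n_pieces=0)


def test_small_cohort_warns():
    cohort, _ = simulate_cohort(recovery_config(seed=8, n=10))
    with pytest.warns(UserWarning, match="fewer than 20"):
        fit_joint(
            JointSpec(association="current_value", n_pieces=1, n_nodes=3), cohort
        )
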