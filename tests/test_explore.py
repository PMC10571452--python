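"""Kaplan-Meier, log-rank, descriptives, profiles, marginal correlation."""

import numpy as np
import pandas as pd
import pytest

from jointvitals.cohort import Cohort
from jointvitals.explore import (
    descriptive_table,
    empirical_correlation_profile,
    kaplan_meier,
    logrank_test,
    marginal_correlation_profile,
    median_survival,
    profiles,
    restricted_mean_survival,
)
from jointvitals.simulate import simulate_cohort

from conftest import recovery_config, small_design


# -- Kaplan-Meier -----------------------------------------------------------


def test_km_no_censoring_equals_empirical_survival():
    km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    assert median_survival(km) == 2.0


def test_km_hand_product_limit_with_censoring():
    # 1 censored at t=1; events at 2 and 3:
    # S(2) = 1 * (1 - 1/2) = 1/2;  S(3) = 1/2 * (1 - 1/1) = 0
    km = kaplan_meier([1.0, 2.0, 3.0], [0, 1, 1])
    assert km.survival_at(2.0) == pytest.approx(0.5)
    assert km.survival_at(3.0) == pytest.approx(0.0)


def test_km_consistency_against_exponential_truth():
    rng = np.random.default_rng(11)
    lam = 0.1
    t = rng.exponential(1 / lam, 5000)
    km = kaplan_meier(t, np.ones(5000, dtype=int))
    sup = np.max(np.abs(km.survival - np.exp(-lam * km.times)))
    assert sup < 0.02


def test_km_curve_invariants_and_all_censored_median():
    cohort, _ = simulate_cohort(recovery_config(seed=2, n=80))
    km = kaplan_meier(cohort.surv["event_time_h"], cohort.surv["status"])
    assert np.all(np.diff(km.survival) <= 1e-12)
    assert np.all((km.survival >= 0) & (km.survival <= 1))
    all_cens = kaplan_meier([5.0, 8.0, 9.0], [0, 0, 0])
    assert np.allclose(all_cens.survival, 1.0)
    assert median_survival(all_cens) is None


def test_km_empty_input_rejected():
    with pytest.raises(ValueError):
        kaplan_meier([], [])


def test_restricted_mean_is_area_under_step():
    km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
    # 1*1 + (2/3)*1 + (1/3)*1
    assert restricted_mean_survival(km) == pytest.approx(2.0)


# -- log-rank ---------------------------------------------------------------


def brute_force_logrank(times, status, groups):
    """Independent O-E/hypergeometric-variance implementation (2 groups)."""
    times = np.asarray(times, float)
    status = np.asarray(status, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    g0 = groups == labels[0]
    O = E = V = 0.0
    for t in np.unique(times[status == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & g0).sum()
        d = ((times == t) & (status == 1)).sum()
        d0 = ((times == t) & (status == 1) & g0).sum()
        O += d0
        E += d * n0 / n
        if n > 1:
            V += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_logrank_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    times = np.concatenate([rng.exponential(10, 30), rng.exponential(16, 30)])
    status = rng.uniform(size=60) < 0.8
    groups = np.repeat(["a", "b"], 30)
    res = logrank_test(times, status.astype(int), groups)
    assert res.statistic == pytest.approx(
        brute_force_logrank(times, status, groups), rel=1e-10
    )
    assert res.df == 1


def test_logrank_identical_groups_statistic_zero():
    times = [2.0, 5.0, 9.0, 2.0, 5.0, 9.0]
    status = [1, 1, 0, 1, 1, 0]
    groups = ["a"] * 3 + ["b"] * 3
    res = logrank_test(times, status, groups)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_invariant_to_input_order_and_needs_two_groups():
    rng = np.random.default_rng(8)
    times = rng.exponential(10, 40)
    status = (rng.uniform(size=40) < 0.7).astype(int)
    groups = rng.choice(["x", "y", "z"], 40)
    r1 = logrank_test(times, status, groups)
    perm = rng.permutation(40)
    r2 = logrank_test(times[perm], status[perm], groups[perm])
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
    assert r1.df == 2
    with pytest.raises(ValueError):
        logrank_test(times, status, np.repeat("x", 40))


# -- descriptive table ------------------------------------------------------


def make_status_cohort(n_rec=183, n_not=31, rural=104):
    n = n_rec + n_not
    status = np.array([1] * n_rec + [0] * n_not)
    res = np.array(["rural"] * rural + ["urban"] * (n - rural))
    surv = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "event_time_h": np.linspace(6, 102, n),
            "status": status,
            "grp": np.where(res == "rural", "b", "a"),
        }
    )
    long = pd.DataFrame(
        {
            "subject_id": ["S0"],
            "outcome": ["PR"],
            "time_h": [6.0],
            "value": [100.0],
        }
    )
    return Cohort(long=long, surv=surv, design=small_design())


def test_descriptive_percentages_from_counts():
    table = descriptive_table(make_status_cohort())
    overall = table[table["covariate"] == "overall"].iloc[0]
    assert overall["pct_of_total"] == pytest.approx(85.51, abs=0.005)
    rural = table[(table["covariate"] == "grp") & (table["level"] == "b")].iloc[0]
    assert rural["pct_of_total"] == pytest.approx(48.6, abs=0.05)
    # per-covariate percentages sum to 100
    for _, grp in table[table["covariate"] != "overall"].groupby("covariate"):
        assert grp["pct_of_total"].sum() == pytest.approx(100.0)


def test_descriptive_empty_level_no_division_error():
    cohort, _ = simulate_cohort(
        recovery_config(seed=3, n=20, covariate_probs={"grp": (1.0, 0.0)})
    )
    table = descriptive_table(cohort)
    row = table[(table["covariate"] == "grp") & (table["level"] == "b")].iloc[0]
    assert row["n"] == 0 and row["pct_of_total"] == 0.0
    assert row["recovered_pct"] == 0.0


# -- profiles ---------------------------------------------------------------


def test_single_subject_mean_profile_equals_trajectory():
    cohort, _ = simulate_cohort(recovery_config(seed=4, n=40))
    sid = cohort.long["subject_id"].iloc[0]
    one = Cohort(
        long=cohort.long[cohort.long["subject_id"] == sid].copy(),
        surv=cohort.surv[cohort.surv["subject_id"] == sid].copy(),
        design=cohort.design,
    )
    indiv, mean = profiles(one, "PR")
    sub = indiv.sort_values("time_h")
    assert np.allclose(mean["mean"].to_numpy(), sub["value"].to_numpy())
    assert np.all(mean["n"] == 1)


def test_mean_profile_omits_empty_visits_and_counts_observed():
    cohort, _ = simulate_cohort(recovery_config(seed=4, n=60))
    _, mean = profiles(cohort, "BT")
    assert np.all(mean["n"] >= 1)
    observed_times = set(cohort.longitudinal("BT")["time_h"])
    assert set(mean["time_h"]) == observed_times


def test_mean_profile_slope_recovers_time_effect_without_truncation():
    # with events pushed beyond the grid there is no truncation bias
    cfg = recovery_config(
        seed=12, n=2000, alpha=(0.0, 0.0), gamma=np.array([0.0]),
        hazard=__import__("jointvitals.hazard", fromlist=["PiecewiseConstantHazard"]
                          ).PiecewiseConstantHazard((48.0,), (1e-6, 1e-6)),
    )
    cohort, _ = simulate_cohort(cfg)
    _, mean = profiles(cohort, "PR")
    slope = np.polyfit(mean["time_h"], mean["mean"], 1)[0]
    assert abs(slope - (-0.4)) < 0.05


# -- marginal correlation ---------------------------------------------------


class _FitStub:
    def __init__(self, D, sigma):
        self.D = D
        self.sigma = sigma


def test_marginal_correlation_zero_cross_block():
    D = np.diag([25.0, 0.04, 1.0, 0.01])
    prof = marginal_correlation_profile(_FitStub(D, (3.0, 0.5)), [6, 12, 48])
    assert np.allclose(prof["correlation"], 0.0)


def test_marginal_correlation_perfect_shared_process():
    blk = np.array([[4.0, 0.1], [0.1, 0.02]])
    D = np.block([[blk, blk], [blk, blk]])
    prof = marginal_correlation_profile(_FitStub(D, (0.0, 0.0)), [0, 6, 60])
    assert np.allclose(prof["correlation"], 1.0, atol=1e-10)


def test_marginal_correlation_bounds_and_simulation_oracle():
    from conftest import RECOVERY_D

    rng = np.random.default_rng(44)
    t = 24.0
    z = np.array([1.0, t])
    n = 100_000
    L = np.linalg.cholesky(RECOVERY_D + 1e-12 * np.eye(4))
    b = rng.standard_normal((n, 4)) @ L.T
    sigma = (3.0, 0.5)
    y1 = b[:, 0] + b[:, 1] * t + sigma[0] * rng.standard_normal(n)
    y2 = b[:, 2] + b[:, 3] * t + sigma[1] * rng.standard_normal(n)
    emp = np.corrcoef(y1, y2)[0, 1]
    prof = marginal_correlation_profile(_FitStub(RECOVERY_D, sigma), [t])
    rho = prof["correlation"].iloc[0]
    assert abs(rho - emp) < 0.01
    grid = np.linspace(0, 102, 18)
    allrho = marginal_correlation_profile(_FitStub(RECOVERY_D, sigma), grid)
    assert np.all(np.abs(allrho["correlation"]) <= 1.0)


def test_marginal_correlation_requires_psd():
    D = np.diag([1.0, 1.0, 1.0, -0.5])
    with pytest.raises(ValueError, match="PSD"):
        marginal_correlation_profile(_FitStub(D, (1.0, 1.0)), [6])


def test_empirical_correlation_profile_matches_visits(cv_cohort):
    cohort, _ = cv_cohort
    emp = empirical_correlation_profile(cohort)
    assert (emp["n"] >= 3).all()
    assert np.all(np.abs(emp["correlation"]) <= 1.0)
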