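"""Shared fixtures: small generator configs and cohorts.

Everything is generated programmatically with fixed seeds; expensive fitted
models are session-scoped so several tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from jointvitals.design import Covariate, CovariateDesign
from jointvitals.hazard import PiecewiseConstantHazard
from jointvitals.simulate import SimulationConfig, simulate_cohort

#: well-conditioned random-effects covariance for recovery studies
#: (order PR int, PR slope, BT int, BT slope)
RECOVERY_D = np.array(
    [
        [25.0, 0.5, 3.0, 0.0],
        [0.5, 0.09, 0.0, 0.01],
        [3.0, 0.0, 1.0, 0.0],
        [0.0, 0.01, 0.0, 0.04],
    ]
)


def small_design() -> CovariateDesign:
    return CovariateDesign(covariates=(Covariate("grp", ("a", "b")),))


def recovery_config(seed: int = 0, n: int = 120, **overrides) -> SimulationConfig:
    """Current-value association config used for parameter-recovery checks:
    moderate event rate, biomarkers on vitals scales, hazard centred at the
    typical biomarker level."""
    base = dict(
        n_subjects=n,
        design=small_design(),
        covariate_probs={"grp": (0.5, 0.5)},
        beta={
            "PR": np.array([110.0, 2.0, -0.4]),
            "BT": np.array([38.0, 0.3, -0.012]),
        },
        D=RECOVERY_D.copy(),
        sigma=(3.0, 0.5),
        hazard=PiecewiseConstantHazard((48.0,), (0.012, 0.015)),
        gamma=np.array([0.3]),
        alpha=(-0.05, -0.5),
        assoc_center=(110.0, 38.0),
        association="current_value",
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cv_cohort():
    """Cohort from the current-value recovery config (seed 7)."""
    return simulate_cohort(recovery_config(seed=7))


@pytest.fixture(scope="session")
def null_assoc_cohort():
    """Cohort with alpha = 0: longitudinal and survival halves independent."""
    cfg = recovery_config(seed=13, alpha=(0.0, 0.0))
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def lmm_fit_small(null_assoc_cohort):
    from jointvitals.lmm import LmmSpec, fit_lmm

    cohort, _ = null_assoc_cohort
    return fit_lmm(LmmSpec(), cohort)


@pytest.fixture(scope="session")
def joint_fit_cv(cv_cohort):
    """Joint fit of the current-value cohort (3 GH nodes per dimension)."""
    from jointvitals.joint import JointSpec, fit_joint

    cohort, _ = cv_cohort
    spec = JointSpec(association="current_value", n_pieces=2, n_nodes=3)
    return fit_joint(spec, cohort)
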