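"""Default study configuration: a prospective pneumonia inpatient cohort.

The defaults emulate a cohort of 214 hospitalised pneumonia patients whose
pulse rate (PR, beats/min) and body temperature (BT, deg C) were recorded
every six hours from admission up to 102 h (at most 17 visits per outcome),
with time to recovery in hours as the event outcome (status 1 = recovered).
Fixed-effect, survival and random-effect defaults are set to the estimates
reported for that cohort so that synthetic data live on realistic scales;
they are configuration values, not a claim of reproducing the original data.
"""

from __future__ import annotations

import numpy as np

from .design import Covariate, CovariateDesign

__all__ = [
    "study_design",
    "study_frequencies",
    "study_beta",
    "study_gamma",
    "study_random_effects_covariance",
    "STUDY_SIGMA",
    "STUDY_ALPHA",
    "STUDY_HAZARD_CUTS",
    "STUDY_HAZARD_RATES",
    "VISIT_GRID",
    "nearest_psd",
]

#: 6-hourly visit schedule, 6..102 h (17 visits per outcome).
VISIT_GRID = tuple(float(t) for t in range(6, 103, 6))

_COVARIATES = (
    ("sex", ("female", "male")),
    ("age", ("le14", "15-24", "25-64", "ge65")),
    ("residence", ("urban", "rural")),
    ("toilet", ("open_pit", "ventilated")),
    ("income", ("le500", "500-1500", "gt1500")),
    ("water", ("piped", "other")),
    ("family_size", ("le4", "gt4")),
    ("symptom", ("cough", "fast_breathing", "other")),
    ("comorbidity", ("no", "yes")),
    ("danger_sign", ("no", "yes")),
    ("occupation", ("unemployed", "employed")),
    ("severity", ("non_severe", "mild_severe", "severe")),
)

#: Observed marginal counts per level in the 214-patient cohort.
_COUNTS = {
    "sex": (101, 113),
    "age": (95, 36, 41, 42),
    "residence": (110, 104),
    "toilet": (126, 88),
    "income": (70, 69, 75),
    "water": (89, 125),
    "family_size": (135, 79),
    "symptom": (44, 103, 67),
    "comorbidity": (84, 130),
    "danger_sign": (110, 104),
    "occupation": (93, 121),
    "severity": (50, 91, 73),
}

# Longitudinal fixed effects (per design column).
_BETA_PR = {
    "intercept": 117.92,
    "sex[male]": 1.998,
    "age[15-24]": -3.9482,
    "age[25-64]": -3.6249,
    "age[ge65]": -2.4263,
    "residence[rural]": -1.4602,
    "toilet[ventilated]": -1.2843,
    "income[500-1500]": -1.8654,
    "income[gt1500]": -1.7802,
    "water[other]": 1.5264,
    "family_size[gt4]": 0.7264,
    "symptom[fast_breathing]": 1.4021,
    "symptom[other]": 1.5192,
    "comorbidity[yes]": 1.2458,
    "danger_sign[yes]": 2.0421,
    "occupation[employed]": 1.0043,
    "severity[mild_severe]": 1.8298,
    "severity[severe]": 2.1463,
    "time_h": -0.4236,
}
_BETA_BT = {
    "intercept": 38.2809,
    "sex[male]": 0.3675,
    "age[15-24]": -1.3351,
    "age[25-64]": -1.5779,
    "age[ge65]": -0.8020,
    "residence[rural]": -0.1550,
    "toilet[ventilated]": -0.4186,
    "income[500-1500]": -0.0798,
    "income[gt1500]": -0.0628,
    "water[other]": 0.1014,
    "family_size[gt4]": 0.6178,
    "symptom[fast_breathing]": 0.5128,
    "symptom[other]": 0.4678,
    "comorbidity[yes]": 0.1260,
    "danger_sign[yes]": 0.6031,
    "occupation[employed]": 0.4265,
    "severity[mild_severe]": 0.0816,
    "severity[severe]": 0.0853,
    "time_h": -0.0119,
}

# Survival (log hazard-ratio) coefficients for the baseline covariates.
_GAMMA = {
    "sex[male]": -1.1859,
    "age[15-24]": 0.9819,
    "age[25-64]": 0.8679,
    "age[ge65]": -0.1043,
    "residence[rural]": 0.1254,
    "toilet[ventilated]": -0.6534,
    "income[500-1500]": 0.3623,
    "income[gt1500]": 0.6364,
    "water[other]": -0.2516,
    "family_size[gt4]": -0.6648,
    "symptom[fast_breathing]": -0.9037,
    "symptom[other]": -0.7462,
    "comorbidity[yes]": -0.8312,
    "danger_sign[yes]": -1.0626,
    "occupation[employed]": -0.2213,
    "severity[mild_severe]": -0.3874,
    "severity[severe]": -0.2612,
}

#: Reported random-effects covariance, order (PR int, PR slope, BT int,
#: BT slope).  As printed it is slightly indefinite (min eigenvalue -0.27);
#: :func:`study_random_effects_covariance` projects to the nearest PSD matrix.
STUDY_D_RAW = np.array(
    [
        [228.94, -8.96, 12.852, -0.984],
        [-8.96, 0.834, -0.186, 0.246],
        [12.852, -0.186, 0.9567, -0.438],
        [-0.984, 0.246, -0.438, 0.376],
    ]
)

#: Residual SDs, reading the reported within-subject variances 13.4975
#: (PR) and 0.4963 (BT) as variances.
STUDY_SIGMA = (float(np.sqrt(13.4975)), float(np.sqrt(0.4963)))

#: Association of the two random slopes with the recovery log-hazard
#: (shared-random-effects parameterisation).
STUDY_ALPHA = (-0.4268, -0.2931)

#: Piecewise-constant baseline hazard.  Rates were calibrated (by solving
#: E[exp(-e^A H0(t))] = S(t) for the baseline cumulative hazard under the
#: default frailty distribution) so the default cohort has median recovery
#: time ~66 h and ~85.5% recovered by the 102 h administrative horizon.
#: The steep final rate reflects the heavy between-subject frailty the
#: covariate and random-slope defaults imply.
STUDY_HAZARD_CUTS = (48.0, 78.0)
STUDY_HAZARD_RATES = (0.09997, 0.21927, 1.70568)


def nearest_psd(mat: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix (eigenvalue clip)."""
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    return (v * np.clip(w, eps, None)) @ v.T


def study_design() -> CovariateDesign:
    """Covariate design of the study: 12 categorical baseline covariates."""
    return CovariateDesign(
        covariates=tuple(Covariate(name, levels) for name, levels in _COVARIATES),
        outcomes=("PR", "BT"),
        time_column="time_h",
    )


def study_frequencies() -> dict:
    """Marginal level probabilities (observed cohort frequencies)."""
    return {
        name: tuple(c / sum(counts) for c in counts)
        for name, counts in ((n, _COUNTS[n]) for n, _ in _COVARIATES)
    }


def study_beta(design: CovariateDesign | None = None) -> dict:
    """Fixed-effect vectors per outcome, aligned to the design columns."""
    design = design or study_design()
    cols = design.longitudinal_columns
    return {
        "PR": np.array([_BETA_PR.get(c, 0.0) for c in cols]),
        "BT": np.array([_BETA_BT.get(c, 0.0) for c in cols]),
    }


def study_gamma(design: CovariateDesign | None = None) -> np.ndarray:
    design = design or study_design()
    return np.array([_GAMMA.get(c, 0.0) for c in design.survival_columns])


def study_random_effects_covariance() -> np.ndarray:
    """PSD-projected default random-effects covariance (eigenvalues floored
    slightly above zero so Cholesky factorisations stay defined)."""
    return nearest_psd(STUDY_D_RAW, eps=1e-6)
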