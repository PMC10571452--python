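"""Canonical parameter naming shared by the generator and the model fits.

The simulated-truth report and every fitted-parameter table use the same
flattened name set for a given design, so parameter-recovery comparisons
are a dictionary join.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ASSOCIATION_TYPES",
    "RE_LABELS",
    "association_param_names",
    "parameter_names",
    "flatten_D",
]

ASSOCIATION_TYPES = (
    "current_value",
    "current_value_and_slope",
    "shared_random_effects",
)

#: Random-effect order used everywhere: PR intercept, PR slope, BT
#: intercept, BT slope.
RE_LABELS = ("PR_int", "PR_slope", "BT_int", "BT_slope")


def association_param_names(association: str, outcomes=("PR", "BT")) -> tuple:
    if association == "current_value":
        return tuple(f"assoc_value_{k}" for k in outcomes)
    if association == "current_value_and_slope":
        return tuple(f"assoc_value_{k}" for k in outcomes) + tuple(
            f"assoc_slope_{k}" for k in outcomes
        )
    if association == "shared_random_effects":
        return tuple(f"assoc_shared_{k}" for k in outcomes)
    if association in (None, "none"):
        return ()
    raise ValueError(f"unknown association type {association!r}")


def flatten_D(D: np.ndarray) -> dict:
    """Lower triangle of the 4x4 random-effects covariance, named entries."""
    out = {}
    for i in range(4):
        for j in range(i + 1):
            out[f"D[{RE_LABELS[i]},{RE_LABELS[j]}]"] = float(D[i, j])
    return out


def parameter_names(
    x_columns,
    w_columns,
    association,
    n_hazard_pieces,
    outcomes=("PR", "BT"),
) -> tuple:
    """Flattened name vector of a joint-model parameter set."""
    names: list[str] = []
    for k in outcomes:
        names.extend(f"{k}:{c}" for c in x_columns)
    names.extend(flatten_D(np.zeros((4, 4))).keys())
    names.extend(f"sigma_{k}" for k in outcomes)
    names.extend(f"surv:{c}" for c in w_columns)
    names.extend(association_param_names(association, outcomes))
    names.extend(f"h0:rate_{p + 1}" for p in range(n_hazard_pieces))
    return tuple(names)
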