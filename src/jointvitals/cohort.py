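"""Cohort data model, CSV I/O, validation and design-matrix construction.

A cohort couples a long-format table of repeated vital-sign measurements
(subject, outcome label, visit time in hours, value) with one survival row
per subject (time to recovery in hours, recovery status, baseline
covariates).  Files are comma-separated UTF-8 text with a mandatory header;
missing values in required columns are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import CovariateDesign, DesignError

__all__ = [
    "LongRecord",
    "SurvRecord",
    "Cohort",
    "DesignMatrices",
    "ValidationReport",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "build_design",
]

LONG_COLUMNS = ("subject_id", "outcome", "time_h", "value")
SURV_BASE_COLUMNS = ("subject_id", "event_time_h", "status")


class CohortFormatError(ValueError):
    """File does not have the declared columns/format."""


class CohortParseError(ValueError):
    """A field could not be parsed as the declared type."""


class CohortValidationError(ValueError):
    """Parsed data violate a cohort invariant."""


@dataclass(frozen=True)
class LongRecord:
    """One longitudinal measurement: y_k(t) for one subject and outcome."""

    subject_id: str
    outcome: str
    time: float
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise CohortValidationError(
                f"subject {self.subject_id}: time {self.time} must be >= 0"
            )
        if not np.isfinite(self.value):
            raise CohortValidationError(
                f"subject {self.subject_id}: non-finite value"
            )


@dataclass(frozen=True)
class SurvRecord:
    """Per-subject recovery time, status (1 = recovered) and covariates."""

    subject_id: str
    event_time: float
    status: int
    covariates: Mapping[str, str]

    def __post_init__(self) -> None:
        if not np.isfinite(self.event_time) or self.event_time <= 0:
            raise CohortValidationError(
                f"subject {self.subject_id}: event_time {self.event_time} must be > 0"
            )
        if self.status not in (0, 1):
            raise CohortValidationError(
                f"subject {self.subject_id}: status must be 0 or 1"
            )


@dataclass
class Cohort:
    """Longitudinal + survival tables under one covariate design.

    ``long`` has columns (subject_id, outcome, time_h, value); ``surv`` has
    (subject_id, event_time_h, status, <one column per covariate>).
    """

    long: pd.DataFrame
    surv: pd.DataFrame
    design: CovariateDesign

    @property
    def subjects(self) -> list[str]:
        return list(self.surv["subject_id"])

    @property
    def n_subjects(self) -> int:
        return len(self.surv)

    def longitudinal(self, outcome: str) -> pd.DataFrame:
        return self.long[self.long["outcome"] == outcome]

    def subject_history(self, subject_id: str, outcome: str) -> pd.DataFrame:
        m = (self.long["subject_id"] == subject_id) & (self.long["outcome"] == outcome)
        return self.long[m].sort_values("time_h")


@dataclass
class ValidationReport:
    n_subjects: int
    n_records: dict
    n_survival_only: int
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class DesignMatrices:
    """Fixed/random design matrices aligned to the cohort tables.

    X[k]: rows of (1, dummies, time) aligned to the longitudinal rows of
    outcome k; Z[k]: (1, time) random intercept + slope design; W: one row
    of baseline dummies per subject in ``surv`` order.
    """

    X: dict
    Z: dict
    W: np.ndarray
    x_columns: tuple
    w_columns: tuple
    long_index: dict          # outcome -> integer index into cohort.long
    subject_of_row: dict      # outcome -> subject id per row
    dropped_columns: tuple = ()


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path):
    raw = df[col]
    if raw.isna().any():
        raise CohortParseError(f"{path}: empty value in required column {col!r}")
    try:
        # float() is correctly rounded, so text -> value round-trips exactly
        return raw.astype(float)
    except (ValueError, TypeError) as exc:
        raise CohortParseError(f"{path}: non-numeric value in {col!r}: {exc}") from exc


def read_cohort(long_path, surv_path, design: CovariateDesign) -> Cohort:
    """Read and validate a cohort from two CSV files.

    Subjects present only in the survival table are legal (a warning is
    emitted with their count); the reverse is a validation error.
    """
    long_df = pd.read_csv(
        long_path,
        dtype={"subject_id": str, "outcome": str},
        float_precision="round_trip",
    )
    surv_df = pd.read_csv(surv_path, dtype=str, float_precision="round_trip")
    _require_columns(long_df, LONG_COLUMNS, long_path)
    _require_columns(surv_df, SURV_BASE_COLUMNS + design.covariate_names, surv_path)

    long_df = long_df.loc[:, list(LONG_COLUMNS)].copy()
    long_df["time_h"] = _numeric(long_df, "time_h", long_path).astype(float)
    long_df["value"] = _numeric(long_df, "value", long_path).astype(float)

    keep = list(SURV_BASE_COLUMNS) + list(design.covariate_names)
    surv_df = surv_df.loc[:, keep].copy()
    surv_df["event_time_h"] = _numeric(surv_df, "event_time_h", surv_path).astype(float)
    status = _numeric(surv_df, "status", surv_path)
    surv_df["status"] = status.astype(int)

    for i, row in surv_df.iterrows():
        for name in design.covariate_names:
            level = row[name]
            if pd.isna(level):
                raise CohortParseError(f"{surv_path}: row {i}: empty {name!r}")
            try:
                design[name].encode(str(level))
            except DesignError as exc:
                raise CohortValidationError(f"{surv_path}: row {i}: {exc}") from exc

    cohort = Cohort(long=long_df, surv=surv_df, design=design)
    validate_cohort(cohort)
    return cohort


def write_cohort(cohort: Cohort, long_path, surv_path) -> None:
    """Write the cohort back to CSV, preserving numeric content.

    Floats use 17 significant digits so write -> read round-trips exactly.
    """
    cohort.long.to_csv(long_path, index=False, float_format="%.17g")
    cohort.surv.to_csv(surv_path, index=False, float_format="%.17g")


def validate_cohort(cohort: Cohort, strict: bool = True) -> ValidationReport:
    """Check cohort invariants; hard violations raise when ``strict``.

    Hard violations: a longitudinal subject without a survival row, a
    measurement after the subject's event time, duplicate
    (subject, outcome, time) rows, non-monotone times, negative times,
    status outside {0, 1}, or a non-positive event time.
    """
    long_df, surv_df = cohort.long, cohort.surv
    violations: list[str] = []

    if surv_df["subject_id"].duplicated().any():
        dups = surv_df.loc[surv_df["subject_id"].duplicated(), "subject_id"]
        violations.append(f"duplicate survival rows for subjects {sorted(set(dups))}")
    if (surv_df["event_time_h"] <= 0).any():
        bad = surv_df.loc[surv_df["event_time_h"] <= 0, "subject_id"]
        violations.append(f"non-positive event time for subjects {list(bad)}")
    if (~surv_df["status"].isin((0, 1))).any():
        bad = surv_df.loc[~surv_df["status"].isin((0, 1)), "subject_id"]
        violations.append(f"status outside {{0,1}} for subjects {list(bad)}")

    if (long_df["time_h"] < 0).any():
        bad = long_df.loc[long_df["time_h"] < 0, "subject_id"]
        violations.append(f"negative longitudinal time for subjects {sorted(set(bad))}")
    bad_outcome = ~long_df["outcome"].isin(cohort.design.outcomes)
    if bad_outcome.any():
        labels = sorted(set(long_df.loc[bad_outcome, "outcome"]))
        violations.append(f"unknown outcome label(s) {labels}")

    surv_subjects = set(surv_df["subject_id"])
    long_subjects = set(long_df["subject_id"])
    orphans = sorted(long_subjects - surv_subjects)
    if orphans:
        violations.append(f"longitudinal subjects without survival row: {orphans}")
    n_survival_only = len(surv_subjects - long_subjects)
    if n_survival_only:
        warnings.warn(
            f"{n_survival_only} subject(s) have a survival row but no "
            "longitudinal measurements",
            stacklevel=2,
        )

    dup = long_df.duplicated(subset=["subject_id", "outcome", "time_h"])
    if dup.any():
        bad = long_df.loc[dup, "subject_id"]
        violations.append(
            f"duplicate (subject, outcome, time) rows for subjects {sorted(set(bad))}"
        )

    if not orphans and len(surv_df):
        ev = surv_df.set_index("subject_id")["event_time_h"]
        mapped = long_df["subject_id"].map(ev)
        late = long_df["time_h"] > mapped + 1e-9
        if late.any():
            bad = sorted(set(long_df.loc[late, "subject_id"]))
            violations.append(
                f"longitudinal time exceeds event time for subjects {bad}"
            )

    report = ValidationReport(
        n_subjects=len(surv_df),
        n_records={
            k: int((long_df["outcome"] == k).sum()) for k in cohort.design.outcomes
        },
        n_survival_only=n_survival_only,
        violations=violations,
    )
    if strict and violations:
        raise CohortValidationError("; ".join(violations))
    return report


def build_design(cohort: Cohort, drop_single_level: bool = True) -> DesignMatrices:
    """Construct X_k, Z_k and W from a validated cohort.

    A covariate level that is never observed away from the reference yields
    an all-zero indicator column; with ``drop_single_level`` such columns
    are removed from both X and W (with a warning) and recorded in
    ``dropped_columns``.  Row order of the inputs never affects any design
    row: encoding depends only on the declared level order.
    """
    design = cohort.design
    surv = cohort.surv
    covmaps = {
        str(r["subject_id"]): {n: str(r[n]) for n in design.covariate_names}
        for _, r in surv.iterrows()
    }
    W = np.vstack(
        [design.encode_baseline(covmaps[s]) for s in surv["subject_id"]]
    ) if len(surv) else np.zeros((0, len(design.indicator_columns)))
    w_cols = design.indicator_columns

    dropped: list[str] = []
    if drop_single_level and W.size:
        constant = [j for j in range(W.shape[1]) if np.all(W[:, j] == W[0, j])
                    and np.all(W[:, j] == 0)]
        if constant:
            dropped = [w_cols[j] for j in constant]
            warnings.warn(
                f"dropping unobserved indicator column(s): {dropped}", stacklevel=2
            )
            keepj = [j for j in range(W.shape[1]) if j not in constant]
            W = W[:, keepj]
            w_cols = tuple(w_cols[j] for j in keepj)

    x_cols = ("intercept",) + w_cols + (design.time_column,)
    widx = {s: i for i, s in enumerate(surv["subject_id"])}

    X: dict[str, np.ndarray] = {}
    Z: dict[str, np.ndarray] = {}
    long_index: dict[str, np.ndarray] = {}
    subject_of_row: dict[str, list[str]] = {}
    for k in design.outcomes:
        sub = cohort.long[cohort.long["outcome"] == k]
        t = sub["time_h"].to_numpy(dtype=float)
        rows_w = (
            W[[widx[s] for s in sub["subject_id"]]]
            if len(sub)
            else np.zeros((0, W.shape[1]))
        )
        Xk = np.column_stack([np.ones(len(sub)), rows_w, t]) if len(sub) else \
            np.zeros((0, len(x_cols)))
        Zk = np.column_stack([np.ones(len(sub)), t]) if len(sub) else np.zeros((0, 2))
        X[k], Z[k] = Xk, Zk
        long_index[k] = sub.index.to_numpy()
        subject_of_row[k] = list(sub["subject_id"])

    return DesignMatrices(
        X=X,
        Z=Z,
        W=W,
        x_columns=x_cols,
        w_columns=w_cols,
        long_index=long_index,
        subject_of_row=subject_of_row,
        dropped_columns=tuple(dropped),
    )
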