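"""Covariate coding and design-vector construction.

Baseline covariates are categorical with a declared level order; the first
(reference) level is encoded as all-zero indicators, so a covariate with L
levels contributes L-1 indicator columns.  Visit time is the only continuous
regressor and enters the longitudinal design in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = ["Covariate", "CovariateDesign"]


class DesignError(ValueError):
    """Invalid covariate design specification."""


@dataclass(frozen=True)
class Covariate:
    """A categorical baseline covariate with ordered levels.

    The reference level defaults to the first declared level and is encoded
    as all-zero indicators.
    """

    name: str
    levels: tuple[str, ...]
    reference: str | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise DesignError(f"covariate {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise DesignError(f"covariate {self.name!r} has duplicate levels")
        ref = self.reference if self.reference is not None else self.levels[0]
        if ref not in self.levels:
            raise DesignError(
                f"reference {ref!r} is not a level of covariate {self.name!r}"
            )
        object.__setattr__(self, "reference", ref)

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(f"{self.name}[{l}]" for l in self.nonreference_levels)

    def encode(self, level: str) -> np.ndarray:
        """Indicator sub-vector (length L-1) for one observed level."""
        if level not in self.levels:
            raise DesignError(
                f"unknown level {level!r} for covariate {self.name!r}; "
                f"declared levels: {list(self.levels)}"
            )
        return np.asarray(
            [1.0 if level == l else 0.0 for l in self.nonreference_levels]
        )


@dataclass
class CovariateDesign:
    """Deterministic mapping from covariate levels to design vectors.

    ``indicator_columns`` is the ordered list of dummy columns shared by the
    longitudinal fixed-effect design (where an intercept and the visit-time
    column are appended) and the survival design (baseline dummies only).
    """

    covariates: tuple[Covariate, ...]
    outcomes: tuple[str, str] = ("PR", "BT")
    time_column: str = "time_h"

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise DesignError("duplicate covariate names")

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    @property
    def indicator_columns(self) -> tuple[str, ...]:
        cols: list[str] = []
        for c in self.covariates:
            cols.extend(c.column_names)
        return tuple(cols)

    @property
    def longitudinal_columns(self) -> tuple[str, ...]:
        return ("intercept",) + self.indicator_columns + (self.time_column,)

    @property
    def survival_columns(self) -> tuple[str, ...]:
        return self.indicator_columns

    def encode_baseline(self, covmap: Mapping[str, str]) -> np.ndarray:
        """Indicator vector w for one subject's baseline covariates."""
        parts = []
        for c in self.covariates:
            if c.name not in covmap:
                raise DesignError(f"missing covariate {c.name!r}")
            parts.append(c.encode(str(covmap[c.name])))
        if not parts:
            return np.zeros(0)
        return np.concatenate(parts)

    def encode_longitudinal(
        self, covmap: Mapping[str, str], times: Iterable[float]
    ) -> np.ndarray:
        """Rows (1, dummies, t) of the longitudinal fixed-effect design."""
        w = self.encode_baseline(covmap)
        t = np.atleast_1d(np.asarray(list(times), dtype=float))
        out = np.empty((t.size, 2 + w.size))
        out[:, 0] = 1.0
        out[:, 1:-1] = w
        out[:, -1] = t
        return out

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "outcomes": list(self.outcomes),
            "time_column": self.time_column,
            "covariates": [
                {"name": c.name, "levels": list(c.levels), "reference": c.reference}
                for c in self.covariates
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateDesign":
        covs = tuple(
            Covariate(
                name=c["name"],
                levels=tuple(str(l) for l in c["levels"]),
                reference=str(c["reference"]) if c.get("reference") else None,
            )
            for c in d.get("covariates", [])
        )
        return cls(
            covariates=covs,
            outcomes=tuple(d.get("outcomes", ("PR", "BT"))),
            time_column=d.get("time_column", "time_h"),
        )

    @classmethod
    def from_yaml(cls, path) -> "CovariateDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
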