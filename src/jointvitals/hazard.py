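"""Piecewise-constant baseline hazard with log-linear subject effects.

Throughout the package a subject's log hazard is affine in time,

    log h_i(t) = log lambda_p(t) + A_i + C_i * t,

where lambda_p is the baseline rate on piece p, and (A_i, C_i) collect the
baseline-covariate and association contributions.  The cumulative hazard is
then available in closed form per piece via int exp(A + C t) dt =
exp(A + C t)/C (with the C -> 0 limit handled), which keeps both the joint
likelihood and event-time simulation exact for linear trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PiecewiseConstantHazard"]


def _expm1_div(c: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """expm1(c*dt)/c with the c->0 limit dt*(1 + c*dt/2)."""
    x = c * dt
    small = np.abs(x) < 1e-8
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.where(small, dt * (1.0 + 0.5 * x), np.expm1(x) / np.where(c == 0.0, 1.0, c))
    return out


@dataclass(frozen=True)
class PiecewiseConstantHazard:
    """Baseline hazard constant on [0,c1), [c1,c2), ..., [c_last, inf)."""

    cuts: tuple
    rates: tuple

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cuts)
        rates = tuple(float(r) for r in self.rates)
        if len(rates) != len(cuts) + 1:
            raise ValueError("need len(rates) == len(cuts) + 1")
        if any(r <= 0 for r in rates):
            raise ValueError("baseline hazard rates must be > 0")
        if any(c <= 0 for c in cuts) or list(cuts) != sorted(set(cuts)):
            raise ValueError("cutpoints must be positive and strictly increasing")
        object.__setattr__(self, "cuts", cuts)
        object.__setattr__(self, "rates", rates)

    @property
    def n_pieces(self) -> int:
        return len(self.rates)

    def starts(self) -> np.ndarray:
        return np.concatenate([[0.0], np.asarray(self.cuts)])

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.cuts), np.asarray(t, dtype=float), side="right")
        return np.asarray(self.rates)[idx]

    def log_hazard(self, t, A, C):
        """log h(t) = log lambda(t) + A + C t (broadcasting)."""
        t = np.asarray(t, dtype=float)
        return np.log(self.rate_at(t)) + np.asarray(A) + np.asarray(C) * t

    def cumulative(self, t, A, C):
        """Lambda(t) = sum_p lambda_p exp(A) [exp(C e_p) - exp(C s_p)]/C.

        Broadcasts over arbitrary leading shapes of t, A and C.
        """
        t = np.asarray(t, dtype=float)
        A = np.asarray(A, dtype=float)
        C = np.asarray(C, dtype=float)
        t, A, C = np.broadcast_arrays(t, A, C)
        starts = self.starts()
        total = np.zeros(t.shape)
        with np.errstate(over="ignore"):
            for p, lam in enumerate(self.rates):
                s = starts[p]
                e = self.cuts[p] if p < len(self.cuts) else np.inf
                dt = np.clip(np.minimum(t, e) - s, 0.0, None)
                total += lam * np.exp(A + C * s) * _expm1_div(C, dt)
        return total

    def invert(self, target, A, C):
        """Smallest t with Lambda(t) = target; inf if never attained.

        Vectorised root isolation: walk the pieces, find the piece whose
        cumulative contribution crosses the remaining target, and solve the
        exp-linear integral on that piece in closed form.
        """
        target = np.asarray(target, dtype=float)
        A = np.asarray(A, dtype=float)
        C = np.asarray(C, dtype=float)
        target, A, C = np.broadcast_arrays(target, A, C)
        if np.any(target < 0) or not np.all(np.isfinite(target)):
            raise ValueError("cumulative-hazard target must be finite and >= 0")

        remaining = target.astype(float).copy()
        t_out = np.full(target.shape, np.inf)
        done = np.zeros(target.shape, dtype=bool)
        starts = self.starts()
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for p, lam in enumerate(self.rates):
                s = starts[p]
                e = self.cuts[p] if p < len(self.cuts) else np.inf
                width = e - s
                # hazard scale at the piece start
                scale = lam * np.exp(A + C * s)
                piece_mass = scale * _expm1_div(C, np.full(target.shape, width)) \
                    if np.isfinite(width) else np.where(
                        C < 0, scale * (-1.0 / np.where(C == 0, -1.0, C)), np.inf
                    )
                crosses = (~done) & (remaining <= piece_mass)
                if np.any(crosses):
                    x = remaining * C / np.where(scale == 0, 1.0, scale)
                    u_lin = remaining / np.where(scale == 0, np.inf, scale)
                    small = np.abs(C) * u_lin < 1e-8
                    u = np.where(small, u_lin, np.log1p(x) / np.where(C == 0, 1.0, C))
                    t_out = np.where(crosses, s + u, t_out)
                    done |= crosses
                remaining = np.where(done, remaining, remaining - piece_mass)
        return t_out
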