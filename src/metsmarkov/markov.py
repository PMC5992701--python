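"""Row-stochastic transition matrices and cohort projection.

The cohort state occupancy at year n is a row vector M(n) over the 7
states; one annual step is M(n+1) = M(n) P where P is the group's annual
transition matrix. The chain is time-homogeneous: the same P is applied at
every step, and no absorbing (mortality) state exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import N_STATES, STATE_LABELS, GroupKey, MetsState

logger = logging.getLogger(__name__)


class MatrixValidationError(ValueError):
    """A matrix violates the row-stochastic contract."""


@dataclass
class ValidationReport:
    ok: bool
    row_sums: np.ndarray
    worst_row: int
    worst_deviation: float
    messages: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def validate_matrix(probs: np.ndarray, tol: float = 1e-6) -> ValidationReport:
    """Check shape, nonnegativity and row sums within ``tol`` of 1."""
    probs = np.asarray(probs, dtype=float)
    messages: list[str] = []
    if probs.shape != (N_STATES, N_STATES):
        return ValidationReport(
            False, np.array([]), -1, np.inf, [f"expected 7x7, got {probs.shape}"]
        )
    row_sums = probs.sum(axis=1)
    dev = np.abs(row_sums - 1.0)
    worst = int(np.argmax(dev))
    neg = probs < 0
    if neg.any():
        rows = sorted(set(np.where(neg)[0].tolist()))
        messages.append(
            "negative entries in row(s): "
            + ", ".join(STATE_LABELS[r] for r in rows)
        )
    bad_rows = np.where(dev > tol)[0]
    for r in bad_rows:
        messages.append(
            f"row {STATE_LABELS[r]!r} sums to {row_sums[r]:.6g} (tol {tol:g})"
        )
    ok = not messages
    return ValidationReport(ok, row_sums, worst, float(dev[worst]), messages)


@dataclass
class TransitionMatrix:
    """A 7x7 annual row-stochastic matrix for one sex x age-band group.

    Rows are renormalized to sum exactly to 1 at construction; inputs whose
    rows deviate by more than ``tol`` are rejected. ``row_support`` records,
    for estimated matrices, how many year-pair matrices contributed to each
    row's average.
    """

    probs: np.ndarray
    group: GroupKey | None = None
    row_support: np.ndarray | None = None
    provenance: str = ""
    tol: float = 1e-3

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        report = validate_matrix(probs, tol=self.tol)
        if not report:
            raise MatrixValidationError("; ".join(report.messages))
        self.probs = probs / probs.sum(axis=1, keepdims=True)
        if self.row_support is not None:
            self.row_support = np.asarray(self.row_support, dtype=int)

    @classmethod
    def from_percent(
        cls, percent: np.ndarray, tol_percent: float = 0.05, **kwargs
    ) -> "TransitionMatrix":
        """Build from a matrix printed in percent (rows summing to ~100)."""
        return cls(np.asarray(percent, dtype=float) / 100.0, tol=tol_percent / 100.0, **kwargs)

    def row(self, state: MetsState) -> np.ndarray:
        return self.probs[int(state)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(STATE_LABELS), columns=list(STATE_LABELS))

    def to_percent_frame(self, decimals: int = 2) -> pd.DataFrame:
        """The 2-decimal percent view used for reporting."""
        return (self.to_frame() * 100).round(decimals)


def as_distribution(values, tol: float = 1e-9) -> np.ndarray:
    """Validate and return a 7-state occupancy row vector summing to 1."""
    d = np.asarray(values, dtype=float)
    if d.shape != (N_STATES,):
        raise ValueError(f"distribution must have {N_STATES} entries, got shape {d.shape}")
    if (d < 0).any():
        raise ValueError("distribution entries must be nonnegative")
    s = d.sum()
    if abs(s - 1.0) > max(tol, 1e-6):
        raise ValueError(f"distribution sums to {s:.6g}, not 1")
    return d / s


def unit_distribution(state: MetsState) -> np.ndarray:
    d = np.zeros(N_STATES)
    d[int(state)] = 1.0
    return d


@dataclass
class Trajectory:
    """Occupancy over the 7 states for years 0..H of a projection."""

    start_label: str
    distributions: np.ndarray  # shape (H+1, 7)

    @property
    def horizon(self) -> int:
        return self.distributions.shape[0] - 1

    def prevalence(self, state: MetsState, year: int) -> float:
        if not 0 <= year <= self.horizon:
            raise IndexError(f"year {year} outside trajectory horizon {self.horizon}")
        return float(self.distributions[year, int(state)])

    def state_series(self, state: MetsState) -> np.ndarray:
        return self.distributions[:, int(state)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.distributions, columns=list(STATE_LABELS))
        df.insert(0, "year", np.arange(self.horizon + 1))
        return df


def step(dist: np.ndarray, matrix: TransitionMatrix) -> np.ndarray:
    """One annual transition: d -> d P, with drift-only renormalization."""
    d = as_distribution(dist)
    out = d @ matrix.probs
    return out / out.sum()


def project(start: np.ndarray, matrix: TransitionMatrix, horizon_years: int,
            start_label: str = "") -> Trajectory:
    """Project ``start`` forward ``horizon_years`` annual steps."""
    if horizon_years < 0:
        raise ValueError("projection horizon must be >= 0")
    d = as_distribution(start)
    out = np.empty((horizon_years + 1, N_STATES))
    out[0] = d
    for n in range(horizon_years):
        out[n + 1] = step(out[n], matrix)
    return Trajectory(start_label=start_label, distributions=out)


def state_prevalence(traj: Trajectory, state: MetsState, year: int) -> float:
    """Occupancy of ``state`` at projection year ``year`` (fraction in [0,1])."""
    return traj.prevalence(state, year)
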