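"""Component-targeted intervention scenarios on the annual transition matrix.

The modelled intervention assumes that, each year, a fraction f (default
one half) of the individuals found in a targeted isolated-component state
revert to the no-component state. Two operator encodings are provided:

``within_year`` (default)
    The reverted fraction re-enters the no-component state at the start of
    the annual cycle and then transitions according to the no-component
    row: row_s' = f * P[no_components] + (1 - f) * row_s.

``end_of_year``
    The reverted fraction ends the year in the no-component state:
    row_s' = f * e_no_components + (1 - f) * row_s.

Both are convex combinations of stochastic rows, so row-stochasticity is
preserved exactly. The relative reduction compares the projected MetS
prevalence at the horizon with and without the intervention:
100 * (natural - intervened) / natural.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import TransitionMatrix, project, unit_distribution
from .states import ISOLATED_STATES, GroupKey, MetsState

ISOLATED_SET = frozenset(ISOLATED_STATES.values())

#: Operator encodings, see module docstring.
MODES = ("within_year", "end_of_year")
DEFAULT_MODE = "within_year"


@dataclass(frozen=True)
class InterventionSpec:
    """Targets (isolated states only) and the annual reversion fraction."""

    targets: tuple[MetsState, ...]
    reversion_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("an intervention needs at least one target state")
        for t in self.targets:
            if MetsState(t) not in ISOLATED_SET:
                raise ValueError(
                    f"intervention target must be an isolated-component state, got {t!r}"
                )
        if not 0.0 <= self.reversion_fraction <= 1.0:
            raise ValueError("reversion_fraction must lie in [0, 1]")

    @classmethod
    def on_components(cls, *names: str, reversion_fraction: float = 0.5) -> "InterventionSpec":
        """Build from component names ('obesity', 'hypertension', ...)."""
        try:
            targets = tuple(ISOLATED_STATES[n] for n in names)
        except KeyError as e:
            raise ValueError(f"unknown component {e.args[0]!r}") from None
        return cls(targets=targets, reversion_fraction=reversion_fraction)


COMBINED = InterventionSpec.on_components(
    "hypertension", "obesity", "hyperglycemia", "dyslipidemia"
)


def apply_intervention(
    matrix: TransitionMatrix, spec: InterventionSpec, mode: str = DEFAULT_MODE
) -> TransitionMatrix:
    """Return the intervention-modified copy of ``matrix``."""
    if mode not in MODES:
        raise ValueError(f"unknown intervention mode {mode!r}; choose from {MODES}")
    f = spec.reversion_fraction
    probs = matrix.probs.copy()
    reverted = (
        matrix.probs[int(MetsState.NO_COMPONENTS)]
        if mode == "within_year"
        else unit_distribution(MetsState.NO_COMPONENTS)
    )
    for s in spec.targets:
        probs[int(s)] = f * reverted + (1 - f) * matrix.probs[int(s)]
    label = "+".join(MetsState(t).name for t in spec.targets)
    return TransitionMatrix(
        probs=probs,
        group=matrix.group,
        row_support=matrix.row_support,
        provenance=f"{matrix.provenance} | intervention f={f} mode={mode} on {label}".strip(" |"),
        tol=1e-6,
    )


def relative_reduction(
    matrix: TransitionMatrix,
    spec: InterventionSpec,
    start: np.ndarray,
    horizon: int,
    mode: str = DEFAULT_MODE,
) -> float:
    """Percent reduction in MetS prevalence at ``horizon`` under ``spec``."""
    if horizon < 1:
        raise ValueError("relative reduction needs a horizon of at least 1 year")
    natural = project(start, matrix, horizon).prevalence(MetsState.METS, horizon)
    if natural == 0:
        raise ZeroDivisionError(
            "natural MetS prevalence is 0 at the horizon; relative reduction undefined"
        )
    modified = apply_intervention(matrix, spec, mode=mode)
    intervened = project(start, modified, horizon).prevalence(MetsState.METS, horizon)
    return 100.0 * (natural - intervened) / natural


REPORT_ROWS = ("hypertension", "obesity", "hyperglycemia", "dyslipidemia", "combined")


def intervention_report(
    group_matrices: dict[GroupKey, TransitionMatrix],
    horizon: int = 10,
    reversion_fraction: float = 0.5,
    mode: str = DEFAULT_MODE,
) -> pd.DataFrame:
    """Relative MetS reduction (%) per intervention (rows) and group (columns).

    Projections start from the unit no-component distribution; rows are the
    four single-component interventions plus the combined intervention.
    """
    start = unit_distribution(MetsState.NO_COMPONENTS)
    out: dict[str, dict[str, float]] = {}
    for group, matrix in group_matrices.items():
        col = {}
        for name in REPORT_ROWS[:-1]:
            spec = InterventionSpec.on_components(name, reversion_fraction=reversion_fraction)
            col[name] = relative_reduction(matrix, spec, start, horizon, mode=mode)
        combined = InterventionSpec.on_components(
            *REPORT_ROWS[:-1], reversion_fraction=reversion_fraction
        )
        col["combined"] = relative_reduction(matrix, combined, start, horizon, mode=mode)
        out[group.label] = col
    df = pd.DataFrame(out).reindex(list(REPORT_ROWS))
    df.index.name = "intervention"
    return df
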