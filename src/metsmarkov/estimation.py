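"""Annual transition-matrix estimation from longitudinal check-up panels.

Estimation follows the consecutive-year pair-counting procedure: for every
subject, each adjacent pair of visits exactly one calendar year apart
contributes one observed transition. Transitions are tallied per group and
per year-pair, each year-pair's count matrix is row-normalized into an
annual matrix, and the group's final matrix is the unweighted mean of the
annual matrices (rows undefined in a given year-pair — no subject occupied
that origin state — are excluded from that row's mean).

A pooled estimator (sum counts over all year-pairs, then normalize) is
available behind a flag but is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import TransitionMatrix
from .states import (
    COMPONENTS,
    N_STATES,
    STATE_FROM_LABEL,
    STATE_LABELS,
    GroupKey,
    MetsState,
    assign_group,
)

logger = logging.getLogger(__name__)


class DuplicateVisitError(ValueError):
    """A subject has two records for the same calendar year."""


class StateNeverObservedError(ValueError):
    """An origin state has no observed transitions in any year-pair."""


@dataclass
class AnnualMatrix:
    """Row-normalized transition frequencies for one group and year-pair."""

    year_pair: tuple[int, int]
    probs: np.ndarray          # 7x7; undefined rows are all-zero
    defined: np.ndarray        # 7 booleans: row had >= 1 observed transition
    n_pairs: int


def build_visit_pairs(panel: pd.DataFrame) -> pd.DataFrame:
    """Extract consecutive-year transitions from a classified panel.

    Expects the output of :func:`metsmarkov.states.classify_panel` (needs
    ``subject_id``, ``visit_year``, ``sex``, ``age_years``, ``state``).
    Returns one row per (subject, year t -> t+1) adjacency with columns
    ``subject_id, sex, age_band, group, from_year, from_state, to_state``
    (states as integer codes). Gaps longer than one year yield no pair;
    subjects whose entry age falls outside [20, 60] are dropped with a
    logged count.
    """
    required = {"subject_id", "visit_year", "sex", "age_years", "state"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"classified panel lacks column(s): {sorted(missing)}")
    df = panel.sort_values(["subject_id", "visit_year"], kind="stable").copy()
    dup = df.duplicated(["subject_id", "visit_year"])
    if dup.any():
        offender = df.loc[dup, ["subject_id", "visit_year"]].iloc[0]
        raise DuplicateVisitError(
            f"subject {offender['subject_id']!r} has multiple records for "
            f"year {int(offender['visit_year'])}"
        )

    df["state_code"] = df["state"].map(STATE_FROM_LABEL).astype(int)

    # group fixed by age at study entry (first visit)
    entry = df.groupby("subject_id", sort=False).first().reset_index()
    age = entry["age_years"].astype(int)
    in_range = age.between(20, 60)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        logger.warning("dropped %d subject(s) with entry age outside [20, 60]", n_dropped)
    groups = {
        sid: assign_group(sex, a)
        for sid, sex, a, ok in zip(entry["subject_id"], entry["sex"], age, in_range)
        if ok
    }
    df = df[df["subject_id"].isin(groups)]

    g = df.groupby("subject_id", sort=False)
    nxt_year = g["visit_year"].shift(-1)
    nxt_state = g["state_code"].shift(-1)
    keep = nxt_year == df["visit_year"] + 1

    pairs = pd.DataFrame(
        {
            "subject_id": df.loc[keep, "subject_id"].to_numpy(),
            "from_year": df.loc[keep, "visit_year"].to_numpy(dtype=int),
            "from_state": df.loc[keep, "state_code"].to_numpy(dtype=int),
            "to_state": nxt_state[keep].to_numpy(dtype=int),
        }
    )
    pairs["group"] = pairs["subject_id"].map(groups)
    pairs["sex"] = pairs["group"].map(lambda k: k.sex.value)
    pairs["age_band"] = pairs["group"].map(lambda k: k.age_band.value)
    return pairs


def count_transitions(
    pairs: pd.DataFrame,
    group: GroupKey | None = None,
    year_pair: tuple[int, int] | None = None,
) -> np.ndarray:
    """7x7 integer tally of from->to transitions, optionally filtered."""
    sel = pairs
    if group is not None:
        sel = sel[sel["group"] == group]
    if year_pair is not None:
        if year_pair[1] != year_pair[0] + 1:
            raise ValueError(f"year pair must be consecutive, got {year_pair}")
        sel = sel[sel["from_year"] == year_pair[0]]
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    np.add.at(counts, (sel["from_state"].to_numpy(), sel["to_state"].to_numpy()), 1)
    return counts


def annual_matrix(counts: np.ndarray, year_pair: tuple[int, int] = (0, 1)) -> AnnualMatrix:
    """Row-normalize a count matrix; all-zero rows are flagged undefined."""
    counts = np.asarray(counts)
    if counts.shape != (N_STATES, N_STATES) or (counts < 0).any():
        raise ValueError("counts must be a nonnegative 7x7 matrix")
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    probs = np.zeros((N_STATES, N_STATES), dtype=float)
    probs[defined] = counts[defined] / row_sums[defined, None]
    return AnnualMatrix(
        year_pair=year_pair, probs=probs, defined=defined, n_pairs=int(counts.sum())
    )


def average_matrices(
    annuals: list[AnnualMatrix], group: GroupKey | None = None
) -> TransitionMatrix:
    """Unweighted mean of annual matrices, row-wise over defined rows.

    Each row of the result averages only the year-pairs in which that row
    was observed; a state never observed as an origin in any year-pair is a
    hard error, since its row cannot be completed.
    """
    if not annuals:
        raise ValueError("need at least one annual matrix")
    support = np.sum([a.defined for a in annuals], axis=0).astype(int)
    never = np.where(support == 0)[0]
    if never.size:
        names = ", ".join(STATE_LABELS[i] for i in never)
        raise StateNeverObservedError(
            f"no observed transitions out of state(s): {names}"
        )
    total = np.sum([a.probs for a in annuals], axis=0)
    probs = total / support[:, None]
    prov = "averaged over year-pairs " + ", ".join(
        f"{a.year_pair[0]}-{a.year_pair[1]}" for a in annuals
    )
    return TransitionMatrix(
        probs=probs, group=group, row_support=support, provenance=prov, tol=1e-6
    )


def estimate_matrix(
    panel: pd.DataFrame, group: GroupKey, pooled: bool = False
) -> TransitionMatrix:
    """Estimate one group's annual matrix from a classified panel."""
    pairs = build_visit_pairs(panel)
    return estimate_matrix_from_pairs(pairs, group, pooled=pooled)


def estimate_matrix_from_pairs(
    pairs: pd.DataFrame, group: GroupKey, pooled: bool = False
) -> TransitionMatrix:
    sel = pairs[pairs["group"] == group]
    if sel.empty:
        raise ValueError(f"no transitions observed for group {group.label}")
    if pooled:
        counts = count_transitions(sel)
        am = annual_matrix(counts)
        if not am.defined.all():
            names = ", ".join(STATE_LABELS[i] for i in np.where(~am.defined)[0])
            raise StateNeverObservedError(f"no observed transitions out of state(s): {names}")
        return TransitionMatrix(
            probs=am.probs, group=group,
            row_support=am.defined.astype(int),
            provenance="pooled counts over all year-pairs", tol=1e-6,
        )
    annuals = [
        annual_matrix(count_transitions(sel, year_pair=(int(y), int(y) + 1)), (int(y), int(y) + 1))
        for y in sorted(sel["from_year"].unique())
    ]
    return average_matrices(annuals, group=group)


def estimate_group_matrices(
    panel: pd.DataFrame, pooled: bool = False
) -> dict[GroupKey, TransitionMatrix]:
    """Estimate matrices for every group present in the panel."""
    pairs = build_visit_pairs(panel)
    out: dict[GroupKey, TransitionMatrix] = {}
    for group in sorted(pairs["group"].unique(), key=lambda g: g.label):
        out[group] = estimate_matrix_from_pairs(pairs, group, pooled=pooled)
    return out


def followup_prevalence(panel: pd.DataFrame) -> pd.DataFrame:
    """Component and MetS prevalence by follow-up year.

    For k = 0..K, among subjects with a visit exactly k years after their
    entry visit: subject count, male count/percent, and count/percent with
    each component and with MetS (state == mets).
    """
    needed = {"subject_id", "visit_year", "sex", "state", *COMPONENTS}
    missing = needed - set(panel.columns)
    if missing:
        raise ValueError(f"classified panel lacks column(s): {sorted(missing)}")
    df = panel.copy()
    entry_year = df.groupby("subject_id")["visit_year"].transform("min")
    df["followup_years"] = (df["visit_year"] - entry_year).astype(int)
    df["is_mets"] = df["state"] == STATE_LABELS[int(MetsState.METS)]
    df["is_male"] = df["sex"].astype(str) == "male"

    rows = []
    for k, sub in df.groupby("followup_years"):
        n = len(sub)
        row = {"followup_years": int(k), "n": n}
        for col, out in [("is_male", "male"), *[(c, c) for c in COMPONENTS], ("is_mets", "mets")]:
            cnt = int(sub[col].sum())
            row[f"{out}_n"] = cnt
            row[f"{out}_pct"] = 100.0 * cnt / n
        rows.append(row)
    return pd.DataFrame(rows).sort_values("followup_years").reset_index(drop=True)
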