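"""Metabolic-syndrome component classification and the 7-state model.

A check-up record carries four biomarker groups (blood pressure, BMI,
fasting glucose, lipids). Each maps to a binary component under the CDS
(Chinese Diabetes Society) criteria:

* obesity            — BMI >= 25 kg/m^2
* hyperglycemia      — fasting glucose >= 6.1 mmol/L, or a history of it
* hypertension       — SBP >= 140 or DBP >= 90 mmHg, or a history of it
* dyslipidemia       — TG >= 1.7 mmol/L, or HDL < 0.9 (men) / < 1.0 (women)

The model state is determined by the component count: none, one of four
isolated states, a pooled 2-component state, and MetS (>= 3 components).
Subjects are grouped by sex and age band at study entry (20-40 vs 40-60).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class AgeBand(str, enum.Enum):
    YOUNG = "20_40"
    MIDDLE = "40_60"


class MetsState(enum.IntEnum):
    """The 7 mutually exclusive model states, in canonical matrix order."""

    NO_COMPONENTS = 0
    ISO_HYPERTENSION = 1
    ISO_OBESITY = 2
    ISO_HYPERGLYCEMIA = 3
    ISO_DYSLIPIDEMIA = 4
    TWO_COMPONENTS = 5
    METS = 6


#: Serialization labels, index-aligned with :class:`MetsState`.
STATE_LABELS: tuple[str, ...] = (
    "no_components",
    "iso_hypertension",
    "iso_obesity",
    "iso_hyperglycemia",
    "iso_dyslipidemia",
    "two_components",
    "mets",
)
STATE_FROM_LABEL: dict[str, MetsState] = {
    lab: MetsState(i) for i, lab in enumerate(STATE_LABELS)
}
N_STATES = 7

#: Isolated single-component states, keyed by component name.
ISOLATED_STATES: dict[str, MetsState] = {
    "hypertension": MetsState.ISO_HYPERTENSION,
    "obesity": MetsState.ISO_OBESITY,
    "hyperglycemia": MetsState.ISO_HYPERGLYCEMIA,
    "dyslipidemia": MetsState.ISO_DYSLIPIDEMIA,
}

COMPONENTS: tuple[str, ...] = ("obesity", "hyperglycemia", "hypertension", "dyslipidemia")


class MissingFieldError(ValueError):
    """A biomarker required for classification is absent."""


class ValidationError(ValueError):
    """A record value violates a basic sanity constraint."""


class AgeOutOfRangeError(ValueError):
    """Entry age falls outside the modelled 20-60 range."""


@dataclass(frozen=True)
class Thresholds:
    """CDS cut-offs for the four components. Units as in the field names."""

    bmi: float = 25.0                # kg/m^2
    glucose: float = 6.1             # mmol/L, fasting
    sbp: float = 140.0               # mmHg
    dbp: float = 90.0                # mmHg
    tg: float = 1.7                  # mmol/L
    hdl_male: float = 0.9            # mmol/L, dyslipidemic below
    hdl_female: float = 1.0          # mmol/L, dyslipidemic below

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"threshold {f.name!r} must be positive")


CDS_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class ComponentProfile:
    obesity: bool
    hyperglycemia: bool
    hypertension: bool
    dyslipidemia: bool

    @property
    def count(self) -> int:
        return int(self.obesity) + int(self.hyperglycemia) + int(self.hypertension) + int(self.dyslipidemia)


@dataclass
class CheckupRecord:
    """One subject-visit. Biomarkers must be positive; history flags optional."""

    subject_id: str
    visit_year: int
    sex: Sex
    age_years: int
    sbp: float
    dbp: float
    bmi: float
    fasting_glucose: float
    tg: float
    hdl: float
    history_hypertension: bool = False
    history_hyperglycemia: bool = False
    cholesterol: float | None = field(default=None)  # read but unused by any criterion

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        for name in ("sbp", "dbp", "bmi", "fasting_glucose", "tg", "hdl"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise MissingFieldError(f"record {self.subject_id!r}: missing biomarker {name!r}")
            if v <= 0:
                raise ValidationError(
                    f"record {self.subject_id!r}: biomarker {name!r} must be positive, got {v!r}"
                )
        if self.age_years < 0:
            raise ValidationError(f"record {self.subject_id!r}: negative age")


@dataclass(frozen=True, order=True)
class GroupKey:
    """One of the four sex x entry-age-band strata."""

    sex: Sex
    age_band: AgeBand

    @property
    def label(self) -> str:
        prefix = "men" if self.sex is Sex.MALE else "women"
        return f"{prefix}_{self.age_band.value}"


GROUPS: tuple[GroupKey, ...] = (
    GroupKey(Sex.MALE, AgeBand.YOUNG),
    GroupKey(Sex.MALE, AgeBand.MIDDLE),
    GroupKey(Sex.FEMALE, AgeBand.YOUNG),
    GroupKey(Sex.FEMALE, AgeBand.MIDDLE),
)
GROUP_FROM_LABEL: dict[str, GroupKey] = {g.label: g for g in GROUPS}


def classify_components(
    record: CheckupRecord, thresholds: Thresholds = CDS_THRESHOLDS
) -> ComponentProfile:
    """Map one record to its four binary components under the CDS criteria."""
    hdl_cut = thresholds.hdl_male if record.sex is Sex.MALE else thresholds.hdl_female
    return ComponentProfile(
        obesity=record.bmi >= thresholds.bmi,
        hyperglycemia=record.fasting_glucose >= thresholds.glucose
        or record.history_hyperglycemia,
        hypertension=record.sbp >= thresholds.sbp
        or record.dbp >= thresholds.dbp
        or record.history_hypertension,
        dyslipidemia=record.tg >= thresholds.tg or record.hdl < hdl_cut,
    )


def assign_state(profile: ComponentProfile) -> MetsState:
    """Collapse a component profile to one of the 7 model states."""
    n = profile.count
    if n == 0:
        return MetsState.NO_COMPONENTS
    if n == 1:
        for name, state in ISOLATED_STATES.items():
            if getattr(profile, name):
                return state
    if n == 2:
        return MetsState.TWO_COMPONENTS
    return MetsState.METS


def assign_group(sex: Sex | str, age_years: int) -> GroupKey:
    """Sex x age-band stratum at study entry.

    Ages in [20, 40) are "young", [40, 60] "middle"; 40 goes to the middle
    band. Group membership is fixed at entry and not revisited as subjects
    age during follow-up.
    """
    if not 20 <= age_years <= 60:
        raise AgeOutOfRangeError(f"entry age {age_years} outside the modelled range [20, 60]")
    band = AgeBand.YOUNG if age_years < 40 else AgeBand.MIDDLE
    return GroupKey(Sex(sex), band)


def classify_record(
    record: CheckupRecord, thresholds: Thresholds = CDS_THRESHOLDS
) -> MetsState:
    return assign_state(classify_components(record, thresholds))


# -- vectorized panel classification ---------------------------------------

REQUIRED_COLUMNS = (
    "subject_id",
    "visit_year",
    "sex",
    "age_years",
    "sbp",
    "dbp",
    "bmi",
    "fasting_glucose",
    "tg",
    "hdl",
)
HISTORY_COLUMNS = ("history_hypertension", "history_hyperglycemia")


def classify_panel(
    panel: pd.DataFrame, thresholds: Thresholds = CDS_THRESHOLDS
) -> pd.DataFrame:
    """Classify every row of a panel table.

    Returns a copy with boolean component columns plus ``component_count``
    and ``state`` (canonical label). Missing history columns default to
    False with a single warning.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise MissingFieldError(f"panel lacks required column(s): {missing}")
    df = panel.copy()
    for col in HISTORY_COLUMNS:
        if col not in df.columns:
            logger.warning("panel lacks %r; assuming no history for all rows", col)
            df[col] = False
        df[col] = df[col].astype(bool)

    for col in ("sbp", "dbp", "bmi", "fasting_glucose", "tg", "hdl"):
        bad = ~(df[col] > 0)
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} row(s) with missing or non-positive {col!r}"
            )

    sex = df["sex"].map(lambda s: Sex(s))
    male = sex == Sex.MALE
    hdl_cut = np.where(male, thresholds.hdl_male, thresholds.hdl_female)

    df["obesity"] = df["bmi"] >= thresholds.bmi
    df["hyperglycemia"] = (df["fasting_glucose"] >= thresholds.glucose) | df[
        "history_hyperglycemia"
    ]
    df["hypertension"] = (
        (df["sbp"] >= thresholds.sbp)
        | (df["dbp"] >= thresholds.dbp)
        | df["history_hypertension"]
    )
    df["dyslipidemia"] = (df["tg"] >= thresholds.tg) | (df["hdl"].to_numpy() < hdl_cut)

    count = (
        df["obesity"].astype(int)
        + df["hyperglycemia"].astype(int)
        + df["hypertension"].astype(int)
        + df["dyslipidemia"].astype(int)
    )
    df["component_count"] = count

    code = np.full(len(df), int(MetsState.TWO_COMPONENTS))
    code[count.to_numpy() == 0] = int(MetsState.NO_COMPONENTS)
    code[count.to_numpy() >= 3] = int(MetsState.METS)
    one = count.to_numpy() == 1
    for name, state in ISOLATED_STATES.items():
        code[one & df[name].to_numpy()] = int(state)
    df["state"] = [STATE_LABELS[c] for c in code]
    return df
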