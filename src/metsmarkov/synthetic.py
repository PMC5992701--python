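"""Synthetic longitudinal check-up panels with known Markov structure.

The generator emulates the kind of cohort the estimator expects: ~5,900
subjects aged 20-60 at entry, 2-6 annual visits with attrition, per-group
state sequences that follow a known 7x7 annual transition matrix (the four
packaged published matrices by default), and biomarker values drawn from
truncated normal distributions on the correct side of every diagnostic
threshold so that classification reproduces the intended state exactly.

The biomarker distributions are plumbing, not science: their only contract
is the exact round trip through classification. Dropout is independent of
state, and biomarkers are drawn independently given the component pattern.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .markov import TransitionMatrix
from .states import (
    COMPONENTS,
    N_STATES,
    STATE_LABELS,
    AgeBand,
    GroupKey,
    MetsState,
    Sex,
    Thresholds,
    CDS_THRESHOLDS,
)

logger = logging.getLogger(__name__)

#: Visit-count distribution over 2..6 visits implied by the published
#: cohort's per-year attrition (5881/5881/3518/2065/1346/825).
DEFAULT_VISITS_PMF: tuple[float, ...] = tuple(
    np.array([2363, 1453, 719, 521, 825]) / 5881.0
)

#: Baseline component marginals of the emulated cohort (fractions):
#: hypertension, obesity, hyperglycemia, dyslipidemia.
DEFAULT_MARGINALS = {
    "hypertension": 0.1258,
    "obesity": 0.3052,
    "hyperglycemia": 0.0900,
    "dyslipidemia": 0.2173,
}

#: Default group allocation: 42.1% male, even young/middle split per sex.
DEFAULT_GROUP_FRACTIONS = {
    "men_20_40": 0.2105,
    "men_40_60": 0.2105,
    "women_20_40": 0.2895,
    "women_40_60": 0.2895,
}


@dataclass(frozen=True)
class TruncNormal:
    """A normal(mean, sd) truncated to [low, high]."""

    mean: float
    sd: float
    low: float
    high: float

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng)


@dataclass(frozen=True)
class BiomarkerEmission:
    """Per-component value distributions on each side of every threshold.

    ``low_hdl_fraction`` is the share of dyslipidemic visits realized via
    low HDL (with normal TG) rather than high TG.
    """

    bmi_normal: TruncNormal = TruncNormal(22.5, 1.5, 15.0, 24.99)
    bmi_obese: TruncNormal = TruncNormal(27.5, 2.0, 25.0, 45.0)
    glucose_normal: TruncNormal = TruncNormal(5.2, 0.5, 3.5, 6.09)
    glucose_high: TruncNormal = TruncNormal(7.0, 0.8, 6.1, 15.0)
    sbp_normal: TruncNormal = TruncNormal(118.0, 8.0, 85.0, 139.9)
    sbp_high: TruncNormal = TruncNormal(152.0, 8.0, 140.0, 210.0)
    dbp_normal: TruncNormal = TruncNormal(74.0, 6.0, 50.0, 89.9)
    dbp_high: TruncNormal = TruncNormal(96.0, 5.0, 90.0, 125.0)
    tg_normal: TruncNormal = TruncNormal(1.1, 0.25, 0.3, 1.69)
    tg_high: TruncNormal = TruncNormal(2.4, 0.6, 1.7, 8.0)
    hdl_normal_male: TruncNormal = TruncNormal(1.25, 0.2, 0.9, 2.5)
    hdl_normal_female: TruncNormal = TruncNormal(1.45, 0.25, 1.0, 3.0)
    # upper bounds sit one reporting decimal below the cut so that the
    # 2-decimal rounding applied at emission cannot cross the threshold
    hdl_low_male: TruncNormal = TruncNormal(0.75, 0.08, 0.4, 0.89)
    hdl_low_female: TruncNormal = TruncNormal(0.85, 0.08, 0.4, 0.99)
    cholesterol: TruncNormal = TruncNormal(4.8, 0.9, 2.5, 9.0)
    low_hdl_fraction: float = 0.3

    def validate(self, thr: Thresholds = CDS_THRESHOLDS) -> None:
        """Reject distributions that straddle a diagnostic threshold."""
        checks = [
            ("bmi_normal", self.bmi_normal.high < thr.bmi),
            ("bmi_obese", self.bmi_obese.low >= thr.bmi),
            ("glucose_normal", self.glucose_normal.high < thr.glucose),
            ("glucose_high", self.glucose_high.low >= thr.glucose),
            ("sbp_normal", self.sbp_normal.high < thr.sbp),
            ("sbp_high", self.sbp_high.low >= thr.sbp),
            ("dbp_normal", self.dbp_normal.high < thr.dbp),
            ("dbp_high", self.dbp_high.low >= thr.dbp),
            ("tg_normal", self.tg_normal.high < thr.tg),
            ("tg_high", self.tg_high.low >= thr.tg),
            ("hdl_normal_male", self.hdl_normal_male.low >= thr.hdl_male),
            ("hdl_normal_female", self.hdl_normal_female.low >= thr.hdl_female),
            ("hdl_low_male", self.hdl_low_male.high < thr.hdl_male),
            ("hdl_low_female", self.hdl_low_female.high < thr.hdl_female),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"emission distribution(s) straddle a threshold: {bad}")
        if not 0.0 <= self.low_hdl_fraction <= 1.0:
            raise ValueError("low_hdl_fraction must lie in [0, 1]")


def initial_distribution_from_marginals(
    marginals: dict[str, float] | None = None,
) -> np.ndarray:
    """7-state distribution implied by independent component marginals."""
    m = dict(DEFAULT_MARGINALS, **(marginals or {}))
    p = {c: m[c] for c in ("hypertension", "obesity", "hyperglycemia", "dyslipidemia")}
    iso_state = {
        "hypertension": MetsState.ISO_HYPERTENSION,
        "obesity": MetsState.ISO_OBESITY,
        "hyperglycemia": MetsState.ISO_HYPERGLYCEMIA,
        "dyslipidemia": MetsState.ISO_DYSLIPIDEMIA,
    }
    dist = np.zeros(N_STATES)
    names = list(p)
    for pattern in itertools.product([False, True], repeat=4):
        prob = 1.0
        for name, present in zip(names, pattern):
            prob *= p[name] if present else 1.0 - p[name]
        k = sum(pattern)
        if k == 0:
            dist[MetsState.NO_COMPONENTS] += prob
        elif k == 1:
            dist[iso_state[names[pattern.index(True)]]] += prob
        elif k == 2:
            dist[MetsState.TWO_COMPONENTS] += prob
        else:
            dist[MetsState.METS] += prob
    return dist / dist.sum()


@dataclass
class SyntheticConfig:
    """Everything the generator needs; the seed is mandatory."""

    seed: int
    n_subjects: int = 5881
    group_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_FRACTIONS)
    )
    visits_pmf: tuple[float, ...] = DEFAULT_VISITS_PMF  # over 2..6 visits
    entry_year_range: tuple[int, int] = (2010, 2016)  # study period; visits fit inside
    ground_truth: dict[GroupKey, TransitionMatrix] | None = None  # None -> fixtures
    initial_state: dict[GroupKey, np.ndarray] | None = None  # None -> marginals
    component_marginals: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    emission: BiomarkerEmission = field(default_factory=BiomarkerEmission)
    emit_history: bool = False
    history_fraction: float = 0.3  # of abnormal visits carrying a history flag instead
    mets_four_fraction: float = 0.2  # MetS visits with all four components
    thresholds: Thresholds = field(default_factory=lambda: CDS_THRESHOLDS)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        pmf = np.asarray(self.visits_pmf, dtype=float)
        if pmf.size != 5 or (pmf < 0).any() or pmf.sum() <= 0:
            raise ValueError("visits_pmf must be 5 nonnegative weights over 2..6 visits")
        self.visits_pmf = tuple(pmf / pmf.sum())
        fr = np.array(list(self.group_fractions.values()), dtype=float)
        if (fr < 0).any() or fr.sum() <= 0:
            raise ValueError("group_fractions must be nonnegative and not all zero")
        self.emission.validate(self.thresholds)

    def resolve_ground_truth(self) -> dict[GroupKey, TransitionMatrix]:
        if self.ground_truth is not None:
            return self.ground_truth
        from .io import load_fixture_matrices

        return load_fixture_matrices()

    def resolve_initial(self, group: GroupKey) -> np.ndarray:
        if self.initial_state is not None:
            return np.asarray(self.initial_state[group], dtype=float)
        return initial_distribution_from_marginals(self.component_marginals)


def _group_sizes(config: SyntheticConfig) -> dict[str, int]:
    fr = {k: v for k, v in config.group_fractions.items() if v > 0}
    total = sum(fr.values())
    sizes = {k: int(round(config.n_subjects * v / total)) for k, v in fr.items()}
    drift = config.n_subjects - sum(sizes.values())
    first = next(iter(sizes))
    sizes[first] += drift
    return sizes


def sample_state_sequences(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Markov state sequences for every subject.

    Returns a long table: one row per subject-visit with ``subject_id``,
    ``group`` (label), ``visit_index`` (0-based) and ``state`` (code).
    The first state is drawn from the group's initial distribution, each
    later state from the ground-truth row of the current state.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = config.resolve_ground_truth()
    sizes = _group_sizes(config)
    frames = []
    sid_offset = 0
    for label, n in sizes.items():
        group = next(g for g in truth if g.label == label)
        P = truth[group].probs
        cum = np.cumsum(P, axis=1)
        lengths = rng.choice(np.arange(2, 7), p=np.asarray(config.visits_pmf), size=n)
        init = config.resolve_initial(group)
        states = np.full((n, 6), -1, dtype=int)
        states[:, 0] = rng.choice(N_STATES, p=init / init.sum(), size=n)
        for t in range(1, 6):
            active = lengths > t
            if not active.any():
                continue
            cur = states[active, t - 1]
            u = rng.random(active.sum())
            states[active, t] = (u[:, None] > cum[cur]).sum(axis=1)
        subj = np.array([f"S{sid_offset + i:06d}" for i in range(n)])
        sid_offset += n
        rows = lengths
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(subj, rows),
                    "group": label,
                    "visit_index": np.concatenate([np.arange(k) for k in rows]),
                    "state": np.concatenate([states[i, : rows[i]] for i in range(n)]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def emit_biomarkers(
    sequences: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Turn state sequences into a check-up table with consistent biomarkers.

    Every visit's values land strictly on the intended side of each CDS
    threshold, so classification round-trips to the intended state with no
    mismatches. For composite states the realized component pattern is
    drawn uniformly (pairs for the 2-component state; triples, or all four
    with probability ``mets_four_fraction``, for MetS).
    """
    em = config.emission
    df = sequences.copy()
    n = len(df)
    state = df["state"].to_numpy()

    # realized component pattern per visit: columns follow COMPONENTS order
    comp = np.zeros((n, 4), dtype=bool)
    comp_index = {c: i for i, c in enumerate(COMPONENTS)}
    iso = {
        MetsState.ISO_HYPERTENSION: "hypertension",
        MetsState.ISO_OBESITY: "obesity",
        MetsState.ISO_HYPERGLYCEMIA: "hyperglycemia",
        MetsState.ISO_DYSLIPIDEMIA: "dyslipidemia",
    }
    for s, name in iso.items():
        comp[state == int(s), comp_index[name]] = True
    pairs = list(itertools.combinations(range(4), 2))
    two = np.where(state == int(MetsState.TWO_COMPONENTS))[0]
    if two.size:
        pick = rng.integers(0, len(pairs), size=two.size)
        for j, (a, b) in enumerate(pairs):
            sel = two[pick == j]
            comp[sel, a] = True
            comp[sel, b] = True
    mets = np.where(state == int(MetsState.METS))[0]
    if mets.size:
        four = rng.random(mets.size) < config.mets_four_fraction
        comp[mets[four]] = True
        triples = mets[~four]
        if triples.size:
            out = rng.integers(0, 4, size=triples.size)  # which component is absent
            comp[triples] = True
            comp[triples, out] = False

    obesity = comp[:, comp_index["obesity"]]
    hyperglycemia = comp[:, comp_index["hyperglycemia"]]
    hypertension = comp[:, comp_index["hypertension"]]
    dyslipidemia = comp[:, comp_index["dyslipidemia"]]

    # demographics: sex from group, entry age uniform within the band,
    # aging one year per visit, entry year chosen so all visits fit the range
    group = df["group"].to_numpy()
    male = np.char.startswith(group.astype(str), "men")
    sex = np.where(male, Sex.MALE.value, Sex.FEMALE.value)
    per_subject = df.groupby("subject_id", sort=False)
    first_idx = per_subject.head(1).index
    n_visits = per_subject["visit_index"].transform("max").to_numpy() + 1
    young = np.char.find(group.astype(str), AgeBand.YOUNG.value) >= 0
    entry_age_subj = np.where(
        young[first_idx], rng.integers(20, 40, size=first_idx.size),
        rng.integers(40, 60, size=first_idx.size),
    )
    y0, y1 = config.entry_year_range
    last_entry = np.maximum(y0, y1 - (n_visits[first_idx] - 1))
    entry_year_subj = y0 + (rng.random(first_idx.size) * (last_entry - y0 + 1)).astype(int)
    entry_age = pd.Series(entry_age_subj, index=df.loc[first_idx, "subject_id"]).reindex(
        df["subject_id"]
    ).to_numpy()
    entry_year = pd.Series(entry_year_subj, index=df.loc[first_idx, "subject_id"]).reindex(
        df["subject_id"]
    ).to_numpy()
    vi = df["visit_index"].to_numpy()

    def draw_sided(flag: np.ndarray, hi: TruncNormal, lo: TruncNormal) -> np.ndarray:
        out = np.empty(n)
        k = int(flag.sum())
        out[flag] = hi.draw(rng, k)
        out[~flag] = lo.draw(rng, n - k)
        return out

    hist_htn = np.zeros(n, dtype=bool)
    hist_hg = np.zeros(n, dtype=bool)
    if config.emit_history:
        hist_htn = hypertension & (rng.random(n) < config.history_fraction)
        hist_hg = hyperglycemia & (rng.random(n) < config.history_fraction)

    # a history flag satisfies the criterion on its own, so flagged visits
    # draw in-range values; unflagged abnormal visits draw beyond-threshold
    bmi = draw_sided(obesity, em.bmi_obese, em.bmi_normal)
    glucose = draw_sided(hyperglycemia & ~hist_hg, em.glucose_high, em.glucose_normal)
    sbp = draw_sided(hypertension & ~hist_htn, em.sbp_high, em.sbp_normal)
    dbp = draw_sided(hypertension & ~hist_htn, em.dbp_high, em.dbp_normal)

    low_hdl = dyslipidemia & (rng.random(n) < em.low_hdl_fraction)
    tg = draw_sided(dyslipidemia & ~low_hdl, em.tg_high, em.tg_normal)
    hdl = np.empty(n)
    for is_male, normal, low in (
        (True, em.hdl_normal_male, em.hdl_low_male),
        (False, em.hdl_normal_female, em.hdl_low_female),
    ):
        sel = male if is_male else ~male
        lo_sel = sel & low_hdl
        hi_sel = sel & ~low_hdl
        hdl[lo_sel] = low.draw(rng, int(lo_sel.sum()))
        hdl[hi_sel] = normal.draw(rng, int(hi_sel.sum()))

    return pd.DataFrame(
        {
            "subject_id": df["subject_id"].to_numpy(),
            "visit_year": entry_year + vi,
            "sex": sex,
            "age_years": entry_age + vi,
            "sbp": np.round(sbp, 1),
            "dbp": np.round(dbp, 1),
            "bmi": np.round(bmi, 2),
            "fasting_glucose": np.round(glucose, 2),
            "tg": np.round(tg, 2),
            "hdl": np.round(hdl, 2),
            "cholesterol": np.round(em.cholesterol.draw(rng, n), 2),
            "history_hypertension": hist_htn,
            "history_hyperglycemia": hist_hg,
        }
    )


def make_panel(config: SyntheticConfig) -> pd.DataFrame:
    """Sample sequences and emit biomarkers; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    sequences = sample_state_sequences(config, rng)
    panel = emit_biomarkers(sequences, config, rng)
    panel.attrs["true_state"] = sequences["state"].to_numpy()
    return panel
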