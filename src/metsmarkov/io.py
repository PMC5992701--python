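"""Panel and matrix readers/writers, packaged fixtures, run configuration.

All tables are comma-separated UTF-8 with '.' as the decimal mark. Matrix
files carry probabilities in [0, 1]: a header row naming the 7 states in
canonical order, then 7 data rows labelled by origin state. The four
published group matrices ship as packaged fixtures in this format.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .markov import TransitionMatrix, validate_matrix
from .states import (
    GROUP_FROM_LABEL,
    REQUIRED_COLUMNS,
    STATE_LABELS,
    CDS_THRESHOLDS,
    GroupKey,
    Thresholds,
)

logger = logging.getLogger(__name__)

FIXTURE_LABELS = ("men_20_40", "men_40_60", "women_20_40", "women_40_60")


class MatrixFormatError(ValueError):
    """A matrix file does not follow the documented layout."""


@dataclass
class RunConfig:
    """User-facing configuration: column mapping, thresholds, horizon."""

    column_map: dict[str, str] = field(default_factory=dict)  # ours -> theirs
    thresholds: Thresholds = field(default_factory=lambda: CDS_THRESHOLDS)
    horizon: int = 10
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = raw.get("thresholds", {})
        return cls(
            column_map=raw.get("column_map", {}) or {},
            thresholds=Thresholds(**thr) if thr else CDS_THRESHOLDS,
            horizon=int(raw.get("horizon", 10)),
            verbosity=raw.get("verbosity", "INFO"),
        )

    def digest(self) -> str:
        payload = json.dumps(
            {
                "column_map": self.column_map,
                "thresholds": vars(self.thresholds),
                "horizon": self.horizon,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_panel(path: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Read a check-up panel table, renaming columns per the config map.

    Rows with missing or non-positive biomarkers are dropped with a logged
    count; unknown extra columns are kept but noted once.
    """
    config = config or RunConfig()
    df = pd.read_csv(path)
    rename = {theirs: ours for ours, theirs in config.column_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MatrixFormatError(
            f"panel {path} lacks required column(s) {missing}; "
            "map them via the column_map config entry"
        )
    known = set(REQUIRED_COLUMNS) | {
        "history_hypertension",
        "history_hyperglycemia",
        "cholesterol",
    }
    extras = [c for c in df.columns if c not in known]
    if extras:
        logger.warning("ignoring %d unknown column(s): %s", len(extras), extras)

    biomarkers = ["sbp", "dbp", "bmi", "fasting_glucose", "tg", "hdl"]
    for col in biomarkers:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[biomarkers].isna().any(axis=1) | (df[biomarkers] <= 0).any(axis=1)
    if bad.any():
        logger.warning(
            "dropped %d row(s) with missing or non-positive biomarker values",
            int(bad.sum()),
        )
        df = df[~bad]
    df["visit_year"] = df["visit_year"].astype(int)
    df["age_years"] = df["age_years"].astype(int)
    return df.reset_index(drop=True)


def write_matrix(matrix: TransitionMatrix, path: str | Path, percent: bool = False) -> None:
    """Write a matrix file; ``percent=True`` gives the 2-decimal report view."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("state," + ",".join(STATE_LABELS) + "\n")
        for i, lab in enumerate(STATE_LABELS):
            if percent:
                vals = ",".join(f"{100 * v:.2f}" for v in matrix.probs[i])
            else:
                vals = ",".join(repr(float(v)) for v in matrix.probs[i])
            f.write(f"{lab},{vals}\n")


def write_matrix_json(matrix: TransitionMatrix, path: str | Path) -> None:
    payload = {
        "group": matrix.group.label if matrix.group else None,
        "provenance": matrix.provenance,
        "states": list(STATE_LABELS),
        "row_support": matrix.row_support.tolist() if matrix.row_support is not None else None,
        "probs": [[float(v) for v in row] for row in matrix.probs],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_matrix(
    path: str | Path, group: GroupKey | None = None, tol: float = 1e-3
) -> TransitionMatrix:
    """Read a matrix file, enforcing layout and row-stochasticity."""
    df = pd.read_csv(path)
    if list(df.columns) != ["state", *STATE_LABELS]:
        raise MatrixFormatError(
            f"matrix file {path}: expected columns ['state', <7 canonical states>], "
            f"got {list(df.columns)}"
        )
    if list(df["state"]) != list(STATE_LABELS):
        raise MatrixFormatError(
            f"matrix file {path}: rows must be the 7 states in canonical order"
        )
    probs = df[list(STATE_LABELS)].to_numpy(dtype=float)
    report = validate_matrix(probs, tol=tol)
    if not report:
        raise MatrixFormatError(f"matrix file {path}: " + "; ".join(report.messages))
    return TransitionMatrix(probs=probs, group=group, provenance=f"read from {path}", tol=tol)


def read_matrix_json(path: str | Path) -> TransitionMatrix:
    payload = json.loads(Path(path).read_text())
    group = GROUP_FROM_LABEL.get(payload.get("group") or "")
    rs = payload.get("row_support")
    return TransitionMatrix(
        probs=np.asarray(payload["probs"], dtype=float),
        group=group,
        row_support=np.asarray(rs, dtype=int) if rs is not None else None,
        provenance=payload.get("provenance", f"read from {path}"),
        tol=1e-6,
    )


def load_fixture_matrix(group: GroupKey | str) -> TransitionMatrix:
    """Load one of the four packaged published group matrices."""
    label = group.label if isinstance(group, GroupKey) else str(group)
    if label not in FIXTURE_LABELS:
        raise KeyError(f"no fixture for {label!r}; choose from {FIXTURE_LABELS}")
    ref = resources.files("metsmarkov") / "fixtures" / f"{label}.csv"
    with resources.as_file(ref) as p:
        m = read_matrix(p, group=GROUP_FROM_LABEL[label])
    m.provenance = f"packaged fixture {label}"
    return m


def load_fixture_matrices() -> dict[GroupKey, TransitionMatrix]:
    return {GROUP_FROM_LABEL[lab]: load_fixture_matrix(lab) for lab in FIXTURE_LABELS}
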