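"""Per-participant study table: reading, validation, standardization, splitting.

The analysis consumes one row per participant: experimental condition
(normative vs. outcome performance goal), baseline heart rate and heart
rate during the task (beats/min, arousal measures), a pre-aggregated facial
anger intensity in [0, 1], and a non-negative achievement score from a
disc-transfer puzzle task.  Everything downstream (cusp regression,
competitor models, diagnostics) works on standardized columns, so this
module also owns the invertible z-score transform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "REQUIRED_COLUMNS",
    "ParticipantRecord",
    "StandardizedTable",
    "ValidationReport",
    "SchemaError",
    "DegenerateVarianceError",
    "read_study_table",
    "records_to_frame",
    "frame_to_records",
    "validate_schema",
    "split_by_condition",
    "standardize_columns",
]

CONDITIONS = ("normative", "outcome")
REQUIRED_COLUMNS = ("participant_id", "condition", "blhr", "hrdt", "anger", "achievement")

# physiologically admissible heart-rate band (bpm) for validation; the
# normal resting band is 60-100 but task arousal can exceed it
HR_MIN, HR_MAX = 30.0, 230.0


class SchemaError(ValueError):
    """A required column is missing or a field cannot be interpreted."""


class DegenerateVarianceError(ValueError):
    """A column to be standardized is constant (or nearly so)."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject's condition, physiology, anger, and achievement."""

    participant_id: str
    condition: str           # "normative" or "outcome"
    blhr: float              # baseline heart rate, beats/min
    hrdt: float              # heart rate during the task, beats/min
    anger: float             # mean facial anger intensity, in [0, 1]
    achievement: float       # task score, non-negative


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of invariant checking over a record list.

    ``violations`` holds (row index, field, message) triples.  In strict
    mode the report fails iff any violation exists; in lenient mode the
    offending rows are dropped and the retained records carried along.
    """

    violations: tuple[tuple[int, str, str], ...]
    passed: bool
    n_input: int
    n_retained: int
    n_dropped: int
    retained: tuple[ParticipantRecord, ...] = field(repr=False, default=())

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "n_dropped": self.n_dropped,
                "violations": [list(v) for v in self.violations],
            },
            indent=2,
        )


@dataclass
class StandardizedTable:
    """z-scored numeric columns alongside the retained raw table.

    The transform uses the sample standard deviation (n-1 denominator) and
    stores per-column mean/sd so it is exactly invertible.
    """

    data: pd.DataFrame            # standardized columns (+ passthrough columns)
    raw: pd.DataFrame             # original values
    means: dict[str, float]
    sds: dict[str, float]

    @property
    def columns(self) -> list[str]:
        return list(self.means)

    def invert(self, column: str, values) -> np.ndarray:
        """Map standardized values of ``column`` back to the raw scale."""
        return np.asarray(values, dtype=float) * self.sds[column] + self.means[column]


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(REQUIRED_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                condition=str(row["condition"]).strip().lower(),
                blhr=float(row["blhr"]),
                hrdt=float(row["hrdt"]),
                anger=float(row["anger"]),
                achievement=float(row["achievement"]),
            )
        )
    return out


def _load_column_map(column_map) -> dict[str, str]:
    """Accept a mapping {source name -> canonical name} or a YAML file path."""
    if column_map is None:
        return {}
    if isinstance(column_map, Mapping):
        return dict(column_map)
    import yaml

    with open(column_map, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, Mapping):
        raise SchemaError("column-map file must contain a mapping")
    return dict(loaded)


def read_study_table(
    path: str | Path,
    format: str = "csv",
    column_map: Mapping[str, str] | str | Path | None = None,
) -> list[ParticipantRecord]:
    """Read a study table from CSV or an SPSS .sav container.

    ``column_map`` renames source columns to the canonical schema
    (``participant_id, condition, blhr, hrdt, anger, achievement``) so a
    deposited file with its own variable names can be ingested without code
    changes.  Missing values are not silently dropped: they surface as NaN
    fields and are reported by :func:`validate_schema`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path, encoding="utf-8")
    elif format == "sav":
        try:
            df = pd.read_spss(path)
        except ImportError as exc:  # pandas delegates .sav parsing to pyreadstat
            raise ImportError(
                "reading SPSS .sav files requires the 'pyreadstat' package; "
                "install it or convert the file to CSV"
            ) from exc
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'sav'")
    rename = _load_column_map(column_map)
    if rename:
        df = df.rename(columns=rename)
    return frame_to_records(df)


def _check_record(i: int, r: ParticipantRecord) -> list[tuple[int, str, str]]:
    v: list[tuple[int, str, str]] = []
    if r.condition not in CONDITIONS:
        v.append((i, "condition", f"unknown condition label {r.condition!r}"))
    for name, value in (("blhr", r.blhr), ("hrdt", r.hrdt)):
        if not math.isfinite(value):
            v.append((i, name, "missing or non-finite"))
        elif not (HR_MIN <= value <= HR_MAX):
            v.append((i, name, f"heart rate {value} outside [{HR_MIN}, {HR_MAX}] bpm"))
    if not math.isfinite(r.anger):
        v.append((i, "anger", "missing or non-finite"))
    elif not (0.0 <= r.anger <= 1.0):
        v.append((i, "anger", f"anger intensity {r.anger} outside [0, 1]"))
    if not math.isfinite(r.achievement):
        v.append((i, "achievement", "missing or non-finite"))
    elif r.achievement < 0:
        v.append((i, "achievement", f"achievement {r.achievement} is negative"))
    return v


def validate_schema(
    records: Sequence[ParticipantRecord], strict: bool = True
) -> ValidationReport:
    """Check every record invariant and report (never raise) the outcome.

    Strict mode (default) fails on any breach; lenient mode drops offending
    rows, retains the rest, and records the counts.
    """
    violations: list[tuple[int, str, str]] = []
    bad_rows: set[int] = set()
    for i, r in enumerate(records):
        v = _check_record(i, r)
        violations.extend(v)
        if v:
            bad_rows.add(i)
    if strict:
        retained = tuple(records)
        passed = not violations
        n_dropped = 0
    else:
        retained = tuple(r for i, r in enumerate(records) if i not in bad_rows)
        passed = True
        n_dropped = len(bad_rows)
    return ValidationReport(
        violations=tuple(violations),
        passed=passed,
        n_input=len(records),
        n_retained=len(retained),
        n_dropped=n_dropped,
        retained=retained,
    )


def split_by_condition(
    records: Sequence[ParticipantRecord],
) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Partition records into (normative, outcome), preserving order."""
    groups: dict[str, list[ParticipantRecord]] = {c: [] for c in CONDITIONS}
    for r in records:
        if r.condition not in groups:
            raise ValueError(f"unknown condition label {r.condition!r}")
        groups[r.condition].append(r)
    return groups["normative"], groups["outcome"]


def standardize_columns(
    records: Sequence[ParticipantRecord] | pd.DataFrame,
    columns: Sequence[str],
) -> StandardizedTable:
    """z-score the named columns (sample sd, n-1 denominator).

    Non-listed columns are carried through untouched so downstream code can
    still see e.g. the condition label.
    """
    raw = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    raw = raw.reset_index(drop=True)
    if len(raw) < 2:
        raise DegenerateVarianceError("standardization needs at least 2 rows")
    data = raw.copy()
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for col in columns:
        if col not in raw.columns:
            raise SchemaError(f"missing required column(s): {col}")
        x = raw[col].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if not np.isfinite(sd) or sd < 1e-12 * max(1.0, abs(mu)):
            raise DegenerateVarianceError(f"column {col!r} has (near-)zero variance")
        data[col] = (x - mu) / sd
        means[col] = mu
        sds[col] = sd
    return StandardizedTable(data=data, raw=raw, means=means, sds=sds)
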