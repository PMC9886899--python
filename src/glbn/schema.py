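"""Cohort data model: variable schemas, longitudinal records, and binning rules.

The analysis operates on two tables per treatment-duration cohort:

* a *baseline* table of categorical covariates (one row per participant), and
* a *longitudinal* record per participant holding daily attendance, the daily
  methadone dose on attended days, and monthly urine-morphine results.

Calendar months are modelled as fixed 30-day blocks from enrollment, so a
6-month analysis window spans 7 observed months (the first month is an
adjustment phase and is excluded from the relapse definition) and 210 days;
a 12-month window spans 13 months and 390 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30

#: roles a variable can play in the analysis
ROLES = ("outcome", "demographic", "drug_use", "sex_behavior", "treatment")

MISSING = ""  # encoding of a missing cell in CSV output


class SchemaError(ValueError):
    """Raised when a table or record violates its declared schema."""


@dataclass(frozen=True)
class VariableSpec:
    """A categorical variable: its levels, dummy-coding group, and role.

    All dummy columns derived from one variable share ``group_id`` so that
    penalised regression can select or drop the variable as a whole.
    """

    name: str
    levels: tuple[str, ...]
    group_id: int
    role: str = "demographic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
        if len(self.levels) < 2:
            raise SchemaError(f"variable {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"variable {self.name!r} has duplicate levels")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.role == "outcome" and set(self.levels) != {"yes", "no"}:
            raise SchemaError("outcome variable must have levels {yes, no}")


def validate_specs(specs: Sequence[VariableSpec]) -> None:
    outcomes = [s for s in specs if s.role == "outcome"]
    if len(outcomes) != 1:
        raise SchemaError(f"exactly one outcome variable required, got {len(outcomes)}")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in schema")


@dataclass
class LongitudinalRecord:
    """Per-participant daily attendance/dose series plus monthly urine results.

    ``attendance[d]`` is True if the participant attended on day ``d``
    (0-based from enrollment); ``daily_dose[d]`` is the methadone dose in mg
    on attended days and NaN elsewhere.  ``urine_results[m]`` is True when
    the urine-morphine test of calendar month ``m+1`` was positive.
    """

    participant_id: str
    attendance: np.ndarray
    daily_dose: np.ndarray
    urine_results: np.ndarray
    enrollment_day: int = 0

    def __post_init__(self) -> None:
        self.attendance = np.asarray(self.attendance, dtype=bool)
        self.daily_dose = np.asarray(self.daily_dose, dtype=float)
        self.urine_results = np.asarray(self.urine_results, dtype=bool)
        if self.attendance.shape != self.daily_dose.shape:
            raise SchemaError("attendance and daily_dose must have equal length")
        if np.any(np.isfinite(self.daily_dose) & ~self.attendance):
            raise SchemaError(
                f"participant {self.participant_id}: dose recorded on absent day"
            )

    @property
    def window_days(self) -> int:
        return int(self.attendance.size)

    @property
    def window_months(self) -> int:
        return int(self.urine_results.size)


@dataclass(frozen=True)
class BinningRule:
    """Cut points mapping a numeric column to interval labels.

    Intervals are left-closed / right-open: with cuts ``[30, 60]`` the labels
    default to ``<30``, ``30-60``, ``>60`` and a value of exactly 30 falls in
    the middle bin.  ``labels`` may override the defaults (e.g. the
    open-ended style ``10-``, ``30-``, ``60-`` used for travel times).
    """

    variable: str
    cuts: tuple[float, ...]
    labels: tuple[str, ...] | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cuts)
        object.__setattr__(self, "cuts", cuts)
        if len(cuts) < 1:
            raise SchemaError(f"rule for {self.variable!r}: at least one cut required")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise SchemaError(f"rule for {self.variable!r}: cuts must strictly increase")
        if self.labels is not None:
            labels = tuple(self.labels)
            object.__setattr__(self, "labels", labels)
            if len(labels) != len(cuts) + 1:
                raise SchemaError(
                    f"rule for {self.variable!r}: need {len(cuts) + 1} labels"
                )

    @property
    def level_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        cuts = [format(c, "g") for c in self.cuts]
        mids = [f"{a}-{b}" for a, b in zip(cuts, cuts[1:])]
        return tuple([f"<{cuts[0]}", *mids, f">{cuts[-1]}"])

    def assign(self, value: float) -> str:
        """Label of the interval containing ``value``."""
        if not np.isfinite(value):
            raise SchemaError(f"{self.variable}: cannot bin non-finite value {value}")
        if self.lower is not None and value < self.lower:
            raise SchemaError(f"{self.variable}: value {value} below covered range")
        if self.upper is not None and value >= self.upper:
            raise SchemaError(f"{self.variable}: value {value} above covered range")
        idx = int(np.searchsorted(self.cuts, value, side="right"))
        return self.level_labels[idx]


class CohortTable:
    """A participant-by-variable categorical table with a missingness mask.

    Wraps a :class:`pandas.DataFrame` (one row per participant, object dtype
    with NaN for missing) together with the :class:`VariableSpec` list it must
    conform to.  Numeric columns are permitted only until :func:`discretize`
    has replaced them; validation skips columns without a spec.
    """

    def __init__(self, df: pd.DataFrame, specs: Sequence[VariableSpec]):
        self.df = df.reset_index(drop=True)
        self.specs = list(specs)
        self._by_name = {s.name: s for s in self.specs}
        self.validate()

    def __len__(self) -> int:
        return len(self.df)

    @property
    def outcome(self) -> str:
        for s in self.specs:
            if s.role == "outcome":
                return s.name
        raise SchemaError("no outcome variable declared")

    def spec(self, name: str) -> VariableSpec:
        return self._by_name[name]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()

    def validate(self) -> None:
        for s in self.specs:
            if s.name not in self.df.columns:
                continue
            col = self.df[s.name]
            if pd.api.types.is_numeric_dtype(col) and not col.dropna().isin(
                s.levels
            ).all():
                continue  # numeric precursor; discretized later
            bad = col.dropna()[~col.dropna().astype(str).isin(s.levels)]
            if len(bad):
                raise SchemaError(
                    f"column {s.name!r}: undeclared level(s) {sorted(set(bad))[:5]}"
                )

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), self.specs)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, na_rep=MISSING)

    @classmethod
    def from_csv(cls, path, specs: Sequence[VariableSpec]) -> "CohortTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df = df.replace(MISSING, np.nan)
        return cls(df, specs)


# -- longitudinal CSV I/O --------------------------------------------------

def records_to_frames(
    records: Iterable[LongitudinalRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten records into (attendance, urine) frames for CSV export.

    The attendance frame has columns participant_id, day, attended, dose_mg
    (day is 1-based in files); the urine frame has participant_id, month,
    result.
    """
    att_rows, ur_rows = [], []
    for rec in records:
        for d in range(rec.window_days):
            att_rows.append(
                (
                    rec.participant_id,
                    d + 1,
                    int(rec.attendance[d]),
                    rec.daily_dose[d] if rec.attendance[d] else MISSING,
                )
            )
        for m in range(rec.window_months):
            ur_rows.append((rec.participant_id, m + 1, int(rec.urine_results[m])))
    att = pd.DataFrame(att_rows, columns=["participant_id", "day", "attended", "dose_mg"])
    ur = pd.DataFrame(ur_rows, columns=["participant_id", "month", "result"])
    return att, ur


def records_from_frames(
    attendance: pd.DataFrame, urine: pd.DataFrame
) -> list[LongitudinalRecord]:
    """Inverse of :func:`records_to_frames`."""
    records = []
    ur_groups = dict(list(urine.groupby("participant_id", sort=False)))
    for pid, grp in attendance.groupby("participant_id", sort=False):
        grp = grp.sort_values("day")
        n_days = int(grp["day"].max())
        att = np.zeros(n_days, dtype=bool)
        dose = np.full(n_days, np.nan)
        days = grp["day"].to_numpy(dtype=int) - 1
        attended = grp["attended"].to_numpy(dtype=float) > 0
        att[days] = attended
        raw = pd.to_numeric(grp["dose_mg"], errors="coerce").to_numpy()
        dose[days[attended]] = raw[attended]
        ug = ur_groups[pid].sort_values("month")
        ur = ug["result"].to_numpy(dtype=float) > 0
        records.append(LongitudinalRecord(str(pid), att, dose, ur))
    return records
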