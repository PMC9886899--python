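"""Operational outcome definitions derived from longitudinal MMT records.

Relapse is defined as at least two consecutive positive monthly
urine-morphine tests, with the first month after enrollment excluded as an
adjustment phase; a 6-month cohort is therefore observed over 7 months and a
12-month cohort over 13.  Dropout is an absence from treatment of more than
14 consecutive days, and "continuous treatment days" counts the days since
the participant resumed treatment after their last dropout (the full window
when they never dropped out) — a compliance proxy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import BinningRule, CohortTable, LongitudinalRecord, SchemaError

DROPOUT_GAP_DAYS = 14  # a gap must strictly exceed this to count as dropout
FIRST_WEEK_DAYS = 7


class IncompleteRecordError(SchemaError):
    """The record does not cover the requested analysis window."""


def derive_relapse(record: LongitudinalRecord, duration_months: int) -> bool:
    """True iff months 2..duration_months+1 contain >=2 consecutive positives.

    The first month is excluded, so a positive pair spanning months 1-2 does
    not count; the pair must lie wholly within the retained window.
    """
    if duration_months not in (6, 12):
        raise ValueError("duration_months must be 6 or 12")
    needed = duration_months + 1
    if record.window_months < needed:
        raise IncompleteRecordError(
            f"participant {record.participant_id}: urine series covers "
            f"{record.window_months} months, need {needed}"
        )
    window = record.urine_results[1:needed]  # months 2..duration+1 (0-based slice)
    return bool(np.any(window[:-1] & window[1:]))


def _absence_runs(attendance: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) inclusive 0-based indices of maximal absence runs."""
    absent = ~np.asarray(attendance, dtype=bool)
    if absent.size == 0:
        raise SchemaError("empty attendance series")
    edges = np.flatnonzero(np.diff(absent.astype(np.int8)))
    starts = [0] if absent[0] else []
    starts += list(edges[absent[edges + 1]] + 1)
    ends = list(edges[~absent[edges + 1]])
    if absent[-1]:
        ends.append(absent.size - 1)
    return list(zip(starts, ends))


def derive_continuous_treatment_days(record: LongitudinalRecord) -> int:
    """Days from the day after the last dropout gap (>14 days absent) to the
    end of the window; the full window length when no such gap exists."""
    runs = _absence_runs(record.attendance)
    dropout_ends = [e for s, e in runs if (e - s + 1) > DROPOUT_GAP_DAYS]
    if not dropout_ends:
        return record.window_days
    return record.window_days - (dropout_ends[-1] + 1)


def derive_initial_dose(record: LongitudinalRecord) -> float:
    """Mean daily methadone dose over attended days of the first week (mg).

    Absent days contribute no terms; NaN when the participant attended no day
    in the first week (the value then flows into imputation).
    """
    week = slice(0, FIRST_WEEK_DAYS)
    att = record.attendance[week]
    if not att.any():
        return float("nan")
    return float(np.nanmean(record.daily_dose[week][att]))


def derive_average_dose(record: LongitudinalRecord) -> float:
    """Mean daily dose over all attended days of the whole window (mg)."""
    att = record.attendance
    if not att.any():
        return float("nan")
    return float(np.nanmean(record.daily_dose[att]))


def discretize(table: CohortTable, rules: list[BinningRule]) -> CohortTable:
    """Replace numeric columns by interval-label categoricals.

    Deterministic left-closed/right-open binning; already-categorical columns
    are left untouched (the mapping is idempotent); missing cells stay
    missing.
    """
    df = table.df.copy()
    for rule in rules:
        if rule.variable not in df.columns:
            raise SchemaError(f"no column {rule.variable!r} to discretize")
        col = df[rule.variable]
        numeric = pd.to_numeric(col, errors="coerce")
        labels = set(rule.level_labels)
        is_categorical = col.dropna().astype(str).isin(labels).all() and len(
            col.dropna()
        )
        if is_categorical:
            continue
        out = col.astype(object).copy()
        for i in numeric.index:
            if pd.isna(col.iloc[i]):
                continue
            if pd.isna(numeric.iloc[i]):
                raise SchemaError(
                    f"{rule.variable}: non-numeric value {col.iloc[i]!r} cannot be binned"
                )
            out.iloc[i] = rule.assign(float(numeric.iloc[i]))
        df[rule.variable] = out
    return CohortTable(df, table.specs)


def derived_frame(
    records: list[LongitudinalRecord],
    duration_months: int,
    dose_covariate: str = "initial",
) -> pd.DataFrame:
    """Per-participant derived outcomes as a numeric frame.

    Columns: participant_id, relapse (yes/no), continuous_days (int),
    dose_mg (initial-week or whole-window average, per ``dose_covariate``).
    """
    if dose_covariate not in ("initial", "average"):
        raise ValueError("dose_covariate must be 'initial' or 'average'")
    dose_fn = derive_initial_dose if dose_covariate == "initial" else derive_average_dose
    rows = []
    for rec in records:
        rows.append(
            (
                rec.participant_id,
                "yes" if derive_relapse(rec, duration_months) else "no",
                derive_continuous_treatment_days(rec),
                dose_fn(rec),
            )
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "relapse", "continuous_days", "dose_mg"]
    )
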