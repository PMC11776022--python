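"""Minute-epoch accelerometer processing: Freedson classification, wear-time
detection, period summaries and pregnancy-mean MVPA / % ST exposures.

Conventions (documented, configurable): non-wear is any run of >= 60
consecutive zero-count minutes; a day is valid with >= 600 wear minutes; a
period is valid with >= 3 valid days; a subject enters analysis with >= 2
valid periods.  Diary swim minutes are added to MVPA (swimming removes the
hip-worn device) but not to wear time, so % ST stays a share of measured
wear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config
from .errors import SubjectExclusionError, ValidationError

__all__ = [
    "PeriodSummary",
    "PregnancyExposure",
    "classify_epoch",
    "detect_wear",
    "summarize_period",
    "average_pregnancy",
    "process_cohort",
]

CATEGORIES = ("sedentary", "light", "mvpa")


@dataclass
class PeriodSummary:
    subject_id: str
    period: str
    n_valid_days: int
    mvpa_min_per_day: float  # swim-adjusted
    st_pct: float
    light_min_per_day: float
    wear_min_per_day: float
    valid: bool


@dataclass
class PregnancyExposure:
    subject_id: str
    mean_mvpa_min_per_day: float
    mean_st_pct: float
    n_periods_used: int


def classify_epoch(counts):
    """Freedson category per epoch: sedentary < 100, light 100-1951, MVPA > 1951.

    Accepts a scalar or array of nonnegative integer counts/min; returns the
    category name(s).
    """
    arr = np.asarray(counts)
    if np.any(arr < 0):
        raise ValidationError("counts must be nonnegative")
    cat = np.where(
        arr <= config.SEDENTARY_MAX_COUNTS,
        "sedentary",
        np.where(arr <= config.LIGHT_MAX_COUNTS, "light", "mvpa"),
    )
    return cat.item() if np.isscalar(counts) else cat


def detect_wear(day: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Per-minute wear flags and wear minutes for one subject-day.

    ``day`` needs ``minute_of_day`` and ``counts`` columns.  Minutes absent
    from the table are treated as zero counts.  Non-wear is any run of
    >= 60 consecutive zeros; everything else is wear.
    """
    minutes = day["minute_of_day"].to_numpy()
    if len(np.unique(minutes)) != len(minutes):
        raise ValidationError("duplicate minute_of_day within a day")
    counts = np.zeros(1440, dtype=np.int64)
    counts[minutes] = day["counts"].to_numpy()

    zero = counts == 0
    wear = ~zero
    # extend wear over zero runs shorter than the non-wear rule
    boundaries = np.flatnonzero(np.diff(np.concatenate(([0], zero.astype(np.int8), [0]))))
    for s, e in zip(boundaries[::2], boundaries[1::2]):
        if e - s < config.NONWEAR_ZERO_RUN_MIN:
            wear[s:e] = True
    return wear, int(wear.sum())


def summarize_period(
    records: pd.DataFrame, swim_diary: pd.DataFrame | None = None
) -> PeriodSummary:
    """Average sedentary / light / MVPA composition over the valid days of
    one subject-period, adding diary swim minutes to each day's MVPA.
    """
    if records.empty:
        raise ValidationError("summarize_period needs at least one day of data")
    sid = records["subject_id"].iloc[0]
    period = records["period"].iloc[0]

    swim_lookup: dict[int, float] = {}
    if swim_diary is not None and len(swim_diary):
        sel = swim_diary[
            (swim_diary["subject_id"] == sid) & (swim_diary["period"] == period)
        ]
        swim_lookup = dict(zip(sel["day"], sel["swim_minutes"]))

    rows = []
    for day_no, day in records.groupby("day"):
        wear_flags, wear_minutes = detect_wear(day)
        if wear_minutes < config.VALID_DAY_WEAR_MIN:
            continue
        counts = np.zeros(1440, dtype=np.int64)
        counts[day["minute_of_day"].to_numpy()] = day["counts"].to_numpy()
        cat = classify_epoch(counts[wear_flags])
        sed = int((cat == "sedentary").sum())
        light = int((cat == "light").sum())
        mvpa = int((cat == "mvpa").sum())
        rows.append((sed, light, mvpa + float(swim_lookup.get(day_no, 0.0)),
                     wear_minutes))
    n_valid = len(rows)
    if n_valid == 0:
        return PeriodSummary(sid, period, 0, 0.0, 0.0, 0.0, 0.0, False)
    sed, light, mvpa, wear = (np.mean([r[i] for r in rows]) for i in range(4))
    return PeriodSummary(
        subject_id=sid,
        period=period,
        n_valid_days=n_valid,
        mvpa_min_per_day=float(mvpa),
        st_pct=float(100.0 * sed / wear),
        light_min_per_day=float(light),
        wear_min_per_day=float(wear),
        valid=n_valid >= config.MIN_VALID_DAYS_PER_PERIOD,
    )


def average_pregnancy(summaries: list[PeriodSummary]) -> PregnancyExposure:
    """Unweighted mean of valid period summaries for one subject.

    Raises :class:`SubjectExclusionError` with the subject id when fewer than
    two periods are valid.
    """
    if not summaries:
        raise ValidationError("no summaries given")
    sid = summaries[0].subject_id
    valid = [s for s in summaries if s.valid]
    if len(valid) < config.MIN_VALID_PERIODS:
        raise SubjectExclusionError(
            sid, f"only {len(valid)} valid period(s); need >= {config.MIN_VALID_PERIODS}"
        )
    return PregnancyExposure(
        subject_id=sid,
        mean_mvpa_min_per_day=float(np.mean([s.mvpa_min_per_day for s in valid])),
        mean_st_pct=float(np.mean([s.st_pct for s in valid])),
        n_periods_used=len(valid),
    )


def process_cohort(
    epochs: pd.DataFrame, swim_diary: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, list[SubjectExclusionError]]:
    """Run the full stage for every subject in an epoch table.

    Returns a tidy exposure table (``subject_id, mean_mvpa_min_per_day,
    mean_st_pct, n_periods_used``) and the list of exclusions.
    """
    out, excluded = [], []
    for sid, sub in epochs.groupby("subject_id", sort=True):
        summaries = [
            summarize_period(per, swim_diary) for _, per in sub.groupby("period")
        ]
        try:
            exp = average_pregnancy(summaries)
        except SubjectExclusionError as err:
            excluded.append(err)
            continue
        out.append(vars(exp))
    return pd.DataFrame(out), excluded
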