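"""Non-wear detection, valid monitoring days, and valid-day averaging.

The sensor is worn continuously for ~48 h; periods off the body (bathing,
forgetting the pendant) must be excluded before any activity parameter is
computed.  A motionless sensor measures constant gravity, hence exactly zero
MAD, so non-wear is detected as long runs of zero minute-level MAD:

* a maximal run of zero-MAD minutes lasting >= 90 min is non-wear;
* up to 2 interior minutes with 0 < MAD < 20 mg do not break the run and are
  absorbed into it; a further interruption closes the run at its last zero
  minute and a fresh run (fresh interruption budget) starts afterwards;
* a valid monitoring day has >= 8 h (480 min) of wear;
* reported parameters are averaged over valid days, and subjects with fewer
  than 2 valid days are excluded.

Days are calendar days on the recording's local clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_core import EpochSeries

SECONDS_PER_DAY = 86400
NONWEAR_MIN = 90
NONWEAR_INTERRUPT_MAX = 2
NONWEAR_INTERRUPT_MAD_MAX = 20.0
VALID_DAY_HOURS = 8.0
REQUIRED_VALID_DAYS = 2
# "no MAD" floor: covers numeric roundoff and filter smear at off-body
# boundaries while staying well under the ~2 mg noise floor of a worn,
# motionless sensor
ZERO_MAD_EPS = 0.5

EXCLUDE_NO_WEAR = "no_wear"
EXCLUDE_LOW_WEAR = "low_wear"
EXCLUDE_INSUFFICIENT_DAYS = "insufficient_valid_days"


class SubjectExcluded(Exception):
    """Raised when a subject fails the wear-validity requirements."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class MinuteSeries:
    """Minute-resolution MAD aggregate aligned to the recording start."""

    t_start: np.ndarray           # seconds since recording start, minute grid
    mad_mg: np.ndarray
    start_clock_s: float = 0.0
    subject_id: str = ""

    @property
    def n_minutes(self) -> int:
        return int(self.t_start.shape[0])

    def day_index(self) -> np.ndarray:
        """Calendar-day index (day 0 contains the recording start)."""
        return ((self.start_clock_s + self.t_start) // SECONDS_PER_DAY).astype(int)


@dataclass
class WearMask:
    """Minute-resolution wear flags (True = worn) over the covered minutes."""

    t_start: np.ndarray
    wear: np.ndarray
    start_clock_s: float = 0.0
    subject_id: str = ""

    def day_index(self) -> np.ndarray:
        return ((self.start_clock_s + self.t_start) // SECONDS_PER_DAY).astype(int)

    def day_summary(self, valid_day_hours: float = VALID_DAY_HOURS) -> pd.DataFrame:
        days = self.day_index()
        rows = []
        for day in np.unique(days):
            wear_min = int(self.wear[days == day].sum())
            rows.append({"day": int(day), "wear_min": wear_min,
                         "valid": wear_min >= valid_day_hours * 60})
        return pd.DataFrame(rows)


def minute_mad(epochs: EpochSeries) -> MinuteSeries:
    """Aggregate epoch MADs to one value per minute (arithmetic mean).

    Only complete minutes are kept: a minute must be fully covered by epochs
    (at 6-s epochs, 10 per minute); partial minutes at the record edges are
    excluded.
    """
    per_min = int(round(60.0 / epochs.epoch_s))
    if not np.isclose(per_min * epochs.epoch_s, 60.0):
        raise ValueError("epoch length must divide 60 s for minute aggregation")
    # align minutes to the recording-start minute grid
    offset = epochs.start_t[0]
    rel = epochs.start_t - offset
    minute_idx = np.floor(rel / 60.0 + 1e-9).astype(int)
    n_minutes = minute_idx.max() + 1
    counts = np.bincount(minute_idx, minlength=n_minutes)
    sums = np.bincount(minute_idx, weights=epochs.mad_mg, minlength=n_minutes)
    full = counts == per_min
    return MinuteSeries(
        t_start=offset + 60.0 * np.flatnonzero(full),
        mad_mg=sums[full] / per_min,
        start_clock_s=epochs.start_clock_s,
        subject_id=epochs.subject_id,
    )


def detect_nonwear(minutes: MinuteSeries,
                   nonwear_min: int = NONWEAR_MIN,
                   interrupt_max: int = NONWEAR_INTERRUPT_MAX,
                   interrupt_mad_max: float = NONWEAR_INTERRUPT_MAD_MAX,
                   zero_eps: float = ZERO_MAD_EPS) -> WearMask:
    """Flag non-wear minutes by the zero-MAD run rule.

    Runs are grown left to right from the first zero-MAD minute: consecutive
    zero minutes extend the run; a block of minutes with 0 < MAD below
    ``interrupt_mad_max`` is absorbed (interior only — a run always starts and
    ends on a zero minute) as long as the cumulative absorbed count stays
    within ``interrupt_max`` and a zero minute follows.  Completed runs of at
    least ``nonwear_min`` minutes are flagged non-wear.
    """
    mad = np.asarray(minutes.mad_mg, dtype=np.float64)
    n = mad.shape[0]
    if n < 1:
        raise ValueError("minute series is empty")
    is_zero = mad <= zero_eps
    is_interrupt = (~is_zero) & (mad < interrupt_mad_max)
    wear = np.ones(n, dtype=bool)

    i = 0
    while i < n:
        if not is_zero[i]:
            i += 1
            continue
        run_start = i
        run_end = i + 1          # exclusive, always points past a zero minute
        absorbed = 0
        j = i + 1
        while j < n:
            if is_zero[j]:
                j += 1
                run_end = j
                continue
            if not is_interrupt[j]:
                break
            k = j
            while k < n and is_interrupt[k]:
                k += 1
            block = k - j
            if k < n and is_zero[k] and absorbed + block <= interrupt_max:
                absorbed += block
                j = k
                continue
            break
        if run_end - run_start >= nonwear_min:
            wear[run_start:run_end] = False
        i = max(run_end, i + 1)

    return WearMask(t_start=minutes.t_start.copy(), wear=wear,
                    start_clock_s=minutes.start_clock_s,
                    subject_id=minutes.subject_id)


def valid_days(mask: WearMask, valid_day_hours: float = VALID_DAY_HOURS) -> pd.DataFrame:
    """Per-calendar-day wear minutes and validity flag (>= 8 h wear)."""
    return mask.day_summary(valid_day_hours)


def average_over_valid_days(daily_values: pd.Series | dict,
                            day_table: pd.DataFrame,
                            required_valid_days: int = REQUIRED_VALID_DAYS) -> float:
    """Arithmetic mean of a daily parameter over valid days.

    Raises :class:`SubjectExcluded` when fewer than ``required_valid_days``
    days are valid — the subject contributes no value, not a number.
    """
    valid = day_table.loc[day_table["valid"], "day"].tolist()
    if len(valid) < required_valid_days:
        raise SubjectExcluded(
            EXCLUDE_INSUFFICIENT_DAYS,
            f"{len(valid)} valid day(s), {required_valid_days} required",
        )
    if isinstance(daily_values, dict):
        daily_values = pd.Series(daily_values)
    vals = daily_values.reindex(valid).dropna()
    if vals.empty:
        return float("nan")
    return float(vals.mean())


def exclusion_reason(mask: WearMask,
                     valid_day_hours: float = VALID_DAY_HOURS,
                     required_valid_days: int = REQUIRED_VALID_DAYS) -> str | None:
    """Classify why a subject fails validity, or ``None`` if retained.

    Mirrors the three failure modes of the monitored cohort: an entirely
    unworn recording ("forgot the sensor"), wear present but no day reaching
    8 h, and too few valid days.
    """
    summary = mask.day_summary(valid_day_hours)
    n_valid = int(summary["valid"].sum())
    if n_valid >= required_valid_days:
        return None
    if int(mask.wear.sum()) == 0:
        return EXCLUDE_NO_WEAR
    if n_valid == 0:
        return EXCLUDE_LOW_WEAR
    return EXCLUDE_INSUFFICIENT_DAYS
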