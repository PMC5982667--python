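"""Per-subject feature assembly: the full sensor-derived parameter set.

Thirty parameters in four blocks — sleep quantity (8), physical activity
pattern (10), stepping (3), and physical activity behavior (9, plus the
guideline-compliance flag) — each computed per valid monitoring day (or per
night) and averaged over the valid days of the 48-h recording.

Behavior bouts are maximal runs of consecutive same-level wear epochs without
interruption.  Behavior totals and percentages use wear time excluding the
nocturnal time in bed as denominator; steps are reported in thousands
(N/1000) with the raw count retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .posture_step import PostureDaySummary
from .signal_core import LEVEL_LIGHT, LEVEL_MTV, LEVEL_SEDENTARY, LEVELS, EpochSeries
from .sleep import SleepNight
from .wear_validity import SECONDS_PER_DAY, WearMask, average_over_valid_days

HHS_DAILY_MTV_MIN = 300 // 7    # >= 300 weekly minutes of MtV -> ~42 min/day

#: canonical feature names -> (description, units, block)
FEATURE_DICTIONARY: dict[str, tuple[str, str, str]] = {
    "tib_min": ("Time in bed", "min", "sleep"),
    "sol_min": ("Sleep onset latency", "min", "sleep"),
    "tst_min": ("Total sleep time", "min", "sleep"),
    "waso_min": ("Wake after sleep onset", "min", "sleep"),
    "se_pct": ("Sleep efficiency", "%", "sleep"),
    "supine_pct": ("Sleep supine position", "% of TiB", "sleep"),
    "prone_pct": ("Sleep prone position", "% of TiB", "sleep"),
    "sides_pct": ("Sleep side position", "% of TiB", "sleep"),
    "sit_pct": ("Total sit", "%", "pattern"),
    "stand_pct": ("Total stand", "%", "pattern"),
    "walk_pct": ("Total walk", "%", "pattern"),
    "lie_pct": ("Total lie", "%", "pattern"),
    "longest_sit_s": ("Longest unbroken sitting bout", "s", "pattern"),
    "median_sit_s": ("Median sitting bout", "s", "pattern"),
    "longest_stand_s": ("Longest unbroken standing bout", "s", "pattern"),
    "median_stand_s": ("Median standing bout", "s", "pattern"),
    "longest_walk_s": ("Longest unbroken walking bout", "s", "pattern"),
    "median_walk_s": ("Median walking bout", "s", "pattern"),
    "total_steps_k": ("Total step", "N/1000", "stepping"),
    "longest_step_bout_n": ("Longest unbroken stepping bout", "N", "stepping"),
    "median_step_bout_n": ("Median stepping bout", "N", "stepping"),
    "median_sed_s": ("Median sedentary bout", "s", "behavior"),
    "total_sed_h": ("Total sedentary", "h", "behavior"),
    "sed_pct": ("Total sedentary", "%", "behavior"),
    "median_light_s": ("Median light bout", "s", "behavior"),
    "total_light_h": ("Total light", "h", "behavior"),
    "light_pct": ("Total light", "%", "behavior"),
    "median_mtv_s": ("Median MtV bout", "s", "behavior"),
    "total_mtv_min": ("Total MtV", "min", "behavior"),
    "mtv_pct": ("Total MtV", "%", "behavior"),
    "hhs_met": ("Meets HHS moderate-to-vigorous guideline", "0/1", "behavior"),
}

FEATURE_NAMES = list(FEATURE_DICTIONARY)


def _epoch_wear_flags(epochs: EpochSeries, mask: WearMask) -> np.ndarray:
    minute_idx = ((epochs.start_t - mask.t_start[0]) // 60).astype(int)
    wear = np.zeros(epochs.n_epochs, dtype=bool)
    ok = (minute_idx >= 0) & (minute_idx < mask.wear.shape[0])
    wear[ok] = mask.wear[minute_idx[ok]]
    return wear


def _epoch_in_tib(epochs: EpochSeries, nights: list[tuple[int, float, float]]) -> np.ndarray:
    in_tib = np.zeros(epochs.n_epochs, dtype=bool)
    for _, t0, t1 in nights:
        in_tib |= (epochs.start_t >= t0) & (epochs.start_t < t1)
    return in_tib


def behavior_bouts(epochs: EpochSeries, wear: np.ndarray) -> pd.DataFrame:
    """Bouts (start, duration_s, level) of consecutive same-level wear epochs."""
    rows = []
    cur_level, cur_start, cur_n = None, 0.0, 0
    for i in range(epochs.n_epochs):
        level = epochs.level[i] if wear[i] else None
        if level == cur_level and level is not None:
            cur_n += 1
            continue
        if cur_level is not None:
            rows.append({"start": cur_start, "duration_s": cur_n * epochs.epoch_s,
                         "level": cur_level})
        cur_level, cur_start, cur_n = level, float(epochs.start_t[i]), 1
    if cur_level is not None:
        rows.append({"start": cur_start, "duration_s": cur_n * epochs.epoch_s,
                     "level": cur_level})
    return pd.DataFrame(rows, columns=["start", "duration_s", "level"])


def behavior_features(epochs: EpochSeries, mask: WearMask,
                      nights: list[tuple[int, float, float]],
                      exclude_tib: bool = True) -> pd.DataFrame:
    """Per-day behavior block: totals, percentages, median bout durations.

    Percentages divide by the day's wear time excluding nocturnal time in bed
    (set ``exclude_tib=False`` for the sensitivity variant).  Totals cover the
    same denominator time.  Units follow the reporting convention: sedentary
    and light totals in hours, MtV total in minutes, medians in seconds.
    """
    wear = _epoch_wear_flags(epochs, mask)
    in_tib = _epoch_in_tib(epochs, nights) if exclude_tib else np.zeros(epochs.n_epochs, bool)
    counted = wear & ~in_tib
    day = ((epochs.start_clock_s + epochs.start_t) // SECONDS_PER_DAY).astype(int)

    bouts = behavior_bouts(epochs, counted)
    if not bouts.empty:
        mid = bouts["start"] + 0.5 * bouts["duration_s"]
        bouts = bouts.assign(day=((epochs.start_clock_s + mid) // SECONDS_PER_DAY).astype(int))

    rows = []
    for d in np.unique(day):
        sel = counted & (day == d)
        denom_s = sel.sum() * epochs.epoch_s
        row: dict = {"day": int(d)}
        for level, key, scale in ((LEVEL_SEDENTARY, "sed", 3600.0),
                                  (LEVEL_LIGHT, "light", 3600.0),
                                  (LEVEL_MTV, "mtv", 60.0)):
            dur_s = float(np.sum(sel & (epochs.level == level)) * epochs.epoch_s)
            unit = "h" if scale == 3600.0 else "min"
            row[f"total_{key}_{unit}"] = dur_s / scale
            row[f"{key}_pct"] = 100.0 * dur_s / denom_s if denom_s > 0 else np.nan
            if bouts.empty:
                level_bouts = np.array([])
            else:
                level_bouts = bouts.loc[(bouts["level"] == level) & (bouts["day"] == d),
                                        "duration_s"].to_numpy()
            row[f"median_{key}_s"] = float(np.median(level_bouts)) if level_bouts.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def hhs_flag(total_mtv_min_per_day: float,
             threshold_min: float = HHS_DAILY_MTV_MIN) -> bool:
    """True when averaged daily MtV minutes meet the weekly guideline's
    per-day equivalent (300 min / 7 days -> 42 min)."""
    return bool(total_mtv_min_per_day >= threshold_min)


@dataclass
class SubjectFeatures:
    """The averaged parameter set for one retained subject."""

    subject_id: str
    values: dict

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        row.update({k: self.values.get(k, np.nan) for k in FEATURE_NAMES})
        return row


def assemble_subject(subject_id: str,
                     behavior_daily: pd.DataFrame,
                     posture_daily: list[PostureDaySummary],
                     nights: list[SleepNight],
                     day_table: pd.DataFrame,
                     required_valid_days: int = 2) -> SubjectFeatures:
    """Average daily blocks over valid days and nights into one feature row.

    Raises :class:`~frailsense.wear_validity.SubjectExcluded` when the
    valid-day requirement fails.  Missing blocks yield explicit NaN values.
    """
    values: dict = {}

    beh = behavior_daily.set_index("day") if not behavior_daily.empty else pd.DataFrame()
    for col, key in (("total_sed_h", "total_sed_h"), ("sed_pct", "sed_pct"),
                     ("median_sed_s", "median_sed_s"),
                     ("total_light_h", "total_light_h"), ("light_pct", "light_pct"),
                     ("median_light_s", "median_light_s"),
                     ("total_mtv_min", "total_mtv_min"), ("mtv_pct", "mtv_pct"),
                     ("median_mtv_s", "median_mtv_s")):
        series = beh[col] if col in beh.columns else pd.Series(dtype=float)
        values[key] = average_over_valid_days(series, day_table, required_valid_days)

    post = pd.DataFrame([s.to_dict() for s in posture_daily])
    post = post.set_index("day") if not post.empty else pd.DataFrame()
    mapping = {
        "sit_pct": "sitting_pct", "stand_pct": "standing_pct",
        "walk_pct": "walking_pct", "lie_pct": "lying_pct",
        "longest_sit_s": "longest_sitting_s", "median_sit_s": "median_sitting_s",
        "longest_stand_s": "longest_standing_s", "median_stand_s": "median_standing_s",
        "longest_walk_s": "longest_walking_s", "median_walk_s": "median_walking_s",
        "longest_step_bout_n": "longest_step_bout",
        "median_step_bout_n": "median_step_bout",
    }
    for key, col in mapping.items():
        series = post[col] if col in post.columns else pd.Series(dtype=float)
        values[key] = average_over_valid_days(series, day_table, required_valid_days)
    steps_series = post["total_steps"] if "total_steps" in post.columns else pd.Series(dtype=float)
    total_steps = average_over_valid_days(steps_series, day_table, required_valid_days)
    values["total_steps_raw"] = total_steps
    values["total_steps_k"] = total_steps / 1000.0

    if nights:
        night_frame = pd.DataFrame([n.to_dict() for n in nights])
        for key in ("tib_min", "sol_min", "tst_min", "waso_min", "se_pct",
                    "supine_pct", "prone_pct", "sides_pct"):
            values[key] = float(night_frame[key].mean())
    else:
        for key in ("tib_min", "sol_min", "tst_min", "waso_min", "se_pct",
                    "supine_pct", "prone_pct", "sides_pct"):
            values[key] = np.nan

    values["hhs_met"] = float(hhs_flag(values["total_mtv_min"])) \
        if np.isfinite(values["total_mtv_min"]) else np.nan
    return SubjectFeatures(subject_id=subject_id, values=values)


def cohort_frame(subjects: list[SubjectFeatures]) -> pd.DataFrame:
    """Subjects x features table in the canonical column order."""
    return pd.DataFrame([s.to_row() for s in subjects])


def save_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def load_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
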