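"""Synthetic study data: labeled 48-h accelerometer signals and cohort tables.

Two generators feed the pipeline with inputs of known truth:

* :func:`sample_schedule` / :func:`render_signal` build a 48-h activity
  schedule (postures, step times, activity intensities, nights with
  programmed SOL/WASO and lying positions, optional non-wear gaps) and render
  it as a 50 Hz tri-axial gravity+inertial signal.  Every programmed quantity
  is recoverable in closed form from the schedule, giving ground truth for
  recovery tests of each pipeline stage.

* :func:`sample_cohort_features` draws subjects x features tables calibrated
  to the reference cohort's per-group means +- SDs (42 non-frail, 78
  pre-frail, 33 frail community-dwelling older adults), using correlated
  Gaussian marginals (within-block correlation 0.5) truncated to physical
  bounds by resampling.  Gaussian marginals stand in for the unknown joint
  structure of real cohort data; see the methods note for what this does and
  does not emulate.

* :func:`exclusion_fixture` reproduces the recruitment attrition structure:
  163 recordings of which 3 fail on low wear time, 5 on too few valid days,
  and 2 on an entirely unworn sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frailty_clinical import STATUS_FRAIL, STATUS_NON_FRAIL, STATUS_PRE_FRAIL
from .signal_core import G_TO_MG, RawRecording
from .wear_validity import SECONDS_PER_DAY, MinuteSeries

# ---------------------------------------------------------------------------
# reference cohort calibration: per-group (mean, SD) of each sensor parameter
# for non-frail / pre-frail / frail community-dwelling older adults
# ---------------------------------------------------------------------------

GROUP_SIZES = {STATUS_NON_FRAIL: 42, STATUS_PRE_FRAIL: 78, STATUS_FRAIL: 33}

REFERENCE_COHORT_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "tib_min": {"non_frail": (494.3, 114.4), "pre_frail": (434.7, 125.3), "frail": (402.4, 127.6)},
    "sol_min": {"non_frail": (16.9, 7.5), "pre_frail": (18.5, 7.9), "frail": (20.0, 8.4)},
    "tst_min": {"non_frail": (367.5, 86.2), "pre_frail": (321.9, 116.5), "frail": (300.9, 119.4)},
    "waso_min": {"non_frail": (103.7, 48.0), "pre_frail": (89.4, 41.7), "frail": (75.5, 43.0)},
    "se_pct": {"non_frail": (78.4, 9.3), "pre_frail": (77.5, 10.9), "frail": (79.6, 11.6)},
    "supine_pct": {"non_frail": (43.6, 21.0), "pre_frail": (41.2, 23.2), "frail": (47.5, 31.4)},
    "prone_pct": {"non_frail": (14.7, 17.5), "pre_frail": (12.3, 16.7), "frail": (18.8, 23.3)},
    "sides_pct": {"non_frail": (34.6, 17.1), "pre_frail": (34.6, 24.2), "frail": (19.7, 21.1)},
    "sit_pct": {"non_frail": (43.3, 15.6), "pre_frail": (46.9, 17.1), "frail": (45.7, 17.1)},
    "stand_pct": {"non_frail": (16.9, 5.8), "pre_frail": (13.6, 5.8), "frail": (11.3, 5.7)},
    "walk_pct": {"non_frail": (8.7, 3.9), "pre_frail": (5.1, 3.3), "frail": (3.2, 3.2)},
    "lie_pct": {"non_frail": (30.9, 15.6), "pre_frail": (34.3, 20.4), "frail": (39.7, 20.9)},
    "longest_sit_s": {"non_frail": (5356.7, 3499.1), "pre_frail": (5351.3, 3042.0), "frail": (5576.5, 3927.4)},
    "median_sit_s": {"non_frail": (96.2, 72.9), "pre_frail": (89.6, 105.2), "frail": (81.1, 92.0)},
    "longest_stand_s": {"non_frail": (385.3, 387.3), "pre_frail": (550.6, 723.8), "frail": (553.2, 360.5)},
    "median_stand_s": {"non_frail": (15.0, 3.2), "pre_frail": (13.3, 7.5), "frail": (13.3, 11.7)},
    "longest_walk_s": {"non_frail": (351.3, 347.9), "pre_frail": (187.9, 223.9), "frail": (110.3, 132.4)},
    "median_walk_s": {"non_frail": (9.7, 1.0), "pre_frail": (9.0, 1.5), "frail": (8.3, 1.9)},
    "total_steps_k": {"non_frail": (12.2, 6.1), "pre_frail": (6.7, 4.2), "frail": (4.3, 4.3)},
    "longest_step_bout_n": {"non_frail": (694.3, 743.0), "pre_frail": (322.9, 411.0), "frail": (162.5, 184.2)},
    "median_step_bout_n": {"non_frail": (13.5, 2.2), "pre_frail": (10.8, 4.7), "frail": (8.8, 5.2)},
    "median_sed_s": {"non_frail": (323.8, 2044.6), "pre_frail": (491.1, 4243.4), "frail": (29.7, 16.7)},
    "total_sed_h": {"non_frail": (9.6, 2.6), "pre_frail": (11.7, 3.2), "frail": (13.2, 4.2)},
    "sed_pct": {"non_frail": (70.4, 12.7), "pre_frail": (81.1, 8.9), "frail": (84.9, 7.0)},
    "median_light_s": {"non_frail": (10.8, 2.2), "pre_frail": (9.6, 2.8), "frail": (8.3, 2.5)},
    "total_light_h": {"non_frail": (3.2, 1.3), "pre_frail": (2.4, 1.2), "frail": (2.1, 0.9)},
    "light_pct": {"non_frail": (23.7, 9.9), "pre_frail": (16.7, 7.7), "frail": (13.9, 6.2)},
    "median_mtv_s": {"non_frail": (6.8, 1.9), "pre_frail": (6.8, 2.4), "frail": (6.3, 1.8)},
    "total_mtv_min": {"non_frail": (47.7, 30.7), "pre_frail": (19.6, 20.5), "frail": (11.2, 14.6)},
    "mtv_pct": {"non_frail": (6.0, 4.0), "pre_frail": (2.2, 2.4), "frail": (1.2, 1.5)},
}

FEATURE_BLOCKS = {
    "sleep": ["tib_min", "sol_min", "tst_min", "waso_min", "se_pct",
              "supine_pct", "prone_pct", "sides_pct"],
    "pattern": ["sit_pct", "stand_pct", "walk_pct", "lie_pct",
                "longest_sit_s", "median_sit_s", "longest_stand_s",
                "median_stand_s", "longest_walk_s", "median_walk_s"],
    "stepping": ["total_steps_k", "longest_step_bout_n", "median_step_bout_n"],
    "behavior": ["median_sed_s", "total_sed_h", "sed_pct", "median_light_s",
                 "total_light_h", "light_pct", "median_mtv_s",
                 "total_mtv_min", "mtv_pct"],
}

#: reference starred set: parameters significant (p < 0.05, d >= 0.4) on both
#: pre-frail contrasts in the calibration cohort
REFERENCE_STARRED = frozenset({
    "walk_pct", "longest_walk_s", "median_walk_s", "total_steps_k",
    "longest_step_bout_n", "total_sed_h", "median_light_s",
    "total_mtv_min", "mtv_pct",
})

PCT_FEATURES = {name for name in REFERENCE_COHORT_STATS if name.endswith("_pct")}


# ---------------------------------------------------------------------------
# activity schedules
# ---------------------------------------------------------------------------

KIND_SIT = "sit"
KIND_STAND = "stand"
KIND_LIGHT = "light"          # standing with light-intensity movement
KIND_EXERCISE = "exercise"    # standing with moderate-to-vigorous movement
KIND_WALK = "walk"
KIND_LYING = "lying"
KIND_TRANSITION = "transition"   # sit<->stand lean signature
KIND_SETTLE = "settle"           # smooth orientation change into/out of bed
KIND_NONWEAR = "nonwear"

#: schedule kind -> true activity-intensity level of the rendered signal
KIND_LEVEL = {KIND_SIT: "sedentary", KIND_STAND: "sedentary",
              KIND_TRANSITION: "sedentary", KIND_SETTLE: "sedentary",
              KIND_LIGHT: "light", KIND_EXERCISE: "mtv", KIND_WALK: "mtv"}

#: schedule kind -> true posture (transitions carry their destination)
KIND_POSTURE = {KIND_SIT: "sitting", KIND_STAND: "standing",
                KIND_LIGHT: "standing", KIND_EXERCISE: "standing",
                KIND_WALK: "walking", KIND_LYING: "lying"}

TRANSITION_S = 2.0
SETTLE_S = 2.0


@dataclass
class Interval:
    start: float
    end: float
    kind: str
    position: str = ""            # lying only: supine/prone/left/right
    wake: bool = False            # lying only
    dest_posture: str = ""        # transition / settle
    steps: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start

    def posture(self) -> str:
        if self.kind in (KIND_TRANSITION, KIND_SETTLE):
            return self.dest_posture
        return KIND_POSTURE.get(self.kind, "")


@dataclass
class SubjectProfile:
    """Programmed per-subject behavior over the 48-h monitoring window."""

    subject_id: str = "synthetic"
    daily_steps: int = 8000
    cadence_hz: float = 1.7
    light_min_per_day: float = 150.0
    exercise_min_per_day: float = 10.0
    tib_min: int = 480
    sol_min: int = 20
    waso_min: int = 60
    terminal_wake_min: int = 10
    bed_clock_h: float = 23.0
    position_shares: tuple[float, float, float] = (0.5, 0.2, 0.3)  # supine/prone/sides
    start_clock_s: float = 20.0 * 3600
    duration_h: float = 48.0
    nonwear_gaps: tuple = ()      # (start_s, duration_min) pairs
    noise_sd_g: float = 0.003

    def validate(self) -> None:
        if not (0 < self.cadence_hz <= 4):
            raise ValueError("cadence outside physiological range")
        if self.sol_min + self.waso_min + self.terminal_wake_min >= self.tib_min:
            raise ValueError("infeasible profile: wake exceeds time in bed")
        if self.daily_steps < 0 or self.light_min_per_day < 0 or self.exercise_min_per_day < 0:
            raise ValueError("negative activity quota")
        active_s = SECONDS_PER_DAY - self.tib_min * 60
        busy = (self.daily_steps / self.cadence_hz
                + 60 * (self.light_min_per_day + self.exercise_min_per_day))
        if busy > 0.8 * active_s:
            raise ValueError("infeasible profile: activity exceeds waking time")


@dataclass
class ActivitySchedule:
    """Interval timeline tiling the recording, plus the generating profile."""

    intervals: list[Interval]
    profile: SubjectProfile
    start_clock_s: float
    duration_s: float

    def step_times(self) -> np.ndarray:
        times = [iv.steps for iv in self.intervals
                 if iv.kind == KIND_WALK and iv.steps is not None]
        return np.concatenate(times) if times else np.array([])

    def nights(self) -> list[dict]:
        """Programmed per-night truth (TiB bounds, SOL/WASO/TST, positions)."""
        nights: dict[int, dict] = {}
        for iv in self.intervals:
            if iv.kind != KIND_LYING:
                continue
            night_idx = int((self.start_clock_s + iv.start) // SECONDS_PER_DAY)
            # lying blocks that begin before midnight belong to that night;
            # blocks after midnight (toward morning) belong to the previous
            clock = (self.start_clock_s + iv.start) % SECONDS_PER_DAY
            if clock < 12 * 3600:
                night_idx -= 1
            rec = nights.setdefault(night_idx, {
                "night": night_idx, "tib_start": iv.start, "tib_end": iv.end,
                "wake_min": 0.0, "minutes": 0.0, "position_min": {}})
            rec["tib_start"] = min(rec["tib_start"], iv.start)
            rec["tib_end"] = max(rec["tib_end"], iv.end)
            minutes = iv.duration / 60.0
            rec["minutes"] += minutes
            if iv.wake:
                rec["wake_min"] += minutes
            rec["position_min"][iv.position] = (
                rec["position_min"].get(iv.position, 0.0) + minutes)
        out = []
        for night_idx in sorted(nights):
            rec = nights[night_idx]
            p = self.profile
            rec["tib_min"] = rec["tib_end"] / 60.0 - rec["tib_start"] / 60.0
            rec["sol_min"] = float(p.sol_min)
            rec["waso_min"] = float(p.waso_min)
            rec["terminal_wake_min"] = float(p.terminal_wake_min)
            rec["tst_min"] = rec["tib_min"] - rec["wake_min"]
            total = rec["minutes"]
            rec["supine_pct"] = 100.0 * rec["position_min"].get("supine", 0.0) / total
            rec["prone_pct"] = 100.0 * rec["position_min"].get("prone", 0.0) / total
            rec["sides_pct"] = 100.0 * (rec["position_min"].get("left", 0.0)
                                        + rec["position_min"].get("right", 0.0)) / total
            out.append(rec)
        return out

    def posture_truth_codes(self) -> np.ndarray:
        """Per-second true posture codes (0 = non-wear / unclassified)."""
        from .posture_step import (CODE_LYING, CODE_SITTING, CODE_STANDING,
                                   CODE_UNCLASSIFIED, CODE_WALKING)
        code_of = {"lying": CODE_LYING, "sitting": CODE_SITTING,
                   "standing": CODE_STANDING, "walking": CODE_WALKING}
        n = int(self.duration_s)
        codes = np.full(n, CODE_UNCLASSIFIED, dtype=np.int8)
        for iv in self.intervals:
            s, e = int(round(iv.start)), int(round(iv.end))
            if iv.kind == KIND_NONWEAR:
                codes[s:e] = CODE_UNCLASSIFIED
            else:
                codes[s:e] = code_of.get(iv.posture(), CODE_UNCLASSIFIED)
        return codes

    def daily_truth(self) -> pd.DataFrame:
        """Closed-form per-calendar-day truth for steps, postures, levels.

        Level durations (sed/light/mtv seconds) cover wear time outside the
        in-bed intervals, matching the reporting convention.
        """
        rows: dict[int, dict] = {}

        def day_row(day: int) -> dict:
            return rows.setdefault(day, {
                "day": day, "steps": 0, "walking_s": 0.0, "sitting_s": 0.0,
                "standing_s": 0.0, "lying_s": 0.0, "nonwear_s": 0.0,
                "sed_s": 0.0, "light_s": 0.0, "mtv_s": 0.0})

        for iv in self.intervals:
            pieces = _split_at_days(iv.start, iv.end, self.start_clock_s)
            for day, s, e in pieces:
                row = day_row(day)
                dur = e - s
                if iv.kind == KIND_NONWEAR:
                    row["nonwear_s"] += dur
                    continue
                posture = iv.posture()
                row[f"{posture}_s"] += dur
                if iv.kind != KIND_LYING:
                    row[f"{KIND_LEVEL[iv.kind][:5].replace('seden', 'sed')}_s"] += dur
                if iv.kind == KIND_WALK and iv.steps is not None:
                    clock = self.start_clock_s + iv.steps
                    row["steps"] += int(np.sum((clock >= day * SECONDS_PER_DAY)
                                               & (clock < (day + 1) * SECONDS_PER_DAY)))
        return pd.DataFrame([rows[d] for d in sorted(rows)])


def _split_at_days(start: float, end: float, clock0: float):
    """Split [start, end) recording-time interval at calendar-day boundaries."""
    out = []
    s = start
    while s < end:
        day = int((clock0 + s) // SECONDS_PER_DAY)
        day_end = (day + 1) * SECONDS_PER_DAY - clock0
        e = min(end, day_end)
        out.append((day, s, e))
        s = e
    return out


def _upright_unit(t: float, kind: str, duration: float, rng,
                  cadence: float | None = None, n_steps: int | None = None) -> list[Interval]:
    """Sit -> transition -> (stand / activity [walk flanked by stands]) ->
    transition -> back toward sitting."""
    out = [Interval(t, t + TRANSITION_S, KIND_TRANSITION, dest_posture="standing")]
    t += TRANSITION_S
    if kind == KIND_WALK:
        lead = float(rng.uniform(8, 20))
        out.append(Interval(t, t + lead, KIND_STAND))
        t += lead
        walk_dur = n_steps / cadence
        steps = t + (np.arange(n_steps) + 0.5) / cadence
        out.append(Interval(t, t + walk_dur, KIND_WALK, steps=steps))
        t += walk_dur
        tail = float(rng.uniform(8, 20))
        out.append(Interval(t, t + tail, KIND_STAND))
        t += tail
    else:
        out.append(Interval(t, t + duration, kind))
        t += duration
    out.append(Interval(t, t + TRANSITION_S, KIND_TRANSITION, dest_posture="sitting"))
    return out


def _build_active_span(t0: float, t1: float, steps_quota: int, light_s: float,
                       exercise_s: float, profile: SubjectProfile, rng) -> list[Interval]:
    """Fill [t0, t1) with sitting interleaved with upright activity units."""
    units: list[list[Interval]] = []
    remaining_steps = steps_quota
    while remaining_steps > 0:
        n = int(min(remaining_steps, rng.integers(40, 160)))
        if remaining_steps - n < 3:
            n = remaining_steps
        units.append(_upright_unit(0.0, KIND_WALK, 0.0, rng,
                                   cadence=profile.cadence_hz, n_steps=n))
        remaining_steps -= n
    for total, kind, chunk in ((light_s, KIND_LIGHT, (300.0, 1200.0)),
                               (exercise_s, KIND_EXERCISE, (240.0, 600.0))):
        left = total
        while left > 1.0:
            dur = float(min(left, rng.uniform(*chunk)))
            if left - dur < 60.0:
                dur = left
            units.append(_upright_unit(0.0, kind, dur, rng))
            left -= dur
    # a few quiet-standing bouts so standing exists apart from activity
    for _ in range(int(rng.integers(2, 5))):
        units.append(_upright_unit(0.0, KIND_STAND, float(rng.uniform(30, 90)), rng))

    rng.shuffle(units)
    busy = sum(iv.duration for unit in units for iv in unit)
    span = t1 - t0
    n_gaps = len(units) + 1
    slack = span - busy
    if slack < 30.0 * n_gaps:
        raise ValueError("infeasible profile: active span cannot hold the schedule")
    gap_weights = rng.dirichlet(np.ones(n_gaps))
    gaps = 30.0 + gap_weights * (slack - 30.0 * n_gaps)

    intervals: list[Interval] = []
    t = t0
    for i, unit in enumerate(units):
        intervals.append(Interval(t, t + gaps[i], KIND_SIT))
        t += gaps[i]
        for iv in unit:
            dur = iv.duration
            intervals.append(replace(
                iv, start=t, end=t + dur,
                steps=(iv.steps - iv.steps[0] + t + 0.5 / profile.cadence_hz)
                if iv.steps is not None else None))
            t += dur
    intervals.append(Interval(t, t1, KIND_SIT))
    return intervals


def _build_night(bed_t: float, profile: SubjectProfile, rng) -> list[Interval]:
    """Lying intervals covering one TiB block, minute-aligned.

    Layout: SOL wake, first sleep run, one or two interior WASO blocks,
    final sleep run, terminal wake.  Lying-position segments overlay the
    whole block with the programmed shares.
    """
    p = profile
    tib = p.tib_min
    waso_blocks = [p.waso_min] if p.waso_min < 20 else [p.waso_min // 2,
                                                        p.waso_min - p.waso_min // 2]
    sleep_total = tib - p.sol_min - p.waso_min - p.terminal_wake_min
    n_sleep_runs = len(waso_blocks) + 1
    base = sleep_total // n_sleep_runs
    sleep_runs = [base] * n_sleep_runs
    sleep_runs[-1] += sleep_total - base * n_sleep_runs

    # wake/sleep segmentation in minutes from TiB start
    segs: list[tuple[int, bool]] = [(p.sol_min, True)]
    for run, waso in zip(sleep_runs, waso_blocks + [None]):
        segs.append((run, False))
        if waso is not None:
            segs.append((waso, True))
    if p.terminal_wake_min:
        segs.append((p.terminal_wake_min, True))

    # position segmentation: each share split into 1-2 segments, interleaved
    shares = dict(zip(("supine", "prone", "sides"), p.position_shares))
    pos_minutes = {k: int(round(v * tib)) for k, v in shares.items()}
    drift = tib - sum(pos_minutes.values())
    pos_minutes["supine"] += drift
    pos_segments: list[tuple[int, str]] = []
    side_labels = ["left", "right"]
    for name, minutes in pos_minutes.items():
        if minutes <= 0:
            continue
        if name == "sides":
            half = minutes // 2
            for m, lab in zip((half, minutes - half), side_labels):
                if m > 0:
                    pos_segments.append((m, lab))
        else:
            pos_segments.append((minutes, name))
    rng.shuffle(pos_segments)

    # overlay the two segmentations
    wake_bounds = np.cumsum([0] + [s for s, _ in segs])
    pos_bounds = np.cumsum([0] + [s for s, _ in pos_segments])
    cuts = np.unique(np.concatenate([wake_bounds, pos_bounds]))
    intervals = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        wake = next(w for (bound, (s, w)) in zip(wake_bounds[1:], segs) if a < bound)
        position = next(lab for (bound, (s, lab)) in zip(pos_bounds[1:], pos_segments)
                        if a < bound)
        intervals.append(Interval(bed_t + 60.0 * a, bed_t + 60.0 * b, KIND_LYING,
                                  position=position, wake=wake))
    return intervals


def sample_schedule(profile: SubjectProfile | None = None,
                    seed: int | np.random.Generator = 0) -> ActivitySchedule:
    """Stochastic 48-h schedule hitting the profile's programmed totals."""
    profile = profile or SubjectProfile()
    profile.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    duration_s = profile.duration_h * 3600
    clock0 = profile.start_clock_s
    bed_clock = profile.bed_clock_h * 3600

    # night n starts at bed_clock of calendar day n (recording time)
    bed_times = []
    day = int(clock0 // SECONDS_PER_DAY)
    while True:
        bed_t = day * SECONDS_PER_DAY + bed_clock - clock0
        if bed_t >= duration_s:
            break
        if bed_t >= 0 and bed_t + profile.tib_min * 60 <= duration_s:
            bed_times.append(bed_t)
        day += 1

    # active spans between nights
    spans = []
    prev_end = 0.0
    for bed_t in bed_times:
        spans.append((prev_end, bed_t - SETTLE_S))
        prev_end = bed_t + profile.tib_min * 60 + SETTLE_S
    spans.append((prev_end, duration_s))
    spans = [(a, b) for a, b in spans if b - a > 60.0]

    total_active = sum(b - a for a, b in spans)
    n_days = profile.duration_h / 24.0
    total_steps = int(round(profile.daily_steps * n_days))
    total_light_s = profile.light_min_per_day * 60 * n_days
    total_exercise_s = profile.exercise_min_per_day * 60 * n_days

    intervals: list[Interval] = []
    remaining_steps = total_steps
    for i, (a, b) in enumerate(spans):
        frac = (b - a) / total_active
        if i == len(spans) - 1:
            steps_quota = remaining_steps
        else:
            steps_quota = int(round(total_steps * frac))
            remaining_steps -= steps_quota
        intervals.extend(_build_active_span(
            a, b, steps_quota, total_light_s * frac, total_exercise_s * frac,
            profile, rng))

    for bed_t in bed_times:
        intervals.append(Interval(bed_t - SETTLE_S, bed_t, KIND_SETTLE,
                                  dest_posture="lying"))
        intervals.extend(_build_night(bed_t, profile, rng))
        tib_end = bed_t + profile.tib_min * 60
        intervals.append(Interval(tib_end, tib_end + SETTLE_S, KIND_SETTLE,
                                  dest_posture="sitting"))

    intervals.sort(key=lambda iv: iv.start)
    schedule = ActivitySchedule(intervals=intervals, profile=profile,
                                start_clock_s=clock0, duration_s=duration_s)
    for gap_start, gap_min in profile.nonwear_gaps:
        schedule = carve_nonwear(schedule, gap_start, gap_min)
    return schedule


def carve_nonwear(schedule: ActivitySchedule, gap_start_s: float,
                  gap_min: float) -> ActivitySchedule:
    """Replace a minute-aligned window of the schedule with non-wear."""
    s = round(gap_start_s / 60.0) * 60.0
    e = s + round(gap_min) * 60.0
    out: list[Interval] = []
    for iv in schedule.intervals:
        if iv.end <= s or iv.start >= e:
            out.append(iv)
            continue
        for a, b in ((iv.start, min(iv.end, s)), (max(iv.start, e), iv.end)):
            if b - a > 1e-9:
                piece = replace(iv, start=a, end=b)
                if piece.steps is not None:
                    piece.steps = piece.steps[(piece.steps >= a) & (piece.steps < b)]
                out.append(piece)
    out.append(Interval(s, e, KIND_NONWEAR))
    out.sort(key=lambda iv: iv.start)
    return replace(schedule, intervals=out)


# ---------------------------------------------------------------------------
# signal rendering
# ---------------------------------------------------------------------------

_ORIENTATIONS = {
    "upright": np.array([1.0, 0.0, 0.0]),
    "supine": np.array([0.05, 1.0, 0.0]),
    "prone": np.array([0.05, -1.0, 0.0]),
    "left": np.array([0.05, 0.0, 1.0]),
    "right": np.array([0.05, 0.0, -1.0]),
    "nonwear": np.array([0.57, 0.57, 0.59]),
}
_ORIENTATIONS = {k: v / np.linalg.norm(v) for k, v in _ORIENTATIONS.items()}

LIGHT_AMP_G = 0.078       # vertical oscillation -> MAD ~ 47 mg (light band)
LIGHT_FREQ_HZ = 4.2       # above the step band, below the 12.5 Hz cut-off
EXERCISE_AMP_G = 0.236    # -> MAD ~ 140 mg (moderate-to-vigorous band)
EXERCISE_FREQ_HZ = 4.8
RESTLESS_AMP_G = 0.070    # wake-in-bed movement -> MAD ~ 42 mg
RESTLESS_FREQ_HZ = 4.2
STEP_BUMP_AMP_G = 0.5
STEP_BUMP_WIDTH_S = 0.35
TRANSITION_LEAN_RAD = np.deg2rad(50.0)


def _orientation_for(iv: Interval) -> np.ndarray:
    if iv.kind == KIND_LYING:
        return _ORIENTATIONS[iv.position if iv.position in _ORIENTATIONS else "supine"]
    if iv.kind == KIND_NONWEAR:
        return _ORIENTATIONS["nonwear"]
    return _ORIENTATIONS["upright"]


def render_signal(schedule: ActivitySchedule, noise_sd: float | None = None,
                  seed: int | np.random.Generator = 0,
                  rate_hz: float = 50.0) -> RawRecording:
    """Render the schedule as a 50 Hz tri-axial acceleration recording.

    Gravity follows the scheduled posture orientation; walking adds a vertical
    bump train peaking at the programmed step times; light / vigorous /
    restless movement adds oscillation outside the step band; non-wear is
    noiseless constant gravity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = schedule.profile
    if noise_sd is None:
        noise_sd = profile.noise_sd_g
    n = int(round(schedule.duration_s * rate_hz))
    xyz = np.zeros((n, 3), dtype=np.float32)
    worn = np.ones(n, dtype=bool)

    prev_orient = _ORIENTATIONS["upright"]
    for iv in schedule.intervals:
        s = int(round(iv.start * rate_hz))
        e = min(n, int(round(iv.end * rate_hz)))
        if e <= s:
            continue
        m = e - s
        tt = (np.arange(m) + s) / rate_hz
        if iv.kind == KIND_TRANSITION:
            theta = TRANSITION_LEAN_RAD * np.sin(np.pi * (tt - iv.start) / iv.duration)
            xyz[s:e, 0] = np.cos(theta)
            xyz[s:e, 1] = -np.sin(theta)       # forward lean: gravity to chest
            prev_orient = _ORIENTATIONS["upright"]
            continue
        orient = _orientation_for(iv)
        if iv.kind == KIND_SETTLE:
            dest = (_ORIENTATIONS["upright"] if iv.dest_posture != "lying"
                    else _ORIENTATIONS["supine"])
            u = ((tt - iv.start) / iv.duration)[:, None]
            seg = prev_orient[None, :] * (1 - u) + dest[None, :] * u
            seg /= np.linalg.norm(seg, axis=1, keepdims=True)
            xyz[s:e] = seg
            prev_orient = dest
            continue
        xyz[s:e] = orient[None, :]
        prev_orient = orient
        if iv.kind == KIND_NONWEAR:
            worn[s:e] = False
        elif iv.kind == KIND_LIGHT:
            xyz[s:e, 0] += LIGHT_AMP_G * np.sin(2 * np.pi * LIGHT_FREQ_HZ * tt)
        elif iv.kind == KIND_EXERCISE:
            xyz[s:e, 0] += EXERCISE_AMP_G * np.sin(2 * np.pi * EXERCISE_FREQ_HZ * tt)
        elif iv.kind == KIND_LYING and iv.wake:
            osc = RESTLESS_AMP_G * np.sin(2 * np.pi * RESTLESS_FREQ_HZ * tt)
            xyz[s:e] += osc[:, None] * orient[None, :]
        elif iv.kind == KIND_WALK and iv.steps is not None:
            half = STEP_BUMP_WIDTH_S / 2.0
            for st in iv.steps:
                a = max(s, int(round((st - half) * rate_hz)))
                b = min(e, int(round((st + half) * rate_hz)))
                if b <= a:
                    continue
                phase = ((np.arange(a, b) / rate_hz) - st) / half
                xyz[a:b, 0] += (STEP_BUMP_AMP_G * 0.5
                                * (1.0 + np.cos(np.pi * np.clip(phase, -1, 1)))
                                ).astype(np.float32)

    noise = rng.standard_normal((n, 3), dtype=np.float32) * np.float32(noise_sd)
    noise[~worn] = 0.0
    xyz += noise
    t = np.arange(n) / rate_hz
    return RawRecording(t=t, xyz=xyz, rate_hz=rate_hz,
                        subject_id=profile.subject_id,
                        start_clock_s=schedule.start_clock_s)


# ---------------------------------------------------------------------------
# cohort feature tables
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Calibrated cohort generator: group sizes, per-group marginals, and
    within-block correlation."""

    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    stats: dict = field(default_factory=lambda: REFERENCE_COHORT_STATS)
    blocks: dict = field(default_factory=lambda: FEATURE_BLOCKS)
    block_corr: float = 0.5
    max_resample: int = 200

    def validate(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        for feat, groups in self.stats.items():
            for g, (mean, sd) in groups.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {feat}/{g}")


def _block_correlation(features: list[str], blocks: dict, rho: float) -> np.ndarray:
    corr = np.eye(len(features))
    index = {f: i for i, f in enumerate(features)}
    for members in blocks.values():
        idx = [index[f] for f in members if f in index]
        for i in idx:
            for j in idx:
                if i != j:
                    corr[i, j] = rho
    # PSD repair: clip negative eigenvalues (no-op for valid block structure)
    w, v = np.linalg.eigh(corr)
    if w.min() < 0:
        import warnings
        warnings.warn("correlation matrix repaired to positive semi-definite")
        w = np.clip(w, 1e-10, None)
        corr = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


def _feature_bounds(name: str) -> tuple[float, float]:
    hi = 100.0 if name in PCT_FEATURES else np.inf
    return 0.0, hi


def sample_cohort_features(spec: CohortSpec | None = None,
                           seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw a subjects x features cohort with frailty labels.

    Per group, features follow a correlated Gaussian with the calibrated
    means/SDs; rows violating physical bounds (negative durations,
    percentages outside [0, 100]) are redrawn (resampling, not clipping, so
    group means are preserved) up to ``max_resample`` rounds, then clipped.
    The guideline flag derives from the drawn MtV minutes.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    features = list(spec.stats)
    corr = _block_correlation(features, spec.blocks, spec.block_corr)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(features)))
    lows = np.array([_feature_bounds(f)[0] for f in features])
    highs = np.array([_feature_bounds(f)[1] for f in features])

    frames = []
    for status, n in spec.group_sizes.items():
        means = np.array([spec.stats[f][status][0] for f in features])
        sds = np.array([spec.stats[f][status][1] for f in features])

        def draw(k: int) -> np.ndarray:
            z = rng.standard_normal((k, len(features)))
            return means + (z @ chol.T) * sds

        x = draw(n)
        for _ in range(spec.max_resample):
            bad = np.any((x < lows) | (x > highs), axis=1)
            if not bad.any():
                break
            x[bad] = draw(int(bad.sum()))
        x = np.clip(x, lows, highs)
        df = pd.DataFrame(x, columns=features)
        df.insert(0, "status", status)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i:03d}" for i in range(len(out))])
    if "total_mtv_min" in out.columns:
        out["hhs_met"] = (out["total_mtv_min"] >= 42.0).astype(float)
    return out


# ---------------------------------------------------------------------------
# exclusion fixture
# ---------------------------------------------------------------------------

FIXTURE_N_TOTAL = 163
FIXTURE_N_LOW_WEAR = 3
FIXTURE_N_ONE_VALID_DAY = 5
FIXTURE_N_NO_WEAR = 2


def _fixture_day(rng, kind: str) -> np.ndarray:
    """One day (1440 min) of minute-MAD values for the exclusion fixture."""
    if kind == "clean":
        mad = 20.0 + np.abs(rng.normal(25.0, 20.0, 1440))
        gap = int(rng.integers(45, 76))          # a bath-length off-body gap
        start = int(rng.integers(480, 1200 - gap))
        mad[start:start + gap] = 0.0
        return mad
    if kind == "short":                           # ~4-5 h of wear only
        mad = np.zeros(1440)
        wear = int(rng.integers(240, 300))
        start = int(rng.integers(400, 700))
        mad[start:start + wear] = 20.0 + np.abs(rng.normal(25.0, 20.0, wear))
        return mad
    if kind == "empty":
        return np.zeros(1440)
    raise ValueError(kind)


def exclusion_fixture(seed: int | np.random.Generator = 0) -> list[dict]:
    """163 synthetic two-day minute-MAD recordings with known attrition.

    3 subjects never reach 8 h of wear on any day, 5 have exactly one valid
    day, 2 wear the sensor not at all, and 153 are clean.  Counts are
    deterministic across seeds; the traces are not.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kinds = (["low_wear"] * FIXTURE_N_LOW_WEAR
             + ["one_valid_day"] * FIXTURE_N_ONE_VALID_DAY
             + ["no_wear"] * FIXTURE_N_NO_WEAR
             + ["clean"] * (FIXTURE_N_TOTAL - FIXTURE_N_LOW_WEAR
                            - FIXTURE_N_ONE_VALID_DAY - FIXTURE_N_NO_WEAR))
    rng.shuffle(kinds)
    day_plan = {"clean": ("clean", "clean"), "low_wear": ("short", "short"),
                "one_valid_day": ("clean", "short"), "no_wear": ("empty", "empty")}
    subjects = []
    for i, kind in enumerate(kinds):
        mad = np.concatenate([_fixture_day(rng, d) for d in day_plan[kind]])
        minutes = MinuteSeries(t_start=60.0 * np.arange(2880), mad_mg=mad,
                               start_clock_s=0.0, subject_id=f"X{i:03d}")
        subjects.append({"subject_id": f"X{i:03d}", "minutes": minutes,
                         "category": kind})
    return subjects
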