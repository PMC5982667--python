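"""Nocturnal time in bed, minute-wise sleep/wake, and sleep-quantity parameters.

Time in bed (TiB) is the longest lying-dominated contiguous block within the
nocturnal window (21:00-11:00) of each night.  Within TiB only, a transparent
logistic rule scores each minute from three features — minute MAD, a rolling
7-min standard deviation of minute MAD, and a lying-position-change indicator
— and labels it wake when the score crosses 0.5.  From the labels:

    SOL  = minutes from TiB start to the first sleep minute
    TST  = total sleep minutes
    WASO = wake minutes between first sleep onset and last sleep offset
    SE   = 100 * TST / (last sleep offset - first sleep onset)

so that SOL + TST + WASO + terminal wake = TiB by construction.  Lying
position per minute (supine / prone / sides) comes from the dominant
horizontal-plane gravity component: the frontal axis is positive toward the
back, so gravity along +frontal means supine, along -frontal prone, and a
dominant lateral component means side-lying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .posture_step import CODE_LYING, _contiguous_runs, _second_average
from .signal_core import RawRecording
from .wear_validity import SECONDS_PER_DAY, MinuteSeries

logger = logging.getLogger(__name__)

NOCTURNAL_WINDOW_H = (21.0, 11.0)      # 21:00 through 11:00 next day
LYING_DOMINANCE = 0.8
MIN_TIB_MIN = 60
ROLLING_SD_WIN = 7

# logistic sleep/wake weights: [intercept, minute MAD (mg), rolling SD (mg),
# position change (0/1)]; calibrated on the synthetic generator's ground truth
DEFAULT_SLEEP_WEIGHTS = (-3.0, 0.12, 0.04, 0.8)
WAKE_PROB_THRESHOLD = 0.5

POS_SUPINE = "supine"
POS_PRONE = "prone"
POS_LEFT = "left"
POS_RIGHT = "right"
POS_NONE = "none"          # brief upright minutes in bed carry no position


@dataclass
class SleepNight:
    """One night's in-bed interval, minute labels, and derived parameters."""

    night: int
    tib_start: float                 # seconds since recording start
    tib_end: float
    wake: np.ndarray                 # per TiB minute, True = wake
    position: np.ndarray             # per TiB minute, one of the POS_* labels
    tib_min: float = 0.0
    sol_min: float = 0.0
    tst_min: float = 0.0
    waso_min: float = 0.0
    se_pct: float = float("nan")
    supine_pct: float = 0.0
    prone_pct: float = 0.0
    sides_pct: float = 0.0

    def to_dict(self) -> dict:
        return {"night": self.night, "tib_min": self.tib_min,
                "sol_min": self.sol_min, "tst_min": self.tst_min,
                "waso_min": self.waso_min, "se_pct": self.se_pct,
                "supine_pct": self.supine_pct, "prone_pct": self.prone_pct,
                "sides_pct": self.sides_pct}


def nocturnal_windows(n_seconds: float, start_clock_s: float,
                      window_h: tuple[float, float] = NOCTURNAL_WINDOW_H):
    """(night_index, window_start_s, window_end_s) in recording time.

    Night ``n`` spans 21:00 of calendar day ``n`` to 11:00 of day ``n + 1``.
    Windows are clipped to the recording; empty windows are dropped.
    """
    out = []
    first_day = int(start_clock_s // SECONDS_PER_DAY)
    last_day = int((start_clock_s + n_seconds) // SECONDS_PER_DAY)
    for night in range(first_day - 1, last_day + 1):
        w_start = night * SECONDS_PER_DAY + window_h[0] * 3600 - start_clock_s
        w_end = (night + 1) * SECONDS_PER_DAY + window_h[1] * 3600 - start_clock_s
        w_start, w_end = max(0.0, w_start), min(float(n_seconds), w_end)
        if w_end - w_start >= MIN_TIB_MIN * 60:
            out.append((night, w_start, w_end))
    return out


def detect_time_in_bed(posture_codes: np.ndarray, start_clock_s: float,
                       window_h: tuple[float, float] = NOCTURNAL_WINDOW_H,
                       lying_dominance: float = LYING_DOMINANCE,
                       min_tib_min: int = MIN_TIB_MIN) -> list[tuple[int, float, float]]:
    """Per-night (night, tib_start_s, tib_end_s) from the posture timeline.

    Within each nocturnal window, minute-wise lying indicators are computed
    and maximal lying runs are greedily merged (absorbing interior non-lying
    gaps) while the merged block keeps at least ``lying_dominance`` lying
    minutes; the longest qualifying block of the night wins.  Nights with no
    block of at least ``min_tib_min`` minutes are skipped with a warning.
    """
    n_seconds = posture_codes.shape[0]
    nights = []
    for night, w_start, w_end in nocturnal_windows(n_seconds, start_clock_s, window_h):
        s0 = int(np.ceil(w_start / 60.0))
        s1 = int(np.floor(w_end / 60.0))
        if s1 - s0 < min_tib_min:
            continue
        lying_min = np.array([
            np.mean(posture_codes[m * 60:(m + 1) * 60] == CODE_LYING) >= 0.5
            for m in range(s0, s1)
        ])
        best = _longest_dominated_block(lying_min, lying_dominance)
        if best is None or best[1] - best[0] < min_tib_min:
            logger.warning("night %d: no lying-dominated block of >= %d min",
                           night, min_tib_min)
            continue
        nights.append((night, (s0 + best[0]) * 60.0, (s0 + best[1]) * 60.0))
    return nights


def _longest_dominated_block(lying: np.ndarray, dominance: float):
    """Longest [start, end) merging lying runs while lying share >= dominance."""
    runs = _contiguous_runs(lying)
    if not runs:
        return None
    best = None
    for i in range(len(runs)):
        start = runs[i][0]
        lying_count = 0
        end = runs[i][1]
        for j in range(i, len(runs)):
            cand_end = runs[j][1]
            cand_lying = lying_count + (runs[j][1] - runs[j][0])
            if cand_lying / (cand_end - start) >= dominance:
                lying_count = cand_lying
                end = cand_end
            else:
                break
        if best is None or (end - start) > (best[1] - best[0]):
            best = (start, end)
    return best


def minute_features(minutes: MinuteSeries, position: np.ndarray,
                    tib_start: float, tib_end: float,
                    sd_window: int = ROLLING_SD_WIN) -> np.ndarray:
    """Feature matrix (MAD, rolling SD of MAD, position change) per TiB minute."""
    m0 = int(round((tib_start - minutes.t_start[0]) / 60.0))
    m1 = int(round((tib_end - minutes.t_start[0]) / 60.0))
    if m0 < 0 or m1 > minutes.n_minutes:
        raise ValueError("TiB interval not covered by the minute series")
    mad = minutes.mad_mg[m0:m1]
    half = sd_window // 2
    sd = np.array([np.std(mad[max(0, i - half): i + half + 1]) for i in range(mad.shape[0])])
    pos_change = np.zeros(mad.shape[0])
    pos_change[1:] = (position[1:] != position[:-1]).astype(float)
    return np.column_stack([mad, sd, pos_change])


def classify_sleep_wake(features: np.ndarray,
                        weights: tuple[float, ...] = DEFAULT_SLEEP_WEIGHTS,
                        threshold: float = WAKE_PROB_THRESHOLD) -> np.ndarray:
    """Minute-wise wake flags from the logistic decision rule.

    ``features`` is (n_minutes, 3): minute MAD (mg), rolling SD (mg), and a
    0/1 position-change indicator.  A minute is wake when the logistic score
    reaches the threshold.
    """
    if features.ndim != 2 or features.shape[1] != len(weights) - 1:
        raise ValueError("feature matrix does not match the weight vector")
    score = weights[0] + features @ np.asarray(weights[1:], dtype=np.float64)
    prob = 1.0 / (1.0 + np.exp(-score))
    return prob >= threshold


def sleep_parameters(night: SleepNight) -> SleepNight:
    """Fill the derived sleep-quantity fields from the minute labels."""
    wake = np.asarray(night.wake, dtype=bool)
    n = wake.shape[0]
    night.tib_min = float(n)
    sleep_idx = np.flatnonzero(~wake)
    if sleep_idx.size == 0:
        night.sol_min = float(n)
        night.tst_min = 0.0
        night.waso_min = 0.0
        night.se_pct = float("nan")
    else:
        onset, offset = int(sleep_idx[0]), int(sleep_idx[-1]) + 1
        night.sol_min = float(onset)
        night.tst_min = float(sleep_idx.size)
        night.waso_min = float(np.sum(wake[onset:offset]))
        night.se_pct = 100.0 * night.tst_min / (offset - onset)
    return night


def lying_positions(rec: RawRecording, posture_codes: np.ndarray,
                    tib_start: float, tib_end: float) -> np.ndarray:
    """Per-TiB-minute lying-position labels from gravity orientation.

    Minutes not dominated by lying posture are unpositioned (``none``).
    Near-45-degree orientations go to the nearest axis (larger magnitude).
    """
    n_seconds = posture_codes.shape[0]
    f = _second_average(rec.xyz[:, 1], rec.rate_hz, n_seconds)
    lat = _second_average(rec.xyz[:, 2], rec.rate_hz, n_seconds)
    m0, m1 = int(tib_start // 60), int(tib_end // 60)
    labels = []
    for m in range(m0, m1):
        sl = slice(m * 60, (m + 1) * 60)
        if np.mean(posture_codes[sl] == CODE_LYING) < 0.5:
            labels.append(POS_NONE)
            continue
        fm, lm = float(np.mean(f[sl])), float(np.mean(lat[sl]))
        if abs(fm) >= abs(lm):
            labels.append(POS_SUPINE if fm >= 0 else POS_PRONE)
        else:
            labels.append(POS_LEFT if lm >= 0 else POS_RIGHT)
    return np.array(labels, dtype=object)


def position_percentages(position: np.ndarray) -> tuple[float, float, float]:
    """Supine/prone/sides shares as % of TiB minutes (unpositioned excluded
    from the numerators but kept in the TiB denominator)."""
    n = position.shape[0]
    if n == 0:
        return (float("nan"),) * 3
    supine = 100.0 * np.sum(position == POS_SUPINE) / n
    prone = 100.0 * np.sum(position == POS_PRONE) / n
    sides = 100.0 * (np.sum(position == POS_LEFT) + np.sum(position == POS_RIGHT)) / n
    return supine, prone, sides


def analyze_night(night_idx: int, tib_start: float, tib_end: float,
                  minutes: MinuteSeries, rec: RawRecording,
                  posture_codes: np.ndarray,
                  weights: tuple[float, ...] = DEFAULT_SLEEP_WEIGHTS) -> SleepNight:
    """Full per-night analysis: positions, sleep/wake labels, parameters."""
    position = lying_positions(rec, posture_codes, tib_start, tib_end)
    feats = minute_features(minutes, position, tib_start, tib_end)
    wake = classify_sleep_wake(feats, weights)
    night = SleepNight(night=night_idx, tib_start=tib_start, tib_end=tib_end,
                       wake=wake, position=position)
    night = sleep_parameters(night)
    night.supine_pct, night.prone_pct, night.sides_pct = position_percentages(position)
    return night
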