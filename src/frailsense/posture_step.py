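"""Step detection, walking episodes, posture classification, bout statistics.

Steps are peaks of the band-pass-filtered vertical (cranio-caudal) axis; a
walking episode is a run of at least three consecutive steps separated by no
more than a maximum inter-step interval.  The remaining (non-walking) time is
split into lying — trunk near-horizontal, vertical gravity component close to
zero — and upright time, which a transition-triggered state machine divides
into sitting and standing: a chest sensor cannot separate the two static
postures by gravity alone, so sit-to-stand / stand-to-sit lean signatures in
the frontal-vertical plane toggle the state, anchored by walking (standing
borders walking) and by lying (sitting borders lying).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.signal import find_peaks

from .signal_core import RawRecording
from .wear_validity import SECONDS_PER_DAY, WearMask

logger = logging.getLogger(__name__)

STEP_THRESHOLD_G = 0.1
STEP_BAND_HZ = (0.5, 3.0)
STEP_REFRACTORY_S = 0.2
MAX_INTERSTEP_S = 2.5
MIN_STEPS_PER_BOUT = 3
LYING_G_MAX = 0.4
TRANSITION_LEAN_G = 0.45
TRANSITION_MIN_GAP_S = 3.0
TRANSITION_EDGE_MARGIN_S = 3.0

POSTURE_LYING = "lying"
POSTURE_SITTING = "sitting"
POSTURE_STANDING = "standing"
POSTURE_WALKING = "walking"
POSTURES = (POSTURE_LYING, POSTURE_SITTING, POSTURE_STANDING, POSTURE_WALKING)

# per-second timeline codes
CODE_UNCLASSIFIED = 0
CODE_LYING = 1
CODE_SITTING = 2
CODE_STANDING = 3
CODE_WALKING = 4
CODE_TO_POSTURE = {CODE_LYING: POSTURE_LYING, CODE_SITTING: POSTURE_SITTING,
                   CODE_STANDING: POSTURE_STANDING, CODE_WALKING: POSTURE_WALKING}


@dataclass
class StepEvents:
    """Detected step peak times (s) and signed peak amplitudes (g)."""

    t: np.ndarray
    amplitude_g: np.ndarray

    @property
    def n_steps(self) -> int:
        return int(self.t.shape[0])


@dataclass
class PostureBout:
    start_t: float
    end_t: float
    posture: str
    n_steps: int = 0

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


def wavelet_bandpass(signal: np.ndarray, rate_hz: float,
                     band_hz: tuple[float, float] = STEP_BAND_HZ,
                     wavelet: str = "db4") -> np.ndarray:
    """Band-pass by keeping DWT detail levels overlapping the target band.

    Detail level L of a dyadic decomposition at rate ``fs`` covers roughly
    [fs/2^(L+1), fs/2^L] Hz; levels whose band intersects ``band_hz`` are
    retained, everything else (including the final approximation) is zeroed.
    """
    sig = np.asarray(signal, dtype=np.float64)
    lo, hi = band_hz
    max_level = int(np.ceil(np.log2(rate_hz / lo))) - 1
    max_level = min(max_level, pywt.dwt_max_level(sig.shape[0], pywt.Wavelet(wavelet)))
    if max_level < 1:
        raise ValueError("signal too short for the requested band")
    coeffs = pywt.wavedec(sig, wavelet, level=max_level, mode="symmetric")
    # coeffs = [approx, detail_max_level, ..., detail_1]
    coeffs[0] = np.zeros_like(coeffs[0])
    for idx in range(1, len(coeffs)):
        level = max_level - idx + 1
        f_hi = rate_hz / 2 ** level
        f_lo = rate_hz / 2 ** (level + 1)
        if f_hi <= lo or f_lo >= hi:
            coeffs[idx] = np.zeros_like(coeffs[idx])
    return pywt.waverec(coeffs, wavelet, mode="symmetric")[: sig.shape[0]]


def detect_steps(vertical_g: np.ndarray, rate_hz: float,
                 step_threshold_g: float = STEP_THRESHOLD_G,
                 band_hz: tuple[float, float] = STEP_BAND_HZ,
                 refractory_s: float = STEP_REFRACTORY_S) -> StepEvents:
    """Detect heel-strike peaks on the band-passed vertical axis.

    A step is a local maximum whose absolute amplitude reaches the threshold,
    with a physiological refractory spacing between successive steps.
    """
    filtered = wavelet_bandpass(vertical_g, rate_hz, band_hz)
    distance = max(1, int(round(refractory_s * rate_hz)))
    peaks, props = find_peaks(filtered, height=step_threshold_g, distance=distance)
    return StepEvents(t=peaks / rate_hz, amplitude_g=props["peak_heights"])


def walking_episodes(steps: StepEvents,
                     max_interstep_s: float = MAX_INTERSTEP_S,
                     min_steps: int = MIN_STEPS_PER_BOUT) -> list[PostureBout]:
    """Group steps into walking bouts.

    Maximal runs of at least ``min_steps`` steps whose consecutive gaps do not
    exceed ``max_interstep_s`` become walking bouts; shorter runs are
    discarded as incidental (non-walking) steps.
    """
    if steps.n_steps == 0:
        return []
    t = np.asarray(steps.t, dtype=np.float64)
    breaks = np.flatnonzero(np.diff(t) > max_interstep_s)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [t.shape[0]]])
    bouts = []
    for s, e in zip(starts, ends):
        n = int(e - s)
        if n >= min_steps:
            # pad by half a typical step period so the bout covers the strides
            pad = 0.5 * float(np.median(np.diff(t[s:e])))
            bouts.append(PostureBout(start_t=float(t[s] - pad),
                                     end_t=float(t[e - 1] + pad),
                                     posture=POSTURE_WALKING, n_steps=n))
    return bouts


def _second_average(x: np.ndarray, rate_hz: float, n_seconds: int) -> np.ndarray:
    per = int(round(rate_hz))
    usable = min(n_seconds * per, x.shape[0] - x.shape[0] % per)
    out = x[:usable].reshape(-1, per).mean(axis=1)
    if out.shape[0] < n_seconds:   # pad the trailing partial second
        out = np.concatenate([out, np.full(n_seconds - out.shape[0], out[-1])])
    return out[:n_seconds]


def _detect_transitions(frontal_1s: np.ndarray, seg_start: int, seg_end: int,
                        lean_g: float, min_gap_s: float, edge_margin_s: float) -> list[int]:
    """Second indices of postural-transition lean peaks inside an upright segment."""
    margin = int(edge_margin_s)
    lo, hi = seg_start + margin, seg_end - margin
    if hi - lo < 1:
        return []
    seg = np.abs(frontal_1s[lo:hi])
    peaks, _ = find_peaks(seg, height=lean_g, distance=max(1, int(min_gap_s)))
    # a lean must be transient: exclude sustained tilts (e.g., reclined rest)
    return [int(p + lo) for p in peaks]


def classify_posture(rec: RawRecording, walking_bouts: list[PostureBout],
                     wear_mask: WearMask | None = None,
                     lying_g_max: float = LYING_G_MAX,
                     transition_lean_g: float = TRANSITION_LEAN_G) -> np.ndarray:
    """Per-second posture codes over the recording.

    Expects a denoised recording.  Walking seconds come from the detected
    bouts; remaining wear time is lying when the 1-s-averaged vertical gravity
    magnitude is below ``lying_g_max``, otherwise upright.  Upright segments
    are split into sitting/standing by the transition state machine; segments
    with no anchor default to sitting (logged).
    Non-wear seconds are left unclassified (code 0).
    """
    n_seconds = int(np.floor(rec.duration_s))
    v = _second_average(rec.xyz[:, 0], rec.rate_hz, n_seconds)
    f = _second_average(rec.xyz[:, 1], rec.rate_hz, n_seconds)

    codes = np.full(n_seconds, CODE_SITTING, dtype=np.int8)
    lying = np.abs(v) < lying_g_max
    codes[lying] = CODE_LYING

    walking = np.zeros(n_seconds, dtype=bool)
    for bout in walking_bouts:
        s = max(0, int(np.floor(bout.start_t)))
        e = min(n_seconds, int(np.ceil(bout.end_t)))
        walking[s:e] = True
    codes[walking] = CODE_WALKING

    nonwear = np.zeros(n_seconds, dtype=bool)
    if wear_mask is not None:
        minute_of_second = np.minimum(
            ((np.arange(n_seconds) - (wear_mask.t_start[0] - rec.t[0])) // 60).astype(int),
            wear_mask.wear.shape[0] - 1)
        in_range = minute_of_second >= 0
        nonwear[in_range] = ~wear_mask.wear[minute_of_second[in_range]]

    # upright (neither lying nor walking nor non-wear) segments
    upright = ~lying & ~walking & ~nonwear
    seg_bounds = _contiguous_runs(upright)
    for s, e in seg_bounds:
        transitions = _detect_transitions(f, s, e, transition_lean_g,
                                          TRANSITION_MIN_GAP_S, TRANSITION_EDGE_MARGIN_S)
        codes[s:e] = _resolve_upright_segment(
            s, e, transitions, walking, lying, n_seconds)

    codes[nonwear] = CODE_UNCLASSIFIED
    return codes


def _contiguous_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if flags.shape[0] == 0:
        return []
    padded = np.concatenate([[False], flags, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _resolve_upright_segment(s: int, e: int, transitions: list[int],
                             walking: np.ndarray, lying: np.ndarray,
                             n_seconds: int) -> np.ndarray:
    """Sitting/standing codes for one upright segment via the state machine."""
    out = np.empty(e - s, dtype=np.int8)
    after_walk = s > 0 and walking[s - 1]
    before_walk = e < n_seconds and walking[e]
    after_lie = s > 0 and lying[s - 1]

    if after_walk:
        state = CODE_STANDING
        forward = True
    elif before_walk:
        # back-propagate: state at segment end is standing
        state = CODE_STANDING if len(transitions) % 2 == 0 else CODE_SITTING
        forward = True
    elif after_lie:
        state = CODE_SITTING
        forward = True
    else:
        logger.warning("upright segment [%d, %d) has no posture anchor; "
                       "defaulting to sitting", s, e)
        state = CODE_SITTING
        forward = True

    if forward:
        cur = state
        prev = s
        for tr in transitions:
            out[prev - s: tr - s] = cur
            cur = CODE_STANDING if cur == CODE_SITTING else CODE_SITTING
            prev = tr
        out[prev - s:] = cur
    return out


def timeline_bouts(codes: np.ndarray, walking_bouts: list[PostureBout],
                   t0: float = 0.0) -> list[PostureBout]:
    """Convert a per-second posture timeline into a bout list.

    Walking bouts keep their detected step counts; other postures get bouts
    from contiguous runs of the per-second codes.
    """
    bouts: list[PostureBout] = []
    for code, posture in CODE_TO_POSTURE.items():
        if code == CODE_WALKING:
            continue
        for s, e in _contiguous_runs(codes == code):
            bouts.append(PostureBout(start_t=t0 + s, end_t=t0 + e, posture=posture))
    # walking bouts keep sub-second boundaries and step counts
    bouts.extend(walking_bouts)
    return sorted(bouts, key=lambda b: b.start_t)


@dataclass
class PostureDaySummary:
    """Per-day posture percentages, bout statistics, and step counts."""

    day: int
    posture_pct: dict = field(default_factory=dict)      # % of classified time
    longest_bout_s: dict = field(default_factory=dict)
    median_bout_s: dict = field(default_factory=dict)
    total_steps: int = 0
    longest_step_bout: float = float("nan")
    median_step_bout: float = float("nan")

    def to_dict(self) -> dict:
        row = {"day": self.day, "total_steps": self.total_steps,
               "longest_step_bout": self.longest_step_bout,
               "median_step_bout": self.median_step_bout}
        for p in POSTURES:
            row[f"{p}_pct"] = self.posture_pct.get(p, 0.0)
            row[f"longest_{p}_s"] = self.longest_bout_s.get(p, float("nan"))
            row[f"median_{p}_s"] = self.median_bout_s.get(p, float("nan"))
        return row


def bout_statistics(bouts: list[PostureBout], start_clock_s: float = 0.0) -> list[PostureDaySummary]:
    """Per-calendar-day posture summaries.

    Each bout is assigned to the calendar day containing its midpoint (bouts
    are not clipped, so "longest unbroken" stays unbroken across midnight).
    Posture percentages use the classified time of the day as denominator, so
    they sum to 100 even on partially covered edge days; on fully covered,
    fully worn days this equals the share of 24 h.  Step-bout statistics are
    step counts; missing postures yield 0 % and missing bout statistics.
    """
    by_day: dict[int, list[PostureBout]] = {}
    for b in bouts:
        day = int((start_clock_s + 0.5 * (b.start_t + b.end_t)) // SECONDS_PER_DAY)
        by_day.setdefault(day, []).append(b)

    summaries = []
    for day in sorted(by_day):
        day_bouts = by_day[day]
        total_classified = sum(b.duration_s for b in day_bouts)
        summary = PostureDaySummary(day=day)
        for posture in POSTURES:
            durs = np.array([b.duration_s for b in day_bouts if b.posture == posture])
            if durs.size == 0:
                summary.posture_pct[posture] = 0.0
                continue
            summary.posture_pct[posture] = 100.0 * durs.sum() / total_classified
            summary.longest_bout_s[posture] = float(durs.max())
            summary.median_bout_s[posture] = float(np.median(durs))
        step_counts = np.array([b.n_steps for b in day_bouts
                                if b.posture == POSTURE_WALKING])
        if step_counts.size:
            summary.total_steps = int(step_counts.sum())
            summary.longest_step_bout = float(step_counts.max())
            summary.median_step_bout = float(np.median(step_counts))
        summaries.append(summary)
    return summaries


def bouts_to_frame(bouts: list[PostureBout]) -> pd.DataFrame:
    return pd.DataFrame([{"start": b.start_t, "end": b.end_t,
                          "posture": b.posture, "n_steps": b.n_steps}
                         for b in bouts])
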