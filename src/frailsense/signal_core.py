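"""Raw-signal preprocessing and per-epoch activity intensity.

The chest-worn sensor records tri-axial acceleration in gravity units (g) at a
nominal 50 Hz.  Activity intensity is summarized per 6-s epoch by the mean
amplitude deviation (MAD) of the acceleration-vector norm, in milligravity
(mg), and mapped to an activity level by fixed cut-points:

    sedentary            MAD < 20 mg
    light                20 mg <= MAD < 90 mg
    moderate-to-vigorous MAD >= 90 mg

Axis convention: column 0 is the vertical (cranio-caudal) axis, column 1 the
frontal (anteroposterior, positive toward the back), column 2 the lateral
(medio-lateral) axis.  Upright posture puts gravity on the vertical axis.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

G_TO_MG = 1000.0
SENSOR_RANGE_G = 16.0
DEFAULT_RATE_HZ = 50.0
DEFAULT_EPOCH_S = 6.0
DEFAULT_CUTPOINTS_MG = (20.0, 90.0)
DEFAULT_WAVELET_ORDER = 4

LEVEL_SEDENTARY = "sedentary"
LEVEL_LIGHT = "light"
LEVEL_MTV = "mtv"
LEVELS = (LEVEL_SEDENTARY, LEVEL_LIGHT, LEVEL_MTV)


@dataclass
class RawRecording:
    """Tri-axial acceleration time series for one subject.

    ``t`` holds seconds since recording start (strictly increasing), ``xyz``
    the (n, 3) acceleration in g.  ``start_clock_s`` anchors sample 0 on the
    local clock (seconds after midnight of calendar day 0) so that calendar
    days and nocturnal windows can be resolved.
    """

    t: np.ndarray
    xyz: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    subject_id: str = ""
    axis_convention: str = "vertical-frontal-lateral"
    start_clock_s: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.xyz = np.asarray(self.xyz)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if self.t.shape[0] != self.xyz.shape[0]:
            raise ValueError("t and xyz lengths differ")

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.n_samples > 1 else 0.0

    def validate(self) -> None:
        """Enforce the recording invariants; raise ``ValueError`` on breach."""
        if self.n_samples < 2:
            raise ValueError("recording must contain at least two samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite samples in recording")
        if np.max(np.abs(self.xyz)) > SENSOR_RANGE_G:
            raise ValueError(f"acceleration exceeds sensor range +-{SENSOR_RANGE_G} g")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")

    def observed_rate_hz(self) -> float:
        return (self.n_samples - 1) / self.duration_s

    @classmethod
    def from_csv(cls, path: str | Path, rate_hz: float = DEFAULT_RATE_HZ,
                 subject_id: str = "", start_clock_s: float = 0.0) -> "RawRecording":
        """Read a ``t,x,y,z`` CSV (seconds, g); ``.gz`` files are accepted."""
        path = Path(path)
        if path.suffix == ".gz":
            with gzip.open(path, "rt") as fh:
                df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
        missing = {"t", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ValueError(f"CSV missing columns: {sorted(missing)}")
        return cls(
            t=df["t"].to_numpy(dtype=np.float64),
            xyz=df[["x", "y", "z"]].to_numpy(dtype=np.float64),
            rate_hz=rate_hz,
            subject_id=subject_id or path.stem,
            start_clock_s=start_clock_s,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"t": self.t, "x": self.xyz[:, 0],
                           "y": self.xyz[:, 1], "z": self.xyz[:, 2]})
        df.to_csv(path, index=False)


def resample_to_nominal(rec: RawRecording, tolerance: float = 0.01) -> RawRecording:
    """Return the recording on the nominal sample grid.

    If the observed rate is within ``tolerance`` (relative) of ``rec.rate_hz``
    the samples are used as-is; otherwise the signal is linearly interpolated
    onto the nominal grid so that epoch sample counts stay meaningful.
    """
    observed = rec.observed_rate_hz()
    if abs(observed - rec.rate_hz) <= tolerance * rec.rate_hz:
        return rec
    n_out = int(np.floor(rec.duration_s * rec.rate_hz)) + 1
    t_new = rec.t[0] + np.arange(n_out) / rec.rate_hz
    xyz_new = np.column_stack(
        [np.interp(t_new, rec.t, rec.xyz[:, k]) for k in range(3)]
    )
    return replace(rec, t=t_new, xyz=xyz_new)


def wavelet_denoise(rec: RawRecording, wavelet_order: int = DEFAULT_WAVELET_ORDER) -> RawRecording:
    """Low-pass each axis below half the Nyquist rate with a Daubechies DWT.

    At 50 Hz a single-level discrete wavelet decomposition splits the band at
    exactly 12.5 Hz, so removing high-frequency content that cannot originate
    from body movement amounts to zeroing the level-1 detail coefficients and
    reconstructing.  The DC (gravity) component is preserved and the output
    has the input length.
    """
    wavelet = pywt.Wavelet(f"db{wavelet_order}")
    n = rec.n_samples
    if n < wavelet.dec_len:
        raise ValueError(
            f"recording of {n} samples is shorter than the db{wavelet_order} "
            f"filter support ({wavelet.dec_len} samples)"
        )
    out = np.empty_like(rec.xyz, dtype=np.float64)
    for k in range(3):
        approx, _detail = pywt.dwt(rec.xyz[:, k], wavelet, mode="symmetric")
        recon = pywt.idwt(approx, None, wavelet, mode="symmetric")
        out[:, k] = recon[:n]
    return replace(rec, xyz=out)


def norm_acceleration(x, y, z):
    """Acceleration-vector norm sqrt(x^2+y^2+z^2), converted from g to mg.

    Works elementwise on arrays; rejects non-finite input.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValueError("non-finite acceleration sample")
    return G_TO_MG * np.sqrt(x * x + y * y + z * z)


def compute_mad(r_values: np.ndarray) -> np.ndarray:
    """Mean amplitude deviation of norm accelerations, per epoch.

    ``r_values`` is (n_epochs, n_per_epoch) in mg (a single epoch may be
    passed as a 1-D array).  MAD = (1/N) * sum_i |r_i - Rave| where Rave is
    the arithmetic epoch mean of the r_i.
    """
    r = np.asarray(r_values, dtype=np.float64)
    squeeze = r.ndim == 1
    if squeeze:
        r = r[None, :]
    r_ave = r.mean(axis=1, keepdims=True)
    mad = np.abs(r - r_ave).mean(axis=1)
    return float(mad[0]) if squeeze else mad


def classify_activity_level(mad_mg, cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS_MG):
    """Map MAD (mg) to an activity level with the printed boundary semantics.

    Strictly below the lower cut-point is sedentary, at or above the upper
    cut-point is moderate-to-vigorous, everything in between is light.
    """
    mad = np.asarray(mad_mg, dtype=np.float64)
    if np.any(mad < 0):
        raise ValueError("MAD must be non-negative")
    lo, hi = cutpoints
    levels = np.where(mad < lo, LEVEL_SEDENTARY,
                      np.where(mad < hi, LEVEL_LIGHT, LEVEL_MTV))
    return str(levels[()]) if levels.ndim == 0 else levels.astype(object)


@dataclass
class EpochSeries:
    """Non-overlapping, contiguous 6-s epochs tiling the recording.

    A trailing partial epoch (fewer than ``epoch_s`` seconds of samples) is
    discarded, never zero-filled.
    """

    start_t: np.ndarray
    r_ave_mg: np.ndarray
    mad_mg: np.ndarray
    level: np.ndarray
    epoch_s: float = DEFAULT_EPOCH_S
    start_clock_s: float = 0.0
    subject_id: str = ""

    @property
    def n_epochs(self) -> int:
        return int(self.start_t.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch_start": self.start_t,
                             "mad_mg": self.mad_mg, "level": self.level})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_epochs(rec: RawRecording, epoch_s: float = DEFAULT_EPOCH_S,
                cutpoints: tuple[float, float] = DEFAULT_CUTPOINTS_MG) -> EpochSeries:
    """Tile the recording into epochs and compute Rave, MAD, and level."""
    n_per = int(round(epoch_s * rec.rate_hz))
    if n_per < 1:
        raise ValueError("epoch shorter than one sample period")
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    r = norm_acceleration(rec.xyz[: n_epochs * n_per, 0],
                          rec.xyz[: n_epochs * n_per, 1],
                          rec.xyz[: n_epochs * n_per, 2]).reshape(n_epochs, n_per)
    r_ave = r.mean(axis=1)
    mad = compute_mad(r)
    start_t = rec.t[0] + np.arange(n_epochs) * epoch_s
    return EpochSeries(
        start_t=start_t,
        r_ave_mg=r_ave,
        mad_mg=mad,
        level=classify_activity_level(mad, cutpoints),
        epoch_s=epoch_s,
        start_clock_s=rec.start_clock_s,
        subject_id=rec.subject_id,
    )
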