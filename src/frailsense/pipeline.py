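"""End-to-end subject processing: raw recording -> feature row.

Chains the processing stages in their canonical order: wavelet denoising,
6-s MAD epochs, minute aggregation, non-wear detection and valid days, step
and walking-bout detection, posture classification, in-bed detection with
minute-wise sleep/wake scoring, and finally the per-subject averaged feature
set.  Subjects failing the two-valid-day requirement raise
:class:`~frailsense.wear_validity.SubjectExcluded`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from . import posture_step as ps
from . import signal_core as sc
from . import sleep as slp
from . import wear_validity as wv


@dataclass
class SubjectResult:
    """All per-subject artifacts produced by one pipeline run."""

    subject_id: str
    epochs: sc.EpochSeries
    minutes: wv.MinuteSeries
    wear_mask: wv.WearMask
    day_table: pd.DataFrame
    steps: ps.StepEvents
    walking_bouts: list
    posture_codes: np.ndarray
    posture_daily: list
    nights: list
    features: feat.SubjectFeatures


def process_recording(rec: sc.RawRecording,
                      required_valid_days: int = wv.REQUIRED_VALID_DAYS,
                      sleep_weights=slp.DEFAULT_SLEEP_WEIGHTS) -> SubjectResult:
    """Run the full chain on one recording.

    Raises :class:`~frailsense.wear_validity.SubjectExcluded` when the
    recording does not meet the valid-day requirement.
    """
    rec.validate()
    rec = sc.resample_to_nominal(rec)
    denoised = sc.wavelet_denoise(rec)

    epochs = sc.make_epochs(denoised)
    minutes = wv.minute_mad(epochs)
    mask = wv.detect_nonwear(minutes)
    day_table = wv.valid_days(mask)

    reason = wv.exclusion_reason(mask, required_valid_days=required_valid_days)
    if reason is not None:
        raise wv.SubjectExcluded(reason, rec.subject_id)

    steps = ps.detect_steps(denoised.xyz[:, 0], denoised.rate_hz)
    walking = ps.walking_episodes(steps)
    codes = ps.classify_posture(denoised, walking, wear_mask=mask)
    bouts = ps.timeline_bouts(codes, walking)
    posture_daily = ps.bout_statistics(bouts, start_clock_s=rec.start_clock_s)

    tib = slp.detect_time_in_bed(codes, rec.start_clock_s)
    nights = [slp.analyze_night(night, t0, t1, minutes, denoised, codes,
                                weights=sleep_weights)
              for night, t0, t1 in tib]

    behavior_daily = feat.behavior_features(epochs, mask, tib)
    subject_features = feat.assemble_subject(
        rec.subject_id, behavior_daily, posture_daily, nights, day_table,
        required_valid_days=required_valid_days)
    return SubjectResult(subject_id=rec.subject_id, epochs=epochs,
                         minutes=minutes, wear_mask=mask, day_table=day_table,
                         steps=steps, walking_bouts=walking,
                         posture_codes=codes, posture_daily=posture_daily,
                         nights=nights, features=subject_features)


def process_cohort(recordings) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process many recordings; returns (feature table, exclusion log)."""
    rows, excluded = [], []
    for rec in recordings:
        try:
            rows.append(process_recording(rec).features.to_row())
        except wv.SubjectExcluded as exc:
            excluded.append({"subject_id": rec.subject_id, "reason": exc.reason})
    return pd.DataFrame(rows), pd.DataFrame(excluded, columns=["subject_id", "reason"])
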