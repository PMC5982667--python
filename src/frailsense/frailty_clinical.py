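"""Fried frailty phenotype scoring and clinical covariates.

The phenotype counts five binary criteria — shrinking (unintentional loss of
more than 10 lb in the prior year), exhaustion, inactivity, slowness
(prolonged 15-ft walk time), and weakness (low grip strength).  Performance
criteria score a point when the participant falls in the cohort's worst
quartile.  The criterion sum maps to a status:

    SUM = 0       non-frail (robust)
    1 <= SUM <= 2 pre-frail
    SUM >= 3      frail
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CRITERIA = ("shrinking", "exhaustion", "inactivity", "slowness", "weakness")

STATUS_NON_FRAIL = "non_frail"
STATUS_PRE_FRAIL = "pre_frail"
STATUS_FRAIL = "frail"
STATUSES = (STATUS_NON_FRAIL, STATUS_PRE_FRAIL, STATUS_FRAIL)


def fried_status(flags: dict | pd.Series) -> str | None:
    """Status from the five criterion flags; ``None`` if any flag is missing."""
    values = []
    for name in CRITERIA:
        v = flags.get(name) if isinstance(flags, dict) else flags.get(name, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        values.append(bool(v))
    total = sum(values)
    if total == 0:
        return STATUS_NON_FRAIL
    if total <= 2:
        return STATUS_PRE_FRAIL
    return STATUS_FRAIL


def fried_status_frame(flags: pd.DataFrame) -> pd.Series:
    """Vectorized status for a criteria table (NaN row -> missing status)."""
    return flags.apply(lambda row: fried_status(row), axis=1)


def quartile_flag(values, higher_is_worse: bool = False) -> np.ndarray:
    """Flag the worst quartile of a cohort-level performance measure.

    The quartile boundary uses linear-interpolation quantiles and is
    inclusive: a value exactly on the boundary is flagged.  When every value
    is identical there is no strict worst quartile and nothing is flagged.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.shape[0] < 4:
        raise ValueError("quartile flags need at least 4 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite measurements")
    if np.min(x) == np.max(x):
        return np.zeros(x.shape[0], dtype=bool)
    if higher_is_worse:
        return x >= np.quantile(x, 0.75, method="linear")
    return x <= np.quantile(x, 0.25, method="linear")


# plausibility ranges for clinical covariates
CLINICAL_RANGES = {"age": (60.0, 110.0), "bmi": (12.0, 60.0),
                   "cesd": (0.0, 60.0), "fes_i": (7.0, 64.0)}


@dataclass
class ClinicalRecord:
    """One subject's clinical covariates."""

    subject_id: str
    age: float
    sex: str
    bmi: float
    cesd: float = np.nan
    fes_i: float = np.nan
    fall_history: str = ""
    n_prescribed: float = np.nan
    n_comorbidities: float = np.nan

    def validate(self) -> None:
        for key in ("age", "bmi"):
            lo, hi = CLINICAL_RANGES[key]
            v = getattr(self, key)
            if not (lo <= v <= hi):
                raise ValueError(f"{key}={v} outside plausible range [{lo}, {hi}]")


def attach_status(clinical: pd.DataFrame, criteria: pd.DataFrame) -> pd.DataFrame:
    """Append the derived ``status`` column to a clinical table."""
    out = clinical.copy()
    out["status"] = fried_status_frame(criteria[list(CRITERIA)]).to_numpy()
    return out
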