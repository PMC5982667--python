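"""Minute aggregation, the non-wear rule, valid days, and averaging."""

import numpy as np
import pandas as pd
import pytest

from frailsense import signal_core as sc
from frailsense import wear_validity as wv


def minutes_from(mad_values, start_clock_s=0.0):
    mad = np.asarray(mad_values, dtype=np.float64)
    return wv.MinuteSeries(t_start=60.0 * np.arange(mad.shape[0]), mad_mg=mad,
                           start_clock_s=start_clock_s)


def nonwear_scan_oracle(mad, gap=90, max_int=2, int_max=20.0, eps=wv.ZERO_MAD_EPS):
    """Independent minute-by-minute transcription of the non-wear rule."""
    n = len(mad)
    flags = [True] * n
    i = 0
    while i < n:
        if mad[i] > eps:
            i += 1
            continue
        members = [i]
        absorbed = 0
        j = i + 1
        pending = []
        while j < n:
            if mad[j] <= eps:
                members.extend(pending + [j])
                absorbed += len(pending)
                pending = []
                j += 1
            elif mad[j] < int_max and absorbed + len(pending) < max_int:
                pending.append(j)
                j += 1
            else:
                break
        # pending interruptions at the tail are not part of the run
        if len(members) >= gap:
            for m in members:
                flags[m] = False
        i = members[-1] + 1
    return np.array(flags)


class TestMinuteMad:
    def test_zero_epochs_give_zero_minute(self):
        epochs = sc.EpochSeries(start_t=6.0 * np.arange(10),
                                r_ave_mg=np.full(10, 1000.0),
                                mad_mg=np.zeros(10),
                                level=np.array(["sedentary"] * 10, dtype=object))
        out = wv.minute_mad(epochs)
        assert out.n_minutes == 1 and out.mad_mg[0] == 0.0

    def test_minute_is_arithmetic_mean_of_epochs(self):
        mad = np.array([0.0] * 9 + [30.0])
        epochs = sc.EpochSeries(start_t=6.0 * np.arange(10),
                                r_ave_mg=np.full(10, 1000.0), mad_mg=mad,
                                level=np.array(["sedentary"] * 10, dtype=object))
        assert wv.minute_mad(epochs).mad_mg[0] == pytest.approx(3.0)

    def test_matches_bruteforce_mean_and_drops_partial_minutes(self, rng):
        n_epochs = 37                       # 3 full minutes + 7 trailing epochs
        mad = rng.uniform(0, 100, n_epochs)
        epochs = sc.EpochSeries(start_t=6.0 * np.arange(n_epochs),
                                r_ave_mg=np.full(n_epochs, 1000.0), mad_mg=mad,
                                level=np.array(["light"] * n_epochs, dtype=object))
        out = wv.minute_mad(epochs)
        assert out.n_minutes == 3
        for m in range(3):
            assert out.mad_mg[m] == pytest.approx(mad[10 * m:10 * (m + 1)].mean())


class TestDetectNonwear:
    def _wear(self, mad):
        return wv.detect_nonwear(minutes_from(mad)).wear

    def test_90_minute_gap_boundary(self):
        for gap, flagged in ((89, False), (90, True)):
            mad = np.concatenate([np.full(30, 50.0), np.zeros(gap), np.full(30, 50.0)])
            wear = self._wear(mad)
            assert (~wear).sum() == (gap if flagged else 0)

    def test_two_interrupted_minutes_absorbed(self):
        mad = np.concatenate([np.full(10, 50.0), np.zeros(40), [10.0],
                              np.zeros(30), [10.0], np.zeros(23), np.full(10, 50.0)])
        wear = self._wear(mad)
        assert (~wear).sum() == 95          # the whole 95-min block is non-wear

    def test_third_interruption_splits_run_into_wear(self):
        # 95 zero minutes cut by 3 interruptions into ~24-min sub-runs: even
        # after absorbing 2 interruptions no run reaches 90 min
        mad = np.concatenate([np.full(5, 50.0)] + [np.zeros(24), [10.0]] * 3
                             + [np.zeros(23), np.full(5, 50.0)])
        assert self._wear(mad).all()

    def test_interruption_above_20_breaks_run(self):
        mad = np.concatenate([np.zeros(60), [25.0], np.zeros(60)])
        assert self._wear(mad).all()        # both halves < 90 min

    def test_run_cannot_end_on_interruption(self):
        # interruption adjacent to the active tail is not absorbed
        mad = np.concatenate([np.zeros(90), [10.0], np.full(20, 50.0)])
        wear = self._wear(mad)
        assert (~wear).sum() == 90 and wear[90]

    def test_matches_independent_scan_oracle(self, rng):
        for _ in range(30):
            mad = rng.choice([0.0, 0.0, 10.0, 50.0], size=400,
                             p=[0.45, 0.25, 0.1, 0.2])
            assert np.array_equal(self._wear(mad),
                                  nonwear_scan_oracle(mad))

    def test_idempotent_on_masked_series(self, rng):
        mad = rng.choice([0.0, 10.0, 50.0], size=500, p=[0.6, 0.1, 0.3])
        first = wv.detect_nonwear(minutes_from(mad))
        masked = mad.copy()
        masked[~first.wear] = 0.0           # non-wear minutes carry no MAD
        second = wv.detect_nonwear(minutes_from(masked))
        assert np.array_equal(first.wear, second.wear)

    def test_extending_a_gap_never_unflags_it(self):
        for extra in (0, 10, 60):
            mad = np.concatenate([np.full(20, 50.0), np.zeros(90 + extra),
                                  np.full(20, 50.0)])
            assert (~self._wear(mad)).sum() == 90 + extra


class TestValidDays:
    def _mask(self, wear_minutes, day_minutes=1440):
        wear = np.zeros(day_minutes, dtype=bool)
        wear[:wear_minutes] = True
        return wv.WearMask(t_start=60.0 * np.arange(day_minutes), wear=wear)

    @pytest.mark.parametrize("wear_min, valid", [(480, True), (479, False),
                                                 (1440, True), (0, False)])
    def test_eight_hour_boundary(self, wear_min, valid):
        table = wv.valid_days(self._mask(wear_min))
        assert bool(table["valid"].iloc[0]) is valid

    def test_inserted_gap_reduces_wear_by_gap_length(self):
        mad = np.full(1440, 50.0)
        base = wv.valid_days(wv.detect_nonwear(minutes_from(mad)))
        gapped = mad.copy()
        gapped[300:420] = 0.0
        after = wv.valid_days(wv.detect_nonwear(minutes_from(gapped)))
        assert base["wear_min"].iloc[0] - after["wear_min"].iloc[0] == 120


class TestAveraging:
    def test_mean_over_valid_days(self):
        table = pd.DataFrame({"day": [0, 1], "wear_min": [600, 700],
                              "valid": [True, True]})
        assert wv.average_over_valid_days({0: 10.0, 1: 14.0}, table) == 12.0

    def test_identical_days_average_to_daily_value(self):
        table = pd.DataFrame({"day": [0, 1], "wear_min": [600, 700],
                              "valid": [True, True]})
        assert wv.average_over_valid_days({0: 7.5, 1: 7.5}, table) == 7.5

    def test_single_valid_day_raises_exclusion(self):
        table = pd.DataFrame({"day": [0, 1], "wear_min": [600, 100],
                              "valid": [True, False]})
        with pytest.raises(wv.SubjectExcluded) as err:
            wv.average_over_valid_days({0: 10.0}, table)
        assert err.value.reason == wv.EXCLUDE_INSUFFICIENT_DAYS


class TestExclusionReason:
    def test_reason_categories(self):
        def mask_for(day_wear):
            wear = np.concatenate([
                np.concatenate([np.ones(m, bool), np.zeros(1440 - m, bool)])
                for m in day_wear])
            return wv.WearMask(t_start=60.0 * np.arange(wear.shape[0]), wear=wear)

        assert wv.exclusion_reason(mask_for([600, 700])) is None
        assert wv.exclusion_reason(mask_for([0, 0])) == wv.EXCLUDE_NO_WEAR
        assert wv.exclusion_reason(mask_for([200, 300])) == wv.EXCLUDE_LOW_WEAR
        assert wv.exclusion_reason(mask_for([600, 300])) == wv.EXCLUDE_INSUFFICIENT_DAYS
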