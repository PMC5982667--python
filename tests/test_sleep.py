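"""In-bed detection, sleep/wake scoring, sleep parameters, lying positions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frailsense import sleep as slp
from frailsense import wear_validity as wv
from frailsense.posture_step import CODE_LYING, CODE_SITTING


def timeline_with_lying(blocks, n_seconds=2 * 86400):
    """Sitting timeline with lying blocks given as (start_s, end_s)."""
    codes = np.full(n_seconds, CODE_SITTING, dtype=np.int8)
    for s, e in blocks:
        codes[int(s):int(e)] = CODE_LYING
    return codes


class TestDetectTimeInBed:
    # recording starts at 20:00 -> 23:00 is t = 10800 s
    START = 20.0 * 3600

    def test_programmed_block_recovered_exactly(self):
        codes = timeline_with_lying([(10800, 10800 + 480 * 60)])
        nights = slp.detect_time_in_bed(codes, self.START)
        assert len(nights) == 1
        _, t0, t1 = nights[0]
        assert (t1 - t0) / 60 == 480

    def test_no_nocturnal_lying_emits_no_night(self):
        codes = timeline_with_lying([])
        assert slp.detect_time_in_bed(codes, self.START) == []

    def test_longest_of_two_blocks_wins(self):
        # blocks far enough apart that the dominance rule cannot merge them
        short = (10800, 10800 + 120 * 60)
        long = (10800 + 300 * 60, 10800 + 300 * 60 + 400 * 60)
        nights = slp.detect_time_in_bed(timeline_with_lying([short, long]),
                                        self.START)
        assert len(nights) == 1
        _, t0, t1 = nights[0]
        assert (t0, t1) == long

    def test_brief_interruptions_absorbed_by_dominance_rule(self):
        # 480-min block with two 10-min upright interruptions still one TiB
        s = 10800
        blocks = [(s, s + 150 * 60), (s + 160 * 60, s + 300 * 60),
                  (s + 310 * 60, s + 480 * 60)]
        nights = slp.detect_time_in_bed(timeline_with_lying(blocks), self.START)
        assert len(nights) == 1
        _, t0, t1 = nights[0]
        assert (t1 - t0) / 60 == 480


class TestClassifySleepWake:
    def _features(self, mad):
        mad = np.asarray(mad, dtype=float)
        sd = np.zeros_like(mad)
        chg = np.zeros_like(mad)
        return np.column_stack([mad, sd, chg])

    def test_quiet_night_is_all_sleep(self):
        wake = slp.classify_sleep_wake(self._features(np.full(480, 2.0)))
        assert not wake.any()

    def test_sustained_high_mad_block_is_wake(self):
        mad = np.full(480, 2.0)
        mad[200:230] = 50.0
        wake = slp.classify_sleep_wake(self._features(mad))
        assert wake[200:230].all()
        assert wake.sum() == 30

    def test_feature_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            slp.classify_sleep_wake(np.zeros((10, 2)))


class TestSleepParameters:
    @staticmethod
    def _night(wake):
        wake = np.asarray(wake, dtype=bool)
        return slp.SleepNight(night=0, tib_start=0.0, tib_end=60.0 * wake.shape[0],
                              wake=wake, position=np.array(["supine"] * wake.shape[0],
                                                           dtype=object))

    def test_printed_definition_arithmetic(self):
        # TiB 480, SOL 20, one 60-min interior wake, 10-min terminal wake
        wake = np.zeros(480, dtype=bool)
        wake[:20] = True
        wake[200:260] = True
        wake[470:] = True
        night = slp.sleep_parameters(self._night(wake))
        assert night.sol_min == 20
        assert night.tst_min == 390
        assert night.waso_min == 60
        assert night.se_pct == pytest.approx(100 * 390 / 450)

    def test_all_sleep_night(self):
        night = slp.sleep_parameters(self._night(np.zeros(400, dtype=bool)))
        assert (night.sol_min, night.waso_min, night.se_pct) == (0, 0, 100.0)
        assert night.tst_min == 400

    def test_no_sleep_night_has_undefined_efficiency(self):
        night = slp.sleep_parameters(self._night(np.ones(300, dtype=bool)))
        assert night.tst_min == 0 and night.sol_min == 300
        assert np.isnan(night.se_pct)

    @given(st.lists(st.booleans(), min_size=1, max_size=600))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_accounting_identity_on_arbitrary_labelings(self, labels):
        wake = np.array(labels, dtype=bool)
        night = slp.sleep_parameters(self._night(wake))
        sleep_idx = np.flatnonzero(~wake)
        terminal = (wake.shape[0] - 1 - sleep_idx[-1]) if sleep_idx.size else 0.0
        assert night.sol_min + night.tst_min + night.waso_min + terminal \
            == night.tib_min


class TestLyingPositions:
    def test_position_shares_sum_to_100_of_lying_minutes(self):
        pos = np.array(["supine"] * 5 + ["prone"] * 3 + ["left"] * 2, dtype=object)
        s, p, d = slp.position_percentages(pos)
        assert s + p + d == pytest.approx(100.0)

    def test_generated_night_recovers_programmed_shares(self, default_schedule,
                                                        default_result):
        truth = default_schedule.nights()
        for night, t in zip(default_result.nights, truth):
            assert night.supine_pct == pytest.approx(t["supine_pct"], abs=2.0)
            assert night.prone_pct == pytest.approx(t["prone_pct"], abs=2.0)
            assert night.sides_pct == pytest.approx(t["sides_pct"], abs=2.0)


class TestEndToEndNights:
    def test_sleep_parameters_recovered_within_5_minutes(self, default_schedule,
                                                         default_result):
        truth = default_schedule.nights()
        assert len(default_result.nights) == len(truth) == 2
        for night, t in zip(default_result.nights, truth):
            assert night.tib_min == pytest.approx(t["tib_min"], abs=5)
            assert night.sol_min == pytest.approx(t["sol_min"], abs=5)
            assert night.tst_min == pytest.approx(t["tst_min"], abs=5)
            assert night.waso_min == pytest.approx(t["waso_min"], abs=5)

    def test_minute_level_sleep_wake_accuracy(self, default_schedule,
                                              default_result):
        """Programmed wake structure: SOL + interior WASO + terminal wake."""
        p = default_schedule.profile
        for night in default_result.nights:
            programmed_wake = p.sol_min + p.waso_min + p.terminal_wake_min
            accuracy = 1 - abs(night.wake.sum() - programmed_wake) / night.tib_min
            assert accuracy >= 0.90

    def test_tst_decreases_with_programmed_nocturnal_wake(self):
        """Monotonicity sweep at label level via the parameter identities."""
        for waso in (0, 60, 120):
            wake = np.zeros(480, dtype=bool)
            wake[:20] = True
            wake[200:200 + waso] = True
            night = slp.sleep_parameters(
                slp.SleepNight(night=0, tib_start=0, tib_end=480 * 60, wake=wake,
                               position=np.array(["supine"] * 480, dtype=object)))
            assert night.tst_min == 480 - 20 - waso
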