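"""Mid-swing/IC/FC detection and seven-event sequence assembly."""

import numpy as np
import pytest

from imugait.core import SIDES
from imugait.events import (
    GaitSequence,
    PeakCriteria,
    SequenceError,
    SideEvents,
    assemble_sequence,
    detect_ic_fc,
    detect_midswing,
    detect_trial_events,
    side_events,
)

FS = 148.0


def gauss(n, center, sigma, amp):
    return amp * np.exp(-0.5 * ((np.arange(n) - center) / sigma) ** 2)


class TestDetectMidswing:
    def test_single_pulse_detected_at_apex(self):
        # brute-force oracle: the apex is the global argmax
        sig = gauss(600, 300, 8, 250.0)
        peaks = detect_midswing(sig)
        assert list(peaks) == [int(np.argmax(sig))] == [300]

    def test_pulse_below_height_threshold_ignored(self):
        assert len(detect_midswing(gauss(600, 300, 8, 80.0))) == 0

    def test_threshold_is_configurable_down_to_50(self):
        sig = gauss(600, 300, 8, 80.0)
        got = detect_midswing(sig, PeakCriteria(ms_min_height=50.0))
        assert list(got) == [300]

    def test_close_pair_keeps_the_higher_peak(self):
        # exhaustive check of the distance-pruning rule
        sig = gauss(600, 300, 4, 250.0) + gauss(600, 320, 4, 260.0)
        got = detect_midswing(sig)
        assert len(got) == 1 and abs(got[0] - 320) <= 1

    def test_close_equal_pair_keeps_the_earlier(self):
        sig = np.zeros(600)
        sig[[300, 320]] = 250.0  # two identical spikes 20 < 30 apart
        got = detect_midswing(sig)
        assert list(got) == [300]

    def test_far_pair_both_kept_ascending(self):
        sig = gauss(600, 200, 8, 250.0) + gauss(600, 400, 8, 220.0)
        got = detect_midswing(sig)
        assert list(got) == [200, 400]

    def test_no_qualifying_peak_returns_empty_not_fallback(self):
        assert detect_midswing(np.zeros(600)).size == 0

    def test_deterministic(self, rng):
        sig = rng.normal(0, 30, 2000) + gauss(2000, 1000, 8, 300.0)
        a = detect_midswing(sig)
        b = detect_midswing(sig.copy())
        np.testing.assert_array_equal(a, b)


class TestDetectIcFc:
    def _stride_signal(self):
        # FC trough at 250, mid-swing at 300, IC trough at 350
        sig = (
            gauss(700, 300, 8, 250.0)
            + gauss(700, 250, 4, -80.0)
            + gauss(700, 350, 4, -120.0)
            + gauss(700, 120, 4, -90.0)  # previous stride's IC, farther away
        )
        return sig

    def test_nearest_flanking_minima_selected(self):
        sig = self._stride_signal()
        ms = detect_midswing(sig)
        pairs = detect_ic_fc(sig, ms)
        assert len(pairs) == 1 and pairs[0] is not None
        fc, ic = pairs[0]
        assert abs(fc - 250) <= 1 and abs(ic - 350) <= 1

    def test_shallow_trough_not_selected(self):
        # a -20 deg/s dip is below the 30 deg/s depth criterion
        sig = gauss(700, 300, 8, 250.0) + gauss(700, 250, 4, -20.0) + gauss(700, 350, 4, -120.0)
        pairs = detect_ic_fc(sig, detect_midswing(sig))
        assert pairs == [None]  # no qualifying FC before the mid-swing

    def test_truncation_at_apex_invalidates_last_cycle_only(self):
        sig = self._stride_signal()
        two = np.concatenate([sig[:400], sig])  # second stride cut right after MS
        two = two[: 400 + 331]
        ms = detect_midswing(two)
        pairs = detect_ic_fc(two, ms)
        assert len(pairs) == 2
        assert pairs[0] is not None and pairs[1] is None

    def test_zero_noise_trial_matches_ground_truth(self, quiet_filtered):
        filtered, truth = quiet_filtered
        for side in SIDES:
            ev = side_events(
                filtered.channel(f"shank_{side}", "gyr", "x"), side, filtered.fs
            )
            for detected, truth_set in ((ev.ic, truth.ic[side][1:]), (ev.fc, truth.fc[side])):
                assert len(detected) == len(truth_set)
                err = np.abs(np.asarray(detected) - np.asarray(truth_set))
                assert err.max() <= 2

    def test_left_mirrored_axis_is_auto_oriented(self, quiet_filtered):
        filtered, truth = quiet_filtered
        raw = filtered.channel("shank_L", "gyr", "x")
        assert abs(raw.min()) > abs(raw.max())  # mirrored by construction
        ev = side_events(raw, "L", filtered.fs)
        assert len(ev.ms) == len(truth.ms["L"])


def _mk_side(side, ics, fcs, fs=FS):
    return SideEvents(
        side=side, fs=fs,
        ms=np.array([], dtype=int),
        ic=np.array(ics, dtype=int),
        fc=np.array(fcs, dtype=int),
    )


class TestAssembleSequence:
    def test_simulator_events_form_seven_event_two_stride_cycle(self, quiet_side_events):
        seq = assemble_sequence(quiet_side_events["L"], quiet_side_events["R"])
        assert len(seq.events) == 7
        got = [(e.side, e.kind) for e in seq.events]
        assert got == [
            ("R", "IC"), ("L", "FC"), ("L", "IC"), ("R", "FC"),
            ("R", "IC"), ("L", "FC"), ("L", "IC"),
        ]
        # exactly one stride per side
        for side in SIDES:
            lo, hi = seq.stride_bounds(side)
            assert hi > lo

    def test_event_times_strictly_increase_and_flank_midswing(self, quiet_side_events):
        seq = assemble_sequence(quiet_side_events["L"], quiet_side_events["R"])
        times = [e.time for e in seq.events]
        assert all(b > a for a, b in zip(times, times[1:]))
        for side in SIDES:
            lo, hi = seq.stride_bounds(side)
            ms_in = [m for m in quiet_side_events[side].ms if lo < m < hi]
            assert len(ms_in) == 1
            fc = seq.fc(side, 0 if side == seq.start_side else 1).index
            assert fc < ms_in[0] < hi

    def test_start_side_configurable(self, quiet_side_events):
        seq = assemble_sequence(quiet_side_events["L"], quiet_side_events["R"], start_side="L")
        assert seq.events[0].side == "L" and seq.events[0].kind == "IC"

    def test_swapped_side_labels_rejected(self, quiet_side_events):
        with pytest.raises(ValueError, match="labelled"):
            assemble_sequence(quiet_side_events["R"], quiet_side_events["L"])

    def test_missing_contralateral_fc_is_validation_error(self):
        right = _mk_side("R", [100, 278, 456], [210, 388])
        left = _mk_side("L", [189, 367], [120])  # only one left FC
        with pytest.raises(SequenceError):
            assemble_sequence(left, right)

    def test_two_same_side_ics_without_contralateral_between_rejected(self):
        right = _mk_side("R", [100, 278, 456], [210, 388])
        left = _mk_side("L", [380, 558], [121, 299])  # left ICs arrive too late
        with pytest.raises(SequenceError, match="pattern"):
            assemble_sequence(left, right)

    def test_fewer_than_two_ics_per_side_rejected(self):
        right = _mk_side("R", [100], [210])
        left = _mk_side("L", [189, 367], [121, 299])
        with pytest.raises(SequenceError, match=">= 2"):
            assemble_sequence(left, right)

    def test_sequence_pattern_validated_on_construction(self, quiet_side_events):
        seq = assemble_sequence(quiet_side_events["L"], quiet_side_events["R"])
        bad = [seq.events[0]] * 7
        with pytest.raises(SequenceError):
            GaitSequence(bad, FS)

    def test_detection_is_deterministic(self, quiet_filtered):
        filtered, _ = quiet_filtered
        a = detect_trial_events(filtered)
        b = detect_trial_events(filtered)
        for side in SIDES:
            np.testing.assert_array_equal(a[side].ic, b[side].ic)
            np.testing.assert_array_equal(a[side].fc, b[side].fc)
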