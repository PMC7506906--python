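import numpy as np
import pytest

from itug.errors import BaselineError, NoActivityError, SegmentationError
from itug.io_device import ImuRecording
from itug.segmentation import (
    SegmentationConfig,
    detect_transitions,
    detect_turns,
    segment_trial,
    split_repetitions,
)
from itug.synthetic import simulate_session, simulate_trial


def _quiet_rec(duration=20.0, fs=100.0):
    n = int(duration * fs)
    t = np.arange(n) / fs
    return ImuRecording(t, np.zeros((n, 3)), np.zeros((n, 3)), nominal_rate=fs)


def _pulse_rec(pulses, duration=20.0, fs=100.0):
    """Recording with raised-cosine yaw pulses [(t0, T, peak), ...]."""
    rec = _quiet_rec(duration, fs)
    for t0, T, peak in pulses:
        tau = (rec.t - t0) / T
        m = (tau >= 0) & (tau <= 1)
        rec.gyro[m, 2] += peak / 2 * (1 - np.cos(2 * np.pi * tau[m]))
    return rec


class TestSplitRepetitions:
    def test_session_splits_into_five_reps_containing_truth(self, profiles):
        rec, gts = simulate_session(profiles[0], seed=8)
        reps = split_repetitions(rec)
        assert len(reps) == 5
        for rep, gt in zip(reps, gts):
            assert rep.t[0] <= gt.boundaries["stw_start"]
            assert rep.t[-1] >= gt.boundaries["sit_end"]

    def test_constant_recording_has_no_activity(self):
        with pytest.raises(NoActivityError):
            split_repetitions(_quiet_rec())

    def test_single_trial_gives_one_repetition(self, trial):
        rec, _ = trial
        assert len(split_repetitions(rec)) == 1


class TestDetectTurns:
    def test_zero_signal_gives_empty_list(self):
        assert detect_turns(_quiet_rec()) == []

    def test_single_180_degree_pulse_recovered(self):
        rec = _pulse_rec([(8.0, 2.0, 180.0)])
        turns = detect_turns(rec)
        assert len(turns) == 1
        tr = turns[0]
        # boundary convention: outward extension stops at 10% of the peak,
        # which for a raised cosine lies 0.1024*T inside the pulse support
        off = 0.10243 * 2.0
        assert tr.start == pytest.approx(8.0 + off, abs=0.10)
        assert tr.end == pytest.approx(10.0 - off, abs=0.10)
        assert tr.angle == pytest.approx(180.0, abs=5.0)
        assert tr.peak == pytest.approx(180.0, rel=0.02)

    def test_two_pulses_returned_in_temporal_order(self):
        rec = _pulse_rec([(5.0, 2.0, 150.0), (10.0, 2.0, -150.0)])
        # walking-like yaw oscillation between the turns
        m = (rec.t >= 7.2) & (rec.t < 9.8)
        rec.gyro[m, 2] += 12 * np.sin(2 * np.pi * 1.9 * rec.t[m])
        turns = detect_turns(rec)
        assert len(turns) == 2
        assert turns[0].end <= turns[1].start
        assert turns[0].angle > 0 > turns[1].angle

    def test_small_constant_bias_does_not_change_angle(self):
        rec = _pulse_rec([(8.0, 2.5, 160.0)])
        biased = ImuRecording(rec.t, rec.acc, rec.gyro + np.array([0, 0, 1.0]),
                              nominal_rate=rec.nominal_rate)
        a0 = detect_turns(rec)[0].angle
        a1 = detect_turns(biased)[0].angle
        assert abs(a0 - a1) < 2.0

    def test_sub_90_degree_excursions_are_discarded(self):
        rec = _pulse_rec([(8.0, 1.0, 100.0)])  # integrates to 50 degrees
        assert detect_turns(rec) == []


class TestDetectTransitions:
    def test_onset_within_tolerance_of_truth(self, trial):
        rec, gt = trial
        onset, sit_end = detect_transitions(rec)
        assert onset == pytest.approx(gt.boundaries["stw_start"], abs=0.15)
        assert sit_end == pytest.approx(gt.boundaries["sit_end"], abs=0.3)

    def test_missing_quiet_lead_in_raises_baseline_error(self, trial):
        rec, gt = trial
        # chop the recording so it starts mid-walk
        start = gt.boundaries["stw_end"] + 0.2
        sub = rec.slice_time(start, rec.t[-1])
        with pytest.raises(BaselineError):
            detect_transitions(sub)

    def test_time_reversal_swaps_onset_and_sit_end(self, trial):
        rec, _ = trial
        onset, sit_end = detect_transitions(rec)
        T = rec.t[-1] + rec.t[0]
        rev = ImuRecording(rec.t, rec.acc[::-1], rec.gyro[::-1],
                           nominal_rate=rec.nominal_rate)
        onset_r, sit_end_r = detect_transitions(rev)
        assert onset_r == pytest.approx(T - sit_end, abs=0.25)
        assert sit_end_r == pytest.approx(T - onset, abs=0.25)


class TestSegmentTrial:
    def test_boundaries_match_ground_truth(self, trial):
        rec, gt = trial
        seg = segment_trial(rec)
        b = gt.boundaries
        assert seg.stw[0] == pytest.approx(b["stw_start"], abs=0.15)
        assert seg.stw[1] == pytest.approx(b["stw_end"], abs=0.15)
        assert seg.ft[0] == pytest.approx(b["ft_start"], abs=0.15)
        assert seg.ft[1] == pytest.approx(b["ft_end"], abs=0.15)
        assert seg.tts[0] == pytest.approx(b["tts_start"], abs=0.15)
        assert seg.tts[1] == pytest.approx(b["sit_end"], abs=0.3)

    def test_phase_order_always_holds(self, noiseless_trial):
        rec, _ = noiseless_trial
        seg = segment_trial(rec)
        assert seg.stw[0] < seg.w1[0] < seg.ft[0] < seg.w2[0] < seg.tts[0]
        assert seg.tts_turn[1] <= seg.tts[1]
        assert seg.total == (seg.stw[0], seg.tts[1])

    def test_spurious_third_turn_fails_with_count(self, trial):
        rec, gt = trial
        t0 = gt.boundaries["sit_end"] - rec.t[0]
        spiked = ImuRecording(rec.t, rec.acc, rec.gyro.copy(),
                              nominal_rate=rec.nominal_rate)
        # inject a third ~110 degree turn into the trailing quiet period
        tau = (spiked.t - (t0 + 0.8)) / 1.2
        m = (tau >= 0) & (tau <= 1)
        spiked.gyro[m, 2] += 90.0 * (1 - np.cos(2 * np.pi * tau[m]))
        with pytest.raises(SegmentationError) as exc:
            segment_trial(spiked)
        assert exc.value.n_turns == 3

    def test_config_thresholds_are_exposed(self):
        cfg = SegmentationConfig(turn_threshold=60.0)
        assert cfg.turn_threshold == 60.0
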