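"""Segmentation of iTUG sessions into repetitions and movement phases.

A session of five repetitions is first split on quiescence gaps in the
gyroscope signal.  Each repetition is then segmented into Sit-to-Walk
(StW), walk-out (W1), First Turn (FT), walk-back (W2) and Turn-to-Sit
(TtS, which contains a turning sub-interval followed by the sit-down):

* turns from the vertical-axis angular velocity (low-pass filtered,
  threshold excursions extended outward to a near-zero crossing);
* the stand-up onset and sit-down end from mediolateral angular velocity
  and anterior-posterior acceleration against a quiescent baseline;
* the StW/W1 boundary from the first detected step after standing up.

All intervals are half-open ``[start, end)`` in seconds on the
recording's time axis.  The thresholds below are package defaults typical
of trunk-worn IMU studies; all are exposed in :class:`SegmentationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._signal import lowpass, moving_sd, runs_of
from .errors import BaselineError, NoActivityError, SegmentationError
from .io_device import ImuRecording

Interval = tuple[float, float]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable thresholds of the segmentation stage."""

    activity_threshold: float = 4.0  # deg/s, moving SD of gyro magnitude
    activity_window: float = 1.0  # s
    min_gap: float = 5.0  # s of quiescence separating repetitions
    pad: float = 1.0  # s of context kept around each repetition
    turn_lowpass_hz: float = 1.5
    turn_threshold: float = 45.0  # deg/s on |yaw velocity|
    turn_boundary_frac: float = 0.1  # of excursion peak
    turn_boundary_floor: float = 5.0  # deg/s
    min_turn_angle: float = 90.0  # deg
    onset_factor: float = 3.0  # multiple of quiescent SD
    onset_min_duration: float = 0.2  # s of sustained supra-threshold signal
    onset_level_frac: float = 0.03  # of the movement peak, boundary refinement
    onset_smooth: float = 0.1  # s, boxcar smoothing of the transition channels
    baseline_window: float = 0.8  # s used to estimate quiescent SD
    baseline_gyro_ceiling: float = 6.0  # deg/s, ML quiescence ceiling
    baseline_acc_ceiling: float = 0.6  # m/s^2, AP quiescence ceiling
    step_min_lead: float = 0.0  # s after onset before the first step may occur


@dataclass(frozen=True)
class TurnEvent:
    """One detected turn: interval, peak/mean |yaw velocity| and angle."""

    start: float
    end: float
    peak: float  # deg/s
    mean: float  # deg/s
    angle: float  # deg, signed


@dataclass
class TrialSegmentation:
    """Phase intervals of one repetition (seconds, half-open)."""

    stw: Interval
    w1: Interval
    ft: Interval
    w2: Interval
    tts: Interval
    tts_turn: Interval
    total: Interval = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.total is None:
            self.total = (self.stw[0], self.tts[1])
        order = [self.stw, self.w1, self.ft, self.w2, self.tts]
        starts = [iv[0] for iv in order]
        if any(iv[1] < iv[0] for iv in order) or starts != sorted(starts):
            raise SegmentationError(f"phase intervals out of order: {order}")
        if not (self.tts[0] <= self.tts_turn[0] and self.tts_turn[1] <= self.tts[1]):
            raise SegmentationError("TtS turning sub-interval not inside TtS")

    def duration(self, phase: str) -> float:
        iv: Interval = getattr(self, phase)
        return iv[1] - iv[0]

    @property
    def walk_duration(self) -> float:
        return self.duration("w1") + self.duration("w2")

    def as_dict(self) -> dict[str, Interval]:
        return {
            "stw": self.stw, "w1": self.w1, "ft": self.ft, "w2": self.w2,
            "tts": self.tts, "tts_turn": self.tts_turn, "total": self.total,
        }


def split_repetitions(
    rec: ImuRecording, config: SegmentationConfig | None = None
) -> list[ImuRecording]:
    """Split a session into repetitions on gyroscope quiescence gaps."""
    cfg = config or SegmentationConfig()
    fs = rec.fs
    mag = np.linalg.norm(rec.gyro, axis=1)
    sd = moving_sd(mag, int(round(cfg.activity_window * fs)))
    runs = runs_of(sd > cfg.activity_threshold)
    if not runs:
        raise NoActivityError("no active movement blocks found")
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if (s - merged[-1][1]) / fs < cfg.min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    pad = int(round(cfg.pad * fs))
    out = []
    for s, e in merged:
        s = max(0, s - pad)
        e = min(len(rec), e + pad)
        out.append(
            ImuRecording(rec.t[s:e], rec.acc[s:e], rec.gyro[s:e],
                         rec.nominal_rate, rec.axis_map)
        )
    return out


def detect_turns(
    rec: ImuRecording, config: SegmentationConfig | None = None
) -> list[TurnEvent]:
    """Detect turns from the vertical-axis angular velocity.

    The yaw velocity is low-pass filtered and de-biased (median over the
    recording); excursions above the threshold are extended outward to the
    nearest crossing of max(floor, frac*peak), overlapping candidates are
    merged, and only turns with an integrated angle of at least
    ``min_turn_angle`` are returned.
    """
    cfg = config or SegmentationConfig()
    fs = rec.fs
    v = lowpass(rec.gyro[:, 2], fs, cfg.turn_lowpass_hz)
    v = v - np.median(v)
    av = np.abs(v)
    runs = runs_of(av > cfg.turn_threshold)
    intervals: list[list[int]] = []
    for s, e in runs:
        peak = float(av[s:e].max())
        level = max(cfg.turn_boundary_floor, cfg.turn_boundary_frac * peak)
        while s > 0 and av[s - 1] >= level:
            s -= 1
        while e < len(av) and av[e] >= level:
            e += 1
        if intervals and s <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], e)
        else:
            intervals.append([s, e])
    events = []
    for s, e in intervals:
        seg = v[s:e]
        angle = float(np.trapezoid(seg) / fs)
        if abs(angle) < cfg.min_turn_angle:
            continue
        events.append(
            TurnEvent(
                start=float(rec.t[s]),
                end=float(rec.t[min(e, len(rec) - 1)]),
                peak=float(np.abs(seg).max()),
                mean=float(np.abs(seg).mean()),
                angle=angle,
            )
        )
    return events


def _quiescent_sd(x: np.ndarray, n_base: int, trailing: bool) -> tuple[float, float]:
    """(baseline mean, SD) over the leading or trailing baseline window."""
    w = x[-n_base:] if trailing else x[:n_base]
    return float(w.mean()), float(w.std())


def detect_transitions(
    rec: ImuRecording, config: SegmentationConfig | None = None
) -> tuple[float, float]:
    """Locate the stand-up onset and the sit-down end of one repetition.

    Onset is the earliest time where filtered mediolateral angular velocity
    or baseline-subtracted anterior-posterior acceleration stays above
    ``onset_factor`` times its quiescent SD for at least
    ``onset_min_duration``; the sit end is the symmetric latest such time.
    Both are refined outward to the nearest sub-SD sample.  Raises
    :class:`BaselineError` when the lead-in or tail is not quiescent.
    """
    cfg = config or SegmentationConfig()
    fs = rec.fs
    n_base = int(round(cfg.baseline_window * fs))
    if len(rec) < 3 * n_base:
        raise BaselineError("recording too short for baseline estimation")
    # short boxcar smoothing: lowers the noise floor for boundary
    # refinement without the infinite precursor tails of an IIR filter
    from scipy.ndimage import uniform_filter1d

    w = max(int(round(cfg.onset_smooth * fs)), 1)
    ml = uniform_filter1d(rec.gyro[:, 1], w, mode="reflect")
    ap = uniform_filter1d(rec.acc[:, 0], w, mode="reflect")
    min_run = int(round(cfg.onset_min_duration * fs))

    def _one_side(trailing: bool) -> float:
        ml_mean, ml_sd = _quiescent_sd(ml, n_base, trailing)
        ap_mean, ap_sd = _quiescent_sd(ap, n_base, trailing)
        if ml_sd > cfg.baseline_gyro_ceiling or ap_sd > cfg.baseline_acc_ceiling:
            raise BaselineError(
                f"{'trailing' if trailing else 'leading'} baseline window is not quiescent"
            )
        a_ml = np.abs(ml - ml_mean)
        a_ap = np.abs(ap - ap_mean)
        active = (a_ml > cfg.onset_factor * max(ml_sd, 1e-9)) | (
            a_ap > cfg.onset_factor * max(ap_sd, 1e-9)
        )
        runs = [r for r in runs_of(active) if r[1] - r[0] >= min_run]
        if not runs:
            raise BaselineError("no sustained movement found above baseline")
        s, e = runs[-1] if trailing else runs[0]
        # refine the boundary: anchor at the strongest sample of the run and
        # walk outward until both channels fall below max(SD, frac*peak) —
        # robust both to noise and to the noiseless zero-SD limit.
        lvl_ml = max(ml_sd, cfg.onset_level_frac * float(a_ml[s:e].max()))
        lvl_ap = max(ap_sd, cfg.onset_level_frac * float(a_ap[s:e].max()))
        score = np.maximum(a_ml / lvl_ml, a_ap / lvl_ap)
        i = s + int(np.argmax(score[s:e]))
        step = 1 if trailing else -1
        while 0 < i < len(score) - 1 and score[i] >= 1.0:
            i += step
        return float(rec.t[i])

    onset = _one_side(trailing=False)
    sit_end = _one_side(trailing=True)
    if sit_end <= onset:
        raise BaselineError("sit end precedes stand-up onset")
    return onset, sit_end


def segment_trial(
    rec: ImuRecording, config: SegmentationConfig | None = None
) -> TrialSegmentation:
    """Segment one repetition into StW / W1 / FT / W2 / TtS phases.

    Requires exactly two major turns; raises :class:`SegmentationError`
    carrying the detected count otherwise.
    """
    from .features import detect_steps  # step detection lives with the features

    cfg = config or SegmentationConfig()
    turns = detect_turns(rec, cfg)
    if len(turns) != 2:
        raise SegmentationError(
            f"expected 2 major turns, found {len(turns)}", n_turns=len(turns)
        )
    ft_ev, tts_ev = turns
    onset, sit_end = detect_transitions(rec, cfg)
    if not onset < ft_ev.start < ft_ev.end < tts_ev.start:
        raise SegmentationError("turns and transitions are out of order")

    steps = detect_steps(rec.acc[:, 2], rec.fs, t0=float(rec.t[0]))
    lead = onset + cfg.step_min_lead
    walk_steps = steps[(steps > lead) & (steps < ft_ev.start)]
    if len(walk_steps) == 0:
        raise SegmentationError("no steps detected between stand-up and first turn")
    first_step = float(walk_steps[0])

    sit_end = max(sit_end, tts_ev.end)
    return TrialSegmentation(
        stw=(onset, first_step),
        w1=(first_step, ft_ev.start),
        ft=(ft_ev.start, ft_ev.end),
        w2=(ft_ev.end, tts_ev.start),
        tts=(tts_ev.start, sit_end),
        tts_turn=(tts_ev.start, tts_ev.end),
        total=(onset, sit_end),
    )
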