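"""The iTUG feature catalogue: 78 signal features per repetition.

The catalogue covers, per phase (Sit-to-Walk, walking = both legs, first
turn, Turn-to-Sit, total task): durations; intensity as the root mean
square (RMS) of each acceleration and angular-velocity axis; angular
velocity ranges; movement smoothness as normalised jerk scores (NJS) of
acceleration and normalised angular jerk scores (NAJS) of the turns; mean
and peak turning velocity; step counts, average step length, gait speed,
cadence; and step regularity from the autocorrelation of trunk
acceleration at the dominant step period.

Conventions (documented package decisions):

* RMS of acceleration is computed on the interval-mean-subtracted signal
  (removes gravity/posture); angular velocity is used raw.
* NJS = sqrt(T^5 / (2 A^2) * integral j(t)^2 dt) with j the derivative of
  acceleration and A the displacement excursion (max - min) of the
  twice-integrated mean-subtracted acceleration.  A minimum-jerk movement
  scores sqrt(360) regardless of its duration or amplitude.
* NAJS uses the same formula on the yaw velocity with A the integrated
  turn angle.
* Gait speed and step length use the nominal 6 m round trip (2 x 3 m).
* Walking-phase features pool the walk-out and walk-back samples; jerk
  scores, which need a contiguous signal, average the two legs.

The exact feature names are frozen in :data:`FEATURE_MANIFEST`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, signal

from ._signal import bandpass, lowpass
from .errors import FeatureError, SchemaError
from .io_device import ImuRecording
from .segmentation import TrialSegmentation

log = logging.getLogger(__name__)

_AXES = ("AP", "ML", "V")
_PHASES = ("StW", "walking", "first turn", "TtS", "total")


def _build_manifest() -> tuple[str, ...]:
    names: list[str] = [
        "StW duration [s]",
        "Walk duration [s]",
        "Turn duration [s]",
        "TtS duration [s]",
        "TtS turning duration [s]",
        "Total duration [s]",
    ]
    for phase in _PHASES:
        names += [f"RMS acc. {phase} {ax} [m/s^2]" for ax in _AXES]
    for phase in _PHASES:
        names += [f"RMS angular velocity {phase} {ax} [°/s]" for ax in _AXES]
    for phase in _PHASES:
        names += [f"Range angular velocity {phase} {ax} [°/s]" for ax in _AXES]
    names += [f"Range acc. walking {ax} [m/s^2]" for ax in _AXES]
    for phase in ("walking", "StW", "TtS"):
        names += [f"Jerk score {phase} {ax}" for ax in _AXES]
    names += [
        "NAJS first turn",
        "NAJS TtS",
        "Mean velocity first turn [°/s]",
        "Peak velocity first turn [°/s]",
        "Mean velocity TtS [°/s]",
        "Peak velocity TtS [°/s]",
        "Number of steps walking",
        "Number of steps in first turn",
        "Number of steps TtS",
        "Total number of steps",
        "Gait speed [m/s]",
        "Average step length [m]",
        "Cadence [steps/s]",
        "Step regularity V [%]",
        "Step regularity AP [%]",
    ]
    return tuple(names)


#: The frozen 78-entry signal-feature catalogue.
FEATURE_MANIFEST: tuple[str, ...] = _build_manifest()
assert len(FEATURE_MANIFEST) == 78

#: Subject descriptives appended to the signal features in predictor models.
DESCRIPTIVE_COLUMNS: tuple[str, ...] = (
    "age", "education", "sex", "height", "weight", "bmi",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of feature extraction."""

    walk_distance: float = 6.0  # m, nominal round trip
    step_band: tuple[float, float] = (0.5, 3.0)  # Hz
    step_prominence: float = 0.3  # m/s^2
    step_min_gap: float = 0.3  # s
    jerk_lowpass_hz: float = 5.0  # smoothing before differentiation
    turn_lowpass_hz: float = 6.0  # denoising for turn mean/peak velocity
    max_missing_frac: float = 0.2


# ---------------------------------------------------------------------------
# feature primitives
# ---------------------------------------------------------------------------

def rms(x: np.ndarray, demean: bool = False) -> float:
    """Root mean square; ``demean`` subtracts the interval mean first."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty interval")
    if demean:
        x = x - x.mean()
    return float(np.sqrt(np.mean(x * x)))


def normalized_jerk_score(acc: np.ndarray, fs: float) -> float:
    """Dimensionless smoothness of an acceleration segment.

    sqrt(T^5/(2 A^2) * int j^2 dt): T is the segment duration, j the jerk
    by central differences, and A the displacement excursion obtained by
    double integration of the mean-subtracted acceleration.
    """
    acc = np.asarray(acc, dtype=float)
    if acc.size < max(3, int(0.2 * fs)):
        raise FeatureError("interval too short for a jerk score")
    dt = 1.0 / fs
    T = (acc.size - 1) * dt
    j = np.gradient(acc, dt)
    int_j2 = float(np.trapezoid(j * j, dx=dt))
    a0 = acc - acc.mean()
    v = integrate.cumulative_trapezoid(a0, dx=dt, initial=0.0)
    x = integrate.cumulative_trapezoid(v, dx=dt, initial=0.0)
    amp = float(np.ptp(x))
    if amp <= 0:
        raise FeatureError("undefined displacement amplitude for jerk score")
    return float(np.sqrt(T**5 / (2 * amp**2) * int_j2))


def normalized_angular_jerk_score(omega: np.ndarray, fs: float) -> float:
    """NJS analogue on angular velocity; amplitude is the integrated angle."""
    omega = np.asarray(omega, dtype=float)
    if omega.size < max(3, int(0.2 * fs)):
        raise FeatureError("interval too short for an angular jerk score")
    dt = 1.0 / fs
    T = (omega.size - 1) * dt
    # explicit central second difference: double np.gradient degrades at the
    # segment edges, where the angular jerk of a smooth turn is largest
    j = np.empty_like(omega)
    j[1:-1] = (omega[2:] - 2 * omega[1:-1] + omega[:-2]) / dt**2
    j[0], j[-1] = j[1], j[-2]
    int_j2 = float(np.trapezoid(j * j, dx=dt))
    amp = abs(float(np.trapezoid(omega, dx=dt)))
    if amp <= 0:
        raise FeatureError("zero integrated angle for angular jerk score")
    return float(np.sqrt(T**5 / (2 * amp**2) * int_j2))


def turn_kinematics(omega: np.ndarray) -> tuple[float, float]:
    """Mean and peak of |yaw velocity| over a turn interval."""
    omega = np.asarray(omega, dtype=float)
    if omega.size == 0:
        raise ValueError("turn kinematics of an empty interval")
    a = np.abs(omega)
    return float(a.mean()), float(a.max())


def detect_steps(
    vacc: np.ndarray,
    fs: float,
    t0: float = 0.0,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Step instants from vertical acceleration (band-passed peak picking)."""
    cfg = config or FeatureConfig()
    vacc = np.asarray(vacc, dtype=float)
    if vacc.size < int(0.4 * fs):
        raise FeatureError("interval too short for step detection")
    x = bandpass(vacc, fs, *cfg.step_band)
    peaks, _ = signal.find_peaks(
        x, prominence=cfg.step_prominence, distance=max(1, int(cfg.step_min_gap * fs))
    )
    return t0 + peaks / fs


def gait_metrics(
    seg: TrialSegmentation, steps: np.ndarray, walk_distance: float = 6.0
) -> tuple[float, float, float]:
    """(gait speed m/s, average step length m, cadence steps/s).

    ``steps`` are step instants; those inside W1 or W2 are counted.
    """
    dur = seg.walk_duration
    if dur <= 0:
        raise ValueError("walk duration must be positive")
    steps = np.asarray(steps, dtype=float)
    n = int(
        np.sum(((steps >= seg.w1[0]) & (steps < seg.w1[1]))
               | ((steps >= seg.w2[0]) & (steps < seg.w2[1])))
    )
    speed = walk_distance / dur
    if n == 0:
        raise FeatureError("no steps in the walk phases; step length undefined")
    return speed, walk_distance / n, n / dur


def step_regularity(
    acc: np.ndarray,
    fs: float,
    step_period: float | None = None,
    n_steps: int | None = None,
) -> float:
    """Autocorrelation-based step regularity, in percent of lag 0.

    Uses the unbiased autocorrelation of the mean-subtracted signal at the
    dominant step period (given, or found as the autocorrelation peak in
    the 0.25-1.2 s lag range).
    """
    if n_steps is not None and n_steps < 4:
        raise FeatureError("step regularity needs at least 4 steps")
    x = np.asarray(acc, dtype=float)
    n = x.size
    if n < int(0.8 * fs):
        raise FeatureError("interval too short for step regularity")
    x = x - x.mean()
    full = np.correlate(x, x, mode="full")[n - 1:]
    lags = np.arange(n)
    unbiased = full / (n - lags)
    ac0 = unbiased[0]
    if ac0 <= 0:
        raise FeatureError("zero-variance signal")
    if step_period is None:
        lo, hi = int(0.25 * fs), min(int(1.2 * fs), n - 1)
        if hi <= lo:
            raise FeatureError("interval too short to find the step period")
        k = lo + int(np.argmax(unbiased[lo:hi]))
    else:
        k = int(round(step_period * fs))
        if not 0 < k < n:
            raise FeatureError("step period outside the autocorrelation range")
    return float(np.clip(100.0 * unbiased[k] / ac0, -100.0, 100.0))


# ---------------------------------------------------------------------------
# per-repetition extraction and averaging
# ---------------------------------------------------------------------------

def _indices(rec: ImuRecording, interval: tuple[float, float]) -> slice:
    i0 = int(np.searchsorted(rec.t, interval[0], side="left"))
    i1 = int(np.searchsorted(rec.t, interval[1], side="left"))
    return slice(i0, max(i1, i0 + 1))


def extract_features(
    rec: ImuRecording,
    seg: TrialSegmentation,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """Compute the full 78-feature catalogue for one segmented repetition.

    Individual feature failures become NaN with a logged reason; the call
    fails only if more than ``max_missing_frac`` of the catalogue is
    missing.
    """
    cfg = config or FeatureConfig()
    fs = rec.fs
    out: dict[str, float] = {}

    def put(name: str, fn):
        try:
            out[name] = float(fn())
        except (FeatureError, ValueError) as exc:
            log.debug("feature %r missing: %s", name, exc)
            out[name] = np.nan

    walking = (seg.w1, seg.w2)

    def samples(arr: np.ndarray, phase: str) -> np.ndarray:
        if phase == "walking":
            return np.concatenate([arr[_indices(rec, iv)] for iv in walking])
        iv = {"StW": seg.stw, "first turn": seg.ft,
              "TtS": seg.tts, "total": seg.total}[phase]
        return arr[_indices(rec, iv)]

    put("StW duration [s]", lambda: seg.duration("stw"))
    put("Walk duration [s]", lambda: seg.walk_duration)
    put("Turn duration [s]", lambda: seg.duration("ft"))
    put("TtS duration [s]", lambda: seg.duration("tts"))
    put("TtS turning duration [s]", lambda: seg.duration("tts_turn"))
    put("Total duration [s]", lambda: seg.duration("total"))

    for phase in _PHASES:
        for ax_i, ax in enumerate(_AXES):
            put(f"RMS acc. {phase} {ax} [m/s^2]",
                lambda p=phase, a=ax_i: rms(samples(rec.acc[:, a], p), demean=True))
    for phase in _PHASES:
        for ax_i, ax in enumerate(_AXES):
            put(f"RMS angular velocity {phase} {ax} [°/s]",
                lambda p=phase, a=ax_i: rms(samples(rec.gyro[:, a], p)))
    for phase in _PHASES:
        for ax_i, ax in enumerate(_AXES):
            put(f"Range angular velocity {phase} {ax} [°/s]",
                lambda p=phase, a=ax_i: np.ptp(samples(rec.gyro[:, a], p)))
    for ax_i, ax in enumerate(_AXES):
        put(f"Range acc. walking {ax} [m/s^2]",
            lambda a=ax_i: np.ptp(samples(rec.acc[:, a], "walking")))

    acc_smooth = np.column_stack(
        [lowpass(rec.acc[:, a], fs, cfg.jerk_lowpass_hz) for a in range(3)]
    )
    for ax_i, ax in enumerate(_AXES):
        put(f"Jerk score walking {ax}",
            lambda a=ax_i: np.mean([
                normalized_jerk_score(acc_smooth[_indices(rec, iv), a], fs)
                for iv in walking
            ]))
    for phase, iv in (("StW", seg.stw), ("TtS", seg.tts)):
        for ax_i, ax in enumerate(_AXES):
            put(f"Jerk score {phase} {ax}",
                lambda i=iv, a=ax_i: normalized_jerk_score(
                    acc_smooth[_indices(rec, i), a], fs))

    gyro_v_smooth = lowpass(rec.gyro[:, 2], fs, cfg.turn_lowpass_hz)
    put("NAJS first turn",
        lambda: normalized_angular_jerk_score(gyro_v_smooth[_indices(rec, seg.ft)], fs))
    put("NAJS TtS",
        lambda: normalized_angular_jerk_score(gyro_v_smooth[_indices(rec, seg.tts)], fs))
    for label, iv in (("first turn", seg.ft), ("TtS", seg.tts_turn)):
        def _tk(i=iv):
            return turn_kinematics(gyro_v_smooth[_indices(rec, i)])
        put(f"Mean velocity {label} [°/s]", lambda i=iv: _tk(i)[0])
        put(f"Peak velocity {label} [°/s]", lambda i=iv: _tk(i)[1])

    steps = detect_steps(rec.acc[:, 2], fs, t0=float(rec.t[0]), config=cfg)

    def count(iv):
        return int(np.sum((steps >= iv[0]) & (steps < iv[1])))

    n_walk = count(seg.w1) + count(seg.w2)
    put("Number of steps walking", lambda: n_walk)
    put("Number of steps in first turn", lambda: count(seg.ft))
    put("Number of steps TtS", lambda: count(seg.tts))
    put("Total number of steps", lambda: count(seg.total))

    def _gait():
        return gait_metrics(seg, steps, cfg.walk_distance)

    put("Gait speed [m/s]", lambda: _gait()[0])
    put("Average step length [m]", lambda: _gait()[1])
    put("Cadence [steps/s]", lambda: _gait()[2])

    walk_steps = steps[((steps >= seg.w1[0]) & (steps < seg.w1[1]))
                       | ((steps >= seg.w2[0]) & (steps < seg.w2[1]))]
    period = float(np.median(np.diff(walk_steps))) if len(walk_steps) >= 2 else None
    for ax_i, ax in ((2, "V"), (0, "AP")):
        put(f"Step regularity {ax} [%]",
            lambda a=ax_i: step_regularity(
                samples(rec.acc[:, a], "walking"), fs,
                step_period=period, n_steps=n_walk))

    missing = [k for k, v in out.items() if not np.isfinite(v)]
    if len(missing) > cfg.max_missing_frac * len(FEATURE_MANIFEST):
        raise FeatureError(
            f"{len(missing)}/{len(FEATURE_MANIFEST)} features missing: {missing[:5]}..."
        )
    assert tuple(out) == FEATURE_MANIFEST
    return out


def average_features(vectors: list[dict[str, float]]) -> dict[str, float]:
    """Arithmetic mean per feature across repetitions, ignoring NaN.

    A feature missing in every repetition stays NaN.  Mismatched feature
    names raise :class:`SchemaError`.
    """
    if not vectors:
        raise ValueError("need at least one feature vector")
    keys = tuple(vectors[0])
    for v in vectors[1:]:
        if tuple(v) != keys:
            raise SchemaError("feature vectors have mismatched names")
    out = {}
    for k in keys:
        vals = np.asarray([v[k] for v in vectors], dtype=float)
        finite = vals[np.isfinite(vals)]
        out[k] = float(finite.mean()) if finite.size else float("nan")
    return out
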