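"""Synthetic iTUG cohorts: latent ability, clinical scores, and IMU signals.

The generator emulates a two-cohort study (community-dwelling seniors and
geriatric outpatients) in which a single latent mobility ability ``theta``
drives the Community Balance and Mobility Scale (CBMS) score, a battery of
clinical tests, and the kinematic parameters of an instrumented Timed Up
and Go (iTUG): stand up from a chair, walk 3 m to a cone, turn ~180°,
walk back, turn and sit down, five repetitions with 30 s rests.

Cohort calibration
------------------
``theta`` is standardised so the community cohort is centred at +1 and the
outpatient cohort at -1.  Every observed variable is a linear map of theta
plus Gaussian noise, clipped to its scale bounds.  Because clipping shifts
moments (e.g. a raw N(15, 17.2) CBMS clipped at 0 would average ~16.9),
the raw Gaussian moments per cohort are obtained by moment-matching a
clipped normal to the published cohort mean/SD with a root solver; the
linear map and per-cohort noise SDs are then derived from those raw
moments.  The calibration is deterministic and independent of the seed.

Signal model
------------
Each repetition is built from canonical movement primitives at 100 Hz:
a minimum-jerk anterior-posterior acceleration pulse plus a mediolateral
angular-velocity pulse for the sit-to-walk, sinusoidal step oscillations
at the subject's cadence during walking (and attenuated stepping inside
turns), raised-cosine vertical-axis angular-velocity pulses of ~180° for
the two turns, and an overlapping sit-down pulse.  Gravity rides on the
vertical accelerometer axis; additive white Gaussian noise is applied to
all channels.

Because a smooth angular-velocity pulse has no sharp "turn onset", the
ground-truth phase boundaries are stored at the same operational
convention the segmentation stage uses: turns begin/end where the
noiseless pulse crosses max(5 deg/s, 10% of its peak).  The walk legs are
sized so the conventional walk-out and walk-back intervals each take
exactly 3 m / gait-speed.  The full pulse supports are stored separately
(``turn_supports``) so tests can integrate the complete turn angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ItugError
from .io_device import ImuRecording, write_log

GRAVITY = 9.80665

#: Default additive sensor noise (SD of white Gaussian noise per channel).
NOISE_ACC_SD = 0.15  # m/s^2
NOISE_GYRO_SD = 3.0  # deg/s

#: Within-subject repetition-to-repetition jitter (SD of a multiplicative
#: log-normal factor on the kinematic parameters).
REPETITION_JITTER = 0.04

#: Turn-boundary convention shared with the segmentation defaults.
TURN_BOUNDARY_FLOOR = 5.0  # deg/s
TURN_BOUNDARY_FRAC = 0.1

#: Measurement noise assumed on the CBMS given theta (points); sets the
#: strength of the latent link (rank correlation theta-CBMS ~ 0.95).
CBMS_NOISE_SD = 6.0

WALK_DISTANCE = 3.0  # m, chair to cone


@dataclass(frozen=True)
class ScaleSpec:
    """Published cohort moments and bounds for one observed variable."""

    name: str
    community: tuple[float, float]  # (mean, sd)
    outpatient: tuple[float, float]
    lo: float
    hi: float
    integer: bool = False


#: Clinical / descriptive variables calibrated to the published cohort table.
CLINICAL_SCALES: tuple[ScaleSpec, ...] = (
    ScaleSpec("cbms", (66.7, 18.3), (15.0, 17.2), 0.0, 96.0, integer=True),
    ScaleSpec("age", (71.8, 7.3), (78.9, 5.9), 60.0, 85.0, integer=True),
    ScaleSpec("education", (14.6, 3.7), (11.5, 4.3), 5.0, 25.0, integer=True),
    ScaleSpec("height", (169.5, 9.6), (165.9, 11.1), 140.0, 200.0),
    ScaleSpec("weight", (72.0, 12.6), (75.5, 16.9), 40.0, 130.0),
    ScaleSpec("tug_s", (8.3, 1.2), (13.9, 4.0), 3.0, 60.0),
    ScaleSpec("gait_speed_habitual", (1.36, 0.20), (0.88, 0.21), 0.2, 2.5),
    ScaleSpec("gait_speed_fast", (1.83, 0.27), (1.18, 0.30), 0.25, 3.5),
    ScaleSpec("sppb", (11.7, 0.9), (9.0, 2.4), 0.0, 12.0, integer=True),
    ScaleSpec("cst30", (15.3, 2.9), (8.8, 3.3), 0.0, 40.0, integer=True),
    ScaleSpec("lbs8", (5.4, 1.5), (4.3, 1.4), 1.0, 8.0, integer=True),
    ScaleSpec("sfesi", (8.1, 1.5), (10.7, 4.0), 7.0, 28.0, integer=True),
)

#: Kinematic parameters of the simulated iTUG, not part of the published
#: table; defaults chosen to be typical of healthy seniors vs outpatients.
KINEMATIC_SCALES: tuple[ScaleSpec, ...] = (
    ScaleSpec("cadence", (1.90, 0.15), (1.65, 0.20), 1.0, 2.6),
    ScaleSpec("turn_peak_velocity", (160.0, 25.0), (100.0, 25.0), 60.0, 300.0),
    ScaleSpec("stw_duration", (1.3, 0.25), (2.3, 0.5), 0.6, 4.5),
    ScaleSpec("sit_duration", (1.5, 0.3), (2.6, 0.6), 0.7, 5.0),
)

#: Fraction of males per cohort (17/40 community, 11/20 outpatient).
P_MALE = {"community": 17 / 40, "outpatient": 11 / 20}


def _clipped_normal_moments(m: float, s: float, lo: float, hi: float):
    """Mean and SD of clip(N(m, s), lo, hi) in closed form."""
    a = (lo - m) / s
    b = (hi - m) / s
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    mean = lo * Fa + hi * (1 - Fb) + m * (Fb - Fa) + s * (fa - fb)
    ex2 = (
        lo**2 * Fa
        + hi**2 * (1 - Fb)
        + (m**2 + s**2) * (Fb - Fa)
        + 2 * m * s * (fa - fb)
        + s**2 * (a * fa - b * fb)
    )
    var = max(ex2 - mean**2, 1e-12)
    return mean, math.sqrt(var)


@lru_cache(maxsize=None)
def _raw_gaussian_params(mean: float, sd: float, lo: float, hi: float):
    """Raw (m, s) such that clip(N(m, s), lo, hi) has the given moments."""

    def residual(x):
        m, log_s = x
        mu, sigma = _clipped_normal_moments(m, math.exp(log_s), lo, hi)
        return [mu - mean, sigma - sd]

    x0 = np.array([mean, math.log(sd)])
    sol = optimize.fsolve(residual, x0, full_output=True)
    x, _, ier, _ = sol
    if ier != 1:  # retry from an inflated guess (heavily clipped scales)
        x, _, ier, msg = optimize.fsolve(
            residual, np.array([mean, math.log(sd * 2.0)]), full_output=True
        )
        if ier != 1:
            raise ItugError(f"cohort calibration failed for bounds ({lo},{hi}): {msg}")
    return float(x[0]), float(math.exp(x[1]))


@dataclass(frozen=True)
class VariableMap:
    """Linear latent map value = intercept + slope*theta + eps, then clip."""

    spec: ScaleSpec
    intercept: float
    slope: float
    noise_sd: dict[str, float]  # per cohort

    def sample(self, theta: np.ndarray, cohort: str, rng: np.random.Generator):
        raw = self.intercept + self.slope * theta
        raw = raw + rng.normal(0.0, self.noise_sd[cohort], size=theta.shape)
        val = np.clip(raw, self.spec.lo, self.spec.hi)
        if self.spec.integer:
            val = np.clip(np.round(val), self.spec.lo, self.spec.hi)
        return val


@dataclass(frozen=True)
class CohortCalibration:
    """Latent-ability moments per cohort plus the per-variable maps."""

    theta_mean: dict[str, float]
    theta_sd: dict[str, float]
    maps: dict[str, VariableMap]


@lru_cache(maxsize=1)
def default_calibration() -> CohortCalibration:
    """Build the documented default calibration (deterministic)."""
    theta_mean = {"community": 1.0, "outpatient": -1.0}

    cbms_spec = CLINICAL_SCALES[0]
    raw = {
        "community": _raw_gaussian_params(*cbms_spec.community, cbms_spec.lo, cbms_spec.hi),
        "outpatient": _raw_gaussian_params(*cbms_spec.outpatient, cbms_spec.lo, cbms_spec.hi),
    }
    slope = (raw["community"][0] - raw["outpatient"][0]) / 2.0
    intercept = (raw["community"][0] + raw["outpatient"][0]) / 2.0
    theta_sd = {
        c: math.sqrt(max(raw[c][1] ** 2 - CBMS_NOISE_SD**2, 1e-6)) / slope
        for c in raw
    }
    maps = {
        "cbms": VariableMap(
            cbms_spec, intercept, slope,
            {c: CBMS_NOISE_SD for c in raw},
        )
    }
    for spec in CLINICAL_SCALES[1:] + KINEMATIC_SCALES:
        r = {
            "community": _raw_gaussian_params(*spec.community, spec.lo, spec.hi),
            "outpatient": _raw_gaussian_params(*spec.outpatient, spec.lo, spec.hi),
        }
        b = (r["community"][0] - r["outpatient"][0]) / 2.0
        a = (r["community"][0] + r["outpatient"][0]) / 2.0
        noise = {}
        for c in r:
            explained = (b * theta_sd[c]) ** 2
            floor = (0.05 * r[c][1]) ** 2
            noise[c] = math.sqrt(max(r[c][1] ** 2 - explained, floor))
        maps[spec.name] = VariableMap(spec, a, b, noise)
    return CohortCalibration(theta_mean, theta_sd, maps)


@dataclass
class SubjectProfile:
    """One simulated subject: descriptives plus iTUG kinematic parameters."""

    id: str
    cohort: str
    theta: float
    age: float
    education: float
    sex: str
    height: float
    weight: float
    gait_speed: float  # m/s, also the habitual gait-speed clinical value
    cadence: float  # steps/s
    turn_peak_velocity: float  # deg/s
    stw_duration: float  # s
    sit_duration: float  # s

    def __post_init__(self):
        kin = (self.gait_speed, self.cadence, self.turn_peak_velocity,
               self.stw_duration, self.sit_duration)
        if any(v <= 0 for v in kin):
            raise ValueError(f"{self.id}: kinematic parameters must be positive")
        if not 0.2 < self.gait_speed < 2.5:
            raise ValueError(f"{self.id}: gait speed {self.gait_speed} outside (0.2, 2.5)")

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


@dataclass
class GroundTruth:
    """Per-repetition truth: phase boundaries, step instants, turn kinematics.

    ``boundaries`` holds, in seconds on the recording's time axis:
    stw_start, stw_end (first step), ft_start, ft_end, tts_start,
    tts_turn_end, sit_end.  Turn boundaries follow the operational
    threshold convention (see module docstring); ``turn_supports`` holds
    the full pulse supports.
    """

    boundaries: dict[str, float]
    step_times: np.ndarray
    turn_supports: list[tuple[float, float]]
    turn_peaks: tuple[float, float]
    turn_angles: tuple[float, float]

    def shifted(self, dt: float) -> "GroundTruth":
        return GroundTruth(
            {k: v + dt for k, v in self.boundaries.items()},
            self.step_times + dt,
            [(s + dt, e + dt) for s, e in self.turn_supports],
            self.turn_peaks,
            self.turn_angles,
        )


@dataclass
class CohortTruth:
    """Cohort-level generating truth: latent abilities and the calibration."""

    theta: pd.Series
    calibration: CohortCalibration
    cbms: pd.Series


def simulate_cohort(
    n_community: int,
    n_outpatient: int,
    seed: int,
    calibration: CohortCalibration | None = None,
):
    """Draw a synthetic cohort.

    Returns ``(profiles, clinical_table, cbms, truth)`` where
    ``clinical_table`` is a DataFrame indexed by subject id with the
    descriptive and clinical-test columns, ``cbms`` the response Series,
    and ``truth`` the :class:`CohortTruth`.
    """
    if n_community < 0 or n_outpatient < 0:
        raise ValueError("cohort sizes must be non-negative")
    cal = calibration or default_calibration()
    rng = np.random.default_rng(seed)

    profiles: list[SubjectProfile] = []
    rows: list[dict] = []
    cbms_vals: list[float] = []
    thetas: list[float] = []
    sid = 0
    for cohort, n in (("community", n_community), ("outpatient", n_outpatient)):
        theta = rng.normal(cal.theta_mean[cohort], cal.theta_sd[cohort], size=n)
        cols = {
            name: vm.sample(theta, cohort, rng) for name, vm in cal.maps.items()
        }
        male = rng.random(n) < P_MALE[cohort]
        for i in range(n):
            sid += 1
            pid = f"S{sid:03d}"
            prof = SubjectProfile(
                id=pid,
                cohort=cohort,
                theta=float(theta[i]),
                age=float(cols["age"][i]),
                education=float(cols["education"][i]),
                sex="M" if male[i] else "F",
                height=float(cols["height"][i]),
                weight=float(cols["weight"][i]),
                gait_speed=float(np.clip(cols["gait_speed_habitual"][i], 0.25, 2.45)),
                cadence=float(cols["cadence"][i]),
                turn_peak_velocity=float(cols["turn_peak_velocity"][i]),
                stw_duration=float(cols["stw_duration"][i]),
                sit_duration=float(cols["sit_duration"][i]),
            )
            profiles.append(prof)
            thetas.append(prof.theta)
            cbms_vals.append(float(cols["cbms"][i]))
            rows.append(
                {
                    "subject_id": pid,
                    "cohort": cohort,
                    "sex": prof.sex,
                    "age": prof.age,
                    "education": prof.education,
                    "height": prof.height,
                    "weight": prof.weight,
                    "bmi": prof.bmi,
                    "tug_s": float(cols["tug_s"][i]),
                    "gait_speed_habitual": float(cols["gait_speed_habitual"][i]),
                    "gait_speed_fast": float(cols["gait_speed_fast"][i]),
                    "sppb": float(cols["sppb"][i]),
                    "cst30": float(cols["cst30"][i]),
                    "lbs8": float(cols["lbs8"][i]),
                    "sfesi": float(cols["sfesi"][i]),
                }
            )
    table = pd.DataFrame(rows).set_index("subject_id") if rows else pd.DataFrame(
        columns=["cohort", "sex", "age", "education", "height", "weight", "bmi",
                 "tug_s", "gait_speed_habitual", "gait_speed_fast", "sppb",
                 "cst30", "lbs8", "sfesi"]
    )
    idx = table.index
    cbms = pd.Series(cbms_vals, index=idx, name="cbms")
    truth = CohortTruth(pd.Series(thetas, index=idx, name="theta"), cal, cbms)
    return profiles, table, cbms, truth


# ---------------------------------------------------------------------------
# signal primitives
# ---------------------------------------------------------------------------

def _minimum_jerk_acc(t: np.ndarray, t0: float, T: float, D: float) -> np.ndarray:
    """Acceleration of a minimum-jerk displacement D over [t0, t0+T]."""
    tau = (t - t0) / T
    m = (tau >= 0) & (tau <= 1)
    out = np.zeros_like(t)
    x = tau[m]
    out[m] = D / T**2 * (60 * x - 180 * x**2 + 120 * x**3)
    return out


def _raised_cosine(t: np.ndarray, t0: float, T: float, peak: float) -> np.ndarray:
    """Bell pulse peak/2*(1-cos(2*pi*tau)) on [t0, t0+T]; integral peak*T/2."""
    tau = (t - t0) / T
    m = (tau >= 0) & (tau <= 1)
    out = np.zeros_like(t)
    out[m] = peak / 2.0 * (1 - np.cos(2 * np.pi * tau[m]))
    return out


def _sin_burst(
    t: np.ndarray, t0: float, t1: float, freq: float, amp: float, taper: float = 0.12
) -> np.ndarray:
    """Sinusoid amp*sin(2*pi*freq*(t-t0)) on [t0, t1) with cosine edge tapers."""
    m = (t >= t0) & (t < t1)
    out = np.zeros_like(t)
    x = t[m]
    sig = amp * np.sin(2 * np.pi * freq * (x - t0))
    w = np.ones_like(x)
    rise = (x - t0) < taper
    fall = (t1 - x) < taper
    w[rise] = 0.5 * (1 - np.cos(np.pi * (x[rise] - t0) / taper))
    w[fall] = 0.5 * (1 - np.cos(np.pi * (t1 - x[fall]) / taper))
    out[m] = sig * w
    return out


def turn_boundary_offset(peak: float, duration: float) -> float:
    """Time from pulse support edge to the conventional turn boundary."""
    level = max(TURN_BOUNDARY_FLOOR, TURN_BOUNDARY_FRAC * peak)
    tau = math.acos(1 - 2 * level / peak) / (2 * math.pi)
    return tau * duration


def simulate_trial(
    profile: SubjectProfile,
    repetition: int = 0,
    seed: int = 0,
    noise_acc_sd: float = NOISE_ACC_SD,
    noise_gyro_sd: float = NOISE_GYRO_SD,
    jitter: float = REPETITION_JITTER,
    rate: float = 100.0,
):
    """Simulate one TUG repetition; returns ``(ImuRecording, GroundTruth)``.

    ``seed`` and ``repetition`` jointly seed the per-repetition random
    stream (kinematic jitter and sensor noise).
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(repetition)])
    jf = np.exp(rng.normal(0.0, jitter, size=5))
    speed = profile.gait_speed * jf[0]
    cadence = profile.cadence * jf[1]
    peak = profile.turn_peak_velocity * jf[2]
    d_stw = profile.stw_duration * jf[3]
    d_sit = profile.sit_duration * jf[4]
    if min(speed, cadence, peak, d_stw, d_sit) <= 0:
        raise ValueError("kinematic parameters must be positive")

    t_turn = 360.0 / peak  # raised cosine: angle = peak * T / 2 = 180 deg
    off = turn_boundary_offset(peak, t_turn)
    walk_t = WALK_DISTANCE / speed  # conventional walk-leg duration

    lead = tail = 2.5
    stw_start = lead
    walk1_sig_start = stw_start + d_stw
    first_step = walk1_sig_start + 0.25 / cadence
    ft_pulse_start = first_step + walk_t - off
    ft_pulse_end = ft_pulse_start + t_turn
    # walk-back sized so the conventional W2 interval is exactly walk_t
    tts_pulse_start = (ft_pulse_end - off) + walk_t - off
    tts_pulse_end = tts_pulse_start + t_turn
    sit_start = tts_pulse_end - 0.5 * d_sit
    sit_end = tts_pulse_end + 0.5 * d_sit
    total = sit_end + tail

    n = int(round(total * rate)) + 1
    t = np.arange(n) / rate
    acc = np.zeros((n, 3))
    gyro = np.zeros((n, 3))

    # --- sit-to-walk: forward minimum-jerk displacement + pitch pulse
    acc[:, 0] += _minimum_jerk_acc(t, stw_start, d_stw, 0.30)
    gyro[:, 1] += _raised_cosine(t, stw_start, d_stw, 50.0)

    # --- walking oscillations (both legs)
    step_times: list[float] = []
    for w0, w1 in ((walk1_sig_start, ft_pulse_start), (ft_pulse_end, tts_pulse_start)):
        acc[:, 2] += _sin_burst(t, w0, w1, cadence, 1.2)
        acc[:, 0] += _sin_burst(t, w0, w1, cadence, 0.8)
        gyro[:, 2] += _sin_burst(t, w0, w1, cadence, 12.0)
        gyro[:, 1] += _sin_burst(t, w0, w1, cadence, 15.0)
        gyro[:, 0] += _sin_burst(t, w0, w1, cadence / 2.0, 8.0)
        k = 0
        while (st := w0 + (k + 0.25) / cadence) < w1:
            step_times.append(st)
            k += 1

    # --- turns: yaw pulses with attenuated stepping inside
    gyro[:, 2] += _raised_cosine(t, ft_pulse_start, t_turn, peak)
    gyro[:, 2] += _raised_cosine(t, tts_pulse_start, t_turn, -peak)
    turn_cadence = 0.85 * cadence
    for p0, p1 in ((ft_pulse_start, ft_pulse_end), (tts_pulse_start, tts_pulse_end)):
        acc[:, 2] += _sin_burst(t, p0, p1, turn_cadence, 0.8)
        k = 0
        while (st := p0 + (k + 0.25) / turn_cadence) < p1:
            step_times.append(st)
            k += 1

    # --- sit-down: pitch pulse + backward minimum-jerk displacement
    gyro[:, 1] += _raised_cosine(t, sit_start, d_sit, -40.0)
    acc[:, 0] += _minimum_jerk_acc(t, sit_start, d_sit, -0.30)

    acc[:, 2] += GRAVITY
    if noise_acc_sd > 0:
        acc += rng.normal(0.0, noise_acc_sd, size=acc.shape)
    if noise_gyro_sd > 0:
        gyro += rng.normal(0.0, noise_gyro_sd, size=gyro.shape)

    step_times = np.sort(np.asarray(step_times))
    gt = GroundTruth(
        boundaries={
            "stw_start": stw_start,
            "stw_end": first_step,
            "ft_start": ft_pulse_start + off,
            "ft_end": ft_pulse_end - off,
            "tts_start": tts_pulse_start + off,
            "tts_turn_end": tts_pulse_end - off,
            "sit_end": sit_end,
        },
        step_times=step_times,
        turn_supports=[(ft_pulse_start, ft_pulse_end), (tts_pulse_start, tts_pulse_end)],
        turn_peaks=(peak, peak),
        turn_angles=(180.0, -180.0),
    )
    rec = ImuRecording(t, acc, gyro, nominal_rate=rate)
    return rec, gt


def simulate_session(
    profile: SubjectProfile,
    seed: int = 0,
    n_repetitions: int = 5,
    rest: float = 30.0,
    noise_acc_sd: float = NOISE_ACC_SD,
    noise_gyro_sd: float = NOISE_GYRO_SD,
    jitter: float = REPETITION_JITTER,
    rate: float = 100.0,
):
    """Concatenate repetitions separated by quiet-sitting rests.

    Returns ``(ImuRecording, list[GroundTruth])`` with ground-truth times
    on the session time axis.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 99991])
    segs_t, segs_acc, segs_gyro = [], [], []
    truths: list[GroundTruth] = []
    offset = 0.0
    dt = 1.0 / rate
    for r in range(n_repetitions):
        rec, gt = simulate_trial(
            profile, repetition=r, seed=seed,
            noise_acc_sd=noise_acc_sd, noise_gyro_sd=noise_gyro_sd,
            jitter=jitter, rate=rate,
        )
        segs_t.append(rec.t + offset)
        segs_acc.append(rec.acc)
        segs_gyro.append(rec.gyro)
        truths.append(gt.shifted(offset))
        offset += rec.duration + dt
        if r < n_repetitions - 1:
            n_rest = int(round(rest * rate))
            tr = np.arange(n_rest) / rate
            acc = rng.normal(0.0, noise_acc_sd, size=(n_rest, 3)) if noise_acc_sd > 0 \
                else np.zeros((n_rest, 3))
            acc[:, 2] += GRAVITY
            gy = rng.normal(0.0, noise_gyro_sd, size=(n_rest, 3)) if noise_gyro_sd > 0 \
                else np.zeros((n_rest, 3))
            segs_t.append(tr + offset)
            segs_acc.append(acc)
            segs_gyro.append(gy)
            offset += n_rest * dt
    rec = ImuRecording(
        np.concatenate(segs_t),
        np.concatenate(segs_acc),
        np.concatenate(segs_gyro),
        nominal_rate=rate,
    )
    return rec, truths


#: Default latent-component response weights and X-side score scales of
#: :func:`simulate_feature_table`.  The decreasing scales make successive
#: components progressively low-variance directions of X that still carry
#: response signal, so a PLS fit genuinely needs ``k_true`` components
#: (with equal scales a single covariance direction would absorb all of
#: the response signal).
FEATURE_TABLE_WEIGHTS = (3.5, 3.0, 2.8, 1.5, 1.0, 0.7)
FEATURE_TABLE_SCALES = (3.0, 1.0, 0.35, 0.2, 0.12, 0.08)


def simulate_feature_table(
    n: int,
    m: int,
    k_true: int,
    noise_sd: float = 0.3,
    seed: int = 0,
    component_weights: np.ndarray | None = None,
    loading_scales: np.ndarray | None = None,
    response_r2: float = 0.85,
):
    """Latent-factor feature table X = T P' + E, Y = T c + e.

    ``T`` has ``k_true`` exactly orthogonal columns of unit variance; the
    columns of ``P`` are scaled by ``loading_scales`` so the latent
    components contribute unequal X variance; the response noise is sized
    so the generating R^2 equals ``response_r2``.  Returns
    ``(FeatureTable, truth_dict)``.
    """
    from .plsr import FeatureTable

    if k_true > min(n, m):
        raise ValueError("k_true must not exceed min(n, m)")
    if k_true > len(FEATURE_TABLE_WEIGHTS) and component_weights is None:
        raise ValueError(f"supply component_weights for k_true > {len(FEATURE_TABLE_WEIGHTS)}")
    rng = np.random.default_rng(seed)
    G = rng.normal(size=(n, k_true))
    G -= G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    T = Q[:, :k_true] * math.sqrt(n)
    c = (np.asarray(FEATURE_TABLE_WEIGHTS[:k_true]) if component_weights is None
         else np.asarray(component_weights, dtype=float))
    s = (np.asarray(FEATURE_TABLE_SCALES[:k_true]) if loading_scales is None
         else np.asarray(loading_scales, dtype=float))
    if c.shape != (k_true,) or s.shape != (k_true,):
        raise ValueError("component_weights/loading_scales must have length k_true")
    P = rng.normal(size=(m, k_true)) * s
    X = T @ P.T + rng.normal(0.0, noise_sd, size=(n, m))
    signal_var = float(np.sum(c**2))
    sigma_e = math.sqrt(signal_var * (1 - response_r2) / response_r2) if response_r2 < 1 else 0.0
    y = T @ c + rng.normal(0.0, sigma_e, size=n)
    names = [f"f{j:03d}" for j in range(m)]
    ids = [f"S{i:03d}" for i in range(n)]
    table = FeatureTable(
        pd.DataFrame(X, columns=names, index=ids),
        pd.Series(y, index=ids, name="y"),
    )
    truth = {"T": T, "P": P, "weights": c, "scales": s,
             "sigma_e": sigma_e, "r2": response_r2}
    return table, truth


def write_cohort(
    out_dir: str | Path,
    n_community: int,
    n_outpatient: int,
    seed: int,
    write_logs: bool = True,
    **session_kwargs,
) -> Path:
    """Simulate a cohort and write TXT logs plus CSV tables to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles, table, cbms, truth = simulate_cohort(n_community, n_outpatient, seed)
    table.to_csv(out / "clinical.csv")
    cbms.to_frame().to_csv(out / "cbms.csv")
    gt_rows = []
    for i, prof in enumerate(profiles):
        rec, gts = simulate_session(prof, seed=seed + 1000 + i, **session_kwargs)
        if write_logs:
            write_log(rec, out / f"{prof.id}.txt")
        for r, gt in enumerate(gts):
            row = {"subject_id": prof.id, "repetition": r}
            row.update(gt.boundaries)
            row["n_steps"] = len(gt.step_times)
            row["turn_peak"] = gt.turn_peaks[0]
            gt_rows.append(row)
    pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)
    truth.theta.to_frame().to_csv(out / "theta.csv")
    return out
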