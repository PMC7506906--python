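"""Reading, resampling and axis alignment of smartphone IMU logs.

Log dialect
-----------
Plain text, one sample per line, header/comment lines start with ``#``.
Columns, whitespace- or comma-separated::

    t_ns  ax  ay  az  gx  gy  gz

``t_ns`` is an integer nanosecond timestamp; acceleration is in m/s^2,
angular velocity in deg/s.  On reading, timestamps are converted to
seconds from the start of the recording.  Channel values are checked
against the sensor ranges (accelerometer +/-4 g, gyroscope +/-500 deg/s)
and clipped with a warning when exceeded.

Axis convention: after :func:`align_axes`, column 0 is anterior-posterior
(AP), column 1 mediolateral (ML) and column 2 vertical (V), for both the
accelerometer and the gyroscope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    IntegrityError,
    LogParseError,
)

#: Sensor full-scale ranges of the target device.
ACC_RANGE = 4 * 9.80665  # m/s^2 (+/- 4 g)
GYRO_RANGE = 500.0  # deg/s

AP, ML, V = 0, 1, 2


@dataclass(frozen=True)
class AxisMap:
    """Signed permutation mapping device axes onto anatomical AP/ML/V axes.

    ``perm[i]`` is the device-column index feeding anatomical axis ``i``
    and ``signs[i]`` its sign.  Example: ``AxisMap.from_tokens("+y,-x,+z")``
    reads AP from +y of the device, ML from -x and V from +z.
    """

    perm: tuple[int, int, int] = (0, 1, 2)
    signs: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        if sorted(self.perm) != [0, 1, 2] or any(s not in (-1, 1) for s in self.signs):
            raise ConfigurationError(
                f"axis map must be a signed permutation, got perm={self.perm} "
                f"signs={self.signs}"
            )

    @classmethod
    def identity(cls) -> "AxisMap":
        return cls()

    @classmethod
    def from_tokens(cls, spec: str) -> "AxisMap":
        """Parse a map like ``"+y,-x,+z"`` (anatomical order AP, ML, V)."""
        names = {"x": 0, "y": 1, "z": 2}
        tokens = [t.strip().lower() for t in spec.split(",")]
        if len(tokens) != 3:
            raise ConfigurationError(f"axis map needs 3 tokens, got {spec!r}")
        perm, signs = [], []
        for tok in tokens:
            sign = 1
            if tok and tok[0] in "+-":
                sign = -1 if tok[0] == "-" else 1
                tok = tok[1:]
            if tok not in names:
                raise ConfigurationError(f"bad axis token {tok!r} in {spec!r}")
            perm.append(names[tok])
            signs.append(sign)
        return cls(tuple(perm), tuple(signs))

    def inverse(self) -> "AxisMap":
        perm = [0, 0, 0]
        signs = [1, 1, 1]
        for anat, (dev, s) in enumerate(zip(self.perm, self.signs)):
            perm[dev] = anat
            signs[dev] = s
        return AxisMap(tuple(perm), tuple(signs))

    def apply(self, arr: np.ndarray) -> np.ndarray:
        """Apply the map to an (n, 3) channel array."""
        return arr[:, self.perm] * np.asarray(self.signs, dtype=float)


@dataclass
class ImuRecording:
    """One inertial recording: timestamps plus triaxial acc and gyro.

    Attributes
    ----------
    t : seconds from session start, strictly increasing.
    acc : (n, 3) acceleration in m/s^2.
    gyro : (n, 3) angular velocity in deg/s.
    nominal_rate : sampling rate in Hz after resampling, else None.
    axis_map : the map that has been applied to bring the channels into
        anatomical AP/ML/V order (identity for raw device-frame data).
    """

    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    nominal_rate: float | None = None
    axis_map: AxisMap = field(default_factory=AxisMap.identity)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float).reshape(len(self.t), 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(len(self.t), 3)
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise IntegrityError("timestamps are not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    @property
    def fs(self) -> float:
        """Sampling rate: nominal if set, else median of timestamp spacing."""
        if self.nominal_rate is not None:
            return float(self.nominal_rate)
        if len(self.t) < 2:
            raise InsufficientDataError("cannot infer rate from < 2 samples")
        return float(1.0 / np.median(np.diff(self.t)))

    def slice_time(self, start: float, end: float) -> "ImuRecording":
        """Return the sub-recording with start <= t < end."""
        m = (self.t >= start) & (self.t < end)
        return ImuRecording(self.t[m], self.acc[m], self.gyro[m],
                            self.nominal_rate, self.axis_map)


def read_log(path: str | Path) -> ImuRecording:
    """Parse a TXT sensor log into a device-frame recording.

    Raises :class:`LogParseError` naming the offending line for malformed
    input and :class:`IntegrityError` for non-monotone timestamps.
    Out-of-range channel values are clipped with a single warning that
    reports the count.
    """
    path = Path(path)
    t_ns: list[int] = []
    chans: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 7:
                raise LogParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                t_ns.append(int(parts[0]))
                chans.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise LogParseError(f"{path.name}:{lineno}: {exc}") from exc
    if not t_ns:
        raise LogParseError(f"{path.name}: no data lines")
    t_arr = np.asarray(t_ns, dtype=np.int64)
    if np.any(np.diff(t_arr) <= 0):
        raise IntegrityError(f"{path.name}: timestamps not strictly increasing")
    t = (t_arr - t_arr[0]) / 1e9
    data = np.asarray(chans, dtype=float)
    acc, gyro = data[:, :3], data[:, 3:]
    n_clip = int(np.sum(np.abs(acc) > ACC_RANGE) + np.sum(np.abs(gyro) > GYRO_RANGE))
    if n_clip:
        warnings.warn(
            f"{path.name}: {n_clip} samples outside sensor range were clipped",
            stacklevel=2,
        )
        acc = np.clip(acc, -ACC_RANGE, ACC_RANGE)
        gyro = np.clip(gyro, -GYRO_RANGE, GYRO_RANGE)
    return ImuRecording(t, acc, gyro)


def write_log(rec: ImuRecording, path: str | Path, t0_ns: int = 0) -> None:
    """Write a recording in the TXT log dialect (inverse of :func:`read_log`)."""
    path = Path(path)
    t_ns = np.round(rec.t * 1e9).astype(np.int64) + t0_ns
    with open(path, "w") as fh:
        fh.write("# t_ns ax ay az gx gy gz\n")
        for i in range(len(rec)):
            vals = " ".join(f"{v:.9g}" for v in (*rec.acc[i], *rec.gyro[i]))
            fh.write(f"{t_ns[i]} {vals}\n")


def resample(rec: ImuRecording, rate: float = 100.0) -> ImuRecording:
    """Linearly interpolate all channels onto a uniform grid at ``rate`` Hz.

    The grid runs from the first to the last timestamp inclusive (when the
    span is an exact multiple of the sample period).
    """
    if len(rec) < 2:
        raise InsufficientDataError("resampling needs at least 2 samples")
    span = rec.t[-1] - rec.t[0]
    n = int(np.floor(span * rate + 1e-9)) + 1
    grid = rec.t[0] + np.arange(n) / rate
    acc = np.column_stack([np.interp(grid, rec.t, rec.acc[:, j]) for j in range(3)])
    gyro = np.column_stack([np.interp(grid, rec.t, rec.gyro[:, j]) for j in range(3)])
    return ImuRecording(grid, acc, gyro, nominal_rate=rate, axis_map=rec.axis_map)


def align_axes(rec: ImuRecording, axis_map: AxisMap) -> ImuRecording:
    """Reorder/sign channels so column 0=AP, 1=ML, 2=V for both sensors."""
    return replace(
        rec,
        acc=axis_map.apply(rec.acc),
        gyro=axis_map.apply(rec.gyro),
        axis_map=axis_map,
    )
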