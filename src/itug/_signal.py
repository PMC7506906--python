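"""Shared low-level signal helpers (zero-phase filters, moving statistics)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal


def lowpass(x: np.ndarray, fs: float, fc: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass."""
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def bandpass(
    x: np.ndarray, fs: float, f_lo: float, f_hi: float, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    sos = signal.butter(order, [f_lo, f_hi], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def moving_sd(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving standard deviation with reflected edges."""
    window = max(int(window), 2)
    m1 = ndimage.uniform_filter1d(x, window, mode="reflect")
    m2 = ndimage.uniform_filter1d(x * x, window, mode="reflect")
    return np.sqrt(np.maximum(m2 - m1 * m1, 0.0))


def runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where a boolean mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))
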