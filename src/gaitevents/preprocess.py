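"""Raw acceleration to smoothed jerk: the signal chain all detection runs on.

The chain is: zero-phase high-pass per axis (drift / gravity removal), composite
acceleration magnitude for walking-onset detection, backward-difference jerk
magnitude, and a causal trailing moving average that suppresses the small
intra-burst jerk peaks so each gait event contributes one dominant peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "AccelTrace",
    "JerkTrace",
    "OnsetResult",
    "highpass_accel",
    "composite_acceleration",
    "detect_onset",
    "jerk_magnitude",
    "moving_average",
]


@dataclass(frozen=True)
class AccelTrace:
    """Timestamped tri-axial acceleration in g.

    ``t`` must be uniform with spacing ``1/fs`` (within 1 µs); all axes share
    one length of at least 2 samples.
    """

    fs: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = len(self.t)
        if n < 2:
            raise ValueError("AccelTrace needs at least 2 samples")
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"axis {name} length differs from time vector")
        dt = np.diff(np.asarray(self.t, dtype=float))
        if np.any(dt <= 0) or np.any(np.abs(dt - 1.0 / self.fs) > 1e-6):
            raise ValueError("time vector must increase uniformly at 1/fs")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def axes(self) -> np.ndarray:
        """(n, 3) array of the three axes."""
        return np.column_stack([self.ax, self.ay, self.az])

    @classmethod
    def from_array(cls, arr: np.ndarray, fs: float) -> "AccelTrace":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("expected an (n, 3) acceleration array")
        t = np.arange(arr.shape[0]) / fs
        return cls(fs=fs, t=t, ax=arr[:, 0], ay=arr[:, 1], az=arr[:, 2])


@dataclass(frozen=True)
class JerkTrace:
    """Smoothed jerk magnitude J(n) in g/s, non-negative, same length as its source."""

    fs: float
    J: np.ndarray
    m: int

    def __post_init__(self):
        if np.any(np.asarray(self.J) < 0):
            raise ValueError("smoothed jerk must be non-negative")

    def __len__(self) -> int:
        return len(self.J)


@dataclass(frozen=True)
class OnsetResult:
    """Walking-onset index (first threshold crossing), absent when never crossed."""

    n_start: int | None
    threshold_used: float


def highpass_accel(trace: AccelTrace, cutoff: float = 0.5, order: int = 2) -> AccelTrace:
    """Zero-phase Butterworth high-pass of each axis.

    Applied forward and backward (``sosfiltfilt``), so the effective magnitude
    response is the squared single-pass response and the phase is zero.

    Raises
    ------
    ValueError
        If the trace is too short for a stable forward-backward filter
        (fewer than ``3 * order + 1`` samples).
    """
    min_len = 3 * order + 1
    if len(trace) < min_len:
        raise ValueError(
            f"trace has {len(trace)} samples; zero-phase order-{order} filtering "
            f"needs at least {min_len}"
        )
    sos = signal.butter(order, cutoff, btype="highpass", fs=trace.fs, output="sos")
    filtered = [signal.sosfiltfilt(sos, np.asarray(a, dtype=float)) for a in (trace.ax, trace.ay, trace.az)]
    return AccelTrace(fs=trace.fs, t=trace.t, ax=filtered[0], ay=filtered[1], az=filtered[2])


def composite_acceleration(trace: AccelTrace) -> np.ndarray:
    """Euclidean magnitude sqrt(ax^2 + ay^2 + az^2), element-wise, in g."""
    return np.sqrt(
        np.asarray(trace.ax, dtype=float) ** 2
        + np.asarray(trace.ay, dtype=float) ** 2
        + np.asarray(trace.az, dtype=float) ** 2
    )


def detect_onset(cacc: np.ndarray, th1: float = 1.0) -> OnsetResult:
    """First sample where the composite acceleration exceeds ``th1`` (strictly).

    An absent onset (the subject never started walking) is a valid result,
    not an error.
    """
    above = np.flatnonzero(np.asarray(cacc) > th1)
    n_start = int(above[0]) if above.size else None
    return OnsetResult(n_start=n_start, threshold_used=th1)


def jerk_magnitude(trace: AccelTrace) -> np.ndarray:
    """Jerk magnitude in g/s from backward first differences.

    Per axis ``da/dt ~ (a[n] - a[n-1]) * fs`` (causal), then the Euclidean
    magnitude across the three axes.  Sample 0 is defined as 0 so length is
    preserved.
    """
    if len(trace) < 2:
        raise ValueError("jerk needs at least 2 samples")
    d = np.diff(trace.axes, axis=0) * trace.fs
    mag = np.sqrt(np.sum(d**2, axis=1))
    return np.concatenate([[0.0], mag])


def moving_average(jerk: np.ndarray, m: int = 30, fs: float = 148.15) -> JerkTrace:
    """Causal trailing mean over the last ``m`` samples.

    During warm-up (``n < m - 1``) the mean is taken over the samples seen so
    far, avoiding the startup spike a zero-padded division by ``m`` would
    produce.
    """
    if m < 1:
        raise ValueError(f"smoothing window must be >= 1 sample, got {m}")
    x = np.asarray(jerk, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - m + 1, 0)
    out = (csum[idx + 1] - csum[lo]) / (idx - lo + 1)
    return JerkTrace(fs=fs, J=out, m=m)


def smoothed_jerk(trace: AccelTrace, m: int = 30) -> JerkTrace:
    """Convenience: jerk_magnitude followed by moving_average."""
    return moving_average(jerk_magnitude(trace), m=m, fs=trace.fs)
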