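"""Reference gait events from heel/toe force-sensitive-resistor (FSR) traces.

Heel strikes are read off the heel channel as upward crossings of 5% of its
observation-window maximum (loading onset); toe offs off the toe channel as
downward crossings of 95% of its window maximum (a 5% decrease from maximum,
i.e. unloading onset).  Thresholds are relative, so the extraction is invariant
to channel gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventKind, GaitEvent

__all__ = ["FsrTrace", "detect_fsr_events"]


@dataclass(frozen=True)
class FsrTrace:
    """Heel and toe force channels (arbitrary units, non-negative, equal length)."""

    fs: float
    heel: np.ndarray
    toe: np.ndarray

    def __post_init__(self):
        if len(self.heel) != len(self.toe):
            raise ValueError("heel and toe channels must have equal length")
        if np.any(np.asarray(self.heel) < 0) or np.any(np.asarray(self.toe) < 0):
            raise ValueError("FSR channels must be non-negative")

    def __len__(self) -> int:
        return len(self.heel)


def _crossings(x: np.ndarray, level: float, direction: str) -> list[int]:
    """Sample index at/after each interpolated crossing of ``level``."""
    x = np.asarray(x, dtype=float)
    if direction == "up":
        hits = np.flatnonzero((x[:-1] <= level) & (x[1:] > level))
    else:
        hits = np.flatnonzero((x[:-1] >= level) & (x[1:] < level))
    out = []
    for i in hits:
        # linear interpolation between i and i+1; event index = first sample
        # at/after the crossing instant
        frac = (level - x[i]) / (x[i + 1] - x[i])
        out.append(int(i + np.ceil(frac)) if frac > 0 else int(i))
    return out


def _debounce(idx: list[int], fs: float) -> list[int]:
    """Drop crossings closer than a quarter of the median inter-event interval."""
    if len(idx) < 3:
        return idx
    median_gap = float(np.median(np.diff(idx)))
    refractory = 0.25 * median_gap
    out = [idx[0]]
    for i in idx[1:]:
        if i - out[-1] >= refractory:
            out.append(i)
    return out


def detect_fsr_events(
    fsr: FsrTrace,
    window: tuple[int, int],
    heel_fraction: float = 0.05,
    toe_fraction: float = 0.95,
) -> list[GaitEvent]:
    """Reference HS/TO events from threshold crossings of the FSR channels.

    ``window`` is the observation-window index range ``(start, stop)`` used to
    define the per-channel maximum amplitudes that the relative thresholds
    refer to.  ``toe_fraction=0.95`` reads "5% decrease in the maximum toe
    amplitude" as falling below 95% of the maximum; pass ``0.05`` for the
    alternative "falls below 5% of maximum" reading.
    """
    a, b = window
    heel_ref = float(np.max(np.asarray(fsr.heel)[a:b]))
    toe_ref = float(np.max(np.asarray(fsr.toe)[a:b]))
    if heel_ref <= 0 or toe_ref <= 0:
        raise ValueError("FSR channel has zero amplitude in the observation window")
    hs_idx = _debounce(_crossings(fsr.heel, heel_fraction * heel_ref, "up"), fsr.fs)
    to_idx = _debounce(_crossings(fsr.toe, toe_fraction * toe_ref, "down"), fsr.fs)
    events = [GaitEvent(kind=EventKind.HS, n=i, t=i / fsr.fs) for i in hs_idx]
    events += [GaitEvent(kind=EventKind.TO, n=i, t=i / fsr.fs) for i in to_idx]
    events.sort(key=lambda e: (e.n, e.kind.value))
    return events
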