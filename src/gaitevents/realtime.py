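"""Streaming gait-event detection: a constant-memory per-sample state machine.

After calibration, each incoming smoothed-jerk sample drives a two-phase
machine.  SEARCH watches for a local jerk peak above the baseline gate
``r_b * TH2``; such a peak becomes the starting point and opens a confirmation
wait (default 15 samples, ~100 ms).  During CONFIRM any larger sample restarts
the wait as the new starting point; if the wait expires unbeaten, the peak is a
candidate and must pass two memberships — amplitude above ``r1 *`` the
calibrated mean peak for the expected event kind, and elapsed time since the
previous event above ``r2 *`` the calibrated phase duration (swing before a
heel strike, stance before a toe off).  Accepted candidates are emitted
timestamped at the peak sample; rejected ones are discarded and the machine
returns to SEARCH.  Kinds therefore strictly alternate, anchored at the last
calibration event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .calibration import ThresholdSet
from .events import EventKind, GaitEvent
from .preprocess import JerkTrace

logger = logging.getLogger(__name__)

__all__ = ["Phase", "DetectorState", "step", "run_stream", "StreamingDetector"]


class Phase(Enum):
    SEARCH = "search"
    CONFIRM = "confirm"


@dataclass(frozen=True)
class DetectorState:
    """Immutable per-sample state; ``step`` returns the successor state."""

    thresholds: ThresholdSet
    last_event: GaitEvent
    fs: float
    wait_len: int = 15
    phase: Phase = Phase.SEARCH
    np_idx: int | None = None  # starting-point peak J(n_p)
    np_amp: float = 0.0
    wait_left: int = 0
    # rolling peak tracker (causal local-maximum detection with plateau-first rule)
    prev_val: float = float("-inf")
    rise_idx: int | None = None  # first sample of the current rising plateau
    rise_val: float = float("-inf")
    last_n: int | None = None
    smoothing_m: int = 30

    def __post_init__(self):
        if not (0 <= self.wait_left <= self.wait_len):
            raise ValueError("wait_left out of range")
        if self.phase is Phase.CONFIRM and self.np_idx is None:
            raise ValueError("CONFIRM phase requires a starting-point peak")


def init_state(
    thresholds: ThresholdSet,
    last_event: GaitEvent | None,
    fs: float,
    wait_len: int = 15,
    smoothing_m: int = 30,
) -> DetectorState:
    if last_event is None:
        raise ValueError("streaming detection needs the last calibration event as anchor")
    return DetectorState(
        thresholds=thresholds, last_event=last_event, fs=fs,
        wait_len=wait_len, smoothing_m=smoothing_m,
    )


def _gate(state: DetectorState, n_c: int, amp: float) -> GaitEvent | None:
    """Amplitude and duration memberships for candidate peak J(n_c)."""
    th = state.thresholds
    kind = state.last_event.kind.opposite
    t_c = n_c / state.fs
    if amp <= th.amplitude_gate(kind):
        logger.debug("candidate n=%d rejected: amplitude %.3g below gate", n_c, amp)
        return None
    if t_c - state.last_event.t <= th.duration_gate(kind):
        logger.debug("candidate n=%d rejected: too soon after last %s", n_c, state.last_event.kind.value)
        return None
    return GaitEvent(kind=kind, n=n_c, t=t_c, amplitude=amp)


def step(state: DetectorState, n: int, J_n: float) -> tuple[DetectorState, GaitEvent | None]:
    """Advance one sample; emit a gait event when a candidate passes both gates.

    ``n`` must increase by exactly one call per sample.  The emitted event is
    timestamped at its peak index, so the emission lags the event by the
    confirmation wait; that latency (plus the smoothing group delay) is
    reported on the event.
    """
    if state.last_n is not None and n <= state.last_n:
        raise ValueError(f"non-monotone sample index: {n} after {state.last_n}")

    emitted: GaitEvent | None = None
    new = {"last_n": n}

    # --- causal local-peak tracking (peak known one sample after its plateau ends)
    peak_idx: int | None = None
    peak_amp = 0.0
    rise_idx, rise_val = state.rise_idx, state.rise_val
    if J_n > state.prev_val:
        rise_idx, rise_val = n, J_n
    elif J_n < state.prev_val and rise_idx is not None:
        peak_idx, peak_amp = rise_idx, rise_val  # confirmed local maximum
        rise_idx, rise_val = None, float("-inf")
    new.update(prev_val=J_n, rise_idx=rise_idx, rise_val=rise_val)

    if state.phase is Phase.SEARCH:
        if peak_idx is not None and peak_amp > state.thresholds.r_b * state.thresholds.TH2:
            new.update(phase=Phase.CONFIRM, np_idx=peak_idx, np_amp=peak_amp,
                       wait_left=state.wait_len)
            logger.debug("starting point J(n_p) at n=%d amp=%.3g", peak_idx, peak_amp)
            state2 = replace(state, **new)
            # zero-length wait degenerates to immediate candidacy
            if state.wait_len == 0:
                emitted = _gate(state2, peak_idx, peak_amp)
                new.update(phase=Phase.SEARCH, np_idx=None, np_amp=0.0, wait_left=0)
                if emitted is not None:
                    new.update(last_event=emitted)
    else:  # CONFIRM
        if J_n > state.np_amp:
            # a larger sample restarts the wait with the larger peak
            new.update(np_idx=n, np_amp=J_n, wait_left=state.wait_len)
        else:
            wait_left = state.wait_left - 1
            if wait_left > 0:
                new.update(wait_left=wait_left)
            else:
                # wait expired unbeaten: J(n_p) becomes candidate J(n_c)
                emitted = _gate(state, state.np_idx, state.np_amp)
                new.update(phase=Phase.SEARCH, np_idx=None, np_amp=0.0, wait_left=0)
                if emitted is not None:
                    new.update(last_event=emitted)

    next_state = replace(state, **new)
    if emitted is not None:
        latency = (n - emitted.n) / state.fs + (state.smoothing_m - 1) / (2 * state.fs)
        emitted = replace(emitted, latency_s=latency)
        next_state = replace(next_state, last_event=replace(next_state.last_event, latency_s=latency))
        logger.debug("emitted %s at n=%d (decision at n=%d)", emitted.kind.value, emitted.n, n)
    return next_state, emitted


def run_stream(
    jerk: JerkTrace,
    thresholds: ThresholdSet,
    start: int,
    last_event: GaitEvent | None,
    wait_len: int = 15,
) -> list[GaitEvent]:
    """Fold ``step`` over samples ``start..end`` of a smoothed-jerk trace."""
    state = init_state(thresholds, last_event, fs=jerk.fs,
                       wait_len=wait_len, smoothing_m=jerk.m)
    out: list[GaitEvent] = []
    J = np.asarray(jerk.J, dtype=float)
    for n in range(start, len(J)):
        state, ev = step(state, n, float(J[n]))
        if ev is not None:
            out.append(ev)
    return out


class StreamingDetector:
    """Thin mutable wrapper over the functional ``step`` for sample-at-a-time use."""

    def __init__(self, thresholds: ThresholdSet, last_event: GaitEvent, fs: float,
                 wait_len: int = 15, smoothing_m: int = 30):
        self.state = init_state(thresholds, last_event, fs, wait_len, smoothing_m)

    def update(self, n: int, J_n: float) -> GaitEvent | None:
        self.state, ev = step(self.state, n, J_n)
        return ev
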