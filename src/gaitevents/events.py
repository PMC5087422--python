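"""Gait-event record shared across detection, reference and scoring code."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class EventKind(str, Enum):
    """The two gait events bounding stance: heel strike starts it, toe off ends it."""

    HS = "HS"
    TO = "TO"

    @property
    def opposite(self) -> "EventKind":
        return EventKind.TO if self is EventKind.HS else EventKind.HS


@dataclass(frozen=True)
class GaitEvent:
    """One detected (or ground-truth) gait event.

    Parameters
    ----------
    kind : EventKind
        Heel strike (``HS``) or toe off (``TO``).
    n : int
        Sample index into the trace the event was detected on (0-based, global).
    t : float
        Event time in seconds from trace start.
    amplitude : float
        Smoothed-jerk amplitude ``J(n)`` at the event peak, in g/s.  Zero for
        references (FSR, simulator truth) that carry no jerk amplitude.
    latency_s : float
        Detection latency in seconds (0 for non-streaming sources): how long
        after the physical peak the decision was available.
    """

    kind: EventKind
    n: int
    t: float
    amplitude: float = 0.0
    latency_s: float = 0.0


def validate_alternation(events: list[GaitEvent]) -> bool:
    """True when consecutive events alternate HS/TO."""
    return all(a.kind != b.kind for a, b in zip(events, events[1:]))
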