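"""Observation-window self-calibration.

Runs once per trial on a short window (default 300 samples, ~2 s) starting at
the walking onset: CWT the smoothed jerk, estimate the event/cycle scales,
extract the two band signals x_e / x_c, segment the window at the negative
peaks of x_e, locate one jerk peak per region, classify each as heel strike or
toe off by the sign of x_c, and summarise everything into the threshold set the
streaming detector runs on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from .events import EventKind, GaitEvent
from .preprocess import JerkTrace
from .wavelet import (
    EnergySpectrum,
    MorletParams,
    Scalogram,
    ScaleEstimate,
    cwt_morlet,
    energy_spectrum,
    prior_energy_spectrum,
    scale_delay,
    split_and_refine,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationWindow",
    "EventBand",
    "ThresholdSet",
    "CalibrationError",
    "extract_bands",
    "segment_regions",
    "detect_window_events",
    "compute_thresholds",
    "calibrate_window",
    "local_maxima",
    "local_minima",
]


class CalibrationError(RuntimeError):
    """The observation window could not be calibrated (names what is missing)."""


@dataclass(frozen=True)
class ObservationWindow:
    """A ``window_len``-sample segment of the smoothed jerk starting at ``start``."""

    J: np.ndarray
    fs: float
    start: int

    def __post_init__(self):
        if len(self.J) < 2:
            raise ValueError("observation window too short")

    @property
    def window_len(self) -> int:
        return len(self.J)

    @classmethod
    def from_trace(cls, jerk: JerkTrace, start: int, window_len: int = 300) -> "ObservationWindow":
        if start + window_len > len(jerk):
            raise CalibrationError(
                f"trace ends at sample {len(jerk)}; observation window needs "
                f"[{start}, {start + window_len})"
            )
        return cls(J=np.asarray(jerk.J[start : start + window_len]), fs=jerk.fs, start=start)


@dataclass(frozen=True)
class EventBand:
    """Filtered real-part CWT coefficient rows at the event and cycle scales."""

    x_e: np.ndarray
    x_c: np.ndarray

    def __post_init__(self):
        if len(self.x_e) != len(self.x_c):
            raise ValueError("band signals must share the window length")


@dataclass(frozen=True)
class ThresholdSet:
    """Per-trial calibration output driving the streaming detector.

    ``TH2`` is the jerk baseline (median of J over the window, g/s); ``TH3`` /
    ``TH4`` are the mean heel-strike / toe-off peak amplitudes (g/s); ``T_swin``
    / ``T_std`` the mean swing (TO->HS) and stance (HS->TO) durations (s).  The
    membership fractions gate candidates by baseline (``r_b``), amplitude
    (``r1``) and elapsed time (``r2``).
    """

    TH2: float
    TH3: float
    TH4: float
    T_swin: float
    T_std: float
    r_b: float = 0.8
    r1: float = 0.5
    r2: float = 0.5

    def __post_init__(self):
        if min(self.TH2, self.TH3, self.TH4) < 0:
            raise ValueError("amplitude thresholds must be non-negative")
        if min(self.T_swin, self.T_std) <= 0:
            raise ValueError("phase durations must be positive")
        for name in ("r_b", "r1", "r2"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"membership {name} must be in (0, 1], got {v}")

    def amplitude_gate(self, kind: EventKind) -> float:
        return self.r1 * (self.TH3 if kind is EventKind.HS else self.TH4)

    def duration_gate(self, kind: EventKind) -> float:
        """Minimum elapsed time before an event of ``kind`` (swing before HS)."""
        return self.r2 * (self.T_swin if kind is EventKind.HS else self.T_std)


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a plateau counts once, at its first sample."""
    return _local_extrema(np.asarray(x, dtype=float))


def local_minima(x: np.ndarray) -> np.ndarray:
    return _local_extrema(-np.asarray(x, dtype=float))


def _local_extrema(x: np.ndarray) -> np.ndarray:
    # scipy's find_peaks with plateau handling; left_edges is the plateau start
    peaks, props = signal.find_peaks(x, plateau_size=1)
    return props["left_edges"]


def extract_bands(
    W: Scalogram,
    est: ScaleEstimate,
    cutoff: float = 10.0,
    order: int = 2,
    kind: str = "lowpass",
) -> EventBand:
    """Band signals x_e / x_c: real part of the CWT rows at the posterior scales,
    then a zero-phase Butterworth filter at ``cutoff`` Hz.

    The filter removes residual high-frequency noise, so the default is a
    low-pass; ``kind="highpass"`` is available as an alternative reading.
    """
    if kind not in ("lowpass", "highpass"):
        raise ValueError(f"band filter kind must be lowpass|highpass, got {kind!r}")
    sos = signal.butter(order, cutoff, btype=kind, fs=W.fs, output="sos")
    x_e = signal.sosfiltfilt(sos, np.real(W.row(est.mu_e_hat)))
    x_c = signal.sosfiltfilt(sos, np.real(W.row(est.mu_c_hat)))
    return EventBand(x_e=x_e, x_c=x_c)


def segment_regions(x_e: np.ndarray) -> list[tuple[int, int]]:
    """Split the window at the negative peaks of the event-band signal.

    Negative peaks are strict local minima with value < 0.  With peaks
    ``p1..pk`` the regions are ``[0, p1], [p1, p2], ..., [pk, N-1]``
    (inclusive, boundaries shared).
    """
    x_e = np.asarray(x_e, dtype=float)
    mins = local_minima(x_e)
    neg = mins[x_e[mins] < 0]
    if neg.size == 0:
        raise CalibrationError("no negative peak in the event band; window not calibratable")
    edges = [0, *neg.tolist(), len(x_e) - 1]
    # a negative peak exactly at an endpoint would create an empty region
    edges = sorted(set(edges))
    return list(zip(edges[:-1], edges[1:]))


def _classify_region(x_c: np.ndarray, a: int, b: int) -> EventKind | None:
    """Sign of the largest-|value| local extremum of x_c within [a, b]."""
    seg = np.asarray(x_c[a : b + 1], dtype=float)
    ext = np.concatenate([local_maxima(seg), local_minima(seg)])
    if ext.size == 0:
        return None
    best = ext[np.argmax(np.abs(seg[ext]))]
    return EventKind.HS if seg[best] > 0 else EventKind.TO


def _repair_alternation(events: list[GaitEvent]) -> list[GaitEvent]:
    """Drop the lower-amplitude offender wherever two neighbours share a kind."""
    out: list[GaitEvent] = []
    for ev in events:
        if out and out[-1].kind == ev.kind:
            keep = ev if ev.amplitude > out[-1].amplitude else out[-1]
            dropped = out[-1] if keep is ev else ev
            logger.info(
                "alternation repair: dropping %s at n=%d (amp %.3g) in favour of n=%d",
                dropped.kind.value, dropped.n, dropped.amplitude, keep.n,
            )
            out[-1] = keep
        else:
            out.append(ev)
    return out


def _drop_inconsistent_boundary(events: list[GaitEvent], r1: float) -> list[GaitEvent]:
    """Amplitude-consistency check for the window's first and last events.

    The boundary regions of the observation window are incomplete by
    construction (the window can start or end mid-gap), so their reported
    peak may be spurious.  An event whose amplitude fails the method's own
    amplitude membership — ``r1 *`` the mean peak of the *other* same-kind
    window events — is dropped (logged).  Only boundary events are eligible,
    so alternation is never broken by the drop.
    """
    events = list(events)
    changed = True
    while changed and len(events) > 2:
        changed = False
        for pos in (len(events) - 1, 0):
            ev = events[pos]
            peers = [e.amplitude for i, e in enumerate(events) if e.kind == ev.kind and i != pos]
            if peers and ev.amplitude <= r1 * float(np.mean(peers)):
                logger.info(
                    "boundary %s at n=%d (amp %.3g) fails amplitude membership "
                    "vs same-kind mean %.3g; dropped",
                    ev.kind.value, ev.n, ev.amplitude, float(np.mean(peers)),
                )
                events.pop(pos)
                changed = True
                break
    return events


def detect_window_events(
    win: ObservationWindow, bands: EventBand, r_b: float = 0.8, r1: float = 0.5
) -> list[GaitEvent]:
    """One gait event per x_e region: the jerk peak, classified by the x_c sign.

    The baseline gate ``r_b * median(J)`` — the same reliability gate the
    streaming stage applies to its starting-point peaks — also applies here:
    the boundary regions of the window need not contain a genuine event, and
    an ungated region rule would then report a sub-baseline noise bump as an
    event, corrupting the mean peak amplitudes and the phase anchor.

    Regions whose jerk peak falls below the gate or whose cycle band has no
    local extremum are excluded (logged); non-alternating sequences are
    repaired by dropping the lower-amplitude offender.  Event indices are
    global (window start added); the jerk-argmax tie within a region breaks
    toward the smallest index.
    """
    regions = segment_regions(bands.x_e)
    baseline_gate = r_b * float(np.median(win.J))
    events: list[GaitEvent] = []
    for a, b in regions:
        rel = a + int(np.argmax(win.J[a : b + 1]))
        if win.J[rel] <= baseline_gate:
            logger.info(
                "region [%d, %d] peak %.3g below baseline gate %.3g; excluded",
                a, b, win.J[rel], baseline_gate,
            )
            continue
        kind = _classify_region(bands.x_c, a, b)
        if kind is None:
            logger.info("region [%d, %d] has no cycle-band extremum; excluded", a, b)
            continue
        n = win.start + rel
        ev = GaitEvent(kind=kind, n=n, t=n / win.fs, amplitude=float(win.J[rel]))
        events.append(ev)
    events.sort(key=lambda e: e.n)
    # shared region boundaries can double-report one peak
    deduped = [e for i, e in enumerate(events) if i == 0 or e.n != events[i - 1].n]
    return _drop_inconsistent_boundary(_repair_alternation(deduped), r1)


def compute_thresholds(
    events: list[GaitEvent],
    win: ObservationWindow,
    r_b: float = 0.8,
    r1: float = 0.5,
    r2: float = 0.5,
) -> ThresholdSet:
    """Summarise the window events into the detector's threshold set.

    Raises
    ------
    CalibrationError
        Naming the missing ingredient when the window lacks either event kind
        or either adjacent-pair type.
    """
    hs = [e for e in events if e.kind is EventKind.HS]
    to = [e for e in events if e.kind is EventKind.TO]
    if not hs or not to:
        missing = "HS" if not hs else "TO"
        raise CalibrationError(f"observation window contains no {missing} event")
    swing = [b.t - a.t for a, b in zip(events, events[1:]) if a.kind is EventKind.TO]
    stance = [b.t - a.t for a, b in zip(events, events[1:]) if a.kind is EventKind.HS]
    if not swing:
        raise CalibrationError("no adjacent TO->HS pair in the window (swing time undefined)")
    if not stance:
        raise CalibrationError("no adjacent HS->TO pair in the window (stance time undefined)")
    return ThresholdSet(
        TH2=float(np.median(win.J)),
        TH3=float(np.mean([e.amplitude for e in hs])),
        TH4=float(np.mean([e.amplitude for e in to])),
        T_swin=float(np.mean(swing)),
        T_std=float(np.mean(stance)),
        r_b=r_b,
        r1=r1,
        r2=r2,
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Everything the observation window produced, JSON-serialisable via report()."""

    estimate: ScaleEstimate
    events: list[GaitEvent]
    thresholds: ThresholdSet
    window: ObservationWindow
    E_obs: EnergySpectrum

    def report(self) -> dict:
        return {
            "scales": {
                "tau": self.estimate.tau,
                "s_lambda": self.estimate.s_lambda,
                "mu_e_hat": self.estimate.mu_e_hat,
                "mu_c_hat": self.estimate.mu_c_hat,
            },
            "events": [
                {"kind": e.kind.value, "n": e.n, "t_s": e.t, "amplitude": e.amplitude}
                for e in self.events
            ],
            "thresholds": asdict(self.thresholds),
            "window": {"start": self.window.start, "len": self.window.window_len},
        }


def calibrate_window(
    win: ObservationWindow,
    s_max: int = 241,
    fc: float = 0.8125,
    prior_mu_e: int = 75,
    prior_mu_c: int = 150,
    prior_sigma1: float = 15,
    prior_sigma2: float = 25,
    band_cutoff: float = 10.0,
    band_kind: str = "lowpass",
    r_b: float = 0.8,
    r1: float = 0.5,
    r2: float = 0.5,
) -> CalibrationResult:
    """Full calibration of one observation window (CWT through threshold set)."""
    scales = np.arange(1, s_max + 1)
    W = cwt_morlet(win.J, scales, fs=win.fs, params=MorletParams(fc=fc))
    E_obs = energy_spectrum(W)
    E_prior = prior_energy_spectrum(s_max, prior_mu_e, prior_mu_c, prior_sigma1, prior_sigma2)
    tau = scale_delay(E_prior, E_obs)
    est = split_and_refine(E_obs, tau, mu_e=prior_mu_e, mu_c=prior_mu_c)
    bands = extract_bands(W, est, cutoff=band_cutoff, kind=band_kind)
    events = detect_window_events(win, bands, r_b=r_b, r1=r1)
    thresholds = compute_thresholds(events, win, r_b=r_b, r1=r1, r2=r2)
    logger.info(
        "calibrated window: tau=%d mu_e=%d mu_c=%d, %d events, TH2=%.3g TH3=%.3g TH4=%.3g",
        tau, est.mu_e_hat, est.mu_c_hat, len(events),
        thresholds.TH2, thresholds.TH3, thresholds.TH4,
    )
    return CalibrationResult(estimate=est, events=events, thresholds=thresholds, window=win, E_obs=E_obs)
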