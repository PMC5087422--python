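"""End-to-end trial processing: preprocess -> calibrate -> stream -> score."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .calibration import CalibrationResult, ObservationWindow, calibrate_window
from .config import PipelineConfig
from .evaluation import MatchResult, match_events, prf1, timing_agreement
from .events import EventKind, GaitEvent
from .fsr import FsrTrace, detect_fsr_events
from .preprocess import (
    AccelTrace,
    composite_acceleration,
    detect_onset,
    highpass_accel,
    jerk_magnitude,
    moving_average,
)
from .realtime import run_stream

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline_on_trace", "evaluate_events"]


@dataclass(frozen=True)
class PipelineResult:
    onset: int
    calibration: CalibrationResult
    stream_events: list[GaitEvent]

    @property
    def events(self) -> list[GaitEvent]:
        """Calibration-window events followed by streamed events."""
        return [*self.calibration.events, *self.stream_events]


def run_pipeline_on_trace(accel: AccelTrace, config: PipelineConfig | None = None) -> PipelineResult:
    """Detect gait events on one tri-axial trace (in-memory core of the CLI `run`)."""
    cfg = config or PipelineConfig()
    filtered = highpass_accel(accel, cutoff=cfg.hp_cutoff, order=cfg.hp_order)
    onset = detect_onset(composite_acceleration(filtered), th1=cfg.th1)
    if onset.n_start is None:
        raise RuntimeError(
            f"no walking onset: composite acceleration never exceeded {cfg.th1} g"
        )
    jerk = moving_average(jerk_magnitude(filtered), m=cfg.smooth_m, fs=accel.fs)
    win = ObservationWindow.from_trace(jerk, onset.n_start, cfg.window_len)
    cal = calibrate_window(
        win,
        s_max=cfg.s_max,
        fc=cfg.fc,
        prior_mu_e=cfg.prior_mu_e,
        prior_mu_c=cfg.prior_mu_c,
        prior_sigma1=cfg.prior_sigma1,
        prior_sigma2=cfg.prior_sigma2,
        band_cutoff=cfg.band_filter_cutoff,
        band_kind=cfg.band_filter_kind,
        r_b=cfg.r_b,
        r1=cfg.r1,
        r2=cfg.r2,
    )
    # stream from right after the last calibrated event, not the window end:
    # the detector is causal, and this closes the window-edge dead zone where
    # a peak would otherwise be seen by neither stage
    stream = run_stream(
        jerk,
        cal.thresholds,
        start=cal.events[-1].n + 1,
        last_event=cal.events[-1],
        wait_len=cfg.wait_len,
    )
    return PipelineResult(onset=onset.n_start, calibration=cal, stream_events=stream)


def _drop_last_cycle(reference: list[GaitEvent]) -> float:
    """Scoring cutoff: the start of the reference's last gait cycle (last HS)."""
    hs_times = [e.t for e in reference if e.kind is EventKind.HS]
    return hs_times[-1] if hs_times else float("inf")


def evaluate_events(
    detected: list[GaitEvent],
    reference: list[GaitEvent],
    tolerance: float = 0.4,
    exclude_last_cycle: bool = True,
) -> dict:
    """Accuracy + timing report of a detected stream against a reference stream.

    The reference's last gait cycle (from its final heel strike onward) is
    excluded from scoring by default, since trial-end deceleration makes the
    final cycle atypical; the cutoff applies to both streams.
    """
    cutoff = _drop_last_cycle(reference) if exclude_last_cycle else float("inf")
    ref = [e for e in reference if e.t < cutoff]
    det = [e for e in detected if e.t < cutoff]
    match = match_events(det, ref, tolerance=tolerance)
    report: dict = {"tolerance_s": tolerance, "n_reference": len(ref), "n_detected": len(det)}
    for label, kind in (("HS", EventKind.HS), ("TO", EventKind.TO), ("pooled", None)):
        tp, fp, fn = match.counts(kind)
        acc = prf1(tp, fp, fn)
        report[label] = {"TP": tp, "FP": fp, "FN": fn, "P": acc.P, "R": acc.R, "F1": acc.F1}
    if len(match.pairs) >= 2:
        tr = timing_agreement(match)
        report["timing_ms"] = {
            "MD": tr.MD, "MD_SD": tr.MD_SD, "AMD": tr.AMD, "AMD_SD": tr.AMD_SD,
            "loa": [tr.loa_low, tr.loa_high], "ci95": list(tr.ci95),
        }
    return report


def membership_sweep(
    accel: AccelTrace,
    reference: list[GaitEvent],
    config: PipelineConfig | None = None,
    grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
) -> list[dict]:
    """Pooled F1 over an (r1, r2) membership grid against a reference stream.

    One row per grid point: {"r1", "r2", "F1_HS", "F1_TO", "F1"}.  Used to
    check the stability plateau around the default r1 = r2 = 0.5.
    """
    from dataclasses import replace as _replace

    cfg = config or PipelineConfig()
    rows = []
    for r1 in grid:
        for r2 in grid:
            try:
                res = run_pipeline_on_trace(accel, _replace(cfg, r1=r1, r2=r2))
                rep = evaluate_events(res.events, reference, tolerance=cfg.match_tolerance)
                rows.append({"r1": r1, "r2": r2, "F1_HS": rep["HS"]["F1"],
                             "F1_TO": rep["TO"]["F1"], "F1": rep["pooled"]["F1"]})
            except RuntimeError as exc:
                logger.warning("sweep point r1=%.1f r2=%.1f failed: %s", r1, r2, exc)
                rows.append({"r1": r1, "r2": r2, "F1_HS": 0.0, "F1_TO": 0.0, "F1": 0.0})
    return rows


def fsr_reference_events(fsr: FsrTrace, result: PipelineResult, config: PipelineConfig | None = None) -> list[GaitEvent]:
    """FSR reference events using the pipeline's observation window for the amplitude refs."""
    cfg = config or PipelineConfig()
    window = (result.onset, result.onset + cfg.window_len)
    return detect_fsr_events(fsr, window, toe_fraction=cfg.toe_fraction)
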