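"""Synthetic gait trials: tri-axial acceleration + FSR traces with ground truth.

Each trial is a quiet lead-in (gravity plus sensor noise) followed by strides
at a jittered cadence.  Every stride places two short damped-sinusoid
acceleration bursts — a heel-strike impact at the stride start and a smaller
toe-off push-off at the end of stance — distributed across the three axes with
fixed direction cosines.  FSR heel/toe channels are trapezoidal contact pulses
keyed to the same event times: heel loading starts at the heel strike, toe
unloading completes at the toe off.  The programmed event times are returned as
ground truth, which makes the whole detection chain testable without recorded
walking data.

The waveforms are stylised: real leg-worn accelerometry carries soft-tissue
resonance, inter-stride waveform variability and orientation drift that these
damped sinusoids do not model, so a perfect score here shows the detection
logic is correct, not that it is robust to every real-world artefact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import EventKind, GaitEvent
from .fsr import FsrTrace
from .preprocess import AccelTrace

__all__ = ["GaitProfile", "SyntheticTrial", "generate_trial", "terrain_presets"]

# fixed unit direction cosines of the two burst types across (x, y, z);
# chosen oblique so no axis is degenerate and the two bursts are distinguishable
_HS_DIR = np.array([0.62, 0.53, 0.58])
_TO_DIR = np.array([0.33, 0.75, 0.57])
_HS_DIR = _HS_DIR / np.linalg.norm(_HS_DIR)
_TO_DIR = _TO_DIR / np.linalg.norm(_TO_DIR)


@dataclass(frozen=True)
class GaitProfile:
    """Parameters of the simulated walk.

    ``cadence`` is in strides (full gait cycles) per second; ``swing_frac`` the
    fraction of the cycle spent in swing, so stance lasts
    ``(1 - swing_frac) / cadence`` seconds.  ``hs_amp`` / ``to_amp`` are the
    peak accelerations (g) of the impact and push-off bursts, which oscillate
    at ``burst_freq`` Hz with exponential decay ``burst_decay`` s.

    Additive noise of standard deviation ``noise_sigma`` g per axis models
    soft-tissue and motion artefact, which dominates leg-worn accelerometry at
    this magnitude and is band-limited: Gaussian noise is zero-phase low-passed
    at ``noise_band`` Hz and rescaled to ``noise_sigma``.  (Full-band white
    noise at the same sigma would, once differentiated at the sampling rate,
    bury the jerk bursts the detector keys on — a regime real recordings do
    not exhibit.)  Set ``noise_band`` to None for unfiltered white noise.
    """

    cadence: float = 0.9
    swing_frac: float = 0.38
    hs_amp: float = 3.0
    to_amp: float = 2.0
    burst_freq: float = 8.0
    burst_decay: float = 0.08
    noise_sigma: float = 0.05
    noise_band: float | None = 15.0
    cadence_jitter: float = 0.02
    lead_in: float = 2.0
    fs: float = 148.15
    # FSR trapezoid geometry (seconds / relative units)
    fsr_rise: float = 0.08
    fsr_heel_level: float = 10.0
    fsr_toe_level: float = 8.0

    def __post_init__(self):
        if not (0 < self.swing_frac < 1):
            raise ValueError("swing fraction must be in (0, 1)")
        if min(self.hs_amp, self.to_amp, self.cadence, self.burst_freq) <= 0:
            raise ValueError("amplitudes, cadence and burst frequency must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


@dataclass(frozen=True)
class SyntheticTrial:
    """A generated trial: signals, ground-truth events, and FSR transition truth."""

    accel: AccelTrace
    fsr: FsrTrace
    truth: list[GaitEvent]
    profile: GaitProfile
    seed: int
    #: programmed FSR threshold-crossing times (s): heel 5%-rise, toe 95%-fall
    fsr_transitions: dict = field(default_factory=dict)


def _burst(t: np.ndarray, t0: float, amp: float, freq: float, decay: float) -> np.ndarray:
    """Damped sinusoid starting at t0: amp * sin(2 pi f (t-t0)) * exp(-(t-t0)/decay)."""
    dt = t - t0
    env = np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / decay), 0.0)
    return amp * np.sin(2 * np.pi * freq * dt) * env


def _bandlimited_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sigma: float,
    band: float | None,
    fs: float,
) -> np.ndarray:
    """Gaussian noise, optionally zero-phase low-passed, rescaled to sigma per axis."""
    from scipy import signal as _signal

    noise = rng.standard_normal(shape)
    if band is not None:
        sos = _signal.butter(4, band, btype="lowpass", fs=fs, output="sos")
        noise = _signal.sosfiltfilt(sos, noise, axis=0)
        noise = noise / np.std(noise, axis=0, keepdims=True)
    return sigma * noise


def _trapezoid(t: np.ndarray, t_on: float, t_off: float, rise: float, level: float) -> np.ndarray:
    """Contact pulse: linear rise from t_on, plateau, linear fall completing at t_off."""
    up = np.clip((t - t_on) / rise, 0.0, 1.0)
    down = np.clip((t_off - t) / rise, 0.0, 1.0)
    return level * np.minimum(up, down)


def generate_trial(profile: GaitProfile, duration: float = 12.0, seed: int = 0) -> SyntheticTrial:
    """Generate one reproducible trial of ``duration`` seconds.

    Raises
    ------
    ValueError
        If the duration cannot hold the lead-in plus at least two gait cycles.
    """
    p = profile
    if duration < p.lead_in + 2.0 / p.cadence:
        raise ValueError(
            f"duration {duration} s cannot hold the {p.lead_in} s lead-in plus two "
            f"gait cycles at cadence {p.cadence}"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * p.fs))
    t = np.arange(n) / p.fs

    # stride schedule with per-cycle cadence jitter
    truth: list[GaitEvent] = []
    hs_times: list[float] = []
    to_times: list[float] = []
    t_cycle_start = p.lead_in
    while True:
        T = (1.0 / p.cadence) * (1.0 + p.cadence_jitter * rng.standard_normal())
        t_hs = t_cycle_start
        t_to = t_hs + (1.0 - p.swing_frac) * T
        if t_to >= duration - 0.05:  # keep the final burst inside the trace
            break
        hs_times.append(t_hs)
        to_times.append(t_to)
        t_cycle_start = t_hs + T

    axes = np.zeros((n, 3))
    axes[:, 2] += 1.0  # gravity along z; removed by the high-pass stage
    for t_hs in hs_times:
        axes += np.outer(_burst(t, t_hs, p.hs_amp, p.burst_freq, p.burst_decay), _HS_DIR)
    for t_to in to_times:
        axes += np.outer(_burst(t, t_to, p.to_amp, p.burst_freq, p.burst_decay), _TO_DIR)
    if p.noise_sigma > 0:
        axes += _bandlimited_noise(rng, axes.shape, p.noise_sigma, p.noise_band, p.fs)

    for t_hs in hs_times:
        truth.append(GaitEvent(kind=EventKind.HS, n=int(round(t_hs * p.fs)), t=t_hs))
    for t_to in to_times:
        truth.append(GaitEvent(kind=EventKind.TO, n=int(round(t_to * p.fs)), t=t_to))
    truth.sort(key=lambda e: e.t)

    # FSR contact pulses; heel contact HS -> ~70% of stance, toe contact from
    # early stance until unloading completes exactly at TO
    heel = np.zeros(n)
    toe = np.zeros(n)
    heel_cross: list[float] = []
    toe_cross: list[float] = []
    for t_hs, t_to in zip(hs_times, to_times):
        stance = t_to - t_hs
        heel_off = t_hs + 0.7 * stance + p.fsr_rise
        heel += _trapezoid(t, t_hs, heel_off, p.fsr_rise, p.fsr_heel_level)
        toe_on = t_hs + 0.25 * stance
        toe += _trapezoid(t, toe_on, t_to, p.fsr_rise, p.fsr_toe_level)
        heel_cross.append(t_hs + 0.05 * p.fsr_rise)  # 5% upward crossing
        toe_cross.append(t_to - 0.95 * p.fsr_rise)  # 95% downward crossing

    accel = AccelTrace(fs=p.fs, t=t, ax=axes[:, 0], ay=axes[:, 1], az=axes[:, 2])
    fsr = FsrTrace(fs=p.fs, heel=heel, toe=toe)
    return SyntheticTrial(
        accel=accel, fsr=fsr, truth=truth, profile=p, seed=seed,
        fsr_transitions={"heel_rise": heel_cross, "toe_fall": toe_cross},
    )


def terrain_presets() -> dict[str, GaitProfile]:
    """The three study terrains as amplitude/cadence variants of one profile.

    Level walking is fastest; stair descent carries the hardest impacts and
    stair ascent the softest, echoing how impact severity orders across
    terrains.  Toe-off bursts are 1.5x smaller than heel-strike bursts in all
    presets.
    """
    return {
        "level": GaitProfile(cadence=0.9, hs_amp=3.0, to_amp=2.0),
        "up": GaitProfile(cadence=0.75, hs_amp=2.2, to_amp=1.47),
        "down": GaitProfile(cadence=0.78, hs_amp=3.6, to_amp=2.4),
    }
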