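"""Morlet continuous wavelet transform and scale-domain calibration estimates.

The calibration stage locates two spectral modes in the scale-dependent energy
spectrum of the smoothed jerk signal: a *gait event* mode (two jerk bursts per
stride, assumed near 1.6 Hz) and a *gait cycle* mode (stride repetition,
assumed near 0.8 Hz).  A Gaussian-mixture prior over scales is cross-correlated
with the observed spectrum to estimate the scale delay of the subject's actual
cadence from the assumed one, after which the two modes are re-estimated by
argmax on either side of the inter-mode energy minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "MorletParams",
    "Scalogram",
    "EnergySpectrum",
    "ScaleEstimate",
    "scale_for_frequency",
    "cwt_morlet",
    "prior_energy_spectrum",
    "energy_spectrum",
    "scale_delay",
    "split_and_refine",
]

#: Canonical Morlet centre frequency (Hz); scale-frequency map f = fc * fs / s.
DEFAULT_FC = 0.8125


@dataclass(frozen=True)
class MorletParams:
    """Complex Morlet wavelet pi^{-1/4} exp(i w0 eta) exp(-eta^2 / 2).

    ``fc`` is the centre frequency used in the frequency-scale map; ``w0`` is
    tied to it by ``w0 = 2 pi fc`` so the map is exact.
    """

    fc: float = DEFAULT_FC

    def __post_init__(self):
        if self.fc <= 0:
            raise ValueError("centre frequency must be positive")

    @property
    def w0(self) -> float:
        return 2.0 * math.pi * self.fc

    def sample(self, eta: np.ndarray) -> np.ndarray:
        """Mother wavelet sampled at dimensionless argument eta."""
        return (
            math.pi**-0.25
            * np.exp(1j * self.w0 * eta)
            * np.exp(-0.5 * eta**2)
        )


@dataclass(frozen=True)
class Scalogram:
    """Complex CWT coefficients, rows indexed by the integer scale grid."""

    W: np.ndarray  # (n_scales, n_samples) complex
    scales: np.ndarray  # integer grid, typically 1..s_max
    fs: float

    def __post_init__(self):
        if self.W.shape[0] != len(self.scales):
            raise ValueError("coefficient rows must match the scale grid")
        if len(self.scales) < 2:
            raise ValueError("need at least 2 scales")

    def row(self, scale: int) -> np.ndarray:
        """Coefficients at one scale; the scale must be on the grid."""
        hit = np.flatnonzero(np.asarray(self.scales) == scale)
        if not hit.size:
            raise ValueError(f"scale {scale} is not on the scalogram grid")
        return self.W[hit[0]]


@dataclass(frozen=True)
class EnergySpectrum:
    """Per-scale non-negative energy over the integer scale grid 1..s_max."""

    E: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.E) < -1e-12):
            raise ValueError("energy spectrum must be non-negative")

    def __len__(self) -> int:
        return len(self.E)

    @property
    def s_max(self) -> int:
        return len(self.E)

    def value_at(self, scale: int) -> float:
        """Energy at 1-based scale index."""
        return float(self.E[scale - 1])


@dataclass(frozen=True)
class ScaleEstimate:
    """Posterior event/cycle scales and the inter-mode split scale.

    Invariant: ``1 <= mu_e_hat <= s_lambda <= mu_c_hat <= s_max``.
    """

    tau: int
    s_lambda: int
    mu_e_hat: int
    mu_c_hat: int

    def __post_init__(self):
        if not (1 <= self.mu_e_hat <= self.s_lambda <= self.mu_c_hat):
            raise ValueError(
                f"scale ordering violated: mu_e={self.mu_e_hat}, "
                f"s_lambda={self.s_lambda}, mu_c={self.mu_c_hat}"
            )


def scale_for_frequency(
    f: float, fc: float = DEFAULT_FC, fs: float = 148.15, rounded: bool = True
) -> int | float:
    """Scale corresponding to frequency ``f`` under ``f = fc * fs / s``.

    Round-half-up to the integer grid when ``rounded`` (the default); the
    un-rounded value is exposed with ``rounded=False``.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    s = fc * fs / f
    if not rounded:
        return s
    return int(math.floor(s + 0.5))


def cwt_morlet(
    x: np.ndarray,
    scales: np.ndarray,
    fs: float,
    params: MorletParams | None = None,
) -> Scalogram:
    """CWT of ``x`` on an integer scale grid with the complex Morlet.

    ``W[s][n] = s^{-1/2} * sum_n' x[n'] conj(psi0((n' - n) / s))`` — i.e. a
    cross-correlation with the scaled wavelet, zero-padded at the boundaries.
    Scales are in samples (the sampling interval is absorbed into the scale,
    matching the ``f = fc * fs / s`` frequency map).
    """
    scales = np.asarray(scales)
    if scales.size == 0:
        raise ValueError("empty scale grid")
    params = params or MorletParams()
    x = np.asarray(x, dtype=float)
    rows = np.empty((scales.size, x.size), dtype=complex)
    for i, s in enumerate(scales):
        half = int(math.ceil(8.0 * s))  # e^(-eta^2/2) < 2e-14 beyond |eta| = 8
        j = np.arange(-half, half + 1)
        kernel = np.conj(params.sample(j / s)) / math.sqrt(s)
        # correlate = sum_j x[n + j] * kernel[j]
        rows[i] = signal.fftconvolve(x, kernel[::-1], mode="same")
    return Scalogram(W=rows, scales=scales, fs=fs)


def prior_energy_spectrum(
    s_max: int,
    mu_e: float = 75,
    mu_c: float = 150,
    sigma1: float = 15,
    sigma2: float = 25,
) -> EnergySpectrum:
    """Two-Gaussian prior over scales for the event and cycle modes.

    ``E[s] = exp(-((s - mu_e)/sigma1)^2) + exp(-((s - mu_c)/sigma2)^2)`` on the
    integer grid ``1..s_max``.
    """
    if min(mu_e, mu_c, sigma1, sigma2) <= 0:
        raise ValueError("prior parameters must be positive")
    if not (mu_e < mu_c <= s_max):
        raise ValueError("prior modes must satisfy mu_e < mu_c <= s_max")
    s = np.arange(1, s_max + 1, dtype=float)
    E = np.exp(-(((s - mu_e) / sigma1) ** 2)) + np.exp(-(((s - mu_c) / sigma2) ** 2))
    return EnergySpectrum(E=E)


def energy_spectrum(W: Scalogram) -> EnergySpectrum:
    """Scale-dependent energy ``E[s] = sum_n |W[s][n]|^2``."""
    return EnergySpectrum(E=np.sum(np.abs(W.W) ** 2, axis=1))


def scale_delay(E_prior: EnergySpectrum, E_obs: EnergySpectrum) -> int:
    """Lag maximising the cross-correlation of prior and observed spectra.

    Both spectra are normalised to unit maximum first so the delay estimate is
    amplitude-invariant.  Positive tau means the observed structure sits at
    larger scales (slower gait) than the prior assumed.  Ties break toward the
    smallest lag.
    """
    if len(E_prior) != len(E_obs):
        raise ValueError("spectra must share one scale grid")
    obs = np.asarray(E_obs.E, dtype=float)
    if np.max(obs) <= 0:
        raise ValueError("observed spectrum is all zero; calibration impossible")
    pri = np.asarray(E_prior.E, dtype=float)
    pri = pri / np.max(pri)
    obs = obs / np.max(obs)
    # full linear cross-correlation; index i corresponds to lag i - (S - 1)
    c = np.correlate(obs, pri, mode="full")
    return int(np.argmax(c)) - (len(pri) - 1)


def split_and_refine(
    E_obs: EnergySpectrum,
    tau: int,
    mu_e: int = 75,
    mu_c: int = 150,
) -> ScaleEstimate:
    """Split the spectrum at its inter-mode minimum and re-estimate both modes.

    The split scale ``s_lambda`` is the argmin of the observed energy over the
    shifted prior-mode interval ``[mu_e + tau, mu_c + tau]`` (clipped to the
    grid); the posterior event scale is the argmax over ``[1, s_lambda]`` and
    the posterior cycle scale the argmax over ``[s_lambda, s_max]``.  All ties
    break toward the smallest scale.
    """
    s_max = E_obs.s_max
    lo = max(1, mu_e + tau)
    hi = min(s_max, mu_c + tau)
    if lo > hi:
        raise ValueError(
            f"shifted mode interval [{mu_e + tau}, {mu_c + tau}] falls outside "
            f"the scale grid [1, {s_max}]"
        )
    E = np.asarray(E_obs.E)
    s_lambda = lo + int(np.argmin(E[lo - 1 : hi]))
    mu_e_hat = 1 + int(np.argmax(E[:s_lambda]))
    mu_c_hat = s_lambda + int(np.argmax(E[s_lambda - 1 :]))
    return ScaleEstimate(tau=tau, s_lambda=s_lambda, mu_e_hat=mu_e_hat, mu_c_hat=mu_c_hat)
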