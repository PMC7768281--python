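"""Generative model of neural power spectra.

A simulated spectrum is the sum, in log10 power, of an aperiodic component

    L(f) = b - chi * log10(f)

(offset ``b`` in log10 au, exponent ``chi`` dimensionless; in linear power
this is the familiar 1/f^chi form) and one Gaussian per periodic peak

    G(f) = a * exp(-(f - c)^2 / (2 w^2))

with center frequency ``c`` (Hz), power ``a`` (log10 au above the aperiodic
component) and bandwidth ``w`` (Hz, the Gaussian width parameter).  White
Gaussian noise (default SD 0.005 au) may be added independently per
frequency bin, also in log10 units.

The module also provides Welch PSD estimation so that measured time series
enter the same :class:`PowerSpectrum` currency as simulated spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "AperiodicParams",
    "PeakParams",
    "SpectralParams",
    "PowerSpectrum",
    "default_freqs",
    "check_freqs",
    "aperiodic_component",
    "peak_component",
    "simulate_spectrum",
    "welch_psd",
]

#: default simulation axis: 1-35 Hz at 0.5 Hz steps, endpoints included.
FREQ_RANGE = (1.0, 35.0)
FREQ_RES = 0.5


def default_freqs(f_min: float = FREQ_RANGE[0], f_max: float = FREQ_RANGE[1],
                  df: float = FREQ_RES) -> np.ndarray:
    """Inclusive frequency grid; generated by count to avoid float drift."""
    n = int(round((f_max - f_min) / df)) + 1
    return f_min + df * np.arange(n)


def check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValueError("frequency axis must be a non-empty 1-D array")
    if np.any(freqs <= 0):
        raise ValueError("all frequencies must be positive (log10(f) must exist)")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency axis must be strictly increasing")
    return freqs


@dataclass(frozen=True)
class AperiodicParams:
    """Aperiodic (1/f-like) component: offset (log10 au) and exponent."""

    offset: float = 0.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.offset) and np.isfinite(self.exponent)):
            raise ValueError("aperiodic parameters must be finite")


@dataclass(frozen=True)
class PeakParams:
    """One periodic peak: center frequency (Hz), power (au), bandwidth (Hz).

    Bandwidth is the Gaussian width parameter ``w`` throughout this package
    (not the full width at half maximum).
    """

    center_frequency: float
    power: float
    bandwidth: float

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("peak center frequency must be > 0")
        if self.power < 0:
            raise ValueError("peak power must be >= 0")
        if self.bandwidth <= 0:
            raise ValueError("peak bandwidth must be > 0")


@dataclass(frozen=True)
class SpectralParams:
    """Full generative description of one spectrum."""

    aperiodic: AperiodicParams = AperiodicParams()
    peaks: tuple[PeakParams, ...] = ()
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_noise(self, noise_sd: float) -> "SpectralParams":
        return replace(self, noise_sd=noise_sd)


@dataclass
class PowerSpectrum:
    """Frequency axis plus power values; ``scale`` tags log10 vs linear."""

    freqs: np.ndarray
    power: np.ndarray
    scale: str = "log10"

    def __post_init__(self) -> None:
        self.freqs = check_freqs(self.freqs)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != self.freqs.shape:
            raise ValueError("power and freqs must have the same length")
        if self.scale not in ("log10", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and np.any(self.power <= 0):
            raise ValueError("linear power must be strictly positive")

    def to_log10(self) -> "PowerSpectrum":
        if self.scale == "log10":
            return self
        return PowerSpectrum(self.freqs, np.log10(self.power), "log10")

    def to_linear(self) -> "PowerSpectrum":
        if self.scale == "linear":
            return self
        return PowerSpectrum(self.freqs, 10.0 ** self.power, "linear")


def aperiodic_component(freqs: np.ndarray, ap: AperiodicParams) -> np.ndarray:
    """Evaluate ``b - chi * log10(f)``; at f = 1 Hz this equals the offset."""
    freqs = check_freqs(freqs)
    return ap.offset - ap.exponent * np.log10(freqs)


def peak_component(freqs: np.ndarray, peaks) -> np.ndarray:
    """Sum of Gaussian peak contributions; empty peak list gives zeros."""
    freqs = check_freqs(freqs)
    out = np.zeros_like(freqs)
    for pk in peaks:
        out += pk.power * np.exp(-((freqs - pk.center_frequency) ** 2)
                                 / (2.0 * pk.bandwidth ** 2))
    return out


def simulate_spectrum(params: SpectralParams,
                      freqs: np.ndarray | None = None,
                      seed=None) -> PowerSpectrum:
    """Simulate one log10 power spectrum from its generative parameters.

    With ``noise_sd = 0`` the output is exactly the deterministic model;
    the same seed always yields bit-identical output.
    """
    if freqs is None:
        freqs = default_freqs()
    freqs = check_freqs(freqs)
    power = aperiodic_component(freqs, params.aperiodic)
    power = power + peak_component(freqs, params.peaks)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        power = power + rng.normal(0.0, params.noise_sd, size=freqs.shape)
    return PowerSpectrum(freqs, power, "log10")


def welch_psd(x: np.ndarray, fs: float, window_seconds: float = 2.0,
              overlap_fraction: float = 0.25,
              f_range: tuple[float, float] = FREQ_RANGE) -> PowerSpectrum:
    """Welch PSD of a time series, returned on log10 scale over ``f_range``.

    Hann windows of ``window_seconds`` with the given fractional overlap,
    mean-averaged.  Two-second windows give the 0.5 Hz resolution the rest
    of the package assumes.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    nperseg = int(round(window_seconds * fs))
    if x.size < nperseg:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one "
            f"{window_seconds}-s window ({nperseg} samples)")
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, pxx = sp_signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                                 noverlap=noverlap, average="mean")
    lo, hi = f_range
    keep = (freqs >= lo) & (freqs <= hi)
    if not np.any(keep):
        raise ValueError("requested frequency range is empty for this signal")
    return PowerSpectrum(freqs[keep], np.log10(pxx[keep]), "log10")
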