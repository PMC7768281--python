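"""Canonical frequency bands and band-ratio measures.

A band ratio divides mean absolute (linear) power in a low band by mean
absolute power in a high band, e.g. the theta/beta ratio is mean 4-8 Hz
power over mean 13-30 Hz power.  Band edges are endpoint-inclusive, so the
shared 8 Hz bin belongs to both theta and alpha, preserving the canonical
printed definitions; supply custom bands for half-open conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

from .spectral_model import PowerSpectrum

__all__ = ["Band", "RatioMeasure", "CANONICAL_BANDS", "DEFAULT_RATIOS",
           "band_power", "compute_ratio", "log_ratio"]


@dataclass(frozen=True)
class Band:
    label: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"band {self.label!r}: need 0 < low < high, "
                             f"got [{self.low}, {self.high}]")


#: canonical bands: theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz.
CANONICAL_BANDS: dict[str, Band] = {
    "theta": Band("theta", 4.0, 8.0),
    "alpha": Band("alpha", 8.0, 13.0),
    "beta": Band("beta", 13.0, 30.0),
}

#: the ratio set computed throughout: theta/beta, theta/alpha, alpha/beta.
DEFAULT_RATIOS: tuple[tuple[str, str], ...] = (
    ("theta", "beta"), ("theta", "alpha"), ("alpha", "beta"))


@dataclass(frozen=True)
class RatioMeasure:
    low_band: Band
    high_band: Band
    value: float
    log_flag: bool = False

    @property
    def label(self) -> str:
        return f"{self.low_band.label}/{self.high_band.label}"


def band_power(spectrum: PowerSpectrum, band: Band) -> float:
    """Mean linear power over all bins with ``band.low <= f <= band.high``."""
    linear = spectrum.to_linear()
    mask = (linear.freqs >= band.low) & (linear.freqs <= band.high)
    if not np.any(mask):
        raise ValueError(
            f"band {band.label!r} [{band.low}, {band.high}] Hz has no bins on "
            f"axis [{linear.freqs[0]}, {linear.freqs[-1]}] Hz")
    return float(np.mean(linear.power[mask]))


def compute_ratio(spectrum: PowerSpectrum, low_band: Band,
                  high_band: Band) -> RatioMeasure:
    """Mean low-band linear power divided by mean high-band linear power."""
    value = band_power(spectrum, low_band) / band_power(spectrum, high_band)
    return RatioMeasure(low_band, high_band, value)


def log_ratio(ratio: RatioMeasure) -> RatioMeasure:
    """log10-transform a raw ratio (ratios are typically right-skewed)."""
    if ratio.log_flag:
        return ratio
    if ratio.value <= 0:
        raise ValueError("cannot log-transform a non-positive ratio")
    return replace(ratio, value=math.log10(ratio.value), log_flag=True)
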