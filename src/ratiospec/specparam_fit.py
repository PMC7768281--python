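"""Spectral parameterization: aperiodic component plus Gaussian peaks.

Decomposes a log10 power spectrum into an aperiodic 1/f-like component
(offset, exponent; "fixed" mode, no knee) and up to ``max_peaks`` Gaussian
peaks, following the staged procedure used by spectral-parameterization
tools in this field:

1. seed aperiodic fit — ordinary least squares of log10 power on log10
   frequency, then a robust re-fit using only the lowest-residual half of
   bins, which guards the aperiodic estimate against peak contamination;
2. flatten the spectrum (subtract the aperiodic fit);
3. iterative Gaussian extraction — repeatedly take the largest point of
   the flattened spectrum as a candidate peak, guessing its width from the
   half-maximum crossing distance (clamped to ``peak_width_bounds``), and
   subtract the guess; stop when the next candidate height falls below
   ``max(min_peak_height, peak_threshold_sd * SD(flattened))`` or when
   ``max_peaks`` have been extracted;
4. joint multi-Gaussian least-squares refit of all extracted peaks;
5. aperiodic re-fit on the peak-removed spectrum;
6. simultaneous least-squares refinement of the aperiodic parameters and
   all peaks together, dropping any peak whose refined height falls below
   the detection threshold (the staged estimates are good starting points
   but inherit bias from peak/aperiodic cross-contamination; the joint
   refinement removes it);
7. final model, r-squared and mean absolute error.

Also derives band-assigned peaks and "parameterized ratios" — ratios of
fitted peak powers, which isolate periodic power from the aperiodic
background (and are absent when either band lacks a detected peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .band_ratios import Band
from .spectral_model import (AperiodicParams, PeakParams, PowerSpectrum,
                             aperiodic_component, peak_component)

__all__ = ["FitSettings", "SpectralFit", "fit_spectrum", "assign_band_peaks",
           "parameterized_ratio", "goodness_of_fit", "r_squared_mae"]

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class FitSettings:
    peak_width_bounds: tuple[float, float] = (1.0, 8.0)
    max_peaks: int = 8
    min_peak_height: float = 0.1
    peak_threshold_sd: float = 2.0
    aperiodic_mode: str = "fixed"

    def __post_init__(self) -> None:
        lo, hi = self.peak_width_bounds
        if not (0 < lo < hi):
            raise ValueError("peak_width_bounds must satisfy 0 < low < high")
        if self.max_peaks < 0:
            raise ValueError("max_peaks must be >= 0")
        if self.min_peak_height < 0 or self.peak_threshold_sd < 0:
            raise ValueError("thresholds must be >= 0")
        if self.aperiodic_mode != "fixed":
            raise ValueError("only 'fixed' (no-knee) aperiodic mode is supported")


@dataclass(frozen=True)
class SpectralFit:
    """Result of parameterizing one spectrum."""

    aperiodic: AperiodicParams
    peaks: tuple[PeakParams, ...]
    r_squared: float
    fit_error: float
    settings: FitSettings = field(default_factory=FitSettings)
    success: bool = True
    message: str = ""

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Regenerate the fitted model (log10 power) on a frequency axis."""
        return (aperiodic_component(freqs, self.aperiodic)
                + peak_component(freqs, self.peaks))


def _lstsq_aperiodic(freqs, power):
    logf = np.log10(freqs)
    design = np.column_stack([np.ones_like(logf), -logf])
    (offset, exponent), *_ = np.linalg.lstsq(design, power, rcond=None)
    return AperiodicParams(float(offset), float(exponent))


def _robust_aperiodic(freqs, power):
    """Seed fit, then re-fit on the lowest-residual half of bins.

    Peaks only push the spectrum up, so the low-residual half is the half
    least contaminated by periodic power.
    """
    seed = _lstsq_aperiodic(freqs, power)
    resid = power - (seed.offset - seed.exponent * np.log10(freqs))
    keep = resid <= np.median(resid)
    if keep.sum() < 2:       # degenerate: all residuals identical
        return seed
    return _lstsq_aperiodic(freqs[keep], power[keep])


def _guess_width(freqs, flat, idx, height, bounds):
    """Half-maximum crossing distance, converted to a Gaussian SD in Hz.

    Crossings are linearly interpolated between bins; the shorter side is
    used, which is robust when a neighbouring peak props up one flank.
    """
    half = flat[idx] - height / 2.0
    df = freqs[1] - freqs[0]
    sides = []
    le = idx
    while le > 0 and flat[le - 1] > half:
        le -= 1
    if le > 0:      # crossing between le-1 and le
        frac = (flat[le] - half) / (flat[le] - flat[le - 1])
        sides.append((idx - le + frac) * df)
    ri = idx
    while ri < flat.size - 1 and flat[ri + 1] > half:
        ri += 1
    if ri < flat.size - 1:
        frac = (flat[ri] - half) / (flat[ri] - flat[ri + 1])
        sides.append((ri - idx + frac) * df)
    fwhm = 2.0 * min(sides) if sides else 2.0 * df
    return float(np.clip(fwhm / _FWHM_TO_SD, *bounds))


def _near_edge(cf, width, freqs):
    # peaks hugging the axis edge are truncated-tail artifacts, not
    # resolvable oscillations
    return cf - width < freqs[0] or cf + width > freqs[-1]


def _extract_peaks(freqs, flat, settings: FitSettings):
    flat = flat.copy()
    guesses: list[tuple[float, float, float]] = []
    while len(guesses) < settings.max_peaks:
        idx = int(np.argmax(flat))
        height = float(flat[idx])
        stop_at = max(settings.min_peak_height,
                      settings.peak_threshold_sd * float(np.std(flat)))
        if height < stop_at:
            break
        cf = float(freqs[idx])
        width = _guess_width(freqs, flat, idx, height, settings.peak_width_bounds)
        if not _near_edge(cf, width, freqs):
            guesses.append((cf, height, width))
        flat -= height * np.exp(-((freqs - cf) ** 2) / (2.0 * width ** 2))
    return guesses


def _gaussian_sum(freqs, *params):
    out = np.zeros_like(freqs)
    for cf, h, w in zip(params[::3], params[1::3], params[2::3]):
        out += h * np.exp(-((freqs - cf) ** 2) / (2.0 * w ** 2))
    return out


def _refit_peaks(freqs, flat, guesses, settings: FitSettings):
    """Joint least-squares refit of all extracted Gaussians."""
    if not guesses:
        return []
    wlo, whi = settings.peak_width_bounds
    p0, lo, hi = [], [], []
    for cf, h, w in guesses:
        p0 += [cf, h, w]
        lo += [max(freqs[0], cf - 2.0 * w), 0.0, wlo]
        hi += [min(freqs[-1], cf + 2.0 * w), np.inf, whi]
    p0 = [float(np.clip(v, l, u)) for v, l, u in zip(p0, lo, hi)]
    popt, _ = curve_fit(_gaussian_sum, freqs, flat, p0=p0, bounds=(lo, hi),
                        maxfev=5000)
    peaks = []
    for cf, h, w in zip(popt[::3], popt[1::3], popt[2::3]):
        if h <= 0:
            continue
        peaks.append(PeakParams(float(cf), float(h),
                                float(np.clip(w, wlo, whi))))
    return peaks


def _full_model(freqs, *params):
    return params[0] - params[1] * np.log10(freqs) + _gaussian_sum(freqs,
                                                                   *params[2:])


def _fit_full_model(freqs, power, ap, peaks, settings: FitSettings):
    wlo, whi = settings.peak_width_bounds
    p0 = [ap.offset, ap.exponent]
    lo, hi = [-np.inf, -np.inf], [np.inf, np.inf]
    for q in peaks:
        p0 += [q.center_frequency, q.power, q.bandwidth]
        lo += [freqs[0], 0.0, wlo]
        hi += [freqs[-1], np.inf, whi]
    popt, _ = curve_fit(_full_model, freqs, power, p0=p0, bounds=(lo, hi),
                        maxfev=5000)
    ap = AperiodicParams(float(popt[0]), float(popt[1]))
    peaks = [PeakParams(float(c), float(h), float(w))
             for c, h, w in zip(popt[2::3], popt[3::3], popt[4::3]) if h > 0]
    return ap, peaks


def _refine_joint(freqs, power, ap, peaks, settings: FitSettings):
    """Simultaneous aperiodic + peaks refinement.

    Peaks whose refined height falls below the detection threshold (or
    that collapse onto an axis edge) are dropped, and the remainder
    re-refined, until the peak set is stable.
    """
    for _ in range(3):
        ap, refined = _fit_full_model(freqs, power, ap, peaks, settings)
        kept = [q for q in refined if q.power >= settings.min_peak_height
                and not _near_edge(q.center_frequency, q.bandwidth, freqs)]
        if len(kept) == len(refined):
            return ap, kept
        peaks = kept
    ap, refined = _fit_full_model(freqs, power, ap, peaks, settings)
    return ap, refined


def fit_spectrum(spectrum: PowerSpectrum,
                 settings: FitSettings | None = None) -> SpectralFit:
    """Parameterize a power spectrum into aperiodic + peak components.

    Non-convergence of the joint peak refit yields a fit-failure result
    (``success=False``, initial guesses retained, diagnostics in
    ``message``) rather than an exception.
    """
    settings = settings or FitSettings()
    spec = spectrum.to_log10()
    freqs, power = spec.freqs, spec.power
    if freqs.size < 10:
        raise ValueError("need at least 10 frequency bins to fit a spectrum")

    ap = _robust_aperiodic(freqs, power)
    flat = power - aperiodic_component(freqs, ap)
    guesses = _extract_peaks(freqs, flat, settings)

    success, message = True, ""
    try:
        peaks = _refit_peaks(freqs, flat, guesses, settings)
    except RuntimeError as err:       # joint refit failed to converge
        success, message = False, f"peak refit did not converge: {err}"
        peaks = [PeakParams(cf, h, w) for cf, h, w in guesses]

    # re-fit the aperiodic component on the peak-removed spectrum, then
    # refine everything together
    ap = _lstsq_aperiodic(freqs, power - peak_component(freqs, peaks))
    if success:
        try:
            ap, peaks = _refine_joint(freqs, power, ap, peaks, settings)
        except RuntimeError as err:
            success = False
            message = f"joint refinement did not converge: {err}"

    fit = SpectralFit(ap, tuple(peaks), np.nan, np.nan, settings,
                      success, message)
    r2, mae = goodness_of_fit(fit, spec)
    return SpectralFit(ap, tuple(peaks), r2, mae, settings, success, message)


def r_squared_mae(model: np.ndarray, data: np.ndarray) -> tuple[float, float]:
    """Squared Pearson correlation of model vs data, and mean abs error.

    Both on log10 power.  Zero variance in either vector makes r-squared
    undefined; it is reported as NaN.
    """
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    mae = float(np.mean(np.abs(model - data)))
    if np.std(data) == 0 or np.std(model) == 0:
        return float("nan"), mae
    r = float(np.corrcoef(model, data)[0, 1])
    return r * r, mae


def goodness_of_fit(fit: SpectralFit,
                    spectrum: PowerSpectrum) -> tuple[float, float]:
    """Evaluate a fit against its spectrum: r-squared and mean abs error."""
    spec = spectrum.to_log10()
    return r_squared_mae(fit.model(spec.freqs), spec.power)


def assign_band_peaks(fit: SpectralFit,
                      bands: list[Band]) -> dict[str, PeakParams | None]:
    """Map each band to its detected peak, if any.

    A peak belongs to a band when its center frequency lies within the
    band's inclusive range; with multiple candidates the highest-power peak
    wins, ties broken toward the lower center frequency.
    """
    table: dict[str, PeakParams | None] = {}
    for band in bands:
        candidates = [p for p in fit.peaks
                      if band.low <= p.center_frequency <= band.high]
        if candidates:
            table[band.label] = min(candidates,
                                    key=lambda p: (-p.power, p.center_frequency))
        else:
            table[band.label] = None
    return table


def parameterized_ratio(table: dict[str, PeakParams | None],
                        low_band: str, high_band: str) -> float | None:
    """Ratio of fitted peak powers between two bands; None when absent."""
    low, high = table.get(low_band), table.get(high_band)
    if low is None or high is None or high.power == 0:
        return None
    return low.power / high.power
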