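"""Parameter-sweep simulation experiments.

Maps spectral parameters to measured band ratios: each sweep varies one
(or, on a Cartesian grid, two) generative parameters across its stated
range while all other parameters sit at their defaults, simulates a
spectrum per grid point, and measures the band ratios.

The default simulation study uses a three-peak spectrum (theta 6 Hz,
alpha 10 Hz, beta 21.5 Hz; each peak power 0.5 au, bandwidth 0.1 Hz) over
a 1/f background with offset 0 and exponent 1.  Note the bandwidth sweep
range (0.2-0.4 Hz) does not contain the 0.1 Hz default; both values are
used verbatim as printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .band_ratios import CANONICAL_BANDS, DEFAULT_RATIOS, compute_ratio
from .spectral_model import (AperiodicParams, PeakParams, SpectralParams,
                             simulate_spectrum)

__all__ = ["SweepSpec", "SweepResult", "GridResult", "default_base_params",
           "PARAMETER_GRIDS", "TEN_PARAMETERS", "grid_values",
           "single_param_sweep", "paired_param_sweep", "count_affected_params"]

#: defaults for the three simulated peaks: (center frequency, power, bandwidth)
_PEAK_DEFAULTS = {
    "theta": (6.0, 0.5, 0.1),
    "alpha": (10.0, 0.5, 0.1),
    "beta": (21.5, 0.5, 0.1),
}

#: (start, stop, increment) sweep grids per parameter, endpoints included.
PARAMETER_GRIDS: dict[str, tuple[float, float, float]] = {
    "theta_cf": (4.0, 8.0, 0.25),
    "alpha_cf": (8.0, 13.0, 0.25),
    "beta_cf": (13.0, 30.0, 1.0),
    "theta_pw": (0.0, 1.0, 0.1),
    "alpha_pw": (0.0, 1.0, 0.1),
    "beta_pw": (0.0, 1.0, 0.1),
    "theta_bw": (0.2, 0.4, 0.2),
    "alpha_bw": (0.2, 0.4, 0.2),
    "beta_bw": (0.2, 0.4, 0.2),
    "offset": (0.0, 2.5, 0.25),
    "exponent": (0.0, 3.0, 0.2),
}

#: the ten-parameter census set: all theta and beta peak parameters, alpha
#: center frequency and power, and the two aperiodic parameters.  Alpha
#: bandwidth also influences ratios and is reported separately when asked.
TEN_PARAMETERS: tuple[str, ...] = (
    "theta_cf", "theta_pw", "theta_bw",
    "beta_cf", "beta_pw", "beta_bw",
    "alpha_cf", "alpha_pw",
    "offset", "exponent",
)


def default_base_params(noise_sd: float = 0.0) -> SpectralParams:
    """The study's default spectrum: three peaks over a 1/f background."""
    peaks = tuple(PeakParams(*_PEAK_DEFAULTS[b])
                  for b in ("theta", "alpha", "beta"))
    return SpectralParams(AperiodicParams(0.0, 1.0), peaks, noise_sd)


def grid_values(start: float, stop: float, increment: float) -> np.ndarray:
    if increment <= 0:
        raise ValueError("grid increment must be > 0")
    n = int(round((stop - start) / increment)) + 1
    values = start + increment * np.arange(n)
    if values.size == 0:
        raise ValueError("empty sweep grid")
    return values


@dataclass(frozen=True)
class SweepSpec:
    parameter: str
    grid: tuple[float, float, float] | None = None
    base: SpectralParams = field(default_factory=default_base_params)

    def values(self) -> np.ndarray:
        grid = self.grid if self.grid is not None else PARAMETER_GRIDS[self.parameter]
        return grid_values(*grid)


@dataclass
class SweepResult:
    parameter: str
    values: np.ndarray
    ratios: dict[str, np.ndarray]          # measure label -> raw ratio values
    noise_sd: float
    seed: object = None

    def log_ratios(self) -> dict[str, np.ndarray]:
        return {k: np.log10(v) for k, v in self.ratios.items()}


@dataclass
class GridResult:
    parameters: tuple[str, str]
    values: tuple[np.ndarray, np.ndarray]
    ratios: dict[str, np.ndarray]          # label -> matrix [len(v1), len(v2)]
    noise_sd: float
    seed: object = None

    def log_ratios(self) -> dict[str, np.ndarray]:
        """Log10 ratios, the scale used for plotting skewed ratio grids."""
        return {k: np.log10(v) for k, v in self.ratios.items()}


def _band_of(param: str) -> tuple[str, str]:
    band, _, attr = param.partition("_")
    return band, attr


def apply_parameter(base: SpectralParams, param: str,
                    value: float) -> SpectralParams:
    """Return a copy of ``base`` with one named parameter set to ``value``."""
    if param == "offset":
        return replace(base, aperiodic=replace(base.aperiodic, offset=value))
    if param == "exponent":
        return replace(base, aperiodic=replace(base.aperiodic, exponent=value))
    band, attr = _band_of(param)
    if band not in CANONICAL_BANDS or attr not in ("cf", "pw", "bw"):
        raise ValueError(f"unknown parameter id {param!r}")
    lo, hi = CANONICAL_BANDS[band].low, CANONICAL_BANDS[band].high
    idx = [i for i, p in enumerate(base.peaks)
           if lo <= p.center_frequency <= hi]
    if not idx:
        raise ValueError(f"base parameters have no {band} peak to vary "
                         f"for {param!r}")
    # bands share edge bins; disambiguate toward the band midpoint so a peak
    # swept onto a band edge is not mistaken for its neighbour's peak
    mid = 0.5 * (lo + hi)
    target = min(idx, key=lambda i: abs(base.peaks[i].center_frequency - mid))
    field_name = {"cf": "center_frequency", "pw": "power", "bw": "bandwidth"}[attr]
    peaks = list(base.peaks)
    peaks[target] = replace(peaks[target], **{field_name: value})
    return replace(base, peaks=tuple(peaks))


def _measure(params: SpectralParams, ratios, rng) -> dict[str, float]:
    spectrum = simulate_spectrum(params, seed=rng)
    out = {}
    for lo, hi in ratios:
        r = compute_ratio(spectrum, CANONICAL_BANDS[lo], CANONICAL_BANDS[hi])
        out[r.label] = r.value
    return out


def single_param_sweep(spec: SweepSpec, ratios=DEFAULT_RATIOS,
                       noise_sd: float = 0.0, seed=None) -> SweepResult:
    """Vary one parameter over its grid; one simulated spectrum per value."""
    values = spec.values()
    rng = np.random.default_rng(seed)
    rows = []
    for v in values:
        params = apply_parameter(spec.base, spec.parameter, v)
        rows.append(_measure(params.with_noise(noise_sd), ratios, rng))
    labels = rows[0].keys()
    return SweepResult(spec.parameter, values,
                       {k: np.array([r[k] for r in rows]) for k in labels},
                       noise_sd, seed)


def paired_param_sweep(spec1: SweepSpec, spec2: SweepSpec,
                       ratios=DEFAULT_RATIOS, noise_sd: float = 0.0,
                       seed=None) -> GridResult:
    """Vary two distinct parameters over their full Cartesian grid."""
    if spec1.parameter == spec2.parameter:
        raise ValueError("paired sweep requires two distinct parameters")
    v1, v2 = spec1.values(), spec2.values()
    rng = np.random.default_rng(seed)
    mats = {f"{lo}/{hi}": np.empty((v1.size, v2.size)) for lo, hi in ratios}
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            params = apply_parameter(spec1.base, spec1.parameter, a)
            params = apply_parameter(params, spec2.parameter, b)
            for label, val in _measure(params.with_noise(noise_sd),
                                       ratios, rng).items():
                mats[label][i, j] = val
    return GridResult((spec1.parameter, spec2.parameter), (v1, v2),
                      mats, noise_sd, seed)


def count_affected_params(base: SpectralParams | None = None,
                          parameters=TEN_PARAMETERS,
                          ratio: tuple[str, str] = ("theta", "beta"),
                          tolerance: float = 1e-6):
    """Census of which parameters alter a band ratio, with noise disabled.

    A parameter "alters" the ratio when the ratio's range across its sweep
    exceeds ``tolerance`` relative to the baseline (all-defaults) ratio.
    Returns ``(count, verdicts)`` where ``verdicts`` maps parameter id to
    bool.
    """
    base = base if base is not None else default_base_params()
    label = f"{ratio[0]}/{ratio[1]}"
    baseline = _measure(base.with_noise(0.0), [ratio], None)[label]
    verdicts: dict[str, bool] = {}
    for param in parameters:
        sweep = single_param_sweep(SweepSpec(param, base=base),
                                   ratios=[ratio], noise_sd=0.0)
        vals = sweep.ratios[label]
        verdicts[param] = bool((vals.max() - vals.min()) / baseline > tolerance)
    return sum(verdicts.values()), verdicts
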