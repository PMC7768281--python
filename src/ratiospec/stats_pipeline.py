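"""Correlation statistics relating band ratios to spectral parameters.

Implements the analysis stage of the study: Spearman rank correlations
with percentile-bootstrap confidence intervals (5000 resamples, 95% CIs
by default), bootstrap difference-of-correlation tests, between-block
difference series, channel-topography correlations, and age-correlation
suites — applied to measured cohorts (synthetic or otherwise).

Missing values (e.g. parameterized ratios for subjects without both band
peaks) are removed listwise per correlation pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .band_ratios import CANONICAL_BANDS, DEFAULT_RATIOS, compute_ratio
from .cohort_synth import CohortResult
from .specparam_fit import (FitSettings, assign_band_peaks, fit_spectrum,
                            parameterized_ratio)

__all__ = ["CorrelationResult", "DiffCorrResult", "BlockDiffSeries",
           "spearman", "bootstrap_ci", "bootstrap_diff_corr",
           "block_differences", "cohort_measures", "block_measures",
           "ratio_param_correlation_table", "topography_correlation",
           "age_correlation_suite"]

#: fitted spectral parameters entering correlation tables (offset excluded:
#: offset shifts cancel out of every ratio measure by construction)
PARAM_COLUMNS = ("theta_cf", "theta_pw", "theta_bw",
                 "alpha_cf", "alpha_pw", "alpha_bw",
                 "beta_cf", "beta_pw", "beta_bw", "exponent")

RATIO_LABELS = tuple(f"{lo}/{hi}" for lo, hi in DEFAULT_RATIOS)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    n: int
    n_resamples: int = 5000
    level: float = 95.0
    n_skipped: int = 0          # zero-variance resamples skipped


@dataclass(frozen=True)
class DiffCorrResult:
    delta_rho: float
    ci_low: float
    ci_high: float
    p: float
    absolute_magnitude: bool
    n: int
    n_resamples: int = 5000


@dataclass(frozen=True)
class BlockDiffSeries:
    """Per-subject consecutive block differences (block minus prior block)."""

    values: np.ndarray          # (n_subjects, n_blocks)
    diffs: np.ndarray           # (n_subjects, n_blocks - 1)

    def pooled(self) -> np.ndarray:
        return self.diffs.ravel()


def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def spearman(x, y) -> float:
    """Spearman rho: Pearson correlation of average-ranked values.

    Returns NaN when either variable has zero rank variance (undefined).
    """
    x, y = _clean_pairs(x, y)
    if x.size < 3:
        return float("nan")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    rho = sp_stats.spearmanr(x, y).statistic
    return float(rho)


def bootstrap_ci(x, y, n_resamples: int = 5000, level: float = 95.0,
                 seed=None) -> CorrelationResult:
    """Percentile bootstrap CI for Spearman rho via paired resampling."""
    x, y = _clean_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    rho = spearman(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_resamples)
    skipped = 0
    for i in range(n_resamples):
        r = float("nan")
        for _ in range(100):      # redraw zero-variance resamples, capped
            idx = rng.integers(0, x.size, x.size)
            r = spearman(x[idx], y[idx])
            if np.isfinite(r):
                break
            skipped += 1
        boots[i] = r if np.isfinite(r) else rho
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(boots, [alpha, 100.0 - alpha])
    return CorrelationResult(rho, float(lo), float(hi), int(x.size),
                             n_resamples, level, skipped)


def bootstrap_diff_corr(x, y1, y2, use_absolute: bool = False,
                        n_resamples: int = 5000, seed=None) -> DiffCorrResult:
    """Bootstrap test of the difference between two correlations to x.

    Per resample, computes rho(x, y1) - rho(x, y2) (of the absolute
    magnitudes when ``use_absolute``); the empirical two-sided p tests
    whether the measured difference differs from zero.
    """
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if not (x.shape == y1.shape == y2.shape):
        raise ValueError("x, y1, y2 must have equal length")
    keep = np.isfinite(x) & np.isfinite(y1) & np.isfinite(y2)
    x, y1, y2 = x[keep], y1[keep], y2[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete triples")

    def delta(xi, y1i, y2i):
        r1, r2 = spearman(xi, y1i), spearman(xi, y2i)
        if use_absolute:
            r1, r2 = abs(r1), abs(r2)
        return r1 - r2

    observed = delta(x, y1, y2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_resamples)
    for i in range(n_resamples):
        d = float("nan")
        for _ in range(100):
            idx = rng.integers(0, x.size, x.size)
            d = delta(x[idx], y1[idx], y2[idx])
            if np.isfinite(d):
                break
        boots[i] = d if np.isfinite(d) else observed
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min(float(np.mean(boots <= 0.0)), float(np.mean(boots >= 0.0)))
    p = float(np.clip(p, 2.0 / (n_resamples + 1), 1.0))
    return DiffCorrResult(float(observed), float(lo), float(hi), p,
                          use_absolute, int(x.size), n_resamples)


def block_differences(values) -> BlockDiffSeries:
    """Consecutive differences of a per-subject block series."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] < 2:
        raise ValueError("need at least 2 blocks to difference")
    return BlockDiffSeries(values, np.diff(values, axis=1))


# ---------------------------------------------------------------------------
# cohort measurement: spectra -> per-subject (or per-cell) measures table

def _measure_one(spectrum, fit: bool, settings: FitSettings | None):
    row: dict[str, float] = {}
    for lo, hi in DEFAULT_RATIOS:
        r = compute_ratio(spectrum, CANONICAL_BANDS[lo], CANONICAL_BANDS[hi])
        row[r.label] = r.value
    if fit:
        sfit = fit_spectrum(spectrum, settings)
        table = assign_band_peaks(sfit, list(CANONICAL_BANDS.values()))
        row["exponent"] = sfit.aperiodic.exponent
        row["offset"] = sfit.aperiodic.offset
        row["r_squared"] = sfit.r_squared
        for band, peak in table.items():
            row[f"{band}_cf"] = peak.center_frequency if peak else np.nan
            row[f"{band}_pw"] = peak.power if peak else np.nan
            row[f"{band}_bw"] = peak.bandwidth if peak else np.nan
        for lo, hi in DEFAULT_RATIOS:
            pr = parameterized_ratio(table, lo, hi)
            row[f"param {lo}/{hi}"] = pr if pr is not None else np.nan
    return row


def cohort_measures(cohort: CohortResult, block: int = 0,
                    channel_average: bool = True, fit: bool = True,
                    fit_settings: FitSettings | None = None) -> pd.DataFrame:
    """Measure ratios (and optionally fitted parameters) across a cohort.

    With ``channel_average`` (default) each subject contributes one row
    measured on their channel-averaged spectrum; otherwise channels are
    pooled, one row per (subject, channel).
    """
    rows = []
    for s in range(cohort.config.n_subjects):
        if channel_average:
            spec = cohort.channel_mean_spectrum(s, block)
            row = {"subject": s, "age": float(cohort.ages[s])}
            row.update(_measure_one(spec, fit, fit_settings))
            rows.append(row)
        else:
            for c in range(cohort.config.n_channels):
                row = {"subject": s, "channel": c,
                       "age": float(cohort.ages[s])}
                row.update(_measure_one(cohort.spectrum(s, c, block),
                                        fit, fit_settings))
                rows.append(row)
    return pd.DataFrame(rows)


def block_measures(cohort: CohortResult, fit: bool = True,
                   fit_settings: FitSettings | None = None) -> pd.DataFrame:
    """Per-subject, per-block measures on channel-averaged spectra."""
    rows = []
    for s in range(cohort.config.n_subjects):
        for b in range(cohort.config.n_blocks):
            row = {"subject": s, "block": b, "age": float(cohort.ages[s])}
            row.update(_measure_one(cohort.channel_mean_spectrum(s, b),
                                    fit, fit_settings))
            rows.append(row)
    return pd.DataFrame(rows)


def ratio_param_correlation_table(measures: pd.DataFrame,
                                  ratio_labels=RATIO_LABELS,
                                  parameters=PARAM_COLUMNS,
                                  n_resamples: int = 5000,
                                  seed=None) -> pd.DataFrame:
    """Spearman + bootstrap CI for every (ratio measure, parameter) pair.

    Pairs with fewer than 3 complete observations yield NaN cells.
    Returns a tidy frame (measure, parameter, rho, ci_low, ci_high, n).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label in ratio_labels:
        for param in parameters:
            if param not in measures.columns or label not in measures.columns:
                continue
            x, y = _clean_pairs(measures[label], measures[param])
            if x.size < 3 or np.unique(y).size < 2 or np.unique(x).size < 2:
                rows.append({"measure": label, "parameter": param,
                             "rho": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "n": int(x.size)})
                continue
            res = bootstrap_ci(x, y, n_resamples=n_resamples, seed=rng)
            rows.append({"measure": label, "parameter": param,
                         "rho": res.rho, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "n": res.n})
    return pd.DataFrame(rows)


def topography_correlation(channel_means_a, channel_means_b,
                           n_resamples: int = 5000,
                           seed=None) -> CorrelationResult:
    """Spatial rank correlation between two per-channel group-mean maps."""
    a = np.asarray(channel_means_a, dtype=float)
    b = np.asarray(channel_means_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need matching channel sets with >= 3 channels")
    return bootstrap_ci(a, b, n_resamples=n_resamples, seed=seed)


def age_correlation_suite(measures: pd.DataFrame,
                          columns=None,
                          n_resamples: int = 5000,
                          seed=None) -> pd.DataFrame:
    """Each measure (ratios, parameterized ratios, exponent) against age.

    Parameterized-ratio columns use only the subjects for which both band
    peaks were detected (listwise removal).
    """
    if "age" not in measures.columns:
        raise ValueError("measures table must carry an 'age' column")
    if columns is None:
        columns = [c for c in measures.columns
                   if c in RATIO_LABELS or c.startswith("param ")
                   or c == "exponent"]
    rng = np.random.default_rng(seed)
    rows = []
    for col in columns:
        x, y = _clean_pairs(measures["age"], measures[col])
        if x.size < 3 or np.unique(x).size < 2 or np.unique(y).size < 2:
            rows.append({"measure": col, "rho": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n": int(x.size)})
            continue
        res = bootstrap_ci(x, y, n_resamples=n_resamples, seed=rng)
        rows.append({"measure": col, "rho": res.rho, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "n": res.n})
    return pd.DataFrame(rows)
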