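"""Synthetic resting-state EEG cohorts with known spectral ground truth.

Emulates the structure of a developmental eyes-closed resting EEG study:
111 subjects aged 6-44 (truncated normal, mean 15.79, SD 8.03), 111
channels, 5 resting blocks per subject.  Each (subject, channel, block)
cell gets a power spectrum generated from hierarchical spectral
parameters:

* the aperiodic exponent declines with age (flattening of the 1/f slope
  over development) plus subject-level noise;
* the offset varies between subjects;
* peaks occur per band with a prevalence probability (alpha effectively
  always present and dominant in eyes-closed data; theta and beta
  sometimes absent), with subject-level center frequency / power /
  bandwidth draws;
* a smooth cosine gradient over the ordered channel index modulates the
  exponent and alpha power, standing in for scalp topography;
* per-block jitter adds within-subject variation over time.

Ground-truth generating parameters are stored losslessly alongside the
simulated spectra, so pipeline outputs can be compared against what truly
generated the data.  Also provides random-phase time-series synthesis so
the Welch estimation stage can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .spectral_model import (AperiodicParams, PeakParams, PowerSpectrum,
                             SpectralParams, aperiodic_component,
                             default_freqs, peak_component, simulate_spectrum)

__all__ = ["BandPeakModel", "CohortConfig", "CohortResult",
           "generate_cohort", "synth_time_series"]

_BANDS = ("theta", "alpha", "beta")


@dataclass(frozen=True)
class BandPeakModel:
    """Subject-level distribution of one band's peak parameters."""

    prevalence: float           # probability a subject expresses this peak
    cf_mean: float              # Hz
    cf_sd: float
    pw_mean: float              # au (log10 height above the aperiodic fit)
    pw_sd: float
    bw_mean: float              # Hz (Gaussian width)
    bw_sd: float
    cf_range: tuple[float, float]
    pw_min: float = 0.15        # keep generated peaks detectably above floor
    bw_range: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        for sd in (self.cf_sd, self.pw_sd, self.bw_sd):
            if sd < 0:
                raise ValueError("SDs must be >= 0")


def _default_peak_models() -> dict[str, BandPeakModel]:
    # alpha: always present, high and variable power (eyes-closed dominance);
    # theta/beta: present in a majority but not all subjects
    return {
        "theta": BandPeakModel(0.6, 6.0, 0.6, 0.4, 0.12, 1.5, 0.3, (4.5, 7.5)),
        "alpha": BandPeakModel(1.0, 10.0, 1.0, 0.7, 0.25, 1.8, 0.4, (8.5, 12.5)),
        "beta": BandPeakModel(0.6, 21.5, 2.0, 0.35, 0.1, 2.0, 0.4, (14.0, 29.0)),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 111
    n_channels: int = 111
    n_blocks: int = 5
    # age model: truncated normal over the study's age range
    age_mean: float = 15.79
    age_sd: float = 8.03
    age_range: tuple[float, float] = (6.0, 44.0)
    # aperiodic model: exponent = baseline + slope * (age - age_mean) + noise.
    # slope is negative: the aperiodic component flattens with age.
    exponent_baseline: float = 1.5
    exponent_age_slope: float = -0.02
    exponent_subject_sd: float = 0.1
    offset_mean: float = 0.0
    offset_sd: float = 0.2
    peak_models: dict[str, BandPeakModel] = field(
        default_factory=_default_peak_models)
    # channel gradient: multiplicative cosine modulation over channel index
    channel_gradient_exponent: float = 0.1
    channel_gradient_alpha_pw: float = 0.2
    # per-block jitter SDs (within subject, additive)
    block_exponent_sd: float = 0.03
    block_pw_sd: float = 0.05
    block_cf_sd: float = 0.2
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_channels, self.n_blocks) < 1:
            raise ValueError("cohort needs >= 1 subject, channel and block")
        if not (self.age_range[0] < self.age_range[1]):
            raise ValueError("invalid age range")
        for sd in (self.age_sd, self.exponent_subject_sd, self.offset_sd,
                   self.block_exponent_sd, self.block_pw_sd,
                   self.block_cf_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("SDs must be >= 0")


@dataclass
class CohortResult:
    """Simulated spectra plus the ground truth that generated them."""

    config: CohortConfig
    seed: int | None
    freqs: np.ndarray
    #: log10 power, shape (n_subjects, n_channels, n_blocks, n_freqs)
    spectra: np.ndarray
    ages: np.ndarray
    #: tidy ground truth: one row per (subject, channel, block)
    truth: pd.DataFrame

    def spectrum(self, subject: int, channel: int, block: int) -> PowerSpectrum:
        return PowerSpectrum(self.freqs,
                             self.spectra[subject, channel, block], "log10")

    def channel_mean_spectrum(self, subject: int, block: int = 0) -> PowerSpectrum:
        """Average log10 power over channels for one subject and block."""
        return PowerSpectrum(self.freqs,
                             self.spectra[subject, :, block].mean(axis=0),
                             "log10")


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                  random_state=rng)


def _calibrated_truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated-normal draws whose *marginal* mean and SD hit the targets.

    Asymmetric truncation (ages: a bound only 1.2 SD below the mean)
    shifts the marginal moments away from the location/scale parameters,
    so those are solved for numerically before sampling.
    """
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))

    def moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = sp_stats.truncnorm.stats(a, b, loc=mu, scale=sigma,
                                        moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    from scipy.optimize import fsolve
    (mu, log_sigma), info, ok, _ = fsolve(moments, [mean, np.log(sd)],
                                          full_output=True)
    if ok != 1:     # fall back to nominal parameters
        mu, log_sigma = mean, np.log(sd)
    sigma = float(np.exp(log_sigma))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return sp_stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size,
                                  random_state=rng)


def _gradient(n: int, amplitude: float) -> np.ndarray:
    """Smooth multiplicative modulation (1 + amp*cos) over channel index."""
    if n == 1:
        return np.ones(1)
    return 1.0 + amplitude * np.cos(np.pi * np.arange(n) / (n - 1))


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> CohortResult:
    """Draw a full synthetic cohort; same seed gives identical output."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    freqs = default_freqs()
    ns, nc, nb = config.n_subjects, config.n_channels, config.n_blocks

    ages = _calibrated_truncnorm(rng, config.age_mean, config.age_sd,
                                 *config.age_range, size=ns)
    exp_subj = (config.exponent_baseline
                + config.exponent_age_slope * (ages - config.age_mean)
                + rng.normal(0.0, config.exponent_subject_sd, ns))
    exp_subj = np.maximum(exp_subj, 0.1)
    off_subj = rng.normal(config.offset_mean, config.offset_sd, ns)

    # subject-level peak draws (presence and parameters fixed per subject)
    peak_subj: dict[str, dict[str, np.ndarray]] = {}
    for band in _BANDS:
        m = config.peak_models[band]
        present = rng.random(ns) < m.prevalence
        cf = _truncnorm(rng, m.cf_mean, m.cf_sd, *m.cf_range, ns)
        pw = np.maximum(rng.normal(m.pw_mean, m.pw_sd, ns), m.pw_min)
        bw = _truncnorm(rng, m.bw_mean, m.bw_sd, *m.bw_range, ns)
        peak_subj[band] = {"present": present, "cf": cf, "pw": pw, "bw": bw}

    grad_exp = _gradient(nc, config.channel_gradient_exponent)
    grad_apw = _gradient(nc, config.channel_gradient_alpha_pw)

    spectra = np.empty((ns, nc, nb, freqs.size))
    rows = []
    for s in range(ns):
        for c in range(nc):
            for b in range(nb):
                exponent = (exp_subj[s] * grad_exp[c]
                            + rng.normal(0.0, config.block_exponent_sd))
                exponent = max(exponent, 0.05)
                offset = off_subj[s]
                row = {"subject": s, "channel": c, "block": b,
                       "age": ages[s], "exponent": exponent, "offset": offset}
                peaks = []
                for band in _BANDS:
                    ps = peak_subj[band]
                    if not ps["present"][s]:
                        row.update({f"{band}_cf": np.nan,
                                    f"{band}_pw": np.nan,
                                    f"{band}_bw": np.nan})
                        continue
                    m = config.peak_models[band]
                    cf = float(np.clip(
                        ps["cf"][s] + rng.normal(0.0, config.block_cf_sd),
                        *m.cf_range))
                    pw = ps["pw"][s] * (grad_apw[c] if band == "alpha" else 1.0)
                    pw = max(pw + rng.normal(0.0, config.block_pw_sd), m.pw_min)
                    bw = float(ps["bw"][s])
                    peaks.append(PeakParams(cf, pw, bw))
                    row.update({f"{band}_cf": cf, f"{band}_pw": pw,
                                f"{band}_bw": bw})
                params = SpectralParams(AperiodicParams(offset, exponent),
                                        tuple(peaks), config.noise_sd)
                spectra[s, c, b] = simulate_spectrum(params, freqs,
                                                     seed=rng).power
                rows.append(row)
    truth = pd.DataFrame(rows)
    return CohortResult(config, seed, freqs, spectra, ages, truth)


def synth_time_series(params: SpectralParams, fs: float = 500.0,
                      duration: float = 30.0, seed=None) -> np.ndarray:
    """Random-phase time series whose PSD matches a target spectral model.

    Inverse-spectral synthesis: each positive Fourier bin gets amplitude
    sqrt(target linear PSD) with a uniform random phase, then an inverse
    real FFT produces the signal.  Welch estimation of the output recovers
    the target log10 spectrum (up to window bias) for durations of tens of
    seconds.
    """
    if fs < 70.0:
        raise ValueError("sampling rate must be >= 70 Hz to represent 35 Hz")
    n = int(round(fs * duration))
    if n < 2:
        raise ValueError("duration too short")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    pos = freqs > 0
    log_power = (aperiodic_component(freqs[pos], params.aperiodic)
                 + peak_component(freqs[pos], params.peaks))
    psd[pos] = 10.0 ** log_power
    rng = np.random.default_rng(seed)
    phases = np.exp(2j * np.pi * rng.random(freqs.size))
    phases[0] = 1.0
    if n % 2 == 0:
        phases[-1] = 1.0            # Nyquist bin must stay real
    # scale so the one-sided periodogram |X|^2 * 2 / (fs * n) equals the PSD
    amplitude = np.sqrt(psd * fs * n / 2.0)
    return np.fft.irfft(amplitude * phases, n=n)
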