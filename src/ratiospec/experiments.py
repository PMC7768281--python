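"""Pre-configured study experiments over synthetic cohorts.

Two cohort designs probe what band ratios measure:

* **exponent-dominated** — between-subject variance concentrated in the
  aperiodic exponent (which declines with age), with stable periodic
  peaks carrying no age effect.  If theta/beta ratio were a periodic
  measure, it would track theta and beta peak power here; instead it
  tracks the exponent, and its age correlation disappears once periodic
  power is isolated (the parameterized ratio).
* **alpha-dominated** — between-subject variance concentrated in alpha
  peak power, the eyes-closed situation.  Any ratio containing the alpha
  band then mostly reflects alpha power, with opposite signs for
  theta/alpha (alpha in the denominator) and alpha/beta (numerator).

Cohorts here use the study's 111 subjects but few channels and a single
block: measures are channel-averaged before correlation, so extra
channels add runtime without adding statistical information.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort_synth import (BandPeakModel, CohortConfig, generate_cohort)
from .stats_pipeline import (age_correlation_suite, bootstrap_ci,
                             bootstrap_diff_corr, cohort_measures,
                             ratio_param_correlation_table)

__all__ = ["exponent_dominated_config", "alpha_dominated_config",
           "dissociation_experiment", "alpha_dominance_experiment"]


def exponent_dominated_config(n_subjects: int = 111, n_channels: int = 5,
                              n_blocks: int = 1) -> CohortConfig:
    """Cohort whose between-subject variance is mostly aperiodic slope.

    All three peaks are always present (so fitted peak powers and
    parameterized ratios exist for every subject) with modest power
    variability unrelated to age; the exponent carries a strong negative
    age slope.
    """
    peaks = {
        "theta": BandPeakModel(1.0, 6.0, 0.4, 0.4, 0.08, 1.5, 0.2, (4.5, 7.5)),
        "alpha": BandPeakModel(1.0, 10.0, 0.6, 0.7, 0.1, 1.8, 0.2, (8.5, 12.5)),
        "beta": BandPeakModel(1.0, 21.5, 1.5, 0.35, 0.08, 2.0, 0.2, (14.0, 29.0)),
    }
    return CohortConfig(n_subjects=n_subjects, n_channels=n_channels,
                        n_blocks=n_blocks, exponent_age_slope=-0.025,
                        exponent_subject_sd=0.08, peak_models=peaks)


def alpha_dominated_config(n_subjects: int = 111, n_channels: int = 5,
                           n_blocks: int = 1) -> CohortConfig:
    """Cohort whose between-subject variance is mostly alpha peak power."""
    peaks = {
        "theta": BandPeakModel(1.0, 6.0, 0.3, 0.4, 0.05, 1.5, 0.15, (4.5, 7.5)),
        "alpha": BandPeakModel(1.0, 10.0, 0.4, 0.7, 0.3, 1.8, 0.15, (8.5, 12.5),
                               pw_min=0.2),
        "beta": BandPeakModel(1.0, 21.5, 1.0, 0.35, 0.05, 2.0, 0.15, (14.0, 29.0)),
    }
    return CohortConfig(n_subjects=n_subjects, n_channels=n_channels,
                        n_blocks=n_blocks, exponent_age_slope=-0.005,
                        exponent_subject_sd=0.03, peak_models=peaks)


def dissociation_experiment(seed: int | None = 0, n_resamples: int = 1000,
                            config: CohortConfig | None = None) -> dict:
    """The headline analysis: what does theta/beta ratio actually track?

    Generates an exponent-dominated cohort, measures raw ratios and
    fitted parameters per subject (channel-averaged spectra), and returns

    - Spearman rho of theta/beta vs fitted exponent, theta power, beta
      power, with bootstrap difference-of-correlation tests (on
      magnitudes) of exponent vs each peak power;
    - age correlations of the raw and the parameterized theta/beta ratio.
    """
    config = config or exponent_dominated_config()
    cohort = generate_cohort(config, seed=seed)
    measures = cohort_measures(cohort, fit=True)
    tbr = measures["theta/beta"].to_numpy()
    exponent = measures["exponent"].to_numpy()
    theta_pw = measures["theta_pw"].to_numpy()
    beta_pw = measures["beta_pw"].to_numpy()

    rng = np.random.default_rng(seed)
    corr_exp = bootstrap_ci(tbr, exponent, n_resamples, seed=rng)
    corr_tpw = bootstrap_ci(tbr, theta_pw, n_resamples, seed=rng)
    corr_bpw = bootstrap_ci(tbr, beta_pw, n_resamples, seed=rng)
    diff_theta = bootstrap_diff_corr(tbr, exponent, theta_pw,
                                     use_absolute=True,
                                     n_resamples=n_resamples, seed=rng)
    diff_beta = bootstrap_diff_corr(tbr, exponent, beta_pw,
                                    use_absolute=True,
                                    n_resamples=n_resamples, seed=rng)
    ages = age_correlation_suite(measures, n_resamples=n_resamples, seed=rng)
    ages = ages.set_index("measure")
    return {
        "measures": measures,
        "rho_exponent": corr_exp, "rho_theta_pw": corr_tpw,
        "rho_beta_pw": corr_bpw,
        "diff_exponent_vs_theta_pw": diff_theta,
        "diff_exponent_vs_beta_pw": diff_beta,
        "age_raw_tbr": ages.loc["theta/beta"],
        "age_param_tbr": ages.loc["param theta/beta"],
        "age_table": ages,
    }


def alpha_dominance_experiment(seed: int | None = 0,
                               n_resamples: int = 1000,
                               config: CohortConfig | None = None) -> dict:
    """Correlation table for a cohort where alpha power dominates.

    Returns the tidy (measure, parameter) correlation table plus, per
    ratio measure, the parameter with the largest |rho|.
    """
    config = config or alpha_dominated_config()
    cohort = generate_cohort(config, seed=seed)
    measures = cohort_measures(cohort, fit=True)
    table = ratio_param_correlation_table(measures, n_resamples=n_resamples,
                                          seed=seed)
    strongest = {}
    for label, grp in table.groupby("measure"):
        grp = grp.dropna(subset=["rho"])
        top = grp.loc[grp["rho"].abs().idxmax()]
        strongest[label] = (top["parameter"], float(top["rho"]))
    return {"measures": measures, "table": table, "strongest": strongest}
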