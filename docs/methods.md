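# Methods

## The measurement problem

A frequency band ratio divides mean power in a low band by mean power in
a high band — θ/β = mean 4–8 Hz power / mean 13–30 Hz power — and is
conventionally read as the relative strength of two oscillations.  But a
neural power spectrum is not a sum of band-limited oscillations: it is a
1/f-like **aperiodic** component, present at every frequency, with
**periodic** peaks riding on top of it.  Any fixed band therefore
captures aperiodic power, and a change in the aperiodic slope moves
every band ratio without any oscillation changing at all.  This package
makes that confound measurable: it simulates spectra with known
periodic/aperiodic content, measures ratios, parameterizes spectra to
separate the two components, and quantifies which generating parameters
the ratios actually track.

## Generative spectral model

A log10-power spectrum over frequencies f is

    P(f) = L(f) + Σₙ Gₙ(f) + ε(f)
    L(f) = b − χ·log10(f)
    Gₙ(f) = aₙ·exp(−(f − cₙ)² / (2wₙ²))

with aperiodic offset `b` (log10 au) and exponent `χ` (dimensionless; in
linear power the component is 1/f^χ), and per-peak center frequency `cₙ`
(Hz), power `aₙ` (log10 au above the aperiodic component) and bandwidth
`wₙ` (Hz, the Gaussian width parameter — full width at half maximum is
2.355·w; "bandwidth" means `w` everywhere in this package).  ε is white
Gaussian noise per frequency bin, default SD 0.005 au, in log10 units
(independent draws per bin).  The default axis is 1–35 Hz at 0.5 Hz
steps, endpoints included (69 bins), generated by count to avoid float
drift.  All logs are base 10.

## Band ratios

Bands are θ 4–8, α 8–13, β 13–30 Hz with **inclusive** edges, preserving
the canonical printed definitions: the 8 Hz bin belongs to both θ and α.
Custom half-open bands can be supplied where that overlap is unwanted.
Averaging is over **linear** power (10^P), matching the absolute-power
convention; ratios are therefore invariant to any offset shift in log
power and to any positive rescaling of linear power.  The standard ratio
set is θ/β, θ/α, α/β; log10 ratios are used for display because raw
ratios are right-skewed.

## Sweep experiments and the parameter census

Single-parameter sweeps hold all generating parameters at their defaults
(θ peak 6 Hz, α 10 Hz, β 21.5 Hz; peak power 0.5 au; bandwidth 0.1 Hz;
offset 0; exponent 1) and vary one parameter over its grid: center
frequencies 4–8/0.25, 8–13/0.25, 13–30/1 Hz; powers 0–1/0.1 au;
bandwidths 0.2–0.4/0.2 Hz; offset 0–2.5/0.25; exponent 0–3/0.2 (both
endpoints included).  Paired sweeps take the Cartesian product of two
grids.  The census counts, with noise disabled, how many of the ten
enumerated parameters (θ and β CF/PW/BW, α CF and PW, offset, exponent)
change θ/β by more than 1e−6 relative to baseline — a tolerance far
above float error (~1e−15) and far below any genuine effect.  The answer
is 8; the exceptions are the offset (multiplies linear power equally in
every band, cancelling from every ratio) and α power (a 0.1 Hz-wide α
peak underflows before reaching either the θ or β band).  α bandwidth is
reported outside the census: over its printed 0.2–0.4 Hz sweep its θ/β
effect is also below working precision.

Two quirks of the printed parameter tables are used verbatim and
documented rather than corrected: (1) the default bandwidth (0.1 Hz)
lies outside its own sweep range (0.2–0.4 Hz); (2) because that default
width is narrower than the 0.5 Hz bin spacing, the θ center-frequency
sweep (increment 0.25 Hz) alternates between on-bin and off-bin
positions, making it non-monotone via a comb artifact.  The classic
rise-then-fall of θ/β as the θ peak crosses its band — rising as the
peak moves into the band, falling as mass leaks toward the α edge —
appears once the peak is wide enough to straddle a band edge; the tests
demonstrate it at a 1 Hz bandwidth, which is also the fit's lower width
bound.

## Spectral parameterization

`fit_spectrum` decomposes a spectrum into aperiodic parameters plus up
to `max_peaks` Gaussians, in the staged fashion of the field's
spectral-parameterization tools:

1. **Seed aperiodic fit** — OLS of log10 power on log10 f, iterated
   three times keeping only the lowest-residual half of bins at each
   step (peaks only push power up, so the low-residual half is the least
   peak-contaminated).
2. **Flatten** — subtract the aperiodic fit.
3. **Iterative extraction** — repeatedly take the maximum of the
   flattened spectrum as a candidate peak; stop when its height falls
   below max(`min_peak_height`, `peak_threshold_sd` × SD of the current
   flattened spectrum) or at `max_peaks`.  The width guess is the
   half-maximum crossing distance (linearly interpolated between bins,
   shorter side, clamped to `peak_width_bounds`); candidates whose
   center lies within one bandwidth of an axis edge are discarded as
   truncated-tail artifacts.  Each accepted or discarded candidate is
   subtracted before the next search.
4. **Joint peak refit** — bounded least squares of all extracted
   Gaussians together against the flattened spectrum.
5. **Aperiodic re-fit** on the peak-removed spectrum.
6. **Joint refinement** — one bounded least-squares fit of aperiodic
   parameters and all peaks simultaneously.  Stages 1–5 give good
   starting points but inherit bias wherever peak and aperiodic
   components overlap (wide low-frequency peaks especially); the
   simultaneous refinement removes that bias.  Peaks whose refined
   height drops below `min_peak_height`, or that collapse onto an axis
   edge, are dropped and the remainder re-refined until stable.

Defaults mirror the study's fitting settings: width bounds 1–8 Hz, max
8 peaks, minimum peak height 0.1 au, detection threshold 2 SD, fixed
(no-knee) aperiodic mode.  Goodness of fit is r² (squared Pearson
correlation of model vs data, computed on log10 power, since the model
is defined in log space) and mean absolute log10 error.  Non-convergent
fits return a diagnostic-carrying failure result rather than raising.

Band assignment gives each band the fitted peak whose center lies inside
it (highest power wins; ties go to the lower frequency).  A
**parameterized ratio** is the quotient of two bands' assigned peak
powers — isolated periodic power, with the aperiodic component already
removed — and is absent whenever either band has no detected peak;
absent values are excluded listwise from correlations.

An independent reference implementation of the same model family
(fooof/specparam) can serve as an optional cross-validation oracle on
shared fixtures; it is not a dependency of this package and is not used
at run time.

### Calibration evidence

`validation.recovery_suite` draws random spectra with 0–3 peaks, one per
band at most, powers 0.3–0.9 au, widths 1–2.5 Hz (inside the fit
bounds), offsets −0.5–1.5 and exponents 0.5–2.5, accepting only draws
whose peak centers are pairwise separated by at least twice the sum of
their widths ("well separated" — overlapping Gaussians have no unique
decomposition, so separation is part of the claim being tested).  On 200
noiseless spectra the fitted exponent lands within 0.05 and every center
within 0.25 Hz in 100% of draws, r² ≥ 0.999 everywhere; at the study's
0.005 au noise level the relaxed tolerances (0.1 / 0.5 Hz) also hold in
100% of 200 draws.  These numbers are recomputed by
`analysis/03_fit_recovery.py` and the test suite, not quoted from
anywhere.

## Welch estimation and time-series synthesis

`welch_psd` uses Hann windows of 2 s with 25% overlap and mean averaging
(window and averaging are conventional defaults; the window length fixes
the 0.5 Hz resolution the rest of the package assumes), restricted to
1–35 Hz and returned in log10.  `synth_time_series` inverts the
spectral model: each positive rfft bin gets amplitude
√(PSD·fs·N/2) and a uniform random phase (DC zero, Nyquist real), so the
one-sided periodogram of the output equals the target PSD.  Default
500 Hz sampling and 30 s duration (the usable eyes-closed interval per
resting block).  Round trip: synthesis at χ = 1 → Welch → fit recovers
the exponent within 0.1 in ≈96% of 50 realizations (estimator variance
of a 19-segment Welch average is the limiting factor).

## Synthetic cohorts

`generate_cohort` emulates the structure of a developmental resting EEG
study without any real data: 111 subjects (ages truncated-normal on
6–44 years; the location/scale are solved numerically so the *marginal*
mean and SD equal the configured 15.79/8.03 — naive parameters would
miss the mean by ~1.7 years because the lower bound sits only 1.2 SD
below it), 111 channels, 5 blocks.  Hierarchy: subject-level exponent =
baseline 1.5 − 0.02·(age − mean age) + N(0, 0.1), floored at 0.1;
subject-level offset N(0, 0.2); per-band peak presence Bernoulli (α 1.0,
θ 0.6, β 0.6 — detection rates are not reported anywhere, so these are
declared assumptions giving parameterized ratios realistic missingness);
peak CF/PW/BW drawn per subject (α power high and variable, reflecting
eyes-closed α dominance; widths 1–3 Hz so generated peaks are fittable);
a smooth cosine gradient over the ordered channel index multiplies the
exponent (±10%) and α power (±20%), standing in for scalp topography
without electrode geometry; per-block jitter on exponent, peak power and
center frequency.  The **negative** exponent–age slope (aperiodic
flattening over development) follows the developmental literature and
the study's own confidence intervals.  Ground-truth parameters are
stored losslessly beside the spectra.

What the generator does *not* emulate: real electrode geometry, artifact
structure (EOG, movement), non-Gaussian and non-stationary dynamics,
subject-specific 1/f knees, harmonics, or any dependence of periodic
power on age.  Passing cohort tests therefore shows the *pipeline* is
correct and that the conflation mechanism operates as predicted when the
generating process is known — not that real EEG obeys these
distributions.

Experiment presets (`experiments.py`): the **exponent-dominated** cohort
concentrates between-subject variance in the aperiodic slope (slope
−0.025/year, subject SD 0.08; all peaks present, power SDs ≤ 0.1,
age-independent) — if ratios measured periodic power, θ/β would track
peak powers here, and it does not; the **alpha-dominated** cohort
concentrates variance in α power (SD 0.3 vs ≤ 0.05 elsewhere, slope
−0.005).  Both default to 111 subjects, 5 channels, 1 block: measures
are channel-averaged before cross-subject correlation, so beyond a few
channels extra channels only add fitting time, and one block suffices
for between-subject questions.  The block/topography analysis
(`analysis/06`) uses 60 subjects × 21 channels × 5 blocks, enough for
240 pooled block differences and 21-channel spatial maps while keeping
the 300 per-block fits affordable.

## Statistics

Spearman rho is the Pearson correlation of average-ranked values
(average ranks for ties); zero rank variance yields an undefined
(absent) result.  Confidence intervals are percentile bootstrap over
paired resamples — 5000 resamples and 95% intervals by default
(experiment presets use 1000 to keep runtimes in seconds at 111
subjects, which changes CI endpoints by thousandths).  Zero-variance
resamples are redrawn (capped, with the skip count reported).
Difference-of-correlation tests bootstrap rho(x,y₁) − rho(x,y₂)
per resample (absolute magnitudes first when comparing strengths
irrespective of sign); the empirical two-sided p is
2·min(share ≤ 0, share ≥ 0), clipped to [2/(n+1), 1] so a finite
resample count never reports p = 0.  No multiple-testing correction is
applied anywhere — outputs carry raw CIs (and p only where a bootstrap
test defines one).  Block differences are value(block) −
value(prior block), pooled across subjects for correlation; topography
correlations rank-correlate per-channel group means.  Subject-level
measures default to channel averages before correlation; a pooled
per-channel mode exists because "across all channels" admits both
readings.

## Known limitations

- Band-edge bins shared by two bands (8 and 13 Hz) make adjacent-band
  ratios slightly conservative; half-open custom bands avoid this.
- The fitter assumes well-separated Gaussian peaks; strongly overlapping
  oscillations have no unique decomposition and recovery guarantees do
  not apply to them.
- The Welch round trip inherits ~0.02–0.05 exponent SD from 19-segment
  estimator variance; single-subject exponent estimates from 30 s of
  data carry that floor irrespective of fit quality.
- Cohort defaults are declared assumptions where the emulated study
  reports no distributional parameters (peak prevalence and parameter
  spreads); conclusions about real data should rerun the pipeline on
  real spectra, not lean on these defaults.
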