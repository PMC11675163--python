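# Methods

## Signals and preprocessing

A subject is a pair of uniformly sampled traces, respiration (RSP) and
heart rate (HR), sharing one sampling rate; sample *i* lives at
*t = i/fs* seconds (0-based). The analysis segment is the first 180 s
(`segment_seconds`). Both traces are band-pass filtered to 0.1–1 Hz
with a Butterworth filter of order 2 per pass applied forward and
backward (zero phase, effective order 4), then z-scored (mean 0, SD 1,
n−1 denominator). The band keeps the respiratory fundamental
(0.15–0.30 Hz at rest) and the respiratory-sinus-arrhythmia component
of HR variability while removing drift and cardiac-scale content;
zero phase matters because the quantity of interest is a time-lag.
The filter is realized as second-order sections (`sosfiltfilt`): at
1 kHz the band edges sit at ~10⁻⁴ of Nyquist, where transfer-function
coefficients are ill-conditioned but SOS are stable. Edge handling is
odd-reflection padding over scipy's default (short) padding length, so
runs are bit-reproducible; note that a short pad cannot suppress the
0.1 Hz high-pass edge transient, which decays on a ~10 s scale at both
ends of a trace (consequences below).

The RSP derivative uses central differences on interior samples,
`(x[i+1] − x[i−1])·fs/2`, with second-order one-sided differences at
the two endpoints (`numpy.gradient`, `edge_order=2`); units are
z-units/s. No extra smoothing is applied — the signal is already
band-limited to ≤ 1 Hz, so high-frequency noise amplification is
bounded. The stage order is fixed: extract → filter → z-score, with the
derivative taken on the filtered, z-scored RSP (the derivative trace is
*not* re-standardized, keeping the model equation literal).

## Time-lag estimation

The lag is the integer-sample shift τ ∈ [−max_lag, +max_lag]
(default max_lag = 10 s) maximizing the normalized cross-correlation of
RSP(t) with HR(t+τ); positive lag = HR delayed. Estimation is
two-stage, and the design is driven by two measured failure modes of
the textbook estimators at respiratory frequencies:

1. The classic 'coeff' normalization (correlation sum divided by the
   full-signal energies) is biased by its overlap taper: for a 0.25 Hz
   component on a 180 s window the argmax shifts by 2–3 samples.
2. Per-overlap Pearson normalization removes that bias but degenerates
   for quasi-periodic signals: peaks at τ ± k·period become near-ties
   once the taper penalty is gone, and the argmax can jump by whole
   periods.

So the **coarse stage** is the 'coeff'-normalized correlation — its
taper is exactly what disambiguates period multiples, and its value at
the chosen lag is the reported, cross-subject-comparable peak
correlation. The **refinement stage** re-scans a ±0.5 s neighbourhood
of the coarse argmax with a true Pearson correlation between a *fixed*
interior window of RSP and sliding windows of HR; the window omits
10 s per side (`edge_trim_s`), keeping filter edge transients out of
the decision entirely. Exact ties break toward the smallest |lag|.
On traces too short for the trim (below roughly half a minute) the
coarse result stands. Verified accuracy: ≤ 1 sample against the
construction on filtered triangular waves across 0.15–0.30 Hz, and
≤ 0.2 samples against the sinusoid closed form.

An inherent limitation, not an estimator defect: for quasi-periodic
signals the lag is only identifiable modulo the breath period. A
subject whose true delay exceeds about half their breath period is
assigned the equivalent smaller-|lag| peak (one period off), exactly as
MATLAB's `xcorr` would. Under the default cohort (delays
~ N(849, 345²) ms, periods 3.3–6.7 s) this affects roughly one subject
in a few cohorts; such subjects surface as lag outliers downstream.

## Mutual information

Plug-in MI from the joint histogram: 16 × 16 equal-width bins spanning
each signal's observed range, `MI = Σ p_ij ln(p_ij/(p_i p_j))`, empty
cells contributing zero; reported in nats (a log base is configurable —
the bin count and base materially change the absolute value, so
cross-study comparisons must match both). Two error sources are worth
separating: the sampling bias of the plug-in estimator,
≈ (B−1)²/(2n) ≈ 6·10⁻⁴ nat at n = 180 000, which is negligible, and the
*quantization loss* of a 16-bin partition, which is not — for a
bivariate Gaussian with ρ = 0.9 the binned MI is ≈ 0.73 nats against
the continuous closed form 0.830. MI values produced here are
therefore estimates of the *discretized* dependence; they order
subjects correctly but sit below the continuous-signal ideal by
roughly 0.1 nat at this bin count.

## Outlier rule and cohort summaries

A subject's lag is an outlier if it lies more than 3 scaled MADs
(scale 1.4826) from the cohort median; when the MAD is zero, any value
off the median is flagged. Uncoupled recordings (emulated in the
synthetic cohort by band-passed independent noise as HR) produce large
spurious lags and low peak correlations and are caught by this rule.
Lag mean/SD are summarized over non-outliers; MI statistics and the
Pearson correlation between MI and peak correlation use all subjects.

## HR models and selection

Per subject, two nested OLS fits of the processed HR on the processed
RSP (and its derivative), using every sample of the segment:

- model 1: HRm = b0 + b1·RSP
- model 2: HRm = b0 + b1·RSP + b2·dRSP/dt

Fits use `numpy.linalg.lstsq`; R² uses mean-centered total sum of
squares. Comparison uses the Gaussian-likelihood corrected AIC,
`AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`, with k counting intercept,
slopes and noise variance (3 vs 4); additive constants cancel in the
comparison, ties go to the smaller model. At n ≈ 180 000 the
small-sample correction is ~10⁻⁴, so AICc and AIC agree; AICc is
implemented because the correction costs nothing and covers short
traces. Residuals of these fits are strongly autocorrelated (both
signals are ~0.2 Hz oscillations sampled at 1 kHz): coefficient point
estimates, R² and AICc ranks are meaningful, classical standard errors
are not, and none are reported.

No lag alignment is applied before fitting — deliberately. Model 1
then sees the raw phase-shifted relation (the closed RSP-vs-HR loop),
and the derivative term of model 2 is what absorbs the shift: for a
single frequency ω, `b1·sin(ωt) + b2·ω·cos(ωt)` reaches any phase, so
model 2 fits a sinusoidal subject essentially perfectly. Two
consequences measured on noise-free synthetic subjects: (i) with the
triangular waveform, in-band harmonics each need a *different* phase
shift, so model-2 R² lands between 0.79 and 0.999 depending on breath
rate rather than at 1; (ii) even in the sinusoid limit the 0.1 Hz
filter edge transient caps pipeline R² near 0.993 on a 180 s trace.
Model 2 still wins AICc by enormous margins in both cases. The fitted
b2 sign equals the injected gain2 sign unless the subject's effective
lag phase ω·lag exceeds π (phase wrap), which mirrors the occasional
positive-b2 subject in real resting cohorts. The sign of b1 is
likewise phase-dependent and is tallied but makes no stable prediction.

## Simulator

`generate_rsp` builds an asymmetric triangular wave (rising,
inspiratory ramp occupying `asymmetry` = 0.4 of each cycle), smoothed
by a centered moving average (`smooth_seconds` = 0.5 s, forced to an
odd sample count) evaluated on an extended grid so there is no edge
distortion, then z-scored. The asymmetry and smoothing width are
package choices — resting inspiration is shorter than expiration, and
0.5 s rounds the ramp corners without flattening the cycle.
`apply_delay` shifts by a whole number of samples (delay rounded half
up) and fills the prefix by periodic extension of one cycle
(`period_s`), so no transient enters lag estimation; with no known
period the whole trace wraps, and zero-fill is available. `simulate_hr`
then forms

```
advanced_HR = gain3·(gain1·delayed + gain2·d(delayed)/dt) + N(0, noise_sd²)
```

with seeded noise. The derivative is taken on the *delayed* trace:
that is the reading under which the derivative term advances the
delayed signal back toward RSP, which is the mechanism being modelled.
gain2 carries seconds (derivative term commensurate with the signal
term); gain1, gain3 are dimensionless.

Sign conventions collected in one place: with this package's
positive-lag-means-HR-delayed convention, a **positive** gain2 advances
HR (measured lag = delay − atan2(gain2·ω, gain1)/ω, the
`sinusoid_lag_oracle` closed form), and a **negative** gain2 retards it.
A negative gain2 is what reproduces the empirical preponderance of
negative fitted b2 (the fit recovers b2 = gain3·gain2 exactly when HR
is regressed on its generating trace), at the price of an effective
cohort lag above the raw injected delay. Both gains are exposed signed;
no "correct" sign is hard-coded.

## Synthetic cohort

The generator emulates the study conditions: 45 subjects, 180 s at
1000 Hz, breath rate uniform on [0.15, 0.30] Hz (the resting range,
truncated at 0.15 Hz so every 10 s lag window holds ≥ 2 cycles), delay
~ N(849.21, 344.84²) ms redrawn until positive, gain1 = 1, gain2
uniform on [−0.6, −0.35] (so |gain2|·ω ≥ 0.3 even at the slowest breath
rate, keeping the derivative term identifiable for every subject),
gain3 = 1, white Gaussian noise of SD 0.2 z-units added to HR *before*
the pipeline's band-pass so the analyzed noise is band-limited like
measurement noise. HR is generated directly as a continuous trace —
the ECG→R-peak→HR extraction step of real acquisitions is out of scope,
so the generator emulates that step's output. Injected outlier
subjects receive independent band-passed noise as HR. All per-subject
randomness derives from `master_seed` via `SeedSequence` spawning:
cohorts are byte-reproducible, and `cohort_truth_table` returns the
ground truth without re-simulating.

What the generator does **not** emulate: realistic HR variability
spectra (LF/VLF structure), ectopic beats, movement artifacts,
breath-to-breath rate variability within a subject, or any
chemoreceptor feedback closing the loop on the gains. Passing tests
therefore demonstrate that the analysis recovers the
delay-plus-derivative mechanism under controlled conditions — not that
real recordings contain no further structure.

## Numerical and scale choices

- Test-suite statistical checks run at reduced scale (60 s at 250 Hz):
  the estimator's resolution (1 sample = 4 ms) stays negligible against
  the 345 ms cohort delay SD, so the statistics are unchanged while
  multi-seed sweeps stay fast. Study-scale checks (180 s, 1 kHz, 45
  subjects) run in the acceptance tests and `scripts/acceptance.py`.
- Thresholds in stochastic tests are frozen from derivations made
  before the tests were run: the MAD-rule detection tally uses a
  Monte-Carlo bound on per-seed exact-detection probability; the
  cohort-mean recovery check pools 10 seeds and uses the 2·SD/√45 band.
- Determinism: identical inputs and configuration yield byte-identical
  CSV/JSON outputs (fixed column order, fixed float formatting);
  timestamps appear only in logs.
- Degenerate inputs fail loudly and early: constant traces are rejected
  before filtering (a band-passed constant is numerical dust, not a
  constant), zero-variance z-scores and single-bin histograms raise,
  rank-deficient designs raise; in cohort runs a failing subject is
  skipped with a warning, and a run with more than half its subjects
  failing aborts.

## Known limitations

- Lag identifiability modulo the breath period (above): delays beyond
  ~half a period cannot be distinguished from their wrapped image.
- Histogram MI at 16 bins under-reports continuous-signal MI by
  ~0.1 nat and is bin/base-sensitive; treat absolute values as
  partition-specific.
- AICc and coefficient estimates ignore residual autocorrelation; no
  inferential statistics are produced, by design.
- The band-pass edge transient (~10 s per end) is kept out of the lag
  decision but not out of the regressions; it caps noise-free R² below
  1 and adds a small, duration-dependent dilution to fitted
  coefficients.
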