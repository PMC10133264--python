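# Methods

This note documents the models, estimators, parameter choices and known
limitations of `seegflow`, in the order the pipeline runs.

## Data model

A dataset is a `TrialTensor`: voltages indexed (lead, trial, sample) at a
base sampling rate of 1 kHz, aligned so that ≥900 ms of pre-onset baseline
precede static-stimulus onset (`validate_baseline` enforces this, since the
GC baseline window spans −900…0 ms).  Invalid data are carried as an
explicit boolean mask, never as sentinel values; after rejection the mask
is all-or-nothing per (lead, trial), and every downstream stage treats
masked combinations as absent.  Time convention: sample 0 is the first
recorded sample, latencies are reported in ms relative to onset, windows
are half-open `[start, end)`.  On disk: HDF5 (`/data`, `/mask`, scalar
attributes, a `/trials` label table), lead metadata as TSV, configuration
as YAML.  The resolved configuration is serialized next to every pipeline
output so each result is traceable to its exact parameter set.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:

* **Baseline**: independent unit-variance white Gaussian noise per lead
  (optional 1/f admixture via `pink_fraction`; default 0, keeping
  closed-form GC oracles valid).
* **Responses**: 50–150 Hz band-limited Gaussian noise multiplied by a
  raised-cosine envelope, added on the gated task's trials.  Defaults:
  onset 170 ms, duration 120 ms — the response regime of gamma-responsive
  temporal-pole leads (onsets ~165–200 ms, durations ~60–115 ms).  The
  default amplitude (1.0 × noise SD at envelope peak) is chosen so a
  responsive lead is unambiguous in the trial average (static-epoch peak
  z ≫ 3) while single-trial power stays weak enough that genuine responses
  do not register as whole-trial power outliers in the feature-vector
  screen — mirroring real recordings, where responses are far smaller than
  artifacts.  Weak-response regimes (trial-averaged z ≈ 0.5–1) are reached
  by lowering `amplitude`.
* **Couplings**: true gated VAR terms
  `x_target[t] += gain · x_source[t − lag]`, applied in time order, active
  only inside `window_s` (default 0.1–0.4 s post-onset) and only on the
  gated task's trials.  Because the generator's couplings live in the same
  model class the engine fits, parameter-recovery tests are meaningful.
  Lags must be integer sample counts at the simulation rate.
* **Artifacts**: one injector per rejection class — whole-trace amplitude
  scaling; narrow-band gamma bursts (×10 local SD); coherent low-frequency
  transients shared (with ±30 % gain jitter) by a fraction of leads;
  coherent step offsets on all leads; exactly constant segments.  Flat
  segments and glitches may not overlap on a sample, keeping the classes
  separable for testing.  Every placement is resolved and recorded in the
  returned `GroundTruth`.

All randomness flows from a single integer seed; identical seeds give
bit-identical tensors.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: volume conduction and shared references, 1/f
spectra with oscillatory peaks, non-stationary baselines, realistic
interictal spike morphology, refractory/overlapping artifact classes, and
smooth (non-square) coupling gain profiles.

## Artifact rejection

All screens except flatness run on linearly detrended traces (flatness
uses raw data, since detrending perturbs exact constancy).  Gender and
action trials are pooled for outlier analysis.

1. **Feature-vector outliers** — per lead, each trial is summarized by
   [log Welch power summed over 50–150 Hz, log SD over time]; components
   below 1e−42 are dropped before the logs.  Center/covariance come from
   the minimum covariance determinant (MCD) estimator; trials whose robust
   Mahalanobis distance exceeds the bivariate-Gaussian reference for the
   configured percentile are flagged (97.5 % ↔ 2.7162 = √χ²₀.₉₇₅(2)).
   Two numerical choices matter at realistic trial counts (~40/lead):
   the MCD support fraction is 0.9 — efficient while still tolerating the
   ~10 % contamination injected artifacts produce — and squared distances
   are rescaled so their median equals χ²₀.₅(2), the standard finite-sample
   calibration without which the nominal percentile over-rejects several
   fold at small n.  Leads with fewer than 10 valid trials are skipped with
   a warning (robust covariance on 2 features needs ≥ ~2× features plus
   margin).
2. **Wavelet blobs** — per (lead, trial), the magnitude of a generalized
   Morse CWT (γ=3, time-bandwidth 60, ten voices/octave, frequencies
   >10 Hz), time-downsampled by 10, binarized at the image's 95th
   percentile, holes filled, 8-connected components labelled; the
   largest-area blob represents the strongest transient oscillatory event.
   Largest blobs are pooled across all combinations ("global" variant) and
   a combination is flagged when its blob centroid frequency exceeds
   10 Hz and its max intensity is *strictly* above the pooled 95th
   percentile (ties at the boundary are kept, so identical trials flag
   nothing).
3. **Putative interictal events** — per trial, leads are z-scored and the
   maximum absolute normalized cross-correlation per lead pair (lags
   ±150 samples, 400-sample windows stepped by 50) is kept across windows;
   a 20-bin histogram of the pairwise maxima summarizes the trial; trials
   are compared by the 1-D earth-mover distance between histograms and the
   distance matrix is split by fuzzy c-means (c=2, m=2, hand-rolled —
   ~40 lines of the standard algorithm).  The smaller cluster (in trial
   count) is the outlier set.  Degeneracy guard: if no trial reaches
   membership 0.6 in either cluster, or the smaller cluster exceeds 40 %
   of trials, the screen declares "no coherent-event cluster" and returns
   empty — exchangeable data must not trigger mass rejection.
4. **Trial amplitude outliers** — per-trial peak |value| across all leads,
   screened by the median ± 3 scaled-MAD rule.
5. **Glitches** — per trial, the mean across leads of |x[t]−x[t−1]|; the
   peak local maximum per trial is screened at `glitch_threshold_factor`
   scaled-MADs.  The statistic is an extreme-value maximum whose clean-data
   dispersion is tiny, so the default factor is 5 (a 3-MAD rule flags
   several percent of clean trials); genuine coherent jumps exceed the
   bound by an order of magnitude.
6. **Flatness** — samples with successive differences <1e−10 are labelled;
   (lead, trial) combinations with more than `replen`=3 fully-labelled
   windows (length 100, step 50) are flagged.  Defaults are chosen so a
   500 ms saturation plateau is flagged while probability-zero events in
   continuous noise are not.

**Combination**: interictal ∪ amplitude trials are removed as whole trials
only when the trial also contains more than `trial_reject_lead_threshold`
(default 5) feature-vector outlier leads; glitch trials are removed
unconditionally; the combined mask is the union of removed trials with the
three combination-based masks.  The report gives lead count, total and
rejected lead-trials (union, counted once), fraction, and median/min
remaining trials per lead.

On clean synthetic data the combined false-positive fraction is ~8 %,
dominated by the two percentile screens (≈2.5 % + ≈5 % by construction).

## Gamma power and lead classification

Power is computed at the ten sub-band centers 55…145 Hz, averaged across
sub-bands, and averaged within non-overlapping 25 ms bins.  The default
wavelet is the complex Morlet (via PyWavelets), whose short temporal
support (~1 cycle SD) preserves onset timing; the Morse family used in
artifact screening (time-bandwidth 60, ~8-cycle support) is available via
`power_wavelet='morse'` but smears burst edges by tens of ms and is not
used for latencies.  Traces are demeaned before the transform (recordings
are AC-coupled; this also removes DC leakage of the convolution).

Per lead the trial-averaged time course is z-scored against the 1 s
baseline; a zero or vanishing baseline SD (dead or constant-power channel)
raises an error.  Classification: *responsive* iff the gender-task z
exceeds 3 in any bin of the static epoch (75–275 ms post-onset);
*selective* iff additionally the action-task static epoch and the
gender-task video epoch stay at or below 3.  Latency and duration of
averaged traces are threshold crossings at z = 2 with linear interpolation
between bins (a 3 SD threshold is used in masking-style analyses; the
caller supplies it).  `gc_power_correlation` returns the Pearson
correlation of connection strengths with source power, target power, and
their product, as the diagnostic that GC is not a power artifact.

## Granger engine

Sliding windows of 100 base-rate samples, stepped by 10, cover the trial.
Within a window the data are decimated by the sample-spacing factor
ns ∈ {1, 2, 4} (plain sample skipping — the intent is to *re-time* the
model, so no anti-alias filter), demeaned per lead over the pooled window,
and a VAR(4) is fitted by OLS with trials pooled as independent
realizations (each trial contributes `win/ns − 4` regression rows).  The
normal equations get a ridge `1e−8·tr(G)/p` only when the Gram matrix
condition number exceeds 1e10.  Time-domain GC per direction is
`ln(σ²_reduced/σ²_full)`; since the reduced regressor set is nested in the
full one on identical rows, F ≥ 0 by construction.  A parametric
frequency-domain decomposition (Geweke, from the fitted transfer function,
101 points from 0 to the setting's effective Nyquist) is available as a
diagnostic only.

Run modes per pair: point estimate on all common trials (selected
per-pair, greedily — pairs with fewer than 12 common trials are skipped);
20 bootstrap runs (trials resampled with replacement) giving per-window
mean/SD; 20 surrogate runs in which each lead's trial order is permuted
independently — surrogate mean/SD turn F into a z-score whose null is "no
trial-locked coupling".  Baseline z-scoring uses the mean/SD of the raw F
over windows wholly inside −900…0 ms (the raw trace, not the
surrogate-normalized one, is z-scored; this is configurable in principle
but raw is the default reading).  GC is computed within one task's trials;
pooling tasks would mix coupling regimes and is not supported by the
model class.

**Strength and typing.**  `C` is the extreme of the baseline-z trace over
windows wholly inside 0.1–0.4 s post-onset (the same wholly-inside
convention as the baseline; windows straddling the response edges mix
regimes and are excluded).  Both extremes positive → max; both negative →
min; mixed with |max−min| < 3 → mean; otherwise the extreme of larger
magnitude, signed.  Typing at |z| = 5 with strict inequalities (ties fall
to the weaker category): D (C₁>5, C₄≤5), M (both), A (C₄>5, −5≤C₁≤5),
N (C₄<−5, C₁<5), opposite (strong with flipped signs — excluded from
downstream statistics), weak otherwise.

**Conditioning.**  A third lead joins the VAR (12 regressors per target;
window length 100 ms keeps the parameter count viable, so exactly one
conditioning lead per pair).  The screen tries every candidate once and
returns those that pull the connection's z below 3.  The conditioned z is
read at the window where the *unconditioned* baseline-z peaks: the
question is whether that connection peak survives conditioning, and a
fresh maximum over the conditioned trace would instead report the max of
~20 overlapping null windows (inflated by estimator noise in exactly the
marginal cases the screen must decide).  A via-lead is an outside lead
with strengths >5 both from the pair's source and to its target;
`region_average_gc` averages traces of one outside lead over the several
leads of a region before strength extraction.

## Onset timing

The 50 %-of-peak onset finds the peak in a search window (default
50–500 ms post-onset, covering observed response latencies with margin),
normalizes by it, and linearly interpolates the first exceedance of 0.5 —
scale-free by construction and equivariant under time shifts.  GC traces
must additionally pass a peak-z > 3 filter.  Two trace populations are
compared by bootstrap: 100 resamples per set, one onset per bootstrap mean
curve, difference of bootstrap means, pooled SD, significance flag at
|diff| > 2·pooled SD (the bootstrap criterion chosen here; error grouping
across channels vs channel pairs is the caller's choice of input sets).

## Problem sizes and numerical checks

Recovery experiments (in `seegflow.evaluation`) run at 2–6 leads and
40–80 trials of 2 s each — small enough for laptop-scale iteration, large
enough that every effect they measure is far from threshold: the
VAR(1)-oracle comparison uses 10⁶ samples (engine vs closed-form
innovation variances from the discrete Lyapunov equation agree to <1 %);
surrogate false-positive rates pool ~7,600 windows; onset recovery
averages 20 seeds.  Coupling gains in the experiments (0.4; 0.9 for the
common-driver motif) put true connections far above the |z| = 5 criterion
while reverse directions stay at noise level.

## Known limitations

* OLS VAR with pooled trials assumes within-window stationarity; square
  gain gates violate it in edge windows, which is why strength extraction
  uses wholly-inside windows.
* 20 surrogates give a z-denominator with ~19 d.f.; surrogate-z tails are
  t-like, not Gaussian (the false-positive bound accounts for this).
* The MCD median recalibration assumes the majority of trials per lead is
  clean; a lead with >50 % artifacts defeats it.
* Decimation without anti-aliasing folds high-frequency power at NS2/NS4;
  this matches the re-timing intent but means NS4 estimates see aliased
  broadband noise.
* The conditioning screen tests one conditioning lead at a time; joint
  multi-lead conditioning is out of scope.
* Mixed-effects group statistics, clinical formats, re-referencing, and
  brain-surface visualization are out of scope.
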