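# Methods

This note documents the models, estimators and design choices behind
`entropath`, what the synthetic cohort does and does not emulate, and the
numerical conventions that a user comparing variants should know about.

## The synthetic cohort

The generator emulates a 28-subject, fixed-order, placebo-controlled
crossover: a 1 mg (functionally inactive) and a 25 mg (fully active)
psilocybin condition, with 4-minute eyes-closed 19-channel 10–20 EEG at
300 Hz recorded at baseline and 1, 2 and 4.5 h post-dose, behavioral
scores after each session, and parcellated resting-state timeseries before
and one month after the active session.

A per-subject latent z-score ("entropy responsiveness") is the single
source of coupled individual differences:

* **EEG.** Each recording is a 10 Hz sinusoid (center of the alpha band,
  random phase per channel) plus white noise band-limited to 1–45 Hz
  (matching the analysis band; 1/f shaping is deliberately omitted — the
  entropy/alpha contrast is the target, not spectral realism). Under
  25 mg the alpha amplitude is scaled by (1 − 0.55·m) and the noise by
  (1 + 0.5·m), where the modulation m is 0.8 at 1 h, 1.0 at 2 h, 0.15 at
  4.5 h, multiplied by (1 + 0.3·latent). Baseline and all 1 mg recordings
  are unmodulated. Identical seeds draw identical phases and noise, so
  paired condition contrasts isolate the amplitude modulation.
* **Behavior.** Standardized chain insight* = 0.55·z + e₁,
  wellbeing_change* = 0.50·insight* + 0.20·z + e₂, with noise SDs chosen
  so both variables have unit variance. Scores are then affine-mapped into
  instrument ranges: insight as a continuous PIS-style sum score (six
  0–100 visual-analogue items, total 0–600; active mean 250 ± 80, placebo
  mean 40 ± 20), well-being as WEMWBS totals clipped to the instrument's
  14–70 range (baseline drawn from the population norm 51 ± 9; active
  change +4.7 ± 6 points). The 0.55/0.50 slopes are the normalized path
  coefficients the emulated design targets; the direct entropy →
  well-being slope 0.20 makes the mediation partial at large n.
* **Parcellated timeseries.** 200 regions in 4 equal modules (remainder to
  the last module), multivariate normal with within-module correlation
  0.30 and between-module 0.05 by default. The post-session matrix adds a
  per-subject between-module shift built to correlate with the planted
  well-being change at −(target r) = +0.4, centered at 60% of the
  admissible shift range — an operating point where the normalized Q
  statistic responds steeply, so the planted correlation survives
  estimation noise. A positive shift raises between-module coupling and
  lowers modularity. Default sample count is 384 (an 8-minute scan at
  TR = 1.25 s); analyses in the demo pipeline use 200 samples, a rough
  effective-sample count for band-passed BOLD.
* **Outcome change table.** Seven named outcomes; a chosen subset loads on
  a shared "coherent change" factor with loading √r (pairwise correlation
  ≈ r, default 0.6), signed by each outcome's planted direction
  (well-being and insight increase; EDS errors, amygdala RSFC,
  emotional-faces BOLD, modularity and axial diffusivity decrease).
  Non-members are independent.

What the generator does **not** emulate: 1/f spectra, eye-blink or muscle
artifacts, electrode impedance drift, volume conduction, hemodynamic
autocorrelation, missing data, or placebo-order effects. Passing tests
therefore demonstrate that the estimators recover known effects embedded
in stationary Gaussian/sinusoidal surrogates — not that they are robust to
real-world artifact structure.

## EEG features

* **Filtering.** 4th-order Butterworth band-pass (1–45 Hz), applied
  forward–backward (`sosfiltfilt`) for zero phase; a 60 Hz tone retains
  < 1% of its power. Non-overlapping 2 s epochs; the trailing partial
  epoch is discarded.
* **Binarization.** Default: magnitude of the analytic (Hilbert) signal
  thresholded at its per-epoch median — the convention of the
  psychedelic-EEG LZc literature. Samples exactly at the threshold get
  symbol 0 (fixed tie rule). A raw-signal-vs-mean variant is available
  (`binarize(..., method="mean")`); note the envelope variant is
  degenerate on noiseless pure tones, whose envelope is constant.
* **LZ76.** Exhaustive production parsing (Kaspar–Schuster scan),
  JIT-compiled; verified exhaustively against a definition-direct
  brute-force parser on all binary strings up to length 12 and on random
  epoch-length strings.
* **Normalization.** Default: divide by the mean parse count of 20
  shuffled surrogates. Because a uniform shuffle depends only on the
  epoch's (length, #ones) composition, the surrogate RNG is keyed to
  (seed, length, composition): epochs with the same composition share one
  normalizer, which makes the normalizer a common constant across
  subjects rather than an extra noise source, and allows caching. The
  asymptotic n/log₂(n) normalizer is available as an option.
  Channel values are epoch means (a median option is not provided; the
  emulated analyses report means).
* **Band power.** `mne` multitaper PSD per epoch (full normalization,
  ±0.5 Hz half-bandwidth of smoothing), averaged over epochs, integrated
  over half-open bands [low, high) so the five default bands tile 1–45 Hz
  without double counting.
* **Cluster test.** Paired t per electrode; two-sided cluster-forming
  threshold p < 0.05; clusters are connected components over an adjacency
  graph built from idealized 2-D 10–20 coordinates with a 0.55
  neighbor-distance threshold (each interior electrode gets 3–5
  neighbors; the graph is connected); cluster mass is the summed |t|
  (extent-based mass is not offered); the null sign-flips each subject's
  condition difference; p uses the (1 + exceedances)/(1 + permutations)
  convention so p ∈ (0, 1].

## The cross-validated predictor

Feature selection uses signed r > ϑ (the emulated analyses predict
positive relationships); an absolute-value mode exists but is off by
default. The ϑ grid is 0.00–0.90 in steps of 0.05. Out-of-sample
R² = 1 − mean(residual²)/var(target) — the residual mean counts as error,
so R² can be negative and is negatively biased under the null. Folds whose
training selection is empty predict the training-target mean, keeping the
grid search total. Ties in the grid search break toward larger ϑ (sparser
model). If ϑ* selects nothing on the full sample (common under a null
target, where the flat tail of the R² curve wins the tie), the final model
degrades to predicting the target mean with a warning rather than
erroring — the surrogate p is still well-defined and calibrated.

Surrogates shuffle the target across subjects and re-run ranking, LOOCV
and threshold optimization in full, comparing grid-maximal R² values; this
preserves exchangeability, so the selection step does not inflate the
false-positive rate (verified: 5.3% rejections at α = 0.05 over 150 null
cohorts). A cheaper fixed-ϑ* surrogate mode exists and warns that it is
anti-conservative. The permutation engine evaluates all (permutation,
threshold) pairs in one vectorized pass per fold, using rank-order
cumulative sums so every threshold shares a single sort.

The all-sensor control averages LZc over electrodes per timepoint, scores
a plain univariate LOOCV regression (no selection), and Bonferroni-adjusts
over the timepoints tested.

## Mediation

Paths are OLS; normalized β comes from refitting on z-scored variables;
the indirect-effect interval is a percentile bootstrap over subject
resamples (vectorized closed-form OLS, 5000 resamples by default;
degenerate resamples are dropped). Verdicts: *full* if a and b are
significant and c′ loses significance with |c′| < |c|; *partial* if a, b
and c′ all stay significant; *none* otherwise. Exactly collinear
predictor/mediator pairs (|r| > 0.999) are rejected — the b and c′ paths
are not identifiable there. No covariates enter by default. At the
emulated design's n = 28 and slopes (0.55, 0.50, 0.20), the joint power of
the a and b tests is only ~55–60%, so single cohorts frequently return
*none*; parameter recovery is tested at large n and verdict behavior at
the operating point is documented rather than asserted.

## Network modularity

Q follows the degree-corrected formula over ordered pairs with the
diagonal excluded; the i = j term of the null model is retained, which
gives the textbook 1 − 1/k for k disconnected equal cliques. Signed
matrices use the standard asymmetric combination
Q = Q⁺ − (l⁻/(l⁺+l⁻))·Q⁻. Louvain operates on the dense signed modularity
matrix (so the aggregation phase reuses the same code path); randomized
node order is the only stochastic element; no consensus clustering is
performed (the subject statistic averages Q, not partitions). The
"rewired" null permutes the off-diagonal upper-triangle weights
symmetrically (preserving the weight distribution, not the degree
sequence), one Louvain run per null.

A caveat discovered while validating: along a sweep that raises
between-module correlation toward the within-module level, raw Q falls
monotonically, but the null's Q falls *faster* (weight-shuffle modularity
is driven by the spread of the weight distribution, which homogenizes), so
the normalized ratio rises. Null-normalized Q is therefore **not** a
monotone index of block-structure erosion in high-coupling regimes; the
test suite documents this divergence. The synthetic cohort plants its
modularity–well-being correlation at a weak-block operating point where
Q_norm does respond in the expected (negative) direction.

## Outcome correlations

The cluster test uses connected components over cells with p < 0.05,
|Fisher-z| cluster mass (clusters may mix positive and negative
correlations), and independent per-outcome subject permutations — the
standard construction for correlation-matrix cluster tests; mass variants
based on raw r or cell counts are not offered. The implementation accepts
any number of outcomes but defaults to the seven-outcome vocabulary. The
baseline-adjusted correlation residualizes both change scores on the
covariate by OLS and tests the residual Pearson r at df = n − 3; a
constant covariate falls back to the plain correlation with a warning.

## Pipeline

Per-stage seeds derive from the global seed via `SeedSequence` hashing of
(seed, stage coordinates), so stages are reproducible and independent.
Reports are JSON with sorted keys and no timestamps; identical config +
seed give byte-identical bytes. The demo `RunConfig` profile uses reduced
sizes (40 s recordings, 100 regions, 20 Louvain/null runs, 500 target
shuffles) so the full chain runs in minutes; study-scale analyses raise
these explicitly.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to keep the suite fast while
retaining statistical resolution, with acceptance bands recomputed at the
sizes actually run: predictor calibration at 200 null cohorts × 500
shuffles (binomial-95% band [0.019, 0.081] around 0.05), predictor power
at 100 cohorts × 500 shuffles, bootstrap coverage at 300 replicates × 600
resamples, cluster-test power at 100 seeds × 1000 permutations and
family-wise error at 300 seeds × 1000 permutations, modularity recovery at
60–200 regions with 8–10 Louvain runs, and group EEG contrasts at n = 28
with 30 s recordings.

## Known limitations

* The generator's Gaussian/sinusoidal surrogates cannot speak to artifact
  robustness; no ICA, channel interpolation or re-referencing is included.
* LZc is computed per 2 s epoch then averaged; concatenated-recording
  parsing would give different absolute values (the normalization reduces
  but does not remove the difference).
* The weight-shuffle null's behavior in high-coupling regimes (above)
  means normalized-Q comparisons across very different mean-correlation
  levels need care.
* The predictor deliberately stays a thresholded-average univariate model;
  no regularized multivariate alternative is provided.
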