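# entropath

Analysis pipeline for placebo-controlled psychedelic neuroimaging designs:
EEG signal entropy and band power, cross-validated brain–behavior
prediction with surrogate significance, entropy → insight → well-being
mediation, resting-state network modularity with rewired-null
normalization, and cluster-corrected correlation matrices of long-term
change scores. A synthetic cohort generator plants every effect the
pipeline is meant to recover, so the whole chain is testable without any
restricted human data.

The package is aimed at researchers who study acute "entropic brain"
effects of serotonergic psychedelics (psilocybin in particular) and their
relationship to lasting psychological change, and who want the bespoke
statistics of that literature — not the generic preprocessing — as tested,
reusable code.

## What it computes

**Brain entropy (LZc).** Recordings are band-passed to 1–45 Hz and cut into
2 s epochs. Each epoch/channel trace is binarized (Hilbert-envelope
amplitude vs its median) and parsed with the Lempel–Ziv 1976 exhaustive
production history; the raw component count c(S) is normalized by the mean
count of shuffled surrogates, removing length/rate bias:

    LZc = c(S) / mean_k c(shuffle_k(S))

Band powers (δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–45 Hz) come from Slepian
multitaper spectra with ±0.5 Hz smoothing. Scalp-level condition contrasts
use paired-t cluster randomization (sign-flip null, summed-|t| cluster
mass) over a 10–20 adjacency graph.

**Cross-validated predictor.** A four-step data-driven model predicts a
behavioral target from electrode × timepoint LZc: (1) rank features by
Pearson r with the target; (2) for a threshold ϑ, average the features with
r > ϑ and score a univariate regression by leave-one-out out-of-sample R²
(selection refit inside every fold); (3) pick ϑ* maximizing R²; (4) refit
at ϑ*, report Spearman r_s of cross-validated predictions vs the target,
with significance from surrogate tests that shuffle the target across
subjects and re-run steps 1–3 in full — so the threshold search leaves the
false-positive rate at its nominal level, affecting only power.

**Mediation.** OLS paths a (X→M), b (M→Y|X), c (X→Y), c′ (X→Y|M); raw and
normalized (z-scored) β with SE and p; percentile-bootstrap interval for
the indirect effect a·b; Baron–Kenny-style full/partial/none verdict. The
identity c = c′ + a·b holds to machine precision on every sample.

**Network modularity.** From a parcellated region × time matrix, the
unthresholded Pearson FC matrix is scored with Louvain modularity

    Q = (1/l) Σ_ij [ w_ij − γ k_i k_j / l ] δ(m_i, m_j)

with negative weights treated asymmetrically (Q = Q⁺ − l⁻/(l⁺+l⁻) · Q⁻),
γ = 1, 100 randomized Louvain runs averaged per subject, and Q normalized
by the mean Q of 100 "rewired" (symmetric weight-permutation) null
matrices.

**Outcome correlation structure.** Pairwise Pearson correlations over seven
change-score outcomes (EDS errors, amygdala RSFC, well-being, emotional-
faces BOLD, modularity, axial diffusivity, insight), with a non-parametric
cluster test: significant cells define an outcome graph, cluster mass is
the summed |Fisher-z(r)|, and the null permutes each outcome's subject
order independently. A baseline-adjusted partial correlation handles the
modularity-change vs well-being-change association.

## Worked example

`examples/03_entropy_predictor.py` plants a posterior-electrode entropy →
insight effect at the 2 h timepoint and runs the four-step model:

```
top-ranked features (electrode, timepoint, r):
  P3  2h   r = +0.79
  O1  2h   r = +0.58
  P4  2h   r = +0.53
  C4  1h   r = +0.40

optimal threshold theta* = 0.45
selected features: [('P3', '2h'), ('P4', '2h'), ('O1', '2h')]
out-of-sample R^2 = 0.63
Spearman r_s(predicted, observed) = 0.63
surrogate p (1000 target shuffles, full re-selection each) = 0.001
```

The threshold search isolates exactly the three planted electrodes at the
planted timepoint; r_s is the rank correlation between leave-one-out
predictions and the observed target, and the surrogate p says how often
shuffled targets reach the model's out-of-sample R² when the entire
selection pipeline is re-run per shuffle.

The other scripts in `examples/` demonstrate cohort simulation, EEG
entropy/band-power extraction with the scalp cluster test, mediation,
network modularity, and the outcome-cluster test, each printing the
numbers it computes and what they mean.

A thin CLI mirrors the pipeline stages:

```bash
entropath run-all --seed 1 --out results/demo
entropath corrcluster --seed 1 --out results/demo
```

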