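# Methods

This note documents the models, parameter choices and numerical
conventions behind `neoqeeg`, and what the synthetic-data tests do and
do not establish about real neonatal EEG.

## The synthetic EEG model

A neonatal background is simulated as a two-state renewal process
alternating **bursts** and **interburst intervals**. State durations are
gamma-distributed — positive by construction, with dispersion set by a
coefficient of variation (`ibi_cv`), shape `1/cv²`. The binary state
track is smoothed with 0.25-s raised-cosine ramps into an amplitude
envelope interpolating between the interburst and burst RMS amplitudes.

Within both states the carrier is coloured Gaussian noise synthesised in
the frequency domain with target PSD `∝ f⁻²` on [0.1, 2) Hz and `∝ f⁻¹`
on [2, 30] Hz, the two pieces weighted so that the expected power
fraction below 2 Hz equals `slow_delta_frac` — the generator's handle on
"persistent extremely slow delta at term age".

Interhemispheric asynchrony: a master burst sequence drives the left
hemisphere and midline; each burst is mirrored on the right except,
with probability `asynchrony_prob`, it is lagged by `asynchrony_lag_ms`.
With `asynchrony_prob = 0` the hemispheres share burst timing exactly
(asserted in tests). Channel labels follow the 10–20 system, restricted
to the 9-electrode reduced neonatal array or the full 19-lead set.

Default profiles (documented config values, not clinical claims):

| parameter | mature | dysmature | unit |
|---|---|---|---|
| ibi_mean_s | 3 | 8 | s |
| ibi_cv | 0.3 | 0.5 | — |
| burst_mean_s | 6 | 4 | s |
| burst_amp_uv | 50 | 60 | µV RMS |
| interburst_amp_uv | 25 | 10 | µV RMS |
| slow_delta_frac | 0.4 | 0.7 | — |
| asynchrony_prob | 0.05 | 0.4 | — |
| asynchrony_lag_ms | 500 | 1500 | ms |

The discontinuity values mirror the qualitative clinical picture (term
interburst intervals of a few seconds vs abnormally long, deeply
suppressed intervals); burst durations and amplitudes sit in the ranges
usually quoted for term trace alternant. No published quantitative IBI
thresholds by gestational age back these exact numbers — they are
placeholders with the right ordering, and a profile flagged dysmature is
required (validated) to be at least as discontinuous, slow and
asynchronous as the mature defaults.

**Deliberate simplifications.** No sleep staging (dysmaturity's "poor
sleep-stage development" is represented only through the
discontinuity/asynchrony knobs), no interictal discharges, seizure
morphology or artifacts, and channel carriers are independent noise
sharing only the hemisphere envelope — so spatial correlation structure
is unrealistic. Consequently, passing direction-of-effect tests shows
the *feature machinery responds to the modelled physiology in the
documented direction*; it does not validate effect sizes on real
infants.

## The cohort model

Each subject's dysmature flag is Bernoulli(`p_dysmature`); the 24-month
ASD outcome is Bernoulli on dysmaturity-conditional probabilities; IED,
focal slowing, electrographic seizures, mutation (TSC1/TSC2/none) and
treatment arm are independent draws at the study cohort's marginal
frequencies. The composite flag `abnormal_eeg` is *derived* (IED or
background abnormality or seizures), never stored independently — the
CSV reader re-checks this invariant. Developmental quotients are
Gaussian, clipped to [0, 160], with means shifted by dysmaturity status
(set to the observed group medians: cognitive 75→62.5, language 68→59,
motor 76→67). ADOS-2 totals are drawn inside the score band implied by
the subject's outcome and verbal status, so categories are consistent
by construction. Exactly one subject per cohort (configurable) has the
ASD/language/motor outcomes missing with cognitive retained, emulating
the incomplete follow-up pattern of real cohorts. Defaults:
`p_dysmature = 14/63`, `P(ASD|dysmature) = 8/14`, `P(ASD|mature) =
11/49`, implying a designed odds ratio of 4.61.

## Feature definitions and numerical choices

**Preprocessing.** Zero-phase 4th-order Butterworth band-pass
0.5–30 Hz. Artifact handling is limited to flagging epochs exceeding
500 µV (clipping detection); visual artifact rejection is a human step
and out of scope. Zero-variance channels yield NaN features, never
silent zeros.

**Band power.** Welch PSD (4-s Hann segments, 50% overlap), trapezoidal
band integration, normalised over the five defined bands so per-channel
relative powers sum to 1. Band edges (δ₁ 0.5–2, δ₂ 2–4, θ 4–8, α 8–16,
β 16–30 Hz) are configurable; the δ₁ upper edge of 2 Hz aligns with the
clinical slow-delta criterion. The literature uses several neonatal
band conventions; none is canonical.

**Range EEG.** Non-overlapping 2-s epochs; per-epoch peak-to-peak; the
summary is the 50th percentile (median M) with 5th/95th-percentile
margins (L, U) and asymmetry `A = ((U−M)−(M−L))/(U−L) ∈ [−1, 1]`,
undefined (not 0) when U = L. A burst-suppression-like trace has many
low-amplitude epochs and a long upper tail, hence A > 0. Window length
and percentile choices are config parameters — the construct is defined
only verbally in the clinical literature.

**Sample entropy.** `SampEn(m, r·SD)` with m = 2, r = 0.2 by default,
Chebyshev distance, self-matches excluded; template pairs are counted
over the first `n − m` windows at both lengths m and m+1 (the PhysioNet
convention), and a zero match count at either length returns NaN — an
explicit "undefined" sentinel rather than ±∞. The implementation is
exactly (test-enforced, bit-equal) the naive O(n²) count, evaluated in
blocks.

**Multiscale entropy.** Coarse-graining by non-overlapping means at
scales τ = 1..20; by default the tolerance is recomputed from each
coarse-grained series' SD. Note this makes MSE of white noise *flat*
across scales (coarse-grained white noise is again white noise); the
classic variant that anchors r to the scale-1 SD — under which white
noise MSE decreases monotonically — is available as `fixed_r=True`, and
both behaviours are pinned by tests. Requires `n ≥ 100·max_scale`
(≥ 100 samples at the coarsest scale). In the extractor the entropy
segment is capped at `mse_max_samples = 3840` samples (60 s at 64 Hz):
the O(n²) cost per channel stays under a second while MSE(20) retains
~190 coarse samples. Longer segments reduce variance at quadratic cost.

**Hurst exponent.** First-order DFA: cumulative profile of the
mean-removed series; ≥ 10 (default 16) logarithmically spaced window
sizes in [4, n/4]; per-window linear detrend; H is the slope of
log F(n) vs log n. DFA was chosen over rescaled-range for robustness to
nonstationarity; H > 1 is allowed. Affine invariance holds to machine
precision (profile scales linearly). Estimation uses up to 16384
samples per channel.

**Aggregation.** For classification, features are aggregated across
channels by the median (configurable), giving 31 features per subject
(5 band powers, 5 band-wise rEEG asymmetries, 20 MSE scales, 1 Hurst).

## Classification

Per feature family (power / entropy / rEEG asymmetry / fractality), the
top-k features (default k = 5) by Fisher score — absolute standardised
mean difference with pooled SD; constant features score 0, features
with zero within-class spread but separated means score ∞ — enter a
two-class LDA with pooled within-class covariance (ridge
`λ·tr(Σ)/p`, λ = 1e-6, added when the covariance is singular or
p ≥ n, logged). "Three-fold testing" is read as stratified 3-fold
cross-validation: selection and fitting on the training two-thirds
only, pooled held-out predictions give E(%) and AUC(%) (AUC via the
Mann-Whitney identity with midranks; per-fold AUCs are also recorded).
The partition is seed-deterministic; a repetition count (default 1) is
available since it is unknown whether the original analysis repeated
folds. A leakage canary test asserts that a feature informative only on
a fold's test third is not exploitable. The published real-cohort
performance (AUC 66–79%) is *not* a reproduction target — the cohort is
unavailable — so classifier acceptance rests on separability,
permutation-null calibration and effect-detection properties instead.

## Clinical statistics

ADOS-2 risk bands: non-verbal 0–9 / 10–13 / >13 and verbal 0–7 / 8–11 /
>11 for no / mild-moderate / high risk; the binary "ASD" outcome used in
2×2 analyses is any-risk vs no-risk. Odds ratios are cross-product
ratios with Wald CIs on the log scale; the Haldane-Anscombe +0.5
correction is applied to all cells iff any cell is zero (flagged).
Reported percentages round half-up to integers, ORs to one decimal —
the printing convention of the clinical literature. Logistic models are
maximum likelihood (statsmodels Newton/IRLS, tolerance 1e-8, max 50
iterations) with Wald standard errors, a likelihood-ratio omnibus χ²
and Nagelkerke R²; a constant outcome returns a flagged non-converged
fit, and a perfectly separating predictor raises an error naming it.
Whether the original CIs were Wald or profile-likelihood is not stated;
Wald is implemented and reproduces the printed intervals at 1-decimal
rounding. Mann-Whitney U uses exact enumeration when n₁+n₂ ≤ 12 without
ties, otherwise the tie-corrected normal approximation with continuity
correction. Cognitive and language DQs are log- and
reciprocal-transformed for linear models; multivariable models enter
predictors in block, with VIF/tolerance collinearity checks.

## Problem sizes in tests and the acceptance script

Simulation-based checks use deliberately modest sizes chosen as a
variance/runtime trade-off: direction-of-effect suites use 40 vs 40
(tests) or 20 vs 20 (acceptance script) recordings of 120 s at 64 Hz on
a C3/C4 montage; white-noise MSE monotonicity uses 6 000-sample series
× 10 seeds; DFA recovery 8 192 samples × 50 seeds; odds-ratio recovery
500 cohorts of n = 63; permutation null 200 relabelings. At these sizes
the asserted effects are detected with large margins (direction-suite
p ≈ 1e-7 at α = 0.01).

## Known limitations

- The generator's spatial model (shared envelope, independent carriers)
  cannot support connectivity or synchrony-topography features.
- Entropy/DFA estimates depend on segment length; cross-study
  comparability requires fixing `mse_max_samples` and the sampling rate.
- The cohort simulator draws covariates independently; it cannot
  reproduce adjusted (multivariable) effect estimates that depend on
  covariate correlation, which is also why the adjusted ORs of the
  original multivariable models are not reproduction targets.
- EDF writing requires integer sampling rates (1-s records) and pads
  the final partial record with zeros.
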