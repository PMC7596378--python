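# neoqeeg

Quantitative EEG dysmaturity analysis for neonatal cohorts.

In infants at high risk of neurodevelopmental comorbidity — the motivating
case is tuberous sclerosis complex (TSC), where autism spectrum disorder
(ASD) is diagnosed in a fifth to a half of patients — the *maturity* of the
early EEG background carries prognostic information. A **dysmature**
background (inappropriate for gestational age: abnormal discontinuity with
long interburst intervals, persistent extremely slow delta below 2 Hz at
term age, interhemispheric asynchrony) is associated with ASD traits and
lower developmental quotients at 24 months. `neoqeeg` packages that entire
analysis chain as tested, reusable code for methodologists and clinical
researchers working with neonatal EEG:

1. **Synthetic data** (`neoqeeg.simulate`) — a generative model of
   mature vs dysmature neonatal EEG (two-state burst/interburst renewal
   process with gamma durations, coloured-noise bursts with a
   controllable sub-2 Hz power fraction, hemisphere-level burst
   asynchrony) and a cohort simulator whose EEG-flag → outcome joint
   distribution is configurable, so every downstream stage is testable
   without patient data.
2. **Dysmaturity features** (`neoqeeg.features`) — the four families
   used to quantify background maturity: relative band power in the
   neonatal bands (δ₁ 0.5–2, δ₂ 2–4, θ 4–8, α 8–16, β 16–30 Hz);
   range-EEG (rEEG, an aEEG surrogate) margin asymmetry
   `A = ((U−M)−(M−L))/(U−L)` from per-epoch peak-to-peak amplitudes;
   multiscale sample entropy MSE(τ), τ = 1..20; and the Hurst exponent
   by detrended fluctuation analysis.
3. **Outcome classification** (`neoqeeg.classify`) — Fisher-score
   feature selection and a pooled-covariance linear discriminant
   (`w = Σ⁻¹(μ₁−μ₀)`), evaluated by stratified three-fold testing with
   in-fold selection (no leakage), reporting misclassification error
   E(%) and ROC AUC(%). Both steps are sklearn-compatible estimators.
4. **Clinical statistics** (`neoqeeg.stats`) — ADOS-2 risk bands
   (verbal/non-verbal cut-offs), 2×2 odds ratios with Wald CIs and
   diagnostic metrics (sensitivity/specificity/PPV/NPV), logistic
   regression with likelihood-ratio omnibus test and Nagelkerke R²,
   Mann-Whitney U tests, DQ transforms, OLS models and VIF/tolerance
   collinearity checks.
5. **I/O and CLI** (`neoqeeg.io`, `neoqeeg.cli`) — 16-bit EDF writing
   and validated reading, a documented cohort CSV schema, YAML
   configuration, and a `neoqeeg` command with `simulate`, `features`,
   `classify`, `stats` and `run` subcommands.

## Worked example

The 2×2 analysis of dysmature background (14 of 63 infants) against the
24-month ASD outcome, from its counts:

```python
from neoqeeg import ContingencyTable2x2, odds_ratio, diagnostic_metrics

t = ContingencyTable2x2(a=8, b=6, c=11, d=38)  # dysmature x ASD
res = odds_ratio(t)
print(f"OR = {res.odds_ratio:.2f}  95% CI [{res.ci_low:.2f}, {res.ci_high:.2f}]")
print(diagnostic_metrics(t).as_percent())
```

```
OR = 4.61  95% CI [1.32, 16.13]
{'sensitivity': 42, 'specificity': 86, 'ppv': 57, 'npv': 78}
```

So the odds of an ASD diagnosis at 24 months are ~4.6-fold higher after
a dysmature first EEG; a mature background argues against a later ASD
diagnosis (specificity 86%, NPV 78%) more strongly than a dysmature one
argues for it (sensitivity 42%).

Feature extraction from a synthetic dysmature recording:

```python
from neoqeeg import generate_eeg, extract_features, DYSMATURE_PROFILE
from neoqeeg.features import aggregate_channels

rec = generate_eeg(DYSMATURE_PROFILE, duration_s=120, fs=64,
                   channels=("C3", "C4"), seed=1)
fv = aggregate_channels(extract_features(rec))
print(fv[["bp_delta1", "reeg_asym_delta1", "mse_20", "hurst"]].round(3))
```

```
bp_delta1           0.264
reeg_asym_delta1    0.614
mse_20              0.981
hurst               0.499
```

Relative to a mature recording (typically δ₁ power ≈ 0.08, rEEG
asymmetry ≈ 0.12, MSE(20) ≈ 1.9, H ≈ 0.37 under the default mature
profile), the dysmature trace shows the expected shifts on all four
families: more slow delta, a more right-skewed amplitude distribution,
less coarse-scale complexity, more long-range regularity.

Full pipeline from a YAML config:

```bash
neoqeeg run --config config.yaml --seed 42 --out results/
# -> cohort.csv, features.csv, classifier_report.csv,
#    stats_report.json, summary.json (all seeded, config-hashed)
```

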