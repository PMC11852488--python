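# emosafe

EEG-based emotion classification and behavioral safety-performance
statistics, built as a fully synthetic, reproducible analysis pipeline.

## The problem

Occupational-safety research asks how negative emotions (fear, anger)
change a worker's ability to spot hazards and judge risk. One study design
couples two arms:

1. **An EEG arm** — classify three induced emotion states (neutral, fear,
   anger) from 14-channel, 128 Hz scalp EEG, using one feature pair per
   frequency band: **sample entropy** (signal irregularity) and **band
   power spectral density** (energy), fed to a k-nearest-neighbor
   classifier. Classification quality is compared across the five
   canonical rhythms: δ (1–4 Hz), θ (4–8), α (8–13), β (13–30), γ (31–47).
2. **A behavioral arm** — per-participant hazard-identification accuracy
   (RA) and response time (RT1), and risk-assessment score (RS, 1–5) and
   response time (RT2), measured under each emotion, analyzed with one-way
   and 3×2 factorial ANOVA (emotion × psychological-capital group,
   median-ish split at 4.0 on a 1–5 scale), simple effects, and multiple
   regression of performance on personal factors with VIF collinearity
   diagnostics.

No raw recordings or trial tables are publicly available for such data,
so this package ships **seeded synthetic generators** for both arms
(`emosafe.synth_eeg`, `emosafe.synth_behavior`) and runs every stage of
the analysis end to end on them. The synthetic populations are documented
emulations (see `docs/methods.md`), not reconstructions of any real
cohort.

## The statistics at the core

- **Sample entropy**: SampEn(m, r, N) = −ln(A/B), where B counts pairs of
  length-m templates and A pairs of length-(m+1) templates within
  Chebyshev tolerance r (defaults m = 2, r = 0.2·SD). Lower values =
  more regular signal.
- **Band PSD**: the raw periodogram |X̂(f)|²/T integrated over a half-open
  band [f_lo, f_hi); Parseval-exact (`sum(psd)·Δf = mean square`).
- **KNN**: Euclidean majority vote on z-scored features, vote-fraction
  scores for one-vs-rest ROC/AUC, stratified k-fold cross-validation.
- **ANOVA**: classical balanced sums-of-squares decomposition with
  classical and partial η², Bonferroni post hoc, simple effects with a
  pooled or within-level error term, and a summary-statistics mode that
  audits printed mean ± SD tables without raw data.
- **OLS + VIF**: statsmodels least squares; VIF_j = 1/(1 − R²_j).

## Worked example

The numbered drivers under `analysis/` run the whole study in order. The
classification stage (`python analysis/03_classify_bands.py`) simulates
216 s of EEG per emotion state, preprocesses (baseline → 0.5–50 Hz
windowed-sinc FIR → 50 Hz notch), band-filters, cuts 216 one-second
epochs per state, extracts (SampEn, band-PSD) on T7/T8 and cross-validates
a k = 5 KNN. It prints:

```
cross-validated accuracy by band (3 states x 216 epochs, k=5):
 band  f_lo  f_hi  accuracy_pct  tp_neutral_pct  tp_fear_pct  tp_anger_pct
delta   1.0   4.0          60.5            40.7         63.4          77.3
theta   4.0   8.0          54.3            43.5         53.2          66.2
alpha   8.0  13.0          76.2            96.8         61.6          70.4
 beta  13.0  30.0          98.3            99.5         98.1          97.2
gamma  31.0  47.0          63.0           100.0         44.4          44.4

best band: beta; shuffled-label control accuracy 33.7% (chance = 33.3%)
```

Reading: each row is one rhythm's classifier; `accuracy_pct` is pooled
5-fold cross-validated accuracy over 648 epochs and `tp_*` the per-class
true-positive rates. The β band separates the three shipped synthetic
profiles almost perfectly because they differ most in β weighting, while
the shuffled-label control collapses to chance — the separation is in the
signal, not the pipeline. The calibration driver
(`python analysis/07_calibration.py`) checks the behavioral arm:

```
null rejection rate at alpha=0.05: 0.060 over 500 tables (nominal 0.05); KS uniformity p = 0.308
injected RA shift 0.10 recovered as 0.1006 +/- 0.0030 (95% MC interval, 200 replicates, n=22)
```

i.e. the two-way ANOVA's emotion test is type-I calibrated on zero-effect
tables, and a known +0.10 RA shift is recovered without bias at the
study's sample size.

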