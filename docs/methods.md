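# Methods

This note documents the models, estimators and design choices behind
`emosafe`, and what the synthetic data do and do not establish.

## Synthetic EEG

Each recording is 14 channels at 128 Hz. A channel is a weighted sum of
five band-limited Gaussian noise components — one per rhythm, weights from
the state's `EmotionProfile` — mixed with broadband white noise:

    x = (1 − c) · Σ_b a_b · n_b  +  c · w,

where `c ∈ [0, 1]` is the profile's *complexity* and each `n_b` is white
noise spectrally masked to its band (an exact brick-wall filter via
rFFT/irFFT) and RMS-normalized. Channels are independent realizations;
each is scaled to 15 µV RMS times its channel gain. The 15 µV figure puts
typical Gaussian peaks near ±50–65 µV — ordinary scalp-EEG scale — so
that the default 100 µV rejection threshold passes clean data and catches
injected ocular artifacts. All draws come from `numpy.random.default_rng(seed)`;
identical arguments give bit-identical recordings.

The three shipped profiles (alpha-dominant/low-complexity neutral,
beta-weighted/moderate fear, slow-wave/high-complexity anger) are
deliberately well-separated test signatures. They are configuration
constants, **not** claims about the electrophysiology of emotion: no
quantitative per-state spectral description exists to calibrate against.
Consequences for interpretation: passing classification tests shows the
pipeline can recover class structure that is present in band power and
complexity; it says nothing about accuracy on real recordings, which have
1/f background spectra, nonstationarity, volume-conduction correlation
between channels and far subtler state differences — none of which the
generator emulates.

Artifact injection adds Hann-shaped ~300 ms transients (full amplitude on
the eight frontal channels, 0.2× elsewhere) at
`round(rate · minutes)` uniformly drawn onsets, plus an optional pure
sinusoid at the mains frequency. The onset schedule is returned so
rejection can be verified against ground truth.

## Preprocessing

* Baseline correction removes each channel's mean.
* Band-pass: Hamming-windowed sinc FIR (length ≈ 3.3·fs/transition-width,
  default transition 1 Hz), applied forward–backward (`filtfilt`) for zero
  phase, so epoch boundaries stay aligned. Default pass band 0.5–50 Hz.
* Notch: second-order IIR notch (`iirnotch`, Q = f0/bandwidth, default
  50 Hz ± 1 Hz), also zero-phase. 60 Hz is a parameter, not a rebuild.
* Epoching: consecutive non-overlapping 1 s windows; a trailing partial
  window is dropped so all epochs share one shape (216 s → 216 epochs).
* Artifact handling is **threshold rejection** of whole epochs
  (|amplitude| > 100 µV or |Δsample| > 200 µV by default), not ICA: with
  a known injection schedule, rejection is verifiable exactly, and no ICA
  step is needed for data with no real ocular sources. The gradient
  default is permissive on purpose — broadband noise at 15 µV RMS has
  legitimate per-sample steps of ~20 µV SD, so a tight gradient limit
  would reject clean data; it exists to catch pathological jumps.

## Features

**Sample entropy.** Richman–Moorman estimator: with embedding dimension
`m` (default 2) and tolerance `r` (default 0.2 × population SD; an
absolute mode exists), count unordered pairs among the first `N − m`
templates whose Chebyshev distance is ≤ r, at lengths `m` (B) and `m + 1`
(A); SampEn = −ln(A/B). Conventions: self-matches excluded, each pair
counted once, both lengths use the same `N − m` template set so A ≤ B. A
constant series returns 0 (every template matches every other); if no
pair matches at either length the estimate is undefined and a dedicated
error is raised rather than returning ±inf. One caveat discovered during
testing: "SampEn is monotone nonincreasing in r" is *not* a theorem —
a pair can leave the B count while remaining counted in A's numerator
history, and short discrete series violate the monotonicity in ~16% of
random cases. It is a reliable empirical regularity for continuous series
at epoch length (N = 128), and is tested only there.

**Band PSD.** Raw one-sided periodogram (boxcar window, no detrend), so
`Σ psd · Δf` equals the time-domain mean square exactly; band power
integrates the periodogram over a half-open interval [f_lo, f_hi). The
half-open convention makes adjacent band powers additive and assigns a
shared edge (4, 8, 13 Hz) to the upper band. The printed 30–31 Hz gap
between beta and gamma is preserved as published rather than closed.
Welch averaging is intentionally absent: with 1 s epochs there is nothing
to average, and the raw |X̂(f)|²/T definition is the estimator under test.

**Feature matrix.** Per band: four columns — SampEn on T7, T8 and
band-PSD on T7, T8 — one row per epoch. SampEn is computed on the samples
as provided; the band-comparison pipeline band-filters the conditioned
recording *before* epoching, so each band's SampEn reflects that rhythm's
complexity. Per-epoch (rather than per-recording) SampEn is required for
216 classification samples per condition. Per-band scalar PSD (rather
than full spectra) matches the per-band classifier design.

## Classification

KNN with Euclidean distance on z-scored features (standardization fit on
the training split only), k = 5 by default, with `select_k` providing
cross-validated selection (smallest k on ties). Vote ties go to the class
of the single nearest neighbor. Scores for one-vs-rest ROC are the
neighbor-vote fractions; AUC is trapezoidal over the exhaustive threshold
sweep. The default evaluation is stratified 5-fold cross-validation at
epoch level, matching the 216-per-class accounting; note that epoch-level
splits of contiguous EEG are optimistic (adjacent epochs are correlated),
so a `split="subject"` leave-one-recording-out mode is available — it
needs more than one recording per class to be meaningful. The 2-D scatter
view is a top-2 PCA of the z-scored features.

## Behavioral synthesis and statistics

`generate_trials` produces one row per participant × emotion (22 × 3 by
default). The linear model per DV is
baseline + emotion shift ± ½·moderation (sign by PsyCap group)
+ Σ slope·(covariate − mean) + noise, with Gaussian noise for the bounded
DVs (RA ∈ [0,1], RS ∈ [1,5]) and lognormal multiplicative noise for the
response times (σ on the log scale, mean-corrected so E[RT] equals the
model mean). PsyCap scores are drawn uniformly on [3.29, 4.0) and
[4.0, 4.75] for the two halves of the sample, giving a balanced split at
the 4.0 threshold by construction. Personal factors follow the reported
ranges (sleep 6–8 h, ordinal 1–4/1–3 counts with means near the published
descriptives).

The shipped `preset_reported_means` places population means at the
emulated study design's reported condition means (RA 54.86/65.22/59.55%
for neutral/fear/anger, etc.) so large-sample orderings reproduce the
reported ordinal pattern; moderation deltas and covariate slopes keep the
reported directions at modest magnitudes. Residual SDs for RA (0.07) and
RS (0.40) sit somewhat below the reported cell SDs: the bounded DVs must
stay strictly inside their ranges (verified over 100 seeds) so the clip
safety net never distorts the linear model, and truncation would
otherwise bias both calibration and recovery checks. The preset emulates
the *pattern* of the findings only; inferential statistics (F, p,
coefficients) are not reproduction targets — raw data are unavailable,
and some reported test statistics are mutually inconsistent anyway.

ANOVA uses the classical balanced decomposition (authored here,
cross-checked against a statsmodels Type II fit, which it equals on
balanced data); unbalanced layouts require an explicit `unbalanced="type2"`
opt-in. Repeated observations per participant are analyzed
between-subjects by default — replicating the randomized-factorial
convention of the study design — with `repeated_measures_anova` provided
as the within-subject sensitivity analysis. Effect sizes are reported as
both classical η² (SS/SS_total; additive, sums to 1 with the error share)
and partial η² (SS/(SS+SS_error)), since published η² columns are often
unlabeled. Simple effects default to the pooled full-model error term
(df preserved); `error="within"` reproduces the one-way ANOVA restricted
to the moderator level. Post hoc comparisons are Welch t-tests with
Bonferroni correction over the three emotion pairs, reported with
direction. `anova_from_summary` rebuilds either design exactly from
per-cell (mean, sd, n) triples — between-SS from means and sizes,
within-SS from pooled (n−1)·sd² — enabling audits of printed tables.

Regression is statsmodels OLS with intercept; VIF_j = 1/(1 − R²_j) from
auxiliary regressions. Rank-deficient predictor matrices raise with the
dependent columns named.

## Problem sizes and numerical conventions

The classification experiments use 3 states × 216 s (648 epochs) with
5-fold CV; calibration uses 500 zero-effect replicates for the type-I
check and 200 replicates for shift recovery at n = 22, sizes at which the
Monte-Carlo intervals are tight enough to be informative while the whole
suite stays interactive. Degenerate inputs fail loudly and early:
all-epochs-rejected, single-class ROC, rank < 2 projection, empty factorial
cells and zero-df effects each have an explicit error or NaN convention
rather than a silent fallback. Seeds are threaded explicitly through every
generator and cross-validation split; derived seeds are drawn below 2³¹
from a parent `default_rng`.

## Known limitations

* Synthetic EEG has a flat (not 1/f) background within each band mixture,
  independent channels, and stationary statistics; accuracy numbers on it
  are internal calibration bars, not performance claims.
* The band-comparison default splits epochs, not recordings; with one
  recording per state the subject-level split is degenerate.
* The behavioral generator draws independent residuals per row; it has no
  participant-level random effect beyond the covariates and PsyCap terms,
  so it understates the within-subject correlation a real repeated-measures
  design would show (the between-subjects ANOVA default is consistent with
  this).
* EDF ingestion is not supported; the interchange format is CSV with a
  JSON sidecar.
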