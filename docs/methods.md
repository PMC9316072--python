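# Methods

## The problem being modelled

A graded lower-body negative pressure (LBNP) session reversibly pools blood
in the legs of a supine volunteer, producing a controlled, stepwise central
hypovolaemia: stroke volume falls progressively while arterial pressures and
heart rate stay near normal ("compensated shock"). The analysis question is
whether the channels of an electrical-cardiometry (EC) monitor, engineered
into window features and combined by a classifier, can detect a ≥ 20% drop
of the echocardiographic reference stroke volume (SV-TTE) — and whether the
multivariate model outperforms each vital sign taken alone. Since the
original human recordings are not publicly available, the package ships a
first-class synthetic-cohort generator that reproduces the *statistical
structure* this analysis depends on, and every downstream method is
evaluated against that generator plus exact/analytic oracles.

## Protocol

Five stages: baseline (0 mmHg, 600 s), −15 / −30 / −45 mmHg (420 s each),
recovery (0 mmHg, 600 s). The analysis window is the final 120 s of each
stage. The first 120 s of every LBNP stage and the first 420 s of recovery
are settling intervals excluded from analysis; the protocol validator
rejects any stage too short to hold its exclusion head plus the window.

## Generation model

All channels are multiplicative on the log scale. For subject *i*, channel
*p*, stage *s*:

```
log X_ips = log B_ip + r_ip * log M_ps + tau_p * Z_ips     (stage level)
log x_ips(t) = log X_ips + cv_p * z(t)                      (beat level)
```

* `B_ip` — subject baseline, log-normal around a population median
  (HR 62 min⁻¹, SV 95 mL, PEP 100 ms, LVET 300 ms, …; baseline HR clipped
  to [50, 100] min⁻¹ and SV to [60, 130] mL);
* `M_ps` — configured median stage multiplier (see below);
* `r_ip = g_i · exp(N(0, 0.10))` — a shared log-normal "response severity"
  `g_i` (sd 0.25) with per-channel jitter, so all responsive channels of a
  subject move together;
* `tau_p` — stage-level idiosyncratic noise (the calibrated quantity);
* `cv_p` — beat-to-beat coefficient of variation (0.03–0.20 per channel);
  beat times follow RR intervals jittered around 60/HR.

Derived channels are exact per-beat identities — CO = SV·HR/1000,
SI = SV/BSA, CI = CO/BSA, STR = PEP/LVET, FTC = LVET/√RR (Bazett) — and the
`ccc` channel is a beat counter excluded from features. The published
channel table defines CO as "SV/HR", which contradicts its printed unit
(L·min⁻¹); the product is enforced. BSA uses the DuBois formula (the common
clinical default; no formula is prescribed by the study design).

The echo reference is generated the way the measurement is made: a fixed
baseline LVOT diameter (~2.2 cm) sets the cross-sectional area; each stage
draws nine VTI samples (cv 4%) around the true stage value and
SV-TTE = CSA × median(VTI). Missing echo measurements are flagged at rate
0.057 per (subject, stage), chosen so that ≈ 11% of relational observations
lose their label (the reported exclusion fraction); whole-recording
("absolute") missingness is available as a config knob but defaults to 0 so
the canonical counts (330/319) are exact.

### Default stage multipliers

Reported cohort medians anchor the trajectories where published (SV-TTE
0.657, SV-EC 0.799 and ICON 0.704 at −45 mmHg; the full HR sequence
0.969/1.022/1.095/0.92; SBP 0.953/0.948; DBP 1.027 and 1.038; MAP recovery
1.02); intermediate stages and the unreported channels (PEP, LVET, SVV,
HRV) interpolate monotone graded responses consistent with the physiology
(PEP lengthens, LVET shortens, SVV rises, HRV falls under falling preload).
The entropy/stationarity channels (HRC, MSE, PNN, STAT, VIC) are
weakly-informative noise (multiplier 1 everywhere). CO being a derived
identity, its −45 mmHg median (≈ 0.87) is implied by SV-EC × HR rather than
set independently.

### Correlation calibration

The generator targets median *intra-subject* Pearson correlations with
SV-TTE across the five stage timepoints: SV-EC +0.856, ICON +0.806,
PEP −0.839, STR −0.902, SVV −0.706, HRV +0.797, SBP +0.624, HR −0.576.
Given the multiplier trajectories, the five-point sample correlation is a
monotone decreasing function of `tau_p`; `tau_p` is solved by bisection on
the Monte-Carlo *median sample correlation* under the exact stage model
(echo noise and subject heterogeneity included), using fixed common random
numbers so calibration is a deterministic function of the configuration.
The naive population-correlation formula is biased for n = 5 timepoints
(the sample-correlation median exceeds the population value by up to
~0.05–0.10 at these magnitudes), which is why the calibration operates on
the finite-sample median directly. STR is derived (PEP/LVET), so its
correlation is emergent; LVET carries an internal target of +0.80, chosen
so the derived STR lands near −0.90. Channels without targets get a flat
stage noise of 0.04 (log scale). A global `noise_factor` scales every noise
source; `GeneratorConfig.low_noise()` halves them for signal-recovery
benchmarks.

## Features and scaling

Seven statistics per channel per window: mean, median, SD and variance with
the n−1 denominator, moment skewness g1 and excess kurtosis g2 (both 0 by
convention for zero-variance windows, avoiding NaN propagation), and IQR
with linear-interpolation quantiles. 17 channels (all but the beat counter)
× 7 statistics = 119 candidate features; zero-variance features are dropped
by the scaler and recorded. The z-score scaler is fitted on training
subjects only inside the evaluation loop — the original description scales
before modelling without stating leakage control; fold-wise fitting is the
defensible choice and is what this package does (a global scaler is used
only for the descriptive relational table, where no model is fitted).

## Relational observations

Differences of z-scored features (target − reference) are scale-free and
make the baseline self-relation representable as the zero vector (labelled
negative by construction). The label compares the two related timepoints
(positive iff SV-TTE fell ≥ 20% between them), matching the pairwise
missingness bookkeeping; pairs with a missing echo value at either endpoint
are emitted with `valid=False` and excluded from modelling but retained in
counts. Whether the original relation was a difference, ratio or
concatenation is not recoverable; the difference is the package's choice.

## Grey-zone ROC

AUC is the trapezoidal area, identical to the Mann-Whitney statistic with
ties counted half (asserted against an exhaustive pairwise oracle). Youden
candidates are midpoints between adjacent unique scores plus ±∞,
classification `score ≥ cutoff → positive`, ties toward the smaller cutoff.
The bootstrap resamples observations (not subjects; subject-level and
class-stratified resampling are available as options), 1000 replicates by
default, percentile CIs. Replicates that are single-class, or whose optimal
cutoff is non-finite (possible only for degenerate all-equal scores), are
skipped and counted. Marker orientation is auto-detected as the direction
with AUC ≥ 0.5 and recorded.

## Cohort statistics

Wilcoxon signed-rank: zero differences dropped before ranking, exact null
for ≤ 25 non-zero tie-free pairs, otherwise the normal approximation with
continuity and tie correction (scipy backend). The type-I simulation helper
vectorises the same corrected approximation used at n = 29. Cohen classes
are a step function of |ρ| with inclusive boundaries 0.1/0.3/0.5. No
multiple-testing correction is applied (none is applied in the analysis
being reproduced).

## Nested cross-validation

Outer loop: 29 repetitions of leave-two-subjects-out; test pairs drawn
uniformly without duplicates while distinct pairs remain (29 < C(29,2), so
duplicates never occur at the canonical size). Inner loop: 10-fold CV,
stratified by label at observation level — only the outer loop is
subject-based. Feature-selection routes follow the per-algorithm defaults
(KNN none; NB recursive elimination, implemented as symmetrical-uncertainty
ranking evaluated over a halving size ladder by inner-CV AUC; radial SVM
gain-ratio filter; linear SVM and RF the union of features scored > 0 by
information gain, gain ratio or symmetrical uncertainty), with a forward
wrapper available for every model. Entropy filters discretize by
equal-frequency 5-bin binning. Grid-search ties break toward the smaller
value on every axis; a chosen value on a grid edge extends that axis by its
step pattern (geometric or arithmetic, at most twice per axis per
direction, never into non-positive territory) and reruns the search. The
published NB grid contains negative bandwidth/smoothing values, which are
undefined; the grids here are clamped to valid settings. Hyperparameter
semantics: k = neighbours; adjust = KDE bandwidth multiplier on Silverman's
rule; fL = additive smoothing of class-prior counts (it has no effect on
continuous likelihoods); sigma = RBF kernel width; cost = margin penalty;
mtry = features per split (RF, 100 trees).

Vital-sign comparators are relational differences of the raw stage values
(cuff SBP/DBP/MAP, window-mean HR), oriented on the training observations
and scored on the same held-out observations as the model; AUC
distributions are compared by a two-sided Mann-Whitney test.

## Problem sizes and numerical choices

Benchmarks and the acceptance script use: 200 subjects for parameter
recovery (median standard errors ≲ 0.01 on relative levels), 29 subjects
for the nested-CV runs with the reduced RF grid mtry ∈ {2, 5, 8} (the full
1–15 grid is the library default), 1000 bootstrap replicates, 100 seeds ×
n = 300 for grey-zone coverage of the analytic equal-variance Gaussian
optimum (μ₊ = 1, μ₋ = 0, σ = 0.5 → cutoff 0.5), and 10⁴ replicates for the
Wilcoxon type-I simulation. All randomness is routed through
`numpy.random.SeedSequence` streams spawned per stage from one master seed;
identical configuration and seed give bit-identical datasets and results.

## What the synthetic cohort does and does not show

The generator reproduces: graded multiplicative stage responses with the
reported medians, between-subject response heterogeneity at roughly the
reported interquartile spread, intra-subject correlation structure at the
reported medians, beat-to-beat noise, echo sampling noise and label
missingness. It deliberately omits: within-stage transients (stage levels
are stationary — the settling dynamics after a pressure change are not
characterized in the source material and are excluded by the protocol
anyway), waveform morphology, autonomic oscillations, cross-channel
dependence beyond the shared severity factor, and any non-log-normal tail
behaviour. Consequently a high nested-CV AUC here demonstrates that the
pipeline is correct and leakage-free and that the configured effect sizes
are detectable — it does not certify performance on real patients, where
channel noise is heavier-tailed and the correlation structure richer. The
null (within-subject label permutation) and calibration checks are the
parts that transfer directly.

## Known limitations

* The exact 109-feature roster of the original analysis is not recoverable
  from its channel table (17 × 7 = 119 here); the retained-channel list is
  configurable.
* caret-style recursive feature elimination is approximated (see above).
* Kernel Naive Bayes evaluates KDE densities exactly (O(n_train) per
  prediction), which is slow for large cohorts.
* Population-level correlations pool stage observations across subjects
  and therefore mix within- and between-subject variance, as in the
  original analysis.
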