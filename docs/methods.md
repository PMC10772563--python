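# Methods

This note documents the models, conventions and numerical choices behind
`ecgdynrisk`, in the order the pipeline runs them.  It describes what each
stage assumes and what the synthetic study conditions do and do not emulate.

## Problem setting

Patients carrying an implantable cardioverter-defibrillator (ICD) accumulate
resting ECGs over years of follow-up.  The package asks whether the
*evolution* of ECG morphology improves prediction of malignant ventricular
arrhythmia (VT/VF treated by the device) over a model that only sees the
implantation-time snapshot.  The pipeline is: per-recording mean-beat
templates → 16-dimensional latent representation (β-VAE) → 90-day
person-period rows with last-value-carried-forward (LVCF) latents → a
Poisson-splitting hazard forest → time-dependent discrimination and
calibration.

## Synthetic cohort generator

Real ICD-cohort data cannot be redistributed, so the generator produces
cohorts with the statistical structure the analysis assumes, plus ground
truth for every quantity the pipeline is supposed to recover.

**Beat model.**  Leads I and II are sums of five Gaussians (P, Q, R, S, T),
each with an amplitude (mV), a centre relative to the R peak (s) and a
width (s); the beat repeats exactly at 60/heart-rate seconds via phase
wrapping.  Leads III, aVR, aVL, aVF follow from the Einthoven/Goldberger
identities *before* noise, so the identities are machine-exact on noiseless
output.  Per-lead additive white noise (default 0.03 mV) and a ≤0.5 Hz
cosine baseline wander (default 0.10 mV, random phase/frequency) emulate
acquisition artefacts.  This is an interpretable ECGSYN-style
simplification: it produces realistic-looking limb-lead beats with
recoverable parameters, not a dipole-model 12-lead simulation, and it never
renders arrhythmia episodes — only event times.

**Population and drift.**  Patient baseline morphologies jitter the
population-typical beat (~15 % on amplitudes, ~10 % on widths, moderate
T-centre and heart-rate spread).  Over follow-up, the T-wave amplitude
performs a Gaussian random walk on the 90-day grid with step SD 0.08 mV per
90 days (T width and heart rate can drift too; their default step SD is 0).
Interval 0 carries the baseline value, so a horizon of sixteen 90-day
intervals accumulates fifteen free steps.  The walk can cross zero,
producing T-flattening and frank T inversion — the morphological change the
latent space is expected to pick up.

**Visits.**  Every patient has a day-0 ECG.  Later visits arrive at gaps
drawn from Normal(180, 45²) days truncated at 30, emulating roughly
bi-yearly follow-up with a realistic median of ~8 ECGs over 4 years.
Recordings after the event/censoring day are discarded, so the risk set is
consistent by construction.

**Covariates.**  The baseline table mirrors a typical ICD cohort: age
(61.7 ± 13.9), male 74.5 %, ischaemic cardiomyopathy 41.6 %, primary
prevention 60.5 %, prior sustained VT/VF 40.6 %, LVEF ≤ 35 % 60.6 %,
β-blocker 76.6 %, amiodarone 8.8 %, plus creatinine, potassium and
NT-proBNP.  Labs lose 10 % of values completely at random; NT-proBNP loses
35 %, deliberately crossing the 30 % exclusion threshold so the imputation
stage's column-dropping rule is always exercised.  Missingness is MCAR —
the simplest mechanism consistent with the imputation stage; informative
missingness is not modelled.

**Events.**  The hazard is piecewise-constant on the 90-day grid:
λ_k = λ₀ · exp(β_T · (Tamp_k − T_ref) + Σ β_c X_c), with defaults
λ₀ = 1.2 × 10⁻⁴ /day, β_T = −4 /mV (a *falling* T amplitude raises risk),
β(prior VT/VF) = 0.7 and β(LVEF ≤ 35 %) = 0.4.  Events occur in interval k
with probability 1 − exp(−λ_k·τ) and land uniformly inside it; everyone
else is censored administratively at 1440 days (48 months).  These defaults
give a cumulative incidence of ≈ 33 % at the 48-month horizon —
deliberately at the upper end of published ICD-cohort therapy rates, which
report ≈ 29 % over a *mean* (much shorter, highly dispersed) follow-up —
and make the planted time-varying effect produce a dynamic-minus-static
AUROC separation of the order seen in real longitudinal ECG cohorts
(≈ 0.07–0.12).

## Preprocessing

Recordings at 500 Hz are decimated to 250 Hz after an anti-aliasing FIR
low-pass.  Each lead is smoothed with a Savitzky–Golay filter (window 15
samples = 60 ms, cubic), then a low-resolution Fourier cosine series
(frequencies k/(2T) Hz up to 0.7 Hz, plus an intercept, fit by least
squares) is subtracted to remove baseline wander.  Note the half-range
cosine basis removes zero-phase cosines almost exactly but attenuates the
quadrature (sine) component of arbitrary-phase wander more slowly — in
practice the beat-frequency content is untouched and the slow trend drops
by well over half even in the worst phase.

R peaks are detected on lead II: band-pass 5–20 Hz, squared derivative,
80 ms moving-average energy, adaptive threshold (20 % of the 99th
percentile), 0.24 s refractory distance, then snapping to the local
extremum of the band-passed signal within ±60 ms.  Any detector meeting the
recall/precision ≥ 0.99 (±40 ms) bar on the synthetic oracle suite is
considered conformant; this one is simply a dependency-free default.

Beats are extracted in a window of 62 samples before and 113 after the R
peak (0.25 s / 0.45 s at 250 Hz, L = 175), averaged per lead, and min–max
normalised to [0, 1] per lead; a constant lead maps to all-0.5 by
convention.  At most one recording per patient per day is kept (the first).
No beat-exclusion or quality gating is applied — noisy records produce
noisier templates and stay in.

The encoder consumes the six leads concatenated in the fixed order I, II,
III, aVR, aVL, aVF (input length 1050); single-lead mode uses lead II alone
(length 175) through the identical code path.

## Latent representation (β-VAE)

A fully connected β-VAE: three encoder layers with ReLU, affine heads for
the posterior mean and log-variance of 16 latent variables (AE0…AE15), a
reparameterised sample, and a three-layer mirrored decoder with a linear
output.  Implemented directly in NumPy (hand-derived gradients, Adam,
seeded Glorot initialisation); the gradient implementation is verified
against central finite differences in the test suite.

**Loss convention.**  The *reported* loss follows the mean convention:
recon = element-wise mean squared error, KL = −½ Σᵢ(1 + log σᵢ² − μᵢ² −
σᵢ²) averaged over the batch, total = recon + β·KL.  The *optimised*
objective weights the reconstruction by its feature-summed squared error
(mean MSE × input dimension), i.e. the standard ELBO with a unit-variance
Gaussian decoder, so β = 1 is the textbook VAE.  Without this scaling the
KL term dwarfs a mean-MSE reconstruction on [0, 1] templates and the
posterior collapses onto the prior.

**Training.**  Default hidden sizes for template-sized inputs are
(256, 128, 64); batch 128, Adam at 10⁻³, a 10 % validation split with
early stopping (patience 20) inside a 200-epoch budget.  Pretrain and
fine-tune share the machinery: pretraining runs on a large synthetic
morphology pool (the stand-in for a big unlabelled hospital ECG archive),
fine-tuning continues from those weights on the cohort's training-fold
templates.  The pool widens the T-amplitude spread (SD 0.12 mV) so the
encoder sees the full support that drifting cohorts occupy.  Downstream
features are always the posterior means μ, never samples — deterministic
features for the survival stage.

**Reconstruction metrics.**  Pearson r, RMSE, PRD = 100·√(Σ(x−x̂)²/Σx²)
(denominator = raw energy of the normalised input) and DTW (unit step
pattern, |·| local cost, O(nm) dynamic programme), all computed after
min–max normalising both signals.  On 500 held-out pool templates the
trained model reaches r ≈ 0.98 and RMSE ≈ 0.05, comfortably beating the
constant-mean-template baseline (RMSE ≈ 0.11).

## Person-period restructuring (CPIUs)

Follow-up is cut into 90-day counting-process information units.  Row k of
a patient covers days [90k, 90k+τ), τ ≤ 90; the final row's τ is the
remainder to the event/censoring day, and an outcome exactly on an interval
boundary closes the previous interval (no zero-length rows).  Σ τ over a
patient's rows equals their follow-up exactly, and an event patient has
exactly one event row — their last.  Features for interval k are the
latents of the most recent ECG with day ≤ 90k (LVCF, no within-interval
look-ahead), plus the static baseline covariates; each row also carries the
ECG age and a carried-forward flag for diagnostics (these are bookkeeping,
not model features).

Baseline covariates are prepared on the training fold only: columns with
≥ 30 % missing are dropped, remaining continuous gaps are filled by
iterative random-forest imputation, flags pass through, any categorical
strings are one-hot encoded, and continuous columns are z-scored with
training-fold statistics.  The fitted encoder records the training patient
set, making leakage auditable.

## Hazard forest

Trees are grown on patient-level bootstrap resamples — all of a patient's
rows enter together, which keeps within-patient correlation out of the
out-of-bag ledger.  At each node, `mtry` (default √p) candidate features
are inspected; candidate thresholds are midpoints between distinct sorted
values, subsampled to at most 32 per feature; the split score is the
Poisson profile log-likelihood improvement

    gain = Σ_children D_c·log(D_c/T_c) − D·log(D/T),   0·log 0 ≡ 0,

with D the event count and T the risk time.  This criterion needs no
proportional-hazards assumption, and isolating an event-free child is a
legitimate, often optimal split.  Nodes stop splitting below 5 events or 10
rows, or at depth 20.  Leaves store the Bayes-shrunk rate
λ = (D + a)/(T + b) with b = 90 days of pseudo risk time (one CPIU) and
a = r₀·b, r₀ the bootstrap sample's marginal rate — so an uninformative
leaf reverts to the marginal hazard.  Prediction averages leaf rates over
trees; the interval event probability is 1 − exp(−λ·90) for prospective
90-day prediction.  (The realised τ of a row is outcome-informative and is
never used in the prediction.)

The **static comparator** pushes the same rows through the same machinery
with every patient's latent features frozen at their interval-0 values.
Using one implementation for both arms isolates the effect of time-varying
information from implementation differences between forest libraries.

Hyperparameters (trees ∈ {100, 300}, mtry ∈ {√p, p/3}, minimum node events
∈ {5, 15}) can be tuned by 5-fold patient-wise cross-validation on the mean
time-varying AUROC, with ties broken toward smaller forests.  The default
experiments use a fixed, mid-grid configuration (150 trees, √p, 5 events)
rather than tuning every run.

A time-varying Cox model over the same counting-process rows (delegated to
lifelines' `CoxTimeVaryingFitter`) provides standard hazard-ratio
inference; non-convergence is raised, not swallowed.

## Evaluation

**Discrimination.**  The time-specific AUROC of interval k is the
Mann–Whitney probability (ties half-credit) that an event row outranks a
non-event row among the rows at risk in k.  Intervals with fewer than 2
events or 2 non-events are flagged and excluded.  The mean time-varying
AUROC is the unweighted mean (± SD) over valid intervals up to 16 intervals
(48 months).  AUROC is invariant under monotone transforms of the
predictions, which the suite checks property-based.

**Uncertainty.**  Patient-level bootstrap: unique patients are resampled
with replacement (all their rows together), the statistic recomputed, and
the 2.5/97.5 percentiles reported; 500 iterations by default.

**Calibration.**  Predictions are cut at their decile quantiles (ties stay
together, so heavily tied predictions merge groups); each group reports its
mean predicted 90-day risk and observed event rate, and the OLS slope of
observed on predicted summarises the table.

**Importance.**  Permutation importance shuffles one feature column across
the test rows, recomputes predictions and the mean time-varying AUROC, and
reports baseline minus permuted, averaged over 5 repeats; latent and
clinical features are equally eligible.

**Subgroups.**  The AUROC summary is repeated within caller-chosen strata
(sex, ischaemic aetiology, …) with group sizes, flagging degenerate groups.

## Interpretation

Factor traversal decodes a reference latent vector (element-wise median of
the cohort latent means) with one dimension swept across the cohort's
5th/25th/75th/95th percentiles; the per-sample absolute difference from the
reference reconstruction localises the morphological region that dimension
controls.  On synthetic cohorts the dimension most correlated with the true
T amplitude perturbs the T-wave window far more than the QRS window.
Latent–feature correlations (Pearson, NaN for zero-variance columns) link
dimensions to generator ground truth or to simple template measurements
(R amplitude, threshold-crossing QRS width, signed T amplitude); the
external-CNN class probabilities used in clinical deployments are replaced
by these ground-truth quantities here.

## Problem sizes and determinism

Default experiment sizes were chosen so that a complete study — encoder
training, ten paired dynamic/static replicates, hazard recovery, and
calibration — runs on a single CPU core in well under an hour: encoder pool
5,000 templates, cohorts of 1,000 patients over 16 intervals, forests of
150–300 trees.  The paired dynamic-vs-static design reuses one trained
encoder across replicates; the encoder's training pool is independent of
every replicate cohort, so no leakage arises.  All randomness descends from
named integer seeds through `numpy.random.SeedSequence` streams; identical
configuration and seed give bitwise-identical cohort tables, model
initialisations and bootstrap draws.

## What passing tests do and do not show

The synthetic cohorts share the *structure* of real longitudinal ICD data —
irregular visits, LVCF staleness, censoring, baseline confounding,
missingness — but their morphology manifold is five Gaussians per lead,
their drift is a single-parameter random walk, and their hazard is exactly
piecewise-constant in the drifting parameter, i.e. the estimator's own
model family.  Recovering the planted signal therefore validates the
machinery (representation, restructuring, splitting, evaluation), not the
clinical effect size: real ECGs carry richer morphology, real drift is not
a random walk, and real hazards are not exactly log-linear in any latent.
Absolute AUROC values on synthetic cohorts are not comparable to clinical
reports; the *differences* between paired arms are the meaningful output.

## Known limitations

- Precordial leads (V1–V6) are out of scope; the beat model covers limb
  leads only.
- MCAR missingness only; informative missingness would need a different
  imputation validation.
- The mean time-varying AUROC weights all valid intervals equally; late
  intervals with few events are noisy, and the degenerate-interval rule
  (< 2 events / < 2 non-events, configurable) is a convention.
- The cosine detrending basis attenuates quadrature wander slowly (see
  above); a full Fourier basis would remove it faster but is not the
  documented convention.
- Competing risks (death before arrhythmia) are not modelled; mortality can
  be analysed as an alternative outcome label, not jointly.
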