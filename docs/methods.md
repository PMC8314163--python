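# Methods

`phenodep` studies whether day-to-day smartphone usage patterns carry a
signal of depressive symptom severity. Because the motivating kind of raw
sensing cohort is not publicly depositable, the package pairs every
analysis stage with a synthetic study generator whose statistical structure
matches what the analyses assume, so the entire pipeline is testable from a
clean checkout.

## The synthetic study

**Population.** Participants receive demographic categories (age group,
gender, education, occupation, country) drawn i.i.d. from fixed marginals
(e.g. 86.8% male, 32.4% aged 25–34), and one IANA time zone tied to their
country. Observation spans are drawn from a fixed histogram over 8–86 days
(57.9% contribute 8–14 days; mean ≈ 22 days), reproducing a short-and-
skewed panel typical of crowdsourced sensing studies.

**Behavior.** Screen and internet connectivity are two-state
continuous-time Markov chains. Each participant has a logit-normal
stationary screen-on probability (`screen_logit_mean = -1.7`,
`screen_logit_sd = 0.7`, plus day-level logit noise of SD 0.3), i.e. a
median of ~3.5 h screen-on per day, and a log-normal number of on/off
cycles per day (median 40). The internet chain is mostly connected
(logit mean 1.6) with ~8 cycles/day. App launches are a marked Poisson
process on screen-on time (~0.12 launches per screen-on minute) with
Zipf-weighted app choice over a 50-app catalog. These process constants
are free calibration parameters — the emulated study reports no generative
description of raw usage — chosen once for realism and exposed in
`SynthConfig`.

**Sampling.** Logs are written opportunistically at ~1% battery-change
events: a homogeneous Poisson schedule of `battery_events_per_day = 100`
events. Each scheduled event logs state *changes* since the last
successful sample plus buffered app launches; with probability
`missing_interval_rate = 0.03` a scheduled event is silently lost (a
*missing log interval*). Because states are only observed at sample times,
reconstructed day summaries carry realistic quantization noise.

**Depression.** Latent severity per 14-day assessment window is a
participant random intercept plus AR(1) innovations
(`latent_icc = 0.7584`, autocorrelation 0.5), standard-normal marginally.
PHQ-8 items follow a graded ordinal-logit response model
(discrimination 1.6, threshold offsets 0/1.1/2.2); the shared threshold
base is solved by bisection (Gauss–Hermite quadrature over severity and
exact 8-fold convolution of the item distribution) so that
P(total ≥ 10) equals the configured prevalence of 0.1681. Observed-outcome
ICC comes out ≈ 0.67 — slightly below the latent 0.7584 because item noise
adds within-participant variance.

**Effect injection.** Windows whose latent severity exceeds the
prevalence quantile are *depressed*. On their days the screen chain's
stationary probability is remapped so the day's normalized screen-state
entropy rises by `entropy_effect` reference SDs (the reference SD is the
model-implied population SD of that feature, computed by quadrature; the
remap inverts the two-state entropy on the same side of ½ and clips at 1).
The default `entropy_effect = 0.54` was calibrated by pilot simulation so
the pooled-sample Pearson correlation between screen normalized entropy
and the PHQ-8 total is ≈ 0.14 (verification at 2,000 participants: mean
r = 0.148 ± 0.012 over four replicates); `entropy_effect_for_r`
re-derives it. With
`nonlinear_effect_flag`, depressed windows additionally flip the internet
chain into one of two extreme regimes (always-connected/very-regular or
50:50/fast-switching, coin per window) — a non-monotone association that
linear statistics cannot see but tree ensembles can.

**What the generator does not emulate.** Real diurnal rhythms (event rates
are homogeneous within the day), weekday/weekend structure, travel or
time-zone changes, battery physics, app-category semantics, and
informative missingness (loss is MCAR). Consequently, passing tests show
that the *pipeline* recovers what was injected under its stated
assumptions — not that real phone data carry these signals.

## Preprocessing and features

Timestamps are converted to participant-local time; each local calendar
date with at least one event becomes a day. States are carried forward
between logs (off/disconnected before the first log); an hour's modal
state is the state holding the majority of its minutes, ties resolved
toward off/disconnected. Days with ≥ 10 missing log intervals are
excluded; responses need ≥ 8 retained days in the 14 calendar days ending
on (and including) the response date. With a generator schedule the
missing count is exact; for schedule-less logs it falls back to counting
gaps longer than twice the participant-day median gap.

The 22 day-level markers: 6 counts (screen on/off, internet
connected/disconnected, app launches, distinct apps), Shannon entropy and
normalized entropy of the day's state-duration proportions (screen,
internet) and per-app launch frequencies (natural log; single-state days
have both entropies 0), 3 regularity indices, 5 epoch-count SDs (sample
SD over the four 6-hour epochs, ddof 1), and first/last app-use minutes.
The regularity index of two days is the mean over 24 h of the product of
hourly values rescaled to [−0.5, 0.5] (binary states map to ±0.5; hourly
distinct-app counts map linearly by the pair maximum, an all-zero pair
scoring 0), so it lives in [−0.25, 0.25]; no additional normalizing
constant is applied, and downstream statistics are invariant to that
scale choice. A day's regularity is its mean pair score against the other
retained days of the same ISO week, missing when the week has no peer.

Pooling: per retained response, count/entropy/regularity/app-time
features average over the window's days (missing values contribute
nothing); epoch-SD features pool as
`sqrt(mean of daily variances)` (equal 3-df days). Labels are
1{PHQ-8 ≥ 10}; exact duplicate rows are dropped.

## Statistics

Pearson correlations use pairwise-complete rows (the generator yields
near-complete tables, so this matches the estimand of likelihood-based
missing-data correlation under MCAR); p values are Holm step-down
adjusted. Note Holm controls the family-wise error rate — we implement it
as named. The association model is a per-feature bivariate linear mixed
model `phq8_total ~ standardized feature + (1 | participant)` (statsmodels
`MixedLM`, REML) over m = 20 single-level PMM imputations (OLS predictive
model on complete columns, refit on a bootstrap resample per imputation,
k = 5 donors), pooled by Rubin's rules with large-sample Wald p values
(no small-sample df correction at these n) and BH adjustment. The ICC
uses one-way ANOVA variance components with the unbalanced-design
correction, truncated at zero, applied to the outcome.

## Classification

Stratified 10-fold outer / 3-fold inner nested CV; inner grid search
selects hyperparameters by macro F1; SMOTE (our implementation: minority
interpolation among k = 5 Euclidean nearest minority neighbors, singleton
minority duplicated with a warning) is applied to training partitions
only, after standardization for the margin/distance learners (SVM-RBF,
KNN, LR; trees are unscaled). Metrics: accuracy, precision/recall/F1 on
the depressed label, ROC AUC from probability or decision scores (midrank
ties), Cohen κ. Baselines: the random weighted classifier (10,000
prediction vectors drawn i.i.d. from the empirical class distribution;
its mean κ is 0 and mean AUC 0.5 analytically, which is what the
acceptance script recomputes) and a decision tree restricted to the
one-hot demographics. Permutation importance is the AUC drop when one
test-fold column is shuffled (5 repeats), averaged over outer folds.

Fold assignment is record-level by default, faithful to the emulated
protocol. Because assessments repeat within participants (outcome ICC
≈ 0.67–0.76) and the markers are participant-identifiable, record-level
CV partially memorizes participants: under a zero-effect generator it
still scores AUC ≈ 0.55–0.64. `group_folds=True` holds participants out
instead and removes that inflation (at these sizes it even dips slightly
below 0.5, a known small-sample anti-learning artifact of grouped CV).
Both modes are first-class; the test suite asserts grouped ≤ record-level.

## Validation design and problem sizes

The feature primitives are tested against brute-force oracles (1e-12 on
1,000 random inputs each). Protocol null calibration uses five
zero-effect 200-participant studies with seeded row-permuted labels —
the permutation removes the participant-level label structure, so every
learner's nested-CV AUC must center on 0.5; a systematic excess would
indicate train/test leakage in the harness. Hyperparameter grids in these
suite runs are compact two-point grids (the protocol shape — 10×3
stratified nested CV, SMOTE, all five learners — is unchanged; the null
property does not depend on grid size). Parameter recovery runs the
default generator at 850 participants (≈ 1,400 pooled samples): the
Pearson r for screen normalized entropy is compared to the 0.14 target
with a participant-level bootstrap SE, and the pooled LMM slope to a
frozen high-precision reference (0.86, replicate SD 0.08) computed once
from four 2,000-participant runs of the same generator — the injection is
a latent threshold shift, so the LMM estimand has no closed form and the
check is a consistency/parameter-stability test; both quantities scatter
between replicates somewhat more than their model SEs suggest (the
depressed-window mix interacts with participant-level entropy headroom),
which the frozen SE constants cover. The importance-ranking check uses ten
150-participant replicates with the nonlinear internet regime enabled and
a fixed random forest over stratified 10-fold CV.

## Known limitations

Single-level (not multilevel) PMM; large-sample Wald inference in the
Rubin pooling; the record-level protocol's optimism is reported, not
"fixed"; the RWC baseline is the literal i.i.d. multinomial predictor, so
only its distribution-free κ and AUC are meaningful summaries; calendar
effects and informative missingness are out of scope.
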