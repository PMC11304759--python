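# Methods

This note documents the models, generators and numerical choices behind
`moodpulse`, and what the synthetic experiments do and do not demonstrate.

## Problem setting

The package implements a population mood-surveillance pipeline. Per-user
mood is estimated for 3-hour frames (half-open `[t, t+3h)` windows anchored
at local midnight — every module shares this convention) from two
modalities:

* **SMM (sensor mood model)** — a classifier over per-frame smartphone
  sensor features, trained on experience-sampling (ESM) self-reports
  (7-level Likert mood, six prompts per day).
* **QMM (query mood model)** — logistic regression over binary
  query-presence features: `x_k = 1` iff vocabulary token *k* was searched
  in the frame. Presence only, never counts; a multi-token query sets each
  of its tokens' indicators.

The **two-step scheme** is the core method: most frames lack a self-report,
so the SMM's predicted class fills in missing labels, enlarging the QMM
training set. Evaluation labels are always annotation-sourced: SMM-imputed
labels never enter a test set.

Per-user QMM scores aggregate into a national (or regional) mood score —
the mean score of users active (≥ 1 query) in the time unit — which feeds
four analyses: weekly rhythm, regional drop vs case counts, hourly event
tracing, and convergent cross-mapping (CCM) against an epidemic curve.
A separate module implements the pairwise mood-conditioned ad-click
statistic with its exact binomial null.

## Design choices in the models

**QMM functional form.** The model is *fit* by L2-regularized logistic
regression, but the mood score reported downstream is the unbounded linear
predictor `y = intercept + Σ w_k x_k`, never the sigmoid output. Aggregated
scores therefore have no fixed range, and ratio-based traces guard against
near-zero denominators.

**Per-sample regularization.** The ridge penalty is expressed per sample
(`C = 1/(n·λ)`, default λ = 1e-4), so the fitted decision function is
invariant to duplicating the training set. With vocabularies pruned at a
minimum frequency of 5 frames, λ = 1e-4 is weak enough not to mask
token effects at a few thousand training rows.

**Pooled models.** Both SMM and QMM are single pooled models trained on
per-user-per-frame rows; a per-user variant of the QMM would be untrainable
from the handful of labeled frames each user contributes.

**Class scheme.** The Likert scale is binarized: 5–7 positive, 1–3
negative, 4 (neutral) excluded from training and test. AUC-based
evaluation presumes a binary target; a 7-class SMM variant exists
(`scheme="likert"`).

**Multiple annotations per frame** are averaged and rounded half-to-even
(so 3 and 5 resolve to the excluded neutral 4). **Class imbalance** is
handled with inverse-frequency class weights in the SMM.

**SMM classifier family** is a random forest (200 trees, min leaf 5, fixed
seed): a strong default for small tabular feature sets that needs no
feature scaling and keeps training deterministic.

**Daily aggregation** is the mean of per-user daily means (heavy searchers
do not dominate); a pooled-over-frames variant is available. The regional
drop is a difference (target − baseline-window mean) by default, with a
ratio option.

## Empirical dynamic modelling (CCM)

Written from scratch in `moodpulse.ccm`:

* **Step 1** — 7-day *trailing* moving average (real-time surveillance
  semantics; a centered option exists), then z-scoring to exactly mean 0 /
  sd 1 (population sd).
* **Step 2** — simplex projection: leave-one-out nearest-neighbor
  forecasting in the time-delay (Takens) embedding, E scanned from 1 to
  ⌊√n⌋ by default, E+1 neighbors with exponential weights
  `exp(−d/d_min)` (uniform when `d_min = 0`), embedding dimension chosen by
  minimum forecast RMSE (ties → smallest E). The s-map test fits locally
  weighted linear forecasts across a θ grid; the verdict is "nonlinear"
  when the best skill at θ > 0 beats the θ = 0 (global linear) skill by a
  margin of 0.02 in forecast correlation; singular local fits fall back to
  a 1e-8 ridge.
* **Step 3** — cross-mapping: "A xmap B" predicts series B from A's
  embedded attractor; skill that rises with library size indicates B
  influences A. Libraries are contiguous random segments (100 draws per
  size by default, seeded). Temporal neighbors within a Theiler window
  (default = τ) are never used as dynamical neighbors.
* **Convergence verdict** — mean ρ at the largest library must exceed mean
  ρ at the smallest, with a bootstrap 95% CI of the difference excluding 0,
  *and* reach a minimum skill of ρ ≥ 0.1. The floor prevents a
  statistically positive but negligible rise in near-zero skill from being
  called causal (uncoupled chaotic maps otherwise occasionally trip the
  CI-only criterion).

The simplex forecaster is validated against an exhaustive brute-force
nearest-neighbor enumeration (exact agreement on series of length 200), and
the CCM module against coupled logistic maps
`x' = x(r_x − r_x x − β_xy y)`, `y' = y(r_y − r_y y − β_yx x)`
(r_x = 3.8, r_y = 3.5): unidirectional forcing must produce convergent
skill only in the direction implied by the coupling, and zero coupling must
leave both directions flat.

## Pairwise ad-click statistic

For one ad-day, draw two distinct records; if exactly one is a click,
compare the mood scores of the two users: "positive" if the clicked user
scored higher. Score ties are counted but excluded from the day's majority
(a strict-alternative option exists). The day's winner is the majority over
comparisons; an ad's statistic is its number of positive-win days out of
14, compared against the exact `Binomial(14, ½)` pmf computed in rational
arithmetic.

Two estimators are provided: Monte-Carlo (default 1e5 draws per ad-day;
draws without exactly one click are discarded but still count toward the
budget) and exact enumeration of all clicked × unclicked pairs
(sorting-based, O(n log n)), used automatically when the day's record count
permits. The enumeration is also the oracle the Monte-Carlo path is tested
against. Per-record mood scores are the QMM score of the user's frame
containing the impression timestamp; impressions without a score are
dropped with a warning.

## The synthetic cohort generator

Latent mood of user *u* in slot *t*:

```
m_ut = baseline_u + A·cos(2π(d(t) − 6.5)/7) + AR1_ut + shock(t) + ε_ut
```

with `d(t)` the day-fraction since Monday 00:00. Defaults: baseline sd 0.5,
weekly amplitude A = 1, AR(1) φ = 0.6 / innovation sd 0.3, slot noise sd
0.3. The sinusoid peaks Sunday noon, so the weekday means run
Mon ≈ +0.60A, Tue ≈ −0.21A, Wed ≈ −0.88A, Thu ≈ −0.87A, Fri ≈ −0.21A,
Sat ≈ +0.60A, Sun ≈ +0.97A: Monday drops hard from the Sunday peak and the
weekend days rise — the qualitative weekday pattern the rhythm analysis
targets. A single sinusoid cannot reproduce every weekday transition (e.g.
a Tuesday rebound); that is a deliberate simplification. Shared shocks are
step events (timestamp, magnitude, duration) added to every user.

Observation models:

* **Annotations** — six prompts/day near 8:00/10:00/12:00/14:00/16:00/18:00
  (±jitter); each answered with probability 1 − missingness (default 0.5);
  the response is an equal-width binning (width 0.6 on the z-scale) of the
  latent value plus response noise (sd 0.3). Exact bin edges round
  half-to-even. At defaults, Spearman(latent, Likert) ≈ 0.92.
* **Sensor features** — six features with linear links to latent mood
  (slopes scaled by a coupling knob, default 1) plus three mood-blind
  context features; Gaussian noise sd 1.
* **Queries** — Poisson(0.7) events per slot; tokens 1 + Poisson(1) per
  event (mean 2 tokens per query) from a 200-token vocabulary in three
  strata (40 positive / 40 negative / 120 neutral); stratum log-odds tilted
  by ±0.8 × latent mood, neutral fixed at log 2.
* **Epidemic** — Gaussian-bump waves over a baseline with Poisson counts;
  optional multiplicative coupling `exp(c · mood_{t−lag})` (negative c:
  high mood suppresses cases).
* **Ads** — each campaign serves 14 days; click indicator is Bernoulli with
  `logit p = logit(base_rate) + δ·score`; δ = 0 is a mood-blind ad.

Every generator is a pure function of (parameters, seed); the cohort seed
spawns independent substreams for latent/annotations/sensors/queries so
changing one observation model never perturbs another.

**What the generator does not emulate:** real query text or Japanese
segmentation (tokens are abstract vocabulary items; whitespace
tokenization stands in), raw 10 Hz sensor waveforms (features are simulated
directly at frame level), GPS realism, non-stationary vocabulary drift, or
demographic structure. Passing tests therefore show the *machinery* is
correct and the method behaves as claimed under its own assumptions — not
that the specific published effect sizes transfer to real data, which come
from private commercial logs and are out of reach here.

## Study conditions and problem sizes

The packaged studies (`moodpulse.studies`, also behind
`scripts/acceptance.py`) use: two-step gain — 200 users × 21 days, 75%
annotation missingness (the upper part of the regime where augmentation
matters), 5 cohort seeds, frame-level 70/30 train/test split; bookkeeping —
2,000 query frames with frame-level 50% annotation coverage (exactly the
regime where augmentation should double the labeled set — the ESM prompt
schedule covers only 5 of 8 daily frames, so a prompt-level cohort would
give a larger ratio); rhythm — 250 users × 364 days on latent-derived
scores (model-estimation noise would only blur a property of the
aggregation itself); CCM benchmark — n = 1,000, β = 0.32, 30 library draws
per size; regional drop — 47 regions, generating correlation −0.43, 10
seeds; ad null calibration — 2,000 mood-blind ads plus 10 with δ = 5,
1,000 impressions/day at base click rate 0.02 (high enough volume that all
14 serving days are usable), day winners by exact enumeration.

## Known limitations

* The two-step gain is a mean effect across seeds; individual seeds can
  show near-zero gain when the annotation-only baseline is already strong.
* The s-map nonlinearity margin (0.02) and the CCM minimum-skill floor
  (0.1) are pragmatic thresholds, not significance tests.
* The rhythm analysis requires the previous calendar day to be present and
  non-holiday; gaps silently reduce the comparison count (reported as `n`).
* `simulate_ad_logs` samples impressions from the provided score table, so
  every impression has a score by construction; score-less impressions only
  arise when joining external event logs (`ads.join_scores` drops them with
  a warning).
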