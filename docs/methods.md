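# Methods

`raschtraj` implements a two-part longitudinal measurement analysis for a
brief computerized cognitive battery (six polytomous tasks, total score
0–24, higher = better): (1) partial-credit Rasch calibration with the full
quality-control battery, differential item functioning (DIF) by testing
session, item splitting, and form equating; (2) group-based trajectory
analysis (GBTA) of the total score over three sessions at months 0/3/6,
with practice-effect adjudication against a half-SD criterion and a
Bland–Altman measurement-error check. A synthetic-cohort generator
reproduces the statistical structure of such a study so every stage runs
and is testable at desk scale.

## Measurement model

The partial credit model (PCM) gives, for a person at ability θ (logits)
and an item with ordered thresholds τ₁…τ_m,

    P(X = k) ∝ exp( Σ_{j≤k} (θ − τ_j) ),  k = 0…m,

with the empty sum zero at k = 0. A threshold is the logit at which two
adjacent categories are equally probable; an item with m+1 response
options has m thresholds. The test characteristic curve (TCC) is the sum
of item expected scores and maps θ to an expected 0–24 total.

**Estimation.** Item thresholds are estimated by conditional maximum
likelihood (CML): conditioning each response vector on its raw total
eliminates the person parameters, leaving a likelihood over elementary
symmetric functions of the item category parameters. CML is consistent in
the number of persons however few items there are and assumes nothing
about the ability distribution. We chose it over joint (unconditional) ML
after measuring JMLE's incidental-parameter bias at six items: thresholds
spread roughly k/(k−1) too wide, with errors above 1 logit on the sparse
extreme categories of the 9-category recall item — too large for the
recovery tolerances this package holds itself to. The conditional
log-likelihood is maximized by L-BFGS with an analytic gradient;
convergence is declared on the optimizer's own criteria (gradient
tolerance 1e-6-scale, ≤200 iterations) and the recorded objective trace is
monotone. The grand mean of item locations (threshold means) is fixed at
zero for identifiability. Optionally the observed information (finite
differences of the analytic gradient, pseudo-inverse across the flat
grand-shift direction) provides a threshold covariance for SE contrasts.

**Person estimates.** Abilities are weighted-likelihood estimates (WLE),
which stay finite at floor/ceiling totals; SEs are 1/√(test information).
Persons at extreme totals are flagged; they contribute nothing to the
conditional item likelihood. Each person-session is estimated as its own
ability ("stacked"), which is what lets session act as a grouping factor
downstream.

**Residuals.** Standardized residuals z = (x − E[x])/√Var[x] at the WLE
ability feed every diagnostic.

## Fit battery

Conventional decision constants are module defaults and configurable:
fit residuals acceptable within ±2.5; ≤5% of subset t values outside
±1.96; residual correlation 0.3 flags dependency; PSI 0.7/0.9 for
group/individual use; intended construct range −4…+4 logits; five class
intervals (chosen for stability around n ≈ 100 per session).

- *Item fit*: the fit residual standardizes Σz² over persons. Because the
  ability is estimated from the same six responses, each squared residual
  is deflated by about the item's share h of the person's test
  information; we rescale z² by 1/(1−h) before aggregating (without this,
  perfectly model-consistent data drifts to fit residuals ≈ −4). No
  kurtosis correction is applied. The class-interval χ² compares observed
  and expected interval mean scores, df = intervals − 1, Bonferroni across
  items.
- *Unidimensionality*: PCA of the residual correlation matrix; items split
  by the sign of their first-component loading; per-person abilities
  re-estimated from each subset (WLE) and compared by t; verdict
  "unidimensional" if the outside-±1.96 proportion is <5% or 5% lies in
  its binomial 95% CI.
- *Dependency*: pairwise residual correlations above 0.3.
- *Targeting*: threshold range vs the central 95% of the person
  distribution; person mean/SD on the item-centred metric.
- *PSI*: (Var θ − mean SE²)/Var θ, floored at 0, non-extreme persons.

## DIF by session and item splitting

Per item, a two-way ANOVA (statsmodels OLS, type-II) of standardized
residuals on session × ability class interval: the session main effect is
uniform DIF, the interaction non-uniform DIF; Bonferroni across items;
either flag triggers the remedy. Empty cells are dropped with a warning.
The default remedy is *splitting*: the item becomes one pseudo-item per
session, observed only at its session, so each form gets its own
difficulty while raw totals are conserved; deletion is configurable. One
split→recalibrate→retest pass is the intended use. Note that with a
pooled calibration a genuinely shifted item leaks small compensatory
session effects into the other items; the retest after splitting is what
restores the null for them.

Splitting a 9-category item leaves ~100 responses per pseudo-item in a
study-sized cohort, so an extreme category can easily go unobserved.
Calibration then refuses with an explicit error naming the item and
category; the pipeline applies the prescribed remedy — a logged,
deliberate `collapse_categories` re-coding to consecutive observed
categories — and retries. Collapse is never silent.

**Equating.** From the split calibration, each form's TCC maps every raw
total to θ and on to the expected total on the reference form (form A);
extreme totals are anchored 0.25 points inside the scale and map to
themselves. Both maps are monotone. Downstream analyses use these
form-equated totals.

## Trajectory model

A finite mixture of polynomial mean trajectories with shared Gaussian
residual σ: person i in group k has y_it ~ N(x_t′β_k, σ²), x_t = (1, t,
…), t in months so a linear slope is in score units/month and change over
the 6-month study is slope × 6. Persons with missing sessions contribute
products over their observed occasions only. Estimation is EM (monotone
log-likelihood, relative tolerance 1e-8, ≤500 iterations) with a
baseline-quantile start plus seeded random restarts; groups are reported
in ascending intercept order; hard labels break posterior ties toward the
lower-intercept group. SEs come from the observed information (numerical
Hessian over mixture logits, coefficients and log σ). BIC (n = persons)
ranks a (K, order) grid; any model whose minimum average posterior
membership probability falls below 0.7 is flagged. We report both the
model weights π̂ and the hard-assignment shares, since published
group-percentage tables can be either.

A plain Gaussian residual is used rather than the censored normal of
classic trajectory software: the intercepts of interest (≈9–19 on a 0–24
scale) sit away from the bounds. Censoring is an extension point.

The end-to-end pipeline selects K by BIC over 1–4 by default. At n ≈ 100
a forced K = 3 fit on weakly separated data occasionally spends a tiny
(π ≈ 0.04) component chasing noise with an extreme slope — a genuine
global optimum, not an EM failure — which the selection step exists to
prevent; a fixed K remains available.

## Practice-effect adjudication

The criterion is half the sample SD (n−1) of session-1 totals. Change
over the period is slope × months exactly, SE scaling identically; a
group *exceeds* on strict inequality (a change of 2.16 does not exceed a
criterion of 2.2). An exceeding group whose assigned members include no
pairs outside the Bland–Altman 95% limits of agreement (mean difference
±1.96 SD of last-minus-first equated totals, first vs last session,
persons missing either session excluded from this check only) is judged
"change within measurement error"; otherwise "practice effect". A
proportion-based within-error rule is configurable. An overall paired
one-tailed t-test (improvement direction) complements the group verdicts;
all-zero differences return p = 0.5.

## Synthetic cohorts

Defaults are the study conditions: 102 persons; three groups with
intercepts 9.2/14.9/18.7 score units, per-month slopes 0.36/0.24/0.47 and
membership 36.1/49.2/14.6% (normalized — the printed shares sum to 99.9);
sessions at months 0/3/6 on forms A/B/C; the session-2 fluency list easier
by 0.8 logits and the recall lists ±0.4 logits apart; ~15/102 incomplete
follow-up. Trajectories are generated on the observed 0–24 scale (that is
the scale the trajectory model operates on), clamped to [0, 24]; each
person-occasion target total is mapped to θ by inverting the TCC of the
session's form, and item categories are sampled from the PCM.

The item bank is six tasks with maxima (3, 3, 4, 2, 4, 8) for Corsi
forward/backward span, binned flanker reaction time, mini trail-making,
binned letter fluency and 8-word recall — recall naturally scores 0–8,
the others are ordinal bins covering the rest of the 0–24 range, which is
all a published total-score range constrains. Thresholds are equally
spaced around item locations chosen to spread difficulty; locations are
centred. Per-item category counts and bin edges are free parameters of
the generator config.

The latent residual SD defaults to 1.6 score units: the response layer
adds ≈2 points of measurement noise, so this calibrates the *observed*
baseline total-score SD to ≈4.4, the study's reported dispersion. (The
ability-level trajectory-recovery experiments pass σ = 2 explicitly, as
their design states.) Dropout is monotone and ability-unrelated: each
person is selected with the dropout probability and keeps sessions up to
a cutoff drawn uniformly from the non-final sessions; nobody loses
session 1 and everybody stays in the analysis.

What the generator does *not* emulate: raw reaction-time streams, audio
fluency scoring, rater behaviour (items are generated at the
ordinal-category level), covariate-dependent group membership,
informative dropout, retest correlation beyond the latent trajectory, or
floor/ceiling censoring of the residual. Passing tests therefore show the
estimators recover the structure they assume, under that structure — not
that real batteries satisfy it.

## Problem sizes used in the test suite

Recovery and power suites run at the sizes their designs state: threshold
recovery at n = 1000 persons; DIF power at 100 replicates of n = 500 and
type-I at 200 DIF-free replicates of n = 250 (pooled over items);
trajectory recovery at 200 replicates of n = 102 with σ = 2; BIC
selection at 30 well-separated (gap ≥ 3σ) replicates; Bland–Altman
coverage at n = 1000; the end-to-end null property at 100 pipeline runs
of n = 102. The whole suite completes in a few minutes on one CPU.

## Known limitations

- CML needs every response category observed at least once per (pseudo-)
  item; the collapse-and-retry loop changes an item's maximum score when
  triggered, so raw-total ceilings can differ across forms (equating
  handles this, but collapsed scores are not comparable to uncollapsed
  runs).
- Threshold SEs ignore the uncertainty of the collapse/split decisions.
- The DIF ANOVA treats residuals as exchangeable within cells; with very
  small cells the type-II F can be fragile (empty cells are dropped).
- Mixture SEs condition on the selected K and ignore selection
  uncertainty; posterior-probability adequacy (0.7) is a convention, not
  an inference.
- The Bland–Altman "within measurement error" rule (zero outliers among a
  group's members) is the strictest reading; the proportion-based
  alternative is configurable but not the default.
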