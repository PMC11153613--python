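# Methods

## Task and learning model

The task is a two-alternative probabilistic reward-learning game: four
30-trial blocks per visit, two *emotional* (happy vs angry expression of one
identity; option 1 is always the happy face) and two *neutral* (two neutral
identities), with 60/40 reward contingencies. One option per block is
designated rich; each trial carries independent Bernoulli availability draws
for both options and the chosen option's draw is paid out. Feedback is given
for the chosen option only; the counterfactual outcome is never shown. The
default block order alternates emotional/neutral (configurable — the
original task's order is not material to choice modelling).

Behaviour is modelled by a double-update Q-learner. Both option values are
updated on every non-missing trial: the chosen value moves toward the
outcome r, the unchosen value toward the complementary outcome 1 − r, with
one shared learning rate. This is the canonical double-update rule for
anticorrelated two-option bandits; it implies that if Q₁ + Q₂ = 1 at a block
start it remains exactly 1, and that Q stays inside [0, 1]² for rewards in
{0, 1} (both are property-tested). Q resets to (0.5, 0.5) at every block
boundary because each block is a fresh learning problem. Choice follows a
softmax on Q₁ − Q₂ with inverse temperature β; simulated agents add an
additive `happy_bias` to the softmax argument in emotional blocks, modelling
the prepotent pull toward the positive expression that the task is designed
to elicit. The bias is a simulation-only parameter: the fitted model is the
two-parameter (α, β) learner, matching how such data are conventionally
scored; fitting a bias term is available behind a flag but off by default.

## Fitting and numerical choices

One (α, β) pair is fitted per participant × visit × condition, pooling that
condition's two blocks with a Q reset between them (ideal-choice proportions
are reported at this granularity, so this is the natural unit). The negative
log-likelihood sums −log p over non-missing trials with per-trial
probabilities floored at 1e−12. Optimisation is multi-start L-BFGS-B
(default 10 starts; seeded Latin-hypercube start points; ftol 1e−8) over
α ∈ [1e−3, 1], β ∈ [0, 50].

The lower α bound deserves a note: at α = 0 the values never leave the
initial tie, every choice probability is 0.5 regardless of β, and the
likelihood surface is flat — an unidentified boundary. Because the
ideal-choice rule counts value ties as ideal, an optimiser resting on that
boundary would score *every* trial ideal, turning non-learners into perfect
performers. Excluding the degenerate point (α ≥ 1e−3) keeps the fit
identified and lets the classifier judge weakly-learning or perseverative
choosers by the sign of their (small but informative) value differences.
Fits recover generating parameters well at the study's trial counts: over
100 agents × 240 trials, rank correlations between true and recovered
parameters are ≈ 0.9 for both α and β (recomputed by
`scripts/acceptance.py`).

## Ideal choices and the emotional-bias score

A trial is *ideal* iff the fitted value of the chosen option at decision
time is ≥ the unchosen option's. The tie rule (≥) makes the first trial of
every block ideal under the symmetric initialisation, which is the stated
convention; missing trials are excluded from proportions. The emotional-bias
score is P(choose happy | angry strictly higher-valued) − P(choose angry |
happy strictly higher-valued) within the emotional condition. Value-tie
trials belong to neither conditioning set (only there is no strictly "ideal
face"); the score is flagged undefined when either conditioning set is
empty, and such participants are dropped from the bias ANOVA with a log
entry. Scores are computed per visit; a pooled per-participant mean is also
emitted.

## Statistical battery

*Chance tests.* One-sample t-tests of per-participant ideal-choice
proportions against 0.5, one per group × visit × condition cell (eight in
the two-group design), flagged at the Bonferroni-adjusted α = 0.05/8 =
0.00625. Cells with n < 2 are skipped with a reason; zero-variance cells
return t = 0 (or ±∞ off-centre) rather than NaN.

*Mixed ANOVAs.* A single split-plot engine serves the 2×2×2
(group × visit × condition) behavioural ANOVA, the group × visit bias ANOVA
and the group × visit glutamate ANOVA. Because every within factor has two
levels, each within effect is exactly a per-subject contrast score, and the
classical split-plot F tests are Type III OLS model-comparison tests on
those contrasts (intercept → within main effect; group term → its
interaction with group; subject means → between effect). Two-level factors
need no sphericity correction; Type III keeps the tests defined for the
unbalanced 15/35 groups. Partial η² is SS_effect / (SS_effect + SS_error).
The engine is validated against pingouin's `mixed_anova` (two-way) and an
independent textbook sums-of-squares decomposition (three-way, balanced).
Participants with incomplete within-cells are dropped and counted.

*MRS statistics.* Metabolite estimates pass the quality gate iff
CRLB < 20 % and SNR > 10 and FWHM < 0.1 ppm — strict inequalities, each
exclusion logged with the failing criteria. Glu/tCr ratios are consumed as
given (no partial-volume correction, no absolute quantification). Reference
stability is a paired t-test on tCr across visits. Activity–glutamate
coupling uses Spearman correlations (midranks for ties, t-approximation p),
and the two groups are compared with Fisher's r-to-z using the 1/(n−3)
variance. Applying the Pearson-style transform to rank correlations is an
approximation, used deliberately because it is the convention this statistic
reproduces.

*Prediction.* Five baseline (visit A) features — right-amygdala (decision),
left-pallidum and mPFC (feedback) betas from the emotional condition, ACC
Glu/tCr, and the overall ideal-choice proportion pooled over conditions —
enter a maximum-likelihood logistic regression on resistant-vs-responsive
status at follow-up. Features are z-scored for the headline fit (the
coefficients are then comparable across units); an unscaled fit is emitted
alongside. The report is the apparent (in-sample) classification at
threshold 0.5 with whole-percent headline metrics and exact fractions
retained; Nagelkerke R² = R²_CS / (1 − exp(2 L0 / n)) with
R²_CS = 1 − exp(2 (L0 − L1)/n). Complete or quasi-complete separation is
detected and flagged (coefficients are reported with that caveat; Wald
p-values are undefined and reported as null). No regularisation and no
cross-validation: this mirrors a post-hoc in-sample model, and an optional
k-fold mode exists but is off by default.

## Synthetic cohort: what it emulates, and what it does not

The generator produces 15 resistant / 35 responsive participants whose
clinical records are sampled to satisfy the rule engine that labels them:
resistant participants meet the positive-symptom threshold (≥ 1 item at 5,
or ≥ 2 items at 4) at follow-up with ≥ 2 adequate medication trials,
adherence and SOFA < 60; responsive participants are adherent and below
threshold at both the 6-month and 1-year visits. Re-classification of a
generated cohort therefore round-trips exactly (property-tested), and sex
is assigned 11/15 vs 25/35 male so the demographic χ² is reproducible.

Agent parameters per group × visit cell (with truncated-normal
between-subject spread) were calibrated once so the cohort reproduces the
qualitative behavioural pattern of the design: responsive cells all clear
the adjusted chance threshold, while resistant agents at follow-up combine
a weaker value signal (α ≈ 0.20, β ≈ 1.8) with a strong happy bias (≈ 2.2),
pulling the emotional — and only the emotional — cell toward chance
(cell mean ≈ 0.54–0.62 across seeds, neutral ≈ 0.64 and clearly above
chance). With identical agents in every cell (happy bias 0.32) the
grand-mean emotional-bias score lands at ≈ 0.07. A consequence of driving
the resistant deficit through the bias term is that the default cohort's
resistant group also shows an elevated bias score at follow-up
(grand mean ≈ 0.17); a design in which bias scores stay group-null while
emotional learning collapses group-specifically is not reachable with this
agent family, and the bias-score calibration is therefore defined on the
uniform-parameter configuration.

ROI betas are single peak-voxel parameter estimates per region × phase
(amygdala/decision, pallidum and mPFC/feedback), drawn around cell means
that follow the study pattern (resistant amygdala/pallidum blunted at
baseline and rising, mPFC falling; responsive mPFC rising). Visit-C mPFC
betas are coupled to visit-C Glu/tCr in the responsive group only, with
latent Pearson ρ = −0.48 so the sample Spearman correlation averages ≈
−0.46 (under bivariate normality r_s ≈ (6/π) asin(ρ/2)); the resistant
group is uncoupled. QC fields are drawn so ≈ 95 % of records pass the gate.

What passing tests on this cohort do **not** show: the generator contains
no reaction times, no stimulus or identity effects, no visit-B symptom
dynamics beyond the threshold flag, no dropout, no medication pharmacology,
and its noise is Gaussian and independent across measures except where a
coupling is injected. Group-level effect sizes other than the calibrated
targets (chance-level emotional learning, the −0.46 coupling) are emergent
and not matched to any particular dataset, so prediction-stage metrics on
synthetic cohorts (e.g. Nagelkerke R² ≈ 0.8) characterise the synthetic
separability, not a clinical effect size.

## Problem sizes and determinism

Default simulations use the study-scale design throughout: 50 participants,
2 visits × 4 blocks × 30 trials (6,000 trials per visit). Monte-Carlo
checks in the test suite use 100–200 replicates for calibration and
type-I-error bounds (nominal α plus two Monte-Carlo standard errors) and
100 agents × 240 trials for parameter recovery. All randomness flows
through `numpy.random.SeedSequence`; the pipeline fans a single global seed
into per-stage child seeds, so stages are individually re-runnable and a
fixed config + seed yields byte-identical bundles.

## Known limitations

* The fitted model has no lapse or perseveration parameter; strongly biased
  agents are absorbed into low-β, low-α fits. This matches the
  two-parameter scoring convention but limits mechanistic interpretation of
  fitted parameters for such choosers.
* The Fisher r-to-z comparison treats Spearman coefficients as Pearson
  ones; for rank correlations the 1/(n−3) variance is slightly liberal.
* Type III tests rely on OLS projections per contrast; designs with more
  than two levels per within factor are out of scope for the ANOVA engine.
* The logistic report is in-sample; with 5 predictors and 15 events it will
  overstate out-of-sample performance (the optional k-fold mode quantifies
  this).
* Unclassified participants are excluded from all downstream stages; no
  sensitivity analysis over the classification rules is implemented.
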