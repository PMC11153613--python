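# emolearn

A tested, reusable implementation of the behavioural–computational analysis
pathway of a longitudinal early-psychosis study design: reinforcement-learning
modelling of an emotion-yoked reward task, model-based choice scoring, MRS
glutamate statistics with spectral quality gating, rule-based
treatment-resistance labelling, and multimodal logistic prediction of
treatment resistance. Because raw clinical data of this kind are not openly
shareable, the package ships a synthetic-cohort generator that reproduces the
study's group structure (15 treatment-resistant / 35 treatment-responsive
participants, two scan visits a year apart), so every stage can be exercised,
calibrated and regression-tested end to end.

It is aimed at computational-psychiatry researchers who want either (a) the
analysis battery for their own trial-level choice, ROI and MRS tables, or
(b) a simulation bench for power and calibration studies of this design.

## The model

Participants repeatedly choose between two faces and learn over 30-trial
blocks which face is rewarded more often (60/40 contingencies). Behaviour is
modelled with a **double-update Q-learner**: on every non-missing trial the
chosen option moves toward the received outcome and the unchosen option
toward the complementary outcome, with a shared learning rate α ∈ [0, 1]:

    Q_c(t+1) = Q_c(t) + α (r_t − Q_c(t))
    Q_u(t+1) = Q_u(t) + α ((1 − r_t) − Q_u(t))

Choices follow a softmax on the value difference with inverse temperature β
(simulated agents add a decision bias toward the happy face in emotional
blocks):

    P(choose 1) = 1 / (1 + exp(−β (Q₁ − Q₂) − bias))

(α, β) are fitted per participant × visit × condition by multi-start bounded
maximum likelihood. A trial is an **ideal choice** when the chosen option's
fitted value at decision time is at least the alternative's (first trial of a
block is ideal by convention). The **emotional-bias score** is
P(choose happy | angry is model-ideal) − P(choose angry | happy is
model-ideal). Downstream statistics: one-sample chance tests at the
Bonferroni-adjusted p = 0.00625, a 2×2×2 mixed ANOVA
(group × visit × condition), a group × visit ANOVA on Glu/tCr after QC
gating (CRLB < 20 %, SNR > 10, FWHM < 0.1 ppm), Spearman activity–glutamate
correlations compared across groups by Fisher's r-to-z

    Z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)),

and a five-feature logistic model of follow-up treatment resistance
summarised by Nagelkerke R², sensitivity, specificity and accuracy.

## Worked example

```bash
emolearn run-all --seed 7 --out out/
```

runs cohort generation → task simulation → RL fitting → behavioural,
MRS and prediction statistics, persists every table as CSV and prints:

```
emolearn pipeline report (seed 7)
============================================
cohort: {'responsive': 35, 'resistant': 15}
sex x group chi2(1) = 0.019, p = 0.891

ideal-choice proportions (group x visit x condition):
  resistant  visit A emotional n=15  M=0.799 SD=0.062
  resistant  visit A neutral   n=15  M=0.796 SD=0.089
  resistant  visit C emotional n=15  M=0.544 SD=0.221
  resistant  visit C neutral   n=15  M=0.636 SD=0.086
  responsive visit A emotional n=35  M=0.864 SD=0.060
  responsive visit A neutral   n=35  M=0.846 SD=0.062
  responsive visit C emotional n=35  M=0.878 SD=0.049
  responsive visit C neutral   n=35  M=0.859 SD=0.061

emotional bias: M = 0.170 (SE 0.029)

mPFC-glutamate coupling at visit C:
  responsive: r_s(34) = -0.422, p = 0.0130
  resistant: r_s(15) = -0.493, p = 0.0620
  Fisher Z = 0.264, p = 0.7915

prediction: Nagelkerke R2 = 0.845; sensitivity 93%, specificity 97%, accuracy 96%
```

Reading the output: the synthetic resistant group learns the emotional
blocks at follow-up only at chance level (M = 0.544, the one cell that fails
the adjusted chance test) while every responsive cell is well above 0.5;
the mean emotional bias is positive (pull toward the happy face); the
responsive group shows the negative activity–glutamate correlation; and the
baseline features separate the outcome groups well in-sample. Per-group
correlations and the Fisher Z fluctuate seed to seed at n = 15/35 — here the
resistant subsample happens to show a negative correlation too, so the
between-group comparison is not significant at this particular seed.

Stage-wise subcommands (`simulate`, `fit-rl`, `behavior-stats`, `mrs`,
`predict`, `report`) run the same machinery on your own CSV tables; schemas
are documented in the module docstrings.

## Layout

| module | contents |
| --- | --- |
| `emolearn.cohort` | participant records, TRRIP-style resistant/responsive rules, synthetic cohorts |
| `emolearn.task` | reward schedules, softmax agents, cohort-level trial simulation |
| `emolearn.rl` | double-update model, likelihood, MLE fitting, ideal-choice classification |
| `emolearn.behavior` | chance tests, 2×2×2 mixed ANOVA, emotional-bias scoring and ANOVA |
| `emolearn.anova` | shared split-plot (mixed) ANOVA engine |
| `emolearn.mrs` | QC gating, glutamate statistics, Fisher r-to-z, MRS/ROI generator |
| `emolearn.predict` | feature assembly, logistic fit, Nagelkerke R², classification report |
| `emolearn.pipeline` / `emolearn.cli` | orchestration, persisted bundles, consolidated report, CLI |

See `docs/methods.md` for the modelling assumptions, calibration choices and
known limitations.
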