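# careseq

Sequence-analysis typologies of early-years childcare and the marginal
structural models that quantify how childcare mediates socioeconomic
inequalities in child mental health.

## The problem

Children of mothers with lower educational qualifications are far more
likely to show raised Strengths and Difficulties Questionnaire (SDQ) Total
Difficulties scores at school entry.  Childcare before the universal
entitlement at age three is a lever policy can pull — but different
childcare types are used very unequally across social groups, and may
themselves affect mental health.  `careseq` operationalises the full
analysis chain for this question, for epidemiologists and quantitative
social scientists working with longitudinal birth-cohort data:

1. **Sequence typologies (mediator construction).**  Each child's dominant
   childcare provider at four sweeps (10 months to 4 years) forms a sequence
   over a 7-state alphabet.  Optimal-matching edit distances
   (substitution/indel costs, dynamic programming) feed survey-weighted Ward
   clustering (weighted Lance–Williams update, nearest-neighbour chain) into
   k typologies, validated by weighted silhouettes and Jaccard bootstrap
   stability, and named by their pre-entitlement modal state: *Parents,
   friends & family*, *Grandparents*, *Private group childcare*, *Single
   professional care*.
2. **Inequality models.**  A survey-weighted multinomial logit quantifies
   education gradients in typology membership (odds ratios vs
   parent/family/friend care), and a modified-Poisson (log-link,
   robust-variance) model estimates typology→outcome risk ratios, all with
   Horvitz–Thompson-type sandwich standard errors.
3. **Causal mediation by MSM.**  With stabilized inverse-probability
   weights — P(A)/P(A|L) for the 4-level education exposure A given baseline
   confounders L, times P(M|A)/P(M|A,L,Z) for the mediator given
   intermediate confounders Z — weighted logistic marginal structural models
   estimate the **average treatment effect** (ATE) of maternal education on
   raised difficulties, and **controlled direct effects** (CDE)
   `exp(beta_a + delta_am)` under hypothetical scenarios in which every
   child receives one childcare type m (private group, or single
   professional), from a model with exposure x mediator interaction.
4. **Synthetic cohort.**  The study data are confidential, so the package
   ships a seeded generator whose default calibration plants published
   estimates as ground truth — education distribution, typology prevalences
   (35.8/32.7/23.5/8.1 %), membership gradients (e.g. single-professional OR
   0.089 for the lowest education group), 10.9 % outcome prevalence, ATE OR
   3.18 and CDE ORs 3.78 / 2.42 for lowest-vs-highest education — making the
   whole pipeline testable by parameter recovery.  See `docs/methods.md`.

## Worked example

```python
import numpy as np, pandas as pd
from careseq import default_calibration, generate_cohort, apply_attrition
from careseq.sequences import build_sequences, CostScheme
from careseq.clustering import cluster_sequences, label_typologies
from careseq.msm import (fit_exposure_propensity, fit_mediator_propensity,
                         compose_weights, estimate_ate, estimate_cde, ScenarioSpec)

params = default_calibration()                       # n = 3205 children
cohort = apply_attrition(generate_cohort(params, seed=1), params)

seqs = build_sequences(cohort)                       # 7-state, 4-sweep sequences
assignment = cluster_sequences(seqs, CostScheme.constant(), k=4)
label_typologies(assignment, seqs)
labels = assignment.named_labels()
prev = pd.Series(seqs.weights).groupby(labels).sum() / seqs.weights.sum() * 100
print(prev.round(1))

efit = fit_exposure_propensity(cohort)
w_ate = compose_weights(cohort["design_weight"].to_numpy(), efit)
print(estimate_ate(cohort, w_ate).effects[["term", "estimate", "ci_low", "ci_high"]])
```

prints (seed 1):

```
Grandparents                 34.0
Parents, friends & family    35.1
Private group childcare      22.4
Single professional care      8.5

                           term  estimate  ci_low  ci_high
             education[Highers]     1.620   0.976    2.691
education[LowerStdGradesOrNone]     3.554   2.097    6.021
      education[UpperStdGrades]     3.438   2.125    5.561
```

The weighted typology shares recover the planted 35.8/32.7/23.5/8.1 %
mixture, and children in the lowest education group have 3.55 (95 % CI
2.10–6.02) times the odds of raised difficulties — one draw around the
planted ATE of 3.18.  Adding the mediator weight and an interaction model
gives the hypothetical-scenario CDEs:

```python
mfit = fit_mediator_propensity(cohort, labels)
w_cde = compose_weights(cohort["design_weight"].to_numpy(), efit, mfit)
cde = estimate_cde(cohort, labels, w_cde,
                   ScenarioSpec(estimand="CDE", fixed_mediator="Private group childcare"))
```

which for this seed estimates a lowest-education CDE OR of 6.09 (1.41–26.3):
single replicates are noisy exactly where the published intervals are wide,
and the recovery study below averages 200 of them.

A CLI covers the same stages (`careseq simulate | sequences | cluster |
models | msm | all`), driven by a YAML config, writing CSV tables with JSON
twins and sequence state-distribution plots.

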