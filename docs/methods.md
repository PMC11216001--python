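# Methods

`careseq` implements a complete analysis of how early-years childcare
patterns mediate socioeconomic inequalities in child mental health, together
with a calibrated synthetic-cohort generator that makes every stage testable
without access to confidential survey data.

## The scientific setting

The exposure **A** is highest maternal education in four ordered levels
(Degree / Highers / Upper Standard Grades / Lower Standard Grades or none;
reference Degree).  The outcome **Y** is a binary indicator of a raised
Strengths and Difficulties Questionnaire Total Difficulties score at the
start of primary school (roughly age five).  The mediator **M** is a
four-group typology of longitudinal childcare use from 10 months to four
years, built by sequence analysis of the dominant childcare provider at four
survey sweeps over a seven-state alphabet (private group, local-authority
group, single professional, family/friends, grandparent, other, none).
Baseline confounders **L** are child ethnicity and mother's age at first
birth; intermediate confounders **Z** are maternal attachment, maternal
mental health, maternal employment, family composition, significant life
events and child general health; child sex and school adjustment are
outcome-only covariates.

## Synthetic cohort generator

The generator simulates one row per child in this causal order: L, then
A | L (multinomial logit with age-band and ethnicity effects), then Z | A,
then M | A from a 4x4 mixing matrix P(typology | education), then the
four-sweep childcare sequence, then Y.  Under the default calibration the
typology depends on measured confounders only through education; an optional
`typology_confounder_coefs` block introduces genuine mediator-outcome
confounding for stress-testing the weighting machinery.

**Sequences.** Each typology has a canonical path (e.g. grandparent care at
sweeps 1-3 then a local-authority place at sweep 4; private-group children
stay with private providers, who can also deliver the universal
entitlement).  Each sweep's state independently deviates from the canonical
path with probability `emission_noise` (default 0.1), replaced by a uniform
draw over the six other states.  This represents within-typology
heterogeneity with a single interpretable parameter; real sequences have
serially correlated deviations and richer minority patterns, so passing
recovery tests show that the pipeline separates typologies at this noise
level, not that it would resolve arbitrarily subtle real-world structure.

**Outcome.** A continuous latent difficulties score is the linear predictor
plus standard logistic noise; the binary outcome thresholds it at a config
constant (default 0, absorbed into the intercept), since published analyses
use validated instrument cut-points without printing them.

**Weights and attrition.** Design weights are mean-one lognormal
(sigma = 0.25) independent of all covariates, standing in for survey
design/response weights whose construction is not public.  The retention
model is logistic in any covariates; the default retains everyone because
the default cohort size (n = 3205) already represents the analytic
complete-case sample whose composition matches the baseline sample almost
exactly.  A 61% covariate-dependent retention configuration is exercised in
tests; `apply_attrition` divides weights by the model retention probability
(inverse-probability-of-response) and renormalises to mean one, so weighted
marginals of the retained subsample track the full cohort.

**Calibration.** All free constants are solved once by
`scripts/calibrate.py` and shipped in `data/default_calibration.yaml` with a
provenance block; nothing is hard-coded.  The solver works on the exact
discrete covariate lattice, integrating the three continuous confounders by
3-point Gauss-Hermite quadrature, and proceeds in three stages:

1. education-model intercepts root-solved so marginal P(A) matches the
   analytic-sample distribution (26.6 / 31.9 / 26.0 / 15.4 %);
2. mixing-matrix intercepts root-solved so that, with the published
   education gradients fixed as multinomial log-odds (e.g. single
   professional care OR 0.089 for the lowest education level), the marginal
   typology prevalences are 35.8 / 32.7 / 23.5 / 8.1 %;
3. outcome coefficients (intercept; three education effects; three typology
   effects; education x typology interactions for the private-group and
   single-professional columns) solved so the implied marginal outcome
   prevalence is 10.9 %, the marginal ATE odds ratios are
   1.352 / 2.596 / 3.181, the controlled-direct-effect odds ratios are
   2.164 / 3.600 / 3.778 (private group) and 0.713 / 1.782 / 2.420 (single
   professional), and the fully adjusted quasi-Poisson risk ratios are
   1.052 / 0.832 / 0.770.  The risk-ratio constraint requires the
   population-level misspecified log-link fit, recomputed inside an outer
   fixed-point loop around the 10-dimensional root solve.  Education x
   grandparent-care interactions are set to zero (no published value
   constrains them).

Potential outcomes simulated from the finished generator (forcing A, or A
and M, for a million children) reproduce all planted contrasts to three
decimals.  Confounder effect sizes (e.g. +0.90 log-odds for poor school
adjustment, -0.04 per attachment point) and the Z | A distributions are
fixed plausible values chosen once; they shape the confounding structure the
weighting must remove but are not themselves targets.

Random numbers come from per-variable-block streams spawned from one master
seed, so adding a variable block never perturbs earlier draws, and cohorts
are byte-reproducible given (params, seed).

## Sequence analysis and typologies

**Optimal matching.** The dissimilarity between two state sequences is the
minimum total cost of substitutions and indels transforming one into the
other, computed by dynamic programming (vectorised across all unique
sequence pairs).  The default cost scheme is constant substitution 2 and
indel 1 — the conventional default of the standard sequence-analysis
toolchain, since the original analysis does not state its costs; a
transition-rate-based substitution matrix (2 - p(i->j) - p(j->i)) is
available behind a config switch.  Indels stay enabled for equal-length
sequences because a shifted alignment can undercut position-wise
substitution.

**Weighted Ward clustering.** Observations carry survey weights, so the
package implements Ward's criterion with case masses: singleton merge cost
2 w_i w_j / (w_i + w_j) * d_ij^2, updated by the weighted Lance-Williams
recurrence, agglomerated by the nearest-neighbour-chain algorithm (O(n^2);
valid because Ward's criterion is reducible).  With unit weights the
partition is identical to classical Ward linkage, and with integer weights
identical to Ward on a replicated sample — both verified against scipy in
the tests, including merge heights.  Merge ties break on the smallest pair
of representative indices; NN-chain merges are re-sorted by height into a
standard linkage array before cutting.  Identical sequences are aggregated
(weights summed) before clustering, which is exactly equivalent and makes
the cost linear in the number of distinct sequences (a few hundred here
rather than 3205).

**Quality and stability.** Cluster quality reports the weighted average
silhouette width (defined as 0 for degenerate points with no distance
spread) and a weighted within/total pseudo-sum-of-squares R^2, per k along
one merge tree.  Stability follows a Jaccard bootstrap: children are
resampled with probability proportional to weight, the resample is
re-clustered, and each reference cluster scores its best Jaccard overlap
with any bootstrap cluster, averaged over resamples; clusters emptied in a
resample score 0 and are logged.  The exact method behind the original
cluster validation is not published, so this standard scheme is named
explicitly rather than attributed.

**Naming.** With k = 4, clusters are named by their weighted modal state
over sweeps 1-3 (most variation in childcare occurs before the universal
entitlement at age three): none/family-friends -> "Parents, friends &
family", grandparent -> "Grandparents", private group -> "Private group
childcare", single professional -> "Single professional care".  Collisions
resolve deterministically by weighted cluster size, larger first, with a
logged numeric suffix; other k get generic names.

## Inequality models

The multinomial model of typology membership on education (reference
typology "Parents, friends & family", reference education Degree, adjusted
for ethnicity) is fitted by weighted maximum likelihood as a
baseline-category logit, written in-package because no installed library
fits a multinomial with observation weights; its equal-weight binary
reduction matches the standard logistic MLE to 1e-6 in tests.  The
typology-outcome association uses the modified-Poisson estimator: a
log-link Poisson-family fit to the binary outcome, giving risk ratios, with
the sandwich variance correcting the misspecified Poisson variance.

Variances throughout are Horvitz-Thompson-type weighted sandwiches —
weights enter both bread and meat, HC0 without finite-sample correction —
and p-values and CIs are Wald-type on the log scale.  Only analysis weights
are honoured: survey strata and cluster identifiers are not modelled (they
are not public for the motivating study), so standard errors should be read
as conditional on that simplification.

Adjustment presets: "partial" covers sex, ethnicity, education, mother's
age, school adjustment, attachment, family composition, baseline maternal
mental health, general health and employment; "full" adds age-five maternal
mental health and significant life events.  The generator's composite
variables represent each longitudinal construct as a single column, so the
partial/full distinction is carried by the baseline-only versus
time-varying maternal mental health and life-events columns.

## Marginal structural models

Exposure propensities come from a weighted multinomial model of education on
baseline confounders; the stabilisation numerator is the weighted marginal
education distribution.  Mediator propensities model the typology on
education plus baseline and intermediate confounders, with a numerator
conditioning on education alone.  Composed weights multiply the design
weight by the stabilized exposure ratio and (for CDEs) the stabilized
mediator ratio; stabilized components have mean ~1 and are checked in
[0.97, 1.03] on default cohorts.  Truncation is off by default (matching the
visibly wide published intervals); percentile winsorisation, e.g. (1, 99),
is a config option and logs how many weights it clips.  Probabilities below
1e-6 raise rather than silently clip.

The ATE is the weighted logistic fit of the outcome on education alone; the
CDE fit adds typology and education x typology terms, and the controlled
direct effect for level a under the scenario fixing M = m is
exp(beta_a + delta_am), with variance from the corresponding sandwich
block.  Because that model is saturated in (education, typology), a
scenario contrast depends only on its own mediator column; cells outside it
may lack outcome events (their coefficients diverge harmlessly) and only
zero-variation cells inside the scenario column raise a separation error.
On default cohorts about one replicate in eight is inestimable for the
single-professional scenario — the same sparsity that produces the very
wide published interval for that scenario (0.20-28.76).  CIs treat weights
as known (sandwich); `bootstrap_msm_ci` re-estimates weights per resample
when propagation of weight-estimation uncertainty is wanted.

Balance diagnostics report, per covariate, the maximum pairwise absolute
weighted standardized mean difference across exposure (or mediator) groups,
with zero-variance covariates flagged at SMD 0.

## Replicate summaries

Across seeded replicates, odds- and risk-ratio estimates are summarised by
their **geometric mean** — the average on the log scale, where these
estimators are (asymptotically and, by simulation, at n = 3205) unbiased.
The arithmetic mean of a ratio estimate with a heavy right tail is inflated
by Jensen's inequality; at the planted private-group CDE of 3.78 the
log-scale spread at n = 3205 is about 0.6, making the arithmetic mean ~4.7
while the geometric mean and median sit at the planted value.  The
single-professional CDE is summarised by its median for the same reason, in
its more extreme form.

## Problem sizes and numerical choices

The recovery study uses 200 replicates at n = 3205 (the analytic sample
size) and completes in under a minute on one CPU; calibration checks use a
single cohort of 100,000 children; the exhaustive optimal-matching oracle
enumerates all alignment paths for every length-4 pair over a 3-state
alphabet.  IRLS tolerance is 1e-10 on the max coefficient step; the
multinomial optimiser standardises covariates internally and maps
coefficients back.  Silhouette of degenerate points is 0 by convention.
Dendrogram heights are Ward criterion values (twice the within-cluster
sum-of-squares increase for Euclidean input), not their square roots.

## Known limitations

* The generator's confounders are mutually independent given education
  unless a dependence structure is configured; real covariates co-vary.
* Emission noise is independent across sweeps; real childcare changes are
  serially correlated.
* No survey strata/PSU machinery; weights only.
* No natural direct/indirect effect decomposition, g-computation or doubly
  robust estimators — controlled direct effects only, as in the analysis
  this package operationalises.
* The sequence stage handles single-channel sequences (one dominant
  provider per sweep); concurrent provision is out of scope.
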