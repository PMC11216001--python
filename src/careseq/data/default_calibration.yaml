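n_children: 3205
education_probs:
- 0.2662662662662663
- 0.31931931931931934
- 0.2602602602602603
- 0.15415415415415418
education_model:
  intercepts:
  - 0.38467014026279284
  - 0.18783536994025715
  - -0.5343052223271506
  age_coefs:
    Under20:
    - 1.0
    - 1.8
    - 2.6
    20to29:
    - 0.0
    - 0.0
    - 0.0
    30plus:
    - -0.6
    - -1.1
    - -1.5
  ethnicity_coefs:
    White:
    - 0.0
    - 0.0
    - 0.0
    Other:
    - -0.2
    - -0.3
    - -0.4
typology_mixing:
- - 0.21823027517649093
  - 0.2838296175054559
  - 0.37157408351985316
  - 0.12636602379819994
- - 0.31023294037246174
  - 0.36878803004449867
  - 0.24139847610202728
  - 0.07958055348101233
- - 0.42978542730321145
  - 0.3493609942016378
  - 0.1544061364248784
  - 0.06644744207027235
- - 0.5748502792864826
  - 0.27513464294533274
  - 0.12038996082580218
  - 0.02962511694238252
typology_confounder_coefs: null
emission_noise: 0.1
outcome_coefs:
  intercept: -3.2504098263771635
  education:
  - 0.014431406574376724
  - 0.5881711124071275
  - 0.5472823308114956
  typology:
  - 0.05959838956167034
  - -0.6312260330763632
  - -0.1269344418346437
  interaction:
  - - 0.0
    - 0.6712587458780501
    - -0.4678934071874696
  - - 0.0
    - 0.5089003182503816
    - -0.21577016150004133
  - - 0.0
    - 0.3393638389052635
    - -0.11482923931381617
  confounders:
    sex_Male: 0.3
    school_adjustment_Low: 0.9
    ethnicity_Other: 0.1
    age_Under20: 0.25
    age_30plus: -0.1
    attachment_per_unit: -0.04
    attachment_center: 39.5
    mmh1_per_unit: -0.01
    mmh1_center: 50.0
    mmh5_per_unit: -0.03
    mmh5_center: 50.0
    employment:
      AlwaysFT: 0.0
      AlwaysPT: 0.0
      MixedFTPT: 0.05
      WorkAndNot: 0.15
      NeverWorked: 0.3
    family_composition:
      AlwaysCouple: 0.0
      AlwaysLone: 0.35
      Mixture: 0.25
    life_events_Yes: 0.3
    general_health_Poor: 0.45
confounder_params:
  maternal_age_probs:
    Under20: 0.172
    20to29: 0.51
    30plus: 0.318
  ethnicity_probs:
    White: 0.957
    Other: 0.043
  sex_probs:
    Male: 0.514
    Female: 0.486
  school_adjustment_probs:
    High: 0.8
    Low: 0.2
  employment_probs_by_education:
  - - 0.22
    - 0.33
    - 0.15
    - 0.22
    - 0.08
  - - 0.17
    - 0.34
    - 0.13
    - 0.25
    - 0.11
  - - 0.12
    - 0.33
    - 0.11
    - 0.27
    - 0.17
  - - 0.05
    - 0.18
    - 0.07
    - 0.3
    - 0.4
  family_composition_probs_by_education:
  - - 0.9
    - 0.03
    - 0.07
  - - 0.84
    - 0.06
    - 0.1
  - - 0.76
    - 0.1
    - 0.14
  - - 0.58
    - 0.22
    - 0.2
  life_events_prob_by_education:
  - 0.3
  - 0.34
  - 0.38
  - 0.45
  general_health_poor_prob_by_education:
  - 0.16
  - 0.2
  - 0.24
  - 0.32
  attachment:
    mean_by_education:
    - 39.9
    - 39.6
    - 39.3
    - 38.7
    sd: 4.0
    min: 8.0
    max: 48.0
  mmh1:
    mean_by_education:
    - 50.6
    - 50.1
    - 49.6
    - 48.6
    sd: 9.0
    min: 0.0
    max: 100.0
  mmh5:
    mean_by_education:
    - 50.3
    - 49.5
    - 48.7
    - 47.5
    sd: 9.5
    min: 0.0
    max: 100.0
attrition_coefs:
  intercept: 30.0
  coefs: {}
design_weight_sigma: 0.25
outcome_threshold: 0.0
seed: 0
provenance:
  solver: scripts/calibrate.py
  targets:
    education_probs:
    - 0.266266
    - 0.319319
    - 0.26026
    - 0.154154
    typology_prevalence:
    - 0.357642
    - 0.326673
    - 0.234765
    - 0.080919
    typology_membership_or:
    - - 0.914
      - 0.457
      - 0.443
    - - 0.625
      - 0.211
      - 0.267
    - - 0.368
      - 0.123
      - 0.089
    outcome_prevalence: 0.109
    ate_or:
    - 1.352
    - 2.596
    - 3.181
    cde_private_group_or:
    - 2.164
    - 3.6
    - 3.778
    cde_single_professional_or:
    - 0.713
    - 1.782
    - 2.42
    fully_adjusted_rr:
    - 1.052
    - 0.832
    - 0.77
  diagnostics:
    implied_prevalence: 0.10899999999999999
    implied_ate_or:
    - 1.352
    - 2.596
    - 3.181
    implied_cde_pg_or:
    - 2.164
    - 3.6
    - 3.778
    implied_cde_sp_or:
    - 0.713
    - 1.782
    - 2.42
    implied_fully_adjusted_rr:
    - 1.052001
    - 0.83201
    - 0.770009
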