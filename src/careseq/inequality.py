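"""Survey-weighted inequality models.

Two estimators quantify socioeconomic patterning of childcare and its
association with child mental health:

* a weighted multinomial (baseline-category) logit of typology membership on
  maternal education, adjusted for ethnicity, with model-robust
  (Horvitz-Thompson-type sandwich) standard errors — odds ratios of using
  each childcare typology rather than parent/family/friend care;
* a weighted modified-Poisson (log-link, robust-variance) regression of the
  binary raised-Total-Difficulties outcome on typology, optionally adjusted
  for the partially or fully adjusted confounder sets — risk ratios of a
  raised score relative to parent/family/friend care.

Only analysis weights are honoured: the survey's strata and cluster
identifiers are not modelled (they are not available for the motivating
study), which the methods note documents as a limitation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .alphabet import TYPOLOGY_NAMES
from .regression import design_matrix, fit_weighted_glm, fit_weighted_multinomial_logit

REFERENCE_TYPOLOGY = TYPOLOGY_NAMES["PFF"]
REFERENCE_EDUCATION = "Degree"

#: Covariate presets.  "partial" adjusts for the time-fixed confounder set
#: (baseline mental health, general health, employment alongside the core
#: covariates); "full" adds the time-varying measures (sweep-5 maternal
#: mental health, significant life events).
ADJUSTMENT_SETS: dict[str, dict] = {
    "unadjusted": {"categorical": {}, "continuous": []},
    "partial": {
        "categorical": {
            "sex": "Female",
            "ethnicity": "White",
            "education": REFERENCE_EDUCATION,
            "maternal_age_band": "20to29",
            "school_adjustment": "High",
            "family_composition": "AlwaysCouple",
            "general_health": "Good",
            "employment": "AlwaysFT",
        },
        "continuous": ["attachment_score", "maternal_mental_health_sw1"],
    },
    "full": {
        "categorical": {
            "sex": "Female",
            "ethnicity": "White",
            "education": REFERENCE_EDUCATION,
            "maternal_age_band": "20to29",
            "school_adjustment": "High",
            "family_composition": "AlwaysCouple",
            "general_health": "Good",
            "employment": "AlwaysFT",
            "life_events": "No",
        },
        "continuous": [
            "attachment_score",
            "maternal_mental_health_sw1",
            "maternal_mental_health_sw5",
        ],
    },
}


@dataclass
class ModelSpec:
    """Declarative description of a weighted regression model."""

    outcome: str
    predictors: dict[str, str] = field(default_factory=dict)  # column -> reference
    weight_column: str = "design_weight"
    adjustment_set: str = "unadjusted"

    def __post_init__(self) -> None:
        if self.adjustment_set not in ADJUSTMENT_SETS:
            raise ValueError(
                f"adjustment_set must be one of {sorted(ADJUSTMENT_SETS)}, "
                f"got {self.adjustment_set!r}"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "outcome": self.outcome,
                    "predictors": self.predictors,
                    "weight_column": self.weight_column,
                    "adjustment_set": self.adjustment_set,
                },
                fh, sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _attach_typology(cohort: pd.DataFrame, labels) -> pd.DataFrame:
    df = cohort.copy()
    df["typology"] = np.asarray(labels)
    return df


def _check_cells(df: pd.DataFrame, row: str, col: str) -> None:
    tab = pd.crosstab(df[row], df[col])
    if (tab == 0).any().any():
        zero = [(r, c) for r in tab.index for c in tab.columns if tab.loc[r, c] == 0]
        raise ValueError(f"empty {row} x {col} cell(s): {zero}; estimates would be separated")


def fit_weighted_multinomial(
    cohort: pd.DataFrame,
    labels,
    weight_column: str = "design_weight",
    adjust_for_ethnicity: bool = True,
) -> pd.DataFrame:
    """Typology-membership odds ratios by maternal education.

    Weighted multinomial logit of the (named) typology on education dummies
    (reference: Degree), adjusted for ethnicity, with sandwich standard
    errors; the reference typology is "Parents, friends & family".
    Returns one row per (typology, term) with OR, 95% CI and p-value.
    """
    df = _attach_typology(cohort, labels)
    _check_cells(df, "typology", "education")
    cats = [REFERENCE_TYPOLOGY] + sorted(
        c for c in df["typology"].unique() if c != REFERENCE_TYPOLOGY
    )
    if REFERENCE_TYPOLOGY not in set(df["typology"]):
        raise ValueError(f"reference typology {REFERENCE_TYPOLOGY!r} not present")
    y = df["typology"].map({c: i for i, c in enumerate(cats)}).to_numpy()
    categorical = {"education": REFERENCE_EDUCATION}
    if adjust_for_ethnicity:
        categorical["ethnicity"] = "White"
    X, names = design_matrix(df, categorical=categorical)
    fit = fit_weighted_multinomial_logit(
        X, y, df[weight_column].to_numpy(), categories=cats, names=names
    )
    tab = fit.table().rename(columns={"category": "typology"})
    return tab


def fit_modified_poisson_rr(
    cohort: pd.DataFrame,
    labels,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Risk ratios of the raised-TD outcome by childcare typology.

    Log-link Poisson-family fit to the binary outcome (the "modified
    Poisson" / quasi-Poisson risk-ratio estimator) with analysis weights and
    sandwich standard errors.  ``spec.adjustment_set`` selects the
    unadjusted, partially adjusted or fully adjusted covariate list.
    """
    spec = spec or ModelSpec(outcome="outcome_raised_td", adjustment_set="full")
    df = _attach_typology(cohort, labels)
    _check_cells(df, "typology", "education")
    adj = ADJUSTMENT_SETS[spec.adjustment_set]
    categorical = {"typology": REFERENCE_TYPOLOGY, **adj["categorical"]}
    X, names = design_matrix(df, categorical=categorical, continuous=adj["continuous"])
    fit = fit_weighted_glm(
        X,
        df[spec.outcome].to_numpy(dtype=float),
        df[spec.weight_column].to_numpy(),
        family="poisson",
        names=names,
    )
    tab = fit.table()
    tab.insert(0, "adjustment", spec.adjustment_set)
    return tab


def typology_or_report(table: pd.DataFrame) -> pd.DataFrame:
    """Education-gradient rows of the multinomial table (typology-membership report)."""
    return table[table["term"].str.startswith("education[")].reset_index(drop=True)


def typology_rr_report(table: pd.DataFrame) -> pd.DataFrame:
    """Typology rows of the risk-ratio table (typology risk-ratio report)."""
    return table[table["term"].str.startswith("typology[")].reset_index(drop=True)
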