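"""Marginal structural models with inverse-probability-of-treatment weights.

The exposure is 4-level maternal education (reference: Degree); the mediator
is the 4-level childcare typology (reference: "Parents, friends & family");
the outcome is the binary raised-Total-Difficulties indicator.

* The average treatment effect (ATE) reweights by stabilized exposure
  weights P(A=a) / P(A=a | L) composed with design weights and fits a
  weighted logistic model of the outcome on education alone: the marginal
  education-mental-health odds ratios with baseline confounding removed.
* Controlled direct effects (CDEs) add a stabilized mediator weight
  P(M=m | A) / P(M=m | A, L, Z) and fit a weighted logistic model with an
  education x typology interaction; the CDE odds ratio for education level a
  with the mediator fixed at m is exp(beta_a + delta_am) — the inequality
  that would remain were everyone to receive childcare type m.

Sandwich variances treat the weights as known; a nonparametric bootstrap
option re-estimates the weights in each resample.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inequality import REFERENCE_EDUCATION, REFERENCE_TYPOLOGY
from .alphabet import EDUCATION_LEVELS
from .regression import design_matrix, effect_table, fit_weighted_glm, fit_weighted_multinomial_logit

logger = logging.getLogger(__name__)

BASELINE_CONFOUNDERS = {"ethnicity": "White", "maternal_age_band": "20to29"}
INTERMEDIATE_CATEGORICAL = {
    "employment": "AlwaysFT",
    "family_composition": "AlwaysCouple",
    "life_events": "No",
    "general_health": "Good",
}
INTERMEDIATE_CONTINUOUS = ["attachment_score", "maternal_mental_health_sw1"]

PROBABILITY_FLOOR = 1e-6


@dataclass
class PropensityFit:
    """Per-child probabilities of the observed exposure or mediator category."""

    target: str                      # "exposure" or "mediator"
    conditioning_set: list[str]
    fitted_probs: np.ndarray         # P(observed category | conditioning set)
    marginal_probs: np.ndarray       # numerator-model probability of same
    prob_matrix: np.ndarray          # (n, K) full conditional distribution
    categories: list[str]

    def __post_init__(self) -> None:
        for name, p in (("fitted", self.fitted_probs), ("marginal", self.marginal_probs)):
            if np.any(p < PROBABILITY_FLOOR) or np.any(p >= 1.0):
                bad = int(np.sum((p < PROBABILITY_FLOOR) | (p >= 1.0)))
                raise ValueError(
                    f"{bad} {name} probabilities outside [{PROBABILITY_FLOOR}, 1); "
                    "consider truncation or a sparser conditioning set"
                )
        rowsum = self.prob_matrix.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-8):
            raise ValueError("per-child category probabilities must sum to 1")


@dataclass
class WeightVector:
    """Composed analysis weights with provenance and diagnostics."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)   # flags: design/exposure/mediator
    truncation: tuple[float, float] | None = None
    n_truncated: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("weights must be strictly positive and finite")
        self.values = v

    def diagnostics(self) -> dict[str, float]:
        v = self.values
        return {
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
            "effective_sample_size": float(v.sum() ** 2 / (v**2).sum()),
            "n_truncated": int(self.n_truncated),
        }


@dataclass
class ScenarioSpec:
    """Hypothetical universal-childcare scenario."""

    estimand: str                      # "ATE" or "CDE"
    fixed_mediator: str | None = None  # typology name, required iff CDE

    def __post_init__(self) -> None:
        if self.estimand not in ("ATE", "CDE"):
            raise ValueError("estimand must be 'ATE' or 'CDE'")
        if self.estimand == "CDE" and not self.fixed_mediator:
            raise ValueError("CDE scenarios must fix the mediator")
        if self.estimand == "ATE" and self.fixed_mediator:
            raise ValueError("ATE scenarios must not fix the mediator")


@dataclass
class MSMResult:
    """Effect estimates plus weight and balance diagnostics."""

    effects: pd.DataFrame              # term, estimate (OR), se_log, ci, p
    estimand: str
    scenario: ScenarioSpec
    weight_diagnostics: dict
    balance: pd.DataFrame | None = None
    model_params: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# propensity models
# ---------------------------------------------------------------------------

def _multinomial_propensity(df, target_col, categories, categorical, continuous,
                            weights, conditioning_set, target_name,
                            numerator_categorical=None) -> PropensityFit:
    y = df[target_col].map({c: i for i, c in enumerate(categories)})
    if y.isna().any():
        bad = df[target_col][y.isna()].iloc[0]
        raise ValueError(f"unknown {target_name} category {bad!r}")
    y = y.to_numpy(dtype=int)
    X, _ = design_matrix(df, categorical=categorical, continuous=continuous)
    fit = fit_weighted_multinomial_logit(X, y, weights, categories=categories)
    denom_matrix = fit.predict_proba(X)

    if numerator_categorical:
        Xn, _ = design_matrix(df, categorical=numerator_categorical)
        nfit = fit_weighted_multinomial_logit(Xn, y, weights, categories=categories)
        num_matrix = nfit.predict_proba(Xn)
    else:
        counts = np.array([np.sum(weights * (y == k)) for k in range(len(categories))])
        num_matrix = np.tile(counts / counts.sum(), (len(df), 1))

    idx = np.arange(len(df))
    return PropensityFit(
        target=target_name,
        conditioning_set=conditioning_set,
        fitted_probs=denom_matrix[idx, y],
        marginal_probs=num_matrix[idx, y],
        prob_matrix=denom_matrix,
        categories=list(categories),
    )


def fit_exposure_propensity(
    cohort: pd.DataFrame,
    baseline_confounders: dict[str, str] | None = None,
    weight_column: str = "design_weight",
) -> PropensityFit:
    """Multinomial model of education on baseline confounders.

    The numerator (stabilization) model is intercept-only, i.e. the weighted
    marginal education distribution.
    """
    categorical = dict(BASELINE_CONFOUNDERS if baseline_confounders is None else baseline_confounders)
    cats = [lv for lv in EDUCATION_LEVELS if lv in set(cohort["education"])]
    return _multinomial_propensity(
        cohort, "education", cats, categorical, [],
        cohort[weight_column].to_numpy(), sorted(categorical), "exposure",
    )


def fit_mediator_propensity(
    cohort: pd.DataFrame,
    labels,
    intermediate_categorical: dict[str, str] | None = None,
    intermediate_continuous: list[str] | None = None,
    weight_column: str = "design_weight",
) -> PropensityFit:
    """Multinomial model of the typology on education plus confounders.

    The denominator conditions on education, baseline and intermediate
    confounders; the stabilization numerator conditions on education only.
    """
    df = cohort.copy()
    df["typology"] = np.asarray(labels)
    cats = [REFERENCE_TYPOLOGY] + sorted(set(df["typology"]) - {REFERENCE_TYPOLOGY})
    cat = {
        "education": REFERENCE_EDUCATION,
        **BASELINE_CONFOUNDERS,
        **(INTERMEDIATE_CATEGORICAL if intermediate_categorical is None else intermediate_categorical),
    }
    cont = INTERMEDIATE_CONTINUOUS if intermediate_continuous is None else intermediate_continuous
    return _multinomial_propensity(
        df, "typology", cats, cat, cont,
        df[weight_column].to_numpy(), sorted(cat) + list(cont), "mediator",
        numerator_categorical={"education": REFERENCE_EDUCATION},
    )


def compose_weights(
    design: np.ndarray,
    exposure_fit: PropensityFit | None = None,
    mediator_fit: PropensityFit | None = None,
    truncation: tuple[float, float] | None = None,
) -> WeightVector:
    """Multiply design weights with stabilized IPT components.

    w_i = design_i x [P(A=a_i)/P(A=a_i|L_i)] x [P(M=m_i|A_i)/P(M=m_i|A_i,L_i,Z_i)].
    ``truncation`` winsorizes the composed weight at the given percentiles
    (e.g. ``(1, 99)``); the number of clipped weights is recorded and logged.
    """
    w = np.asarray(design, dtype=float).copy()
    prov = {"design": True, "exposure": False, "mediator": False}
    for fit, key in ((exposure_fit, "exposure"), (mediator_fit, "mediator")):
        if fit is not None:
            w = w * (fit.marginal_probs / fit.fitted_probs)
            prov[key] = True
    n_trunc = 0
    if truncation is not None:
        lo, hi = np.percentile(w, truncation)
        n_trunc = int(np.sum((w < lo) | (w > hi)))
        if n_trunc:
            logger.info("truncated %d weights to percentiles %s", n_trunc, truncation)
        w = np.clip(w, lo, hi)
    return WeightVector(values=w, provenance=prov, truncation=truncation, n_truncated=n_trunc)


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------

def _smd_columns(df: pd.DataFrame, covariates: list[str]) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for c in covariates:
        if pd.api.types.is_numeric_dtype(df[c]):
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
        else:
            vals = df[c].astype(str)
            for lv in sorted(vals.unique())[1:]:
                cols.append((vals == lv).to_numpy(dtype=float))
                names.append(f"{c}[{lv}]")
    return np.column_stack(cols), names


def covariate_balance(
    cohort: pd.DataFrame,
    weights,
    covariates: list[str],
    group: str = "education",
) -> pd.DataFrame:
    """Weighted standardized mean differences across exposure/mediator groups.

    For every covariate (categorical ones expanded to level indicators) the
    maximum pairwise absolute SMD across groups is reported, before
    (design/unit weights implicit in ``weights``=1) and with the supplied
    weights.  Zero-variance covariates get SMD 0 with a flag.
    """
    w = np.asarray(getattr(weights, "values", weights), dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    X, names = _smd_columns(cohort, covariates)
    groups = cohort[group].astype(str).to_numpy()
    levels = sorted(pd.unique(groups))
    rows = []
    for j, name in enumerate(names):
        x = X[:, j]
        means, variances = {}, {}
        for lv in levels:
            m = groups == lv
            wm = w[m]
            mu = np.average(x[m], weights=wm)
            means[lv] = mu
            variances[lv] = np.average((x[m] - mu) ** 2, weights=wm)
        smd_max, flagged = 0.0, False
        for a in range(len(levels)):
            for b in range(a + 1, len(levels)):
                la, lb = levels[a], levels[b]
                pooled = np.sqrt((variances[la] + variances[lb]) / 2.0)
                if pooled == 0:
                    flagged = True
                    continue
                smd_max = max(smd_max, abs(means[la] - means[lb]) / pooled)
        rows.append({"covariate": name, "max_abs_smd": smd_max, "zero_variance": flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MSM estimation
# ---------------------------------------------------------------------------

def _education_order(df: pd.DataFrame) -> list[str]:
    return [lv for lv in EDUCATION_LEVELS if lv in set(df["education"])]


def estimate_ate(
    cohort: pd.DataFrame,
    weights: WeightVector,
    balance_covariates: list[str] | None = None,
) -> MSMResult:
    """Weighted logistic MSM of the outcome on education alone.

    Returns odds ratios per education level vs Degree with sandwich standard
    errors treating the weights as known.
    """
    w = weights.values
    if float(w.sum()) <= 0:
        raise ValueError("zero effective sample size")
    X, names = design_matrix(cohort, categorical={"education": REFERENCE_EDUCATION})
    y = cohort["outcome_raised_td"].to_numpy(dtype=float)
    for lv in _education_order(cohort)[1:]:
        m = cohort["education"] == lv
        if y[m.to_numpy()].sum() == 0 or y[m.to_numpy()].sum() == m.sum():
            raise ValueError(f"outcome separation in education level {lv!r}")
    fit = fit_weighted_glm(X, y, w, family="binomial", names=names)
    tab = fit.table()
    effects = tab[tab["term"].str.startswith("education[")].reset_index(drop=True)
    balance = None
    if balance_covariates:
        balance = covariate_balance(cohort, w, balance_covariates, group="education")
    return MSMResult(
        effects=effects,
        estimand="ATE",
        scenario=ScenarioSpec(estimand="ATE"),
        weight_diagnostics=weights.diagnostics(),
        balance=balance,
        model_params=tab,
    )


def estimate_cde(
    cohort: pd.DataFrame,
    labels,
    weights: WeightVector,
    scenario: ScenarioSpec,
) -> MSMResult:
    """Weighted logistic MSM with education x typology interaction.

    The controlled direct effect for education level a under the scenario's
    fixed mediator m is exp(beta_a + delta_am); its variance comes from the
    corresponding 2x2 block of the sandwich covariance.
    """
    if scenario.estimand != "CDE":
        raise ValueError("estimate_cde requires a CDE scenario")
    df = cohort.copy()
    df["typology"] = np.asarray(labels)
    tab = pd.crosstab(df["education"], df["typology"])
    if (tab == 0).any().any():
        zero = [(r, c) for r in tab.index for c in tab.columns if tab.loc[r, c] == 0]
        raise ValueError(
            f"empty education x typology cell(s) {zero}: the interaction model "
            "is inestimable on this sample"
        )
    fixed = scenario.fixed_mediator
    if fixed not in set(df["typology"]):
        raise ValueError(f"scenario mediator {fixed!r} not among typologies")
    # the interaction model is saturated in (education, typology), so the
    # scenario contrast depends only on the fixed-mediator column: require
    # outcome variation there and tolerate divergence elsewhere
    events = pd.crosstab(df["education"], df["typology"],
                         values=df["outcome_raised_td"], aggfunc="sum")
    sep = [(r, fixed) for r in tab.index
           if events.loc[r, fixed] in (0, tab.loc[r, fixed])]
    if sep:
        raise ValueError(
            f"outcome separation: education x typology cell(s) {sep} have no "
            "outcome variation, so the scenario contrast diverges"
        )
    X, names = design_matrix(
        df,
        categorical={"education": REFERENCE_EDUCATION, "typology": REFERENCE_TYPOLOGY},
        interactions=[("education", "typology")],
    )
    y = df["outcome_raised_td"].to_numpy(dtype=float)
    # cells outside the scenario column may lack outcome variation, sending
    # their own coefficients to +-inf without touching the saturated
    # scenario contrast, so convergence is not required of them
    fit = fit_weighted_glm(X, y, weights.values, family="binomial", names=names,
                           require_convergence=False)
    rows = []
    for lv in _education_order(df)[1:]:
        main = names.index(f"education[{lv}]")
        grad = np.zeros(len(names))
        grad[main] = 1.0
        if fixed != REFERENCE_TYPOLOGY:
            inter = names.index(f"education[{lv}]:typology[{fixed}]")
            grad[inter] = 1.0
        est = float(grad @ fit.params)
        var = float(grad @ fit.cov @ grad)
        rows.append((f"education[{lv}]", est, var))
    effects = effect_table(
        [r[0] for r in rows], [r[1] for r in rows], np.diag([r[2] for r in rows])
    )
    return MSMResult(
        effects=effects,
        estimand="CDE",
        scenario=scenario,
        weight_diagnostics=weights.diagnostics(),
        model_params=fit.table(),
    )


def bootstrap_msm_ci(
    cohort: pd.DataFrame,
    labels,
    scenario: ScenarioSpec,
    B: int = 200,
    seed: int = 0,
    truncation: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Nonparametric bootstrap CIs that re-estimate weights in each resample."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    n = len(cohort)
    draws: dict[str, list[float]] = {}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        blab = labels[idx]
        try:
            efit = fit_exposure_propensity(boot)
            if scenario.estimand == "ATE":
                wv = compose_weights(boot["design_weight"].to_numpy(), efit,
                                     truncation=truncation)
                res = estimate_ate(boot, wv)
            else:
                mfit = fit_mediator_propensity(boot, blab)
                wv = compose_weights(boot["design_weight"].to_numpy(), efit, mfit,
                                     truncation=truncation)
                res = estimate_cde(boot, blab, wv, scenario)
        except (ValueError, RuntimeError) as exc:
            logger.info("bootstrap resample skipped: %s", exc)
            continue
        for _, row in res.effects.iterrows():
            draws.setdefault(row["term"], []).append(np.log(row["estimate"]))
    rows = []
    for term, vals in draws.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        rows.append({
            "term": term,
            "estimate": float(np.exp(np.median(vals))),
            "ci_low": float(np.exp(lo)),
            "ci_high": float(np.exp(hi)),
            "n_resamples": len(vals),
        })
    return pd.DataFrame(rows)
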