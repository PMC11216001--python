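"""Synthetic early-years cohort generator.

Simulates, one row per child, the data structure the analysis pipeline
consumes: a 4-level maternal-education exposure, baseline and intermediate
confounders, a 4-class latent childcare typology whose class probabilities
depend on education, per-sweep childcare states emitted from the typology's
canonical path with noise, a binary "raised Total Difficulties" outcome from
a logistic model with exposure x typology interaction, survey design weights
and a retention (attrition) model.

The default parameter set (:func:`default_calibration`) is calibrated so the
generator's implied marginals and causal contrasts match published estimates
for a Scottish birth cohort: education distribution, typology prevalences
(35.8 / 32.7 / 23.5 / 8.1 %), education gradients in typology membership,
a ~10.9 % marginal outcome prevalence, and planted ATE / controlled-direct-
effect odds ratios.  Calibration constants are produced by the documented
solver in ``scripts/calibrate.py`` and stored in ``data/default_calibration.yaml``;
they are never hard-coded here.
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .alphabet import (
    CANONICAL_PATHS,
    CHILDCARE_STATES,
    EDUCATION_LEVELS,
    N_SWEEPS,
    SWEEP_COLUMNS,
    TYPOLOGY_NAMES,
)

TYPOLOGY_CODES = tuple(TYPOLOGY_NAMES)  # ("PFF", "GP", "PG", "SP")

AGE_BANDS = ("Under20", "20to29", "30plus")
EMPLOYMENT_LEVELS = ("AlwaysFT", "AlwaysPT", "MixedFTPT", "WorkAndNot", "NeverWorked")
FAMILY_LEVELS = ("AlwaysCouple", "AlwaysLone", "Mixture")

#: Named random-number streams, spawned in this fixed order from the master
#: seed so that adding a new variable block never perturbs earlier draws.
_RNG_BLOCKS = (
    "baseline",      # ethnicity, maternal age band
    "education",
    "covariates",    # sex, school adjustment
    "intermediate",  # employment, family composition, life events, health,
                     # attachment, maternal mental health
    "typology",
    "sequence",
    "outcome",
    "weights",
    "attrition",
)


class CalibrationError(RuntimeError):
    """Raised when a parameter set cannot reproduce its calibration targets."""


def _as_prob_vector(v, name: str, n: int) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {a.shape}")
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    s = a.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"{name} must sum to 1 (got {s:.8f})")
    return a / s  # exact renormalisation


@dataclass
class GeneratorParams:
    """Full parameter set for the synthetic cohort generator.

    All probability vectors are validated to sum to one; categorical values
    are drawn from the declared supports only.  ``typology_mixing`` rows are
    P(latent typology | education) over (PFF, GP, PG, SP); by default the
    latent typology depends on confounders only through education, and the
    optional ``typology_confounder_coefs`` block adds log-odds offsets
    (relative to PFF) per covariate level to build mediator-confounded
    scenarios.
    """

    n_children: int = 3205
    education_probs: Any = None                 # length-4, order EDUCATION_LEVELS
    education_model: dict = field(default_factory=dict)
    typology_mixing: Any = None                 # 4x4, rows=education, cols=typology
    typology_confounder_coefs: dict | None = None
    emission_noise: float = 0.1
    outcome_coefs: dict = field(default_factory=dict)
    confounder_params: dict = field(default_factory=dict)
    attrition_coefs: dict = field(default_factory=dict)
    design_weight_sigma: float = 0.25
    outcome_threshold: float = 0.0              # cut on the latent TD score
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if int(self.n_children) < 1:
            raise ValueError("n_children must be >= 1")
        self.n_children = int(self.n_children)
        if not (0.0 <= self.emission_noise < 0.5):
            raise ValueError("emission_noise must lie in [0, 0.5)")
        self.education_probs = _as_prob_vector(self.education_probs, "education_probs", 4)
        tm = np.asarray(self.typology_mixing, dtype=float)
        if tm.shape != (4, 4):
            raise ValueError("typology_mixing must be 4x4 (education x typology)")
        self.typology_mixing = np.vstack(
            [_as_prob_vector(row, f"typology_mixing[{i}]", 4) for i, row in enumerate(tm)]
        )
        cp = self.confounder_params
        for key, levels in (
            ("maternal_age_probs", AGE_BANDS),
            ("ethnicity_probs", ("White", "Other")),
            ("sex_probs", ("Male", "Female")),
            ("school_adjustment_probs", ("High", "Low")),
        ):
            vec = [cp[key][lv] for lv in levels]
            _as_prob_vector(vec, key, len(levels))
        for key, ncol in (
            ("employment_probs_by_education", len(EMPLOYMENT_LEVELS)),
            ("family_composition_probs_by_education", len(FAMILY_LEVELS)),
        ):
            mat = np.asarray(cp[key], dtype=float)
            if mat.shape != (4, ncol):
                raise ValueError(f"{key} must be 4x{ncol}")
            for i, row in enumerate(mat):
                _as_prob_vector(row, f"{key}[{i}]", ncol)
        for key in ("life_events_prob_by_education", "general_health_poor_prob_by_education"):
            v = np.asarray(cp[key], dtype=float)
            if v.shape != (4,) or np.any((v < 0) | (v > 1)):
                raise ValueError(f"{key} must be 4 probabilities in [0,1]")
        if self.design_weight_sigma < 0:
            raise ValueError("design_weight_sigma must be >= 0")

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = copy.deepcopy(
            {
                "n_children": self.n_children,
                "education_probs": np.asarray(self.education_probs).tolist(),
                "education_model": self.education_model,
                "typology_mixing": np.asarray(self.typology_mixing).tolist(),
                "typology_confounder_coefs": self.typology_confounder_coefs,
                "emission_noise": float(self.emission_noise),
                "outcome_coefs": self.outcome_coefs,
                "confounder_params": self.confounder_params,
                "attrition_coefs": self.attrition_coefs,
                "design_weight_sigma": float(self.design_weight_sigma),
                "outcome_threshold": float(self.outcome_threshold),
                "seed": int(self.seed),
                "provenance": self.provenance,
            }
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        return cls(**copy.deepcopy(d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "GeneratorParams":
        return GeneratorParams.from_dict(self.to_dict())


def default_calibration() -> GeneratorParams:
    """Load the calibrated default parameter set shipped with the package.

    The constants were solved once (see ``scripts/calibrate.py``) so that the
    generator's implied marginals and causal contrasts reproduce the target
    estimates recorded in the file's provenance block.  Raises
    :class:`CalibrationError` if the stored file fails validation.
    """
    ref = resources.files("careseq").joinpath("data/default_calibration.yaml")
    with ref.open() as fh:
        d = yaml.safe_load(fh)
    try:
        return GeneratorParams.from_dict(d)
    except ValueError as exc:  # pragma: no cover - corrupt install
        raise CalibrationError(f"stored calibration is invalid: {exc}") from exc


# ---------------------------------------------------------------------------
# generation helpers
# ---------------------------------------------------------------------------

def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(int(seed)).spawn(len(_RNG_BLOCKS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_RNG_BLOCKS, children)}


def _draw_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorised categorical draw with per-row probability vectors."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1).clip(0, probs.shape[1] - 1)


def education_logits(params: GeneratorParams, age_idx: np.ndarray, eth_idx: np.ndarray) -> np.ndarray:
    """Log-odds (vs Degree) of the three non-reference education levels."""
    em = params.education_model
    inter = np.asarray(em["intercepts"], dtype=float)          # (3,)
    age_c = np.asarray([em["age_coefs"][b] for b in AGE_BANDS])  # (3,3)
    eth_c = np.asarray([em["ethnicity_coefs"][e] for e in ("White", "Other")])
    return inter[None, :] + age_c[age_idx] + eth_c[eth_idx]


def education_probs_given_confounders(params, age_idx, eth_idx) -> np.ndarray:
    lg = education_logits(params, age_idx, eth_idx)
    full = np.concatenate([np.zeros((lg.shape[0], 1)), lg], axis=1)
    full -= full.max(axis=1, keepdims=True)
    p = np.exp(full)
    return p / p.sum(axis=1, keepdims=True)


def typology_probs(params: GeneratorParams, edu_idx: np.ndarray,
                   covariates: dict[str, np.ndarray] | None = None) -> np.ndarray:
    """P(latent typology | education [, confounders]) per child, cols (PFF,GP,PG,SP)."""
    base = np.asarray(params.typology_mixing)[edu_idx]  # (n, 4)
    if not params.typology_confounder_coefs:
        return base
    # log-odds offsets relative to PFF, per covariate level
    logit = np.log(base / base[:, [0]])
    for col, level_map in params.typology_confounder_coefs.items():
        if covariates is None or col not in covariates:
            raise ValueError(f"typology_confounder_coefs references missing covariate {col!r}")
        vals = covariates[col]
        for level, offs in level_map.items():
            mask = vals == level
            logit[mask, 1:] += np.asarray(offs, dtype=float)
    logit -= logit.max(axis=1, keepdims=True)
    p = np.exp(logit)
    return p / p.sum(axis=1, keepdims=True)


def outcome_linear_predictor(
    params: GeneratorParams,
    edu_idx: np.ndarray,
    typ_idx: np.ndarray,
    covs: dict[str, np.ndarray],
) -> np.ndarray:
    """Linear predictor of the latent Total Difficulties score.

    ``covs`` carries arrays (or broadcastable scalars) for: sex, ethnicity,
    maternal_age_band, school_adjustment, employment, family_composition,
    life_events, general_health (categorical codes) and attachment_score,
    maternal_mental_health_sw1/_sw5 (continuous).
    """
    oc = params.outcome_coefs
    cf = oc["confounders"]
    edu = np.concatenate([[0.0], np.asarray(oc["education"], dtype=float)])
    typ = np.concatenate([[0.0], np.asarray(oc["typology"], dtype=float)])
    inter = np.zeros((4, 4))
    inter[1:, 1:] = np.asarray(oc["interaction"], dtype=float)  # rows edu H/U/L, cols GP/PG/SP
    eta = oc["intercept"] + edu[edu_idx] + typ[typ_idx] + inter[edu_idx, typ_idx]
    eta = eta + np.where(covs["sex"] == "Male", cf["sex_Male"], 0.0)
    eta = eta + np.where(covs["ethnicity"] == "Other", cf["ethnicity_Other"], 0.0)
    eta = eta + np.where(covs["maternal_age_band"] == "Under20", cf["age_Under20"], 0.0)
    eta = eta + np.where(covs["maternal_age_band"] == "30plus", cf["age_30plus"], 0.0)
    eta = eta + np.where(covs["school_adjustment"] == "Low", cf["school_adjustment_Low"], 0.0)
    eta = eta + np.where(covs["life_events"] == "Yes", cf["life_events_Yes"], 0.0)
    eta = eta + np.where(covs["general_health"] == "Poor", cf["general_health_Poor"], 0.0)
    emp = cf["employment"]
    eta = eta + np.asarray(
        [emp[v] for v in np.asarray(covs["employment"]).ravel()]
    ).reshape(np.shape(covs["employment"]))
    fam = cf["family_composition"]
    eta = eta + np.asarray(
        [fam[v] for v in np.asarray(covs["family_composition"]).ravel()]
    ).reshape(np.shape(covs["family_composition"]))
    eta = eta + cf["attachment_per_unit"] * (covs["attachment_score"] - cf["attachment_center"])
    eta = eta + cf["mmh1_per_unit"] * (covs["maternal_mental_health_sw1"] - cf["mmh1_center"])
    eta = eta + cf["mmh5_per_unit"] * (covs["maternal_mental_health_sw5"] - cf["mmh5_center"])
    return np.asarray(eta, dtype=float)


def retention_probability(params: GeneratorParams, cohort: pd.DataFrame) -> np.ndarray:
    ac = params.attrition_coefs or {}
    eta = np.full(len(cohort), float(ac.get("intercept", 30.0)))
    for col, level_map in (ac.get("coefs") or {}).items():
        if col not in cohort.columns:
            raise ValueError(f"attrition model references missing column {col!r}")
        for level, val in level_map.items():
            eta[cohort[col].to_numpy() == level] += float(val)
    return expit(eta)


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def generate_cohort(params: GeneratorParams, seed: int | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort; deterministic given ``(params, seed)``.

    Returns one row per child with exposure, confounders, per-sweep childcare
    states, the latent typology (generator truth, withheld from estimators),
    the latent and binary outcome, design weights and retention indicator.
    """
    params.validate()
    if seed is None:
        seed = params.seed
    n = params.n_children
    rngs = _rngs(seed)
    cp = params.confounder_params

    age_p = np.array([cp["maternal_age_probs"][b] for b in AGE_BANDS])
    eth_p = np.array([cp["ethnicity_probs"][e] for e in ("White", "Other")])
    r = rngs["baseline"]
    age_idx = _draw_rows(r, np.tile(age_p / age_p.sum(), (n, 1)))
    eth_idx = _draw_rows(r, np.tile(eth_p / eth_p.sum(), (n, 1)))

    edu_idx = _draw_rows(rngs["education"], education_probs_given_confounders(params, age_idx, eth_idx))

    r = rngs["covariates"]
    sex_p = np.array([cp["sex_probs"][s] for s in ("Male", "Female")])
    sadj_p = np.array([cp["school_adjustment_probs"][s] for s in ("High", "Low")])
    sex_idx = _draw_rows(r, np.tile(sex_p / sex_p.sum(), (n, 1)))
    sadj_idx = _draw_rows(r, np.tile(sadj_p / sadj_p.sum(), (n, 1)))

    r = rngs["intermediate"]
    emp_idx = _draw_rows(r, np.asarray(cp["employment_probs_by_education"])[edu_idx])
    fam_idx = _draw_rows(r, np.asarray(cp["family_composition_probs_by_education"])[edu_idx])
    life = r.random(n) < np.asarray(cp["life_events_prob_by_education"])[edu_idx]
    ghealth = r.random(n) < np.asarray(cp["general_health_poor_prob_by_education"])[edu_idx]
    att_cfg = cp["attachment"]
    attach = np.clip(
        r.normal(np.asarray(att_cfg["mean_by_education"])[edu_idx], att_cfg["sd"]),
        att_cfg["min"], att_cfg["max"],
    )
    m1 = cp["mmh1"]
    mmh1 = np.clip(r.normal(np.asarray(m1["mean_by_education"])[edu_idx], m1["sd"]), m1["min"], m1["max"])
    m5 = cp["mmh5"]
    mmh5 = np.clip(r.normal(np.asarray(m5["mean_by_education"])[edu_idx], m5["sd"]), m5["min"], m5["max"])

    covs = {
        "sex": np.array(["Male", "Female"])[sex_idx],
        "ethnicity": np.array(["White", "Other"])[eth_idx],
        "maternal_age_band": np.array(AGE_BANDS)[age_idx],
        "school_adjustment": np.array(["High", "Low"])[sadj_idx],
        "employment": np.array(EMPLOYMENT_LEVELS)[emp_idx],
        "family_composition": np.array(FAMILY_LEVELS)[fam_idx],
        "life_events": np.where(life, "Yes", "No"),
        "general_health": np.where(ghealth, "Poor", "Good"),
        "attachment_score": attach,
        "maternal_mental_health_sw1": mmh1,
        "maternal_mental_health_sw5": mmh5,
    }

    typ_idx = _draw_rows(rngs["typology"], typology_probs(params, edu_idx, covs))

    # sequences: canonical path + independent per-sweep emission noise
    state_index = {s: i for i, s in enumerate(CHILDCARE_STATES)}
    paths = np.array(
        [[state_index[s] for s in CANONICAL_PATHS[t]] for t in TYPOLOGY_CODES], dtype=int
    )
    seq = paths[typ_idx].copy()  # (n, 4)
    r = rngs["sequence"]
    if params.emission_noise > 0:
        flip = r.random((n, N_SWEEPS)) < params.emission_noise
        # uniform over the 6 states other than the canonical one
        alt = r.integers(0, len(CHILDCARE_STATES) - 1, size=(n, N_SWEEPS))
        alt = alt + (alt >= seq)
        seq = np.where(flip, alt, seq)

    eta = outcome_linear_predictor(params, edu_idx, typ_idx, covs)
    r = rngs["outcome"]
    td_latent = eta + r.logistic(0.0, 1.0, n)
    outcome = (td_latent > params.outcome_threshold).astype(int)

    r = rngs["weights"]
    sig = params.design_weight_sigma
    design_weight = np.exp(r.normal(0.0, sig, n)) / np.exp(sig**2 / 2) if sig > 0 else np.ones(n)

    cohort = pd.DataFrame(
        {
            "child_id": np.arange(1, n + 1),
            "education": np.array(EDUCATION_LEVELS)[edu_idx],
            **{k: covs[k] for k in covs},
            **{SWEEP_COLUMNS[t]: np.array(CHILDCARE_STATES)[seq[:, t]] for t in range(N_SWEEPS)},
            "latent_typology": typ_idx + 1,
            "td_latent": td_latent,
            "outcome_raised_td": outcome,
            "design_weight": design_weight,
        }
    )
    p_ret = retention_probability(params, cohort)
    cohort["retained"] = (rngs["attrition"].random(n) < p_ret).astype(int)
    return cohort


def apply_attrition(cohort: pd.DataFrame, params: GeneratorParams) -> pd.DataFrame:
    """Return the retained subsample with attrition-corrected weights.

    Design weights are divided by the model retention probability (mimicking
    combined sample and response weights) and renormalised to mean 1, so
    weighted marginals of the retained subsample approximate the full-cohort
    marginals even when retention depends on covariates.
    """
    retained = cohort[cohort["retained"] == 1].copy()
    if len(retained) == 0:
        raise ValueError("attrition removed every child; no retained rows")
    p = retention_probability(params, retained)
    w = retained["design_weight"].to_numpy() / p
    retained["design_weight"] = w / w.mean()
    return retained.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path, params: GeneratorParams | None = None,
                 seed: int | None = None) -> None:
    """Write the cohort as RFC-4180 CSV plus a JSON sidecar with provenance."""
    cohort.to_csv(path, index=False, lineterminator="\r\n")
    from . import __version__

    sidecar = {
        "seed": seed if seed is not None else (params.seed if params else None),
        "package_version": __version__,
        "n_rows": int(len(cohort)),
        "calibration_provenance": (params.provenance if params else None),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_cohort(path) -> pd.DataFrame:
    # "None" is a legitimate childcare state, not a missing value
    return pd.read_csv(path, keep_default_na=False, na_values=[""])
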