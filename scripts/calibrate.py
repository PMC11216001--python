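"""One-time calibration solver for the default synthetic-cohort parameters.

Solves, by numeric root finding against exact marginalisation over the
discrete covariate lattice (continuous confounders integrated by 3-point
Gauss-Hermite quadrature), for:

1. education-model intercepts so the marginal education distribution matches
   the analytic-sample targets;
2. typology-mixing intercepts so, with the published education gradients as
   fixed log-odds, marginal typology prevalences match their targets;
3. outcome-model coefficients (intercept, education main effects, typology
   main effects, education x typology interactions for the private-group and
   single-professional columns) so that the generator's implied marginal
   outcome prevalence, marginal ATE odds ratios, controlled-direct-effect
   odds ratios under both universal-childcare scenarios, and fully adjusted
   quasi-Poisson typology risk ratios all match their targets.

Writes ``src/careseq/data/default_calibration.yaml`` with a provenance block
recording the targets and achieved residuals.  Run from the repo root:

    python scripts/calibrate.py
"""
from __future__ import annotations

import itertools
import sys
from pathlib import Path

import numpy as np

import yaml
from scipy.optimize import root
from scipy.special import expit, logit

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from careseq.synthetic import (  # noqa: E402
    AGE_BANDS,
    EMPLOYMENT_LEVELS,
    FAMILY_LEVELS,
    CalibrationError,
    GeneratorParams,
    outcome_linear_predictor,
)

# ---------------------------------------------------------------------------
# calibration targets (analytic-sample marginals and published contrasts)
# ---------------------------------------------------------------------------
EDUCATION_TARGET = np.array([26.6, 31.9, 26.0, 15.4]) / 99.9
TYPOLOGY_TARGET = np.array([35.8, 32.7, 23.5, 8.1]) / 100.1  # PFF, GP, PG, SP
# typology-membership odds ratios vs Degree (rows Highers/Upper/Lower,
# cols GP/PG/SP), multinomial with PFF baseline
TABLE2_OR = np.array(
    [[0.914, 0.457, 0.443],
     [0.625, 0.211, 0.267],
     [0.368, 0.123, 0.089]]
)
PREVALENCE_TARGET = 0.109
ATE_OR = np.array([1.352, 2.596, 3.181])        # Highers, Upper, Lower vs Degree
CDE_PG_OR = np.array([2.164, 3.600, 3.778])
CDE_SP_OR = np.array([0.713, 1.782, 2.420])
RR_TARGET = np.array([1.052, 0.832, 0.770])     # GP, PG, SP vs PFF, fully adjusted

# ---------------------------------------------------------------------------
# fixed structural configuration (chosen once as plausible survey values)
# ---------------------------------------------------------------------------
BASE = {
    "n_children": 3205,
    "emission_noise": 0.1,
    "design_weight_sigma": 0.25,
    "outcome_threshold": 0.0,
    "seed": 0,
    "confounder_params": {
        "maternal_age_probs": {"Under20": 0.172, "20to29": 0.510, "30plus": 0.318},
        "ethnicity_probs": {"White": 0.957, "Other": 0.043},
        "sex_probs": {"Male": 0.514, "Female": 0.486},
        "school_adjustment_probs": {"High": 0.80, "Low": 0.20},
        "employment_probs_by_education": [
            [0.22, 0.33, 0.15, 0.22, 0.08],
            [0.17, 0.34, 0.13, 0.25, 0.11],
            [0.12, 0.33, 0.11, 0.27, 0.17],
            [0.05, 0.18, 0.07, 0.30, 0.40],
        ],
        "family_composition_probs_by_education": [
            [0.90, 0.03, 0.07],
            [0.84, 0.06, 0.10],
            [0.76, 0.10, 0.14],
            [0.58, 0.22, 0.20],
        ],
        "life_events_prob_by_education": [0.30, 0.34, 0.38, 0.45],
        "general_health_poor_prob_by_education": [0.16, 0.20, 0.24, 0.32],
        "attachment": {"mean_by_education": [39.9, 39.6, 39.3, 38.7], "sd": 4.0,
                       "min": 8.0, "max": 48.0},
        "mmh1": {"mean_by_education": [50.6, 50.1, 49.6, 48.6], "sd": 9.0,
                 "min": 0.0, "max": 100.0},
        "mmh5": {"mean_by_education": [50.3, 49.5, 48.7, 47.5], "sd": 9.5,
                 "min": 0.0, "max": 100.0},
    },
    "education_age_coefs": {
        "Under20": [1.0, 1.8, 2.6],
        "20to29": [0.0, 0.0, 0.0],
        "30plus": [-0.6, -1.1, -1.5],
    },
    "education_eth_coefs": {"White": [0.0, 0.0, 0.0], "Other": [-0.2, -0.3, -0.4]},
    "outcome_confounders": {
        "sex_Male": 0.30,
        "school_adjustment_Low": 0.90,
        "ethnicity_Other": 0.10,
        "age_Under20": 0.25,
        "age_30plus": -0.10,
        "attachment_per_unit": -0.04,
        "attachment_center": 39.5,
        "mmh1_per_unit": -0.010,
        "mmh1_center": 50.0,
        "mmh5_per_unit": -0.030,
        "mmh5_center": 50.0,
        "employment": {"AlwaysFT": 0.0, "AlwaysPT": 0.0, "MixedFTPT": 0.05,
                       "WorkAndNot": 0.15, "NeverWorked": 0.30},
        "family_composition": {"AlwaysCouple": 0.0, "AlwaysLone": 0.35, "Mixture": 0.25},
        "life_events_Yes": 0.30,
        "general_health_Poor": 0.45,
    },
}

GH_NODES = np.array([-np.sqrt(3.0), 0.0, np.sqrt(3.0)])
GH_WEIGHTS = np.array([1.0 / 6.0, 2.0 / 3.0, 1.0 / 6.0])


def softmax_ref(logits3: np.ndarray) -> np.ndarray:
    """4-category probabilities from 3 non-reference logits (ref first)."""
    full = np.concatenate([np.zeros(logits3.shape[:-1] + (1,)), logits3], axis=-1)
    full = full - full.max(axis=-1, keepdims=True)
    p = np.exp(full)
    return p / p.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# stage 1: education-model intercepts
# ---------------------------------------------------------------------------
def solve_education_model() -> dict:
    cp = BASE["confounder_params"]
    age_p = np.array([cp["maternal_age_probs"][b] for b in AGE_BANDS])
    eth_p = np.array([cp["ethnicity_probs"][e] for e in ("White", "Other")])
    age_c = np.array([BASE["education_age_coefs"][b] for b in AGE_BANDS])
    eth_c = np.array([BASE["education_eth_coefs"][e] for e in ("White", "Other")])

    cells = list(itertools.product(range(3), range(2)))
    wcell = np.array([age_p[a] * eth_p[e] for a, e in cells])

    def implied(inter):
        lg = np.array([inter + age_c[a] + eth_c[e] for a, e in cells])
        return wcell @ softmax_ref(lg)

    def f(inter):
        return (implied(inter) - EDUCATION_TARGET)[1:]

    sol = root(f, logit(EDUCATION_TARGET[1:]) - logit(EDUCATION_TARGET[0]), tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-10:
        raise CalibrationError(f"education intercepts failed: {sol.message}, resid {sol.fun}")
    return {
        "intercepts": sol.x.tolist(),
        "age_coefs": BASE["education_age_coefs"],
        "ethnicity_coefs": BASE["education_eth_coefs"],
    }


# ---------------------------------------------------------------------------
# stage 2: typology mixing matrix
# ---------------------------------------------------------------------------
def solve_typology_mixing() -> np.ndarray:
    log_or = np.vstack([np.zeros(3), np.log(TABLE2_OR)])  # (4 edu, 3 typ)

    def mixing(t):
        return softmax_ref(t[None, :] + log_or)  # (4, 4)

    def f(t):
        marg = EDUCATION_TARGET @ mixing(t)
        return (marg - TYPOLOGY_TARGET)[1:]

    sol = root(f, np.zeros(3), tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-10:
        raise CalibrationError(f"typology mixing failed: {sol.message}, resid {sol.fun}")
    return mixing(sol.x)


# ---------------------------------------------------------------------------
# stage 3: outcome model
# ---------------------------------------------------------------------------
def build_lattice():
    """Product grid over discrete confounders and Gauss-Hermite nodes.

    Returns level-index arrays, the A-independent cell weight, and per-
    education Z weights / covariate dictionaries.
    """
    cp = BASE["confounder_params"]
    grids = {
        "age": 3, "eth": 2, "sex": 2, "sadj": 2,
        "emp": 5, "fam": 3, "life": 2, "gh": 2,
        "att": 3, "m1": 3, "m5": 3,
    }
    idx = np.array(list(itertools.product(*[range(n) for n in grids.values()])))
    col = {k: idx[:, i] for i, k in enumerate(grids)}

    age_p = np.array([cp["maternal_age_probs"][b] for b in AGE_BANDS])
    eth_p = np.array([cp["ethnicity_probs"][e] for e in ("White", "Other")])
    sex_p = np.array([cp["sex_probs"][s] for s in ("Male", "Female")])
    sadj_p = np.array([cp["school_adjustment_probs"][s] for s in ("High", "Low")])
    lw = age_p[col["age"]] * eth_p[col["eth"]] * sex_p[col["sex"]] * sadj_p[col["sadj"]]

    zw, covs_by_a = [], []
    for a in range(4):
        emp_p = np.array(cp["employment_probs_by_education"][a])
        fam_p = np.array(cp["family_composition_probs_by_education"][a])
        life_p = cp["life_events_prob_by_education"][a]
        gh_p = cp["general_health_poor_prob_by_education"][a]
        w = (
            emp_p[col["emp"]] * fam_p[col["fam"]]
            * np.where(col["life"] == 1, life_p, 1 - life_p)
            * np.where(col["gh"] == 1, gh_p, 1 - gh_p)
            * GH_WEIGHTS[col["att"]] * GH_WEIGHTS[col["m1"]] * GH_WEIGHTS[col["m5"]]
        )
        zw.append(w)
        att = cp["attachment"]
        m1, m5 = cp["mmh1"], cp["mmh5"]
        covs_by_a.append({
            "sex": np.where(col["sex"] == 0, "Male", "Female"),
            "ethnicity": np.where(col["eth"] == 0, "White", "Other"),
            "maternal_age_band": np.array(AGE_BANDS)[col["age"]],
            "school_adjustment": np.where(col["sadj"] == 0, "High", "Low"),
            "employment": np.array(EMPLOYMENT_LEVELS)[col["emp"]],
            "family_composition": np.array(FAMILY_LEVELS)[col["fam"]],
            "life_events": np.where(col["life"] == 1, "Yes", "No"),
            "general_health": np.where(col["gh"] == 1, "Poor", "Good"),
            "attachment_score": np.clip(
                att["mean_by_education"][a] + GH_NODES[col["att"]] * att["sd"],
                att["min"], att["max"]),
            "maternal_mental_health_sw1": np.clip(
                m1["mean_by_education"][a] + GH_NODES[col["m1"]] * m1["sd"],
                m1["min"], m1["max"]),
            "maternal_mental_health_sw5": np.clip(
                m5["mean_by_education"][a] + GH_NODES[col["m5"]] * m5["sd"],
                m5["min"], m5["max"]),
        })
    return col, lw, zw, covs_by_a


def make_params(education_model, mixing, outcome_coefs) -> GeneratorParams:
    return GeneratorParams(
        n_children=BASE["n_children"],
        education_probs=EDUCATION_TARGET.tolist(),
        education_model=education_model,
        typology_mixing=np.asarray(mixing).tolist(),
        emission_noise=BASE["emission_noise"],
        outcome_coefs=outcome_coefs,
        confounder_params=BASE["confounder_params"],
        attrition_coefs={"intercept": 30.0, "coefs": {}},
        design_weight_sigma=BASE["design_weight_sigma"],
        outcome_threshold=BASE["outcome_threshold"],
        seed=BASE["seed"],
    )


def confounder_eta(lattice):
    """Per-education confounder contribution to the outcome linear predictor.

    Independent of the coefficients being solved, so computed once.
    """
    col, lw, zw, covs_by_a = lattice
    zero = {
        "intercept": 0.0, "education": [0.0] * 3, "typology": [0.0] * 3,
        "interaction": [[0.0] * 3 for _ in range(3)],
        "confounders": BASE["outcome_confounders"],
    }
    params = GeneratorParams(
        n_children=1, education_probs=[0.25] * 4,
        education_model={"intercepts": [0, 0, 0],
                         "age_coefs": BASE["education_age_coefs"],
                         "ethnicity_coefs": BASE["education_eth_coefs"]},
        typology_mixing=[[0.25] * 4] * 4, emission_noise=0.0,
        outcome_coefs=zero, confounder_params=BASE["confounder_params"],
    )
    n = len(lw)
    zi = np.zeros(n, dtype=int)
    return [outcome_linear_predictor(params, zi, zi, covs_by_a[a]) for a in range(4)]


def implied_quantities(oc, mixing, lattice, pA_by_cell, conf_eta):
    """Exact E[Y_{a,m}], E[Y_a] and marginal prevalence under the generator."""
    col, lw, zw, covs_by_a = lattice
    mixing = np.asarray(mixing)
    edu = np.concatenate([[0.0], np.asarray(oc["education"], dtype=float)])
    typ = np.concatenate([[0.0], np.asarray(oc["typology"], dtype=float)])
    inter = np.zeros((4, 4))
    inter[1:, 1:] = np.asarray(oc["interaction"], dtype=float)
    ey_am = np.zeros((4, 4))
    prev = 0.0
    for a in range(4):
        w_cells = lw * zw[a]                       # sums to 1
        joint = lw * pA_by_cell[:, a] * zw[a]      # sums to P(A=a)
        for m in range(4):
            p = expit(conf_eta[a] + oc["intercept"] + edu[a] + typ[m] + inter[a, m])
            ey_am[a, m] = w_cells @ p
            prev += mixing[a, m] * (joint @ p)
    ey_a = (mixing * ey_am).sum(axis=1)
    return ey_am, ey_a, prev


def build_rr_design(lattice, pA_by_cell, mixing):
    """Fixed design matrix and weights for the fully adjusted RR population fit."""
    col, lw, zw, covs_by_a = lattice
    mixing = np.asarray(mixing)
    rows_X, rows_w = [], []
    for a in range(4):
        joint = lw * pA_by_cell[:, a] * zw[a]
        covs = covs_by_a[a]
        n = len(lw)
        base_cols = [
            np.ones(n),
            (covs["sex"] == "Male").astype(float),
            (covs["ethnicity"] == "Other").astype(float),
            (covs["maternal_age_band"] == "Under20").astype(float),
            (covs["maternal_age_band"] == "30plus").astype(float),
            (covs["school_adjustment"] == "Low").astype(float),
            covs["attachment_score"],
            covs["maternal_mental_health_sw1"],
            covs["maternal_mental_health_sw5"],
            (covs["life_events"] == "Yes").astype(float),
            (covs["general_health"] == "Poor").astype(float),
        ]
        base_cols += [(covs["employment"] == lv).astype(float) for lv in EMPLOYMENT_LEVELS[1:]]
        base_cols += [(covs["family_composition"] == lv).astype(float) for lv in FAMILY_LEVELS[1:]]
        base_cols += [np.full(n, float(a == j)) for j in range(1, 4)]  # education dummies
        for m in range(4):
            X = np.column_stack(
                base_cols + [np.full(n, float(m == j)) for j in range(1, 4)])
            rows_X.append(X.astype(np.float32))
            rows_w.append(joint * mixing[a, m])
    return np.vstack(rows_X).astype(float), np.concatenate(rows_w)


def implied_rr(oc, conf_eta, rr_X, rr_w):
    """Fully adjusted quasi-Poisson typology risk ratios implied by the model."""
    edu = np.concatenate([[0.0], np.asarray(oc["education"], dtype=float)])
    typ = np.concatenate([[0.0], np.asarray(oc["typology"], dtype=float)])
    inter = np.zeros((4, 4))
    inter[1:, 1:] = np.asarray(oc["interaction"], dtype=float)
    ys = []
    for a in range(4):
        for m in range(4):
            ys.append(expit(conf_eta[a] + oc["intercept"] + edu[a] + typ[m] + inter[a, m]))
    y = np.concatenate(ys)
    beta = _poisson_irls(rr_X, y, rr_w)
    return np.exp(beta[-3:])  # GP, PG, SP


def _poisson_irls(X, y, w, maxiter=60, tol=1e-12):
    """Weighted log-link Poisson MLE by IRLS with controlled memory."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(np.average(y, weights=w), 1e-8))
    for _ in range(maxiter):
        eta = X @ beta
        mu = np.exp(eta)
        ww = w * mu
        z = eta + (y - mu) / mu
        XtW = X.T * ww
        new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


def solve_outcome(education_model, mixing):
    lattice = build_lattice()
    col, lw, zw, covs_by_a = lattice
    # P(A | age, eth) per lattice cell
    age_c = np.array([BASE["education_age_coefs"][b] for b in AGE_BANDS])
    eth_c = np.array([BASE["education_eth_coefs"][e] for e in ("White", "Other")])
    inter = np.array(education_model["intercepts"])
    pA_by_cell = softmax_ref(inter[None, :] + age_c[col["age"]] + eth_c[col["eth"]])

    conf_eta = confounder_eta(lattice)
    rr_X, rr_w = build_rr_design(lattice, pA_by_cell, mixing)
    gamma = np.log(RR_TARGET)  # starting typology main effects

    def coefs_from(x, gamma):
        beta0, betaA, dPG, dSP = x[0], x[1:4], x[4:7], x[7:10]
        interaction = np.column_stack([np.zeros(3), dPG, dSP])  # cols GP, PG, SP
        return {
            "intercept": float(beta0),
            "education": betaA.tolist(),
            "typology": gamma.tolist(),
            "interaction": interaction.tolist(),
            "confounders": BASE["outcome_confounders"],
        }

    def resid(x, gamma):
        ey_am, ey_a, prev = implied_quantities(
            coefs_from(x, gamma), mixing, lattice, pA_by_cell, conf_eta)
        lo = logit
        r = [prev - PREVALENCE_TARGET]
        r += list(lo(ey_a[1:]) - lo(ey_a[0]) - np.log(ATE_OR))
        r += list(lo(ey_am[1:, 2]) - lo(ey_am[0, 2]) - np.log(CDE_PG_OR))
        r += list(lo(ey_am[1:, 3]) - lo(ey_am[0, 3]) - np.log(CDE_SP_OR))
        return np.array(r)

    x = np.concatenate([[logit(PREVALENCE_TARGET)], np.log(ATE_OR),
                        np.log(CDE_PG_OR / ATE_OR), np.log(CDE_SP_OR / ATE_OR)])
    for it in range(12):
        sol = root(resid, x, args=(gamma,), tol=1e-12)
        if not sol.success:
            raise CalibrationError(f"outcome solve failed at iter {it}: {sol.message}")
        x = sol.x
        rr = implied_rr(coefs_from(x, gamma), conf_eta, rr_X, rr_w)
        step = np.log(RR_TARGET) - np.log(rr)
        print(f"  outer iter {it}: max|resid|={np.max(np.abs(sol.fun)):.2e}, "
              f"RR={np.round(rr, 4)}, step={np.round(step, 5)}")
        if np.max(np.abs(step)) < 2e-5:
            break
        gamma = gamma + step
    else:
        raise CalibrationError(f"typology main effects did not converge; last RR {rr}")
    final = coefs_from(x, gamma)
    ey_am, ey_a, prev = implied_quantities(final, mixing, lattice, pA_by_cell, conf_eta)
    diag = {
        "implied_prevalence": float(prev),
        "implied_ate_or": np.exp(
            logit(ey_a[1:]) - logit(ey_a[0])).round(6).tolist(),
        "implied_cde_pg_or": np.exp(logit(ey_am[1:, 2]) - logit(ey_am[0, 2])).round(6).tolist(),
        "implied_cde_sp_or": np.exp(logit(ey_am[1:, 3]) - logit(ey_am[0, 3])).round(6).tolist(),
        "implied_fully_adjusted_rr": implied_rr(final, conf_eta, rr_X, rr_w).round(6).tolist(),
    }
    return final, diag


def main():
    print("stage 1: education-model intercepts")
    education_model = solve_education_model()
    print("stage 2: typology mixing")
    mixing = solve_typology_mixing()
    print("stage 3: outcome model")
    outcome_coefs, diag = solve_outcome(education_model, mixing)

    params = make_params(education_model, mixing, outcome_coefs)
    tol = {"implied_prevalence": (PREVALENCE_TARGET, 1e-4),
           "implied_ate_or": (ATE_OR, 1e-3),
           "implied_cde_pg_or": (CDE_PG_OR, 1e-3),
           "implied_cde_sp_or": (CDE_SP_OR, 1e-3),
           "implied_fully_adjusted_rr": (RR_TARGET, 1e-3)}
    for key, (target, eps) in tol.items():
        got = np.asarray(diag[key], dtype=float)
        if np.max(np.abs(got - np.asarray(target))) > eps:
            raise CalibrationError(
                f"calibration target {key} missed: got {got}, want {target}")
    params.provenance = {
        "solver": "scripts/calibrate.py",
        "targets": {
            "education_probs": EDUCATION_TARGET.round(6).tolist(),
            "typology_prevalence": TYPOLOGY_TARGET.round(6).tolist(),
            "typology_membership_or": TABLE2_OR.tolist(),
            "outcome_prevalence": PREVALENCE_TARGET,
            "ate_or": ATE_OR.tolist(),
            "cde_private_group_or": CDE_PG_OR.tolist(),
            "cde_single_professional_or": CDE_SP_OR.tolist(),
            "fully_adjusted_rr": RR_TARGET.tolist(),
        },
        "diagnostics": diag,
    }
    out = Path(__file__).resolve().parents[1] / "src" / "careseq" / "data" / "default_calibration.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    params.to_yaml(out)
    print(f"wrote {out}")
    print(yaml.safe_dump(diag, sort_keys=False))


if __name__ == "__main__":
    main()
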