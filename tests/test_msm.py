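"""Propensity models, weight composition, balance, ATE and CDE estimation."""
import numpy as np
import pandas as pd
import pytest

from careseq import generate_cohort
from careseq.alphabet import TYPOLOGY_NAMES
from careseq.msm import (
    ScenarioSpec,
    WeightVector,
    compose_weights,
    covariate_balance,
    estimate_ate,
    estimate_cde,
    fit_exposure_propensity,
    fit_mediator_propensity,
)

NAMES = np.array(list(TYPOLOGY_NAMES.values()))
LOWEST = "education[LowerStdGradesOrNone]"


def _true_labels(cohort):
    return NAMES[cohort["latent_typology"] - 1]


class TestPropensities:
    def test_no_confounders_reduce_to_marginals(self, small_cohort):
        fit = fit_exposure_propensity(small_cohort, baseline_confounders={})
        w = small_cohort["design_weight"].to_numpy()
        marg = {lv: w[small_cohort["education"] == lv].sum() / w.sum()
                for lv in small_cohort["education"].unique()}
        expect = np.array([marg[lv] for lv in small_cohort["education"]])
        assert np.allclose(fit.fitted_probs, expect, atol=1e-5)
        assert np.allclose(fit.marginal_probs, expect, atol=1e-5)

    def test_saturated_binary_confounder_matches_cell_frequencies(self, rng):
        n = 3000
        z = rng.integers(0, 2, n)
        p1 = np.where(z == 1, 0.7, 0.3)
        a = np.where(rng.random(n) < p1, "Degree", "Highers")
        df = pd.DataFrame({"education": a, "ethnicity": np.where(z == 1, "Other", "White"),
                           "design_weight": np.ones(n)})
        fit = fit_exposure_propensity(df, baseline_confounders={"ethnicity": "White"})
        for zv, eth in ((0, "White"), (1, "Other")):
            m = df["ethnicity"] == eth
            emp = (df.loc[m, "education"] == "Degree").mean()
            got = fit.prob_matrix[m.to_numpy(), 0][0]
            assert got == pytest.approx(emp, abs=1e-6)

    def test_mediator_weights_near_one_without_mediator_confounding(self, default_params):
        # default generator: typology depends on confounders only through
        # education, so stabilized mediator weights concentrate on 1; their
        # residual spread is pure estimation noise and grows with the size of
        # the conditioning set
        p = default_params.copy()
        p.n_children = 10_000
        cohort = generate_cohort(p, seed=31)
        lean = fit_mediator_propensity(
            cohort, _true_labels(cohort),
            intermediate_categorical={"family_composition": "AlwaysCouple"},
            intermediate_continuous=[])
        sw = lean.marginal_probs / lean.fitted_probs
        assert abs(sw.mean() - 1.0) < 0.02
        assert sw.std() < 0.05
        full = fit_mediator_propensity(cohort, _true_labels(cohort))
        sw_full = full.marginal_probs / full.fitted_probs
        assert abs(sw_full.mean() - 1.0) < 0.02
        assert sw_full.std() < 0.10


class TestComposeWeights:
    def test_without_propensities_weights_equal_design(self, small_cohort):
        design = small_cohort["design_weight"].to_numpy()
        wv = compose_weights(design)
        assert np.array_equal(wv.values, design)
        assert wv.provenance == {"design": True, "exposure": False, "mediator": False}

    def test_truncation_winsorizes_only_the_tails(self, rng):
        w = np.concatenate([np.ones(98), [0.01, 50.0]])
        wv = compose_weights(w, truncation=(1, 99))
        lo, hi = np.percentile(w, [1, 99])
        assert wv.n_truncated == 2
        assert wv.values.max() == pytest.approx(hi)
        assert wv.values.min() == pytest.approx(lo)
        assert np.array_equal(wv.values[1:-2], w[1:-2])

    def test_stabilized_exposure_weights_have_mean_near_one(self, full_cohort):
        efit = fit_exposure_propensity(full_cohort)
        sw = efit.marginal_probs / efit.fitted_probs
        assert 0.97 < sw.mean() < 1.03

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            WeightVector(values=np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="positive"):
            WeightVector(values=np.array([1.0, np.inf]))

    def test_effective_sample_size_never_exceeds_n(self, full_cohort):
        efit = fit_exposure_propensity(full_cohort)
        wv = compose_weights(full_cohort["design_weight"].to_numpy(), efit)
        assert wv.diagnostics()["effective_sample_size"] <= len(full_cohort)


class TestBalance:
    def test_identical_groups_have_zero_smd(self):
        df = pd.DataFrame({
            "education": np.repeat(["Degree", "Highers"], 50),
            "x": np.tile(np.arange(50.0), 2),
        })
        bal = covariate_balance(df, np.ones(100), ["x"])
        assert bal["max_abs_smd"].iloc[0] == 0.0

    def test_zero_variance_covariate_flagged(self):
        df = pd.DataFrame({"education": ["Degree"] * 5 + ["Highers"] * 5,
                           "x": np.ones(10)})
        bal = covariate_balance(df, np.ones(10), ["x"])
        assert bal["zero_variance"].iloc[0]
        assert bal["max_abs_smd"].iloc[0] == 0.0

    def test_equal_weights_match_unweighted_smd(self, small_cohort):
        a = covariate_balance(small_cohort, np.ones(len(small_cohort)),
                              ["attachment_score"])
        b = covariate_balance(small_cohort, np.full(len(small_cohort), 3.7),
                              ["attachment_score"])
        assert a["max_abs_smd"].iloc[0] == pytest.approx(b["max_abs_smd"].iloc[0])

    def test_iptw_restores_baseline_balance(self, default_params):
        p = default_params.copy()
        p.n_children = 20_000
        cohort = generate_cohort(p, seed=37)
        unweighted = covariate_balance(cohort, np.ones(len(cohort)),
                                       ["maternal_age_band"])
        assert unweighted["max_abs_smd"].max() > 0.2  # confounded by design
        efit = fit_exposure_propensity(cohort)
        wv = compose_weights(cohort["design_weight"].to_numpy(), efit)
        weighted = covariate_balance(cohort, wv.values, ["maternal_age_band", "ethnicity"])
        assert weighted["max_abs_smd"].max() < 0.1


class TestATE:
    def test_unconfounded_generator_matches_crude_or(self, default_params):
        p = default_params.copy()
        p.n_children = 40_000
        em = p.education_model
        em["age_coefs"] = {k: [0.0] * 3 for k in em["age_coefs"]}
        em["ethnicity_coefs"] = {k: [0.0] * 3 for k in em["ethnicity_coefs"]}
        cohort = generate_cohort(p, seed=41)
        cohort["design_weight"] = 1.0
        efit = fit_exposure_propensity(cohort)
        wv = compose_weights(cohort["design_weight"].to_numpy(), efit)
        ate = estimate_ate(cohort, wv).effects.set_index("term")
        rate = cohort.groupby("education")["outcome_raised_td"].mean()
        odds = rate / (1 - rate)
        crude = odds["LowerStdGradesOrNone"] / odds["Degree"]
        assert ate.loc[LOWEST, "estimate"] == pytest.approx(crude, rel=0.02)

    def test_null_exposure_cis_cover_one(self, default_params):
        # null total effect: every outcome path from education (direct,
        # through the typology, through the intermediate confounders) zeroed
        p = default_params.copy()
        p.n_children = 2500
        oc = p.outcome_coefs
        oc["education"] = [0.0] * 3
        oc["typology"] = [0.0] * 3
        oc["interaction"] = [[0.0] * 3 for _ in range(3)]
        for key, val in list(oc["confounders"].items()):
            if isinstance(val, dict):
                oc["confounders"][key] = {k: 0.0 for k in val}
            elif not key.endswith("_center"):
                oc["confounders"][key] = 0.0
        covered = []
        for s in range(40):
            cohort = generate_cohort(p, seed=500 + s)
            efit = fit_exposure_propensity(cohort)
            wv = compose_weights(cohort["design_weight"].to_numpy(), efit)
            eff = estimate_ate(cohort, wv).effects
            covered.append(((eff["ci_low"] <= 1.0) & (1.0 <= eff["ci_high"])).to_numpy())
        per_term = np.asarray(covered).mean(axis=0)
        assert (per_term >= 0.85).all()

    def test_weight_diagnostics_reported(self, full_cohort):
        efit = fit_exposure_propensity(full_cohort)
        wv = compose_weights(full_cohort["design_weight"].to_numpy(), efit)
        res = estimate_ate(full_cohort, wv,
                           balance_covariates=["ethnicity", "maternal_age_band"])
        d = res.weight_diagnostics
        assert set(d) >= {"min", "max", "mean", "effective_sample_size"}
        assert (res.balance["max_abs_smd"] < 0.1).all()


class TestCDE:
    def test_cde_equals_ate_without_mediation(self, default_params):
        # gamma_m = delta_am = 0: fixing the mediator cannot change anything
        p = default_params.copy()
        p.n_children = 30_000
        oc = p.outcome_coefs
        oc["typology"] = [0.0] * 3
        oc["interaction"] = [[0.0] * 3 for _ in range(3)]
        cohort = generate_cohort(p, seed=43)
        labels = _true_labels(cohort)
        efit = fit_exposure_propensity(cohort)
        wv = compose_weights(cohort["design_weight"].to_numpy(), efit)
        ate = estimate_ate(cohort, wv).effects.set_index("term")
        mfit = fit_mediator_propensity(cohort, labels)
        wv2 = compose_weights(cohort["design_weight"].to_numpy(), efit, mfit)
        for scenario in ("Private group childcare", "Single professional care"):
            cde = estimate_cde(cohort, labels, wv2,
                               ScenarioSpec(estimand="CDE", fixed_mediator=scenario)
                               ).effects.set_index("term")
            for term in ate.index:
                # agreement within 3 Monte-Carlo SEs of the difference
                tol = 3.0 * np.hypot(cde.loc[term, "se_log"], ate.loc[term, "se_log"])
                assert np.log(cde.loc[term, "estimate"]) == pytest.approx(
                    np.log(ate.loc[term, "estimate"]), abs=tol)

    def test_scenario_spec_contract(self):
        with pytest.raises(ValueError, match="fix the mediator"):
            ScenarioSpec(estimand="CDE")
        with pytest.raises(ValueError, match="must not fix"):
            ScenarioSpec(estimand="ATE", fixed_mediator="Grandparents")

    def test_empty_interaction_cell_raises(self, full_cohort):
        labels = _true_labels(full_cohort)
        mask = (full_cohort["education"] == "LowerStdGradesOrNone") \
            & (labels == "Single professional care")
        labels = np.where(mask, "Grandparents", labels)
        with pytest.raises(ValueError, match="empty education x typology"):
            estimate_cde(
                full_cohort, labels,
                compose_weights(full_cohort["design_weight"].to_numpy()),
                ScenarioSpec(estimand="CDE", fixed_mediator="Single professional care"))

    def test_zero_event_scenario_cell_raises_separation(self, full_cohort):
        labels = _true_labels(full_cohort)
        cohort = full_cohort.copy()
        mask = (cohort["education"] == "LowerStdGradesOrNone") \
            & (labels == "Single professional care")
        cohort.loc[mask, "outcome_raised_td"] = 0
        with pytest.raises(ValueError, match="separation"):
            estimate_cde(cohort, labels,
                         compose_weights(cohort["design_weight"].to_numpy()),
                         ScenarioSpec(estimand="CDE",
                                      fixed_mediator="Single professional care"))


def test_bias_shrinks_with_sample_size(default_params, truths):
    """Consistency: the ATE estimate approaches the planted value as n grows."""
    errs = []
    for n in (3205, 30_000, 120_000):
        p = default_params.copy()
        p.n_children = n
        logs = []
        for s in (61, 62, 63):
            cohort = generate_cohort(p, seed=s)
            efit = fit_exposure_propensity(cohort)
            wv = compose_weights(cohort["design_weight"].to_numpy(), efit)
            eff = estimate_ate(cohort, wv).effects.set_index("term")
            logs.append(np.log(eff.loc[LOWEST, "estimate"]))
        errs.append(abs(np.mean(logs) - np.log(truths["ate_lowest_or"])))
    assert errs[-1] < errs[0]
    assert errs[-1] < 0.05
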