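"""Survey-weighted multinomial and modified-Poisson estimators."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from careseq import generate_cohort
from careseq.inequality import (
    ModelSpec,
    fit_modified_poisson_rr,
    fit_weighted_multinomial,
)
from careseq.regression import (
    design_matrix,
    fit_weighted_glm,
    fit_weighted_multinomial_logit,
)


class TestWeightedMultinomialCore:
    def test_binary_equal_weight_reduction_matches_logit_mle(self, rng):
        n = 600
        x = rng.normal(size=n)
        eta = -0.4 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        X = np.column_stack([np.ones(n), x])
        fit = fit_weighted_multinomial_logit(X, y, np.ones(n), ["no", "yes"])
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.params[0], ref.params, atol=1e-6)

    def test_three_categories_recover_cell_frequencies(self, rng):
        n = 4000
        g = rng.integers(0, 2, n)
        probs = np.array([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]])
        u = rng.random(n)
        y = (u[:, None] > np.cumsum(probs[g], axis=1)).sum(axis=1)
        X = np.column_stack([np.ones(n), g.astype(float)])
        fit = fit_weighted_multinomial_logit(X, y, np.ones(n), ["a", "b", "c"])
        pred = fit.predict_proba(X)
        for gv in (0, 1):
            emp = np.bincount(y[g == gv], minlength=3) / (g == gv).sum()
            assert np.allclose(pred[g == gv][0], emp, atol=1e-6)

    def test_weight_rescaling_leaves_estimates_unchanged(self, rng):
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.integers(0, 3, n)
        w = rng.uniform(0.5, 2.0, n)
        a = fit_weighted_multinomial_logit(X, y, w, ["a", "b", "c"])
        b = fit_weighted_multinomial_logit(X, y, 11.0 * w, ["a", "b", "c"])
        assert np.allclose(a.params, b.params, atol=1e-6)


class TestMultinomialInequalities:
    def test_education_gradient_recovered(self, full_cohort, truths):
        from careseq.alphabet import TYPOLOGY_NAMES
        labels = np.array(list(TYPOLOGY_NAMES.values()))[
            full_cohort["latent_typology"] - 1]
        tab = fit_weighted_multinomial(full_cohort, labels)
        row = tab[(tab["typology"] == "Single professional care")
                  & (tab["term"] == "education[LowerStdGradesOrNone]")]
        est = float(row["estimate"].iloc[0])
        # single replicate: within a few sampling SDs of the planted 0.089
        assert 0.03 < est < 0.25
        assert float(row["ci_low"].iloc[0]) < est < float(row["ci_high"].iloc[0])

    def test_null_education_gives_or_near_one(self, small_cohort, rng):
        cov_ok = 0
        n_sim = 50
        for s in range(n_sim):
            df = small_cohort.copy()
            df["education"] = np.random.default_rng(s).permutation(
                df["education"].to_numpy())
            labels = np.where(df["latent_typology"] == 4,
                              "Single professional care", "Parents, friends & family")
            tab = fit_weighted_multinomial(df, labels, adjust_for_ethnicity=False)
            sub = tab[tab["term"].str.startswith("education[")]
            if ((sub["ci_low"] <= 1.0) & (1.0 <= sub["ci_high"])).all():
                cov_ok += 1
        assert cov_ok >= 0.9 * n_sim - 5

    def test_empty_cell_raises_named_error(self, small_cohort):
        labels = np.where(small_cohort["latent_typology"] == 1,
                          "Parents, friends & family", "Grandparents")
        df = small_cohort.copy()
        mask = (df["education"] == "Degree") & (labels == "Grandparents")
        labels = np.where(mask, "Parents, friends & family", labels)
        with pytest.raises(ValueError, match="empty.*cell"):
            fit_weighted_multinomial(df, labels)


class TestModifiedPoisson:
    def test_two_by_two_risk_ratio_exact(self):
        # exposed risk 0.2, unexposed 0.1 -> RR exactly 2
        rows = []
        for typ, risk, n in (("Private group childcare", 0.2, 200),
                             ("Parents, friends & family", 0.1, 200)):
            for i in range(n):
                rows.append({"typology_": typ, "y": int(i < risk * n)})
        df = pd.DataFrame(rows)
        X, names = design_matrix(df, categorical={"typology_": "Parents, friends & family"})
        fit = fit_weighted_glm(X, df["y"].to_numpy(float), np.ones(len(df)),
                               family="poisson", names=names)
        assert fit.table().set_index("term").loc[
            "typology_[Private group childcare]", "estimate"] == pytest.approx(2.0, abs=1e-9)

    def test_sandwich_close_to_model_se_when_correctly_specified(self, rng):
        # true Poisson data, equal weights: robust and model-based SEs agree
        n = 10_000
        x = rng.integers(0, 2, n).astype(float)
        mu = np.exp(-1.5 + 0.4 * x)
        y = rng.poisson(mu)
        X = np.column_stack([np.ones(n), x])
        fit = fit_weighted_glm(X, y.astype(float), np.ones(n), family="poisson")
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(fit.params, ref.params, atol=1e-6)
        assert np.sqrt(fit.cov[1, 1]) == pytest.approx(ref.bse[1], rel=0.10)

    def test_rr_cis_cover_one_under_null(self, default_params):
        # outcome independent of the typology (and of everything upstream of
        # it, so that no marginal association leaks through education)
        p = default_params.copy()
        p.n_children = 1200
        oc = p.outcome_coefs
        oc["education"] = [0.0] * 3
        oc["typology"] = [0.0] * 3
        oc["interaction"] = [[0.0] * 3 for _ in range(3)]
        for key, val in list(oc["confounders"].items()):
            if isinstance(val, dict):
                oc["confounders"][key] = {k: 0.0 for k in val}
            elif not key.endswith("_center"):
                oc["confounders"][key] = 0.0
        from careseq.alphabet import TYPOLOGY_NAMES
        names = np.array(list(TYPOLOGY_NAMES.values()))
        covered = []
        n_sim = 40
        for s in range(n_sim):
            cohort = generate_cohort(p, seed=1000 + s)
            labels = names[cohort["latent_typology"] - 1]
            tab = fit_modified_poisson_rr(
                cohort, labels, ModelSpec(outcome="outcome_raised_td",
                                          adjustment_set="unadjusted"))
            sub = tab[tab["term"].str.startswith("typology[")]
            covered.append(((sub["ci_low"] <= 1.0) & (1.0 <= sub["ci_high"])).to_numpy())
        # per-interval 95% coverage under the null, with binomial slack at 40 sims
        per_term = np.asarray(covered).mean(axis=0)
        assert (per_term >= 0.85).all()
        assert per_term.mean() >= 0.90

    def test_weight_rescaling_invariance(self, full_cohort):
        from careseq.alphabet import TYPOLOGY_NAMES
        labels = np.array(list(TYPOLOGY_NAMES.values()))[
            full_cohort["latent_typology"] - 1]
        a = fit_modified_poisson_rr(full_cohort, labels)
        scaled = full_cohort.copy()
        scaled["design_weight"] *= 7.0
        b = fit_modified_poisson_rr(scaled, labels)
        assert np.allclose(a["estimate"], b["estimate"], atol=1e-8)


def test_reference_swap_inverts_odds_ratio(rng):
    n = 800
    g = rng.integers(0, 2, n)
    y = (rng.random(n) < np.where(g == 1, 0.4, 0.2)).astype(int)
    df = pd.DataFrame({"grp": np.where(g == 1, "B", "A"), "y": y})
    ors = {}
    for ref, other in (("A", "B"), ("B", "A")):
        X, names = design_matrix(df, categorical={"grp": ref})
        fit = fit_weighted_glm(X, df["y"].to_numpy(float), np.ones(n),
                               family="binomial", names=names)
        ors[ref] = float(np.exp(fit.params[names.index(f"grp[{other}]")]))
    assert ors["A"] == pytest.approx(1.0 / ors["B"], rel=1e-9)


def test_model_spec_rejects_unknown_adjustment():
    with pytest.raises(ValueError, match="adjustment_set"):
        ModelSpec(outcome="y", adjustment_set="everything")
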