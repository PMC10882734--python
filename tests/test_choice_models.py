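"""Logistic and multinomial-logit choice models: closed-form saturated
identities, independent-library cross-checks, optimiser contracts, and
separation handling."""

import numpy as np
import pandas as pd
import pytest

from carecov.choice_models import (
    GRAD_TOL,
    build_design,
    fit_binary_choice,
    fit_multinomial_choice,
    preference_choice_models,
    render_table,
)
from carecov.synthetic.survey import ChoiceDGP, gen_respondents


def binary_frame(rng, n=800, p_x=0.4, beta=0.7, alpha=-0.3):
    x = (rng.random(n) < p_x).astype(float)
    p = 1 / (1 + np.exp(-(alpha + beta * x)))
    y = np.where(rng.random(n) < p, "non_bpjs_partner", "bpjs_partner")
    return pd.DataFrame({"x": x, "y": y})


class TestSaturatedIdentities:
    def test_binary_single_covariate_equals_cross_product_ratio(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            df = binary_frame(rng, n=int(rng.integers(200, 1200)))
            tab = pd.crosstab(df.x, df.y)
            if (tab.to_numpy() == 0).any():
                continue
            cpr = (tab.loc[1.0, "non_bpjs_partner"] * tab.loc[0.0, "bpjs_partner"]) / (
                tab.loc[0.0, "non_bpjs_partner"] * tab.loc[1.0, "bpjs_partner"]
            )
            m = fit_binary_choice(df, "y", ["x"])
            assert m.exp_effect("non_bpjs_partner", "x") == pytest.approx(cpr, abs=1e-6, rel=1e-6)

    def test_multinomial_saturated_equals_category_cross_products(self):
        rng = np.random.default_rng(1)
        cats = ["bpjs_partner", "pharmacy", "self_medication"]
        for _ in range(10):
            n = 900
            x = (rng.random(n) < 0.5).astype(float)
            probs = rng.dirichlet(np.ones(3), size=2)  # per level of x
            y = np.array([cats[rng.choice(3, p=probs[int(v)])] for v in x])
            df = pd.DataFrame({"x": x, "y": y})
            tab = pd.crosstab(df.x, df.y)
            if (tab.to_numpy() == 0).any():
                continue
            m = fit_multinomial_choice(df, "y", ["x"], reference="bpjs_partner")
            for cat in cats[1:]:
                cpr = (tab.loc[1.0, cat] * tab.loc[0.0, "bpjs_partner"]) / (
                    tab.loc[0.0, cat] * tab.loc[1.0, "bpjs_partner"]
                )
                assert m.exp_effect(cat, "x") == pytest.approx(cpr, abs=1e-6, rel=1e-6)

    def test_two_category_multinomial_collapses_to_binary(self):
        rng = np.random.default_rng(2)
        df = binary_frame(rng, n=600)
        df["z"] = rng.normal(size=600)
        mb = fit_binary_choice(df, "y", ["x", "z"])
        mm = fit_multinomial_choice(df, "y", ["x", "z"], reference="bpjs_partner")
        pd.testing.assert_series_equal(
            mb.table.coef, mm.table.coef, rtol=1e-6, atol=1e-8
        )


class TestAgainstStatsmodels:
    def test_binary_coefficients_and_se(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        df = binary_frame(rng, n=2000)
        df["z"] = rng.normal(size=2000)
        m = fit_binary_choice(df, "y", ["x", "z"])
        X = sm.add_constant(df[["x", "z"]])
        ref = sm.Logit((df.y == "non_bpjs_partner").astype(float), X).fit(disp=0)
        assert np.allclose(m.table.coef, ref.params.values, atol=1e-6)
        assert np.allclose(m.table.se, ref.bse.values, atol=1e-6)

    def test_multinomial_coefficients(self):
        import statsmodels.api as sm

        dgp = ChoiceDGP(
            intercepts={"pharmacy": -1.0, "self_medication": -0.2, "non_bpjs_partner": -0.7},
            covariate_effects={"self_medication": {"pbi": 0.8},
                               "non_bpjs_partner": {"pbi": -0.5}},
        )
        df = gen_respondents(4000, choice_dgps={"mild": dgp},
                             covariate_dists={"pbi": {"kind": "bern", "p": 0.6}},
                             missing_rates={}, seed=4)
        m = fit_multinomial_choice(df, "choice_mild", ["pbi"])
        # code the outcome so category 0 is the reference: statsmodels'
        # column j then matches our non-reference category j+1
        y = pd.Categorical(df.choice_mild, categories=m.categories)
        X = sm.add_constant(df[["pbi"]].astype(float))
        ref = sm.MNLogit(np.asarray(y.codes), X).fit(disp=0)
        mine = m.table.coef.to_numpy().reshape(len(m.categories) - 1, 2)
        theirs = ref.params.to_numpy().T
        assert np.allclose(mine, theirs, atol=1e-5)


class TestOptimiserContracts:
    def test_gradient_zero_and_probabilities_sum_to_one(self, survey_2000):
        m = fit_multinomial_choice(
            survey_2000, "choice_mild", ["age", "chronic_illness", "other_insurance"]
        )
        assert m.converged
        assert np.allclose(m.fitted_probabilities.sum(axis=1), 1.0, atol=1e-10)
        # recompute the score at the optimum: must be numerically zero
        sub = survey_2000[["choice_mild", "age", "chronic_illness", "other_insurance"]].dropna()
        X, _ = build_design(sub, ["age", "chronic_illness", "other_insurance"])
        Y = np.zeros((len(sub), len(m.categories)))
        for i, v in enumerate(sub.choice_mild):
            Y[i, m.categories.index(v)] = 1
        g = (Y[:, 1:] - m.fitted_probabilities[:, 1:]).T @ X
        assert np.abs(g).max() < GRAD_TOL

    def test_exponentiated_effect_and_ci_ordering(self, survey_2000):
        m = fit_binary_choice(survey_2000, "choice_actual", ["age", "pbi"])
        t = m.table[~m.table.withheld]
        assert np.allclose(t.exp_coef, np.exp(t.coef), rtol=1e-10)
        assert ((t.ci_low < t.exp_coef) & (t.exp_coef < t.ci_high)).all()

    def test_null_dgp_aor_near_one_with_ci_coverage(self):
        dgp = ChoiceDGP(intercepts={"non_bpjs_partner": 0.1})
        df = gen_respondents(20000, choice_dgps={"actual": dgp},
                             covariate_dists={"pbi": {"kind": "bern", "p": 0.5}},
                             missing_rates={}, seed=6)
        m = fit_binary_choice(df, "choice_actual", ["pbi"])
        row = m.table[m.table.term == "pbi"].iloc[0]
        assert 0.9 < row.exp_coef < 1.1
        assert row.ci_low <= 1.0 <= row.ci_high


class TestDegenerateDesigns:
    def test_separation_flagged_and_estimates_withheld(self):
        x = np.array([0.0] * 30 + [1.0] * 30)
        y = np.where(x == 1, "non_bpjs_partner", "bpjs_partner")
        m = fit_binary_choice(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert not m.converged
        assert "non_bpjs_partner" in m.separation
        assert m.table.withheld.all()

    def test_rank_deficiency_names_offenders(self):
        rng = np.random.default_rng(7)
        df = binary_frame(rng, 200)
        df["x2"] = df["x"]
        with pytest.raises(ValueError, match="x2"):
            fit_binary_choice(df, "y", ["x", "x2"])

    def test_missing_reference_category_rejected(self):
        df = pd.DataFrame({"y": ["a", "b"] * 20, "x": [0.0, 1.0] * 20})
        with pytest.raises(ValueError, match="reference"):
            fit_multinomial_choice(df, "y", ["x"], reference="bpjs_partner")

    def test_categorical_covariate_dummy_reference(self):
        rng = np.random.default_rng(8)
        df = binary_frame(rng, 500)
        df["edu"] = rng.choice(["higher", "primary", "secondary"], 500)
        m = fit_binary_choice(df, "y", ["x", "edu"],
                              reference_levels={"edu": "primary"})
        terms = set(m.table.term)
        assert "edu[higher]" in terms and "edu[secondary]" in terms
        assert "edu[primary]" not in terms

    def test_listwise_deletion_reports_n(self, survey_2000):
        m = fit_binary_choice(survey_2000, "choice_actual", ["age", "pbi"])
        assert m.n == len(survey_2000[["choice_actual", "age", "pbi"]].dropna())


class TestPreferenceModels:
    def test_null_scores_give_unit_rrr(self):
        dgp = ChoiceDGP(intercepts={"self_medication": 0.0, "non_bpjs_partner": -0.3})
        df = gen_respondents(20000, choice_dgps={"chronic": dgp},
                             covariate_dists={}, missing_rates={}, seed=9)
        scores = df[[f"factor_chronic_{k}" for k in range(5)]].to_numpy()
        m = preference_choice_models(scores, df, "chronic")
        t = m.table[m.table.term.str.startswith("PC")]
        assert ((t.ci_low <= 1.0) & (1.0 <= t.ci_high)).all()
        assert np.abs(np.log(t.exp_coef)).max() < 0.1

    def test_misaligned_scores_rejected(self, survey_2000):
        with pytest.raises(ValueError, match="row-aligned"):
            preference_choice_models(np.zeros((10, 5)), survey_2000, "mild")

    def test_render_table_contains_stars_and_reference(self, survey_2000):
        m = fit_binary_choice(survey_2000, "choice_actual", ["pbi", "other_insurance"])
        text = render_table(m)
        assert "reference = bpjs_partner" in text
        assert "pbi" in text
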