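"""Cone-year classification, AICc machinery, and the three model families."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bearfall.models import (
    ModelSpec,
    aicc,
    akaike_weights,
    candidate_specs,
    classify_cone_year,
    fit_linear_weighted,
    fit_mixed,
    fit_quantile,
    lrt_random_effect,
    predict_contrast,
    rank_models,
)
from conftest import CONE_SERIES


class TestClassifyConeYear:
    def test_reference_series_ratings(self):
        counts = list(CONE_SERIES.items())
        ratings = dict(zip(CONE_SERIES, classify_cone_year(counts)))
        expected = {2000: "poor", 2001: "good", 2002: "poor", 2003: "good",
                    2004: "poor", 2005: "good", 2006: "good", 2007: "good",
                    2008: "poor", 2009: "good", 2010: "poor", 2011: "good"}
        assert ratings == expected

    def test_count_at_median_rates_good(self):
        # 8 is the overall median of the reference series and rates good
        counts = list(CONE_SERIES.items())
        ratings = dict(zip(CONE_SERIES, classify_cone_year(counts)))
        assert ratings[2005] == "good" and ratings[2007] == "good"

    def test_all_equal_counts_all_good(self):
        assert classify_cone_year([(y, 8) for y in range(4)]) == ["good"] * 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_cone_year([])


class TestAICcAndWeights:
    def test_closed_form(self):
        assert aicc(-5, 3, 10) == pytest.approx(20.0)

    def test_reduces_to_aic_for_large_n(self):
        assert aicc(-5, 3, 100_000) == pytest.approx(10 + 6, abs=1e-3)

    def test_extra_parameter_strictly_penalized(self):
        assert aicc(-5, 4, 50) > aicc(-5, 3, 50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-5, 3, 4)

    @pytest.mark.parametrize("deltas,top", [
        ([0, 2.19, 6.95], 0.73),
        ([0, 2.19, 4.89], 0.70),
        ([0, 3.84, 33.09], 0.87),
        ([0], 1.0),
    ])
    def test_weights_match_published_rounding(self, deltas, top):
        w = akaike_weights(deltas)
        assert round(float(w[0]), 2) == top
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([-1, 0])


def mc_dataset(n=60, seed=0, year_slope=0.0, noise=0.05):
    rng = np.random.default_rng(seed)
    years = rng.integers(0, 12, n)
    cones = np.array([CONE_SERIES[2000 + y] for y in years], dtype=float)
    sex = rng.choice(["F", "M"], n)
    mc = 0.6 + year_slope * years + rng.normal(0, noise, n)
    return pd.DataFrame({"MC": mc, "YEAR": years, "CONES": cones, "SEX": sex,
                         "w": rng.uniform(0.87, 1.0, n)})


class TestLinearWeighted:
    def spec(self, terms="CONES + C(SEX) + CONES:C(SEX) + YEAR", name="Base + YEAR"):
        return ModelSpec(response="MC", family="linear-weighted", name=name,
                         formula_terms=terms)

    def test_exact_fit_recovers_slope(self):
        df = mc_dataset(seed=1, noise=0.0)
        df["MC"] = 0.9 - 0.02 * df["YEAR"]
        fit = fit_linear_weighted(df, self.spec(), weights="w")
        assert fit.params["YEAR"] == pytest.approx(-0.02, abs=1e-10)
        assert np.abs(fit.extra["result"].resid).max() < 1e-10

    def test_matches_normal_equations_oracle(self):
        df = mc_dataset(n=15, seed=2, year_slope=-0.01)
        spec = ModelSpec(response="MC", family="linear-weighted", name="toy",
                         formula_terms="YEAR + CONES")
        fit = fit_linear_weighted(df, spec, weights="w")
        X = np.column_stack([np.ones(len(df)), df.YEAR, df.CONES])
        W = np.diag(df.w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ df.MC)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_equal_weights_match_unweighted(self):
        df = mc_dataset(seed=3, year_slope=-0.01)
        f_w = fit_linear_weighted(df, self.spec(), weights=np.full(len(df), 0.5))
        f_u = fit_linear_weighted(df, self.spec())
        assert np.allclose(f_w.params, f_u.params, atol=1e-10)

    def test_aliased_term_rejected(self):
        df = mc_dataset(seed=4)
        df["CONES"] = df["YEAR"] * 2.0  # perfectly collinear
        with pytest.raises(ValueError, match="rank"):
            fit_linear_weighted(df, self.spec("YEAR + CONES", "aliased"))


class TestQuantile:
    def int_spec(self, tau):
        return ModelSpec(response="y", family="quantile", name="intercept",
                         formula_terms="1", tau=tau)

    def test_intercept_only_median(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4, 100]})
        fit = fit_quantile(df, self.int_spec(0.5), n_boot=0)
        assert fit.params["Intercept"] == pytest.approx(3.0)

    def test_constant_response_returned_at_every_tau(self):
        df = pd.DataFrame({"y": [7.0] * 10})
        for tau in (0.1, 0.5, 0.9):
            fit = fit_quantile(df, self.int_spec(tau), n_boot=0)
            assert fit.params["Intercept"] == pytest.approx(7.0)

    def test_intercept_only_returns_sample_quantiles(self):
        rng = np.random.default_rng(5)
        y = np.sort(rng.uniform(200, 280, 201))
        df = pd.DataFrame({"y": y})
        for tau in (0.1, 0.5, 0.9):
            fit = fit_quantile(df, self.int_spec(tau), n_boot=0)
            # for n = 201 the tau-quantile order statistic is an exact minimizer
            assert fit.params["Intercept"] == pytest.approx(
                np.quantile(y, tau, method="inverted_cdf"), abs=1e-6)

    def test_slope_matches_bruteforce_checkloss_grid(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 40)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.3, 40)
        df = pd.DataFrame({"y": y, "x": x})
        spec = ModelSpec(response="y", family="quantile", name="slope",
                         formula_terms="x", tau=0.5)
        fit = fit_quantile(df, spec, n_boot=0)

        def loss(b0, b1):
            r = y - b0 - b1 * x
            return np.sum(r * (0.5 - (r < 0)))

        b0g = np.arange(1.0, 3.0, 0.02)
        b1g = np.arange(0.0, 1.0, 0.02)
        losses = np.array([[loss(b0, b1) for b1 in b1g] for b0 in b0g])
        i, j = np.unravel_index(losses.argmin(), losses.shape)
        assert fit.params["Intercept"] == pytest.approx(b0g[i], abs=0.04)
        assert fit.params["x"] == pytest.approx(b1g[j], abs=0.04)

    def test_bootstrap_se_positive_and_seeded(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"y": rng.normal(240, 10, 80),
                           "x": rng.uniform(0, 10, 80)})
        spec = ModelSpec(response="y", family="quantile", name="m",
                         formula_terms="x", tau=0.5)
        f1 = fit_quantile(df, spec, n_boot=50, seed=1)
        f2 = fit_quantile(df, spec, n_boot=50, seed=1)
        assert (f1.bse > 0).all()
        assert np.allclose(f1.bse, f2.bse)


def mixed_dataset(n_bears=30, n_days=30, re_sd=0.5, resid_sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_bears):
        u = rng.normal(0, re_sd)
        year = int(rng.integers(0, 12))
        cones = CONE_SERIES[2000 + year]
        sex = "F" if b % 2 == 0 else "M"
        for d in range(n_days):
            rows.append({"resp": 0.5 + u + rng.normal(0, resid_sd),
                         "bear_year": f"b{b}", "YEAR": year, "CONES": cones,
                         "SEX": sex})
    return pd.DataFrame(rows)


class TestMixed:
    def spec(self):
        return ModelSpec(response="resp", family="mixed-linear", name="Base",
                         formula_terms="CONES + C(SEX) + CONES:C(SEX)")

    def test_zero_variance_favors_fixed_effects(self):
        df = mixed_dataset(re_sd=0.0, seed=8)
        mixed = fit_mixed(df, self.spec())
        import statsmodels.formula.api as smf

        ols = smf.ols(self.spec().formula, data=df).fit()
        from bearfall.models import ModelFit

        fixed = ModelFit(spec=self.spec(), params=ols.params, bse=ols.bse,
                         cov=ols.cov_params(), loglik=float(ols.llf),
                         n=int(ols.nobs), K=len(ols.params) + 1,
                         aicc=aicc(ols.llf, len(ols.params) + 1, int(ols.nobs)))
        stat, p = lrt_random_effect(fixed, mixed)
        assert mixed.extra["group_var"] < 0.02
        assert p > 0.05

    def test_variance_components_recovered(self):
        df = mixed_dataset(n_bears=50, n_days=40, re_sd=0.5, resid_sd=0.5, seed=9)
        fit = fit_mixed(df, self.spec())
        ratio = fit.extra["group_var"] / 0.25
        assert 0.5 <= ratio <= 2.0

    def test_single_group_falls_back_to_ols(self):
        df = mixed_dataset(n_bears=1, seed=10)
        fit = fit_mixed(df, ModelSpec(response="resp", family="mixed-linear",
                                      name="intercept", formula_terms="1"))
        assert "fixed-effects" in fit.note

    def test_intercept_backtransform_is_median_scale(self):
        rng = np.random.default_rng(11)
        d = pd.DataFrame({"resp": np.log(rng.lognormal(np.log(1.4), 0.5, 2000)),
                          "g": ["a"] * 2000})
        fit = fit_mixed(d, ModelSpec(response="resp", family="mixed-linear",
                                     name="int", formula_terms="1"), groups="g")
        assert np.exp(fit.params["Intercept"]) == pytest.approx(1.4, rel=0.1)


class TestLRT:
    def test_boundary_arithmetic(self):
        df = mixed_dataset(n_bears=5, n_days=5, seed=12)
        spec = ModelSpec(response="resp", family="mixed-linear", name="Base",
                         formula_terms="CONES")
        fit = fit_mixed(df, spec)
        same = fit_mixed(df, spec)
        stat, p = lrt_random_effect(fit, same)
        assert stat == 0.0 and p == 0.5

    def test_known_statistic(self):
        from bearfall.models import ModelFit

        spec = ModelSpec(response="r", family="mixed-linear", name="m",
                         formula_terms="x")
        mk = lambda ll: ModelFit(spec=spec, params=pd.Series(dtype=float),
                                 bse=pd.Series(dtype=float), cov=pd.DataFrame(),
                                 loglik=ll, n=50, K=3, aicc=0.0)
        stat, p = lrt_random_effect(mk(-10.0), mk(-8.08))
        assert stat == pytest.approx(3.84)
        assert p == pytest.approx(0.5 * stats.chi2.sf(3.84, 1), abs=1e-6)
        assert p == pytest.approx(0.025, abs=5e-4)

    def test_non_nested_rejected(self):
        from bearfall.models import ModelFit

        s1 = ModelSpec(response="r", family="mixed-linear", name="a",
                       formula_terms="x")
        s2 = ModelSpec(response="r", family="mixed-linear", name="b",
                       formula_terms="x + z")
        mk = lambda s: ModelFit(spec=s, params=pd.Series(dtype=float),
                                bse=pd.Series(dtype=float), cov=pd.DataFrame(),
                                loglik=0.0, n=50, K=3, aicc=0.0)
        with pytest.raises(ValueError):
            lrt_random_effect(mk(s1), mk(s2))


class TestRanking:
    def test_year_effect_detected_in_most_replicates(self):
        wins = 0
        for r in range(60):
            df = mc_dataset(n=60, seed=100 + r, year_slope=-0.019, noise=0.08)
            fits = rank_models([
                fit_linear_weighted(df, sp, weights="w")
                for sp in candidate_specs("MC", "linear-weighted")
            ])
            order = [f.spec.name for f in fits]
            wins += order.index("Base") > 0  # a YEAR model ranks above Base
        assert wins >= 0.8 * 60

    def test_null_data_favors_base_plurality(self):
        top = {"Base": 0, "Base + YEAR": 0, "Base + YEAR + YEAR x CONES": 0}
        for r in range(60):
            df = mc_dataset(n=60, seed=500 + r, year_slope=0.0, noise=0.08)
            fits = rank_models([
                fit_linear_weighted(df, sp, weights="w")
                for sp in candidate_specs("MC", "linear-weighted")
            ])
            top[fits[0].spec.name] += 1
        assert top["Base"] == max(top.values())

    def test_weights_order_isomorphic_to_aicc(self):
        df = mc_dataset(n=60, seed=7, year_slope=-0.019)
        fits = rank_models([
            fit_linear_weighted(df, sp, weights="w")
            for sp in candidate_specs("MC", "linear-weighted")
        ])
        aiccs = [f.aicc for f in fits]
        ws = [f.akaike_weight for f in fits]
        assert aiccs == sorted(aiccs)
        assert ws == sorted(ws, reverse=True)
        assert fits[0].delta_aicc == 0.0
        assert sum(ws) == pytest.approx(1.0, abs=1e-9)

    def test_single_candidate_trivial(self):
        df = mc_dataset(n=30, seed=8)
        fit = fit_linear_weighted(df, candidate_specs("MC", "linear-weighted")[0],
                                  weights="w")
        ranked = rank_models([fit])
        assert ranked[0].akaike_weight == pytest.approx(1.0)

    def test_differing_n_rejected(self):
        df = mc_dataset(n=40, seed=9)
        f1 = fit_linear_weighted(df, candidate_specs("MC", "linear-weighted")[0])
        f2 = fit_linear_weighted(df.iloc[:30], candidate_specs("MC", "linear-weighted")[1])
        with pytest.raises(ValueError):
            rank_models([f1, f2])


class TestContrasts:
    def hand_fit(self):
        from bearfall.models import ModelFit

        names = ["Intercept", "YEAR"]
        return ModelFit(
            spec=ModelSpec(response="MC", family="linear-weighted", name="m",
                           formula_terms="YEAR"),
            params=pd.Series([1.0, 0.5], index=names),
            bse=pd.Series([0.1, 0.2], index=names),
            cov=pd.DataFrame(np.diag([0.01, 0.04]), index=names, columns=names),
            loglik=0.0, n=50, K=3, aicc=0.0,
        )

    def test_null_contrast(self):
        c = predict_contrast(self.hand_fit(), {"YEAR": 5}, {"YEAR": 5})
        assert c.estimate == 0.0
        assert c.ci_lower <= 0 <= c.ci_upper
        assert c.ci_lower == pytest.approx(-c.ci_upper)

    def test_linear_algebra_oracle(self):
        c = predict_contrast(self.hand_fit(), {"YEAR": 11}, {"YEAR": 0})
        assert c.estimate == pytest.approx(5.5)
        assert c.se == pytest.approx(2.2)
        assert c.ci_lower == pytest.approx(1.188, abs=1e-3)
        assert c.ci_upper == pytest.approx(9.812, abs=1e-3)

    def test_missing_term_rejected(self):
        with pytest.raises(ValueError):
            predict_contrast(self.hand_fit(), {"X": 1}, {"X": 0})

    def test_recovered_year_contrast_near_programmed_decline(self):
        ests = []
        for r in range(30):
            df = mc_dataset(n=60, seed=900 + r, year_slope=-0.019, noise=0.08)
            spec = ModelSpec(response="MC", family="linear-weighted",
                             name="Base + YEAR",
                             formula_terms="CONES + C(SEX) + CONES:C(SEX) + YEAR")
            fit = fit_linear_weighted(df, spec, weights="w")
            mean_cones = df.CONES.mean()
            c = predict_contrast(
                fit,
                {"YEAR": 11, "CONES": mean_cones, "C(SEX)[T.M]": 0.5},
                {"YEAR": 0, "CONES": mean_cones, "C(SEX)[T.M]": 0.5},
            )
            ests.append(c.estimate)
        assert np.mean(ests) == pytest.approx(-0.209, abs=0.02)
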