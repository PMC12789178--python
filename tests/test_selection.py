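"""Hatchling estimator, model suite, backward reduction, prediction bands."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chronest import (
    ModelSpec,
    SimulationConfig,
    Term,
    build_model_suite,
    estimate_hatchlings,
    fit_model,
    gen_biometric_tables,
    gen_population,
    simulate_prediction_band,
    stepwise_reduce,
    truth_chronotypes,
)
from chronest.selection import SelectionError, reduction_table


@pytest.fixture(scope="module")
def suite_tables():
    cfg = SimulationConfig(seed=50, n_females=120, n_years=3)
    truth, broods = gen_population(cfg)
    cond, nest = gen_biometric_tables(cfg, truth, broods)
    chrono = truth_chronotypes(truth, broods)
    return chrono, broods, cond, nest


class TestHatchlings:
    @pytest.mark.parametrize("c,m,u,expected", [(10, 8, 0, 9.0), (9, 7, 2, 7.0), (8, 8, 0, 8.0)])
    def test_formula(self, c, m, u, expected):
        assert estimate_hatchlings(c, m, u) == expected

    def test_inconsistent_counts_name_the_brood(self):
        with pytest.raises(SelectionError, match="B7"):
            estimate_hatchlings(
                np.array([10, 5]), np.array([8, 4]), np.array([0, 3]),
                brood_id=np.array(["B1", "B7"]),
            )

    @given(c=st.integers(0, 15), m=st.integers(0, 15), u=st.integers(0, 15))
    @settings(deadline=None, derandomize=True)
    def test_bounds_hold_on_valid_lattice(self, c, m, u):
        if c < m + u:
            return
        est = estimate_hatchlings(c, m, u)
        assert m <= est <= c - u
        assert est == m + (c - m - u) / 2


class TestTerms:
    def test_marginality_containment(self):
        C = Term({"chronotype": 1})
        C2 = Term({"chronotype": 2})
        CY = Term({"chronotype": 1, "year": 1})
        C2Y = Term({"chronotype": 2, "year": 1})
        Y = Term({"year": 1})
        assert C2.contains(C)
        assert C2Y.contains(C2) and C2Y.contains(CY) and C2Y.contains(Y) and C2Y.contains(C)
        assert CY.contains(C) and CY.contains(Y)
        assert not C.contains(C2)
        assert not Y.contains(C)
        assert not C2.contains(C2)


class TestSuite:
    def test_eight_specs_with_documented_term_sets(self, suite_tables):
        chrono, broods, cond, nest = suite_tables
        specs = build_model_suite(chrono, broods, cond, nest)
        assert len(specs) == 8
        by_name = {s.name: s for s in specs}
        base = {"intercept", "chronotype", "chronotype^2", "year",
                "chronotype:year", "chronotype^2:year"}
        names = lambda s: {t.name for t in s.terms}
        assert names(by_name["lay_date"]) == base
        assert names(by_name["clutch_size"]) == base | {"lay_date_c"}
        assert names(by_name["second_brood"]) == base | {"lay_date_c", "n_fledglings"}
        assert names(by_name["female_weight"]) == base | {
            "lay_date_c", "time_of_day", "time_of_day^2", "tarsus"}
        assert names(by_name["nestling_weight"]) == base | {
            "hatch_date_c", "chick_age", "n_fledglings", "time_of_day", "time_of_day^2"}
        assert by_name["fledge_success"].family == "binomial"
        assert by_name["nestling_weight"].family == "gaussian-mixed"

    def test_lay_date_model_has_no_lay_date_covariate(self, suite_tables):
        chrono, broods, _, _ = suite_tables
        specs = build_model_suite(chrono, broods)
        lay = next(s for s in specs if s.name == "lay_date")
        assert "lay_date_c" not in {t.name for t in lay.terms}

    def test_second_brood_rows_all_fledged(self, suite_tables):
        chrono, broods, _, _ = suite_tables
        specs = build_model_suite(chrono, broods)
        sb = next(s for s in specs if s.name == "second_brood")
        assert (sb.data["n_fledglings"] >= 1).all()

    def test_exclusion_counts(self, suite_tables):
        chrono, broods, _, _ = suite_tables
        specs = {s.name: s for s in build_model_suite(chrono, broods)}
        joined = broods.merge(chrono[["brood_id"]], on="brood_id")
        n_des = int((joined["deserted_flag"] == 1).sum())
        assert specs["hatchlings"].n == specs["lay_date"].n - n_des

    def test_missing_columns_reported(self, suite_tables):
        chrono, broods, _, _ = suite_tables
        with pytest.raises(SelectionError, match="clutch_size"):
            build_model_suite(chrono, broods.drop(columns=["clutch_size"]))


class TestFit:
    def test_gaussian_recovery_within_three_se(self):
        rng = np.random.default_rng(8)
        n = 10_000
        df = pd.DataFrame({"chronotype": rng.normal(0, 0.5, n),
                           "year": rng.choice([2020, 2021], n)})
        df["y"] = 2.0 + 3.0 * df["chronotype"] - 1.0 * df["chronotype"] ** 2 \
            + rng.normal(0, 1, n)
        terms = [Term(), Term({"chronotype": 1}), Term({"chronotype": 2})]
        fit = fit_model(ModelSpec("t", "y", "gaussian", terms, df))
        for name, truth in [("intercept", 2.0), ("chronotype", 3.0), ("chronotype^2", -1.0)]:
            assert abs(fit.params[name] - truth) < 3 * fit.bse[name]

    def test_binomial_recovery_within_three_se(self):
        rng = np.random.default_rng(9)
        n = 5000
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(0.5 + 1.2 * x)))
        df = pd.DataFrame({"chronotype": x, "y": rng.binomial(1, p), "year": 2020})
        fit = fit_model(ModelSpec("t", "y", "binomial",
                                  [Term(), Term({"chronotype": 1})], df))
        assert abs(fit.params["chronotype"] - 1.2) < 3 * fit.bse["chronotype"]

    def test_row_permutation_invariance(self, suite_tables):
        chrono, broods, _, _ = suite_tables
        specs = build_model_suite(chrono, broods)
        lay = next(s for s in specs if s.name == "lay_date")
        f1 = fit_model(lay)
        shuffled = ModelSpec(lay.name, lay.response, lay.family, lay.terms,
                             lay.data.sample(frac=1, random_state=0).reset_index(drop=True))
        f2 = fit_model(shuffled)
        assert np.allclose(f1.params, f2.params, atol=1e-8)

    def test_all_zero_binomial_response_flagged(self):
        df = pd.DataFrame({"chronotype": np.linspace(-1, 1, 40), "y": 0, "year": 2020})
        fit = fit_model(ModelSpec("t", "y", "binomial", [Term(), Term({"chronotype": 1})], df))
        assert any("degenerate" in f for f in fit.flags)

    def test_mixed_model_brood_intercept_shrinks_se(self):
        # siblings share a brood effect; ignoring it understates SEs
        rng = np.random.default_rng(10)
        broods = np.repeat(np.arange(60), 5)
        eff = rng.normal(0, 1.0, 60)[broods]
        df = pd.DataFrame({"brood_id": broods, "chronotype": rng.normal(0, 0.5, 300),
                           "year": 2020})
        df["y"] = 17 + eff + rng.normal(0, 0.5, 300)
        spec = ModelSpec("t", "y", "gaussian-mixed",
                         [Term(), Term({"chronotype": 1})], df, groups="brood_id")
        mixed = fit_model(spec)
        ols = fit_model(ModelSpec("t", "y", "gaussian", spec.terms, df))
        assert mixed.bse["intercept"] > ols.bse["intercept"]


class TestStepwise:
    def test_null_covariate_dropped_with_f_test_matching_direct_oracle(self):
        rng = np.random.default_rng(11)
        n = 120
        df = pd.DataFrame({"chronotype": rng.normal(0, 0.5, n), "year": 2020})
        df["y"] = 5 + rng.normal(0, 1, n)
        spec = ModelSpec("t", "y", "gaussian", [Term(), Term({"chronotype": 1})], df)
        fit = stepwise_reduce(spec)
        assert [t.name for t in fit.terms] == ["intercept"]
        tt = fit.reduction_path[0]
        # direct F-test oracle from the two residual sums of squares
        full = np.linalg.lstsq(np.column_stack([np.ones(n), df["chronotype"]]),
                               df["y"], rcond=None)
        red = np.linalg.lstsq(np.ones((n, 1)), df["y"], rcond=None)
        rss_f, rss_r = full[1][0], red[1][0]
        f_oracle = (rss_r - rss_f) / (rss_f / (n - 2))
        assert tt.stat == pytest.approx(f_oracle, rel=1e-10)
        assert tt.p == pytest.approx(stats.f.sf(f_oracle, 1, n - 2), rel=1e-10)

    def test_significant_quadratic_protects_linear(self):
        rng = np.random.default_rng(12)
        n = 400
        df = pd.DataFrame({"chronotype": rng.normal(0, 0.7, n), "year": 2020})
        df["y"] = 4 * df["chronotype"] ** 2 + rng.normal(0, 1, n)
        spec = ModelSpec("t", "y", "gaussian",
                         [Term(), Term({"chronotype": 1}), Term({"chronotype": 2})], df)
        fit = stepwise_reduce(spec)
        names = {t.name for t in fit.terms}
        assert "chronotype^2" in names and "chronotype" in names
        prot = [tt for tt in fit.reduction_path if tt.term.name == "chronotype"]
        assert prot and prot[0].protected

    def test_interaction_protects_its_components(self, suite_tables):
        chrono, broods, _, _ = suite_tables
        lay = next(s for s in build_model_suite(chrono, broods) if s.name == "lay_date")
        fit = fit_model(lay)
        droppable = [
            t for t in fit.terms
            if t.powers and not any(o.contains(t) for o in fit.terms)
        ]
        assert {t.name for t in droppable} == {"chronotype^2:year"}

    def test_reduction_path_deterministic(self, suite_tables):
        chrono, broods, _, _ = suite_tables
        lay = next(s for s in build_model_suite(chrono, broods) if s.name == "lay_date")
        t1 = reduction_table(stepwise_reduce(lay))
        t2 = reduction_table(stepwise_reduce(lay))
        pd.testing.assert_frame_equal(t1, t2)

    def test_every_term_in_path_or_final(self, suite_tables):
        chrono, broods, cond, nest = suite_tables
        for spec in build_model_suite(chrono, broods, cond, nest):
            fit = stepwise_reduce(spec)
            recorded = {tt.term.name for tt in fit.reduction_path}
            original = {t.name for t in spec.terms if t.powers}
            assert recorded == original
            dropped = {tt.term.name for tt in fit.reduction_path if tt.dropped}
            final = {t.name for t in fit.terms if t.powers}
            assert dropped | final == original and not dropped & final

    def test_force_retain_keeps_term(self):
        rng = np.random.default_rng(13)
        n = 100
        df = pd.DataFrame({"chronotype": rng.normal(0, 0.5, n),
                           "lay_date_c": rng.normal(0, 5, n), "year": 2020})
        df["y"] = 5 + rng.normal(0, 1, n)
        spec = ModelSpec("t", "y", "gaussian",
                         [Term(), Term({"lay_date_c": 1})], df)
        fit = stepwise_reduce(spec, force_retain=("lay_date_c",))
        assert "lay_date_c" in {t.name for t in fit.terms}


class TestPredictionBand:
    def test_zero_covariance_gives_zero_width(self):
        df = pd.DataFrame({"chronotype": np.linspace(-1, 1, 30), "year": 2020})
        df["y"] = 2 + df["chronotype"]
        fit = fit_model(ModelSpec("t", "y", "gaussian", [Term(), Term({"chronotype": 1})], df))
        fit.cov_params.loc[:, :] = 0.0
        band = simulate_prediction_band(fit, df, n_draws=100, seed=0)
        assert np.allclose(band["upper"] - band["lower"], 0.0)

    def test_binomial_band_within_unit_interval(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame({"chronotype": rng.normal(0, 1, 200), "year": 2020})
        df["y"] = rng.binomial(1, 0.5, 200)
        fit = fit_model(ModelSpec("t", "y", "binomial", [Term(), Term({"chronotype": 1})], df))
        band = simulate_prediction_band(fit, df, seed=1)
        assert (band[["lower", "upper", "predicted"]] >= 0).all().all()
        assert (band[["lower", "upper", "predicted"]] <= 1).all().all()

    def test_gaussian_band_matches_closed_form(self):
        rng = np.random.default_rng(15)
        n = 500
        df = pd.DataFrame({"chronotype": rng.normal(0, 1, n), "year": 2020})
        df["y"] = 1 + 2 * df["chronotype"] + rng.normal(0, 1, n)
        fit = fit_model(ModelSpec("t", "y", "gaussian", [Term(), Term({"chronotype": 1})], df))
        new = pd.DataFrame({"chronotype": [-1.0, 0.0, 1.0], "year": 2020})
        band = simulate_prediction_band(fit, new, n_draws=40_000, seed=2)
        X = np.column_stack([np.ones(3), new["chronotype"]])
        se = np.sqrt(np.diag(X @ fit.cov_params.to_numpy() @ X.T))
        mu = X @ fit.params.to_numpy()
        assert np.allclose(band["lower"], mu - 1.96 * se, atol=0.02)
        assert np.allclose(band["upper"], mu + 1.96 * se, atol=0.02)

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame({"chronotype": rng.normal(0, 1, 100), "year": 2020})
        df["y"] = df["chronotype"] + rng.normal(0, 1, 100)
        fit = fit_model(ModelSpec("t", "y", "gaussian", [Term(), Term({"chronotype": 1})], df))
        b1 = simulate_prediction_band(fit, df, seed=3)
        b2 = simulate_prediction_band(fit, df, seed=3)
        pd.testing.assert_frame_equal(b1, b2)
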