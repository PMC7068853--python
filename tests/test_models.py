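"""Humidity-structure model family: designs, ML fitting, AIC selection."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from floralhum import lmm, models, simulate


class TestSpecs:
    def test_family_sizes(self):
        assert len(models.X_SPECS) == 11
        assert len(models.Z_SPECS) == 5

    @pytest.mark.parametrize(
        "mid,terms",
        [
            ("m0", "I"), ("m1", "I A"), ("m2", "I B"), ("m3", "I A B"),
            ("m4", "I r2 r3 r4"), ("m5", "I A r2 r3 r4"),
            ("m6", "I B r2 r3 r4"), ("m7", "I A B r2 r3 r4"),
            ("m8", "I A r2 r3 r4 g2 g3 g4"),
            ("m9", "I B r2 r3 r4 c2 c3 c4"),
            ("m10", "I A B r2 r3 r4 g2 g3 g4 c2 c3 c4"),
            ("z0", "I"), ("z1", "I B"), ("z2", "I r2 r3 r4"),
            ("z3", "I B r2 r3 r4"), ("z4", "I B r2 r3 r4 c2 c3 c4"),
        ],
    )
    def test_included_terms_match_family_table(self, mid, terms):
        assert models.get_spec(mid).column_names == terms.split()

    def test_interactions_require_main_terms(self):
        with pytest.raises(models.ModelFamilyError):
            models.ModelSpec("x", "bad", has_A=False, has_B=False,
                             has_r=True, has_g=True, has_c=False)


class TestBuildDesign:
    def test_m0_single_intercept_column(self):
        X = models.build_design(models.get_spec("m0"), [0, 5], [1, 2])
        np.testing.assert_array_equal(X, [[1.0], [1.0]])

    def test_m10_replicate1_row(self):
        X = models.build_design(models.get_spec("m10"), [-30.0], [1])
        np.testing.assert_array_equal(
            X[0], [1, -30, 900, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        )

    def test_m10_replicate3_row_activates_interactions(self):
        X = models.build_design(models.get_spec("m10"), [10.0], [3])
        np.testing.assert_array_equal(
            X[0], [1, 10, 100, 0, 1, 0, 0, 10, 0, 0, 100, 0]
        )

    def test_z3_log_design_row(self):
        X = models.build_design(models.get_spec("z3"), [5.0], [3])
        np.testing.assert_allclose(X[0], [1.0, np.log(5.0), 0.0, 1.0, 0.0])

    def test_axis_validation(self):
        with pytest.raises(models.ModelFamilyError, match="positive"):
            models.build_design(models.get_spec("z1"), [0.0], [1])
        with pytest.raises(models.ModelFamilyError, match="1..4"):
            models.build_design(models.get_spec("m0"), [0.0], [5])


def _sim_records(mid, params, seed, **kw):
    return simulate.generate_delta_rh_records(mid, params, seed=seed, **kw)


class TestFitModel:
    def test_constant_response_hits_boundary(self):
        recs = _sim_records("m0", {"I": 2.5}, seed=0, flower_sd=0.0,
                            resid_sd=0.0)
        fit = models.fit_model(models.get_spec("m0"), recs)
        assert fit.fixed_effects["I"] == pytest.approx(2.5)
        assert fit.boundary
        assert fit.sigma2_flower == 0.0

    def test_no_group_variance_reduces_to_ols(self):
        recs = _sim_records("m2", {"I": 1.0, "B": -0.002}, seed=1,
                            flower_sd=0.0, resid_sd=0.05)
        fit = models.fit_model(models.get_spec("m2"), recs)
        y = np.array([r.delta_rh for r in recs])
        X = models.build_design(
            models.get_spec("m2"),
            [r.offset for r in recs],
            [r.replicate for r in recs],
        )
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        if fit.boundary:
            np.testing.assert_allclose(
                [fit.fixed_effects["I"], fit.fixed_effects["B"]],
                beta_ols, atol=1e-8,
            )
        # truth within 3 standard errors either way
        se = np.sqrt(np.diag(fit.lmm.beta_cov))
        assert abs(fit.fixed_effects["I"] - 1.0) < 3 * se[0]
        assert abs(fit.fixed_effects["B"] + 0.002) < 3 * se[1]

    def test_loglik_matches_dense_mvn_oracle(self):
        recs = _sim_records("m6", {"I": 1.0, "B": -0.002, "r2": 0.2,
                                   "r3": -0.1, "r4": -0.3},
                            n_flowers=4, seed=2, flower_sd=0.15,
                            resid_sd=0.05)
        spec = models.get_spec("m6")
        fit = models.fit_model(spec, recs)
        y = np.array([r.delta_rh for r in recs])
        X = models.build_design(spec, [r.offset for r in recs],
                                [r.replicate for r in recs])
        flowers = np.array([r.flower_id for r in recs])
        _, codes = np.unique(flowers, return_inverse=True)
        Z = np.eye(codes.max() + 1)[codes]
        cov = fit.sigma2 * np.eye(len(y)) + fit.sigma2_flower * (Z @ Z.T)
        beta = np.array([fit.fixed_effects[c] for c in spec.column_names])
        oracle = multivariate_normal.logpdf(y, mean=X @ beta, cov=cov)
        assert fit.log_likelihood == pytest.approx(oracle, abs=1e-6)
        blockwise = lmm.marginal_loglik(
            y, X, flowers, beta, fit.sigma2, fit.sigma2_flower
        )
        assert blockwise == pytest.approx(oracle, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        recs = _sim_records("m7", {"I": 1.0, "A": 0.01, "B": -0.002,
                                   "r2": 0.3, "r3": -0.2, "r4": -0.4},
                            seed=3, flower_sd=0.2, resid_sd=0.05)
        spec = models.get_spec("m7")
        fit = models.fit_model(spec, recs)
        y = np.array([r.delta_rh for r in recs])
        X = models.build_design(spec, [r.offset for r in recs],
                                [r.replicate for r in recs])
        groups = np.array([r.flower_id for r in recs])
        sm_fit = sm.MixedLM(y, X, groups).fit(reml=False)
        assert fit.log_likelihood == pytest.approx(sm_fit.llf, abs=1e-4)
        np.testing.assert_allclose(
            np.array([fit.fixed_effects[c] for c in spec.column_names]),
            sm_fit.fe_params, rtol=1e-4, atol=1e-6,
        )

    def test_aic_parameter_count(self):
        recs = _sim_records("m2", {"I": 1.0, "B": -0.002}, seed=4)
        fit = models.fit_model(models.get_spec("m2"), recs)
        # k = 2 fixed effects + 2 variance components
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * 4)

    def test_missing_replicate_levels_named(self):
        recs = _sim_records("m2", {"I": 1.0, "B": -0.002}, seed=5,
                            replicates=(1, 2))
        with pytest.raises(models.ModelFamilyError, match=r"\[3, 4\]"):
            models.fit_model(models.get_spec("m6"), recs)

    def test_nesting_never_decreases_loglik(self):
        nested_pairs = [("m0", "m1"), ("m1", "m3"), ("m2", "m6"),
                        ("m6", "m7"), ("m7", "m10"), ("m5", "m8"),
                        ("z0", "z1"), ("z1", "z3"), ("z3", "z4")]
        for seed in range(4):
            recs_x = _sim_records(
                "m7", {"I": 1.0, "A": 0.01, "B": -0.002, "r2": 0.2,
                       "r3": -0.1, "r4": -0.2}, seed=seed)
            recs_z = _sim_records("z3", {"I": 1.0, "B": -0.3, "r2": 0.1,
                                         "r3": -0.1, "r4": -0.2}, seed=seed)
            for small, large in nested_pairs:
                recs = recs_x if small.startswith("m") else recs_z
                ll_small = models.fit_model(models.get_spec(small),
                                            recs).log_likelihood
                ll_large = models.fit_model(models.get_spec(large),
                                            recs).log_likelihood
                assert ll_large >= ll_small - 1e-6, (small, large, seed)

    def test_x_reflection_symmetry(self):
        recs = _sim_records("m1", {"I": 1.0, "A": 0.02}, seed=6)
        fit = models.fit_model(models.get_spec("m1"), recs)
        flipped = [
            type(r)(r.flower_id, r.species_id, r.replicate, r.axis,
                    -r.offset, r.delta_rh, r.within_period_sd, r.n_readings)
            for r in recs
        ]
        fit_f = models.fit_model(models.get_spec("m1"), flipped)
        assert fit_f.fixed_effects["A"] == pytest.approx(
            -fit.fixed_effects["A"], rel=1e-8)
        assert fit_f.fixed_effects["I"] == pytest.approx(
            fit.fixed_effects["I"], rel=1e-8)
        assert fit_f.aic == pytest.approx(fit.aic, abs=1e-6)


class TestSelectBest:
    def test_chosen_has_zero_delta_aic(self):
        recs = _sim_records("m6", {"I": 1.0, "B": -0.002, "r2": 0.2,
                                   "r3": -0.1, "r4": -0.3}, seed=7)
        sel = models.select_best(recs, "x")
        assert sel.chosen in sel.best_set
        deltas = {row["id"]: row["delta_aic"] for row in sel.table
                  if not row["failed"]}
        assert deltas[sel.chosen] == pytest.approx(0.0)
        assert all(d >= 0 for d in deltas.values())

    def test_structureless_data_selects_null_by_parsimony(self):
        # with no structure at all, every model fits equally well and
        # the smallest parameter count must win the AIC comparison
        recs = _sim_records("m0", {"I": 0.3}, n_flowers=4, seed=8,
                            flower_sd=0.0, resid_sd=0.0)
        sel = models.select_best(recs, "x")
        assert sel.chosen == "m0"

    def test_strong_m6_truth_recovered(self):
        recs = _sim_records("m6", {"I": 1.0, "B": -0.003, "r2": 0.4,
                                   "r3": -0.3, "r4": -0.6}, seed=9,
                            flower_sd=0.1, resid_sd=0.05)
        sel = models.select_best(recs, "x")
        assert "m6" in sel.best_set

    def test_failed_specs_stay_in_table(self):
        recs = _sim_records("m2", {"I": 1.0, "B": -0.002}, seed=10,
                            replicates=(1, 2))
        sel = models.select_best(recs, "x")
        failed = [row["id"] for row in sel.table if row["failed"]]
        assert set(failed) == {"m4", "m5", "m6", "m7", "m8", "m9", "m10"}
        assert sel.chosen in ("m0", "m1", "m2", "m3")

    def test_mixed_species_rejected(self):
        a = _sim_records("m0", {"I": 0.0}, seed=11, species_id="a")
        b = _sim_records("m0", {"I": 0.0}, seed=12, species_id="b")
        with pytest.raises(models.ModelFamilyError, match="one species"):
            models.select_best(a + b, "x")


class TestLMMCore:
    def test_singular_design_names_aliased_column(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(lmm.LMMError, match="dup"):
            lmm.fit_random_intercept(
                rng.normal(size=30), X, np.repeat([0, 1, 2], 10),
                column_names=["I", "x", "dup"],
            )

    def test_single_group_falls_back_to_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ [1.0, 2.0] + rng.normal(0, 0.1, 20)
        fit = lmm.fit_random_intercept(y, X, np.zeros(20))
        assert fit.single_group and fit.boundary
        np.testing.assert_allclose(
            fit.beta, np.linalg.lstsq(X, y, rcond=None)[0], atol=1e-10
        )

    def test_recovers_variance_components(self):
        rng = np.random.default_rng(2)
        g, n = 40, 25
        u = rng.normal(0, 0.5, g)
        codes = np.repeat(np.arange(g), n)
        y = 2.0 + u[codes] + rng.normal(0, 0.2, g * n)
        fit = lmm.fit_random_intercept(y, np.ones((g * n, 1)), codes)
        assert np.sqrt(fit.sigma2) == pytest.approx(0.2, rel=0.1)
        assert np.sqrt(fit.sigma2_group) == pytest.approx(0.5, rel=0.25)
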