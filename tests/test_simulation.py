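import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ratiomi import simulation as sim
from ratiomi.simulation import _expected_auc


class TestGenerator:
    def test_denominator_cv_matches_lognormal_theory(self):
        # log SD 0.11 implies CV(a2) = sqrt(exp(0.11^2) - 1) ~= 0.110,
        # the "CV = 0.1" regime; the high-CV preset hits 0.3 exactly
        assert sim.component_cv(0.11) == pytest.approx(0.1103, abs=2e-4)
        assert sim.component_cv(sim.EPIC_LOG_SD_A2) == pytest.approx(0.3)

    def test_components_match_log_scale_parameters(self):
        cfg = sim.make_config(0.1, "MCAR", n=100_000, seed=0)
        a1, a2, x = sim.gen_components(cfg, np.random.default_rng(1))
        l1, l2 = np.log(a1), np.log(a2)
        assert l1.mean() == pytest.approx(4.0, abs=3 * 0.21 / np.sqrt(1e5))
        assert l2.mean() == pytest.approx(0.97, abs=3 * 0.11 / np.sqrt(1e5))
        assert np.corrcoef(l1, l2)[0, 1] == pytest.approx(0.22, abs=0.01)
        np.testing.assert_allclose(x, a1 / a2, rtol=1e-12)

    def test_zero_log_corr_gives_independent_components(self):
        cfg = sim.make_config(0.1, "MCAR", n=100_000, log_corr=0.0, seed=0)
        a1, a2, _ = sim.gen_components(cfg, np.random.default_rng(2))
        r = np.corrcoef(np.log(a1), np.log(a2))[0, 1]
        assert abs(r) < 3 / np.sqrt(100_000)

    def test_outcome_hits_target_r_squared(self):
        for r2 in (0.1, 0.5):
            cfg = sim.make_config(r2, "MCAR", n=100_000, seed=0)
            g = np.random.default_rng(3)
            _, _, x = sim.gen_components(cfg, g)
            _, var_x = sim.ratio_moments(cfg)
            y = sim.gen_outcome(x, cfg.beta1, r2, g, var_x)
            resid = y - 2.0 * x
            r2_emp = 1 - resid.var() / y.var()
            assert r2_emp == pytest.approx(r2, abs=0.005)

    def test_r2_half_splits_variance_equally(self):
        cfg = sim.make_config(0.5, "MCAR")
        _, var_x = sim.ratio_moments(cfg)
        assert sim.residual_variance(cfg) == pytest.approx(cfg.beta1**2 * var_x)


class TestMissingness:
    def test_mcar_params_are_logit_of_response_prob(self):
        p = sim.mcar_params(0.75)
        assert p.gamma1 == 0.0
        assert p.gamma0 == pytest.approx(logit(0.75))  # ~1.0986

    def test_zero_gamma1_gives_auc_half(self):
        y = np.sort(np.random.default_rng(0).standard_normal(10_000))
        assert _expected_auc(expit(1.0986 + 0.0 * y)) == pytest.approx(0.5, abs=1e-9)

    def test_mcar_missing_fraction_is_seven_sixteenths(self):
        cfg = sim.make_config(0.1, "MCAR", n=100_000, seed=0)
        g = np.random.default_rng(5)
        _, _, x = sim.gen_components(cfg, g)
        _, var_x = sim.ratio_moments(cfg)
        y = sim.gen_outcome(x, 2.0, 0.1, g, var_x)
        r1, r2 = sim.gen_missingness(y, sim.mcar_params(), g)
        frac = np.mean(~(r1 & r2))
        se = np.sqrt(0.4375 * 0.5625 / 100_000)
        assert abs(frac - 0.4375) < 4 * se

    def test_calibrated_mar_hits_auc_on_fresh_draw(self):
        cfg = sim.make_config(0.1, "MAR", cv_a2=0.1)
        params = sim.calibrate_mar(cfg)
        g = np.random.default_rng(6)
        big = sim.make_config(0.1, "MAR", cv_a2=0.1, n=100_000)
        _, _, x = sim.gen_components(big, g)
        _, var_x = sim.ratio_moments(cfg)
        y = sim.gen_outcome(x, 2.0, 0.1, g, var_x)
        r1, _ = sim.gen_missingness(y, params, g)
        auc = sim.empirical_auc(y, r1)
        assert abs(max(auc, 1 - auc) - 0.65) < 0.01
        assert abs(r1.mean() - 0.75) < 0.01

    def test_mar_inflates_simultaneous_missingness(self):
        # gamma1 common to both indicators induces positive dependence, so
        # P(both missing) exceeds the MCAR product 0.25^2
        cfg = sim.make_config(0.1, "MAR", cv_a2=0.1)
        params = sim.calibrate_mar(cfg)
        g = np.random.default_rng(7)
        big = sim.make_config(0.1, "MAR", cv_a2=0.1, n=200_000)
        _, _, x = sim.gen_components(big, g)
        _, var_x = sim.ratio_moments(cfg)
        y = sim.gen_outcome(x, 2.0, 0.1, g, var_x)
        r1, r2 = sim.gen_missingness(y, params, g)
        both = np.mean(~r1 & ~r2)
        assert both > 0.0625
        # and the missing-ratio fraction is correspondingly below 43.75%
        assert np.mean(~(r1 & r2)) < 0.4375

    def test_huge_gamma1_is_step_function(self):
        y = np.linspace(-1, 1, 1001)
        r1, _ = sim.gen_missingness(
            y, sim.MissingnessParams(0.0, 1e8), np.random.default_rng(8)
        )
        np.testing.assert_array_equal(r1, y > 0)

    def test_empirical_auc_against_known_case(self):
        # perfectly separated scores give AUC 1
        assert sim.empirical_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert sim.empirical_auc([4, 3, 2, 1], [0, 0, 1, 1]) == 0.0


@pytest.fixture(scope="module")
def tiny_result():
    cfg = sim.make_config(0.3, "MCAR", cv_a2=0.1, n=200, reps=20, m=3, seed=99)
    return cfg, sim.run_scenario(
        cfg,
        methods=("complete_data", "complete_cases", "M1"),
        engine_overrides=dict(burn_in=50, thin=2),
    )


class TestRunScenario:
    def test_output_schema(self, tiny_result):
        _, res = tiny_result
        assert list(res.index) == ["complete_data", "complete_cases", "M1"]
        for col in ("bias", "bias_mcse", "emp_se", "coverage", "coverage_mcse"):
            assert col in res.columns
        assert (res["n_reps"] == 20).all()
        assert (res["failures"] == 0).all()
        assert res["emp_se"].gt(0).all()
        assert res["coverage"].between(0, 1).all()

    def test_seeded_rerun_bit_identical(self, tiny_result):
        cfg, res = tiny_result
        res2 = sim.run_scenario(
            cfg,
            methods=("complete_data", "complete_cases", "M1"),
            engine_overrides=dict(burn_in=50, thin=2),
        )
        pd.testing.assert_frame_equal(res, res2)

    def test_unknown_method_rejected(self):
        cfg = sim.make_config(0.1, "MCAR", reps=2)
        with pytest.raises(ValueError, match="unknown"):
            sim.run_scenario(cfg, methods=("M9",))

    def test_complete_data_unbiased_at_small_scale(self, tiny_result):
        _, res = tiny_result
        row = res.loc["complete_data"]
        assert abs(row["bias"]) < 4 * row["bias_mcse"]
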