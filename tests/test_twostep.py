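import numpy as np
import pandas as pd
import pytest

from sightabund import (MCMCConfig, rhat, summarize_abundance, two_step_fit)


class TestRhat:
    def test_identical_chains_give_exactly_one(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal(500)
        assert rhat(np.vstack([c, c])) == pytest.approx(1.0, abs=1e-12)

    def test_diverged_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(10, 1, 1000)
        assert rhat(np.vstack([a, b])) > 3

    def test_well_mixed_chains_pass(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((2, 2000))
        assert 1.0 <= rhat(chains) < 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


class TestSummarize:
    def test_constant_draws(self):
        draws = pd.DataFrame({"tau[2005]": [40.0] * 100, "tau[2006]": [40.0] * 100})
        s = summarize_abundance(draws)
        assert (s.table["mean"] == 40.0).all()
        assert (s.table["q05"] == s.table["q95"]).all()
        assert (s.rate_table["rate_mean"] == 0.0).all()

    def test_lognormal_quantiles_match_closed_form(self):
        rng = np.random.default_rng(3)
        mu, sigma = 6.0, 0.25
        draws = pd.DataFrame({"tau[2005]": rng.lognormal(mu, sigma, 50_000)})
        s = summarize_abundance(draws)
        from scipy import stats
        want_lo = stats.lognorm.ppf(0.05, sigma, scale=np.exp(mu))
        want_hi = stats.lognorm.ppf(0.95, sigma, scale=np.exp(mu))
        assert s.table["q05"].iloc[0] == pytest.approx(want_lo, rel=0.02)
        assert s.table["q95"].iloc[0] == pytest.approx(want_hi, rel=0.02)

    def test_single_year_omits_rate(self):
        draws = pd.DataFrame({"tau[2005]": [1.0, 2.0]})
        s = summarize_abundance(draws)
        assert len(s.rate_table) == 0


class TestTwoStepFit:
    @pytest.fixture(scope="class")
    def tiny_inputs(self):
        from sightabund import TruthConfig, simulate_survey

        cfg = TruthConfig(years=(2005,), N_ht=(6, 5, 4), B_h=(8, 10, 12), seed=17)
        sv = simulate_survey(cfg)
        return sv

    def test_pooled_draw_count(self, tiny_inputs):
        sv = tiny_inputs
        cfg = MCMCConfig(s=3, n_chains=2, n_iter=60, n_burn=30, thin=2, seed=0,
                         step1_iter=600, step1_burn=200)
        dr = two_step_fit(sv.sightability_table, sv.operational_table,
                          sv.design_table, "FE", cfg, B_h=(8, 10, 12))
        assert len(dr) == 3 * 2 * 15

    def test_end_to_end_determinism(self, tiny_inputs):
        sv = tiny_inputs
        cfg = MCMCConfig(s=2, n_chains=1, n_iter=60, n_burn=30, thin=2, seed=5,
                         step1_iter=600, step1_burn=200)
        a = two_step_fit(sv.sightability_table, sv.operational_table,
                         sv.design_table, "FE", cfg, B_h=(8, 10, 12))
        b = two_step_fit(sv.sightability_table, sv.operational_table,
                         sv.design_table, "FE", cfg, B_h=(8, 10, 12))
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_outer_loop_is_single_conditional_fit(self, tiny_inputs):
        sv = tiny_inputs
        phi = pd.DataFrame({"beta0g": [0.33], "beta1g": [-0.99]})
        cfg = MCMCConfig(s=1, n_chains=1, n_iter=80, n_burn=40, thin=2, seed=2)
        dr = two_step_fit(sv.sightability_table, sv.operational_table,
                          sv.design_table, "FE", cfg, B_h=(8, 10, 12),
                          phi_draws=phi)
        assert (dr["s"] == 0).all()
        assert (dr["beta0g"] == 0.33).all()
        assert len(dr) == 20

    def test_pool_mode_last_keeps_one_row_per_chain(self, tiny_inputs):
        sv = tiny_inputs
        cfg = MCMCConfig(s=2, n_chains=2, n_iter=60, n_burn=30, thin=2, seed=3,
                         step1_iter=600, step1_burn=200, pool_mode="last")
        dr = two_step_fit(sv.sightability_table, sv.operational_table,
                          sv.design_table, "FE", cfg, B_h=(8, 10, 12))
        assert len(dr) == 2 * 2

    def test_empty_trials_rejected(self, tiny_inputs):
        sv = tiny_inputs
        with pytest.raises(ValueError, match="trials"):
            two_step_fit(pd.DataFrame(columns=["z", "x"]), sv.operational_table,
                         sv.design_table, "FE", MCMCConfig(s=1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(s=0)
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, n_burn=100)
        with pytest.raises(ValueError):
            MCMCConfig(pool_mode="middle")


class TestFeTracksMht:
    def test_fe_posterior_mean_close_to_mht(self):
        # with plenty of sampled plots the model-based estimate follows
        # the design-based expansion within 10%
        from sightabund import (TruthConfig, simulate_survey, fit_mle,
                                mht_estimate)

        cfg = TruthConfig(years=(2005,), N_ht=(200, 150, 100), seed=23)
        sv = simulate_survey(cfg)
        params = fit_mle(sv.sightability_table)
        est = mht_estimate(sv.operational_table, sv.design_table, params,
                           year=2005)
        phi = pd.DataFrame({"beta0g": [params.beta0g], "beta1g": [params.beta1g]})
        cfg_mc = MCMCConfig(s=1, n_chains=1, n_iter=1500, n_burn=500, thin=2,
                            seed=1)
        dr = two_step_fit(sv.sightability_table, sv.operational_table,
                          sv.design_table, "FE", cfg_mc, phi_draws=phi)
        fe_mean = dr["tau[2005]"].mean()
        assert fe_mean == pytest.approx(est.tau_hat, rel=0.10)
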