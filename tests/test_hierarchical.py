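import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sightabund import DetectionParams
from sightabund.hierarchical import (AugmentedData, GibbsSampler, PriorConfig,
                                     augment, log_density_fe, log_density_ts)
from sightabund.spline import natural_cubic_basis
from sightabund._mcmc import invlogit, logit


class TestAugment:
    def test_empty_plots_fill_to_budget(self):
        op = pd.DataFrame(columns=["year", "stratum", "plot", "y", "x"])
        des = pd.DataFrame({"year": [2005] * 3, "stratum": [1, 2, 3],
                            "N": [5, 5, 5], "n": [1, 1, 1]})
        res = augment(op, (40, 60, 100), des)
        assert res.m == 0
        assert res.m_aug == 200
        assert len(res.records) == 200
        assert (res.records["q"] == 0).all()

    def test_observed_records_flagged_present(self, micro_tables):
        op, des = micro_tables
        res = augment(op, (5, 5, 5), des)
        obs = res.records[res.records["observed"]]
        assert len(obs) == res.m == 3
        assert (obs["z"] == 1).all() and (obs["q"] == 1).all()
        assert res.m_aug == 15
        # each sampled plot holds exactly B_h records
        sizes = res.records.groupby(["stratum", "plot"]).size()
        assert (sizes == 5).all()

    def test_overfull_plot_demands_larger_budget(self, micro_tables):
        op, des = micro_tables
        op3 = pd.concat([op] * 3, ignore_index=True)
        with pytest.raises(ValueError, match="B_h"):
            augment(op3, (2, 2, 2), des)

    def test_trial_ratio_attached(self, micro_tables):
        op, des = micro_tables
        res = augment(op, (40, 60, 100), des, R=124)
        assert res.ratio == pytest.approx(124 / 200)


def _single_record_setup():
    """One sampled plot, B = 1, a single observed group."""
    op = pd.DataFrame({"year": [2005], "stratum": [1], "plot": ["p1"],
                       "y": [3.0], "x": [0.4]})
    des = pd.DataFrame({"year": [2005], "stratum": [1], "N": [1], "n": [1]})
    data = AugmentedData.from_tables(op, des, (1,))
    phi = DetectionParams(0.33, -0.99)
    smp = GibbsSampler(data, "FE", phi, rng=np.random.default_rng(0))
    return data, phi, smp


class TestLogDensity:
    def test_single_observed_record_matches_hand_sum(self):
        data, phi, smp = _single_record_setup()
        st = smp.state
        key = (1, 2005)
        st.mu_psi[key], st.rho_psi[key] = 0.3, 5.0
        st.lam[key] = 1.7
        st.mu_x[key], st.rho_x[key] = 0.45, 4.0
        st.psi[key][:] = 0.25
        got = log_density_fe(st, phi, data, include_priors=False)
        a_p, b_p = 0.3 * 5.0, 5.0 - 0.3 * 5.0
        a_x, b_x = 0.45 * 4.0, 4.0 - 0.45 * 4.0
        g = invlogit(0.33 - 0.99 * 0.4)
        want = (
            stats.bernoulli.logpmf(1, 0.25)            # q ~ Bern(psi)
            + stats.beta.logpdf(0.25, a_p, b_p)        # psi ~ Beta
            + stats.poisson.logpmf(2, 1.7)             # y - 1 ~ Poisson
            + stats.beta.logpdf(0.4, a_x, b_x)         # x ~ Beta
            + stats.bernoulli.logpmf(1, g)             # z | x, q ~ Bern(g q)
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_detected_but_absent_is_impossible(self):
        data, phi, smp = _single_record_setup()
        st = smp.state
        st.latent_q[(1, 2005)][:] = 0  # q = 0 for an observed (z = 1) record
        assert log_density_fe(st, phi, data) == -np.inf

    def test_doubling_plots_doubles_data_loglik(self):
        op = pd.DataFrame({"year": [2005], "stratum": [1], "plot": ["p1"],
                           "y": [3.0], "x": [0.4]})
        op2 = pd.DataFrame({"year": [2005, 2005], "stratum": [1, 1],
                            "plot": ["p1", "p2"], "y": [3.0, 3.0], "x": [0.4, 0.4]})
        des1 = pd.DataFrame({"year": [2005], "stratum": [1], "N": [2], "n": [1]})
        des2 = pd.DataFrame({"year": [2005], "stratum": [1], "N": [2], "n": [2]})
        phi = DetectionParams(0.33, -0.99)
        vals = []
        for op_, des_ in ((op, des1), (op2, des2)):
            data = AugmentedData.from_tables(op_, des_, (1,))
            smp = GibbsSampler(data, "FE", phi, rng=np.random.default_rng(0))
            st = smp.state
            key = (1, 2005)
            st.mu_psi[key], st.rho_psi[key] = 0.3, 5.0
            st.lam[key], st.mu_x[key], st.rho_x[key] = 1.7, 0.45, 4.0
            st.psi[key][:] = 0.25
            vals.append(log_density_fe(st, phi, data, include_priors=False))
        assert vals[1] == pytest.approx(2 * vals[0], abs=1e-10)

    def test_ts_reduces_to_fe_with_flat_spline_and_zero_effects(self):
        op = pd.DataFrame({
            "year": [2005, 2006], "stratum": [1, 1], "plot": ["p1", "p2"],
            "y": [2.0, 4.0], "x": [0.3, 0.6],
        })
        des = pd.DataFrame({"year": [2005, 2006], "stratum": [1, 1],
                            "N": [2, 2], "n": [1, 1]})
        # df=1 spline needs >= 2 distinct years; 3 strata needed for dummies?
        # a single stratum keeps the dummy block to one column
        data = AugmentedData.from_tables(op, des, (1,))
        basis = natural_cubic_basis([2004, 2005, 2006], df=1)
        phi = DetectionParams(0.33, -0.99)
        ts = GibbsSampler(data, "TS", phi, basis=basis, rng=np.random.default_rng(1))
        fe = GibbsSampler(data, "FE", phi, rng=np.random.default_rng(1))
        lam_star, mu_star = 1.4, 0.22
        st_ts, st_fe = ts.state, fe.state
        st_ts.beta_psi = np.array([logit(mu_star), 0.0])
        for h in [1]:
            st_ts.mu_h[h] = math.log(lam_star)
            st_ts.sigma_h[h] = 0.5
        for key in data.blocks:
            st_ts.delta[key] = 0.0
            st_fe.mu_psi[key] = mu_star
            st_fe.lam[key] = lam_star
            for st in (st_ts, st_fe):
                st.rho_psi[key] = 5.0
                st.mu_x[key], st.rho_x[key] = 0.4, 4.0
                st.psi[key][:] = 0.3
            st_ts.latent_x[key][:] = st_fe.latent_x[key]
            st_ts.latent_y[key][:] = st_fe.latent_y[key]
            st_ts.latent_q[key][:] = st_fe.latent_q[key]
        got = log_density_ts(st_ts, phi, data, basis, include_priors=False)
        want = log_density_fe(st_fe, phi, data, include_priors=False)
        assert got == pytest.approx(want, abs=1e-9)


class TestGibbsSampler:
    def test_certain_detection_forces_absence_of_undetected(self, micro_tables):
        op, des = micro_tables
        data = AugmentedData.from_tables(op, des, (5, 5, 5))
        smp = GibbsSampler(data, "FE", DetectionParams(50.0, 0.0),
                           rng=np.random.default_rng(2))
        for _ in range(20):
            smp.sweep()
            for key, blk in data.blocks.items():
                q = smp.state.latent_q[key]
                assert (q[~blk.obs] == 0).all()

    def test_blind_survey_returns_prior_for_presence(self):
        # g = 0: non-detection carries no information, psi-mean posterior
        # equals its Uniform(0.01, 0.99) prior
        op = pd.DataFrame(columns=["year", "stratum", "plot", "y", "x"])
        des = pd.DataFrame({"year": [2005], "stratum": [1], "N": [3], "n": [2]})
        data = AugmentedData.from_tables(op, des, (8,))
        smp = GibbsSampler(data, "FE", DetectionParams(-50.0, 0.0),
                           rng=np.random.default_rng(3),
                           update={"lambda": False, "x_hyper": False})
        vals = []
        for i in range(4000):
            smp.sweep()
            if i >= 500:
                vals.append(smp.state.mu_psi[(1, 2005)])
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_abundance_never_below_observed(self, micro_tables):
        op, des = micro_tables
        data = AugmentedData.from_tables(op, des, (5, 5, 5))
        smp = GibbsSampler(data, "FE", DetectionParams(0.33, -0.99),
                           rng=np.random.default_rng(4))
        observed = op["y"].sum()
        for _ in range(200):
            smp.sweep()
            assert smp.abundance_draw()[2005] >= observed

    def test_posterior_predictive_mean_with_no_sampled_plots(self):
        # no plots sampled: E[tau] = N * B * E[psi] * (lambda + 1)
        op = pd.DataFrame(columns=["year", "stratum", "plot", "y", "x"])
        des = pd.DataFrame({"year": [2005], "stratum": [1], "N": [5], "n": [0]})
        data = AugmentedData.from_tables(op, des, (10,))
        smp = GibbsSampler(data, "FE", DetectionParams(0.33, -0.99),
                           rng=np.random.default_rng(5))
        key = (1, 2005)
        smp.state.mu_psi[key], smp.state.rho_psi[key] = 0.3, 5.0
        smp.state.lam[key] = 1.5
        draws = np.array([smp.abundance_draw()[2005] for _ in range(10_000)])
        expect = 5 * 10 * 0.3 * (1.5 + 1.0)
        assert abs(draws.mean() - expect) < 3 * draws.std() / 100

    def test_augmentation_size_does_not_move_abundance(self):
        from sightabund import TruthConfig, simulate_survey

        cfg = TruthConfig(years=(2005,), N_ht=(12, 10, 8), B_h=(10, 15, 20),
                          seed=31)
        sv = simulate_survey(cfg)
        phi = DetectionParams(0.33, -0.99)
        means = {}
        for mult in (1, 2):
            B = tuple(b * mult for b in cfg.B_h)
            per_seed = []
            for seed in (0, 1):
                data = AugmentedData.from_tables(sv.operational_table,
                                                 sv.design_table, B)
                smp = GibbsSampler(data, "FE", phi,
                                   rng=np.random.default_rng(seed))
                dr = smp.run(2500, 500, thin=2)
                per_seed.append(dr["tau[2005]"].mean())
            means[mult] = per_seed
        spread = np.std(means[1] + means[2])
        gap = abs(np.mean(means[1]) - np.mean(means[2]))
        assert gap < 3 * max(spread, 30.0)

    def test_joint_with_no_survey_matches_trials_only_posterior(self, trials_124):
        from sightabund import sample_posterior

        des = pd.DataFrame(columns=["year", "stratum", "N", "n"])
        op = pd.DataFrame(columns=["year", "stratum", "plot", "y", "x"])
        data = AugmentedData.from_tables(op, des, (40, 60, 100))
        smp = GibbsSampler(data, "JOINT", DetectionParams(0.0, 0.0),
                           trials=trials_124, rng=np.random.default_rng(6))
        dr = smp.run(12_000, 2000, thin=2)
        direct = sample_posterior(trials_124, seed=8)
        ks = stats.ks_2samp(dr["beta1g"].to_numpy()[:5000],
                            direct["beta1g"].to_numpy()[:5000]).statistic
        assert ks < 0.05
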