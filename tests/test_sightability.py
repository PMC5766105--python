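import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from sightabund import (DetectionParams, detect_prob, fit_mle,
                        inflation_factor, sample_posterior,
                        simulate_sightability_trials)
from sightabund._mcmc import invlogit


class TestDetectProb:
    @pytest.mark.parametrize("b0,b1,x,expected", [
        (0.0, 0.0, 0.5, 0.5),
        (0.33, -0.99, 0.0, 0.5817593),   # inverse logit of 0.33
        (0.33, -0.99, 1.0, 0.3407396),   # inverse logit of -0.66
    ])
    def test_values(self, b0, b1, x, expected):
        assert detect_prob(DetectionParams(b0, b1), x) == pytest.approx(expected, abs=1e-6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            detect_prob(DetectionParams(0.0, 0.0), 1.2)

    def test_strictly_decreasing_iff_negative_slope(self):
        x = np.linspace(0, 1, 50)
        down = detect_prob(DetectionParams(0.3, -1.2), x)
        up = detect_prob(DetectionParams(0.3, 1.2), x)
        assert np.all(np.diff(down) < 0)
        assert np.all(np.diff(up) > 0)


class TestFitMle:
    def test_two_support_point_closed_form(self):
        # x=0: 9 detected, 1 missed; x=1: 1 detected, 9 missed
        z = [1] * 9 + [0] + [1] + [0] * 9
        x = [0.0] * 10 + [1.0] * 10
        p = fit_mle(pd.DataFrame({"z": z, "x": x}))
        assert p.beta0g == pytest.approx(np.log(9), abs=1e-4)
        assert p.beta1g == pytest.approx(-2 * np.log(9), abs=1e-4)

    def test_consistency_at_large_r(self):
        tr = simulate_sightability_trials(0.33, -0.99, R=5000, seed=1)
        p = fit_mle(tr)
        se = np.sqrt(np.diag(p.cov))
        assert abs(p.beta0g - 0.33) < 3 * se[0]
        assert abs(p.beta1g + 0.99) < 3 * se[1]

    def test_no_covariate_variation_raises(self):
        df = pd.DataFrame({"z": [0, 1] * 5, "x": [0.4] * 10})
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_mle(df)

    def test_all_same_z_raises(self):
        df = pd.DataFrame({"z": [1] * 10, "x": np.linspace(0, 1, 10)})
        with pytest.raises(ValueError):
            fit_mle(df)

    def test_complete_separation_raises(self):
        df = pd.DataFrame({"z": [1] * 5 + [0] * 5,
                           "x": list(np.linspace(0, 0.4, 5)) + list(np.linspace(0.6, 1, 5))})
        with pytest.raises(ValueError, match="separation"):
            fit_mle(df)


class TestSamplePosterior:
    def test_saturated_intercept_detects_everything(self):
        tr = simulate_sightability_trials(20.0, 0.0, R=200, seed=0)
        assert tr["z"].all()

    def test_detection_fraction_matches_quadrature(self):
        # x ~ Uniform(0,1): detection rate = integral of the logistic
        tr = simulate_sightability_trials(
            0.33, -0.99, R=10_000,
            x_distribution=lambda rng, n: rng.random(n), seed=5)
        expect, _ = integrate.quad(lambda x: invlogit(0.33 - 0.99 * x), 0, 1)
        se = np.sqrt(expect * (1 - expect) / 10_000)
        assert abs(tr["z"].mean() - expect) < 3 * se

    def test_matches_mle_at_large_r(self, bvm_draws=None):
        tr = simulate_sightability_trials(0.33, -0.99, R=5000, seed=11)
        mle = fit_mle(tr)
        draws = sample_posterior(tr, n_iter=4000, n_burn=1500, seed=2)
        se = np.sqrt(np.diag(mle.cov))
        assert abs(draws["beta0g"].mean() - mle.beta0g) < 0.1
        assert abs(draws["beta1g"].mean() - mle.beta1g) < 0.1
        assert draws["beta0g"].std() == pytest.approx(se[0], rel=0.2)
        assert draws["beta1g"].std() == pytest.approx(se[1], rel=0.2)

    def test_tight_prior_dominates(self, trials_124):
        draws = sample_posterior(trials_124, prior_sd=0.001, n_iter=3000,
                                 n_burn=1000, seed=3)
        assert abs(draws["beta0g"].mean()) < 0.01
        assert abs(draws["beta1g"].mean()) < 0.01

    def test_deterministic_given_seed(self, trials_124):
        a = sample_posterior(trials_124, n_iter=500, n_burn=200, seed=9)
        b = sample_posterior(trials_124, n_iter=500, n_burn=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_retained_draw_count_matches_settings(self, trials_124):
        draws = sample_posterior(trials_124, n_chains=2, n_iter=1000,
                                 n_burn=400, thin=2, seed=1)
        assert len(draws) == 2 * 300


class TestInflationFactor:
    def test_zero_cov_identity(self):
        p = DetectionParams(0.0, 0.0, cov=np.zeros((2, 2)))
        assert inflation_factor(p, 0.3) == pytest.approx(2.0)
        # with no parameter uncertainty, theta is exactly 1/g
        p2 = DetectionParams(0.33, -0.99, cov=np.zeros((2, 2)))
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(inflation_factor(p2, x),
                                   1.0 / detect_prob(p2, x), rtol=1e-12)

    def test_variance_correction(self):
        p = DetectionParams(0.0, 0.0, cov=np.array([[2.0, 0.0], [0.0, 0.0]]))
        assert inflation_factor(p, 0.0) == pytest.approx(1 + np.exp(-1), abs=1e-9)

    def test_always_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            b = rng.normal(scale=2, size=2)
            a = rng.normal(size=(2, 2))
            p = DetectionParams(b[0], b[1], cov=a @ a.T)
            assert np.all(inflation_factor(p, rng.random(5)) >= 1.0)

    def test_missing_cov_raises(self):
        with pytest.raises(ValueError):
            inflation_factor(DetectionParams(0.0, 0.0), 0.5)
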