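"""Logistic sightability model for detection/non-detection trials.

A sightability model relates the probability g of detecting an animal
group during an aerial survey to visual obstruction x (the proportion of
screening cover around the first animal seen, in [0, 1]):

    logit(g) = beta0g + beta1g * x

It is fit to trials with radiocollared groups, where missed groups are
recovered by telemetry so both detections (z = 1) and non-detections
(z = 0) are recorded.  Two fitting routes are provided: maximum
likelihood (feeding the design-based modified Horvitz-Thompson
estimator) and MCMC under vague normal priors (feeding the hierarchical
model's two-step, cut-posterior fit).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._mcmc import AdaptiveMvRW, invlogit

__all__ = [
    "DetectionParams",
    "detect_prob",
    "fit_mle",
    "sample_posterior",
    "inflation_factor",
    "SightabilityConvergenceWarning",
    "DEFAULT_PRIOR_SD",
]

#: Vague prior sd for the detection coefficients (sd sqrt(10) ~ 3.16,
#: the conventional weakly-informative logit-scale choice).
DEFAULT_PRIOR_SD = 3.16


class SightabilityConvergenceWarning(UserWarning):
    """Raised when MCMC chains for the detection parameters fail R-hat < 1.1."""


@dataclass
class DetectionParams:
    """Detection-curve parameters (logit scale), optionally with covariance.

    `cov` is the 2x2 covariance of (beta0g, beta1g); present for MLE
    fits (inverse observed information), absent for single posterior
    draws.
    """

    beta0g: float
    beta1g: float
    cov: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.cov is not None:
            c = np.asarray(self.cov, dtype=float)
            if c.shape != (2, 2):
                raise ValueError("cov must be 2x2")
            if not np.allclose(c, c.T, atol=1e-8):
                raise ValueError("cov must be symmetric")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise ValueError("cov must be positive semidefinite")
            self.cov = c


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1) | ~np.isfinite(x)):
        raise ValueError("visual obstruction x must lie in [0, 1]")
    return x


def detect_prob(params: DetectionParams, x):
    """Detection probability g = logit^-1(beta0g + beta1g * x), x in [0, 1]."""
    x = _check_x(x)
    return invlogit(params.beta0g + params.beta1g * x)


def _validate_trials(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(trials["z"], dtype=float)
    x = _check_x(trials["x"])
    if not np.all(np.isin(z, (0.0, 1.0))):
        raise ValueError("z must be binary (0/1)")
    if z.sum() == 0 or z.sum() == len(z):
        raise ValueError(
            "trials must contain at least one detection and one non-detection"
        )
    return z, x


def fit_mle(trials: pd.DataFrame) -> DetectionParams:
    """Maximum-likelihood fit of the sightability curve to trial data.

    Returns the Bernoulli-likelihood maximizer with the inverse
    observed-information covariance.  Raises on complete separation,
    constant z, or no covariate variation (beta1g unidentifiable).
    """
    z, x = _validate_trials(trials)
    if np.ptp(x) == 0:
        raise ValueError(
            "no variation in x: obstruction slope beta1g is unidentifiable"
        )
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(z, X).fit(disp=False)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as e:
            raise ValueError(f"complete separation in sightability trials: {e}") from e
    cov = np.asarray(res.cov_params())
    if not np.all(np.isfinite(cov)) or np.any(np.abs(res.params) > 50):
        raise ValueError("complete separation in sightability trials")
    return DetectionParams(float(res.params[0]), float(res.params[1]), cov)


def _log_posterior(beta: np.ndarray, z: np.ndarray, x: np.ndarray, prior_sd: float) -> float:
    eta = beta[0] + beta[1] * x
    # Bernoulli log-lik: z*eta - log(1 + e^eta), numerically stable
    ll = float(np.sum(z * eta - np.logaddexp(0.0, eta)))
    lp = -0.5 * float(beta @ beta) / prior_sd**2
    return ll + lp


def sample_posterior(
    trials: pd.DataFrame,
    prior_sd: float = DEFAULT_PRIOR_SD,
    n_chains: int = 2,
    n_iter: int = 10_000,
    n_burn: int = 3_000,
    thin: int = 2,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """MCMC draws from [Phi | Z] under independent N(0, prior_sd) priors.

    Random-walk Metropolis on (beta0g, beta1g) jointly, with the proposal
    covariance adapted during burn-in.  Defaults (2 chains x 10,000
    iterations, 3,000 burn-in, thin 2) retain 7,000 draws.

    Returns a DataFrame with columns (chain, iter, beta0g, beta1g) and a
    ``.attrs['rhat']`` dict; emits :class:`SightabilityConvergenceWarning`
    if R-hat >= 1.1 on either coordinate.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    if n_burn >= n_iter:
        raise ValueError("n_burn must be < n_iter")
    z, x = _validate_trials(trials)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = []
    for c, child in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(child)
        beta = rng.normal(scale=0.5, size=2)
        lp = _log_posterior(beta, z, x, prior_sd)
        prop = AdaptiveMvRW(2, step=0.5)
        keep_b, keep_i = [], []
        for it in range(n_iter):
            if it == n_burn:
                prop.freeze()
            cand = prop.propose(beta, rng)
            lp_cand = _log_posterior(cand, z, x, prior_sd)
            if np.log(rng.random()) < lp_cand - lp:
                beta, lp = cand, lp_cand
                prop.register(True, beta)
            else:
                prop.register(False, beta)
            if it >= n_burn and (it - n_burn) % thin == 0:
                keep_b.append(beta.copy())
                keep_i.append(it)
        arr = np.array(keep_b)
        out.append(
            pd.DataFrame(
                {
                    "chain": c,
                    "iter": keep_i,
                    "beta0g": arr[:, 0],
                    "beta1g": arr[:, 1],
                }
            )
        )
    draws = pd.concat(out, ignore_index=True)
    rhat = {}
    if n_chains >= 2:
        from .twostep import rhat as _rhat

        for par in ("beta0g", "beta1g"):
            mat = np.array(
                [g[par].to_numpy() for _, g in draws.groupby("chain", sort=True)]
            )
            rhat[par] = _rhat(mat)
            if rhat[par] >= 1.1:
                warnings.warn(
                    f"R-hat = {rhat[par]:.3f} >= 1.1 for {par}; chains may not "
                    "have converged",
                    SightabilityConvergenceWarning,
                )
    draws.attrs["rhat"] = rhat
    return draws


def inflation_factor(params: DetectionParams, x):
    """Sightability inflation factor theta >= 1 for obstruction x.

    theta = 1 + exp(-beta0g - beta1g*x - (s00 + 2*s01*x + s11*x^2)/2),
    the lognormal bias-corrected reciprocal of the detection probability:
    with beta-hat ~ N(beta, Sigma), E[theta - 1] = exp(-x'beta) = 1/g - 1.
    Requires the parameter covariance (MLE fits).
    """
    if params.cov is None:
        raise ValueError("inflation_factor requires parameter covariance")
    x = _check_x(x)
    s = params.cov
    var = s[0, 0] + 2.0 * s[0, 1] * x + s[1, 1] * x**2
    return 1.0 + np.exp(-params.beta0g - params.beta1g * x - 0.5 * var)
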