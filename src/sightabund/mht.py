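"""Design-based modified Horvitz-Thompson (mHT) abundance estimation.

Each detected group's count y is expanded by a sightability inflation
factor theta (roughly the reciprocal of its detection probability, with
a correction for detection-parameter uncertainty) and by the plot
inclusion probability pi:

    tau_hat_t = sum_h sum_i sum_j  y_hijt * theta_hijt / pi_hit

The variance has three components, in the spirit of the classical
sightability-model decomposition:

* plot sampling: between-plot variance of estimated plot totals,
  expanded by the finite-population factor N(N - n)/n, with the
  within-plot detection noise subtracted so it is not counted twice;
* detection: Bernoulli thinning of groups, estimated by
  sum y^2 theta (theta - 1) / pi^2 over detected groups;
* detection parameters: lognormal covariance of the theta's induced by
  the sampling distribution of the fitted logistic coefficients,
  Cov(theta_j, theta_k) ~= (theta_j - 1)(theta_k - 1)(exp(x_j' S x_k) - 1).

Confidence intervals are lognormal at level 1 - alpha (default 0.10).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sightability import DetectionParams, inflation_factor

__all__ = ["MhtEstimate", "mht_estimate", "mht_total", "lognormal_ci"]


def mht_total(y, theta, pi) -> float:
    """The raw mHT expansion sum: sum of y * theta / pi over detected groups."""
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("plot inclusion probability pi must be > 0")
    return float(np.sum(y * theta / pi))


@dataclass
class MhtEstimate:
    """Year-specific mHT abundance estimate with variance and lognormal CI."""

    year: int
    tau_hat: float
    variance: float
    ci_low: float
    ci_high: float
    alpha: float = 0.10
    components: dict | None = None

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def lognormal_ci(tau_hat: float, variance: float, alpha: float = 0.10) -> tuple[float, float]:
    """Lognormal confidence interval (tau/C, tau*C).

    C = exp(z_{1-alpha/2} * sqrt(ln(1 + variance / tau_hat^2))).
    """
    if tau_hat <= 0:
        raise ValueError("tau_hat must be positive for a lognormal interval")
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    z = stats.norm.ppf(1 - alpha / 2)
    C = np.exp(z * np.sqrt(np.log1p(variance / tau_hat**2)))
    return float(tau_hat / C), float(tau_hat * C)


def mht_estimate(
    operational: pd.DataFrame,
    design: pd.DataFrame,
    params: DetectionParams,
    year: int | None = None,
    alpha: float = 0.10,
) -> MhtEstimate:
    """Modified Horvitz-Thompson abundance estimate for one survey year.

    Parameters
    ----------
    operational
        Detected groups: columns (year, stratum, plot, y, x).
    design
        Per stratum (and year): columns (year, stratum, N, n) and
        optionally pi (defaults to n/N, stratified SRS).
    params
        Fitted detection parameters with covariance (see
        :func:`sightabund.sightability.fit_mle`).
    year
        Survey year; may be omitted when the tables hold a single year.
    """
    if params.cov is None:
        raise ValueError("mHT requires detection parameters with covariance")
    op = operational.copy()
    des = design.copy()
    if year is None:
        yrs = set(op["year"].unique()) | set(des["year"].unique())
        if len(yrs) != 1:
            raise ValueError("multiple years present; pass year explicitly")
        year = int(next(iter(yrs)))
    op = op[op["year"] == year]
    des = des[des["year"] == year]
    if des.empty:
        raise ValueError(f"design table has no rows for year {year}")
    if "pi" not in des.columns:
        des = des.assign(pi=des["n"] / des["N"])
    if np.any(des["pi"] <= 0):
        raise ValueError("plot inclusion probability pi must be > 0")
    if len(op) and (op["y"] < 1).any():
        raise ValueError("group sizes y must be >= 1")

    des = des.set_index("stratum")
    strata = des.index.to_numpy()
    if len(op) and not set(op["stratum"]).issubset(set(strata)):
        raise ValueError("operational records reference strata missing from design")
    # groups per plot must not exceed sampled plots
    plots_per = op.groupby("stratum")["plot"].nunique()
    for h, nplots in plots_per.items():
        if nplots > des.loc[h, "n"]:
            raise ValueError(
                f"stratum {h}: {nplots} distinct plots with detections exceeds "
                f"n = {des.loc[h, 'n']} sampled plots"
            )

    x = op["x"].to_numpy(dtype=float) if len(op) else np.array([])
    y = op["y"].to_numpy(dtype=float) if len(op) else np.array([])
    theta = inflation_factor(params, x) if len(op) else np.array([])
    pi = des.loc[op["stratum"], "pi"].to_numpy(dtype=float) if len(op) else np.array([])

    tau_hat = mht_total(y, theta, pi) if len(op) else 0.0

    # --- variance components -------------------------------------------
    S = params.cov
    var_samp = 0.0
    var_detect = 0.0
    for h in strata:
        N_h, n_h, pi_h = (float(des.loc[h, c]) for c in ("N", "n", "pi"))
        sub = op[op["stratum"] == h]
        t_hat = np.zeros(int(n_h))  # estimated totals incl. empty sampled plots
        v_hat = np.zeros(int(n_h))  # within-plot detection variance estimates
        if len(sub):
            th = inflation_factor(params, sub["x"].to_numpy(dtype=float))
            yv = sub["y"].to_numpy(dtype=float)
            codes, _ = pd.factorize(sub["plot"])
            np.add.at(t_hat, codes, yv * th)
            np.add.at(v_hat, codes, yv**2 * th * (th - 1.0))
        var_detect += float(v_hat.sum()) / pi_h**2
        if n_h >= 2:
            s2 = float(np.var(t_hat, ddof=1))
            s2_corr = max(0.0, s2 - float(v_hat.mean()))
            var_samp += N_h * (N_h - n_h) / n_h * s2_corr
    # detection-parameter component: shared beta-hat correlates all groups
    var_model = 0.0
    if len(op):
        X = np.column_stack([np.ones_like(x), x])
        C = X @ S @ X.T                     # x_j' S x_k
        w = y * (theta - 1.0) / pi
        var_model = float(w @ (np.expm1(C)) @ w)
    variance = var_samp + var_detect + var_model
    lo, hi = lognormal_ci(tau_hat, variance, alpha) if tau_hat > 0 else (0.0, 0.0)
    return MhtEstimate(
        year=year, tau_hat=tau_hat, variance=variance, ci_low=lo, ci_high=hi,
        alpha=alpha,
        components={"sampling": var_samp, "detection": var_detect,
                    "model": var_model},
    )
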