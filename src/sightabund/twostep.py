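"""Two-step (cut-posterior) fitting of the hierarchical abundance models.

The detection curve must be informed only by the detection/non-detection
trial data, never by the detection-only operational surveys.  The target
factorizes as

    [Theta, Phi | Y, Z]  propto  [Y | Theta, Phi] [Phi | Z] [Theta]

and is sampled in two stages:

1. draw from [Phi | Z] by MCMC on the trials alone;
2. select s of those draws, run the hierarchical sampler for Theta with
   each Phi^(s) fixed as data, and pool all retained draws.

Pooling across the s conditional chains yields samples from the cut
posterior: the Phi marginal of the pooled output coincides with
[Phi | Z] by construction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import sightability
from .hierarchical import AugmentedData, GibbsSampler, PriorConfig
from .sightability import DetectionParams
from .spline import SplineBasis, natural_cubic_basis

__all__ = ["MCMCConfig", "two_step_fit", "summarize_abundance", "rhat",
           "AbundanceSummary"]


@dataclass
class MCMCConfig:
    """MCMC settings for the two-step fit.

    Defaults follow the reference analysis: step 1 runs 2 chains of
    10,000 iterations (burn 3,000, thin 2; 7,000 retained draws of Phi);
    step 3 uses s = 75 outer draws, each with 2 chains of 3,000
    iterations (burn 2,000, thin 2), pooling to 75,000 draws.
    """

    s: int = 75
    n_chains: int = 2
    n_iter: int = 3000
    n_burn: int = 2000
    thin: int = 2
    seed: int = 0
    step1_chains: int = 2
    step1_iter: int = 10_000
    step1_burn: int = 3000
    step1_thin: int = 2
    prior_sd: float = sightability.DEFAULT_PRIOR_SD
    pool_mode: str = "all"   # "all" or "last": which inner draws to pool

    def __post_init__(self):
        if self.s < 1:
            raise ValueError("s must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be < n_iter")
        if self.pool_mode not in ("all", "last"):
            raise ValueError("pool_mode must be 'all' or 'last'")


@dataclass
class AbundanceSummary:
    """Posterior summaries of yearly abundance and its log rate of change."""

    table: pd.DataFrame          # year, mean, q05, q95
    rate_table: pd.DataFrame     # year, rate_mean, rate_q05, rate_q95 (t vs t-1)


def rhat(chains) -> float:
    """Potential scale reduction factor of a scalar parameter.

    ``chains`` is an (m, n) array of m >= 2 chains.  Computed as the
    square root of pooled variance over mean within-chain variance
    (population-variance convention), the classic between/within
    decomposition: identical chains give exactly 1, diverged chains
    give values well above 1.
    """
    a = np.asarray(chains, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("rhat requires at least 2 chains (2-d input)")
    if a.shape[1] < 10:
        raise ValueError("rhat requires at least 10 draws per chain")
    W = a.var(axis=1, ddof=0).mean()
    V = a.var(ddof=0)
    if W == 0:
        return 1.0 if V == 0 else np.inf
    return float(np.sqrt(V / W))


def _fit_once(model: str, operational, design, B_h, phi: DetectionParams,
              cfg: MCMCConfig, priors: PriorConfig, basis, trials,
              seed_seq: np.random.SeedSequence, s_index: int,
              rhat_records: list) -> pd.DataFrame:
    chains = []
    children = seed_seq.spawn(cfg.n_chains)
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(children[c])
        data = AugmentedData.from_tables(operational, design, B_h)
        smp = GibbsSampler(data, model, phi, priors=priors, basis=basis,
                           trials=trials, rng=rng,
                           init_jitter=0.3 if cfg.n_chains > 1 else 0.0)
        draws = smp.run(cfg.n_iter, cfg.n_burn, cfg.thin)
        draws.insert(0, "chain", c)
        chains.append(draws)
    out = pd.concat(chains, ignore_index=True)
    out.insert(0, "s", s_index)
    if cfg.n_chains >= 2:
        cols = [c for c in out.columns
                if c not in ("s", "chain", "iter") and not c.startswith("tau[")]
        for col in cols:
            mat = np.array([g[col].to_numpy()
                            for _, g in out.groupby("chain", sort=True)])
            try:
                r = rhat(mat)
            except ValueError:
                continue
            if r >= 1.1:
                rhat_records.append({"s": s_index, "param": col, "rhat": r})
    return out


def two_step_fit(
    trials: pd.DataFrame,
    operational: pd.DataFrame,
    design: pd.DataFrame,
    model: str = "TS",
    cfg: MCMCConfig = None,
    B_h=(40, 60, 100),
    priors: PriorConfig = None,
    basis: Optional[SplineBasis] = None,
    spline_knots=None,
    phi_draws: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Robust two-step fit of the FE or TS model.

    Step 1 samples [Phi | Z] from the trials; step 2 selects s retained
    draws uniformly without replacement; step 3 runs the hierarchical
    sampler with each Phi^(s) fixed as data; step 4 pools the draws.

    Returns the pooled draws: one row per retained inner iteration with
    columns (s, chain, iter, beta0g, beta1g, <parameters>, tau[year]).
    ``.attrs`` carries 'rhat_warnings' (inner chains with R-hat >= 1.1)
    and 'config'.  ``phi_draws`` can supply a precomputed step-1 sample.
    """
    cfg = cfg or MCMCConfig()
    priors = priors or PriorConfig()
    model = model.upper()
    if model not in ("FE", "TS"):
        raise ValueError("two_step_fit supports FE and TS models")
    if trials is None or not len(trials):
        raise ValueError("trials table must be nonempty")
    ss = np.random.SeedSequence(cfg.seed)
    ss_step1, ss_pick, ss_fit = ss.spawn(3)

    years = sorted(design["year"].unique().astype(int))
    if model == "TS" and basis is None:
        basis = natural_cubic_basis(years, df=3, knots=spline_knots)

    if phi_draws is None:
        phi_draws = sightability.sample_posterior(
            trials, prior_sd=cfg.prior_sd, n_chains=cfg.step1_chains,
            n_iter=cfg.step1_iter, n_burn=cfg.step1_burn,
            thin=cfg.step1_thin, seed=ss_step1,
        )
    if cfg.s > len(phi_draws):
        raise ValueError(
            f"s = {cfg.s} exceeds the {len(phi_draws)} retained step-1 draws")
    pick = np.random.default_rng(ss_pick).choice(
        len(phi_draws), size=cfg.s, replace=False)
    phis = phi_draws.iloc[np.sort(pick)][["beta0g", "beta1g"]].to_numpy()

    rhat_records: list = []
    pooled = []
    children = ss_fit.spawn(cfg.s)
    for si in range(cfg.s):
        phi = DetectionParams(float(phis[si, 0]), float(phis[si, 1]))
        draws = _fit_once(model, operational, design, B_h, phi, cfg, priors,
                          basis, trials, children[si], si, rhat_records)
        if cfg.pool_mode == "last":
            draws = draws.groupby("chain", sort=True).tail(1)
        draws.insert(1, "beta0g", phi.beta0g)
        draws.insert(2, "beta1g", phi.beta1g)
        pooled.append(draws)
    out = pd.concat(pooled, ignore_index=True)
    out.attrs["rhat_warnings"] = rhat_records
    out.attrs["config"] = cfg
    out.attrs["model"] = model
    # full step-1 sample of [Phi | Z]: the cut posterior of the detection
    # parameters, of which the s atoms in the pooled table are a subsample
    out.attrs["phi_draws"] = phi_draws
    if rhat_records:
        warnings.warn(
            f"{len(rhat_records)} inner chain parameter(s) had R-hat >= 1.1",
            UserWarning,
        )
    return out


def summarize_abundance(draws: pd.DataFrame, level: float = 0.90) -> AbundanceSummary:
    """Posterior mean and central credible interval of yearly abundance.

    Also summarizes the log rate of change r_t = log(tau_t / tau_{t-1}),
    computed per draw and then summarized; omitted when only one year is
    present.
    """
    tau_cols = sorted([c for c in draws.columns if c.startswith("tau[")],
                      key=lambda c: int(c[4:-1]))
    if not tau_cols:
        raise ValueError("draws contain no tau[year] columns")
    qlo, qhi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for c in tau_cols:
        v = draws[c].to_numpy(dtype=float)
        rows.append({"year": int(c[4:-1]), "mean": v.mean(),
                     "q05": np.quantile(v, qlo), "q95": np.quantile(v, qhi)})
    table = pd.DataFrame(rows)
    rrows = []
    for c0, c1 in zip(tau_cols[:-1], tau_cols[1:]):
        v0 = draws[c0].to_numpy(dtype=float)
        v1 = draws[c1].to_numpy(dtype=float)
        ok = (v0 > 0) & (v1 > 0)
        r = np.log(v1[ok] / v0[ok])
        rrows.append({"year": int(c1[4:-1]), "rate_mean": r.mean(),
                      "rate_q05": np.quantile(r, qlo),
                      "rate_q95": np.quantile(r, qhi)})
    rate = pd.DataFrame(rrows, columns=["year", "rate_mean", "rate_q05", "rate_q95"])
    return AbundanceSummary(table=table, rate_table=rate)
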