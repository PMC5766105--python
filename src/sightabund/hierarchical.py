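"""Data-augmented hierarchical abundance models (FE, TS, joint).

Each sampled plot in stratum h is padded to B_h candidate group records.
Record j carries a presence indicator q ~ Bernoulli(psi_plot), a group
size y with y - 1 ~ Poisson(lambda_ht), an obstruction value
x ~ Beta(a_x, b_x), and a detection indicator z | x, q ~ Bernoulli(g(x) q)
with logit(g) = beta0g + beta1g x.  Observed groups have z = q = 1 and
fixed (y, x); augmented records have z = 0 and latent (q, y, x).
Per-plot presence probabilities psi are Beta(mu*rho, rho - mu*rho) with
stratum-by-year mean mu and concentration rho.

Model variants
--------------
FE     year- and stratum-specific (mu_psi, rho_psi, lambda, mu_x, rho_x);
       detection parameters Phi passed in as data (two-step fit).
TS     as FE, but log(lambda_ht) = mu_h + delta_ht with exchangeable
       yearly random effects, and logit(mean psi) follows a natural
       cubic spline over years with stratum-specific intercepts.
JOINT  FE structure with Phi sampled inside the chain, informed by both
       the trial data and the operational (detection-only) records --
       the specification whose detection curve is known to drift as
       detection-only data accumulate.

Inference is Metropolis-within-Gibbs.  Conjugate updates are used for q
(Bernoulli) and psi (Beta); latent x for present-but-undetected records
uses an independence Metropolis step with the Beta marginal as proposal;
everything else is adaptive random-walk Metropolis on unconstrained
transforms.  Latent draws that carry no likelihood terms (group sizes of
augmented records, obstruction of absent records) are redrawn from their
conditionals after the parameter updates, which partially collapses the
corresponding parameter moves and speeds mixing without changing the
target.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from ._mcmc import AdaptiveMvRW, AdaptiveScalarRW, invlogit, logit
from .sightability import DetectionParams
from .spline import SplineBasis

__all__ = [
    "PriorConfig", "AugmentResult", "augment", "AugmentedData", "ThetaState",
    "log_density_fe", "log_density_ts", "GibbsSampler", "gibbs_step",
    "abundance_draw",
]

_NEG_INF = -np.inf


# ----------------------------------------------------------------------
# priors
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior settings (all normal scales are standard deviations)."""

    mu_bounds: tuple[float, float] = (0.01, 0.99)   # mu_psi, mu_x ~ Uniform
    rho_mean: float = 5.0                           # rho ~ N(5, 1) trunc
    rho_sd: float = 1.0
    rho_bounds: tuple[float, float] = (0.01, 10.0)
    log_lambda_sd: float = 3.16                     # log(lambda) ~ N(0, sd)
    phi_sd: float = 3.16                            # beta0g, beta1g ~ N(0, sd)
    mu_h_sd: float = 3.16                           # TS stratum mean, log scale
    sigma_bound: float = 3.0                        # TS sigma_h ~ Uniform(0, 3)
    spline_sd: float = 5.0                          # TS spline coefs ~ N(0, sd)


def _clip01(x):
    """Keep Beta draws strictly inside (0, 1) for log-density evaluation."""
    return np.clip(x, 1e-12, 1.0 - 1e-12)


def _log_beta_pdf(x, a, b):
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)


def _log_shifted_pois(y, lam):
    k = y - 1.0
    return k * np.log(lam) - lam - gammaln(k + 1.0)


# ----------------------------------------------------------------------
# data augmentation
# ----------------------------------------------------------------------
@dataclass
class AugmentResult:
    """Augmented record table with its bookkeeping counts."""

    records: pd.DataFrame
    m: int        # observed groups
    m_aug: int    # total records after padding = sum over sampled plots of B_h

    @property
    def ratio(self) -> float | None:
        """Sightability-to-augmented data ratio R / m_aug, if R was given."""
        return self.records.attrs.get("ratio")


def augment(operational: pd.DataFrame, B_h, design: pd.DataFrame,
            R: int | None = None) -> AugmentResult:
    """Pad every sampled plot to B_h candidate group records.

    Observed groups keep (y, x) and get z = q = 1; padding records get
    z = 0 and latent (q, y, x).  Sampled plots without any detection
    (known only by count from the design table) receive synthetic plot
    ids and B_h fully augmented records.

    ``R``, when given, is the sightability-trial count used to report
    the trials-to-augmented-data ratio R / m_aug.
    """
    B_h = {h + 1: int(b) for h, b in enumerate(B_h)} if not isinstance(B_h, dict) else B_h
    rows = []
    m = 0
    m_aug = 0
    for _, drow in design.iterrows():
        t, h, n = int(drow["year"]), int(drow["stratum"]), int(drow["n"])
        B = B_h[h]
        sub = operational[(operational["year"] == t) & (operational["stratum"] == h)]
        plots = list(sub["plot"].unique())
        if len(plots) > n:
            raise ValueError(
                f"stratum {h}, year {t}: detections reference {len(plots)} plots "
                f"but only n = {n} were sampled"
            )
        plots = plots + [f"empty{h}_{t}_{k}" for k in range(n - len(plots))]
        for p in plots:
            obs = sub[sub["plot"] == p]
            mp = len(obs)
            if mp > B:
                raise ValueError(
                    f"stratum {h}, year {t}, plot {p}: {mp} observed groups exceed "
                    f"B_h = {B}; augmentation requires B_h >> observed group count"
                )
            m += mp
            m_aug += B
            for slot, (_, r) in enumerate(obs.iterrows(), start=1):
                rows.append((t, h, p, slot, True, float(r["y"]), float(r["x"]), 1, 1))
            for slot in range(mp + 1, B + 1):
                rows.append((t, h, p, slot, False, np.nan, np.nan, 0, 0))
    rec = pd.DataFrame(
        rows, columns=["year", "stratum", "plot", "slot", "observed", "y", "x", "z", "q"]
    )
    if R is not None and m_aug > 0:
        rec.attrs["ratio"] = R / m_aug
    return AugmentResult(records=rec, m=m, m_aug=m_aug)


@dataclass
class _Block:
    """Per stratum-year arrays over sampled plots (P plots x B slots)."""

    h: int
    t: int
    B: int
    N: int            # total plots in the stratum-year
    plots: list
    obs: np.ndarray   # (P, B) bool
    x: np.ndarray     # (P, B)
    y: np.ndarray     # (P, B)
    q: np.ndarray     # (P, B)

    @property
    def P(self) -> int:
        return self.obs.shape[0]

    # sufficient statistics of the observed records
    def obs_stats(self):
        n_obs = int(self.obs.sum())
        sum_y = float(self.y[self.obs].sum()) if n_obs else 0.0
        return n_obs, sum_y


@dataclass
class AugmentedData:
    """Augmented survey data arranged in per-(stratum, year) blocks."""

    blocks: dict
    years: tuple
    strata: tuple
    B_h: dict
    design: pd.DataFrame

    @classmethod
    def from_tables(cls, operational: pd.DataFrame, design: pd.DataFrame, B_h,
                    rng: Optional[np.random.Generator] = None) -> "AugmentedData":
        aug = augment(operational, B_h, design)
        rec = aug.records
        B_map = {h + 1: int(b) for h, b in enumerate(B_h)} if not isinstance(B_h, dict) else B_h
        des = design.set_index(["stratum", "year"])
        blocks = {}
        years = tuple(sorted(design["year"].unique().astype(int)))
        strata = tuple(sorted(design["stratum"].unique().astype(int)))
        for h in strata:
            for t in years:
                if (h, t) not in des.index:
                    continue
                B = B_map[h]
                sub = rec[(rec["year"] == t) & (rec["stratum"] == h)]
                plots = list(dict.fromkeys(sub["plot"]))
                P = len(plots)
                obs = np.zeros((P, B), dtype=bool)
                x = np.full((P, B), np.nan)
                y = np.ones((P, B))
                q = np.zeros((P, B), dtype=np.int8)
                for i, p in enumerate(plots):
                    ps = sub[sub["plot"] == p]
                    k = ps["slot"].to_numpy(dtype=int) - 1
                    obs[i, k] = ps["observed"].to_numpy(dtype=bool)
                    x[i, k] = ps["x"].to_numpy(dtype=float)
                    yv = ps["y"].to_numpy(dtype=float)
                    y[i, k] = np.where(np.isnan(yv), 1.0, yv)
                    q[i, k] = ps["q"].to_numpy(dtype=np.int8)
                blocks[(h, t)] = _Block(
                    h=h, t=t, B=B, N=int(des.loc[(h, t), "N"]), plots=plots,
                    obs=obs, x=x, y=y, q=q,
                )
        return cls(blocks=blocks, years=years, strata=strata, B_h=B_map, design=design)


# ----------------------------------------------------------------------
# model state
# ----------------------------------------------------------------------
@dataclass
class ThetaState:
    """All non-detection parameters of one MCMC state.

    Keys of the per-block dicts are (stratum, year).  TS-only fields are
    None for the FE and joint models.
    """

    psi: dict                      # (h,t) -> (P,) per-plot presence probs
    mu_psi: dict                   # (h,t) -> float (FE/joint; derived under TS)
    rho_psi: dict
    lam: dict                      # (h,t) -> shifted-Poisson rate
    mu_x: dict
    rho_x: dict
    mu_h: Optional[dict] = None    # TS: stratum mean of log lambda
    delta: Optional[dict] = None   # TS: (h,t) -> yearly random effect
    sigma_h: Optional[dict] = None # TS: random-effect sd per stratum
    beta_psi: Optional[np.ndarray] = None  # TS: 6 spline/intercept coefs
    # latent record arrays (views into the sampler's data blocks)
    latent_x: dict = field(default_factory=dict)
    latent_y: dict = field(default_factory=dict)
    latent_q: dict = field(default_factory=dict)

    def copy(self) -> "ThetaState":
        return ThetaState(
            psi={k: v.copy() for k, v in self.psi.items()},
            mu_psi=dict(self.mu_psi), rho_psi=dict(self.rho_psi),
            lam=dict(self.lam), mu_x=dict(self.mu_x), rho_x=dict(self.rho_x),
            mu_h=dict(self.mu_h) if self.mu_h is not None else None,
            delta=dict(self.delta) if self.delta is not None else None,
            sigma_h=dict(self.sigma_h) if self.sigma_h is not None else None,
            beta_psi=None if self.beta_psi is None else self.beta_psi.copy(),
            latent_x={k: v.copy() for k, v in self.latent_x.items()},
            latent_y={k: v.copy() for k, v in self.latent_y.items()},
            latent_q={k: v.copy() for k, v in self.latent_q.items()},
        )


def _shapes(mu: float, rho: float) -> tuple[float, float]:
    return mu * rho, rho - mu * rho


def _ts_design(strata, years, basis: SplineBasis) -> dict:
    """Design rows for the yearly presence-probability mean.

    Stratum dummies followed by the spline basis at each year.  The
    spline columns are centered and scaled to unit sd over the year
    grid: the dummies span the intercept, so the column space (and hence
    the model) is unchanged while the coefficients stay O(1), which both
    conditions the random-walk updates and makes the vague normal prior
    act symmetrically across columns.
    """
    years = list(years)
    strata = list(strata)
    G = basis.evaluate([float(t) for t in years])
    G = G - G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    G = G / sd
    rows = {}
    for h in strata:
        for j, t in enumerate(years):
            row = np.zeros(len(strata) + basis.df)
            row[strata.index(h)] = 1.0
            row[len(strata):] = G[j]
            rows[(h, t)] = row
    return rows


# ----------------------------------------------------------------------
# joint log densities
# ----------------------------------------------------------------------
def _log_density(state: ThetaState, phi: DetectionParams, data: AugmentedData,
                 priors: PriorConfig, model: str,
                 basis: Optional[SplineBasis] = None,
                 include_priors: bool = True) -> float:
    """Unnormalized log joint of (state, latents | Phi) for FE or TS.

    With ``include_priors=False`` only the data-level terms are summed:
    q ~ Bern(psi), psi ~ Beta, (y-1) ~ Poisson, x ~ Beta, z ~ Bern(g q).
    """
    lo, hi = priors.mu_bounds
    rlo, rhi = priors.rho_bounds
    total = 0.0
    if model == "TS":
        if basis is None or state.beta_psi is None:
            raise ValueError("TS density requires a spline basis and beta_psi")
        rows = _ts_design(data.strata, data.years, basis)
        X = np.array([rows[key] for key in data.blocks])
        mu_psi_ts = dict(zip(data.blocks, invlogit(X @ state.beta_psi)))
    for key, blk in data.blocks.items():
        h, t = key
        psi = state.psi[key]
        if np.any((psi <= 0) | (psi >= 1)):
            return _NEG_INF
        if model == "TS":
            mu_p = mu_psi_ts[key]
            lam = math.exp(state.mu_h[h] + state.delta[key])
        else:
            mu_p = state.mu_psi[key]
            lam = state.lam[key]
            if not (lo < mu_p < hi):
                return _NEG_INF
        rho_p = state.rho_psi[key]
        mu_xv, rho_xv = state.mu_x[key], state.rho_x[key]
        if not (rlo < rho_p < rhi and rlo < rho_xv < rhi and lo < mu_xv < hi):
            return _NEG_INF
        if lam <= 0:
            return _NEG_INF
        a_p, b_p = _shapes(mu_p, rho_p)
        a_x, b_x = _shapes(mu_xv, rho_xv)
        q = state.latent_q[key]
        x = state.latent_x[key]
        y = state.latent_y[key]
        if np.any(q[blk.obs] != 1):
            return _NEG_INF          # detected group marked absent
        if np.any((x <= 0) | (x >= 1)) or np.any(y < 1):
            return _NEG_INF
        g = invlogit(phi.beta0g + phi.beta1g * x)
        # z | x, q: observed records z=1 -> log g; augmented z=0 -> log(1 - g q)
        total += float(np.log(g[blk.obs]).sum())
        aug1 = (~blk.obs) & (q == 1)
        total += float(np.log1p(-g[aug1]).sum())
        total += float(_log_shifted_pois(y, lam).sum())
        total += float(_log_beta_pdf(x, a_x, b_x).sum())
        kq = q.sum(axis=1)
        total += float((kq * np.log(psi) + (blk.B - kq) * np.log1p(-psi)).sum())
        total += float(_log_beta_pdf(psi, a_p, b_p).sum())
        # theta priors (block-level)
        if include_priors:
            if model != "TS":
                total += -0.5 * (math.log(lam) / priors.log_lambda_sd) ** 2
            for rho in (rho_p, rho_xv):
                total += -0.5 * ((rho - priors.rho_mean) / priors.rho_sd) ** 2
            # uniform priors on mu contribute constants
    if include_priors and model == "TS":
        for h in data.strata:
            s = state.sigma_h[h]
            if not 0 < s < priors.sigma_bound:
                return _NEG_INF
            total += -0.5 * (state.mu_h[h] / priors.mu_h_sd) ** 2
            deltas = [state.delta[(hh, t)] for (hh, t) in data.blocks if hh == h]
            total += sum(-0.5 * (d / s) ** 2 - math.log(s) for d in deltas)
        total += float(-0.5 * np.sum((state.beta_psi / priors.spline_sd) ** 2))
    return total


def log_density_fe(state: ThetaState, phi: DetectionParams, data: AugmentedData,
                   priors: PriorConfig = PriorConfig(),
                   include_priors: bool = True) -> float:
    """Joint log density of the fixed-effects model (priors on Theta only)."""
    return _log_density(state, phi, data, priors, "FE",
                        include_priors=include_priors)


def log_density_ts(state: ThetaState, phi: DetectionParams, data: AugmentedData,
                   basis: SplineBasis, priors: PriorConfig = PriorConfig(),
                   include_priors: bool = True) -> float:
    """Joint log density of the temporally-smoothed model."""
    return _log_density(state, phi, data, priors, "TS", basis,
                        include_priors=include_priors)


# ----------------------------------------------------------------------
# the sampler
# ----------------------------------------------------------------------
_ALL_UPDATES = ("latent_x", "latent_y", "q", "psi", "psi_hyper", "x_hyper",
                "lambda", "phi")


class GibbsSampler:
    """Metropolis-within-Gibbs sampler for the FE, TS and joint models.

    Parameters
    ----------
    data
        Augmented survey data (see :class:`AugmentedData`).
    model
        "FE", "TS" or "JOINT".
    phi
        Detection parameters; fixed for FE/TS (passed as data), the
        starting value for JOINT.
    trials
        Sightability-trial table (required for JOINT).
    basis
        Year spline basis (required for TS).
    update
        Optional mapping from update-block name to bool, to freeze parts
        of the sweep (used by diagnostics and micro-scale validation).
    hyper_reps
        Number of Metropolis repetitions per sweep for the block-level
        parameters (they are cheap relative to the latent-record updates
        and mix slowest; repeating them shortens burn-in).
    """

    def __init__(self, data: AugmentedData, model: str, phi: DetectionParams,
                 priors: PriorConfig = PriorConfig(),
                 trials: Optional[pd.DataFrame] = None,
                 basis: Optional[SplineBasis] = None,
                 update: Optional[dict] = None,
                 rng: Optional[np.random.Generator] = None,
                 init_jitter: float = 0.0,
                 hyper_reps: int = 3):
        model = model.upper()
        if model not in ("FE", "TS", "JOINT"):
            raise ValueError("model must be FE, TS or JOINT")
        if model == "TS" and basis is None:
            raise ValueError("TS model requires a year spline basis")
        if model == "JOINT" and trials is None:
            raise ValueError("JOINT model requires the sightability trials")
        self.data = data
        self.model = model
        self.priors = priors
        self.basis = basis
        self.rng = rng if rng is not None else np.random.default_rng()
        self.phi = np.array([phi.beta0g, phi.beta1g], dtype=float)
        self.update = {k: True for k in _ALL_UPDATES}
        if update:
            self.update.update(update)
        self.hyper_reps = max(1, int(hyper_reps))
        if trials is not None:
            self._tz = trials["z"].to_numpy(dtype=float)
            self._tx = trials["x"].to_numpy(dtype=float)
        if model == "TS":
            rows = _ts_design(data.strata, data.years, basis)
            self._X = {key: rows[key] for key in data.blocks}
        self._init_state(init_jitter)
        self._init_proposals()

    # ------------------------------------------------------------------
    def _init_state(self, jitter: float) -> None:
        d, rng = self.data, self.rng
        g0 = max(float(invlogit(self.phi[0] + self.phi[1] * 0.4)), 1e-3)
        psi, mu_psi, rho_psi, lam, mu_x, rho_x = {}, {}, {}, {}, {}, {}
        for key, blk in d.blocks.items():
            n_obs, sum_y = blk.obs_stats()
            lam0 = max((sum_y / n_obs - 1.0) if n_obs else 1.0, 0.1)
            xo = blk.x[blk.obs]
            mu_x0 = float(np.clip(xo.mean() if xo.size else 0.4, 0.05, 0.95))
            mdet = blk.obs.sum(axis=1).mean() if blk.P else 0.0
            psi0 = float(np.clip(mdet / (blk.B * g0), 0.02, 0.9))
            if jitter > 0:
                lam0 = float(lam0 * np.exp(jitter * rng.standard_normal()))
                mu_x0 = float(np.clip(mu_x0 + jitter * 0.2 * rng.standard_normal(), 0.05, 0.95))
                psi0 = float(np.clip(psi0 * np.exp(jitter * rng.standard_normal()), 0.02, 0.9))
            mu_psi[key], rho_psi[key] = psi0, 5.0
            lam[key] = lam0
            mu_x[key], rho_x[key] = mu_x0, 5.0
            psi[key] = np.full(blk.P, psi0)
        st = ThetaState(psi=psi, mu_psi=mu_psi, rho_psi=rho_psi, lam=lam,
                        mu_x=mu_x, rho_x=rho_x)
        for key, blk in d.blocks.items():
            a_x, b_x = _shapes(mu_x[key], rho_x[key])
            x = _clip01(blk.x.copy())
            miss = ~blk.obs
            x[miss] = _clip01(rng.beta(a_x, b_x, size=int(miss.sum())))
            y = blk.y.copy()
            y[miss] = 1.0 + rng.poisson(lam[key], size=int(miss.sum()))
            q = blk.q.copy()
            q[miss] = (rng.random(miss.shape) < 0.5 * psi[key][:, None])[miss]
            st.latent_x[key] = x
            st.latent_y[key] = y
            st.latent_q[key] = q
        if self.model == "TS":
            st.mu_h = {h: math.log(max(np.mean([lam[k] for k in d.blocks if k[0] == h]), 0.1))
                       for h in d.strata}
            st.delta = {key: 0.0 for key in d.blocks}
            st.sigma_h = {h: 0.5 for h in d.strata}
            # start the spline coefs by least squares on logit(initial mu_psi)
            X = np.array([self._X[key] for key in d.blocks])
            target = logit(np.array([mu_psi[key] for key in d.blocks]))
            st.beta_psi, *_ = np.linalg.lstsq(X, target, rcond=None)
            if jitter > 0:
                st.beta_psi = st.beta_psi + jitter * self.rng.standard_normal(len(st.beta_psi))
        self.state = st

    def _init_proposals(self) -> None:
        d = self.data
        self._rw = {}
        for key in d.blocks:
            for par in ("mu_psi", "rho_psi", "mu_x", "rho_x", "lam", "delta"):
                self._rw[(par, key)] = AdaptiveScalarRW(step=0.3)
        for h in d.strata:
            self._rw[("mu_h", h)] = AdaptiveScalarRW(step=0.2)
            self._rw[("sigma", h)] = AdaptiveScalarRW(step=0.4)
        if self.model == "TS":
            self._rw_spline = AdaptiveMvRW(len(d.strata) + self.basis.df, step=0.1)
        if self.model == "JOINT":
            self._rw_phi = AdaptiveMvRW(2, step=0.1)

    def freeze_adaptation(self) -> None:
        for rw in self._rw.values():
            rw.freeze()
        if self.model == "TS":
            self._rw_spline.freeze()
        if self.model == "JOINT":
            self._rw_phi.freeze()

    # ------------------------------------------------------------------
    # scalar MH helpers on transformed scales
    # ------------------------------------------------------------------
    def _mh_interval(self, key, value, lo, hi, loglik, logprior):
        """RW Metropolis on the scaled-logit transform of (lo, hi)."""
        rw = self._rw[key]
        u = math.log((value - lo) / (hi - value))
        u_new = rw.propose(u, self.rng)
        # tanh saturates for |u| > ~37; keep the proposal strictly interior
        # so the Jacobian term stays finite
        s_new = min(max(0.5 * (1.0 + math.tanh(0.5 * u_new)), 1e-12), 1.0 - 1e-12)
        v_new = lo + (hi - lo) * s_new
        # log Jacobian of the transform: log((v-lo)(hi-v)/(hi-lo))
        lj = math.log((value - lo) * (hi - value))
        lj_new = math.log((v_new - lo) * (hi - v_new))
        num = loglik(v_new) + logprior(v_new) + lj_new
        den = loglik(value) + logprior(value) + lj
        if math.isfinite(num) and math.log(self.rng.random()) < num - den:
            rw.register(True)
            return v_new
        rw.register(False)
        return value

    def _mh_real(self, key, value, logpost):
        rw = self._rw[key]
        v_new = rw.propose(value, self.rng)
        lp_new = logpost(v_new)
        if math.isfinite(lp_new) and math.log(self.rng.random()) < lp_new - logpost(value):
            rw.register(True)
            return v_new
        rw.register(False)
        return value

    # ------------------------------------------------------------------
    def sweep(self) -> None:
        """One full sweep of updates over parameters and latents."""
        st, d, pr, rng = self.state, self.data, self.priors, self.rng
        phi0, phi1 = self.phi
        lo, hi = pr.mu_bounds
        rlo, rhi = pr.rho_bounds

        # ---- group-size rates ----------------------------------------
        if self.update["lambda"]:
            for _ in range(self.hyper_reps):
                if self.model == "TS":
                    self._sweep_lambda_ts()
                else:
                    for key, blk in d.blocks.items():
                        n_obs, sum_y = blk.obs_stats()

                        def lp(loglam, n_obs=n_obs, sum_y=sum_y):
                            lam = math.exp(loglam)
                            return ((sum_y - n_obs) * loglam - n_obs * lam
                                    - 0.5 * (loglam / pr.log_lambda_sd) ** 2)

                        st.lam[key] = math.exp(
                            self._mh_real(("lam", key), math.log(st.lam[key]), lp))

        # ---- obstruction-distribution parameters ---------------------
        if self.update["x_hyper"]:
            for key, blk in d.blocks.items():
                x = st.latent_x[key]
                use = blk.obs | (st.latent_q[key] == 1)
                xs = x[use]
                n = xs.size
                slx = float(np.log(xs).sum()) if n else 0.0
                sl1x = float(np.log1p(-xs).sum()) if n else 0.0

                def ll_mu(mu, key=key, n=n, slx=slx, sl1x=sl1x):
                    a, b = _shapes(mu, st.rho_x[key])
                    return (a - 1) * slx + (b - 1) * sl1x - n * betaln(a, b)

                def ll_rho(rho, key=key, n=n, slx=slx, sl1x=sl1x):
                    a, b = _shapes(st.mu_x[key], rho)
                    return (a - 1) * slx + (b - 1) * sl1x - n * betaln(a, b)

                for _ in range(self.hyper_reps):
                    st.mu_x[key] = self._mh_interval(
                        ("mu_x", key), st.mu_x[key], lo, hi, ll_mu, lambda v: 0.0)
                    st.rho_x[key] = self._mh_interval(
                        ("rho_x", key), st.rho_x[key], rlo, rhi, ll_rho,
                        lambda v: -0.5 * ((v - pr.rho_mean) / pr.rho_sd) ** 2)

        # ---- latent obstruction and group sizes ----------------------
        for key, blk in d.blocks.items():
            x, y, q = st.latent_x[key], st.latent_y[key], st.latent_q[key]
            miss = ~blk.obs
            if self.update["latent_x"]:
                a_x, b_x = _shapes(st.mu_x[key], st.rho_x[key])
                m0 = miss & (q == 0)
                n0 = int(m0.sum())
                if n0:
                    x[m0] = _clip01(rng.beta(a_x, b_x, size=n0))
                m1 = miss & (q == 1)
                n1 = int(m1.sum())
                if n1:
                    prop = _clip01(rng.beta(a_x, b_x, size=n1))
                    cur = x[m1]
                    g_prop = invlogit(phi0 + phi1 * prop)
                    g_cur = invlogit(phi0 + phi1 * cur)
                    acc = rng.random(n1) < (1.0 - g_prop) / np.maximum(1.0 - g_cur, 1e-300)
                    cur[acc] = prop[acc]
                    x[m1] = cur
            if self.update["latent_y"]:
                n_miss = int(miss.sum())
                if n_miss:
                    y[miss] = 1.0 + rng.poisson(st.lam[key] if self.model != "TS"
                                                else math.exp(st.mu_h[key[0]] + st.delta[key]),
                                                size=n_miss)
            # ---- presence indicators ---------------------------------
            if self.update["q"]:
                g = invlogit(phi0 + phi1 * x)
                psi_col = st.psi[key][:, None]
                w1 = psi_col * (1.0 - g)
                p_q1 = w1 / (w1 + (1.0 - psi_col))
                draw = rng.random(q.shape) < p_q1
                q[miss] = draw[miss]

        # ---- per-plot presence probabilities -------------------------
        if self.update["psi"]:
            for key, blk in d.blocks.items():
                mu_p = self._mu_psi(key)
                a_p, b_p = _shapes(mu_p, st.rho_psi[key])
                k = st.latent_q[key].sum(axis=1)
                st.psi[key] = _clip01(rng.beta(a_p + k, b_p + blk.B - k))

        # ---- presence hyper-parameters -------------------------------
        if self.update["psi_hyper"]:
            if self.model == "TS":
                for _ in range(self.hyper_reps):
                    self._sweep_psi_ts()
            else:
                for key in d.blocks:
                    psi = st.psi[key]
                    slp = float(np.log(psi).sum())
                    sl1p = float(np.log1p(-psi).sum())
                    n = psi.size

                    def ll_mu(mu, key=key, n=n, slp=slp, sl1p=sl1p):
                        a, b = _shapes(mu, st.rho_psi[key])
                        return (a - 1) * slp + (b - 1) * sl1p - n * betaln(a, b)

                    def ll_rho(rho, key=key, n=n, slp=slp, sl1p=sl1p):
                        a, b = _shapes(st.mu_psi[key], rho)
                        return (a - 1) * slp + (b - 1) * sl1p - n * betaln(a, b)

                    for _ in range(self.hyper_reps):
                        st.mu_psi[key] = self._mh_interval(
                            ("mu_psi", key), st.mu_psi[key], lo, hi, ll_mu, lambda v: 0.0)
                        st.rho_psi[key] = self._mh_interval(
                            ("rho_psi", key), st.rho_psi[key], rlo, rhi, ll_rho,
                            lambda v: -0.5 * ((v - pr.rho_mean) / pr.rho_sd) ** 2)

        # ---- detection parameters (joint model only) -----------------
        if self.model == "JOINT" and self.update["phi"]:
            self._sweep_phi()

    # ------------------------------------------------------------------
    def _mu_psi(self, key) -> float:
        if self.model == "TS":
            # clamp so the induced Beta shapes stay strictly positive
            eta = float(self._X[key] @ self.state.beta_psi)
            mu = 0.5 * (1.0 + math.tanh(0.5 * eta))
            return min(max(mu, 1e-6), 1.0 - 1e-6)
        return self.state.mu_psi[key]

    def _sweep_lambda_ts(self) -> None:
        st, d, pr = self.state, self.data, self.priors
        stats = {key: blk.obs_stats() for key, blk in d.blocks.items()}
        for h in d.strata:
            keys_h = [k for k in d.blocks if k[0] == h]

            def lp_mu(mu_h):
                out = -0.5 * (mu_h / pr.mu_h_sd) ** 2
                for k in keys_h:
                    n_obs, sum_y = stats[k]
                    ll = mu_h + st.delta[k]
                    out += (sum_y - n_obs) * ll - n_obs * math.exp(ll)
                return out

            st.mu_h[h] = self._mh_real(("mu_h", h), st.mu_h[h], lp_mu)
            sig = st.sigma_h[h]
            for k in keys_h:
                n_obs, sum_y = stats[k]

                def lp_d(dv, n_obs=n_obs, sum_y=sum_y, mu=st.mu_h[h], sig=sig):
                    ll = mu + dv
                    return ((sum_y - n_obs) * ll - n_obs * math.exp(ll)
                            - 0.5 * (dv / sig) ** 2)

                st.delta[k] = self._mh_real(("delta", k), st.delta[k], lp_d)

            ssq = sum(st.delta[k] ** 2 for k in keys_h)
            T = len(keys_h)

            def lp_sig(s, ssq=ssq, T=T):
                return -T * math.log(s) - 0.5 * ssq / s ** 2

            st.sigma_h[h] = self._mh_interval(
                ("sigma", h), st.sigma_h[h], 1e-6, pr.sigma_bound,
                lp_sig, lambda v: 0.0)

    def _sweep_psi_ts(self) -> None:
        st, d, pr = self.state, self.data, self.priors
        rlo, rhi = pr.rho_bounds
        # rho_psi per block
        for key in d.blocks:
            psi = st.psi[key]
            slp = float(np.log(psi).sum())
            sl1p = float(np.log1p(-psi).sum())
            n = psi.size
            mu_p = self._mu_psi(key)

            def ll_rho(rho, mu_p=mu_p, n=n, slp=slp, sl1p=sl1p):
                a, b = _shapes(mu_p, rho)
                return (a - 1) * slp + (b - 1) * sl1p - n * betaln(a, b)

            st.rho_psi[key] = self._mh_interval(
                ("rho_psi", key), st.rho_psi[key], rlo, rhi, ll_rho,
                lambda v: -0.5 * ((v - pr.rho_mean) / pr.rho_sd) ** 2)
        # spline coefficients, joint MV move
        keys = list(d.blocks)
        X = np.array([self._X[k] for k in keys])
        slp = np.array([float(np.log(st.psi[k]).sum()) for k in keys])
        sl1p = np.array([float(np.log1p(-st.psi[k]).sum()) for k in keys])
        nn = np.array([st.psi[k].size for k in keys], dtype=float)
        rho = np.array([st.rho_psi[k] for k in keys])

        def lp(beta):
            mu = invlogit(X @ beta)
            if np.any((mu <= 1e-12) | (mu >= 1 - 1e-12)):
                return _NEG_INF
            a = mu * rho
            b = rho - a
            ll = float(np.sum((a - 1) * slp + (b - 1) * sl1p - nn * betaln(a, b)))
            return ll - 0.5 * float(beta @ beta) / pr.spline_sd ** 2

        rw = self._rw_spline
        cand = rw.propose(st.beta_psi, self.rng)
        if math.log(self.rng.random()) < lp(cand) - lp(st.beta_psi):
            st.beta_psi = cand
            rw.register(True, cand)
        else:
            rw.register(False, st.beta_psi)

    def _phi_loglik(self, phi: np.ndarray) -> float:
        eta = phi[0] + phi[1] * self._tx
        ll = float(np.sum(self._tz * eta - np.logaddexp(0.0, eta)))
        for key, blk in self.data.blocks.items():
            x = self.state.latent_x[key]
            q = self.state.latent_q[key]
            xo = x[blk.obs]
            if xo.size:
                eo = phi[0] + phi[1] * xo
                ll += float(np.sum(eo - np.logaddexp(0.0, eo)))
            xa = x[(~blk.obs) & (q == 1)]
            if xa.size:
                ll += float(np.sum(-np.logaddexp(0.0, phi[0] + phi[1] * xa)))
        return ll - 0.5 * float(phi @ phi) / self.priors.phi_sd ** 2

    def _sweep_phi(self) -> None:
        rw = self._rw_phi
        cand = rw.propose(self.phi, self.rng)
        if math.log(self.rng.random()) < self._phi_loglik(cand) - self._phi_loglik(self.phi):
            self.phi = cand
            rw.register(True, cand)
        else:
            rw.register(False, self.phi)

    # ------------------------------------------------------------------
    def abundance_draw(self) -> dict:
        """One posterior(-predictive) draw of yearly abundance.

        Sampled plots contribute sum(y*q) over their B_h records;
        unsampled plots are drawn fresh from the current parameters
        (psi ~ Beta, group count ~ Binomial(B, psi), sizes shifted
        Poisson).
        """
        st, d, rng = self.state, self.data, self.rng
        tau = {t: 0.0 for t in d.years}
        for key, blk in d.blocks.items():
            h, t = key
            tau[t] += float((st.latent_y[key] * st.latent_q[key]).sum())
            n_unsamp = blk.N - blk.P
            if n_unsamp < 0:
                raise ValueError(
                    f"stratum {h}, year {t}: design lists {blk.N} plots but "
                    f"{blk.P} were sampled")
            if n_unsamp:
                mu_p = self._mu_psi(key)
                a_p, b_p = _shapes(mu_p, st.rho_psi[key])
                lam = (st.lam[key] if self.model != "TS"
                       else math.exp(st.mu_h[h] + st.delta[key]))
                psi_u = rng.beta(a_p, b_p, size=n_unsamp)
                k = rng.binomial(blk.B, psi_u)
                ktot = int(k.sum())
                tau[t] += ktot + (rng.poisson(lam * ktot) if ktot else 0)
        return tau

    # ------------------------------------------------------------------
    def monitored(self) -> dict:
        """Current values of all top-level (non-latent) parameters."""
        st = self.state
        out = {}
        for key in self.data.blocks:
            h, t = key
            out[f"rho_psi[{h},{t}]"] = st.rho_psi[key]
            out[f"mu_x[{h},{t}]"] = st.mu_x[key]
            out[f"rho_x[{h},{t}]"] = st.rho_x[key]
            if self.model == "TS":
                out[f"delta[{h},{t}]"] = st.delta[key]
            else:
                out[f"mu_psi[{h},{t}]"] = st.mu_psi[key]
                out[f"lambda[{h},{t}]"] = st.lam[key]
        if self.model == "TS":
            for h in self.data.strata:
                out[f"mu_h[{h}]"] = st.mu_h[h]
                out[f"sigma_h[{h}]"] = st.sigma_h[h]
            for i, b in enumerate(st.beta_psi):
                out[f"beta_psi[{i}]"] = float(b)
        if self.model == "JOINT":
            out["beta0g"] = float(self.phi[0])
            out["beta1g"] = float(self.phi[1])
        return out

    def run(self, n_iter: int, n_burn: int, thin: int = 1,
            record_abundance: bool = True) -> pd.DataFrame:
        """Run the chain and return retained draws as a DataFrame."""
        if n_burn >= n_iter:
            raise ValueError("n_burn must be < n_iter")
        rows = []
        for it in range(n_iter):
            if it == n_burn:
                self.freeze_adaptation()
            self.sweep()
            if it >= n_burn and (it - n_burn) % thin == 0:
                row = {"iter": it}
                row.update(self.monitored())
                if record_abundance:
                    for t, v in self.abundance_draw().items():
                        row[f"tau[{t}]"] = v
                rows.append(row)
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# functional wrappers (spec surface)
# ----------------------------------------------------------------------
def gibbs_step(sampler: GibbsSampler) -> ThetaState:
    """Advance the sampler one full sweep and return a state snapshot."""
    sampler.sweep()
    return sampler.state


def abundance_draw(sampler: GibbsSampler) -> dict:
    """Posterior(-predictive) yearly abundance at the sampler's current state."""
    return sampler.abundance_draw()
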