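"""Small adaptive Metropolis helpers shared by the samplers.

All proposals are Gaussian random walks on an unconstrained scale; step
sizes adapt toward a target acceptance rate during burn-in (Robbins-Monro
on the log step size) and are frozen afterwards so the chains target the
exact posterior.
"""
from __future__ import annotations

import math

import numpy as np

__all__ = ["AdaptiveScalarRW", "AdaptiveMvRW", "invlogit", "logit"]


def invlogit(u):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(u, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


class AdaptiveScalarRW:
    """Scalar random-walk Metropolis step with burn-in adaptation.

    Parameters are updated on an unconstrained scale supplied by the
    caller; this class only manages the step size and accept/reject.
    """

    def __init__(self, step: float = 0.5, target: float = 0.44):
        self.log_step = float(np.log(step))
        self.target = target
        self.n_prop = 0
        self.n_acc = 0
        self.adapting = True

    def propose(self, value: float, rng: np.random.Generator) -> float:
        return value + math.exp(self.log_step) * rng.standard_normal()

    def register(self, accepted: bool) -> None:
        self.n_prop += 1
        self.n_acc += int(accepted)
        if self.adapting:
            gamma = min(0.25, 2.0 / math.sqrt(self.n_prop + 10.0))
            self.log_step += gamma * ((1.0 if accepted else 0.0) - self.target)
            self.log_step = min(max(self.log_step, -8.0), 4.0)

    def freeze(self) -> None:
        self.adapting = False

    @property
    def acceptance_rate(self) -> float:
        return self.n_acc / self.n_prop if self.n_prop else float("nan")


class AdaptiveMvRW:
    """Multivariate Gaussian random-walk proposal with covariance adaptation.

    During burn-in the proposal covariance tracks the running sample
    covariance of the chain (scaled by 2.38^2/d), the standard adaptive
    Metropolis recipe; adaptation is frozen afterwards.
    """

    def __init__(self, dim: int, step: float = 0.1, target: float = 0.3):
        self.dim = dim
        self.scale = float(step)
        self.target = target
        self.chol = np.eye(dim)
        self._mean = np.zeros(dim)
        self._cov = np.eye(dim)
        self.n_prop = 0
        self.n_acc = 0
        self.adapting = True

    def propose(self, value: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return value + self.scale * (self.chol @ rng.standard_normal(self.dim))

    def register(self, accepted: bool, value: np.ndarray) -> None:
        self.n_prop += 1
        self.n_acc += int(accepted)
        if not self.adapting:
            return
        n = self.n_prop
        gamma = min(0.25, 2.0 / np.sqrt(n + 10.0))
        self.scale *= float(np.exp(gamma * ((1.0 if accepted else 0.0) - self.target)))
        self.scale = float(np.clip(self.scale, 1e-4, 50.0))
        w = 1.0 / (n + 10.0)
        d = value - self._mean
        self._mean = self._mean + w * d
        self._cov = (1 - w) * self._cov + w * np.outer(d, d)
        if n % 50 == 0:
            try:
                self.chol = np.linalg.cholesky(
                    self._cov + 1e-8 * np.eye(self.dim)
                )
            except np.linalg.LinAlgError:
                pass

    def freeze(self) -> None:
        self.adapting = False

    @property
    def acceptance_rate(self) -> float:
        return self.n_acc / self.n_prop if self.n_prop else float("nan")
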