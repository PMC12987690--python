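"""Sigmoid policy class, action sampling, and importance-sampling weights.

A policy is parameterized by a vector ``theta`` of length d+1 (intercept
first) and a fixed scale ``tau``: the probability of action ``a`` given
features ``x`` is ``sigmoid(a * g(x, theta) / tau)`` with linear decision
score ``g(x, theta) = theta_0 + sum_j x_j theta_j``.  The class constrains
``||theta||_2 <= 1``; ``tau`` is a configuration constant (default 0.2),
never optimized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import as_rng
from .data_model import TrajectoryDataset

__all__ = [
    "PolicyParams",
    "decision_score",
    "action_prob",
    "sample_action",
    "stepwise_weights",
    "normalized_weights",
]

_BALL_TOL = 1e-8


@dataclass
class PolicyParams:
    """theta = (intercept, coefficients); tau = positive scale."""

    theta: np.ndarray
    tau: float = 0.2

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 1 or self.theta.size < 1:
            raise ValueError("theta must be a 1-d vector of length d+1")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")
        if np.linalg.norm(self.theta) > 1.0 + _BALL_TOL:
            raise ValueError(f"||theta||_2 = {np.linalg.norm(self.theta)} exceeds 1")
        if not (self.tau > 0):
            raise ValueError("tau must be positive")

    @property
    def d(self) -> int:
        return self.theta.size - 1


def decision_score(params: PolicyParams, x) -> np.ndarray | float:
    """Linear score theta_0 + x . theta_{1:d}; x may be (d,) or (..., d)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.d:
        raise ValueError(f"feature length {x.shape[-1]} != d={params.d}")
    return params.theta[0] + x @ params.theta[1:]


def _log_sigmoid(z):
    return -np.logaddexp(0.0, -z)


def action_prob(params: PolicyParams, x, a) -> np.ndarray | float:
    """pi_theta(a | x) = sigmoid(a * g(x, theta) / tau), strictly in (0, 1)."""
    a = np.asarray(a)
    if not np.all(np.isin(a, (-1, 1))):
        raise ValueError("action must be -1 or +1")
    g = decision_score(params, x)
    return np.exp(_log_sigmoid(a * g / params.tau))


def sample_action(params: PolicyParams, x, rng) -> np.ndarray | int:
    """Draw +1 with probability pi_theta(+1|x), else -1. Vectorized over x."""
    rng = as_rng(rng)
    p_plus = action_prob(params, x, 1)
    u = rng.random(np.shape(p_plus))
    a = np.where(u < p_plus, 1, -1)
    return int(a) if a.ndim == 0 else a


def stepwise_weights(params: PolicyParams, ds: TrajectoryDataset,
                     cap: float | None = None) -> np.ndarray:
    """Cumulative importance weights rho_{i,1:t} for t = 0..T.

    Column t holds prod_{k<=t} pi_theta(A_k|X_k) / mu_k(A_k|H_k); column 0
    is the empty product 1.  Computed in log-space for long horizons.
    ``cap`` truncates individual weights from above; it is off by default —
    the estimators stabilize through self-normalization, not truncation.
    """
    if np.any(ds.behavior_prob <= 0):
        raise ValueError("behavior_prob must be strictly positive")
    g = params.theta[0] + ds.features @ params.theta[1:]  # (n, T)
    log_pi = _log_sigmoid(ds.actions * g / params.tau)
    log_ratio = log_pi - np.log(ds.behavior_prob)
    log_rho = np.cumsum(log_ratio, axis=1)
    rho = np.empty((ds.n, ds.T + 1))
    rho[:, 0] = 1.0
    rho[:, 1:] = np.exp(log_rho)
    if not np.all(np.isfinite(rho)):
        raise FloatingPointError("importance weights overflowed")
    if cap is not None:
        if cap <= 0:
            raise ValueError("cap must be positive")
        np.minimum(rho, cap, out=rho)
    return rho


def normalized_weights(rho: np.ndarray):
    """Self-normalize weights: omega_t = mean_i rho_{i,1:t}; rho / omega.

    Returns ``(omega, normalized)`` with omega of length T+1 (omega_0 = 1)
    and ``normalized`` having column means exactly 1.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("weights must be positive")
    omega = rho.mean(axis=0)
    assert np.all(omega > 0)
    return omega, rho / omega
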