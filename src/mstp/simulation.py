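"""Synthetic trajectory generators, policy evaluation, and grid search.

Two scenarios share the same skeleton: multivariate-normal initial states,
exponentially weighted moving-average (EWMA) state summaries, Gaussian
innovations, and a uniform-random behavior policy.  Only the first two
features drive the dynamics of the reward-relevant coordinates; features
j >= 3 are autoregressive noise.  The reward attached to stage t is a
function of the *next* state and the stage-t action, so generation runs
one stage past the returned horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import as_rng
from .data_model import TrajectoryDataset
from .policy import PolicyParams, action_prob, normalized_weights, stepwise_weights

__all__ = [
    "ScenarioConfig",
    "EvalResult",
    "covariance_matrix",
    "simulate",
    "evaluate_on_policy",
    "ipw_value",
    "grid_search_theta_star",
]


@dataclass
class ScenarioConfig:
    scenario: int
    n: int
    T: int
    d: int
    sigma_diag: float = 4.0
    sigma_12: float = 1.0
    sigma_band: float = 0.2
    innovation_sd: float = 0.4
    ewma_old: float = 0.2
    ewma_new: float = 0.8
    behavior_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.d < 2:
            raise ValueError("d must be at least 2")
        if not (self.n >= 1 and self.T >= 1):
            raise ValueError("n and T must be positive")
        if not (0.0 < self.behavior_prob < 1.0):
            raise ValueError("behavior_prob must lie in (0, 1)")
        np.linalg.cholesky(covariance_matrix(self))  # positive definite or raise


@dataclass
class EvalResult:
    mean_average_reward: float
    se: float
    n_eval: int

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("se must be nonnegative")


def covariance_matrix(cfg: ScenarioConfig) -> np.ndarray:
    """Initial-state covariance: common variance, (1,2) covariance, band."""
    sigma = np.zeros((cfg.d, cfg.d))
    np.fill_diagonal(sigma, cfg.sigma_diag)
    sigma[0, 1] = sigma[1, 0] = cfg.sigma_12
    for j in range(2, cfg.d):  # 1-based pairs (j-1, j) for j in 3..d
        sigma[j - 1, j] = sigma[j, j - 1] = cfg.sigma_band
    return sigma


def _transition(cfg: ScenarioConfig, xt: np.ndarray, a: np.ndarray,
                eps: np.ndarray) -> np.ndarray:
    """One state update from the EWMA summary ``xt`` (n, d) and action a (n,)."""
    nxt = np.empty_like(xt)
    if cfg.scenario == 1:
        nxt[:, 0] = 0.8 * xt[:, 0] + 0.3 * a * xt[:, 0] + 0.2 * xt[:, 1]
        nxt[:, 1] = (0.8 * xt[:, 1] - 0.3 * a * xt[:, 1]
                     + a * np.tanh((xt[:, 0] - xt[:, 1]) / 2.0))
    else:
        nxt[:, 0] = 0.8 * xt[:, 0] + 0.3 * a * xt[:, 0] + 0.1 * xt[:, 1]
        nxt[:, 1] = 0.8 * xt[:, 0] + 0.2 * a * xt[:, 1] + 0.2 * xt[:, 1]
    if cfg.d > 2:
        nxt[:, 2:] = 0.9 * xt[:, 2:]
    return nxt + eps


def _reward(cfg: ScenarioConfig, x_next: np.ndarray, a: np.ndarray) -> np.ndarray:
    s = x_next[:, 0] + x_next[:, 1]
    if cfg.scenario == 1:
        return np.logaddexp(0.0, s) - 0.5 * a  # log(1 + exp(s))
    return s - 0.6 * a


def _simulate_from_noise(cfg: ScenarioConfig, policy, z1, eps, u) -> TrajectoryDataset:
    """Deterministic generator given standard-normal and uniform draws.

    ``z1`` (n, d) seeds the initial state, ``eps`` (n, T, d) the
    innovations, ``u`` (n, T) the action draws.  Sharing these across
    candidate policies yields common-random-number evaluation.
    """
    L = np.linalg.cholesky(covariance_matrix(cfg))
    x = z1 @ L.T
    x_ewma = x.copy()
    n = x.shape[0]
    features = np.empty((n, cfg.T, cfg.d))
    actions = np.empty((n, cfg.T), dtype=int)
    rewards = np.empty((n, cfg.T))
    mu = np.empty((n, cfg.T))
    for t in range(cfg.T):
        features[:, t, :] = x
        if policy is None or (isinstance(policy, str) and policy == "behavior"):
            p_plus = np.full(n, cfg.behavior_prob)
        else:
            p_plus = np.asarray(action_prob(policy, x, 1))
        a = np.where(u[:, t] < p_plus, 1, -1)
        actions[:, t] = a
        mu[:, t] = np.where(a == 1, p_plus, 1.0 - p_plus)
        x = _transition(cfg, x_ewma, a, cfg.innovation_sd * eps[:, t, :])
        rewards[:, t] = _reward(cfg, x, a)
        x_ewma = cfg.ewma_old * x_ewma + cfg.ewma_new * x
    return TrajectoryDataset(features, actions, rewards, mu)


def simulate(cfg: ScenarioConfig, policy=None, seed=None) -> TrajectoryDataset:
    """Generate n trajectories of T stages under the behavior policy
    (``policy=None`` or ``"behavior"``) or a supplied :class:`PolicyParams`."""
    rng = as_rng(cfg.seed if seed is None else seed)
    z1 = rng.standard_normal((cfg.n, cfg.d))
    eps = rng.standard_normal((cfg.n, cfg.T, cfg.d))
    u = rng.random((cfg.n, cfg.T))
    return _simulate_from_noise(cfg, policy, z1, eps, u)


def evaluate_on_policy(cfg: ScenarioConfig, policy, n_eval: int,
                       seed=None) -> EvalResult:
    """Monte-Carlo average reward (1/T) sum_t R_t under the given policy."""
    if n_eval < 1:
        raise ValueError("n_eval must be positive")
    eval_cfg = ScenarioConfig(**{**cfg.__dict__, "n": n_eval})
    rng = as_rng(cfg.seed if seed is None else seed)
    ds = simulate(eval_cfg, policy, seed=rng)
    per_subject = ds.rewards.mean(axis=1)
    se = per_subject.std(ddof=1) / np.sqrt(n_eval) if n_eval > 1 else 0.0
    return EvalResult(float(per_subject.mean()), float(se), n_eval)


def ipw_value(ds_test: TrajectoryDataset, policy: PolicyParams) -> EvalResult:
    """Normalized-IPW estimate of the average reward of ``policy`` from
    held-out behavior-policy data."""
    rho = stepwise_weights(policy, ds_test)
    _, rho_n = normalized_weights(rho)
    contrib = (rho_n[:, 1:] * ds_test.rewards).mean(axis=1)  # per-subject
    se = contrib.std(ddof=1) / np.sqrt(ds_test.n) if ds_test.n > 1 else 0.0
    return EvalResult(float(contrib.mean()), float(se), ds_test.n)


def _sphere_grid(k: int, res: float) -> np.ndarray:
    """Angular grid on the unit sphere in R^k (k in 1..3), step ~res radians."""
    if k == 1:
        return np.array([[1.0], [-1.0]])
    if k == 2:
        ang = np.arange(0.0, 2.0 * np.pi, res)
        return np.column_stack([np.cos(ang), np.sin(ang)])
    if k == 3:
        phis = np.arange(0.0, np.pi + res / 2.0, res)
        pts = []
        for phi in phis:
            n_psi = max(1, int(np.ceil(2.0 * np.pi * max(np.sin(phi), 1e-9) / res)))
            for psi in np.arange(n_psi) * (2.0 * np.pi / n_psi):
                pts.append([np.cos(phi), np.sin(phi) * np.cos(psi),
                            np.sin(phi) * np.sin(psi)])
        return np.array(pts)
    raise ValueError("grid search supports at most 3 active coordinates")


def grid_search_theta_star(cfg: ScenarioConfig, grid_resolution: float = 0.05,
                           n_eval: int = 200_000, active=(0, 1, 2),
                           tau: float = 0.2, seed=None):
    """Locate the best policy on the sphere restricted to ``active`` coords.

    ``active`` indexes the policy vector (0 = intercept).  Coordinates
    outside ``active`` are irrelevant to the reward by construction and are
    held at zero.  All candidates are evaluated on common random numbers;
    only the features the policy or dynamics read are simulated.  Returns
    (PolicyParams of full length d+1, value table).
    """
    active = sorted(set(active))
    k = len(active)
    if k == 0:
        raise ValueError("active must be nonempty")
    grid = _sphere_grid(k, grid_resolution)
    if grid.size == 0:
        raise ValueError("empty grid")

    # reward depends only on features 1..2; simulate the minimal block
    d_sim = max(2, max([a for a in active if a > 0], default=2))
    sim_cfg = ScenarioConfig(**{**cfg.__dict__, "n": n_eval, "d": d_sim})
    rng = as_rng(cfg.seed if seed is None else seed)
    z1 = rng.standard_normal((n_eval, d_sim))
    eps = rng.standard_normal((n_eval, cfg.T, d_sim))
    u = rng.random((n_eval, cfg.T))

    values = np.empty(len(grid))
    for g, point in enumerate(grid):
        theta_sim = np.zeros(d_sim + 1)
        theta_sim[active] = point
        ds = _simulate_from_noise(sim_cfg, PolicyParams(theta_sim, tau), z1, eps, u)
        values[g] = ds.rewards.mean()
    best = int(np.argmax(values))  # ties: first index
    theta = np.zeros(cfg.d + 1)
    theta[active] = grid[best]
    table = {"grid": grid, "values": values, "active": active,
             "best_index": best, "n_eval": n_eval}
    return PolicyParams(theta, tau), table
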