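"""Doubly robust value loss and its symmetric-difference derivatives.

The loss for one trajectory is

    l_i(theta) = - sum_t { rho_{i,1:t} [R_{i,t} - Q_t(X_{i,t}, A_{i,t})]
                           + rho_{i,1:t-1} U_t(X_{i,t}) },

with U_t the exact pi_theta-expectation of Q_t over both actions, and the
overall loss l(theta) the average over trajectories (equal to minus the
estimated value).  Weights may be self-normalized by their per-stage means
(omega), in which case omega is treated as a function of theta and
recomputed at every evaluation point.

Derivatives are numeric symmetric difference quotients.  Evaluation points
that leave the unit ball are renormalized onto the sphere; when the base
point itself lies on the sphere both perturbed points are projected onto
the sphere so the quotients estimate derivatives of the loss restricted to
the sphere (the constrained estimand's geometry).  A degenerate projected
pair falls back to the one-sided Newton quotient toward the feasible side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_model import TrajectoryDataset
from .nuisance import NuisanceModel, q_value_arrays
from .policy import PolicyParams

__all__ = [
    "LossContext",
    "trajectory_loss",
    "loss",
    "penalized_loss",
    "numeric_gradient",
    "numeric_hessian",
    "per_subject_gradients",
    "numdiff_gradient",
    "numdiff_hessian",
]

_SPHERE_TOL = 1e-8


def _log_sigmoid(z):
    return -np.logaddexp(0.0, -z)


@dataclass
class LossContext:
    """Dataset + fitted nuisance + evaluation settings, with caches."""

    ds: TrajectoryDataset
    nuisance: NuisanceModel
    tau: float
    use_normalized_weights: bool = True
    diff_step: float = 1e-4

    def __post_init__(self):
        if not (0.0 < self.diff_step <= 0.1):
            raise ValueError("diff_step must lie in (0, 0.1]")
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        ds = self.ds
        self._X2d = np.ascontiguousarray(ds.features.reshape(ds.n * ds.T, ds.d))
        self._A = ds.actions.astype(float)
        self._plus_mask = (ds.actions == 1)[..., None]
        self._inv_mu = (1.0 / ds.behavior_prob)[..., None]
        self._logmu = np.log(ds.behavior_prob)
        self._q_taken, self._q_plus, self._q_minus = q_value_arrays(self.nuisance, ds)
        self._q_taken3 = self._q_taken[..., None]
        self._r3 = ds.rewards[..., None]
        self._qp3 = self._q_plus[..., None]
        self._qm3 = self._q_minus[..., None]

    @property
    def dim(self) -> int:
        return self.ds.d + 1

    def step_for(self, theta: np.ndarray) -> float:
        return self.diff_step * max(1.0, float(np.linalg.norm(theta)))

    # ---- batched evaluation ------------------------------------------------

    def eval_batch(self, thetas: np.ndarray, per_subject: bool = False,
                   omega_override: np.ndarray | None = None) -> np.ndarray:
        """Loss at each row of ``thetas`` (P, d+1).

        Rows with L2 norm > 1 are renormalized to the sphere before
        evaluation.  Returns shape (P,) or, with ``per_subject``, (n, P).
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        norms = np.linalg.norm(thetas, axis=1)
        scale = np.where(norms > 1.0 + _SPHERE_TOL, norms, 1.0)
        thetas = thetas / scale[:, None]

        n, T = self.ds.n, self.ds.T
        P = thetas.shape[0]
        g = (self._X2d @ thetas[:, 1:].T).reshape(n, T, P) + thetas[:, 0]
        pi_plus = expit(g / self.tau)
        pi_taken = np.where(self._plus_mask, pi_plus, 1.0 - pi_plus)
        ratio = pi_taken * self._inv_mu
        # products of bounded ratios; columns that fully underflow are rejected
        rho = np.cumprod(ratio, axis=1) if T > 1 else ratio  # (n, T, P)

        if self.use_normalized_weights:
            omega = rho.mean(axis=0) if omega_override is None else omega_override
            if np.any(omega <= 0.0):
                raise FloatingPointError("importance weights underflowed to zero")
            rho_cur = rho / omega
            omega_prev = np.vstack([np.ones((1, P)), omega[:-1]])
            rho_prev = np.concatenate(
                [np.ones((n, 1, P)), rho[:, :-1, :]], axis=1
            ) / omega_prev
        else:
            rho_cur = rho
            rho_prev = np.concatenate([np.ones((n, 1, P)), rho[:, :-1, :]], axis=1)

        u = pi_plus * self._qp3 + (1.0 - pi_plus) * self._qm3
        li = -(
            (rho_cur * (self._r3 - self._q_taken3)).sum(axis=1)
            + (rho_prev * u).sum(axis=1)
        )  # (n, P)
        return li if per_subject else li.mean(axis=0)

    def omega_at(self, theta: np.ndarray) -> np.ndarray | None:
        """Per-stage weight means omega_{1:t} at theta, shape (T,); None if off."""
        if not self.use_normalized_weights:
            return None
        theta = np.asarray(theta, dtype=float)
        n, T = self.ds.n, self.ds.T
        g = (self._X2d @ theta[1:]).reshape(n, T) + theta[0]
        log_rho = np.cumsum(_log_sigmoid(self._A * g / self.tau) - self._logmu, axis=1)
        return np.exp(log_rho).mean(axis=0)


def trajectory_loss(ctx: LossContext, theta: PolicyParams, i: int) -> float:
    """l_i at subject i (0-based index); omega shared from the full dataset."""
    if not (0 <= i < ctx.ds.n):
        raise IndexError(f"subject index {i} out of range")
    li = ctx.eval_batch(theta.theta[None, :], per_subject=True)
    return float(li[i, 0])


def loss(ctx: LossContext, theta: PolicyParams) -> float:
    """Average trajectory loss; equals minus the estimated value."""
    return float(ctx.eval_batch(theta.theta[None, :])[0])


def penalized_loss(ctx: LossContext, theta: PolicyParams, lambda_theta: float) -> float:
    """loss + lambda * ||theta||_1 (L1 over all coordinates incl. intercept)."""
    if lambda_theta < 0:
        raise ValueError("lambda_theta must be nonnegative")
    return loss(ctx, theta) + lambda_theta * float(np.abs(theta.theta).sum())


# ---- generic symmetric-difference machinery --------------------------------


def _pair_points(theta: np.ndarray, j: int, h: float):
    """Evaluation pair for coordinate j with unit-ball constraint handling.

    Returns (p_plus, p_minus, denom) where the quotient is
    (f(p_plus) - f(p_minus)) / denom.
    """
    on_sphere = np.linalg.norm(theta) >= 1.0 - _SPHERE_TOL
    p_plus = theta.copy()
    p_plus[j] += h
    p_minus = theta.copy()
    p_minus[j] -= h
    if on_sphere:
        q_plus = p_plus / np.linalg.norm(p_plus)
        q_minus = p_minus / np.linalg.norm(p_minus)
        if np.linalg.norm(q_plus - q_minus) < 1e-12:
            # purely radial coordinate: only the one-sided quotient is usable
            feas = p_minus if np.linalg.norm(p_minus) <= 1.0 else p_plus
            return theta.copy(), feas, h if feas is p_minus else -h
        return q_plus, q_minus, 2.0 * h
    return p_plus, p_minus, 2.0 * h


def numdiff_gradient(f, theta: np.ndarray, h: float) -> np.ndarray:
    """Symmetric-difference gradient of a batched callable f(thetas)->(P,)."""
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    pts, denoms = [], []
    for j in range(p):
        a, b, denom = _pair_points(theta, j, h)
        pts.extend([a, b])
        denoms.append(denom)
    vals = f(np.array(pts))
    grad = np.empty(p)
    for j in range(p):
        grad[j] = (vals[2 * j] - vals[2 * j + 1]) / denoms[j]
    return grad


def numdiff_hessian(f, theta: np.ndarray, h: float) -> np.ndarray:
    """Central second-difference Hessian, symmetrized by construction.

    On the sphere every stencil point is projected back onto the sphere, so
    the result estimates the Hessian of f restricted to the sphere's
    coordinate curves.
    """
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    on_sphere = np.linalg.norm(theta) >= 1.0 - _SPHERE_TOL

    def fix(pt):
        nrm = np.linalg.norm(pt)
        if nrm > 1.0 + _SPHERE_TOL or (on_sphere and nrm > 0):
            return pt / nrm
        return pt

    pts = [theta.copy()]
    radial = []  # coordinates whose projected pair collapses onto theta
    for j in range(p):
        pair = []
        for s in (h, -h):
            q = theta.copy()
            q[j] += s
            pair.append(fix(q))
        if (np.linalg.norm(pair[0] - theta) < 1e-12
                and np.linalg.norm(pair[1] - theta) < 1e-12):
            # purely radial coordinate on the sphere: fall back to the
            # one-sided (Newton) stencil on feasible interior points
            radial.append(j)
            inner1 = theta.copy(); inner1[j] -= h
            inner2 = theta.copy(); inner2[j] -= 2 * h
            pair = [inner1, inner2]
        pts.extend(pair)
    pairs = [(j, k) for j in range(p) for k in range(j + 1, p)]
    for j, k in pairs:
        for sj, sk in ((h, h), (h, -h), (-h, h), (-h, -h)):
            q = theta.copy()
            q[j] += sj
            q[k] += sk
            pts.append(fix(q))
    vals = f(np.array(pts))

    hess = np.empty((p, p))
    f0 = vals[0]
    for j in range(p):
        fp, fm = vals[1 + 2 * j], vals[2 + 2 * j]
        if j in radial:  # one-sided: f(x), f(x-h), f(x-2h)
            hess[j, j] = (f0 - 2.0 * fp + fm) / h**2
        else:
            hess[j, j] = (fp - 2.0 * f0 + fm) / h**2
    base = 1 + 2 * p
    for m, (j, k) in enumerate(pairs):
        fpp, fpm, fmp, fmm = vals[base + 4 * m: base + 4 * m + 4]
        hess[j, k] = hess[k, j] = (fpp - fpm - fmp + fmm) / (4.0 * h**2)
    return 0.5 * (hess + hess.T)


def numeric_gradient(ctx: LossContext, theta: PolicyParams) -> np.ndarray:
    """Gradient of the loss at theta via symmetric difference quotients."""
    h = ctx.step_for(theta.theta)
    return numdiff_gradient(lambda ts: ctx.eval_batch(ts), theta.theta, h)


def numeric_hessian(ctx: LossContext, theta: PolicyParams) -> np.ndarray:
    """Hessian of the loss at theta via central second differences."""
    h = ctx.step_for(theta.theta)
    return numdiff_hessian(lambda ts: ctx.eval_batch(ts), theta.theta, h)


def per_subject_gradients(ctx: LossContext, theta: PolicyParams,
                          freeze_omega: bool = True) -> np.ndarray:
    """Row i = symmetric-difference gradient of l_i; shape (n, d+1).

    With normalization on and ``freeze_omega`` (the default), the shared
    omega is held fixed at its full-data value at theta, so the rows are
    i.i.d. per-subject scores suitable for a sample covariance.
    """
    h = ctx.step_for(theta.theta)
    omega = ctx.omega_at(theta.theta) if freeze_omega else None

    def f(ts):
        if omega is not None:
            return ctx.eval_batch(ts, per_subject=True,
                                  omega_override=omega[:, None] * np.ones((1, len(ts))))
        return ctx.eval_batch(ts, per_subject=True)

    p = theta.theta.size
    pts, denoms = [], []
    for j in range(p):
        a, b, denom = _pair_points(theta.theta, j, h)
        pts.extend([a, b])
        denoms.append(denom)
    vals = f(np.array(pts))  # (n, 2p)
    grads = np.empty((ctx.ds.n, p))
    for j in range(p):
        grads[:, j] = (vals[:, 2 * j] - vals[:, 2 * j + 1]) / denoms[j]
    return grads
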