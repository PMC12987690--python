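"""Per-stage basis regressions used as the augmentation term.

Three estimators of the stage-wise Q functions are supported:

* method 0 — no augmentation, all coefficients zero;
* method 1 — backward-recursive penalized least squares on the pseudo
  response built from the next stage's fitted values (Q-learning style);
* method 2 — variance-minimizing penalized least squares with weighted
  responses and centered designs, fit independently per stage.

Every penalized fit selects its L1 penalty by trajectory-level K-fold
cross validation and is then refit by ordinary least squares on the
selected support (intercept always included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .data_model import TrajectoryDataset
from .policy import PolicyParams, action_prob, normalized_weights, stepwise_weights

__all__ = [
    "BasisSpec",
    "NuisanceModel",
    "basis_features",
    "fit_q_zero",
    "fit_q_backward",
    "fit_q_varmin",
    "predict_q",
    "predict_u",
]


@dataclass
class BasisSpec:
    """Feature basis phi(x). Only the linear kind (intercept, x_1..x_d)."""

    kind: str = "linear"
    includes_intercept: bool = True
    d_prime: int = 0  # dimension of phi(x); 0 means "infer from data" (d+1)

    def __post_init__(self):
        if self.kind != "linear":
            raise ValueError(f"unsupported basis kind: {self.kind!r}")
        if not self.includes_intercept:
            raise ValueError("basis must include an intercept")

    def phi(self, x: np.ndarray) -> np.ndarray:
        """phi(x) = (1, x_1, ..., x_d) applied along the last axis."""
        x = np.asarray(x, dtype=float)
        ones = np.ones(x.shape[:-1] + (1,))
        return np.concatenate([ones, x], axis=-1)

    def resolve(self, d: int) -> "BasisSpec":
        dp = d + 1
        if self.d_prime and self.d_prime != dp:
            raise ValueError(f"d_prime={self.d_prime} inconsistent with d={d}")
        return BasisSpec(self.kind, self.includes_intercept, dp)


def basis_features(basis: BasisSpec, x, a) -> np.ndarray:
    """Phi(x, a) = (phi(x), a * phi(x)), length 2 * d_prime.

    Broadcasts over leading axes of ``x``; ``a`` may be scalar or match
    the leading shape of ``x``.
    """
    a = np.asarray(a)
    if not np.all(np.isin(a, (-1, 1))):
        raise ValueError("action must be -1 or +1")
    phi = basis.phi(x)
    return np.concatenate([phi, a[..., None] * phi if phi.ndim > 1 else a * phi], axis=-1)


@dataclass
class NuisanceModel:
    """Fitted augmentation model: one coefficient vector per stage."""

    method: int
    betas: list  # T arrays, each of length 2 * d_prime
    basis: BasisSpec
    theta_check: PolicyParams | None = None

    def __post_init__(self):
        if self.method not in (0, 1, 2):
            raise ValueError("method must be 0, 1 or 2")
        self.betas = [np.asarray(b, dtype=float) for b in self.betas]
        for b in self.betas:
            if not np.all(np.isfinite(b)):
                raise ValueError("betas must be finite")
        if self.method == 0 and any(np.any(b != 0) for b in self.betas):
            raise ValueError("method 0 requires all-zero betas")

    @property
    def T(self) -> int:
        return len(self.betas)

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "basis": {"kind": self.basis.kind, "d_prime": self.basis.d_prime},
            "betas": [b.tolist() for b in self.betas],
            "theta_check": None
            if self.theta_check is None
            else {"theta": self.theta_check.theta.tolist(), "tau": self.theta_check.tau},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, s: str) -> "NuisanceModel":
        obj = json.loads(s)
        basis = BasisSpec(kind=obj["basis"]["kind"], d_prime=obj["basis"]["d_prime"])
        tc = obj.get("theta_check")
        theta_check = None if tc is None else PolicyParams(np.array(tc["theta"]), tc["tau"])
        return cls(obj["method"], [np.array(b) for b in obj["betas"]], basis, theta_check)


def fit_q_zero(ds: TrajectoryDataset, basis: BasisSpec | None = None) -> NuisanceModel:
    """Naive method: zero penalty weight on everything, Q_t identically 0."""
    basis = (basis or BasisSpec()).resolve(ds.d)
    zeros = [np.zeros(2 * basis.d_prime) for _ in range(ds.T)]
    model = NuisanceModel(0, zeros, basis)
    model.chosen_lambdas = [0.0] * ds.T
    return model


def _default_lambda_grid(Z: np.ndarray, y: np.ndarray, size: int = 50) -> np.ndarray:
    lam_max = 2.0 * np.max(np.abs(Z.T @ y)) / len(y)
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * 1e-4, size)


def _lasso_cv_refit(Z, y, lambda_grid, cv_folds, seed, fixed_lambda=None):
    """L1-penalized LS with trajectory-level CV over lambda, then OLS refit.

    Rows of Z are subjects (one per trajectory at the current stage), so
    plain row folds are trajectory-level folds.  The loss convention is
    (1/n)||y - Z b||^2 + lambda ||b||_1, i.e. sklearn alpha = lambda / 2.
    With ``fixed_lambda`` the CV step is skipped (bootstrap reuse).
    Returns (refit coefficient vector, lambda used).
    """
    n = len(y)
    if np.allclose(y, 0.0):
        return np.zeros(Z.shape[1]), 0.0 if fixed_lambda is None else fixed_lambda

    if fixed_lambda is not None:
        alphas = np.array([max(fixed_lambda, 1e-12) / 2.0])
        best = 0
        lambda_grid = np.array([fixed_lambda])
    else:
        if lambda_grid is None:
            lambda_grid = _default_lambda_grid(Z, y)
        lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
        alphas = lambda_grid / 2.0
        if n >= max(2, cv_folds) and len(lambda_grid) > 1:
            kf = KFold(n_splits=min(cv_folds, n), shuffle=True,
                       random_state=seed % (2**31))
            sse = np.zeros(len(alphas))
            for tr, te in kf.split(Z):
                _, coefs, _ = lasso_path(Z[tr], y[tr], alphas=alphas, max_iter=5000)
                pred = Z[te] @ coefs  # (n_te, n_alphas)
                sse += ((pred - y[te][:, None]) ** 2).sum(axis=0)
            best = int(np.argmin(sse))
        else:
            best = len(alphas) - 1  # no CV possible: weakest penalty, refit debiases
    _, coefs, _ = lasso_path(Z, y, alphas=alphas, max_iter=5000)
    beta = coefs[:, best]

    support = np.flatnonzero(beta != 0.0)
    support = np.union1d(support, [0])  # intercept column always refit
    beta_refit = np.zeros_like(beta)
    sol, *_ = np.linalg.lstsq(Z[:, support], y, rcond=None)
    beta_refit[support] = sol
    return beta_refit, float(lambda_grid[best])


def _phi_both_actions(basis: BasisSpec, X: np.ndarray):
    """Phi(x, +1) and Phi(x, -1) for a (n, d) block of features."""
    phi = basis.phi(X)
    return (
        np.concatenate([phi, phi], axis=-1),
        np.concatenate([phi, -phi], axis=-1),
    )


def fit_q_backward(
    ds: TrajectoryDataset,
    basis: BasisSpec | None,
    theta_check: PolicyParams,
    lambda_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
    fixed_lambdas=None,
) -> NuisanceModel:
    """Backward-recursive fit (method 1).

    Stage T is a penalized regression of R_T on Phi(X_T, A_T); earlier
    stages add the policy-averaged fitted continuation value at the next
    stage's features to the reward before regressing.  ``fixed_lambdas``
    (one per stage, 1-based order) bypasses CV, e.g. inside the bootstrap.
    """
    basis = (basis or BasisSpec()).resolve(ds.d)
    betas = [None] * ds.T
    chosen = [None] * ds.T
    beta_next = np.zeros(2 * basis.d_prime)
    for t in range(ds.T - 1, -1, -1):
        y = ds.rewards[:, t].copy()
        if t < ds.T - 1:
            X_next = ds.features[:, t + 1, :]
            Phi_p, Phi_m = _phi_both_actions(basis, X_next)
            p_plus = action_prob(theta_check, X_next, 1)
            y = y + p_plus * (Phi_p @ beta_next) + (1.0 - p_plus) * (Phi_m @ beta_next)
        Z = basis_features(basis, ds.features[:, t, :], ds.actions[:, t])
        fixed = None if fixed_lambdas is None else fixed_lambdas[t]
        betas[t], chosen[t] = _lasso_cv_refit(Z, y, lambda_grid, cv_folds, seed + t,
                                              fixed_lambda=fixed)
        beta_next = betas[t]
    model = NuisanceModel(1, betas, basis, theta_check)
    model.chosen_lambdas = chosen
    return model


def fit_q_varmin(
    ds: TrajectoryDataset,
    basis: BasisSpec | None,
    theta_check: PolicyParams,
    lambda_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
    fixed_lambdas=None,
) -> NuisanceModel:
    """Variance-minimizing fit (method 2); stages are fit independently.

    Response: rho~_{1:t} R_t.  Predictor: rho~_{1:t} Phi(X_t, A_t)
    - rho~_{1:t-1} sum_a pi_theta_check(a|X_t) Phi(X_t, a), where rho~ are
    the self-normalized importance weights under theta_check.
    """
    basis = (basis or BasisSpec()).resolve(ds.d)
    rho = stepwise_weights(theta_check, ds)
    _, rho_n = normalized_weights(rho)  # (n, T+1), col 0 == 1
    betas = []
    chosen = []
    for t in range(ds.T):
        X_t = ds.features[:, t, :]
        w_cur = rho_n[:, t + 1]
        w_prev = rho_n[:, t]
        y = w_cur * ds.rewards[:, t]
        Phi_taken = basis_features(basis, X_t, ds.actions[:, t])
        Phi_p, Phi_m = _phi_both_actions(basis, X_t)
        p_plus = action_prob(theta_check, X_t, 1)
        Phi_avg = p_plus[:, None] * Phi_p + (1.0 - p_plus)[:, None] * Phi_m
        Z = w_cur[:, None] * Phi_taken - w_prev[:, None] * Phi_avg
        fixed = None if fixed_lambdas is None else fixed_lambdas[t]
        beta, lam = _lasso_cv_refit(Z, y, lambda_grid, cv_folds, seed + t,
                                    fixed_lambda=fixed)
        betas.append(beta)
        chosen.append(lam)
    model = NuisanceModel(2, betas, basis, theta_check)
    model.chosen_lambdas = chosen
    return model


def predict_q(model: NuisanceModel, x, a, t: int):
    """Q_t(x, a) = Phi(x, a)' beta_t for 1-based stage t."""
    if not (1 <= t <= model.T):
        raise ValueError(f"stage t={t} out of range 1..{model.T}")
    return basis_features(model.basis, x, a) @ model.betas[t - 1]


def predict_u(model: NuisanceModel, theta: PolicyParams, x, t: int):
    """U_t(x) = sum_a pi_theta(a|x) Q_t(x, a): the exact policy expectation."""
    p_plus = action_prob(theta, x, 1)
    return p_plus * predict_q(model, x, 1, t) + (1.0 - p_plus) * predict_q(model, x, -1, t)


def q_value_arrays(model: NuisanceModel, ds: TrajectoryDataset):
    """Precompute (Q_taken, Q_plus, Q_minus), each (n, T), for fast loss evals."""
    n, T = ds.n, ds.T
    q_taken = np.empty((n, T))
    q_plus = np.empty((n, T))
    q_minus = np.empty((n, T))
    for t in range(T):
        X_t = ds.features[:, t, :]
        Phi_p, Phi_m = _phi_both_actions(model.basis, X_t)
        q_plus[:, t] = Phi_p @ model.betas[t]
        q_minus[:, t] = Phi_m @ model.betas[t]
        q_taken[:, t] = np.where(ds.actions[:, t] == 1, q_plus[:, t], q_minus[:, t])
    return q_taken, q_plus, q_minus
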