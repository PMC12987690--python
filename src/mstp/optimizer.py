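"""Sparse policy estimation on the unit ball.

Pipeline: an initial estimator (zero augmentation, self-normalized
weights), nuisance fitting elsewhere, then the final sparse estimator with
augmentation.  Both estimators minimize  loss + lambda * ||theta||_1
subject to ||theta||_2 <= 1 via proximal coordinate descent with
per-cycle L2 normalization and multi-start, followed by an unpenalized
refit on the selected support with a trust-region constrained solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize
from sklearn.model_selection import KFold

from ._utils import soft_threshold, substream
from .data_model import TrajectoryDataset
from .nuisance import NuisanceModel, fit_q_zero
from .objective import LossContext, numdiff_gradient, numdiff_hessian
from .policy import PolicyParams

__all__ = [
    "FitConfig",
    "proximal_cd",
    "fit_initial",
    "fit_sparse",
    "refit_on_support",
    "tune_lambda_theta",
]

logger = logging.getLogger(__name__)

_CURV_FLOOR = 1e-2


@dataclass
class FitConfig:
    """Knobs for sparse policy estimation."""

    lambda_grid_theta: np.ndarray | None = None  # None: data-driven grid
    n_starts: int = 5
    max_iter: int = 100
    tol: float = 1e-4
    cv_folds: int = 5
    seed: int = 0
    cv_n_starts: int = 1  # multi-starts used inside cross-validation fits
    lambda_grid_size: int = 10  # length of the data-driven default grid

    def __post_init__(self):
        if self.n_starts < 1 or self.max_iter < 1 or self.cv_folds < 2:
            raise ValueError("n_starts, max_iter positive; cv_folds >= 2")
        if not (0 < self.tol < 1e-2):
            raise ValueError("tol must lie in (0, 1e-2)")


def _project_ball(theta: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(theta)
    return theta / nrm if nrm > 1.0 else theta


def proximal_cd(ctx: LossContext, lambda_theta: float, start: PolicyParams,
                cfg: FitConfig) -> PolicyParams:
    """Proximal coordinate descent with per-cycle L2 normalization.

    Each coordinate takes a soft-thresholding step built from the local
    symmetric-difference slope and (floored) curvature; a step is kept only
    if it does not increase the penalized objective (with up to three
    halvings).  After every full cycle the iterate is projected onto the
    unit ball.  The post-cycle penalized objective is non-increasing.
    """
    theta = _project_ball(start.theta.astype(float).copy())
    p = theta.size
    lam = float(lambda_theta)
    h = ctx.diff_step

    def F(th):
        return float(ctx.eval_batch(th[None, :])[0]) + lam * np.abs(th).sum()

    obj = F(theta)
    if not np.isfinite(obj):
        raise ValueError("non-finite objective at the starting point")
    trace = [obj]
    converged = False
    for _ in range(cfg.max_iter):
        delta_max = 0.0
        f0 = float(ctx.eval_batch(theta[None, :])[0])
        # slope/curvature for every coordinate in one batched evaluation;
        # within the cycle they go stale, but each accepted step is checked
        # against the true objective, so descent is never violated
        pts = np.repeat(theta[None, :], 2 * p, axis=0)
        idx = np.arange(p)
        pts[2 * idx, idx] += h
        pts[2 * idx + 1, idx] -= h
        vals = ctx.eval_batch(pts)
        slopes = (vals[2 * idx] - vals[2 * idx + 1]) / (2.0 * h)
        curvs = np.maximum((vals[2 * idx] - 2.0 * f0 + vals[2 * idx + 1]) / h**2,
                           _CURV_FLOOR)
        for j in range(p):
            g, c = slopes[j], curvs[j]
            new = soft_threshold(theta[j] - g / c, lam / c)
            if new == theta[j]:
                continue
            cur = f0 + lam * np.abs(theta).sum()
            for _bt in range(3):
                cand = theta.copy()
                cand[j] = new
                f_cand = float(ctx.eval_batch(cand[None, :])[0])
                if f_cand + lam * np.abs(cand).sum() <= cur + 1e-12:
                    delta_max = max(delta_max, abs(new - theta[j]))
                    theta = cand
                    f0 = f_cand
                    break
                new = theta[j] + 0.5 * (new - theta[j])
        nrm = np.linalg.norm(theta)
        if nrm > 1.0:
            theta = theta / nrm  # loss unchanged (sphere projection), L1 shrinks
        obj_new = F(theta)
        trace.append(obj_new)
        stalled = obj - obj_new < 1e-7 * max(1.0, abs(obj_new))
        obj = obj_new
        if delta_max < cfg.tol or stalled:
            converged = True
            break

    result = PolicyParams(_project_ball(theta), ctx.tau)
    result.fit_info = {"objective_trace": trace, "converged": converged,
                       "lambda_theta": lam}
    return result


def _multi_start(ctx: LossContext, lambda_theta: float, cfg: FitConfig,
                 extra_starts=(), n_starts: int | None = None) -> PolicyParams:
    """Run proximal CD from several starts; keep the best penalized objective.

    Ties are broken by smaller L1 norm, then by start index.
    """
    p = ctx.dim
    # warm starts first so a single-start budget uses the best available point
    starts = [np.asarray(s, dtype=float) for s in extra_starts] + [np.zeros(p)]
    total = cfg.n_starts if n_starts is None else n_starts
    rng = substream(cfg.seed, "starts")
    while len(starts) < total:
        v = rng.standard_normal(p)
        starts.append(v / np.linalg.norm(v))
    starts = starts[:max(total, 1)]

    best = None
    for k, s in enumerate(starts):
        fit = proximal_cd(ctx, lambda_theta, PolicyParams(_project_ball(s), ctx.tau), cfg)
        obj = fit.fit_info["objective_trace"][-1]
        key = (obj, np.abs(fit.theta).sum(), k)
        if best is None or key < best[0]:
            best = (key, fit)
    return best[1]


def tune_lambda_theta(ds: TrajectoryDataset, tau: float, nuisance: NuisanceModel,
                      cfg: FitConfig, extra_starts=()):
    """Pick lambda_theta by trajectory-level K-fold cross validation.

    Criterion: held-out unpenalized self-normalized loss (minus the
    estimated value on held-out subjects).  Returns (lambda, table) where
    the table has one row per grid value with the per-fold losses.
    """
    ctx_full = LossContext(ds, nuisance, tau)
    grid = cfg.lambda_grid_theta
    if grid is None:
        grid = default_lambda_grid_theta(ctx_full, size=cfg.lambda_grid_size)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    if grid.size == 1 or ds.n < 2:
        lam = float(np.max(grid))
        return lam, [{"lambda": lam, "cv_losses": []}]

    kf = KFold(n_splits=min(cfg.cv_folds, ds.n), shuffle=True,
               random_state=cfg.seed % (2**31))
    folds = list(kf.split(np.arange(ds.n)))
    table = []
    for lam in grid:
        losses = []
        for tr, te in folds:
            ctx_tr = LossContext(ds.subset(tr), nuisance, tau)
            fit = _multi_start(ctx_tr, lam, cfg, extra_starts=extra_starts,
                               n_starts=cfg.cv_n_starts)
            ctx_te = LossContext(ds.subset(te), nuisance, tau)
            losses.append(float(ctx_te.eval_batch(fit.theta[None, :])[0]))
        table.append({"lambda": float(lam), "cv_losses": losses,
                      "mean_cv_loss": float(np.mean(losses))})
    # held-out value criterion with a one-SE preference for sparser fits:
    # among lambdas within one standard error of the best mean CV loss,
    # take the largest
    means = np.array([row["mean_cv_loss"] for row in table])
    best = int(np.argmin(means))
    folds_best = np.array(table[best]["cv_losses"])
    se = folds_best.std(ddof=1) / np.sqrt(len(folds_best)) if len(folds_best) > 1 else 0.0
    eligible = [k for k in range(len(table)) if means[k] <= means[best] + se]
    chosen = max(eligible, key=lambda k: table[k]["lambda"])
    return float(table[chosen]["lambda"]), table


def default_lambda_grid_theta(ctx: LossContext, size: int = 10) -> np.ndarray:
    """Data-driven grid: from the sup-norm of the gradient at 0 downwards."""
    g0 = numdiff_gradient(lambda ts: ctx.eval_batch(ts), np.zeros(ctx.dim),
                          ctx.diff_step)
    gmax = max(float(np.max(np.abs(g0))), 1e-6)
    return np.geomspace(gmax, gmax * 1e-2, size)


def fit_initial(ds: TrajectoryDataset, tau: float, cfg: FitConfig,
                lambda_theta: float | None = None,
                extra_starts=()) -> PolicyParams:
    """Initial sparse estimator: zero augmentation, self-normalized weights."""
    nuisance = fit_q_zero(ds)
    ctx = LossContext(ds, nuisance, tau)
    if lambda_theta is None:
        lambda_theta, _ = tune_lambda_theta(ds, tau, nuisance, cfg)
    fit = _multi_start(ctx, lambda_theta, cfg, extra_starts=extra_starts)
    refit = refit_on_support(ctx, fit)
    refit.fit_info = {**fit.fit_info, "refit": True}
    return refit


def fit_sparse(ds: TrajectoryDataset, tau: float, nuisance: NuisanceModel,
               cfg: FitConfig, lambda_theta: float | None = None,
               theta_check: PolicyParams | None = None) -> PolicyParams:
    """Final sparse estimator with augmentation; lands on the unit sphere."""
    ctx = LossContext(ds, nuisance, tau)
    extra = [theta_check.theta] if theta_check is not None else []
    if lambda_theta is None:
        lambda_theta, _ = tune_lambda_theta(ds, tau, nuisance, cfg, extra_starts=extra)
    fit = _multi_start(ctx, lambda_theta, cfg, extra_starts=extra)
    refit = refit_on_support(ctx, fit)
    theta = refit.theta
    nrm = np.linalg.norm(theta)
    if nrm > 1e-10:
        theta = theta / nrm  # the estimated policy sits on the sphere
    out = PolicyParams(theta, tau)
    out.fit_info = {**fit.fit_info, "refit": True, "final_norm": float(np.linalg.norm(theta))}
    return out


def refit_on_support(ctx: LossContext, theta_hat: PolicyParams) -> PolicyParams:
    """Minimize the unpenalized loss over the support, constrained to the ball.

    Uses the trust-region constrained solver started at theta_hat.  If the
    solver fails or does not improve the loss, the input is returned.
    """
    support = np.flatnonzero(theta_hat.theta != 0.0)
    if support.size == 0:
        return theta_hat

    def embed(v):
        th = np.zeros(ctx.dim)
        th[support] = v
        return th

    def f_batch(V):
        V = np.atleast_2d(V)
        TH = np.zeros((len(V), ctx.dim))
        TH[:, support] = V
        return ctx.eval_batch(TH)

    def fun(v):
        return float(f_batch(v[None, :])[0])

    def jac(v):
        return numdiff_gradient(f_batch, v, ctx.diff_step)

    def hess(v):
        return numdiff_hessian(f_batch, v, ctx.diff_step)

    x0 = theta_hat.theta[support]
    f_start = fun(x0)
    con = NonlinearConstraint(lambda v: float(v @ v), -np.inf, 1.0,
                              jac=lambda v: 2.0 * v[None, :],
                              hess=lambda v, lam: 2.0 * lam[0] * np.eye(v.size))
    try:
        res = minimize(fun, x0, jac=jac, hess=hess, method="trust-constr",
                       constraints=[con], options={"maxiter": 30, "gtol": 1e-7,
                                                   "xtol": 1e-10, "verbose": 0})
    except Exception as exc:  # pragma: no cover - solver crash path
        logger.warning("refit_on_support failed (%s); keeping input", exc)
        return theta_hat
    v = res.x
    if float(v @ v) > 1.0:
        v = v / np.linalg.norm(v)
    if fun(v) > f_start + 1e-12:
        logger.warning("refit_on_support did not improve the loss; keeping input")
        return theta_hat
    return PolicyParams(embed(v), ctx.tau)
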