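"""Decorrelated-score one-step estimation and bootstrap confidence intervals.

For each coordinate j of the policy parameter, a minimum-L1 decorrelation
vector w_j is found by linear programming (Dantzig form), giving the
decorrelated score S_j and the information contrast I_{j|nu}.  The
one-step estimate is a single Newton correction of the sparse estimate.
Confidence intervals come from a trajectory-level bootstrap that re-runs
the whole pipeline per replicate with all tuning parameters frozen at
their full-data values; a plug-in normal interval is reported alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.stats import norm as normal_dist
from sklearn.model_selection import KFold

from ._utils import substream
from .data_model import TrajectoryDataset, bootstrap_resample
from .nuisance import fit_q_backward, fit_q_varmin, fit_q_zero
from .objective import (LossContext, numeric_gradient, numeric_hessian,
                        per_subject_gradients)
from .optimizer import FitConfig, fit_initial, fit_sparse, tune_lambda_theta
from .policy import PolicyParams

__all__ = [
    "ScoreComponents",
    "InferenceResult",
    "dantzig_w",
    "decorrelated_score",
    "information_contrast",
    "one_step",
    "plugin_variance",
    "tune_lambda_w",
    "infer",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreComponents:
    """Gradient/Hessian of the loss at theta_hat plus per-coordinate pieces."""

    grad: np.ndarray
    hess: np.ndarray
    w_hat: dict  # j -> decorrelation vector (length d)
    s_hat: dict  # j -> decorrelated score
    info: dict  # j -> information contrast I_{j|nu}
    sigma_hat: dict  # j -> plug-in variance v' Sigma v

    def __post_init__(self):
        if not np.allclose(self.hess, self.hess.T, atol=1e-8):
            raise ValueError("Hessian must be symmetric")


@dataclass
class InferenceResult:
    theta_hat: PolicyParams
    theta_tilde: np.ndarray  # (d+1,), NaN where not computed
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    B: int
    alpha: float
    bootstrap_draws: np.ndarray  # (B_effective, d+1), NaN where not computed
    plugin_ci_lower: np.ndarray = None
    plugin_ci_upper: np.ndarray = None
    plugin_se: np.ndarray = None
    scores: ScoreComponents = None
    n_failed: int = 0
    seed: int | None = None

    def to_report(self) -> dict:
        """Per-coordinate JSON-ready report (Table-style layout)."""
        rows = []
        for j in range(self.theta_tilde.size):
            rows.append({
                "j": j,
                "theta_hat": float(self.theta_hat.theta[j]),
                "theta_tilde": _f(self.theta_tilde[j]),
                "ci_lower": _f(self.ci_lower[j]),
                "ci_upper": _f(self.ci_upper[j]),
                "plugin_se": _f(self.plugin_se[j]) if self.plugin_se is not None else None,
                "selected": bool(self.theta_hat.theta[j] != 0.0),
            })
        return {"alpha": self.alpha, "B": self.B, "n_failed": self.n_failed,
                "seed": self.seed, "coordinates": rows}

    def to_json(self) -> str:
        return json.dumps(self.to_report(), indent=2)


def _f(x):
    return None if x is None or not np.isfinite(x) else float(x)


def _nu_index(p: int, j: int) -> np.ndarray:
    """Indices of nu_j = all coordinates except j, in natural order."""
    return np.array([k for k in range(p) if k != j])


def dantzig_w(hess: np.ndarray, j: int, lambda_wj: float) -> np.ndarray:
    """Minimum-L1 w with ||H_{j,nu} - w' H_{nu,nu}||_inf <= lambda_wj.

    Solved as an LP over the positive/negative parts of w.  Always feasible
    for lambda_wj >= ||H_{j,nu}||_inf (w = 0).
    """
    hess = np.asarray(hess, dtype=float)
    p = hess.shape[0]
    nu = _nu_index(p, j)
    c = hess[j, nu]
    H = hess[np.ix_(nu, nu)]
    m = p - 1
    if lambda_wj < 0:
        raise ValueError("lambda_wj must be nonnegative")
    # variables z = (u, v), w = u - v, u, v >= 0
    cost = np.ones(2 * m)
    A = np.block([[H, -H], [-H, H]])  # H symmetric: w' H == H w
    b = np.concatenate([lambda_wj + c, lambda_wj - c])
    res = linprog(cost, A_ub=A, b_ub=b, bounds=[(0, None)] * (2 * m),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"Dantzig LP failed for j={j}: {res.message} "
                           f"(lambda={lambda_wj}, ||c||_inf={np.max(np.abs(c))})")
    return res.x[:m] - res.x[m:]


def decorrelated_score(grad: np.ndarray, w_hat_j: np.ndarray, j: int) -> float:
    """S_j = grad_j - w_j' grad_{nu_j}."""
    grad = np.asarray(grad, dtype=float)
    nu = _nu_index(grad.size, j)
    return float(grad[j] - w_hat_j @ grad[nu])


def information_contrast(hess: np.ndarray, w_hat_j: np.ndarray, j: int) -> float:
    """I_{j|nu} = H_jj - w_j' H_{nu,j}; warns when near singular."""
    hess = np.asarray(hess, dtype=float)
    nu = _nu_index(hess.shape[0], j)
    val = float(hess[j, j] - w_hat_j @ hess[nu, j])
    if abs(val) < 1e-8:
        logger.warning("information contrast nearly singular for j=%d: %g", j, val)
    return val


def one_step(theta_hat: PolicyParams, s_hat_j: float, info_j: float, j: int) -> float:
    """One Newton correction: theta_hat_j - S_j / I_{j|nu}."""
    if info_j == 0:
        raise ZeroDivisionError("singular information")
    return float(theta_hat.theta[j] - s_hat_j / info_j)


def plugin_variance(per_subject_grads: np.ndarray, w_hat_j: np.ndarray, j: int) -> float:
    """sigma_j = v' Sigma v with v = e_j - w on nu and Sigma the sample
    covariance of per-subject gradient rows."""
    G = np.asarray(per_subject_grads, dtype=float)
    if G.shape[0] < 2:
        raise ValueError("need at least two subjects")
    p = G.shape[1]
    nu = _nu_index(p, j)
    v = np.zeros(p)
    v[j] = 1.0
    v[nu] = -np.asarray(w_hat_j)
    proj = G @ v
    return float(proj.var(ddof=1))


def tune_lambda_w(fold_hessians, j: int, grid=None, tiebreak: float = 1e-6):
    """Pick lambda_wj by K-fold CV on held-out infeasibility.

    ``fold_hessians`` is a list of (H_train, H_test) pairs.  Criterion:
    mean over folds of ||H_{j,nu}^test - w' H_{nu,nu}^test||_inf with a
    small L1 tiebreak.  Returns (lambda, table).
    """
    p = fold_hessians[0][0].shape[0]
    nu = _nu_index(p, j)
    if grid is None:
        cmax = max(np.max(np.abs(H_tr[j, nu])) for H_tr, _ in fold_hessians)
        cmax = max(cmax, 1e-8)
        grid = np.geomspace(cmax, cmax * 1e-3, 10)
    table = []
    for lam in np.asarray(grid, dtype=float):
        scores = []
        for H_tr, H_te in fold_hessians:
            try:
                w = dantzig_w(H_tr, j, lam)
            except RuntimeError:
                scores.append(np.inf)
                continue
            infeas = np.max(np.abs(H_te[j, nu] - w @ H_te[np.ix_(nu, nu)]))
            scores.append(infeas + tiebreak * np.abs(w).sum())
        table.append({"lambda": float(lam), "score": float(np.mean(scores))})
    best = min(range(len(table)), key=lambda k: table[k]["score"])
    return float(table[best]["lambda"]), table


def quantile_ci(draws: np.ndarray, alpha: float):
    """Empirical (alpha/2, 1-alpha/2) quantiles of the bootstrap draws."""
    draws = np.asarray(draws, dtype=float)
    return (float(np.quantile(draws, alpha / 2.0)),
            float(np.quantile(draws, 1.0 - alpha / 2.0)))


def _one_step_or_fallback(theta_hat, s, info, j):
    """One-step estimate; a 0/0 score-information pair (constant loss, e.g.
    a single trajectory with self-normalized weights) leaves theta_hat_j."""
    if info == 0.0 and s == 0.0:
        logger.warning("zero score and information for j=%d; keeping theta_hat", j)
        return float(theta_hat.theta[j])
    return one_step(theta_hat, s, info, j)


def _fit_nuisance(ds, method_m, theta_check, cfg, fixed_lambdas=None):
    if method_m == 0:
        return fit_q_zero(ds)
    if method_m == 1:
        return fit_q_backward(ds, None, theta_check, cv_folds=cfg.cv_folds,
                              seed=cfg.seed, fixed_lambdas=fixed_lambdas)
    if method_m == 2:
        return fit_q_varmin(ds, None, theta_check, cv_folds=cfg.cv_folds,
                            seed=cfg.seed, fixed_lambdas=fixed_lambdas)
    raise ValueError("method_m must be 0, 1 or 2")


def _score_pieces(ctx, theta_hat, coords, lambdas_w, grid_w=None, fold_hessians=None):
    """Gradient, Hessian and per-coordinate decorrelated-score objects."""
    grad = numeric_gradient(ctx, theta_hat)
    hess = numeric_hessian(ctx, theta_hat)
    psg = per_subject_gradients(ctx, theta_hat)
    w_hat, s_hat, info, sigma = {}, {}, {}, {}
    for j in coords:
        lam = lambdas_w[j]
        w = dantzig_w(hess, j, lam)
        w_hat[j] = w
        s_hat[j] = decorrelated_score(grad, w, j)
        info[j] = information_contrast(hess, w, j)
        sigma[j] = plugin_variance(psg, w, j) if psg.shape[0] >= 2 else np.nan
    return ScoreComponents(grad, hess, w_hat, s_hat, info, sigma)


def infer(ds: TrajectoryDataset, tau: float, method_m: int, cfg: FitConfig,
          B: int, alpha: float, coords=None,
          bootstrap_n_starts: int = 2) -> InferenceResult:
    """Full estimation + inference pipeline with trajectory bootstrap CIs.

    All tuning parameters (lambda for the initial and final sparse
    estimators, the per-stage nuisance penalties, and each lambda_wj) are
    selected once on the full data and frozen during the bootstrap.
    ``coords`` restricts one-step inference to a subset of coordinates
    (default: all d+1).
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    p = ds.d + 1
    coords = list(range(p)) if coords is None else sorted(set(coords))

    # --- full-data pipeline, tuning everything once -------------------------
    nuis0 = fit_q_zero(ds)
    lam_check, _ = tune_lambda_theta(ds, tau, nuis0, cfg)
    theta_check = fit_initial(ds, tau, cfg, lambda_theta=lam_check)
    nuisance = _fit_nuisance(ds, method_m, theta_check, cfg)
    lambdas_beta = getattr(nuisance, "chosen_lambdas", None)
    lam_theta, _ = tune_lambda_theta(ds, tau, nuisance, cfg,
                                     extra_starts=[theta_check.theta])
    theta_hat = fit_sparse(ds, tau, nuisance, cfg, lambda_theta=lam_theta,
                           theta_check=theta_check)
    ctx = LossContext(ds, nuisance, tau)

    # lambda_wj via K-fold CV on fold Hessians (shared across coordinates)
    lambdas_w = {}
    if ds.n >= 2:
        kf = KFold(n_splits=min(cfg.cv_folds, ds.n), shuffle=True,
                   random_state=cfg.seed % (2**31))
        fold_hessians = []
        for tr, te in kf.split(np.arange(ds.n)):
            H_tr = numeric_hessian(LossContext(ds.subset(tr), nuisance, tau),
                                   theta_hat)
            H_te = numeric_hessian(LossContext(ds.subset(te), nuisance, tau),
                                   theta_hat)
            fold_hessians.append((H_tr, H_te))
        for j in coords:
            lambdas_w[j], _ = tune_lambda_w(fold_hessians, j)
    else:  # no CV possible: the conservative feasible-at-zero choice
        H_full = numeric_hessian(LossContext(ds, nuisance, tau), theta_hat)
        for j in coords:
            nu = _nu_index(p, j)
            lambdas_w[j] = float(np.max(np.abs(H_full[j, nu])))

    scores = _score_pieces(ctx, theta_hat, coords, lambdas_w)
    theta_tilde = np.full(p, np.nan)
    for j in coords:
        theta_tilde[j] = _one_step_or_fallback(theta_hat, scores.s_hat[j],
                                               scores.info[j], j)

    # plug-in normal CIs (asymptotic-normality secondary output)
    z = normal_dist.ppf(1.0 - alpha / 2.0)
    plugin_se = np.full(p, np.nan)
    plo = np.full(p, np.nan)
    phi = np.full(p, np.nan)
    for j in coords:
        se = np.sqrt(scores.sigma_hat[j]) / (np.sqrt(ds.n) * abs(scores.info[j]))
        plugin_se[j] = se
        plo[j] = theta_tilde[j] - z * se
        phi[j] = theta_tilde[j] + z * se

    # --- trajectory bootstrap with frozen tuning ----------------------------
    boot_cfg = FitConfig(
        lambda_grid_theta=cfg.lambda_grid_theta, n_starts=bootstrap_n_starts,
        max_iter=cfg.max_iter, tol=cfg.tol, cv_folds=cfg.cv_folds, seed=cfg.seed,
    )
    draws = []
    n_failed = 0
    for b in range(B):
        rng = substream(cfg.seed, "bootstrap", b)
        try:
            ds_b = bootstrap_resample(ds, rng)
            check_b = fit_initial(ds_b, tau, boot_cfg, lambda_theta=lam_check,
                                  extra_starts=[theta_check.theta])
            nuis_b = _fit_nuisance(ds_b, method_m, check_b, boot_cfg,
                                   fixed_lambdas=lambdas_beta)
            hat_b = fit_sparse(ds_b, tau, nuis_b, boot_cfg,
                               lambda_theta=lam_theta, theta_check=check_b)
            ctx_b = LossContext(ds_b, nuis_b, tau)
            sc_b = _score_pieces(ctx_b, hat_b, coords, lambdas_w)
            row = np.full(p, np.nan)
            for j in coords:
                row[j] = _one_step_or_fallback(hat_b, sc_b.s_hat[j],
                                               sc_b.info[j], j)
            draws.append(row)
        except Exception as exc:
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
    if n_failed > 0.2 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    draws = np.array(draws) if draws else np.empty((0, p))

    ci_lo = np.full(p, np.nan)
    ci_hi = np.full(p, np.nan)
    for j in coords:
        ci_lo[j], ci_hi[j] = quantile_ci(draws[:, j], alpha)

    return InferenceResult(
        theta_hat=theta_hat, theta_tilde=theta_tilde, ci_lower=ci_lo,
        ci_upper=ci_hi, B=B, alpha=alpha, bootstrap_draws=draws,
        plugin_ci_lower=plo, plugin_ci_upper=phi, plugin_se=plugin_se,
        scores=scores, n_failed=n_failed, seed=cfg.seed,
    )
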