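import numpy as np
import pytest
from scipy.special import expit

from mstp.data_model import TrajectoryDataset
from mstp.nuisance import BasisSpec, NuisanceModel, fit_q_zero
from mstp.objective import (LossContext, loss, numdiff_gradient, numdiff_hessian,
                            numeric_gradient, numeric_hessian, penalized_loss,
                            per_subject_gradients, trajectory_loss)
from mstp.policy import PolicyParams, action_prob, stepwise_weights
from mstp.simulation import ScenarioConfig, evaluate_on_policy, simulate


def analytic_m0_derivatives(ds, theta, tau):
    """Closed-form gradient and Hessian of the unnormalized zero-augmentation
    loss  -(1/n) sum_i sum_t rho_{i,1:t} R_{i,t}.

    Uses d log pi(a|x) / d theta = (a/tau) sigmoid(-a g / tau) * (1, x) and
    the product rule on the stage-wise weight products.  Independent of the
    package's difference-quotient code path.
    """
    n, T, d = ds.n, ds.T, ds.d
    p = d + 1
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for i in range(n):
        s_cum = np.zeros(p)  # sum of score vectors up to stage t
        m_cum = np.zeros((p, p))  # sum of d(score)/d(theta) up to stage t
        rho = 1.0
        for t in range(T):
            x = np.concatenate([[1.0], ds.features[i, t]])
            a = ds.actions[i, t]
            g = float(x @ theta)
            z = a * g / tau
            pi = expit(z)
            rho *= pi / ds.behavior_prob[i, t]
            s_cum = s_cum + (a / tau) * expit(-z) * x
            m_cum = m_cum - (pi * expit(-z) / tau**2) * np.outer(x, x)
            grad += -rho * ds.rewards[i, t] * s_cum / n
            hess += -rho * ds.rewards[i, t] * (np.outer(s_cum, s_cum) + m_cum) / n
    return grad, hess


@pytest.fixture
def m0_ctx_unnormalized(toy_dataset):
    return LossContext(toy_dataset, fit_q_zero(toy_dataset), tau=0.2,
                       use_normalized_weights=False)


@pytest.fixture
def random_nuisance(toy_dataset, rng):
    basis = BasisSpec(d_prime=toy_dataset.d + 1)
    betas = [rng.normal(size=2 * basis.d_prime) for _ in range(toy_dataset.T)]
    return NuisanceModel(1, betas, basis)


class TestTrajectoryLoss:
    def test_zero_rewards_zero_loss(self, toy_dataset):
        ds = TrajectoryDataset(toy_dataset.features, toy_dataset.actions,
                               np.zeros_like(toy_dataset.rewards),
                               toy_dataset.behavior_prob)
        ctx = LossContext(ds, fit_q_zero(ds), 0.2, use_normalized_weights=False)
        theta = PolicyParams(np.array([0.1, -0.2, 0.3]))
        assert trajectory_loss(ctx, theta, 0) == pytest.approx(0.0, abs=1e-14)

    def test_m0_brute_force_two_stage(self, rng):
        n, T, d = 2, 2, 2
        ds = TrajectoryDataset(rng.normal(size=(n, T, d)),
                               rng.choice([-1, 1], size=(n, T)),
                               rng.normal(size=(n, T)),
                               rng.uniform(0.3, 0.7, size=(n, T)))
        theta = PolicyParams(np.array([0.2, -0.3, 0.1]))
        ctx = LossContext(ds, fit_q_zero(ds), 0.2, use_normalized_weights=False)
        for i in range(n):
            expected = 0.0
            rho = 1.0
            for t in range(T):
                pi = float(action_prob(theta, ds.features[i, t],
                                       int(ds.actions[i, t])))
                rho *= pi / ds.behavior_prob[i, t]
                expected -= rho * ds.rewards[i, t]
            assert trajectory_loss(ctx, theta, i) == pytest.approx(expected, rel=1e-10)

    def test_augmentation_cancels_under_behavior_policy(self, toy_dataset,
                                                        random_nuisance):
        # enumerate both actions: sum_a mu(a) [pi(a)/mu(a) Q(x,a) - U(x)] == 0
        from mstp.nuisance import predict_q, predict_u
        theta = PolicyParams(np.zeros(toy_dataset.d + 1))  # pi == mu == 0.5
        for i in range(toy_dataset.n):
            for t in range(1, toy_dataset.T + 1):
                x = toy_dataset.features[i, t - 1]
                u = predict_u(random_nuisance, theta, x, t)
                total = sum(
                    0.5 * (float(action_prob(theta, x, a)) / 0.5
                           * predict_q(random_nuisance, x, a, t) - u)
                    for a in (-1, 1)
                )
                assert total == pytest.approx(0.0, abs=1e-12)


class TestLoss:
    def test_single_subject_equals_trajectory_loss(self, rng):
        ds = TrajectoryDataset(rng.normal(size=(1, 2, 2)),
                               rng.choice([-1, 1], size=(1, 2)),
                               rng.normal(size=(1, 2)), np.full((1, 2), 0.5))
        ctx = LossContext(ds, fit_q_zero(ds), 0.2)
        theta = PolicyParams(np.array([0.1, 0.2, 0.3]))
        assert loss(ctx, theta) == pytest.approx(trajectory_loss(ctx, theta, 0))

    def test_subject_permutation_invariance(self, toy_dataset):
        theta = PolicyParams(np.array([0.3, -0.1, 0.2]))
        ctx = LossContext(toy_dataset, fit_q_zero(toy_dataset), 0.2)
        perm = np.array([2, 0, 3, 1])
        ds2 = toy_dataset.subset(perm)
        ctx2 = LossContext(ds2, fit_q_zero(ds2), 0.2)
        assert loss(ctx, theta) == pytest.approx(loss(ctx2, theta), rel=1e-12)

    def test_on_policy_mean_reward(self):
        # theta = 0 makes pi identical to the uniform behavior policy, so the
        # loss estimates -E[sum_t R_t] under the behavior policy itself
        cfg = ScenarioConfig(scenario=2, n=20_000, T=2, d=3, seed=31)
        ds = simulate(cfg)
        ctx = LossContext(ds, fit_q_zero(ds), 0.2, use_normalized_weights=False)
        theta = PolicyParams(np.zeros(4))
        total = ds.rewards.sum(axis=1)
        se = total.std(ddof=1) / np.sqrt(cfg.n)
        assert abs(-loss(ctx, theta) - total.mean()) < 3 * se + 1e-9

    def test_normalized_equals_unnormalized_at_matching_policy(self):
        cfg = ScenarioConfig(scenario=2, n=5000, T=2, d=3, seed=32)
        ds = simulate(cfg)
        theta = PolicyParams(np.zeros(4))
        l_norm = loss(LossContext(ds, fit_q_zero(ds), 0.2), theta)
        l_raw = loss(LossContext(ds, fit_q_zero(ds), 0.2,
                                 use_normalized_weights=False), theta)
        assert l_norm == pytest.approx(l_raw, rel=1e-10)  # weights exactly 1


class TestPenalizedLoss:
    def test_lambda_zero(self, m0_ctx_unnormalized):
        theta = PolicyParams(np.array([0.2, 0.1, -0.1]))
        assert penalized_loss(m0_ctx_unnormalized, theta, 0.0) == pytest.approx(
            loss(m0_ctx_unnormalized, theta))

    def test_zero_theta(self, m0_ctx_unnormalized):
        theta = PolicyParams(np.zeros(3))
        assert penalized_loss(m0_ctx_unnormalized, theta, 2.0) == pytest.approx(
            loss(m0_ctx_unnormalized, theta))

    def test_monotone_in_lambda(self, m0_ctx_unnormalized):
        theta = PolicyParams(np.array([0.2, 0.1, -0.1]))
        vals = [penalized_loss(m0_ctx_unnormalized, theta, lam)
                for lam in (0.0, 0.5, 1.0, 5.0)]
        assert np.all(np.diff(vals) >= 0)


class TestNumdiffGeneric:
    def test_gradient_exact_on_quadratic(self):
        theta = np.array([0.3, -0.2, 0.1])

        def f(ts):
            return (ts**2).sum(axis=1)

        for h in (1e-4, 1e-2, 0.05):
            grad = numdiff_gradient(f, theta, h)
            np.testing.assert_allclose(grad, 2 * theta, atol=1e-9)

    def test_gradient_exact_on_linear(self):
        c = np.array([1.0, -2.0, 0.5])
        grad = numdiff_gradient(lambda ts: ts @ c, np.array([0.1, 0.1, 0.1]), 0.05)
        np.testing.assert_allclose(grad, c, atol=1e-10)

    def test_hessian_recovers_quadratic_matrix(self, rng):
        M = rng.normal(size=(3, 3))
        M = M + M.T

        def f(ts):
            return 0.5 * np.einsum("pi,ij,pj->p", ts, M, ts)

        H = numdiff_hessian(f, np.array([0.2, 0.0, -0.3]), 0.05)
        np.testing.assert_allclose(H, M, atol=1e-8)

    def test_hessian_symmetric(self, m0_ctx_unnormalized):
        theta = PolicyParams(np.array([0.3, -0.2, 0.1]))
        H = numeric_hessian(m0_ctx_unnormalized, theta)
        np.testing.assert_allclose(H, H.T)


class TestAnalyticOracle:
    def test_gradient_matches_analytic(self, rng):
        n, T, d = 3, 2, 2
        ds = TrajectoryDataset(rng.normal(size=(n, T, d)),
                               rng.choice([-1, 1], size=(n, T)),
                               rng.normal(size=(n, T)), np.full((n, T), 0.5))
        theta = np.array([0.25, -0.3, 0.15])
        ctx = LossContext(ds, fit_q_zero(ds), 0.2, use_normalized_weights=False,
                          diff_step=1e-4)
        grad_num = numeric_gradient(ctx, PolicyParams(theta))
        grad_ana, _ = analytic_m0_derivatives(ds, theta, 0.2)
        np.testing.assert_allclose(grad_num, grad_ana, atol=1e-5)

    def test_hessian_matches_analytic(self, rng):
        n, T, d = 3, 2, 2
        ds = TrajectoryDataset(rng.normal(size=(n, T, d)),
                               rng.choice([-1, 1], size=(n, T)),
                               rng.normal(size=(n, T)), np.full((n, T), 0.5))
        theta = np.array([0.25, -0.3, 0.15])
        ctx = LossContext(ds, fit_q_zero(ds), 0.2, use_normalized_weights=False,
                          diff_step=1e-4)
        hess_num = numeric_hessian(ctx, PolicyParams(theta))
        _, hess_ana = analytic_m0_derivatives(ds, theta, 0.2)
        np.testing.assert_allclose(hess_num, hess_ana, atol=1e-3)


class TestPerSubjectGradients:
    def test_single_subject_row_equals_gradient(self, rng):
        ds = TrajectoryDataset(rng.normal(size=(1, 2, 2)),
                               rng.choice([-1, 1], size=(1, 2)),
                               rng.normal(size=(1, 2)), np.full((1, 2), 0.5))
        ctx = LossContext(ds, fit_q_zero(ds), 0.2, use_normalized_weights=False)
        theta = PolicyParams(np.array([0.1, 0.2, -0.2]))
        rows = per_subject_gradients(ctx, theta)
        np.testing.assert_allclose(rows[0], numeric_gradient(ctx, theta),
                                   atol=1e-12)

    def test_row_mean_matches_gradient(self, m0_ctx_unnormalized):
        theta = PolicyParams(np.array([0.1, 0.2, -0.2]))
        rows = per_subject_gradients(m0_ctx_unnormalized, theta)
        np.testing.assert_allclose(rows.mean(axis=0),
                                   numeric_gradient(m0_ctx_unnormalized, theta),
                                   atol=1e-10)

    def test_sample_covariance_psd(self, small_sim):
        ctx = LossContext(small_sim, fit_q_zero(small_sim), 0.2)
        theta = PolicyParams(np.array([0.1, 0.2, -0.2, 0.0, 0.1]))
        rows = per_subject_gradients(ctx, theta)
        cov = np.cov(rows, rowvar=False)
        eig = np.linalg.eigvalsh(cov)
        assert eig.min() > -1e-10


class TestUnbiasedness:
    def test_aipw_unbiased_for_random_nuisance(self, rng):
        # small-scale version of the central identity: the unnormalized
        # negative per-trajectory loss estimates V(theta) for ANY nuisance
        cfg = ScenarioConfig(scenario=2, n=20_000, T=3, d=3, seed=41)
        ds = simulate(cfg)
        theta = PolicyParams(np.array([0.2, 0.5, -0.3, 0.1]))
        basis = BasisSpec(d_prime=cfg.d + 1)
        betas = [rng.normal(size=2 * basis.d_prime) for _ in range(cfg.T)]
        nuis = NuisanceModel(1, betas, basis)
        ctx = LossContext(ds, nuis, 0.2, use_normalized_weights=False)
        li = ctx.eval_batch(theta.theta[None, :], per_subject=True)[:, 0]
        est, se_est = -li.mean(), li.std(ddof=1) / np.sqrt(cfg.n)
        ev = evaluate_on_policy(cfg, theta, n_eval=100_000, seed=rng)
        truth, se_truth = cfg.T * ev.mean_average_reward, cfg.T * ev.se
        assert abs(est - truth) < 3 * np.sqrt(se_est**2 + se_truth**2)


class TestContextValidation:
    def test_diff_step_range(self, toy_dataset):
        with pytest.raises(ValueError):
            LossContext(toy_dataset, fit_q_zero(toy_dataset), 0.2, diff_step=0.5)

    def test_constraint_violation_in_penalized(self, m0_ctx_unnormalized):
        with pytest.raises(ValueError):
            penalized_loss(m0_ctx_unnormalized,
                           PolicyParams(np.array([0.9, 0.9, 0.9])), 0.1)
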