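import math

import numpy as np
import pytest

from gomclust import (
    CountMatrix,
    FitConfig,
    GoMFit,
    aligned_membership_error,
    compute_p,
    em_step,
    fit_gom,
    log_likelihood,
)
from gomclust.fit import _run_em

from conftest import random_count_matrix


def make_fit(q, theta):
    return GoMFit(q=np.asarray(q, float), theta=np.asarray(theta, float))


class TestComputeP:
    def test_one_hot_membership_returns_profile(self):
        theta = np.array([[0.7, 0.2, 0.1], [0.1, 0.1, 0.8]])
        p = compute_p(make_fit([[0.0, 1.0]], theta))
        np.testing.assert_array_equal(p[0], theta[1])

    def test_symmetric_mixture(self):
        p = compute_p(make_fit([[0.5, 0.5]], [[0.8, 0.2], [0.2, 0.8]]))
        np.testing.assert_allclose(p[0], [0.5, 0.5])

    def test_matches_scalar_loop(self, rng):
        q = rng.dirichlet(np.ones(2), size=3)
        theta = rng.dirichlet(np.ones(4), size=2)
        p = compute_p(make_fit(q, theta))
        for n in range(3):
            for g in range(4):
                assert p[n, g] == pytest.approx(
                    sum(q[n, k] * theta[k, g] for k in range(2)), abs=1e-14
                )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="clusters"):
            compute_p(make_fit(np.ones((2, 3)) / 3, np.ones((2, 4)) / 4))


class TestLogLikelihood:
    def setup_method(self):
        self.m = CountMatrix(np.array([[2, 2]]), ["s"], ["g1", "g2"])
        self.fit = make_fit([[1.0]], [[0.5, 0.5]])

    def test_direct_value(self):
        assert log_likelihood(self.m, self.fit) == pytest.approx(
            4 * math.log(0.5), abs=1e-10
        )

    def test_multinomial_coefficient(self):
        base = log_likelihood(self.m, self.fit)
        full = log_likelihood(self.m, self.fit, include_multinomial_coefficient=True)
        assert full - base == pytest.approx(math.log(6), abs=1e-10)

    def test_empirical_proportions_maximize(self, rng):
        m = random_count_matrix(rng, n=4, g=6)
        p_hat = m.counts / m.row_totals[:, None]
        fit = GoMFit(q=np.eye(4), theta=p_hat)
        best = log_likelihood(m, fit)
        for _ in range(20):
            perturbed = p_hat + 0.01 * rng.dirichlet(np.ones(6), size=4) - 0.01 / 6
            perturbed = np.abs(perturbed)
            perturbed /= perturbed.sum(axis=1, keepdims=True)
            assert log_likelihood(m, GoMFit(q=np.eye(4), theta=perturbed)) <= best

    def test_zero_probability_returns_neg_inf_with_warning(self):
        fit = make_fit([[1.0]], [[1.0, 0.0]])
        with pytest.warns(RuntimeWarning, match="zero probability"):
            assert log_likelihood(self.m, fit) == -np.inf


class TestEmStep:
    def test_k1_fixed_point(self):
        m = CountMatrix(np.array([[3, 1], [1, 3]]), ["a", "b"], ["g1", "g2"])
        cfg = FitConfig(K=1, alpha_theta=1.1)
        theta_star = np.array([[(4 + 0.1) / (8 + 0.2), (4 + 0.1) / (8 + 0.2)]])
        fit = make_fit(np.ones((2, 1)), theta_star)
        out = em_step(m, fit, cfg)
        np.testing.assert_allclose(out.theta, theta_star, atol=1e-12)
        np.testing.assert_allclose(out.q, fit.q, atol=1e-12)

    def test_monotone_on_random_inits(self, rng):
        cfg = FitConfig(K=2, seed=0)
        for _ in range(10):
            m = random_count_matrix(rng, n=6, g=10)
            q = rng.dirichlet(np.ones(2), size=6)
            theta = rng.dirichlet(np.ones(10), size=2)
            fit = make_fit(q, theta)
            from gomclust.fit import _log_prior, log_posterior

            before = log_posterior(m, fit, cfg)
            after = log_posterior(m, em_step(m, fit, cfg), cfg)
            assert after >= before - 1e-8 * abs(before)

    def test_responsibilities_match_hand_computation(self):
        # one sample, two genes, K=2: push the E/M update through by hand
        m = CountMatrix(np.array([[3, 1]]), ["s"], ["g1", "g2"])
        q = np.array([[0.6, 0.4]])
        theta = np.array([[0.8, 0.2], [0.3, 0.7]])
        cfg = FitConfig(K=2, alpha_theta=1.0, alpha_q=1.0)
        p = q @ theta
        r = np.empty((2, 2))  # r[g, k]
        for g in range(2):
            for k in range(2):
                r[g, k] = q[0, k] * theta[k, g] / p[0, g]
        c = np.array([3.0, 1.0])
        q_expected = np.array([c @ r[:, 0], c @ r[:, 1]])
        q_expected /= q_expected.sum()
        theta_expected = np.array(
            [[c[0] * r[0, 0], c[1] * r[1, 0]], [c[0] * r[0, 1], c[1] * r[1, 1]]]
        )
        theta_expected /= theta_expected.sum(axis=1, keepdims=True)
        out = em_step(m, GoMFit(q=q, theta=theta), cfg)
        np.testing.assert_allclose(out.q, q_expected[None, :], atol=1e-12)
        np.testing.assert_allclose(out.theta, theta_expected, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        m = random_count_matrix(rng, n=8, g=12)
        cfg = FitConfig(K=3)
        q = rng.dirichlet(np.ones(3), size=8)
        theta = rng.dirichlet(np.ones(12), size=3)
        perm = [2, 0, 1]
        out = em_step(m, make_fit(q, theta), cfg)
        out_p = em_step(m, make_fit(q[:, perm], theta[perm]), cfg)
        np.testing.assert_allclose(out_p.q, out.q[:, perm], atol=1e-12)
        np.testing.assert_allclose(out_p.theta, out.theta[perm], atol=1e-12)


class TestFitGom:
    def test_k1_closed_form_asymmetric(self):
        m = CountMatrix(np.array([[5, 1, 0], [2, 7, 3]]), ["a", "b"], ["g1", "g2", "g3"])
        cfg = FitConfig(K=1, alpha_theta=1.1, seed=0)
        fit = fit_gom(m, cfg)
        col = m.counts.sum(axis=0)
        expected = (col + 0.1) / (m.counts.sum() + 3 * 0.1)
        np.testing.assert_allclose(fit.theta[0], expected, atol=1e-10)
        np.testing.assert_allclose(fit.q, 1.0, atol=1e-12)

    def test_separated_groups_recovered(self):
        # two groups of 20 samples from profiles with disjoint support
        rng = np.random.default_rng(3)
        theta = np.zeros((2, 40))
        theta[0, :20] = rng.dirichlet(np.ones(20))
        theta[1, 20:] = rng.dirichlet(np.ones(20))
        counts = np.vstack(
            [rng.multinomial(1000, theta[0], size=20),
             rng.multinomial(1000, theta[1], size=20)]
        )
        m = CountMatrix(counts, [f"s{i}" for i in range(40)], [f"g{j}" for j in range(40)])
        fit = fit_gom(m, FitConfig(K=2, seed=1))
        assign = fit.q.argmax(axis=1)
        assert len(set(assign[:20])) == 1
        assert len(set(assign[20:])) == 1
        assert assign[0] != assign[-1]

    def test_seeded_determinism(self, small_counts):
        cfg = FitConfig(K=2, seed=42, max_iter=50)
        f1, f2 = fit_gom(small_counts, cfg), fit_gom(small_counts, cfg)
        np.testing.assert_array_equal(f1.q, f2.q)
        np.testing.assert_array_equal(f1.theta, f2.theta)
        assert f1.log_posterior_trace == f2.log_posterior_trace

    def test_best_of_restarts(self, small_counts):
        cfg = FitConfig(K=2, seed=7, n_restarts=3, max_iter=30)
        best = fit_gom(small_counts, cfg)
        singles = [_run_em(small_counts, cfg, r) for r in range(3)]
        assert best.log_likelihood == max(s.log_likelihood for s in singles)

    def test_k0_rejected(self):
        with pytest.raises(ValueError, match="K"):
            FitConfig(K=0)

    def test_zero_total_sample_rejected(self):
        m = CountMatrix.__new__(CountMatrix)  # bypass validation deliberately
        m.counts = np.array([[0, 0], [1, 2]])
        m.sample_ids, m.gene_ids = ["a", "b"], ["g1", "g2"]
        m.row_totals = m.counts.sum(axis=1)
        with pytest.raises(ValueError, match="zero total"):
            fit_gom(m, FitConfig(K=1))


class TestRecovery:
    def test_membership_recovery_on_simulated_data(self, simulated_k3):
        _, m, q_true, _ = simulated_k3
        fit = fit_gom(m, FitConfig(K=3, seed=5, n_restarts=2, max_iter=500))
        assert aligned_membership_error(q_true, fit.q) < 0.08
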