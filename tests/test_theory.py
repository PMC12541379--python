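import numpy as np
import pytest

from hievi.synthetic import random_unit_vectors
from hievi.theory import (
    FamilyModel,
    alpha_from_kappa,
    expected_dot,
    expected_sq_distance,
    expected_sq_norm,
    monte_carlo_moments,
)


def orthogonal_model(K, d, alpha, kappa=None):
    mu = np.zeros((K, d))
    mu[np.arange(K), np.arange(K)] = 1.0
    kap = None if kappa is None else np.full(K, float(kappa))
    return FamilyModel(mu, np.asarray(alpha, dtype=float), kap)


def pair_sum_oracle(model, assignment):
    """Direct double sum over i != j of alpha_i alpha_j mu_i . mu_j."""
    total = 0.0
    for i, ki in enumerate(assignment):
        for j, kj in enumerate(assignment):
            if i != j:
                total += (
                    model.alpha[ki]
                    * model.alpha[kj]
                    * float(model.mu[ki] @ model.mu[kj])
                )
    return total


def dot_oracle(model, n_u, n_v):
    """Direct double sum over families k, l (k = l and k != l terms)."""
    K = model.K
    first = sum(n_u[k] * n_v[k] * model.alpha[k] ** 2 for k in range(K))
    second = sum(
        n_u[k] * n_v[l] * model.alpha[k] * model.alpha[l] * float(model.mu[k] @ model.mu[l])
        for k in range(K)
        for l in range(K)
        if k != l
    )
    return (first + second) / (n_u.sum() * n_v.sum())


class TestExpectedSqNorm:
    def test_single_protein_is_one(self):
        model = orthogonal_model(3, 4, [0.2, 0.9, 0.5])
        assert expected_sq_norm(model, assignment=[1]) == 1.0

    def test_two_orthogonal_families_cross_terms_vanish(self):
        model = orthogonal_model(2, 4, [0.3, 0.8])
        assert abs(expected_sq_norm(model, assignment=[0, 1]) - 0.5) < 1e-15

    def test_three_in_one_family_hand_value(self):
        # 1/3 + (1/9) * 6 * 0.8^2 = 0.76
        model = orthogonal_model(1, 4, [0.8])
        value = expected_sq_norm(model, assignment=[0, 0, 0])
        assert abs(value - 0.76) < 1e-12

    def test_matches_pairwise_summation_oracle(self):
        rng = np.random.default_rng(6)
        mu = random_unit_vectors(4, 8, rng)
        model = FamilyModel(mu, rng.uniform(0, 1, 4))
        assignment = [0, 1, 1, 3, 2, 0, 0]
        m = len(assignment)
        oracle = 1 / m + pair_sum_oracle(model, assignment) / m**2
        assert abs(expected_sq_norm(model, assignment=assignment) - oracle) < 1e-12

    def test_counts_and_assignment_agree(self):
        model = orthogonal_model(3, 5, [0.5, 0.7, 0.2])
        by_assignment = expected_sq_norm(model, assignment=[0, 0, 2, 1])
        by_counts = expected_sq_norm(model, counts=np.array([2.0, 1.0, 1.0]))
        assert abs(by_assignment - by_counts) < 1e-15

    def test_empty_assignment_rejected(self):
        model = orthogonal_model(2, 3, [0.5, 0.5])
        with pytest.raises(ValueError, match="empty"):
            expected_sq_norm(model, assignment=[])


class TestExpectedDot:
    def test_disjoint_orthogonal_families_give_zero(self):
        model = orthogonal_model(2, 4, [0.9, 0.6])
        value = expected_dot(model, np.array([2.0, 0.0]), np.array([0.0, 3.0]))
        assert abs(value) < 1e-15

    def test_identical_single_family_alpha_one(self):
        model = orthogonal_model(1, 3, [1.0])
        assert expected_dot(model, np.array([1.0]), np.array([1.0])) == 1.0

    def test_printed_formula_hand_value(self):
        # n_u=(2,1), n_v=(1,3), orthogonal, alpha=(0.9, 0.7):
        # (1/12)(2*1*0.81 + 1*3*0.49) = 0.2575
        model = orthogonal_model(2, 4, [0.9, 0.7])
        value = expected_dot(model, np.array([2.0, 1.0]), np.array([1.0, 3.0]))
        assert abs(value - 0.2575) < 1e-12

    def test_matches_double_sum_oracle_nonorthogonal(self):
        rng = np.random.default_rng(12)
        mu = random_unit_vectors(3, 6, rng)
        model = FamilyModel(mu, rng.uniform(0, 1, 3))
        n_u = np.array([2.0, 0.0, 5.0])
        n_v = np.array([1.0, 3.0, 1.0])
        assert abs(expected_dot(model, n_u, n_v) - dot_oracle(model, n_u, n_v)) < 1e-12

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        mu = random_unit_vectors(4, 5, rng)
        model = FamilyModel(mu, rng.uniform(0, 1, 4))
        n_u = np.array([1.0, 2.0, 0.0, 1.0])
        n_v = np.array([0.0, 1.0, 3.0, 2.0])
        assert abs(
            expected_dot(model, n_u, n_v) - expected_dot(model, n_v, n_u)
        ) < 1e-15

    def test_out_of_model_family_rejected(self):
        model = orthogonal_model(2, 3, [0.5, 0.5])
        with pytest.raises(ValueError, match="outside"):
            expected_dot(model, {5: 1}, {0: 1})


class TestExpectedSqDistance:
    def test_identical_deterministic_phages_distance_zero(self):
        model = orthogonal_model(1, 3, [1.0])
        counts = np.array([4.0])
        assert abs(expected_sq_distance(model, counts, counts)) < 1e-15

    def test_disjoint_orthogonal_alpha_one_singletons(self):
        model = orthogonal_model(2, 4, [1.0, 1.0])
        value = expected_sq_distance(model, np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert abs(value - 2.0) < 1e-15

    def test_non_negative_for_random_models(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            K = int(rng.integers(1, 5))
            mu = random_unit_vectors(K, 6, rng)
            model = FamilyModel(mu, rng.uniform(0, 1, K))
            n_u = rng.integers(0, 4, K).astype(float)
            n_v = rng.integers(0, 4, K).astype(float)
            if n_u.sum() == 0 or n_v.sum() == 0:
                continue
            assert expected_sq_distance(model, n_u, n_v) >= -1e-12

    def test_matches_monte_carlo_small_model(self):
        rng = np.random.default_rng(15)
        kappa = 10.0
        d = 8
        mu = random_unit_vectors(2, d, rng)
        alpha = alpha_from_kappa(kappa, d)
        model = FamilyModel(mu, np.full(2, alpha), np.full(2, kappa))
        report = monte_carlo_moments(model, [0, 0, 1], [1, 1], 10_000, seed=16)
        for stats in report.values():
            assert abs(stats["z"]) < 3.0


class TestAlphaFromKappa:
    def test_zero_kappa_is_uniform(self):
        assert alpha_from_kappa(0.0, 16) == 0.0

    def test_monotone_in_kappa(self):
        alphas = [alpha_from_kappa(k, 16) for k in (1.0, 10.0, 100.0)]
        assert alphas[0] < alphas[1] < alphas[2]
        assert all(0 < a < 1 for a in alphas)

    @pytest.mark.parametrize("d,kappa", [(16, 25.0), (3, 5.0), (64, 50.0)])
    def test_matches_direct_bessel_ratio(self, d, kappa):
        # A_d(kappa) = I_{d/2}(kappa) / I_{d/2-1}(kappa)
        from scipy.special import ive

        closed = float(ive(d / 2, kappa) / ive(d / 2 - 1, kappa))
        assert abs(alpha_from_kappa(kappa, d) - closed) < 1e-12

    def test_finite_where_direct_bessel_underflows(self):
        value = alpha_from_kappa(50.0, 2560)
        assert 0.0 < value < 0.05

    def test_sampler_realizes_the_analytic_compactness(self):
        # consistency: the vMF sampler's mean resultant length matches A_d(kappa)
        from hievi.theory import alpha_empirical

        d, kappa = 16, 25.0
        assert abs(alpha_empirical(kappa, d, 100_000, 3) - alpha_from_kappa(kappa, d)) < 5e-3

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            alpha_from_kappa(-1.0, 8)


class TestAnalyticVsSimulation:
    """Empirical moments of simulated proteome pairs match the formulas."""

    @pytest.mark.parametrize("K,d,m", [(1, 8, 5), (2, 8, 1), (5, 64, 5)])
    def test_moments_within_three_standard_errors(self, K, d, m):
        rng = np.random.default_rng(100 + K + d + m)
        kappa = 30.0
        mu = random_unit_vectors(K, d, rng)
        alpha = alpha_from_kappa(kappa, d)
        model = FamilyModel(mu, np.full(K, alpha), np.full(K, kappa))
        assignment_u = rng.integers(0, K, m)
        assignment_v = rng.integers(0, K, m)
        report = monte_carlo_moments(
            model, assignment_u, assignment_v, 4000, seed=int(rng.integers(2**31))
        )
        for name, stats in report.items():
            assert abs(stats["z"]) < 3.5, (name, stats)
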