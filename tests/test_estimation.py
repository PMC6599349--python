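"""Network estimation: SKEPTIC correlations, glasso, EBIC selection."""

import warnings

import numpy as np
import pytest
from scipy import stats

from honosnet.estimation import (
    ebic,
    estimate_network,
    graphical_lasso,
    kendall_tau_b,
    precision_to_partial,
    skeptic_correlation,
)
from honosnet.simulate import make_true_network, sample_ordinal_matrix

from .oracles import (
    glasso_objective,
    glasso_oracle_3x3,
    partial_corr_3x3_recursion,
    tau_b_bruteforce,
)


class TestKendallTau:
    def test_perfect_agreement(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert kendall_tau_b(x, x) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert kendall_tau_b(x, x[::-1]) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_pair_count_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 8).astype(float)
        y = rng.integers(0, 4, 8).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert kendall_tau_b(x, y) == pytest.approx(
            tau_b_bruteforce(x, y), abs=1e-12
        )

    def test_constant_vector_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert kendall_tau_b(np.ones(5), np.arange(5.0)) == 0.0

    def test_matrix_kernel_agrees_with_scipy(self, rng):
        from honosnet.estimation import _tau_b_matrix

        X = rng.integers(0, 5, (40, 12)).astype(float)
        tau, _ = _tau_b_matrix(X)
        for i in range(12):
            for j in range(i):
                ref = stats.kendalltau(X[:, i], X[:, j]).statistic
                assert tau[i, j] == pytest.approx(ref, abs=1e-12)


class TestSkeptic:
    def test_sine_transform_closed_forms(self):
        # tau = 1/3 on three points -> r = sin(pi/6) = 0.5
        X = np.column_stack([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]])
        S = skeptic_correlation(X)
        assert S.values[0, 1] == pytest.approx(0.5, abs=1e-12)
        # tau = 1 -> r = sin(pi/2) = 1; the singular result triggers the
        # eigenvalue-clipping repair, which nudges it just below 1
        X2 = np.column_stack([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        S2 = skeptic_correlation(X2)
        assert S2.psd_repaired
        assert S2.values[0, 1] == pytest.approx(1.0, abs=2e-4)

    def test_invariant_under_monotone_column_transforms(self, rng):
        X = rng.normal(size=(50, 12))
        Y = X.copy()
        Y[:, 0] = np.exp(Y[:, 0])
        Y[:, 5] = Y[:, 5] ** 3
        Y[:, 11] = np.arctan(Y[:, 11])
        a = skeptic_correlation(X).values
        b = skeptic_correlation(Y).values
        assert np.allclose(a, b, atol=1e-12)

    def test_output_always_positive_definite(self, rng):
        for _ in range(10):
            X = rng.integers(0, 5, (15, 12)).astype(float)
            S = skeptic_correlation(X)
            assert np.min(np.linalg.eigvalsh(S.values)) >= 1e-8
            assert np.allclose(np.diag(S.values), 1.0)

    def test_constant_column_warns_and_zeroes(self, rng):
        X = rng.integers(0, 5, (20, 12)).astype(float)
        X[:, 4] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            S = skeptic_correlation(X)
        off = np.delete(S.values[4], 4)
        assert np.allclose(off, 0.0)


class TestGraphicalLasso:
    def test_full_shrinkage_gives_diagonal_precision(self, rng):
        X = rng.normal(size=(50, 6))
        S = np.corrcoef(X.T)
        lam = np.max(np.abs(S - np.eye(6))) * 1.001
        K = graphical_lasso(S, lam)
        assert np.allclose(K - np.diag(np.diag(K)), 0.0, atol=1e-12)

    def test_identity_input_at_zero_penalty(self):
        assert np.allclose(graphical_lasso(np.eye(5), 0.0), np.eye(5))

    def test_zero_penalty_returns_inverse(self, rng):
        X = rng.normal(size=(80, 8))
        S = np.corrcoef(X.T)
        K = graphical_lasso(S, 0.0)
        assert np.max(np.abs(K - np.linalg.inv(S))) < 1e-5

    @pytest.mark.parametrize("seed", range(4))
    def test_three_variable_objective_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(60, 3))
        A[:, 2] += 0.5 * A[:, 0]
        S = np.corrcoef(A.T)
        lam = 0.1
        K = graphical_lasso(S, lam)
        mine = glasso_objective(K, S, lam)
        oracle = glasso_oracle_3x3(S, lam, seed=seed)
        assert mine <= oracle + 1e-4
        assert abs(mine - oracle) < 1e-4

    def test_matches_sklearn_objective(self, rng):
        from sklearn.covariance import graphical_lasso as skl_glasso

        X = rng.normal(size=(100, 12)) @ rng.normal(size=(12, 12)) * 0.2
        X += rng.normal(size=(100, 12))
        S = np.corrcoef(X.T)
        lam_max = np.max(np.abs(S - np.eye(12)))
        for ratio in (0.5, 0.1, 0.02):
            lam = ratio * lam_max
            K = graphical_lasso(S, lam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, K_ref = skl_glasso(S, alpha=lam, tol=1e-10, max_iter=3000)
            assert abs(
                glasso_objective(K, S, lam) - glasso_objective(K_ref, S, lam)
            ) < 1e-5

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            graphical_lasso(np.eye(3), -0.1)


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self, rng):
        X = rng.normal(size=(100, 5))
        S = np.corrcoef(X.T)
        K = np.linalg.inv(S)
        n = 100
        sign, logdet = np.linalg.slogdet(K)
        L = (n / 2) * (logdet - np.trace(S @ K))
        E = 10  # dense 5-node precision: all off-diagonal pairs
        assert ebic(K, S, n, gamma=0.0) == pytest.approx(
            -2 * L + E * np.log(n), rel=1e-12
        )

    def test_one_extra_edge_penalty_difference(self):
        # two models with equal likelihood term: the EBIC difference is
        # log n + 4 gamma log p exactly
        n, gamma, p = 200, 0.5, 3
        S = np.eye(3)
        K1 = np.eye(3)
        K2 = np.eye(3)
        K2[0, 1] = K2[1, 0] = 1e-9  # counted edge, negligible likelihood
        diff = ebic(K2, S, n, gamma) - ebic(K1, S, n, gamma)
        expected = np.log(n) + 4 * gamma * np.log(p)
        assert diff == pytest.approx(expected, abs=1e-5)

    def test_hand_computed_three_by_three(self):
        S = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.2], [0.0, 0.2, 1.0]])
        K = np.array([[1.2, -0.3, 0.0], [-0.3, 1.3, -0.2], [0.0, -0.2, 1.1]])
        n, gamma = 100, 0.5
        logdet = np.log(np.linalg.det(K))
        L = (n / 2) * (logdet - np.sum(S * K))
        expected = -2 * L + 2 * np.log(n) + 4 * 2 * gamma * np.log(3)
        assert ebic(K, S, n, gamma) == pytest.approx(expected, rel=1e-12)

    def test_singular_precision_rejected(self):
        with pytest.raises(ValueError):
            ebic(np.zeros((3, 3)), np.eye(3), 100)


class TestPrecisionToPartial:
    def test_diagonal_precision_gives_empty_network(self):
        net = precision_to_partial(np.diag([1.0, 2.0, 3.0]))
        assert np.allclose(net.weights, 0.0)
        assert net.edge_count == 0

    def test_bivariate_identity(self):
        r = 0.42
        S = np.array([[1.0, r], [r, 1.0]])
        net = precision_to_partial(np.linalg.inv(S))
        assert net.weights[0, 1] == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_three_variable_recursion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(200, 3)) @ rng.normal(size=(3, 3))
        R = np.corrcoef(A.T)
        net = precision_to_partial(np.linalg.inv(R))
        assert np.allclose(
            net.weights + np.eye(3) * 0.0,
            partial_corr_3x3_recursion(R) - np.diag(np.diag(
                partial_corr_3x3_recursion(R))),
            atol=1e-10,
        )

    def test_non_positive_diagonal_rejected(self):
        K = np.eye(3)
        K[1, 1] = -1.0
        with pytest.raises(ValueError):
            precision_to_partial(K)


class TestEstimateNetwork:
    def test_deterministic(self, rng):
        b = make_true_network(12, 0.2, (0.2, 0.4), seed=0)
        X = sample_ordinal_matrix(b, 120, rng).astype(float)
        n1, f1 = estimate_network(X)
        n2, f2 = estimate_network(X)
        assert np.array_equal(n1.weights, n2.weights)
        assert f1.selected_index == f2.selected_index

    def test_edge_count_nonincreasing_along_path(self, rng):
        b = make_true_network(12, 0.25, (0.2, 0.4), seed=3)
        X = sample_ordinal_matrix(b, 200, rng).astype(float)
        _, fit = estimate_network(X)
        # lambda decreases along the path, so edges should not vanish in
        # bulk; small local dips are tolerated (and logged by the module)
        assert np.all(np.diff(fit.edge_counts) >= -2)

    def test_selected_index_minimizes_ebic(self, rng):
        b = make_true_network(12, 0.2, (0.2, 0.4), seed=4)
        X = sample_ordinal_matrix(b, 150, rng).astype(float)
        _, fit = estimate_network(X)
        assert fit.ebic_values[fit.selected_index] == fit.ebic_values.min()

    def test_empty_truth_rarely_yields_spurious_edges(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            b = make_true_network(12, 0.0, (0.0, 0.0), seed=seed)
            X = sample_ordinal_matrix(b, 500, rng).astype(float)
            net, _ = estimate_network(X)
            if net.edge_count <= 2:
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_three_edge_truth_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cand = 1000 * seed
            while True:  # find a truth with exactly 3 edges
                b = make_true_network(12, 3 / 66, (0.3, 0.4), seed=cand)
                if b.edge_mask().sum() == 3:
                    break
                cand += 1
            X = sample_ordinal_matrix(b, 1000, rng).astype(float)
            net, _ = estimate_network(X)
            if np.all(~b.edge_mask() | net.edge_mask()):
                hits += 1
        assert hits >= 18  # all 3 edges found in >= 90% of seeds
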