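"""Transport-core tests: prior-kernel Sinkhorn, COOT contractions and the
alternating solver, checked against independent brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import linprog

from cootalign.ot_core import (
    CootResult,
    PriorMatrix,
    coot_feature_cost,
    coot_sample_cost,
    pairwise_cost,
    prior_coot,
    sinkhorn_divergence,
    sinkhorn_prior,
)


def entropic_objective(P, C, Q, eps):
    """Independent evaluation of <P, C> + eps * sum P (log(P/Q) - 1)."""
    mask = P > 0
    ent = np.sum(P[mask] * (np.log(P[mask] / Q[mask]) - 1.0))
    return float(np.sum(P * C) + eps * ent)


class TestPairwiseCost:
    def test_single_point_zero_self_distance(self):
        c = pairwise_cost(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]))
        np.testing.assert_allclose(c.values, [[0.0]])

    def test_two_point_line(self):
        c = pairwise_cost(np.array([[0.0], [1.0]]), np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(c.values, [[0.0, 1.0], [1.0, 0.0]])

    def test_rescaled_to_unit_max(self):
        rng = np.random.default_rng(0)
        c = pairwise_cost(rng.normal(size=(7, 3)) * 100, rng.normal(size=(5, 3)) * 100)
        assert c.values.min() >= 0
        assert c.values.max() == pytest.approx(1.0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            pairwise_cost(np.zeros((2, 3)), np.zeros((2, 4)))

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            pairwise_cost(np.array([[np.nan]]), np.array([[0.0]]))


class TestSinkhornPrior:
    def test_constant_cost_uniform_prior_gives_product_coupling(self):
        plan = sinkhorn_prior(np.ones((2, 2)), np.ones((2, 2)), eps=0.1)
        np.testing.assert_allclose(plan.values, np.full((2, 2), 0.25), atol=1e-8)

    def test_diagonal_prior_support_forces_diagonal_plan(self):
        C = np.array([[0.3, 0.1], [0.9, 0.2]])
        plan = sinkhorn_prior(C, np.eye(2), eps=0.05)
        np.testing.assert_allclose(plan.values, np.diag([0.5, 0.5]), atol=1e-8)
        assert plan.values[0, 1] == 0.0 and plan.values[1, 0] == 0.0

    def test_symmetric_2x2_matches_grid_search_oracle(self):
        # By symmetry the plan is [[p, .5-p], [.5-p, p]]; minimize the entropic
        # objective over p with a fine grid as an independent oracle.
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        Q = np.full((2, 2), 0.25)
        eps = 0.05
        p = np.linspace(1e-9, 0.5 - 1e-9, 200001)
        q = 0.5 - p
        # <P,C> = 2q; entropic term evaluated on the two distinct entries
        objs = 2.0 * q + eps * 2.0 * (
            p * (np.log(p / 0.25) - 1.0) + q * (np.log(q / 0.25) - 1.0)
        )
        p_star = p[int(np.argmin(objs))]
        plan = sinkhorn_prior(C, Q, eps=eps, tol=1e-12, max_iter=5000)
        assert plan.values[0, 0] == pytest.approx(p_star, abs=1e-5)
        assert plan.values[1, 1] == pytest.approx(p_star, abs=1e-5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_marginal_conservation_random_10x10(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.random((10, 10))
        Q = rng.random((10, 10)) + 0.05
        plan = sinkhorn_prior(C, Q, eps=0.05)
        plan.validate(tol=1e-6)

    def test_plan_support_equals_prior_support(self):
        rng = np.random.default_rng(3)
        Q = rng.random((8, 8))
        Q[Q < 0.4] = 0.0
        Q[:, 0] = 0.5  # keep support feasible
        Q[0, :] = 0.5
        plan = sinkhorn_prior(rng.random((8, 8)), Q, eps=0.05)
        assert np.array_equal(plan.values > 0, Q > 0)

    def test_small_eps_approaches_lp_optimum(self):
        rng = np.random.default_rng(7)
        C = rng.random((3, 3))
        C /= C.max()
        a = b = np.full(3, 1 / 3)
        # LP oracle over vec(P)
        A_eq = np.zeros((6, 9))
        for i in range(3):
            A_eq[i, i * 3 : (i + 1) * 3] = 1.0
        for j in range(3):
            A_eq[3 + j, j::3] = 1.0
        res = linprog(C.ravel(), A_eq=A_eq, b_eq=np.concatenate([a, b]), bounds=(0, None))
        assert res.success
        plan = sinkhorn_prior(C, np.ones((3, 3)), eps=1e-3, max_iter=200000, tol=1e-10)
        assert float(np.sum(plan.values * C)) == pytest.approx(res.fun, abs=1e-3)

    def test_large_eps_recovers_prior_coupling(self):
        rng = np.random.default_rng(11)
        Q = rng.random((3, 3)) + 0.2
        # KL projection of Q onto couplings = zero-cost Sinkhorn fixed point
        proj = sinkhorn_prior(np.zeros((3, 3)), Q, eps=1.0, tol=1e-12, max_iter=5000).values
        plan = sinkhorn_prior(rng.random((3, 3)), Q, eps=10.0, tol=1e-12, max_iter=5000)
        assert np.max(np.abs(plan.values - proj)) < 1e-2

    def test_infeasible_prior_support_raises(self):
        Q = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            sinkhorn_prior(np.ones((2, 2)), Q, eps=0.1)

    def test_degenerate_prior_row_rejected_by_type(self):
        with pytest.raises(ValueError):
            PriorMatrix(np.array([[0.0, 0.0], [1.0, 1.0]]))


def explicit_sample_cost(X, Y, Pv):
    n, m = X.shape[0], Y.shape[0]
    out = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            for k in range(X.shape[1]):
                for l in range(Y.shape[1]):
                    out[i, j] += (X[i, k] - Y[j, l]) ** 2 * Pv[k, l]
    return out


def explicit_feature_cost(X, Y, Ps):
    dx, dy = X.shape[1], Y.shape[1]
    out = np.zeros((dx, dy))
    for k in range(dx):
        for l in range(dy):
            for i in range(X.shape[0]):
                for j in range(Y.shape[0]):
                    out[k, l] += (X[i, k] - Y[j, l]) ** 2 * Ps[i, j]
    return out


class TestCootContractions:
    def test_matched_features_zero_diagonal(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        Pv = np.diag([0.5, 0.5])
        c = coot_sample_cost(X, X, Pv)
        np.testing.assert_allclose(np.diag(c.values), 0.0, atol=1e-12)

    def test_2x2_instance_known_values(self):
        X = Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        Pv = np.diag([0.5, 0.5])
        c = coot_sample_cost(X, Y, Pv)
        np.testing.assert_allclose(c.values, explicit_sample_cost(X, Y, Pv), atol=1e-12)
        np.testing.assert_allclose(c.values, [[0.0, 1.0], [1.0, 0.0]], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_decomposition_matches_explicit_sum(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 3))
        Y = rng.normal(size=(4, 2))
        Pv = rng.random((3, 2))
        Pv /= Pv.sum()
        Ps = rng.random((5, 4))
        Ps /= Ps.sum()
        np.testing.assert_allclose(
            coot_sample_cost(X, Y, Pv).values, explicit_sample_cost(X, Y, Pv), atol=1e-10
        )
        np.testing.assert_allclose(
            coot_feature_cost(X, Y, Ps).values, explicit_feature_cost(X, Y, Ps), atol=1e-10
        )

    def test_all_zero_inputs_give_zero_cost(self):
        X = np.zeros((3, 2))
        Y = np.zeros((2, 2))
        Ps = np.full((3, 2), 1 / 6)
        np.testing.assert_allclose(coot_feature_cost(X, Y, Ps).values, 0.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            coot_sample_cost(np.zeros((3, 2)), np.zeros((2, 2)), np.zeros((3, 2)))


class TestPriorCoot:
    def test_permutation_recovery(self):
        rng = np.random.default_rng(0)
        centers = rng.normal(scale=4.0, size=(30, 10))
        X = centers + rng.normal(scale=0.1, size=(30, 10))
        sigma = rng.permutation(30)
        Y = X[sigma]  # row j of Y is row sigma[j] of X, so the plan pairs
        # X-row i with Y-row sigma^{-1}(i)
        res = prior_coot(X, Y, eps=0.05, n_outer=10)
        recovered = np.argmax(res.sample_plan.values, axis=1)
        assert np.mean(recovered == np.argsort(sigma)) >= 0.95
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs <= 1e-6)

    def test_constant_matrices_give_product_coupling(self):
        X = np.full((6, 4), 2.0)
        Y = np.full((5, 3), 2.0)
        res = prior_coot(X, Y, eps=0.05, n_outer=3)
        np.testing.assert_allclose(res.sample_plan.values, np.full((6, 5), 1 / 30), atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 5))
        Y = rng.normal(size=(20, 5))
        res = prior_coot(X, Y, eps=0.05, n_outer=8, tol=1e-5)
        assert isinstance(res, CootResult)
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs <= 1e-6), diffs

    def test_swap_transposes_plans(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        Y = rng.normal(size=(6, 3))
        res_xy = prior_coot(X, Y, eps=0.05, n_outer=5)
        res_yx = prior_coot(Y, X, eps=0.05, n_outer=5)
        np.testing.assert_allclose(
            res_xy.sample_plan.values, res_yx.sample_plan.values.T, atol=1e-5
        )
        np.testing.assert_allclose(
            res_xy.feature_plan.values, res_yx.feature_plan.values.T, atol=1e-5
        )

    def test_plans_satisfy_coupling_invariants(self):
        rng = np.random.default_rng(9)
        res = prior_coot(rng.normal(size=(12, 6)), rng.normal(size=(10, 5)), eps=0.05)
        res.sample_plan.validate()
        res.feature_plan.validate()


class TestSinkhornDivergence:
    def test_zero_at_equality(self):
        rng = np.random.default_rng(0)
        U = rng.normal(size=(15, 4))
        assert abs(sinkhorn_divergence(U, U.copy(), eps=0.1)) < 1e-6

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            U = rng.normal(size=(12, 3))
            V = rng.normal(size=(14, 3))
            assert sinkhorn_divergence(U, V, eps=0.1, n_iter=200) >= -1e-9

    def test_monotone_in_translation_offset(self):
        rng = np.random.default_rng(2)
        U = rng.normal(size=(20, 3))
        vals = [
            float(sinkhorn_divergence(U, U + off, eps=0.1, n_iter=200))
            for off in (0.5, 1.0, 2.0)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_differentiable_wrt_embeddings(self):
        from autograd import grad

        rng = np.random.default_rng(3)
        U = rng.normal(size=(8, 3))
        V = rng.normal(size=(9, 3))
        g = grad(lambda v: sinkhorn_divergence(U, v, eps=0.1, n_iter=30))(V)
        assert g.shape == V.shape
        assert np.all(np.isfinite(g)) and np.any(g != 0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sinkhorn_divergence(np.zeros((0, 3)), np.zeros((4, 3)))
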