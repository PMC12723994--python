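"""Alignment-machinery tests: plan mixing, barycentric projection, the
confidence pipeline against a step-by-step oracle, GMM anchor thresholds,
and the loss assembly."""

import math

import numpy as np
import pytest

from cootalign.alignment import (
    AnchorPartition,
    LossWeights,
    alignment_confidence,
    barycentric_project,
    bary_loss,
    gmm_bayes_threshold,
    mix_plans,
    partition_anchors,
    reg_loss,
    total_loss,
)


class TestMixPlans:
    def test_endpoints(self):
        P = np.array([[0.5, 0.0], [0.0, 0.5]])
        Ps = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_array_equal(mix_plans(P, Ps, 0.0).values, P)
        np.testing.assert_array_equal(mix_plans(P, Ps, 1.0).values, Ps)

    def test_halfway_mix(self):
        P = np.array([[0.5, 0.0], [0.0, 0.5]])
        Ps = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(mix_plans(P, Ps, 0.5).values, np.full((2, 2), 0.25))

    def test_mix_remains_coupling(self):
        rng = np.random.default_rng(0)
        A = rng.random((4, 5)); A /= A.sum()
        B = rng.random((4, 5)); B /= B.sum()
        M = mix_plans(A, B, 0.3).values
        assert M.sum() == pytest.approx(1.0)
        assert np.all(M >= 0)

    def test_lambda_out_of_range_raises(self):
        with pytest.raises(ValueError):
            mix_plans(np.ones((2, 2)) / 4, np.ones((2, 2)) / 4, 1.5)


class TestBarycentricProjection:
    def test_scaled_identity_plan_reproduces_anchors(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(5, 3))
        np.testing.assert_allclose(barycentric_project(np.eye(5) / 5, u), u)

    def test_uniform_plan_gives_mean(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(6, 2))
        proj = barycentric_project(np.full((6, 4), 1 / 24), u)
        np.testing.assert_allclose(proj, np.tile(u.mean(axis=0), (4, 1)))

    def test_weighted_average_arithmetic(self):
        u = np.array([[0.0, 0.0], [2.0, 0.0]])
        plan = np.array([[0.25], [0.75]])
        np.testing.assert_allclose(barycentric_project(plan, u), [[1.5, 0.0]])

    def test_zero_column_raises(self):
        with pytest.raises(ValueError, match="no mass"):
            barycentric_project(np.array([[0.5, 0.0], [0.5, 0.0]]), np.zeros((2, 2)))

    def test_projection_in_convex_hull(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=(8, 4))
        plan = rng.random((8, 6)); plan /= plan.sum()
        proj = barycentric_project(plan, u)
        assert proj.min() >= u.min() - 1e-12
        assert proj.max() <= u.max() + 1e-12


class TestBaryLoss:
    def test_zero_at_equality(self):
        u = np.random.default_rng(0).normal(size=(7, 3))
        assert float(bary_loss(u, u.copy())) == 0.0

    def test_single_cell_pythagorean(self):
        assert float(bary_loss(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))) == 25.0

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(5, 2))
        ub = rng.normal(size=(5, 2))
        base = float(bary_loss(u, ub))
        doubled = float(bary_loss(u, u + 2 * (ub - u)))
        assert doubled == pytest.approx(4 * base)


def confidence_oracle(D_within, D_cross, k_c):
    """Independent step-by-step evaluation of the confidence pipeline on a
    hand-held instance."""
    n_x, n_y = D_cross.shape
    s_cross = np.array([np.mean(np.sort(D_cross[:, i])[:k_c]) for i in range(n_y)])
    tau = np.median([D_within[i, j] for i in range(n_y) for j in range(n_y)
                     if i != j and D_within[i, j] > 0])
    s_within = np.zeros(n_y)
    for i in range(n_y):
        sims = np.array([math.exp(-D_within[i, j] / tau)
                         for j in range(n_y) if j != i])
        pi = sims / sims.sum()
        ent = -sum(p * math.log(p) for p in pi if p > 0)
        s_within[i] = ent / math.log(n_y - 1)

    def mm(x):
        return (x - x.min()) / (x.max() - x.min()) if x.max() > x.min() else np.zeros_like(x)

    s = 0.5 * (mm(s_cross) + mm(s_within))
    m = np.median(s)
    sig = max(np.median(np.abs(s - m)), 1e-8)
    return 1.0 / (1.0 + np.exp((s - m) / sig))


class TestAlignmentConfidence:
    def test_three_cell_worked_instance_matches_oracle(self):
        D_within = np.array([[0.0, 1.0, 4.0],
                             [1.0, 0.0, 2.0],
                             [4.0, 2.0, 0.0]])
        D_cross = np.array([[0.5, 3.0, 1.0],
                            [1.5, 2.5, 4.0],
                            [2.0, 1.0, 0.5]])
        conf = alignment_confidence(D_within, D_cross, k_c=2)
        oracle = confidence_oracle(D_within, D_cross, k_c=2)
        np.testing.assert_allclose(conf.c, oracle, atol=1e-12)

    def test_identical_scores_give_half_confidence(self):
        D_within = np.ones((4, 4)) - np.eye(4)
        D_cross = np.ones((4, 4))
        conf = alignment_confidence(D_within, D_cross, k_c=2)
        np.testing.assert_allclose(conf.c, 0.5)

    def test_increasing_cross_distance_never_raises_confidence(self):
        rng = np.random.default_rng(0)
        D_within = np.abs(rng.normal(size=(6, 6))) + 0.1
        np.fill_diagonal(D_within, 0.0)
        D_within = 0.5 * (D_within + D_within.T)
        D_cross = np.abs(rng.normal(size=(5, 6))) + 0.1
        base = alignment_confidence(D_within, D_cross, k_c=3).c[2]
        worse = D_cross.copy()
        worse[:, 2] += 10.0
        bumped = alignment_confidence(D_within, worse, k_c=3).c[2]
        assert bumped <= base

    def test_scale_invariance_of_confidence(self):
        rng = np.random.default_rng(1)
        D_within = np.abs(rng.normal(size=(6, 6))) + 0.1
        np.fill_diagonal(D_within, 0.0)
        D_cross = np.abs(rng.normal(size=(6, 6))) + 0.1
        a = alignment_confidence(D_within, D_cross, k_c=3).c
        b = alignment_confidence(7.3 * D_within, 7.3 * D_cross, k_c=3).c
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_invalid_k_raises(self):
        with pytest.raises(ValueError):
            alignment_confidence(np.zeros((3, 3)), np.zeros((2, 3)), k_c=5)


def bisection_threshold(means, variances, weights, lo, hi, iters=200):
    """Independent bisection on the posterior-equality equation."""
    import numpy as np

    def f(x):
        n1 = weights[0] * np.exp(-(x - means[0]) ** 2 / (2 * variances[0])) / np.sqrt(variances[0])
        n2 = weights[1] * np.exp(-(x - means[1]) ** 2 / (2 * variances[1])) / np.sqrt(variances[1])
        return n1 - n2

    a, b = lo, hi
    for _ in range(iters):
        mid = 0.5 * (a + b)
        if f(a) * f(mid) <= 0:
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)


class TestAnchorPartition:
    def test_symmetric_components_give_midpoint(self):
        thr = gmm_bayes_threshold([0.2, 0.8], [0.01, 0.01], [0.5, 0.5])
        assert thr == pytest.approx(0.5, abs=1e-9)

    def test_unequal_variances_match_bisection_oracle(self):
        means, variances, weights = [0.3, 0.7], [0.02, 0.005], [0.4, 0.6]
        thr = gmm_bayes_threshold(means, variances, weights)
        oracle = bisection_threshold(means, variances, weights, 0.3, 0.7)
        assert thr == pytest.approx(oracle, abs=1e-8)

    def test_two_tight_clusters_partition_exactly(self):
        rng = np.random.default_rng(0)
        c = np.concatenate([rng.normal(0.2, 0.01, 40), rng.normal(0.85, 0.01, 25)])
        part = partition_anchors(c, seed=0)
        assert set(part.anchors) == set(range(40, 65))
        assert set(part.non_anchors) == set(range(40))

    def test_constant_scores_anchor_everyone_with_warning(self):
        with pytest.warns(RuntimeWarning):
            part = partition_anchors(np.full(10, 0.5))
        assert part.anchors.size == 10 and part.non_anchors.size == 0

    def test_too_few_cells_raise(self):
        with pytest.raises(ValueError):
            partition_anchors(np.array([0.1, 0.9]))


class TestRegLoss:
    def make_part(self, n_non, n_anch):
        return AnchorPartition(np.arange(n_non, n_non + n_anch), np.arange(n_non), 0.5)

    def test_zero_when_projections_equal_embeddings(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(6, 3))
        part = self.make_part(2, 4)
        assert float(reg_loss(u, u.copy(), part)) == 0.0

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(6, 3))
        part = self.make_part(3, 3)
        assert float(reg_loss(u, u + np.array([5.0, -2.0, 1.0]), part)) == pytest.approx(0.0, abs=1e-12)

    def test_worked_two_anchor_example(self):
        # one non-anchor at distances (1, 2) before and (2, 2) after
        u = np.array([[0.0], [1.0], [-2.0]])        # non-anchor, anchors
        ub = np.array([[0.0], [2.0], [-2.0]])
        part = AnchorPartition(np.array([1, 2]), np.array([0]), 0.5)
        assert float(reg_loss(u, ub, part)) == pytest.approx(0.5)

    def test_empty_non_anchor_set_warns_and_returns_zero(self):
        u = np.random.default_rng(2).normal(size=(4, 2))
        part = AnchorPartition(np.arange(4), np.array([], dtype=int), 0.5)
        with pytest.warns(RuntimeWarning):
            assert reg_loss(u, u + 1.0, part) == 0.0


class TestTotalLoss:
    def test_only_omics_when_extra_weights_zero(self):
        w = LossWeights(lambda_graph=0.0, lambda_regbary=0.0, lambda_div=0.0)
        comps = dict(omics=3.5, graph=9.9, bary=1.0, reg=1.0, div=1.0)
        assert total_loss(comps, w, epoch=100, tuning_epochs=300) == 3.5

    def test_default_weights_unit_components_at_full_ramp(self):
        w = LossWeights(ramp_fraction=1.0)  # ramp hits exactly 1 at the end
        comps = dict(omics=1.0, graph=1.0, bary=1.0, reg=1.0, div=1.0)
        val = total_loss(comps, w, epoch=300, tuning_epochs=300)
        assert val == pytest.approx(1 + 1 * 1 + 0.1 * (1 + 0.1 * 1) + 0.01 * 1)

    def test_tuning_start_has_zero_ramp(self):
        w = LossWeights()
        comps = dict(omics=2.0, graph=1.0, bary=5.0, reg=5.0, div=5.0)
        assert total_loss(comps, w, epoch=0, tuning_epochs=300) == pytest.approx(2.0 + 1.0)

    def test_ramp_grows_past_one(self):
        w = LossWeights(ramp_fraction=0.1)
        assert w.ramp(30, 300) == pytest.approx(1.0)
        assert w.ramp(300, 300) == pytest.approx(10.0)


def test_permutation_plan_projection_gives_exact_pairing():
    """With lambda_prior = 1 and a permutation-like stage-1 plan, cells whose
    embeddings equal their barycentric image are exactly paired with their
    plan-assigned anchors."""
    rng = np.random.default_rng(0)
    n = 12
    u_x = rng.normal(size=(n, 4))
    sigma = rng.permutation(n)
    Ps = np.zeros((n, n))
    Ps[sigma, np.arange(n)] = 1.0 / n  # cell j of Y matches X cell sigma[j]
    mixed = mix_plans(np.full((n, n), 1.0 / n**2), Ps, 1.0)
    u_bar = barycentric_project(mixed, u_x)
    u_y = u_bar.copy()
    assert float(bary_loss(u_y, u_bar)) == 0.0
    np.testing.assert_allclose(u_y, u_x[sigma])
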