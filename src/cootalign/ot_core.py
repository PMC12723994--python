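"""Entropic optimal transport with a non-uniform prior kernel.

This module houses the transport machinery used for diagonal integration of
unpaired single-cell modalities:

* :func:`sinkhorn_prior` — entropic OT where the Gibbs kernel is modulated by a
  nonnegative prior matrix ``Q``, i.e. ``K_ij = Q_ij * exp(-C_ij / eps)``.  The
  solution minimizes ``<P, C> - eps * H(P | Q)`` over couplings, so the plan is
  pulled toward ``Q`` while still adapting to the cost.
* :func:`prior_coot` — the alternating co-optimal-transport (COOT) solver that
  jointly infers a cell-level and a feature-level coupling, refreshing the
  priors with the plans of the previous sweep (a proximal-point scheme).
* :func:`sinkhorn_divergence` — the debiased entropic OT cost used as a
  distributional-alignment training loss; implemented over ``autograd.numpy``
  so gradients flow into the embeddings.

All Sinkhorn iterations run in the log domain, which keeps zero prior entries
exactly zero in the plan and avoids kernel underflow at small ``eps``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
from scipy.special import logsumexp

import autograd.numpy as anp
from autograd.scipy.special import logsumexp as ag_logsumexp

__all__ = [
    "CostMatrix",
    "PriorMatrix",
    "TransportPlan",
    "CootResult",
    "pairwise_cost",
    "sinkhorn_prior",
    "coot_sample_cost",
    "coot_feature_cost",
    "prior_coot",
    "sinkhorn_divergence",
]

MARGINAL_TOL = 1e-6
MASS_TOL = 1e-8


@dataclass
class CostMatrix:
    """Nonnegative ground-cost matrix between two point sets."""

    values: np.ndarray
    metric_tag: str = "sqeuclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cost matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("cost matrix contains negative entries")


@dataclass
class PriorMatrix:
    """Nonnegative prior ``Q`` entering the kernel ``K_ij = Q_ij e^{-C_ij/eps}``."""

    values: np.ndarray
    support_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("prior must be nonnegative and finite")
        self.support_mask = self.values > 0
        if not self.support_mask.any(axis=1).all() or not self.support_mask.any(axis=0).all():
            raise ValueError(
                "degenerate prior: every row and column needs at least one "
                "strictly positive entry"
            )


@dataclass
class TransportPlan:
    """Coupling matrix with prescribed row/column marginals."""

    values: np.ndarray
    row_marginal: np.ndarray
    col_marginal: np.ndarray
    eps: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_marginal = np.asarray(self.row_marginal, dtype=float)
        self.col_marginal = np.asarray(self.col_marginal, dtype=float)

    def validate(self, tol: float = MARGINAL_TOL) -> None:
        if np.any(self.values < 0):
            raise ValueError("transport plan has negative entries")
        if np.max(np.abs(self.values.sum(axis=1) - self.row_marginal)) > tol:
            raise ValueError("row marginals violated")
        if np.max(np.abs(self.values.sum(axis=0) - self.col_marginal)) > tol:
            raise ValueError("column marginals violated")
        if abs(self.values.sum() - 1.0) > MASS_TOL:
            raise ValueError("total mass differs from 1")


@dataclass
class CootResult:
    """Output of the alternating COOT solver."""

    sample_plan: TransportPlan
    feature_plan: TransportPlan
    objective_trace: list[float]
    n_outer: int


# ---------------------------------------------------------------------------
# ground costs and contractions
# ---------------------------------------------------------------------------

def pairwise_cost(X: np.ndarray, Y: np.ndarray, rescale: bool = True) -> CostMatrix:
    """Squared-Euclidean cost between rows of ``X`` and rows of ``Y``.

    The matrix is rescaled by its maximum so the largest entry is 1, which
    makes a single entropic weight ``eps`` meaningful across inputs of very
    different numeric scale.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape} vs {Y.shape}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite input")
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    np.maximum(sq, 0.0, out=sq)
    if rescale:
        m = sq.max()
        if m > 0:
            sq = sq / m
    return CostMatrix(sq)


def _marginals(P: TransportPlan | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    V = P.values if isinstance(P, TransportPlan) else np.asarray(P, dtype=float)
    return V.sum(axis=1), V.sum(axis=0)


def coot_sample_cost(X: np.ndarray, Y: np.ndarray, Pv: TransportPlan | np.ndarray) -> CostMatrix:
    """Cell-level cost from the feature coupling: the contraction
    ``values[i, j] = sum_{k, l} (X[i, k] - Y[j, l])^2 * Pv[k, l]``.

    Computed through the marginal decomposition, never the 4-index sum:
    ``(X∘X) r 1' + 1 (c' (Y∘Y)') - 2 X Pv Y'`` with ``r, c`` the marginals
    of ``Pv``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    V = Pv.values if isinstance(Pv, TransportPlan) else np.asarray(Pv, dtype=float)
    if V.shape != (X.shape[1], Y.shape[1]):
        raise ValueError(
            f"feature plan shape {V.shape} incompatible with X {X.shape} / Y {Y.shape}"
        )
    r, c = _marginals(V)
    out = (
        (X**2) @ r[:, None]
        + ((Y**2) @ c[:, None]).T
        - 2.0 * X @ V @ Y.T
    )
    np.maximum(out, 0.0, out=out)
    return CostMatrix(out)


def coot_feature_cost(X: np.ndarray, Y: np.ndarray, Ps: TransportPlan | np.ndarray) -> CostMatrix:
    """Feature-level cost from the cell coupling:
    ``values[k, l] = sum_{i, j} (X[i, k] - Y[j, l])^2 * Ps[i, j]``."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    V = Ps.values if isinstance(Ps, TransportPlan) else np.asarray(Ps, dtype=float)
    if V.shape != (X.shape[0], Y.shape[0]):
        raise ValueError(
            f"sample plan shape {V.shape} incompatible with X {X.shape} / Y {Y.shape}"
        )
    r, c = _marginals(V)
    out = (
        (X**2).T @ r[:, None]
        + ((Y**2).T @ c[:, None]).T
        - 2.0 * X.T @ V @ Y
    )
    np.maximum(out, 0.0, out=out)
    return CostMatrix(out)


# ---------------------------------------------------------------------------
# Sinkhorn with a prior kernel
# ---------------------------------------------------------------------------

def sinkhorn_prior(
    C: CostMatrix | np.ndarray,
    Q: PriorMatrix | np.ndarray,
    eps: float,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> TransportPlan:
    """Solve ``min <P, C> - eps * H(P | Q)`` over couplings with marginals
    ``(a, b)`` by log-domain diagonal scaling of the kernel
    ``K_ij = Q_ij * exp(-C_ij / eps)``.

    Entries of the returned plan are exactly zero wherever ``Q`` is zero.
    Non-convergence within ``max_iter`` raises a warning, not an error.
    """
    Cv = C.values if isinstance(C, CostMatrix) else np.asarray(C, dtype=float)
    Qm = Q if isinstance(Q, PriorMatrix) else PriorMatrix(np.asarray(Q, dtype=float))
    Qv = Qm.values
    if Cv.shape != Qv.shape:
        raise ValueError(f"cost {Cv.shape} and prior {Qv.shape} shapes differ")
    if eps <= 0:
        raise ValueError("eps must be positive")
    n, m = Cv.shape
    a = np.full(n, 1.0 / n) if a is None else np.asarray(a, dtype=float)
    b = np.full(m, 1.0 / m) if b is None else np.asarray(b, dtype=float)
    if abs(a.sum() - 1.0) > 1e-9 or abs(b.sum() - 1.0) > 1e-9:
        raise ValueError("marginals must sum to 1")
    support = Qm.support_mask
    if np.any((a > 0) & ~support.any(axis=1)) or np.any((b > 0) & ~support.any(axis=0)):
        raise ValueError("infeasible prior support")

    with np.errstate(divide="ignore"):
        logQ = np.where(support, np.log(np.where(support, Qv, 1.0)), -np.inf)
    log_a = np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), -np.inf)
    log_b = np.where(b > 0, np.log(np.where(b > 0, b, 1.0)), -np.inf)

    # epsilon scaling: at very small eps plain Sinkhorn converges slowly, so
    # anneal from a moderate eps and warm-start the dual potentials (kept in
    # cost units, hence invariant across eps levels)
    eps_levels = []
    e = max(eps, 0.05)
    while e > eps * 1.0000001:
        eps_levels.append(e)
        e /= 2.0
    eps_levels.append(eps)

    phi = np.zeros(n)  # dual potentials in cost units
    psi = np.zeros(m)
    converged = False
    for level, e in enumerate(eps_levels):
        logK = logQ - Cv / e
        f = phi / e
        g = psi / e
        iters = 50 if level < len(eps_levels) - 1 else max_iter
        for it in range(iters):
            f = log_a - logsumexp(logK + g[None, :], axis=1)
            g = log_b - logsumexp(logK + f[:, None], axis=0)
            if level == len(eps_levels) - 1 and (it % 10 == 9 or it == iters - 1):
                logP = logK + f[:, None] + g[None, :]
                row = np.exp(logsumexp(logP, axis=1))
                col = np.exp(logsumexp(logP, axis=0))
                if max(np.max(np.abs(row - a)), np.max(np.abs(col - b))) < 0.5 * tol:
                    converged = True
                    break
        phi = f * e
        psi = g * e
        if converged:
            break
    logK = logQ - Cv / eps
    # final row update so row marginals hold exactly and mass is exactly 1
    f = log_a - logsumexp(logK + g[None, :], axis=1)
    logP = logK + f[:, None] + g[None, :]
    P = np.exp(logP)
    P[~support] = 0.0
    if not converged:
        col_violation = np.max(np.abs(P.sum(axis=0) - b))
        if col_violation >= tol:
            warnings.warn(
                f"Sinkhorn did not converge in {max_iter} iterations "
                f"(column violation {col_violation:.2e})",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            converged = True
    return TransportPlan(P, a, b, eps, converged=converged)


def _kl_projection(Q: np.ndarray, a: np.ndarray, b: np.ndarray, max_iter: int = 1000) -> np.ndarray:
    """KL-project a nonnegative matrix onto the coupling polytope (zero cost
    Sinkhorn), used to turn a raw prior into a valid initial plan."""
    plan = sinkhorn_prior(np.zeros_like(Q, dtype=float), Q, eps=1.0, a=a, b=b, max_iter=max_iter)
    return plan.values


def prior_coot(
    X: np.ndarray,
    Y: np.ndarray,
    Qs0: PriorMatrix | np.ndarray | None = None,
    Qv0: PriorMatrix | np.ndarray | None = None,
    eps: float = 0.05,
    n_outer: int = 10,
    n_inner: int = 2000,
    tol: float = 1e-6,
    rel_tol: float = 1e-6,
) -> CootResult:
    """Alternating COOT with iterative prior refreshment.

    Per outer sweep ``t``: (i) with the feature plan fixed, contract the
    feature coupling into a cell-level cost and solve prior Sinkhorn with
    prior ``Q_s^(t)``; (ii) symmetrically for the feature plan with prior
    ``Q_v^(t)``; (iii) set ``Q^(t+1)`` to the plans just obtained, so each
    sweep is a KL-proximal step around the previous iterate.

    The cell plan starts at the product coupling; the feature plan starts at
    ``Qv0`` KL-projected onto the coupling polytope.  Both contraction costs
    are rescaled by the scale fixed on the first sweep so ``eps`` keeps a
    comparable meaning throughout.  ``objective_trace`` records the transport
    cost ``<sample_cost, Ps>`` after each sweep.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n_x, d_x = X.shape
    n_y, d_y = Y.shape
    a = np.full(n_x, 1.0 / n_x)
    b = np.full(n_y, 1.0 / n_y)
    fa = np.full(d_x, 1.0 / d_x)
    fb = np.full(d_y, 1.0 / d_y)

    Qs = np.outer(a, b) if Qs0 is None else (Qs0.values if isinstance(Qs0, PriorMatrix) else np.asarray(Qs0, dtype=float))
    Qv_raw = np.outer(fa, fb) if Qv0 is None else (Qv0.values if isinstance(Qv0, PriorMatrix) else np.asarray(Qv0, dtype=float))
    PriorMatrix(Qs)  # feasibility check
    PriorMatrix(Qv_raw)

    Ps = np.outer(a, b)
    Pv = _kl_projection(Qv_raw, fa, fb)
    Qv = Pv.copy()

    scale_s: float | None = None
    scale_v: float | None = None
    trace: list[float] = []
    sample_plan = TransportPlan(Ps, a, b, eps)
    feature_plan = TransportPlan(Pv, fa, fb, eps)
    t = 0
    for t in range(1, n_outer + 1):
        Cs = coot_sample_cost(X, Y, Pv).values
        if scale_s is None:
            scale_s = max(float(Cs.max()), 1e-30)
        Cs = Cs / scale_s
        sample_plan = sinkhorn_prior(Cs, Qs, eps, a, b, max_iter=n_inner, tol=tol)
        Ps = sample_plan.values

        Cv = coot_feature_cost(X, Y, Ps).values
        if scale_v is None:
            scale_v = max(float(Cv.max()), 1e-30)
        Cv = Cv / scale_v
        feature_plan = sinkhorn_prior(Cv, Qv, eps, fa, fb, max_iter=n_inner, tol=tol)
        Pv = feature_plan.values

        # refresh priors with the plans of this sweep
        Qs, Qv = Ps, Pv

        obj = float(np.sum(coot_sample_cost(X, Y, Pv).values / scale_s * Ps))
        trace.append(obj)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(prev - obj) < rel_tol * max(abs(prev), 1e-30):
                break
    return CootResult(sample_plan, feature_plan, trace, t)


# ---------------------------------------------------------------------------
# Sinkhorn divergence (differentiable)
# ---------------------------------------------------------------------------

def _ag_sqdist(U, V):
    return (
        anp.sum(U**2, axis=1)[:, None]
        + anp.sum(V**2, axis=1)[None, :]
        - 2.0 * anp.dot(U, V.T)
    )


def _ag_ot_dual(U, V, eps: float, n_iter: int):
    """Entropic OT dual value between uniform empirical measures, by unrolled
    log-domain Sinkhorn; differentiable with respect to both point clouds."""
    n, m = U.shape[0], V.shape[0]
    C = _ag_sqdist(U, V)
    log_a = anp.full(n, -anp.log(n))
    log_b = anp.full(m, -anp.log(m))
    g = anp.zeros(m)
    for _ in range(n_iter):
        f = -eps * ag_logsumexp(log_b[None, :] + (g[None, :] - C) / eps, axis=1)
        g = -eps * ag_logsumexp(log_a[:, None] + (f[:, None] - C) / eps, axis=0)
    return anp.mean(f) + anp.mean(g)


def sinkhorn_divergence(U, V, eps: float = 0.05, n_iter: int = 50):
    """Debiased entropic OT divergence
    ``OT_eps(U, V) - 1/2 OT_eps(U, U) - 1/2 OT_eps(V, V)`` between uniform
    empirical measures on two embedding sets (squared-Euclidean ground cost).

    Accepts autograd arrays, so it can be used directly as a training loss.
    """
    if U.shape[0] == 0 or V.shape[0] == 0:
        raise ValueError("empty input")
    if U.shape[1] != V.shape[1]:
        raise ValueError("embedding dimensions differ")
    return (
        _ag_ot_dual(U, V, eps, n_iter)
        - 0.5 * _ag_ot_dual(U, U, eps, n_iter)
        - 0.5 * _ag_ot_dual(V, V, eps, n_iter)
    )
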