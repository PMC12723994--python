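"""Regularized barycentric mapping and the two-stage training loop.

Stage 2 of the framework: modality-specific VAEs and the prior-graph VGAE are
first warmed up on reconstruction alone; a tuning stage then adds

* a **barycentric pull**: each updating-modality cell is drawn toward the
  plan-weighted average of anchor-modality embeddings under a mixed plan
  ``P~ = (1 - lambda_prior) P + lambda_prior Ps`` combining the stage-1 cell
  plan ``Ps`` with a plan ``P`` recomputed from the current embeddings;
* an **anchor-based geometry regularizer**: per-cell alignment confidence is
  estimated from cross-modality proximity and within-modality entropy, a
  two-component Gaussian mixture on the confidence scores yields a Bayes
  decision threshold separating high-confidence anchor cells from the rest,
  and non-anchor cells are required to keep their distances to all anchors
  consistent between the embedding and its barycentric image — this is what
  leaves modality-unique populations unaligned;
* a **Sinkhorn divergence** between the two embedding clouds.

The anchor modality is RNA and only the ATAC embeddings receive the
barycentric pull (asymmetric update).  The embedding-derived plan and the
barycentric targets are refreshed every ``refresh_interval`` epochs of
tuning; the confidence scores and the anchor partition are computed once at
tuning start from data-space distances when those are supplied (see
:func:`train`), else from the evolving embeddings at every refresh.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist
from sklearn.mixture import GaussianMixture

import autograd.numpy as anp

from .model import (
    Adam,
    edge_weight,
    graph_elbo_terms,
    graph_encode,
    init_graph_params,
    init_omics_params,
    normalized_adjacency,
    omics_encode,
    decoder_mean,
    nb_log_likelihood,
    gaussian_kl,
    reduce_atac,
    reduce_rna,
    sample_negative_edges,
)
from .ot_core import CootResult, TransportPlan, pairwise_cost, sinkhorn_divergence, sinkhorn_prior
from .priors import FeaturePrior, build_prior_graph

__all__ = [
    "MixedPlan",
    "ConfidenceScores",
    "AnchorPartition",
    "LossWeights",
    "TrainConfig",
    "TrainResult",
    "mix_plans",
    "barycentric_project",
    "bary_loss",
    "alignment_confidence",
    "gmm_bayes_threshold",
    "partition_anchors",
    "reg_loss",
    "total_loss",
    "train",
]


@dataclass
class MixedPlan:
    """Convex combination of the embedding-derived and the stage-1 cell plan."""

    values: np.ndarray
    lambda_prior: float


@dataclass
class ConfidenceScores:
    """Per-cell alignment confidence of the updating modality."""

    s_cross: np.ndarray
    s_within: np.ndarray
    s: np.ndarray
    c: np.ndarray
    k_c: int
    m: float
    sigma_hat: float


@dataclass
class AnchorPartition:
    anchors: np.ndarray  # int indices
    non_anchors: np.ndarray
    threshold: float
    gmm_means: np.ndarray | None = None
    gmm_vars: np.ndarray | None = None
    gmm_weights: np.ndarray | None = None


@dataclass
class LossWeights:
    lambda_graph: float = 1.0
    lambda_regbary: float = 0.1
    lambda_div: float = 0.01
    lambda_reg: float = 0.1
    lambda_prior: float = 0.8
    ramp_fraction: float = 0.1

    def ramp(self, epoch: int, tuning_epochs: int) -> float:
        """Dynamically increasing multiplier for the tuning-stage alignment
        terms: linear in the epoch, reaching 1 after ``ramp_fraction`` of the
        tuning stage and continuing to grow thereafter, so the alignment
        pull strengthens as reconstruction converges."""
        horizon = max(1.0, self.ramp_fraction * tuning_epochs)
        return float(epoch / horizon)


# ---------------------------------------------------------------------------
# plan mixing and barycentric mapping
# ---------------------------------------------------------------------------

def mix_plans(P: TransportPlan | np.ndarray, Ps: TransportPlan | np.ndarray,
              lambda_prior: float) -> MixedPlan:
    """``P~ = (1 - lambda_prior) P + lambda_prior Ps`` (entrywise)."""
    if not 0.0 <= lambda_prior <= 1.0:
        raise ValueError("lambda_prior must lie in [0, 1]")
    A = P.values if isinstance(P, TransportPlan) else np.asarray(P, dtype=float)
    B = Ps.values if isinstance(Ps, TransportPlan) else np.asarray(Ps, dtype=float)
    if A.shape != B.shape:
        raise ValueError("plans must have identical shapes")
    return MixedPlan((1.0 - lambda_prior) * A + lambda_prior * B, lambda_prior)


def barycentric_project(Pmix: MixedPlan | np.ndarray, u_x: np.ndarray) -> np.ndarray:
    """Column-normalized plan times anchor-modality embeddings:
    ``u-bar_{y,j} = sum_i Pbar_ij u_{x,i}`` with ``Pbar`` the column-normalized
    mixed plan.  Every projected cell lies in the convex hull of ``u_x``."""
    V = Pmix.values if isinstance(Pmix, MixedPlan) else np.asarray(Pmix, dtype=float)
    u_x = np.asarray(u_x, dtype=float)
    col = V.sum(axis=0)
    if np.any(col <= 0):
        raise ValueError("cell receives no mass")
    return (V / col[None, :]).T @ u_x


def bary_loss(u_y, u_bar_y):
    """Mean squared residual ``1/n_y sum_j ||u_{y,j} - u-bar_{y,j}||^2``."""
    return anp.mean(anp.sum((u_y - u_bar_y) ** 2, axis=1))


# ---------------------------------------------------------------------------
# alignment confidence and anchors
# ---------------------------------------------------------------------------

def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def alignment_confidence(D_within: np.ndarray, D_cross: np.ndarray, k_c: int = 15) -> ConfidenceScores:
    """Per-cell alignment confidence for the updating modality.

    ``D_within`` is n_y x n_y over updating-modality cells; ``D_cross`` is
    n_x x n_y (anchor rows, updating columns).  Cross proximity is the mean
    distance to the ``k_c`` nearest anchor-modality cells; within uncertainty
    is the normalized entropy of a self-excluded softmax of negative
    within-modality distances (temperature = median nonzero distance).  The
    two scores are min-max rescaled, averaged, robust-z-normalized with the
    median absolute deviation and squashed by a sigmoid, so high proximity
    and low entropy give confidence near 1.
    """
    D_within = np.asarray(D_within, dtype=float)
    D_cross = np.asarray(D_cross, dtype=float)
    n_x, n_y = D_cross.shape
    if D_within.shape != (n_y, n_y):
        raise ValueError("D_within must be n_y x n_y")
    if not 1 <= k_c <= n_x:
        raise ValueError("k_c must lie in [1, n_x]")
    s_cross = np.mean(np.sort(D_cross, axis=0)[:k_c, :], axis=0)

    off = D_within[~np.eye(n_y, dtype=bool)].reshape(n_y, n_y - 1)
    nz = off[off > 0]
    tau = np.median(nz) if nz.size else 1.0
    logits = -off / max(tau, 1e-12)
    logits -= logits.max(axis=1, keepdims=True)
    pi = np.exp(logits)
    pi /= pi.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(pi > 0, pi * np.log(pi), 0.0), axis=1)
    s_within = ent / math.log(max(n_y - 1, 2))

    s = 0.5 * (_minmax(s_cross) + _minmax(s_within))
    m = float(np.median(s))
    sigma = max(float(np.median(np.abs(s - m))), 1e-8)
    c = 1.0 / (1.0 + np.exp((s - m) / sigma))
    return ConfidenceScores(s_cross, s_within, s, c, k_c, m, sigma)


def gmm_bayes_threshold(means, variances, weights) -> float:
    """Bayes decision point of a two-component 1-D Gaussian mixture: the root
    of ``w1 N(x|m1,v1) = w2 N(x|m2,v2)`` between the two means (fallback:
    midpoint of the means when no root lies between them)."""
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(means)
    (m1, m2) = means[order]
    (v1, v2) = variances[order]
    (w1, w2) = weights[order]

    def diff(x):
        l1 = np.log(w1) - 0.5 * np.log(2 * np.pi * v1) - (x - m1) ** 2 / (2 * v1)
        l2 = np.log(w2) - 0.5 * np.log(2 * np.pi * v2) - (x - m2) ** 2 / (2 * v2)
        return l1 - l2

    if m2 - m1 < 1e-12:
        return float(0.5 * (m1 + m2))
    a, b = m1 + 1e-12, m2 - 1e-12
    if diff(a) * diff(b) > 0:
        return float(0.5 * (m1 + m2))
    return float(brentq(diff, a, b, xtol=1e-12))


def partition_anchors(c: np.ndarray, seed: int = 0) -> AnchorPartition:
    """Two-component GMM on the confidence scores; cells at or above the Bayes
    decision point are anchors.  Degenerate inputs (all values equal) make
    every cell an anchor, with a warning."""
    c = np.asarray(c, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 cells to partition")
    if np.ptp(c) < 1e-12:
        warnings.warn("confidence scores are constant; all cells anchored",
                      RuntimeWarning, stacklevel=2)
        return AnchorPartition(np.arange(c.size), np.array([], dtype=int),
                               float(c[0]))
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         random_state=seed, init_params="kmeans", n_init=1)
    gm.fit(c[:, None])
    means = gm.means_.ravel()
    variances = gm.covariances_.ravel()
    weights = gm.weights_.ravel()
    thr = gmm_bayes_threshold(means, variances, weights)
    anchors = np.nonzero(c >= thr)[0]
    non_anchors = np.nonzero(c < thr)[0]
    if anchors.size == 0:  # numerical edge: threshold above max
        anchors, non_anchors = non_anchors, anchors
    return AnchorPartition(anchors, non_anchors, thr, means, variances, weights)


def reg_loss(u_y, u_bar_y, part: AnchorPartition):
    """Anchor-geometry regularizer: mean over (non-anchor, anchor) pairs of the
    squared difference between embedding distances and projected distances."""
    if part.non_anchors.size == 0 or part.anchors.size == 0:
        warnings.warn("empty anchor or non-anchor set; regularizer is 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    nu = u_y[part.non_anchors]
    au = u_y[part.anchors]
    nb = u_bar_y[part.non_anchors]
    ab = u_bar_y[part.anchors]
    D_u = anp.sqrt(anp.maximum(
        anp.sum(nu**2, 1)[:, None] + anp.sum(au**2, 1)[None, :]
        - 2 * anp.dot(nu, au.T), 1e-30))
    D_b = anp.sqrt(anp.maximum(
        anp.sum(nb**2, 1)[:, None] + anp.sum(ab**2, 1)[None, :]
        - 2 * anp.dot(nb, ab.T), 1e-30))
    return anp.mean((D_u - D_b) ** 2)


def total_loss(components: dict, weights: LossWeights, epoch: int,
               tuning_epochs: int, tuning: bool = True):
    """Weighted training objective.  ``components`` holds the loss terms
    (``omics``, ``graph``, ``bary``, ``reg``, ``div``); during tuning the
    regularized-barycentric and divergence terms are ramped in linearly."""
    ramp = weights.ramp(epoch, tuning_epochs) if tuning else 0.0
    L = components["omics"] + weights.lambda_graph * components["graph"]
    if tuning:
        regbary = components["bary"] + weights.lambda_reg * components["reg"]
        L = L + ramp * (weights.lambda_regbary * regbary
                        + weights.lambda_div * components["div"])
    return L


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    latent_dim: int = 32
    hidden: int = 256
    graph_hidden: int = 64
    graph_embed: int = 64
    warmup_epochs: int = 1000
    tuning_epochs: int = 3000
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    eps: float = 0.05
    weights: LossWeights = field(default_factory=LossWeights)
    k_c: int = 15
    refresh_interval: int = 10
    n_neg: int = 1
    div_iters: int = 10
    reduced_dim: int = 100
    batch_size: int = 64
    # the anchor modality trains through the ramp-in phase of tuning, then is
    # frozen so the barycentric targets and the anchor frame stay stable
    anchor_freeze_fraction: float = 0.1
    seed: int = 0


@dataclass
class TrainResult:
    u_rna: np.ndarray
    u_atac: np.ndarray
    v: np.ndarray
    edge_weights: dict
    anchors: AnchorPartition | None
    history: list[dict]
    coot: CootResult
    gene_index: list[str]
    peak_index: list[str]
    params: dict | None = None


def _embedding_plan(u_x: np.ndarray, u_y: np.ndarray, eps: float) -> np.ndarray:
    C = pairwise_cost(u_x, u_y)
    return sinkhorn_prior(C, np.ones(C.values.shape), eps=eps).values


class _FastEdgeWeights:
    """Edge weights precomputed in ``PriorGraph.edge_array`` order."""

    def __init__(self, pg, vector: np.ndarray):
        self.pg = pg
        self.vector = vector


def train(
    rna_counts: np.ndarray,
    atac_counts: np.ndarray,
    fp: FeaturePrior,
    coot: CootResult,
    config: TrainConfig | None = None,
    reduced_rna: np.ndarray | None = None,
    reduced_atac: np.ndarray | None = None,
    confidence_dists: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainResult:
    """Two-stage training of the omics VAEs and the VGAE.

    Warm-up optimizes reconstruction only; tuning adds the ramped
    regularized-barycentric and Sinkhorn-divergence terms.  RNA is the anchor
    modality: the barycentric image is built from *detached* RNA embeddings,
    so the pull acts on the ATAC encoder alone.  All randomness derives from
    ``config.seed``; two runs with identical inputs produce identical
    histories.

    ``confidence_dists`` optionally supplies data-space distance matrices
    (D_within over updating cells, D_cross anchor x updating) measured in a
    space where cross-modality geometry is meaningful *before* alignment —
    e.g. the shared gene-activity space.  The confidence scores and anchor
    partition are then computed once at tuning start and held fixed.  Without
    it, confidence falls back to the evolving embedding space, which is
    circular: cells that were already over-aligned look maximally confident.
    """
    cfg = config or TrainConfig()
    w = cfg.weights
    rng = np.random.default_rng(cfg.seed)

    rna_counts = np.asarray(rna_counts)
    atac_counts = np.asarray(atac_counts)
    n_x, n_genes = rna_counts.shape
    n_y, n_peaks = atac_counts.shape
    if reduced_rna is None:
        reduced_rna = reduce_rna(rna_counts, cfg.reduced_dim)
    if reduced_atac is None:
        reduced_atac = reduce_atac(atac_counts, cfg.reduced_dim)

    pg = build_prior_graph(fp)
    A_norm = normalized_adjacency(pg.adjacency)
    ew = edge_weight(coot.feature_plan, fp)
    Ps = coot.sample_plan.values
    n_nodes = len(pg.nodes)

    state = {
        "rna": init_omics_params(n_genes, reduced_rna.shape[1], cfg.latent_dim,
                                 cfg.hidden, rng),
        "atac": init_omics_params(n_peaks, reduced_atac.shape[1], cfg.latent_dim,
                                  cfg.hidden, rng),
        "graph": init_graph_params(n_nodes, cfg.latent_dim, cfg.graph_embed,
                                   cfg.graph_hidden, rng),
    }
    opt = Adam(lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    lib_r = np.maximum(rna_counts.sum(axis=1).astype(float), 1.0)
    lib_a = np.maximum(atac_counts.sum(axis=1).astype(float), 1.0)
    counts_r = rna_counts.astype(float)
    counts_a = atac_counts.astype(float)
    n_edges = pg.graph.number_of_edges()

    # static per-edge weight vector, aligned with pg.edge_array() order
    edges = pg.edge_array()
    w_vec = np.array([
        ew[(fp.gene_index[i], fp.peak_index[j])] for i, j in edges
    ]) if n_edges else np.zeros(0)
    ew_fast = _FastEdgeWeights(pg, w_vec)

    # context refreshed every cfg.refresh_interval tuning epochs: the column-
    # normalized mixed plan, the barycentric targets, an updating-modality
    # snapshot for anchor distances, the anchor partition, and the per-cell
    # confidence used to weight the barycentric pull
    ctx: dict = {"ubar": None, "part": None, "u_y_snap": None, "conf_c": None}

    def make_loss(epoch: int, tuning: bool, bx, by, noises, neg_edges):
        nbx, nby = len(bx), len(by)

        def loss(s):
            mu_r, lv_r = omics_encode(s["rna"], reduced_rna[bx])
            mu_a, lv_a = omics_encode(s["atac"], reduced_atac[by])
            vmu, vlv = graph_encode(s["graph"], A_norm)
            u_r = mu_r + anp.exp(0.5 * lv_r) * noises["rna"]
            u_a = mu_a + anp.exp(0.5 * lv_a) * noises["atac"]
            v = vmu + anp.exp(0.5 * vlv) * noises["graph"]
            v_g, v_p = v[:n_genes], v[n_genes:]

            rec_r = nb_log_likelihood(
                counts_r[bx], decoder_mean(u_r, v_g, s["rna"]["dec_bias"], lib_r[bx]),
                anp.exp(s["rna"]["dec_log_theta"]))
            rec_a = nb_log_likelihood(
                counts_a[by], decoder_mean(u_a, v_p, s["atac"]["dec_bias"], lib_a[by]),
                anp.exp(s["atac"]["dec_log_theta"]))
            # per-entry normalization keeps the reconstruction terms on a
            # scale comparable to the O(1) alignment losses, so the default
            # loss weights are meaningful
            omics = -(rec_r - gaussian_kl(mu_r, lv_r)) / (nbx * n_genes) \
                - (rec_a - gaussian_kl(mu_a, lv_a)) / (nby * n_peaks)

            pos, neg, kl = graph_elbo_terms(pg, ew_fast, s["graph"], A_norm,
                                            noises["graph"], neg_edges)
            graph = -(pos + neg - kl) / max(n_edges, 1)

            comps = {"omics": omics, "graph": graph,
                     "bary": 0.0, "reg": 0.0, "div": 0.0}
            if tuning:
                # the alignment terms are population-level objectives, so they
                # are evaluated on the full embedding clouds even though the
                # reconstruction is minibatched
                mu_r_full, _ = omics_encode(s["rna"], reduced_rna)
                mu_a_full, _ = omics_encode(s["atac"], reduced_atac)
                # anchor machinery (active when lambda_reg > 0):
                # confidence-weighted pull — low-confidence (likely
                # modality-unique) cells are barely pulled toward their
                # barycentric image; the anchor-geometry regularizer
                # positions them relative to the anchors instead.  With
                # lambda_reg = 0 the mapping degrades to the unregularized,
                # uniformly weighted barycentric pull.
                if w.lambda_reg > 0:
                    resid = anp.sum((mu_a_full - ctx["ubar"]) ** 2, axis=1)
                    comps["bary"] = anp.mean(ctx["conf_c"] * resid)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        comps["reg"] = reg_loss(mu_a_full, ctx["ubar"], ctx["part"])
                else:
                    comps["bary"] = bary_loss(mu_a_full, ctx["ubar"])
                comps["div"] = sinkhorn_divergence(mu_r_full, mu_a_full,
                                                   eps=cfg.eps,
                                                   n_iter=cfg.div_iters)
            return total_loss(comps, w, epoch, cfg.tuning_epochs, tuning), comps
        return loss

    history: list[dict] = []
    bs = max(1, cfg.batch_size)
    n_steps = max(-(-n_x // bs), -(-n_y // bs))

    def run_stage(n_epochs: int, tuning: bool, stage_name: str):
        nonlocal state
        for epoch in range(n_epochs):
            ep_rng = np.random.default_rng(
                (cfg.seed * 1_000_003 + (1 if tuning else 0) * 500_000 + epoch)
                % (2**31 - 1))
            if tuning and epoch % cfg.refresh_interval == 0:
                _refresh(state)
            perm_x = ep_rng.permutation(n_x)
            perm_y = ep_rng.permutation(n_y)
            ep_comps = {k: 0.0 for k in ("total", "omics", "graph", "bary", "reg", "div")}
            for step in range(n_steps):
                bx = perm_x[step::n_steps]
                by = perm_y[step::n_steps]
                noises = {
                    "rna": ep_rng.standard_normal((len(bx), cfg.latent_dim)),
                    "atac": ep_rng.standard_normal((len(by), cfg.latent_dim)),
                    "graph": ep_rng.standard_normal((n_nodes, cfg.latent_dim)),
                }
                neg_edges = sample_negative_edges(
                    pg, cfg.n_neg * n_edges, int(ep_rng.integers(2**31 - 1)))
                lossfun = make_loss(epoch, tuning, bx, by, noises, neg_edges)
                (val, comps), grads = _value_and_grad(lossfun, state)
                if not np.isfinite(val):
                    raise FloatingPointError(
                        f"non-finite loss at {stage_name} epoch {epoch}: {comps}")
                if tuning and epoch >= cfg.anchor_freeze_fraction * cfg.tuning_epochs:
                    grads["rna"] = {k: np.zeros_like(v)
                                    for k, v in grads["rna"].items()}
                state = opt.step(state, grads)
                ep_comps["total"] += val / n_steps
                for k in ("omics", "graph", "bary", "reg", "div"):
                    ep_comps[k] += comps[k] / n_steps
            part = ctx["part"]
            history.append({
                "stage": stage_name, "epoch": epoch, **ep_comps,
                "ramp": w.ramp(epoch, cfg.tuning_epochs) if tuning else 0.0,
                "n_anchors": int(part.anchors.size) if part else 0,
                "n_non_anchors": int(part.non_anchors.size) if part else 0,
            })

    def _refresh(s):
        """Recompute the embedding plan, mixed plan and barycentric targets
        from the current full embeddings; the confidence scores and anchor
        partition come from the fixed data-space distances when available
        (computed once), else from the evolving embedding space."""
        mu_r, _ = omics_encode(s["rna"], reduced_rna)
        mu_a, _ = omics_encode(s["atac"], reduced_atac)
        mu_r, mu_a = np.asarray(mu_r), np.asarray(mu_a)
        P = _embedding_plan(mu_r, mu_a, cfg.eps)
        mixed = mix_plans(P, Ps, w.lambda_prior)
        ctx["ubar"] = barycentric_project(mixed, mu_r)
        ctx["u_y_snap"] = mu_a
        if confidence_dists is not None:
            if ctx["part"] is None:
                D_within, D_cross = confidence_dists
                conf = alignment_confidence(D_within, D_cross,
                                            k_c=min(cfg.k_c, D_cross.shape[0]))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    ctx["part"] = partition_anchors(conf.c, seed=cfg.seed)
                # mean-normalized so the average pull strength is unchanged
                ctx["conf_c"] = conf.c / max(float(conf.c.mean()), 1e-8)
            return
        conf = alignment_confidence(cdist(mu_a, mu_a), cdist(mu_r, mu_a),
                                    k_c=min(cfg.k_c, n_x))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ctx["part"] = partition_anchors(conf.c, seed=cfg.seed)
        ctx["conf_c"] = conf.c / max(float(conf.c.mean()), 1e-8)

    run_stage(cfg.warmup_epochs, tuning=False, stage_name="warmup")
    run_stage(cfg.tuning_epochs, tuning=True, stage_name="tuning")

    mu_r, _ = omics_encode(state["rna"], reduced_rna)
    mu_a, _ = omics_encode(state["atac"], reduced_atac)
    vmu, _ = graph_encode(state["graph"], A_norm)
    return TrainResult(
        u_rna=np.asarray(mu_r), u_atac=np.asarray(mu_a), v=np.asarray(vmu),
        edge_weights=ew, anchors=ctx["part"], history=history, coot=coot,
        gene_index=list(fp.gene_index), peak_index=list(fp.peak_index),
        params=state,
    )


def _unbox(x):
    while hasattr(x, "_value"):
        x = x._value
    return x


def _value_and_grad(lossfun, state):
    """Single-pass value+gradient of a loss returning (value, aux)."""
    from autograd import value_and_grad as vag

    aux = {}

    def wrapped(s):
        val, comps = lossfun(s)
        aux["comps"] = comps
        return val

    val, g = vag(wrapped)(state)
    comps = {k: float(np.asarray(_unbox(v))) for k, v in aux["comps"].items()}
    return (float(val), comps), g
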