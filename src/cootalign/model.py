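"""Variational autoencoders over cells and the prior graph.

Cells of each modality are encoded from a 100-dimensional reduced input
(PCA for RNA, TF-IDF + SVD for ATAC) into a shared-size latent space by a
two-layer (256-256, LeakyReLU) Gaussian encoder.  The decoder reconstructs
the *raw* count matrix through a negative-binomial likelihood whose mean is
the per-cell library size times softplus inner products between cell and
feature embeddings (row-normalized), with a learned per-feature dispersion.

Feature embeddings come from a variational graph autoencoder on the bipartite
gene-peak prior graph: a learned node-lookup table refined by a two-layer
graph convolution, with an inner-product Bernoulli edge decoder.  The
positive-edge reconstruction term is weighted per edge by the feature-level
transport plan (``edge_weight``), which down-weights prior edges that receive
little OT mass — the denoising step that distinguishes this model from a
plain graph autoencoder.

Everything is written over ``autograd.numpy``: each ELBO is a scalar
function of a parameter dictionary, differentiable end to end.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

import autograd.numpy as anp
from autograd.scipy.special import gammaln

from .ot_core import TransportPlan
from .priors import FeaturePrior, PriorGraph, lognorm

__all__ = [
    "edge_weight",
    "init_graph_params",
    "init_omics_params",
    "graph_encode",
    "omics_encode",
    "graph_elbo",
    "graph_elbo_terms",
    "omics_elbo",
    "sample_negative_edges",
    "normalized_adjacency",
    "reduce_rna",
    "reduce_atac",
    "gaussian_kl",
    "Adam",
]

LATENT_DIM = 32
HIDDEN = 256
LEAK = 0.01


# ---------------------------------------------------------------------------
# transport-plan edge reweighting
# ---------------------------------------------------------------------------

def edge_weight(Pv: TransportPlan | np.ndarray, Qv0: FeaturePrior) -> dict[tuple[str, str], float]:
    """Per-edge reconstruction weights from the feature transport plan.

    For each prior edge (i, j): ``w = min(1, Pv(i,j) / mean_{k in S_i} Pv(i,k))``
    where ``S_i`` are the peaks linked to gene i in the binary prior.  An edge
    at or above its gene's average OT mass keeps full weight 1; edges below
    average are down-weighted proportionally.  A zero mean yields w = 0.
    """
    V = Pv.values if isinstance(Pv, TransportPlan) else np.asarray(Pv, dtype=float)
    if V.shape != Qv0.matrix.shape:
        raise ValueError(
            f"plan shape {V.shape} does not match prior shape {Qv0.matrix.shape}"
        )
    weights: dict[tuple[str, str], float] = {}
    for i in range(Qv0.matrix.shape[0]):
        support = np.nonzero(Qv0.matrix[i])[0]
        if support.size == 0:
            continue
        mean_mass = V[i, support].mean()
        for j in support:
            if mean_mass <= 0:
                w = 0.0
            else:
                w = min(1.0, float(V[i, j] / mean_mass))
            weights[(Qv0.gene_index[i], Qv0.peak_index[j])] = w
    return weights


# ---------------------------------------------------------------------------
# parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-s, s, size=(n_in, n_out))


def init_graph_params(n_nodes: int, latent_dim: int = LATENT_DIM,
                      embed_dim: int = 64, hidden: int = 64,
                      rng: np.random.Generator | None = None) -> dict:
    """VGAE parameters: learned node-lookup embeddings (indexed by node
    position) refined by a two-layer graph convolution into Gaussian latents."""
    rng = rng or np.random.default_rng(0)
    return {
        "embed": rng.normal(scale=0.1, size=(n_nodes, embed_dim)),
        "gcn1": _glorot(rng, embed_dim, hidden),
        "gcn2": _glorot(rng, hidden, hidden),
        "w_mu": _glorot(rng, hidden, latent_dim),
        "w_logvar": _glorot(rng, hidden, latent_dim),
    }


def init_omics_params(n_features: int, input_dim: int,
                      latent_dim: int = LATENT_DIM, hidden: int = HIDDEN,
                      rng: np.random.Generator | None = None) -> dict:
    """Omics VAE parameters for one modality: two-layer encoder and the
    negative-binomial decoder's per-feature bias and log-dispersion."""
    rng = rng or np.random.default_rng(0)
    return {
        "enc_w1": _glorot(rng, input_dim, hidden),
        "enc_b1": np.zeros(hidden),
        "enc_w2": _glorot(rng, hidden, hidden),
        "enc_b2": np.zeros(hidden),
        "w_mu": _glorot(rng, hidden, latent_dim),
        "w_logvar": _glorot(rng, hidden, latent_dim),
        "dec_bias": np.zeros(n_features),
        "dec_log_theta": np.zeros(n_features),
    }


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _leaky_relu(x):
    return anp.where(x > 0, x, LEAK * x)


def _softplus(x):
    return anp.logaddexp(0.0, x)


def gaussian_kl(mu, logvar):
    """KL(N(mu, diag e^logvar) || N(0, I)), summed over all entries."""
    return 0.5 * anp.sum(anp.exp(logvar) + mu**2 - 1.0 - logvar)


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN propagation matrix D^{-1/2} (A + I) D^{-1/2}."""
    A_hat = np.asarray(A, dtype=float) + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


def graph_encode(params: Mapping, A_norm: np.ndarray):
    """Node latent mean and log-variance from the lookup table refined by two
    graph-convolution layers."""
    h = _leaky_relu(A_norm @ (params["embed"] @ params["gcn1"]))
    h = _leaky_relu(A_norm @ (h @ params["gcn2"]))
    return h @ params["w_mu"], h @ params["w_logvar"]


def omics_encode(params: Mapping, reduced: np.ndarray):
    """Cell latent mean and log-variance from the reduced input."""
    h = _leaky_relu(reduced @ params["enc_w1"] + params["enc_b1"])
    h = _leaky_relu(h @ params["enc_w2"] + params["enc_b2"])
    return h @ params["w_mu"], h @ params["w_logvar"]


def sample_negative_edges(pg: PriorGraph, n_neg: int, rng_seed: int) -> np.ndarray:
    """Uniformly sample ``n_neg`` node pairs that are not edges (and not
    self-pairs) of the prior graph, as (i, j) positions into node order."""
    n_g = len(pg.gene_index)
    n = n_g + len(pg.peak_index)
    pos = {(int(i), int(n_g + j)) for i, j in pg.edge_array()}
    rng = np.random.default_rng(rng_seed)
    out: list[tuple[int, int]] = []
    while len(out) < n_neg:
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in pos:
            continue
        out.append((i, j))
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# ELBOs
# ---------------------------------------------------------------------------

def _log_sigmoid(x):
    return -_softplus(-x)


def graph_elbo_terms(
    pg: PriorGraph,
    w: Mapping[tuple[str, str], float],
    params: Mapping,
    A_norm: np.ndarray,
    noise: np.ndarray,
    neg_edges: np.ndarray,
):
    """(positive term, negative term, KL) of the weighted VGAE ELBO, given the
    reparameterization noise and the sampled negative edges."""
    if pg.graph.number_of_edges() == 0:
        raise ValueError("edgeless prior graph")
    mu, logvar = graph_encode(params, A_norm)
    v = mu + anp.exp(0.5 * logvar) * noise
    n_g = len(pg.gene_index)
    edges = pg.edge_array()
    gi, pj = edges[:, 0], n_g + edges[:, 1]
    if hasattr(w, "vector"):  # precomputed weights in edge_array order
        w_vec = w.vector
    else:
        w_vec = np.array(
            [w[(pg.gene_index[i], pg.peak_index[j - n_g])] for i, j in zip(gi, pj)]
        )
    pos_logits = anp.sum(v[gi] * v[pj], axis=1)
    pos = anp.sum(w_vec * _log_sigmoid(pos_logits))
    neg_logits = anp.sum(v[neg_edges[:, 0]] * v[neg_edges[:, 1]], axis=1)
    neg = anp.sum(_log_sigmoid(-neg_logits))
    return pos, neg, gaussian_kl(mu, logvar)


def graph_elbo(
    pg: PriorGraph,
    w: Mapping[tuple[str, str], float],
    params: Mapping,
    n_neg: int = 1,
    rng_seed: int = 0,
    A_norm: np.ndarray | None = None,
    noise: np.ndarray | None = None,
):
    """Weighted VGAE evidence lower bound (higher is better): transport-plan
    weighted Bernoulli log-likelihood on prior edges, unweighted on ``n_neg``
    sampled negatives per positive, minus the standard-normal KL."""
    if A_norm is None:
        A_norm = normalized_adjacency(pg.adjacency)
    n_edges = pg.graph.number_of_edges()
    if n_edges == 0:
        raise ValueError("edgeless prior graph")
    rng = np.random.default_rng(rng_seed)
    if noise is None:
        noise = rng.standard_normal((A_norm.shape[0], params["w_mu"].shape[1]))
    neg_edges = sample_negative_edges(pg, n_neg * n_edges, rng_seed + 1)
    pos, neg, kl = graph_elbo_terms(pg, w, params, A_norm, noise, neg_edges)
    return pos + neg - kl


def nb_log_likelihood(counts, mean, theta):
    """Negative-binomial log-likelihood, summed; ``theta`` is the per-feature
    inverse-dispersion (variance = mean + mean^2 / theta)."""
    mean = anp.maximum(mean, 1e-10)
    return anp.sum(
        gammaln(counts + theta)
        - gammaln(theta)
        - gammaln(counts + 1.0)
        + theta * anp.log(theta / (theta + mean))
        + counts * anp.log(mean / (theta + mean))
    )


def decoder_mean(u, v, dec_bias, library):
    """NB mean: library size times row-normalized softplus inner products."""
    rho = _softplus(anp.dot(u, v.T) + dec_bias)
    rho = rho / anp.sum(rho, axis=1, keepdims=True)
    return library[:, None] * rho


def omics_elbo(
    counts: np.ndarray,
    reduced: np.ndarray,
    params: Mapping,
    v,
    noise: np.ndarray | None = None,
    rng_seed: int = 0,
):
    """Omics VAE evidence lower bound (higher is better): one-sample
    reparameterized NB reconstruction of the raw counts from cell and feature
    embeddings, minus the standard-normal KL on the cell latents.

    ``v`` holds this modality's feature embeddings (rows aligned to columns
    of ``counts``)."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    mu, logvar = omics_encode(params, reduced)
    if noise is None:
        noise = np.random.default_rng(rng_seed).standard_normal(mu.shape)
    u = mu + anp.exp(0.5 * logvar) * noise
    library = counts.sum(axis=1).astype(float)
    library = np.maximum(library, 1.0)
    mean = decoder_mean(u, v, params["dec_bias"], library)
    recon = nb_log_likelihood(counts.astype(float), mean, anp.exp(params["dec_log_theta"]))
    return recon - gaussian_kl(mu, logvar)


# ---------------------------------------------------------------------------
# input reduction
# ---------------------------------------------------------------------------

def reduce_rna(counts: np.ndarray, n_components: int = 100, random_state: int = 0) -> np.ndarray:
    """Log-normalized PCA representation of RNA counts, z-scored per component."""
    from sklearn.decomposition import PCA

    x = lognorm(counts)
    k = min(n_components, x.shape[1], x.shape[0] - 1)
    z = PCA(n_components=k, random_state=random_state).fit_transform(x)
    return _standardize(z)


def reduce_atac(counts: np.ndarray, n_components: int = 100, random_state: int = 0) -> np.ndarray:
    """LSI representation of ATAC counts: TF-IDF then truncated SVD, z-scored
    per component."""
    from sklearn.decomposition import TruncatedSVD

    counts = np.asarray(counts, dtype=float)
    tf = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1.0)
    idf = np.log1p(counts.shape[0] / np.maximum((counts > 0).sum(axis=0), 1.0))
    x = tf * idf
    k = min(n_components, x.shape[1] - 1, x.shape[0] - 1)
    z = TruncatedSVD(n_components=k, random_state=random_state).fit_transform(x)
    return _standardize(z)


def _standardize(z: np.ndarray) -> np.ndarray:
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    return (z - z.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled weight decay over (nested) dicts of arrays."""

    def __init__(self, lr: float = 1e-3, weight_decay: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        return self._step(params, grads, self.m, self.v, ())

    def _step(self, params, grads, m, v, path):
        out = {}
        for key, val in params.items():
            if isinstance(val, dict):
                out[key] = self._step(val, grads[key], m.setdefault(key, {}),
                                      v.setdefault(key, {}), path + (key,))
            else:
                g = grads[key]
                mk = m.setdefault(key, np.zeros_like(val))
                vk = v.setdefault(key, np.zeros_like(val))
                mk[:] = self.b1 * mk + (1 - self.b1) * g
                vk[:] = self.b2 * vk + (1 - self.b2) * g**2
                m_hat = mk / (1 - self.b1**self.t)
                v_hat = vk / (1 - self.b2**self.t)
                out[key] = val - self.lr * (
                    m_hat / (np.sqrt(v_hat) + self.eps) + self.wd * val
                )
        return out
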