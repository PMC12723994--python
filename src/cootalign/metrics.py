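"""Evaluation metrics for diagonal integration.

Alignment accuracy (requires ground-truth pairing or labels):

* :func:`foscttm` — fraction of opposite-modality cells strictly closer than
  the true match, averaged over cells and both directions; 0 is perfect.
* :func:`ctm` — fraction of cells whose nearest cross-modality neighbour
  shares their cell type, averaged over both directions.

Embedding accuracy (joint embedding + labels):

* :func:`ami` — adjusted mutual information between labels and communities
  found on a shared-nearest-neighbour graph, with the Leiden resolution tuned
  so the community count matches the label count.
* :func:`batch_asw` — modality-mixing silhouette score in the scib
  convention: per cell type, mean of ``1 - |silhouette|`` with modality as the
  grouping, averaged over types.
* :func:`graph_connectivity` — per cell type, largest connected component of
  the type-restricted kNN graph over the type size, averaged over types.

Imbalance-aware geometric distortion:

* :func:`within_distortion` / :func:`cross_distortion` — one minus the
  Pearson correlation between flattened unique-vs-shared distance matrices of
  an imbalanced run and of a perfectly paired reference run, averaged over
  modalities (resp. directions).
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_mutual_info_score, silhouette_samples
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "PairedEmbeddings",
    "DistortionInput",
    "foscttm",
    "ctm",
    "ami",
    "batch_asw",
    "graph_connectivity",
    "within_distortion",
    "cross_distortion",
    "evaluate_all",
]


@dataclass
class PairedEmbeddings:
    """Positionally paired embeddings: row i of each matrix is the same cell."""

    u_x: np.ndarray
    u_y: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_x.shape != self.u_y.shape:
            raise ValueError("paired embeddings must have identical shapes")


@dataclass
class DistortionInput:
    """Unique/shared embedding subsets under an imbalanced run and under the
    perfectly paired reference run (same index sets in both runs)."""

    x_uniq: np.ndarray
    x_share: np.ndarray
    y_uniq: np.ndarray
    y_share: np.ndarray
    ref_x_uniq: np.ndarray
    ref_x_share: np.ndarray
    ref_y_uniq: np.ndarray
    ref_y_share: np.ndarray


def foscttm(pe: PairedEmbeddings) -> float:
    """Fraction of samples closer than the true match, in [0, 1].

    Per cell, the fraction of the *other* opposite-modality cells that lie
    strictly closer than the true match; averaged over all cells and both
    directions.  0 = every cell is nearest to its own match."""
    n = pe.u_x.shape[0]
    if n < 2:
        return 0.0
    D = cdist(pe.u_x, pe.u_y)
    d_true = np.diag(D)
    fwd = np.mean((D < d_true[:, None]).sum(axis=1) / (n - 1))
    rev = np.mean((D < d_true[None, :]).sum(axis=0) / (n - 1))
    return float(0.5 * (fwd + rev))


def ctm(u_x: np.ndarray, u_y: np.ndarray, labels_x: np.ndarray, labels_y: np.ndarray) -> float:
    """Cell-type match: nearest cross-modality neighbour shares the label.

    Ties in distance resolve to the lowest index (argmin convention)."""
    labels_x = np.asarray(labels_x)
    labels_y = np.asarray(labels_y)
    D = cdist(np.asarray(u_x, float), np.asarray(u_y, float))
    fwd = np.mean(labels_y[D.argmin(axis=1)] == labels_x)
    rev = np.mean(labels_x[D.argmin(axis=0)] == labels_y)
    return float(0.5 * (fwd + rev))


def _snn_leiden(embeddings: np.ndarray, n_clusters: int, k: int = 15,
                seed: int = 0, max_iter: int = 20) -> np.ndarray:
    """Leiden communities on a shared-nearest-neighbour graph, bisecting the
    resolution until the community count matches ``n_clusters`` (or the search
    exhausts)."""
    n = embeddings.shape[0]
    k = min(k, n - 1)
    knn = kneighbors_graph(embeddings, k, mode="connectivity")
    # SNN weights: number of shared neighbours, normalized
    snn = (knn @ knn.T).tocoo()
    snn.data = snn.data / k
    mask = snn.data > 1.0 / 15.0
    g = ig.Graph(
        n=n,
        edges=list(zip(snn.row[mask], snn.col[mask])),
        edge_attrs={"weight": snn.data[mask].tolist()},
    ).simplify(combine_edges="max")
    lo, hi = 1e-3, 10.0
    best = None
    for _ in range(max_iter):
        res = float(np.sqrt(lo * hi))
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights="weight", resolution_parameter=res, seed=seed,
        )
        labels = np.asarray(part.membership)
        n_found = labels.max() + 1
        if best is None or abs(n_found - n_clusters) < best[0]:
            best = (abs(n_found - n_clusters), labels)
        if n_found == n_clusters:
            return labels
        if n_found < n_clusters:
            lo = res
        else:
            hi = res
    return best[1]


def ami(embeddings: np.ndarray, labels: np.ndarray, k: int = 15, seed: int = 0) -> float:
    """AMI between ground-truth labels and SNN-graph Leiden communities."""
    labels = np.asarray(labels)
    clusters = _snn_leiden(np.asarray(embeddings, float),
                           n_clusters=len(np.unique(labels)), k=k, seed=seed)
    return float(adjusted_mutual_info_score(labels, clusters))


def batch_asw(embeddings: np.ndarray, modality_labels: np.ndarray,
              cell_type_labels: np.ndarray) -> float:
    """Modality-mixing score in [0, 1]: per cell type, mean of
    ``1 - |silhouette|`` with modality as the grouping; averaged over the
    cell types that contain both modalities."""
    embeddings = np.asarray(embeddings, float)
    modality_labels = np.asarray(modality_labels)
    cell_type_labels = np.asarray(cell_type_labels)
    scores = []
    for t in np.unique(cell_type_labels):
        idx = cell_type_labels == t
        mods = modality_labels[idx]
        if len(np.unique(mods)) < 2 or idx.sum() < 3:
            continue
        sil = silhouette_samples(embeddings[idx], mods)
        scores.append(float(np.mean(1.0 - np.abs(sil))))
    if not scores:
        raise ValueError("no cell type contains both modalities")
    return float(np.mean(scores))


def graph_connectivity(embeddings: np.ndarray, cell_type_labels: np.ndarray,
                       k: int = 15) -> float:
    """Average over cell types of |largest connected component| / |type| in
    the type-restricted kNN graph."""
    embeddings = np.asarray(embeddings, float)
    cell_type_labels = np.asarray(cell_type_labels)
    scores = []
    for t in np.unique(cell_type_labels):
        idx = np.nonzero(cell_type_labels == t)[0]
        if idx.size == 1:
            scores.append(1.0)
            continue
        kk = min(k, idx.size - 1)
        g = kneighbors_graph(embeddings[idx], kk, mode="connectivity")
        n_comp, comp = connected_components(g, directed=False)
        largest = np.bincount(comp).max()
        scores.append(largest / idx.size)
    return float(np.mean(scores))


def _flat_corr_delta(A: np.ndarray, B: np.ndarray) -> float:
    a, b = np.ravel(A), np.ravel(B)
    if a.size < 2:
        raise ValueError("need at least 2 distance entries for a correlation")
    if np.array_equal(a, b):
        return 0.0  # rho = 1 exactly, immune to floating-point round-off
    return float(1.0 - pearsonr(a, b).statistic)


def within_distortion(di: DistortionInput) -> float:
    """Within-modality distortion: 1 - Pearson correlation between the
    flattened unique-vs-shared distance matrices of the imbalanced and the
    reference run, averaged over the two modalities.  0 = geometry preserved."""
    dx = _flat_corr_delta(cdist(di.x_uniq, di.x_share),
                          cdist(di.ref_x_uniq, di.ref_x_share))
    dy = _flat_corr_delta(cdist(di.y_uniq, di.y_share),
                          cdist(di.ref_y_uniq, di.ref_y_share))
    return 0.5 * (dx + dy)


def cross_distortion(di: DistortionInput) -> float:
    """Cross-modality distortion: as within-modality distortion, but with
    distances taken between one modality's unique subset and the *other*
    modality's shared subset, both directions averaged."""
    dxy = _flat_corr_delta(cdist(di.x_uniq, di.y_share),
                           cdist(di.ref_x_uniq, di.ref_y_share))
    dyx = _flat_corr_delta(cdist(di.y_uniq, di.x_share),
                           cdist(di.ref_y_uniq, di.ref_x_share))
    return 0.5 * (dxy + dyx)


def evaluate_all(
    u_x: np.ndarray,
    u_y: np.ndarray,
    labels_x: np.ndarray,
    labels_y: np.ndarray,
    pairing: np.ndarray | None = None,
    k: int = 15,
    seed: int = 0,
) -> dict[str, float]:
    """Joint report of the alignment and embedding metrics.

    ``pairing`` is an (n, 2) array of (x index, y index) ground-truth pairs;
    FOSCTTM is reported only when it is provided.
    """
    u_x = np.asarray(u_x, float)
    u_y = np.asarray(u_y, float)
    out: dict[str, float] = {}
    if pairing is not None and len(pairing):
        pe = PairedEmbeddings(u_x[pairing[:, 0]], u_y[pairing[:, 1]])
        out["foscttm"] = foscttm(pe)
    out["ctm"] = ctm(u_x, u_y, labels_x, labels_y)
    joint = np.vstack([u_x, u_y])
    labels = np.concatenate([labels_x, labels_y])
    modality = np.array(["rna"] * len(u_x) + ["atac"] * len(u_y))
    out["ami"] = ami(joint, labels, k=k, seed=seed)
    out["batch_asw"] = batch_asw(joint, modality, labels)
    out["graph_connectivity"] = graph_connectivity(joint, labels, k=k)
    return out
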