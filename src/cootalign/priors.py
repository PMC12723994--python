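"""Construction of the cross-modality priors.

Two priors seed the transport solver:

* a binary **feature-level prior** linking a gene to a peak whenever the peak
  intersects the gene body extended upstream (strand-aware) — the usual
  gene-activity window heuristic;
* a dense **cell-level prior** obtained by entropic OT between RNA expression
  and an ATAC-derived gene-activity matrix on the intersection of their gene
  universes, after library-size normalization, log1p and a shared linear
  (PCA) reduction.

The feature prior additionally defines a bipartite gene–peak *prior graph*
whose edges are later reweighted by the feature transport plan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from sklearn.decomposition import PCA

from .ot_core import TransportPlan, pairwise_cost, sinkhorn_prior

__all__ = [
    "GeneRecord",
    "PeakRecord",
    "FeaturePrior",
    "CellPrior",
    "PriorGraph",
    "build_feature_prior",
    "build_cell_prior",
    "build_prior_graph",
    "read_bed_peaks",
    "read_gene_table",
    "read_matrix",
    "write_edge_list",
    "lognorm",
]

DEFAULT_UPSTREAM = 2000
DEFAULT_DOWNSTREAM = 0


@dataclass(frozen=True)
class GeneRecord:
    """Gene locus, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class PeakRecord:
    """Accessibility peak, 0-based half-open coordinates."""

    peak_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.peak_id}: start must be < end")


@dataclass
class FeaturePrior:
    """Binary genes x peaks overlap matrix."""

    matrix: np.ndarray
    gene_index: list[str]
    peak_index: list[str]


@dataclass
class CellPrior:
    """Cell-level coupling derived by entropic OT on a shared gene space."""

    matrix: np.ndarray
    construction_eps: float

    @property
    def plan(self) -> TransportPlan:
        n, m = self.matrix.shape
        return TransportPlan(
            self.matrix, np.full(n, 1 / n), np.full(m, 1 / m), self.construction_eps
        )


@dataclass
class PriorGraph:
    """Bipartite gene-peak graph with a symmetric adjacency over all features."""

    graph: nx.Graph
    gene_index: list[str]
    peak_index: list[str]
    adjacency: np.ndarray = field(repr=False, default=None)

    @property
    def nodes(self) -> list[str]:
        return self.gene_index + self.peak_index

    @property
    def edges(self) -> set[tuple[str, str]]:
        out = set()
        for u, v in self.graph.edges:
            if u in self.graph.nodes and self.graph.nodes[u].get("bipartite") == 0:
                out.add((u, v))
            else:
                out.add((v, u))
        return out

    def edge_array(self) -> np.ndarray:
        """Edges as (gene_pos, peak_pos) integer index pairs into node order."""
        gpos = {g: i for i, g in enumerate(self.gene_index)}
        ppos = {p: i for i, p in enumerate(self.peak_index)}
        return np.array(
            sorted((gpos[g], ppos[p]) for g, p in self.edges), dtype=int
        ).reshape(-1, 2)


def _extended_window(g: GeneRecord, upstream: int, downstream: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.start - upstream, g.end + downstream
    return g.start - downstream, g.end + upstream


def build_feature_prior(
    genes: Sequence[GeneRecord],
    peaks: Sequence[PeakRecord],
    upstream_ext: int = DEFAULT_UPSTREAM,
    downstream_ext: int = DEFAULT_DOWNSTREAM,
) -> FeaturePrior:
    """Binary genes x peaks matrix: 1 iff the peak intersects the gene body
    extended ``upstream_ext`` bp past the 5' end and ``downstream_ext`` bp past
    the 3' end (strand-aware), on the same chromosome.  Half-open intervals.
    """
    gene_ids = [g.gene_id for g in genes]
    peak_ids = [p.peak_id for p in peaks]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicated gene identifiers")
    if len(set(peak_ids)) != len(peak_ids):
        raise ValueError("duplicated peak identifiers")
    M = np.zeros((len(genes), len(peaks)), dtype=np.int8)
    by_chrom: dict[str, list[int]] = {}
    for j, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append(j)
    for i, g in enumerate(genes):
        cols = by_chrom.get(g.chrom)
        if not cols:
            continue
        lo, hi = _extended_window(g, upstream_ext, downstream_ext)
        ps = np.array([peaks[j].start for j in cols])
        pe = np.array([peaks[j].end for j in cols])
        hit = (ps < hi) & (pe > lo)
        M[i, np.asarray(cols)[hit]] = 1
    return FeaturePrior(M, gene_ids, peak_ids)


def lognorm(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalization to ``target_sum`` followed by log1p."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * target_sum)


def build_cell_prior(
    rna_counts: np.ndarray,
    gene_activity: np.ndarray,
    eps: float = 0.05,
    rna_genes: Sequence[str] | None = None,
    activity_genes: Sequence[str] | None = None,
    n_components: int = 50,
    random_state: int = 0,
) -> CellPrior:
    """Cell-level prior coupling via entropic OT between RNA expression and the
    imputed gene-activity matrix.

    Both matrices are restricted to the shared ordered gene list, library-size
    normalized, log1p-transformed and projected by a single PCA fitted on the
    row-wise concatenation, so squared-Euclidean costs are comparable across
    modalities.  The OT uses uniform marginals and a uniform prior kernel.
    """
    rna_counts = np.asarray(rna_counts, dtype=float)
    gene_activity = np.asarray(gene_activity, dtype=float)
    if rna_genes is not None or activity_genes is not None:
        if rna_genes is None or activity_genes is None:
            raise ValueError("provide gene lists for both matrices or neither")
        shared = [g for g in rna_genes if g in set(activity_genes)]
        if not shared:
            raise ValueError("empty gene intersection")
        ridx = {g: i for i, g in enumerate(rna_genes)}
        aidx = {g: i for i, g in enumerate(activity_genes)}
        rna_counts = rna_counts[:, [ridx[g] for g in shared]]
        gene_activity = gene_activity[:, [aidx[g] for g in shared]]
    elif rna_counts.shape[1] != gene_activity.shape[1]:
        raise ValueError("gene dimensions differ and no gene lists were given")
    if rna_counts.shape[1] == 0:
        raise ValueError("empty gene intersection")

    xr = lognorm(rna_counts)
    xa = lognorm(gene_activity)
    k = min(n_components, xr.shape[1], xr.shape[0] + xa.shape[0] - 1)
    pca = PCA(n_components=k, random_state=random_state)
    joint = pca.fit_transform(np.vstack([xr, xa]))
    zr, za = joint[: xr.shape[0]], joint[xr.shape[0] :]
    C = pairwise_cost(zr, za)
    plan = sinkhorn_prior(C, np.ones(C.values.shape), eps=eps)
    return CellPrior(plan.values, eps)


def build_prior_graph(fp: FeaturePrior) -> PriorGraph:
    """Bipartite graph with one node per gene and per peak and one undirected
    edge per nonzero prior entry; adjacency ordered genes-then-peaks, zero
    diagonal."""
    n_g, n_p = fp.matrix.shape
    G = nx.Graph()
    G.add_nodes_from(fp.gene_index, bipartite=0, kind="gene")
    G.add_nodes_from(fp.peak_index, bipartite=1, kind="peak")
    gi, pi = np.nonzero(fp.matrix)
    if gi.size == 0:
        warnings.warn("feature prior has no edges; prior graph is degenerate",
                      RuntimeWarning, stacklevel=2)
    G.add_edges_from(
        (fp.gene_index[i], fp.peak_index[j]) for i, j in zip(gi, pi)
    )
    A = np.zeros((n_g + n_p, n_g + n_p), dtype=np.int8)
    A[gi, n_g + pi] = 1
    A[n_g + pi, gi] = 1
    return PriorGraph(G, list(fp.gene_index), list(fp.peak_index), A)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bed_peaks(path) -> list[PeakRecord]:
    """BED3+ peaks; BED is already 0-based half-open.  Peak ids come from the
    4th column when present, else ``chrom:start-end``."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    records = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        name = row[3] if len(row) > 3 else None
        pid = str(name) if name is not None and not pd.isna(name) else f"{chrom}:{start}-{end}"
        records.append(PeakRecord(pid, chrom, start, end))
    return records


def read_gene_table(path, one_based: bool = True) -> list[GeneRecord]:
    """Tab-separated gene table (gene_id, chrom, start, end, strand).  GTF-style
    1-based inclusive coordinates are converted to 0-based half-open on read."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["gene_id", "chrom", "start", "end", "strand"], comment="#",
    )
    off = 1 if one_based else 0
    return [
        GeneRecord(str(r.gene_id), str(r.chrom), int(r.start) - off, int(r.end),
                   str(r.strand))
        for r in df.itertuples(index=False)
    ]


def read_matrix(path) -> np.ndarray:
    """Dense matrix from Matrix-Market (.mtx) or TSV."""
    path = str(path)
    if path.endswith(".mtx"):
        m = spio.mmread(path)
        return np.asarray(m.todense() if sparse.issparse(m) else m, dtype=float)
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)


def write_edge_list(pg: PriorGraph, path, weights: dict | None = None) -> None:
    """Prior graph as a TSV edge list (gene_id, peak_id, weight)."""
    rows = []
    for g, p in sorted(pg.edges):
        w = 1.0 if weights is None else weights.get((g, p), 0.0)
        rows.append((g, p, w))
    pd.DataFrame(rows, columns=["gene_id", "peak_id", "weight"]).to_csv(
        path, sep="\t", index=False
    )
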