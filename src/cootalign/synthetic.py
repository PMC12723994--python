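"""Synthetic paired multi-omics generator.

Emulates jointly profiled scRNA-seq / scATAC-seq data with a shared latent
cell state per cell, so that every component of the integration pipeline can
be exercised against known ground truth: positional cell pairing, cell-type
labels, true gene-peak regulatory edges, and a coordinate layout on a
synthetic genome under which the interval-overlap prior recovers exactly the
true edges.

Generative model
----------------
Cell types are Gaussian blobs in a latent space: per type a center is drawn,
and each cell's latent state is its type center plus isotropic noise.  Gene
(log-)activities are a linear read-out of the latent state; RNA counts are
negative binomial with per-cell library sizes and cell-wise softmax rates.
Each gene drives ``peaks_per_gene`` linked peaks whose accessibility follows
the gene's activity plus noise, again drawn as (sparser) negative binomial
counts.  The imputed gene-activity matrix is the per-gene sum of linked peak
counts with additive noise — a deliberately simple stand-in for
fragment-based gene-activity scoring.

The imbalance procedure removes disjoint sets of cell types from each
modality, flagging surviving cells of a removed type in the *other* modality
as modality-unique; the positional pairing is restricted to shared cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .priors import GeneRecord, PeakRecord

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_paired", "apply_imbalance", "write_dataset"]

_GENE_SPACING = 100_000
_GENE_LENGTH = 2_000
_CHROM_GENES = 40  # genes per synthetic chromosome


@dataclass(frozen=True)
class SyntheticConfig:
    n_types: int = 8
    cells_per_type: int = 25
    n_genes: int = 60
    n_peaks: int = 180
    peaks_per_gene: int = 3
    latent_dim: int = 10
    noise_sd: float = 0.6
    center_sd: float = 2.0
    nb_dispersion: float = 8.0
    atac_dispersion: float = 3.0
    rna_library: float = 2500.0
    atac_library: float = 1200.0
    peak_noise_sd: float = 0.4
    activity_noise_sd: float = 0.5
    binarize_atac: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_types", "cells_per_type", "n_genes", "n_peaks",
                     "peaks_per_gene", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_peaks < self.n_genes * self.peaks_per_gene:
            raise ValueError("n_peaks must cover the linked peaks")


@dataclass
class SyntheticDataset:
    rna_counts: np.ndarray
    atac_counts: np.ndarray
    gene_activity: np.ndarray
    labels_x: np.ndarray
    labels_y: np.ndarray
    gene_records: list[GeneRecord]
    peak_records: list[PeakRecord]
    true_edges: set[tuple[str, str]]
    pairing: np.ndarray  # (n_shared, 2): row -> (index in X, index in Y)
    unique_x: np.ndarray  # bool over X cells, True = modality-unique
    unique_y: np.ndarray
    orig_index_x: np.ndarray  # positions in the pre-imbalance dataset
    orig_index_y: np.ndarray
    latent_x: np.ndarray
    latent_y: np.ndarray
    config: SyntheticConfig

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.gene_records]

    @property
    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self.peak_records]


def _layout(cfg: SyntheticConfig) -> tuple[list[GeneRecord], list[PeakRecord], set]:
    """Genes 100 kb apart on synthetic chromosomes; linked peaks inside the
    gene body (hence recovered by any nonnegative extension window); unlinked
    peaks 50 kb away from every gene, outside the default window."""
    genes: list[GeneRecord] = []
    peaks: list[PeakRecord] = []
    edges: set[tuple[str, str]] = set()
    slot = _GENE_LENGTH // cfg.peaks_per_gene
    width = min(400, max(50, slot - 100))
    if width + 10 > slot:
        raise ValueError("infeasible layout: too many peaks per gene body")
    for g in range(cfg.n_genes):
        chrom = f"chr{g // _CHROM_GENES + 1}"
        start = 10_000 + (g % _CHROM_GENES) * _GENE_SPACING
        gid = f"gene{g}"
        genes.append(GeneRecord(gid, chrom, start, start + _GENE_LENGTH,
                                "+" if g % 2 == 0 else "-"))
        for k in range(cfg.peaks_per_gene):
            ps = start + 50 + k * slot
            pid = f"peak{g * cfg.peaks_per_gene + k}"
            peaks.append(PeakRecord(pid, chrom, ps, ps + width))
            edges.add((gid, pid))
    n_linked = cfg.n_genes * cfg.peaks_per_gene
    for j in range(n_linked, cfg.n_peaks):
        g = (j - n_linked) % cfg.n_genes
        chrom = f"chr{g // _CHROM_GENES + 1}"
        ps = 10_000 + (g % _CHROM_GENES) * _GENE_SPACING + 50_000 \
            + ((j - n_linked) // cfg.n_genes) * 1_000
        peaks.append(PeakRecord(f"peak{j}", chrom, ps, ps + 400))
    return genes, peaks, edges


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + np.maximum(mean, 1e-12))
    return rng.negative_binomial(dispersion, p).astype(np.int64)


def generate_paired(cfg: SyntheticConfig | None = None, **kw) -> SyntheticDataset:
    """Draw a perfectly paired dataset under ``cfg`` (fully seeded)."""
    if cfg is None:
        cfg = SyntheticConfig(**kw)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_types * cfg.cells_per_type

    centers = rng.normal(scale=cfg.center_sd, size=(cfg.n_types, cfg.latent_dim))
    labels = np.repeat(np.arange(cfg.n_types), cfg.cells_per_type)
    Z = centers[labels] + rng.normal(scale=cfg.noise_sd, size=(n, cfg.latent_dim))

    W = rng.normal(size=(cfg.latent_dim, cfg.n_genes)) / np.sqrt(cfg.latent_dim)
    gene_logits = Z @ W  # (cells x genes) latent gene activity

    lib_r = cfg.rna_library * np.exp(rng.normal(scale=0.2, size=n))
    rho = np.exp(gene_logits - gene_logits.max(axis=1, keepdims=True))
    rho /= rho.sum(axis=1, keepdims=True)
    rna = _nb_counts(rng, lib_r[:, None] * rho, cfg.nb_dispersion)

    # linked peaks track their gene's activity; any surplus peaks are driven
    # by latent-independent noise
    n_linked = cfg.n_genes * cfg.peaks_per_gene
    peak_logits = np.empty((n, cfg.n_peaks))
    peak_logits[:, :n_linked] = (
        np.repeat(gene_logits, cfg.peaks_per_gene, axis=1)
        + rng.normal(scale=cfg.peak_noise_sd, size=(n, n_linked))
    )
    if cfg.n_peaks > n_linked:
        peak_logits[:, n_linked:] = rng.normal(
            scale=1.0, size=(n, cfg.n_peaks - n_linked)
        )
    lib_a = cfg.atac_library * np.exp(rng.normal(scale=0.2, size=n))
    rho_a = np.exp(peak_logits - peak_logits.max(axis=1, keepdims=True))
    rho_a /= rho_a.sum(axis=1, keepdims=True)
    atac = _nb_counts(rng, lib_a[:, None] * rho_a, cfg.atac_dispersion)
    if cfg.binarize_atac:
        atac = (atac > 0).astype(np.int64)

    # gene activity: per-gene sum of linked peak counts, plus noise
    ga = atac[:, :n_linked].reshape(n, cfg.n_genes, cfg.peaks_per_gene).sum(axis=2)
    ga = np.maximum(
        ga + rng.normal(scale=cfg.activity_noise_sd, size=ga.shape), 0.0
    )

    genes, peaks, edges = _layout(cfg)
    pairing = np.stack([np.arange(n), np.arange(n)], axis=1)
    return SyntheticDataset(
        rna_counts=rna, atac_counts=atac, gene_activity=ga,
        labels_x=labels.copy(), labels_y=labels.copy(),
        gene_records=genes, peak_records=peaks, true_edges=edges,
        pairing=pairing,
        unique_x=np.zeros(n, dtype=bool), unique_y=np.zeros(n, dtype=bool),
        orig_index_x=np.arange(n), orig_index_y=np.arange(n),
        latent_x=Z.copy(), latent_y=Z.copy(), config=cfg,
    )


def apply_imbalance(
    ds: SyntheticDataset, n_remove: int, seed: int = 0
) -> tuple[SyntheticDataset, np.ndarray, np.ndarray]:
    """Remove ``n_remove`` cell types from each modality (disjoint sets).

    Types removed from the RNA side survive only in ATAC (and vice versa);
    those surviving cells are flagged modality-unique.  The positional pairing
    is restricted to cells whose type survives in both modalities.
    """
    cfg = ds.config
    if 2 * n_remove >= cfg.n_types:
        raise ValueError("2 * n_remove must be < n_types")
    if n_remove == 0:
        return ds, np.array([], dtype=int), np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    chosen = rng.permutation(cfg.n_types)[: 2 * n_remove]
    removed_x, removed_y = np.sort(chosen[:n_remove]), np.sort(chosen[n_remove:])

    keep_x = ~np.isin(ds.labels_x, removed_x)
    keep_y = ~np.isin(ds.labels_y, removed_y)
    idx_x = np.nonzero(keep_x)[0]
    idx_y = np.nonzero(keep_y)[0]
    pos_x = {old: new for new, old in enumerate(idx_x)}
    pos_y = {old: new for new, old in enumerate(idx_y)}
    shared_old = np.nonzero(keep_x & keep_y)[0]
    pairing = np.array([[pos_x[i], pos_y[i]] for i in shared_old], dtype=int)

    out = replace(
        ds,
        rna_counts=ds.rna_counts[idx_x],
        atac_counts=ds.atac_counts[idx_y],
        gene_activity=ds.gene_activity[idx_y],
        labels_x=ds.labels_x[idx_x],
        labels_y=ds.labels_y[idx_y],
        pairing=pairing,
        unique_x=np.isin(ds.labels_x[idx_x], removed_y),
        unique_y=np.isin(ds.labels_y[idx_y], removed_x),
        orig_index_x=ds.orig_index_x[idx_x],
        orig_index_y=ds.orig_index_y[idx_y],
        latent_x=ds.latent_x[idx_x],
        latent_y=ds.latent_y[idx_y],
    )
    return out, removed_x, removed_y


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the fixture set: MTX counts, TSV gene activity, BED peaks, gene
    table, labels and ground-truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "rna_counts.mtx", sparse.csr_matrix(ds.rna_counts))
    spio.mmwrite(outdir / "atac_counts.mtx", sparse.csr_matrix(ds.atac_counts))
    pd.DataFrame(ds.gene_activity).to_csv(
        outdir / "gene_activity.tsv", sep="\t", header=False, index=False
    )
    with open(outdir / "peaks.bed", "w") as fh:
        for p in ds.peak_records:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")
    with open(outdir / "genes.tsv", "w") as fh:
        for g in ds.gene_records:
            # gene table convention: 1-based inclusive
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start + 1}\t{g.end}\t{g.strand}\n")
    pd.DataFrame({"label": ds.labels_x}).to_csv(outdir / "labels_x.tsv", sep="\t", index=False)
    pd.DataFrame({"label": ds.labels_y}).to_csv(outdir / "labels_y.tsv", sep="\t", index=False)
    pd.DataFrame(ds.pairing, columns=["index_x", "index_y"]).to_csv(
        outdir / "pairing.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(ds.true_edges), columns=["gene_id", "peak_id"]).to_csv(
        outdir / "true_edges.tsv", sep="\t", index=False
    )
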