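# cootalign

Diagonal integration of unpaired single-cell multi-omics data: aligning
scRNA-seq and scATAC-seq cell populations that share **no cells and no
features**, via prior-informed co-optimal transport (COOT) and regularized
barycentric mapping.

## The problem

Single-cell assays are destructive, so transcriptome and chromatin
accessibility are usually measured in *different* cells.  To study gene
regulation across both layers the two populations must be aligned
computationally.  Existing approaches either trust noisy prior feature
links (gene ↔ nearby peak) unrefined, or assume every cell has a
counterpart in the other modality — an assumption broken whenever a cell
type was captured in only one assay.

## The method

**Stage 1 — prior-informed COOT.**  Co-optimal transport jointly infers a
cell-level coupling `P_s` and a feature-level (gene x peak) coupling `P_v`
between the two count matrices,

    min  ⟨ L(X,Y) ⊗ P_v , P_s ⟩  −  ε H(P_s|Q_s)  −  ε H(P_v|Q_v),

where the entropy terms are taken *relative to priors* through the Sinkhorn
kernel `K_ij = Q_ij e^{−C_ij/ε}`: a binary gene-body/peak overlap matrix
seeds `Q_v`, an entropic-OT coupling between RNA expression and an imputed
gene-activity matrix seeds `Q_s`, and after every alternating sweep the
priors are replaced by the freshly inferred plans, so the prior knowledge is
refined by the data instead of being locked in.

**Stage 2 — transport-guided representation learning.**  Per-modality
negative-binomial VAEs embed cells; a variational graph autoencoder embeds
genes and peaks on the prior gene-peak graph, with each edge's
reconstruction weight set by the transport mass it received in `P_v`
(denoising the prior graph).  ATAC cells are pulled toward the plan-weighted
barycenters of RNA cells under a mixed plan `(1−λ)P + λP_s`; a per-cell
alignment confidence (cross-modality proximity + within-modality entropy,
thresholded at the Bayes decision point of a two-component Gaussian mixture)
splits cells into anchors and non-anchors, the pull is weighted by that
confidence, and non-anchor cells are instead held to consistent distances
to all anchors — so cell types present in only one modality are left
unaligned instead of being absorbed into the wrong cluster.

Outputs: cell embeddings for both modalities in one latent space, feature
embeddings for genes and peaks, the two transport plans, and (optionally)
significance-tested gene-peak regulatory links (cosine score, peak-label
permutation null, Benjamini-Hochberg).

See `docs/methods.md` for the full model description, defaults, and design
rationale.

## Worked example

Simulate a paired benchmark with ground truth (8 cell types x 25 cells,
60 genes, 180 peaks, known gene-peak edges), run the full pipeline with the
short test profile (100 warm-up / 300 tuning epochs), and evaluate:

```bash
cootalign simulate --out demo/data --seed 0
cootalign run --data demo/data --out demo/run --seed 0 \
          --warmup-epochs 100 --tuning-epochs 300
```

which prints the metric report (identical numbers are written to
`demo/run/metrics.json`):

```json
{
  "ami": 0.6855684759744017,
  "batch_asw": 0.7549674414647755,
  "ctm": 0.9550000000000001,
  "foscttm": 0.014924623115577889,
  "graph_connectivity": 1.0
}
```

FOSCTTM ≈ 0.015 means that, for an average cell, only ~1.5 % of the
opposite-modality cells lie closer than its true (simulated) counterpart —
near-perfect cell-level alignment; CTM = 0.955 means 95.5 % of cells have a
nearest cross-modality neighbour of their own cell type; graph
connectivity = 1.0 says every cell type is fully connected in the joint
embedding; batch-ASW = 0.75 indicates good mixing of the two modalities
within each type; AMI = 0.69 reflects that unsupervised Leiden communities
on this short training profile partly merge related cell types.  The run directory also holds the transport
plans (`sample_plan.mtx`, `feature_plan.mtx`), embeddings (TSV), the
denoised edge weights and the training log.

Python API equivalent:

```python
from cootalign.synthetic import SyntheticConfig, generate_paired
from cootalign.pipeline import integrate, RunConfig

ds = generate_paired(SyntheticConfig(seed=0))
out = integrate(ds.rna_counts, ds.atac_counts, ds.gene_records,
                ds.peak_records, ds.gene_activity,
                RunConfig(warmup_epochs=100, tuning_epochs=300, seed=0))
u_rna, u_atac = out.result.u_rna, out.result.u_atac
```

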