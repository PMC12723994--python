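"""End-to-end orchestration: configuration, staging, artifact I/O.

A run directory is produced from a data directory holding the standard
fixture layout (Matrix-Market counts, BED peaks, a tab-separated gene table,
optional labels / pairing / gene-activity files).  Stages: prior construction
-> prior-informed COOT -> two-stage VAE training -> evaluation -> optional
regulatory inference.  Every artifact is written next to the configuration
and its hash, and a fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .alignment import LossWeights, TrainConfig, TrainResult, train
from .metrics import evaluate_all
from .ot_core import CootResult, prior_coot
from .priors import (
    build_cell_prior,
    build_feature_prior,
    build_prior_graph,
    lognorm,
    read_bed_peaks,
    read_gene_table,
    read_matrix,
    write_edge_list,
)
from .regnet import score_pairs

__all__ = ["RunConfig", "run_pipeline", "load_data_dir", "integrate",
           "IntegrationOutput", "read_embeddings", "imbalance_experiment"]


@dataclass
class RunConfig:
    """Every tunable of the pipeline; unknown keys are rejected on load."""

    data_dir: str = ""
    out_dir: str = "run"
    seed: int = 0
    # priors
    upstream_ext: int = 2000
    downstream_ext: int = 0
    prior_eps: float = 0.05
    n_hvg: int = 2000
    # COOT
    eps: float = 0.05
    n_outer: int = 10
    n_inner: int = 2000
    # training (reference profile 1000/3000; test profile 100/300)
    warmup_epochs: int = 1000
    tuning_epochs: int = 3000
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    div_iters: int = 10
    latent_dim: int = 32
    lambda_graph: float = 1.0
    lambda_regbary: float = 0.1
    lambda_div: float = 0.01
    lambda_reg: float = 0.1
    lambda_prior: float = 0.8
    ramp_fraction: float = 0.1
    k_c: int = 15
    refresh_interval: int = 10
    # evaluation / regnet
    knn_k: int = 15
    run_regnet: bool = False
    n_permutations: int = 999
    alpha: float = 0.05
    skip_train: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            latent_dim=self.latent_dim,
            warmup_epochs=self.warmup_epochs,
            tuning_epochs=self.tuning_epochs,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            batch_size=self.batch_size,
            div_iters=self.div_iters,
            eps=self.eps,
            weights=LossWeights(
                lambda_graph=self.lambda_graph,
                lambda_regbary=self.lambda_regbary,
                lambda_div=self.lambda_div,
                lambda_reg=self.lambda_reg,
                lambda_prior=self.lambda_prior,
                ramp_fraction=self.ramp_fraction,
            ),
            k_c=self.k_c,
            refresh_interval=self.refresh_interval,
            seed=self.seed,
        )


def load_data_dir(data_dir) -> dict:
    """Read the fixture layout produced by ``synthetic.write_dataset`` (or an
    equivalent real-data export)."""
    d = Path(data_dir)
    required = ["rna_counts.mtx", "atac_counts.mtx", "peaks.bed", "genes.tsv"]
    missing = [f for f in required if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs in {d}: {missing}")
    out = {
        "rna_counts": read_matrix(d / "rna_counts.mtx"),
        "atac_counts": read_matrix(d / "atac_counts.mtx"),
        "genes": read_gene_table(d / "genes.tsv"),
        "peaks": read_bed_peaks(d / "peaks.bed"),
    }
    if (d / "gene_activity.tsv").exists():
        out["gene_activity"] = read_matrix(d / "gene_activity.tsv")
    for name, col in (("labels_x", "label"), ("labels_y", "label")):
        f = d / f"{name}.tsv"
        if f.exists():
            out[name] = pd.read_csv(f, sep="\t")[col].to_numpy()
    if (d / "pairing.tsv").exists():
        out["pairing"] = pd.read_csv(d / "pairing.tsv", sep="\t").to_numpy()
    return out


def _write_plan(path_prefix: Path, plan, extra: dict) -> None:
    spio.mmwrite(str(path_prefix) + ".mtx", sparse.coo_matrix(plan.values))
    meta = {
        "eps": plan.eps,
        "row_marginal": "uniform",
        "col_marginal": "uniform",
        "converged": bool(plan.converged),
        **extra,
    }
    Path(str(path_prefix) + ".json").write_text(json.dumps(meta, indent=2))


def read_embeddings(path) -> tuple[list[str], np.ndarray]:
    """Embedding TSV (id, dim_1..dim_k) -> (ids, matrix); the round-trip
    float parser makes re-read embeddings bit-identical to what was written."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df["id"].tolist(), df.drop(columns="id").to_numpy(dtype=float)


def _write_embeddings(path: Path, ids, mat: np.ndarray) -> None:
    df = pd.DataFrame(mat, columns=[f"dim_{i + 1}" for i in range(mat.shape[1])])
    df.insert(0, "id", list(ids))
    # %.17g guarantees exact float64 round-trip, so re-evaluating from the
    # written embeddings reproduces the in-memory metrics bit for bit
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _select_features(data: dict, fp, n_hvg: int):
    """COOT feature universe: highly-variable genes that carry prior edges and
    peaks with at least one prior edge."""
    gene_deg = fp.matrix.sum(axis=1)
    peak_deg = fp.matrix.sum(axis=0)
    x = lognorm(data["rna_counts"])
    var = x.var(axis=0)
    eligible = np.nonzero(gene_deg > 0)[0]
    order = eligible[np.argsort(var[eligible])[::-1]]
    g_idx = np.sort(order[:n_hvg])
    p_idx = np.nonzero(fp.matrix[g_idx].sum(axis=0) > 0)[0]
    return g_idx, p_idx


def imbalance_experiment(
    seed: int,
    n_remove: int = 2,
    config: RunConfig | None = None,
    arms: dict[str, dict] | None = None,
) -> dict:
    """Imbalance study on the synthetic benchmark: train a perfectly paired
    reference run and, per arm, an imbalanced run with ``n_remove`` cell
    types removed from each modality; report within-/cross-modality
    distortion of the modality-unique cells against the reference and
    FOSCTTM on the shared cells.

    ``arms`` maps an arm name to RunConfig field overrides; the default pair
    is the full model vs the anchor-regularization ablation (lambda_reg=0).
    """
    from .metrics import (DistortionInput, PairedEmbeddings, cross_distortion,
                          foscttm, within_distortion)
    from .synthetic import SyntheticConfig, apply_imbalance, generate_paired

    base = dataclasses.asdict(config or RunConfig())
    base["seed"] = seed
    if arms is None:
        arms = {"full": {}, "no_reg": {"lambda_reg": 0.0}}

    ds = generate_paired(SyntheticConfig(seed=seed))
    ds_imb, removed_x, removed_y = apply_imbalance(ds, n_remove, seed=seed)

    ref = integrate(ds.rna_counts, ds.atac_counts, ds.gene_records,
                    ds.peak_records, ds.gene_activity, RunConfig(**base))
    out: dict = {"seed": seed, "removed_x": removed_x.tolist(),
                 "removed_y": removed_y.tolist(), "arms": {}}
    for name, overrides in arms.items():
        cfg = RunConfig(**{**base, **overrides})
        run = integrate(ds_imb.rna_counts, ds_imb.atac_counts,
                        ds_imb.gene_records, ds_imb.peak_records,
                        ds_imb.gene_activity, cfg)
        ux, uy = run.result.u_rna, run.result.u_atac
        di = DistortionInput(
            x_uniq=ux[ds_imb.unique_x],
            x_share=ux[~ds_imb.unique_x],
            y_uniq=uy[ds_imb.unique_y],
            y_share=uy[~ds_imb.unique_y],
            ref_x_uniq=ref.result.u_rna[ds_imb.orig_index_x[ds_imb.unique_x]],
            ref_x_share=ref.result.u_rna[ds_imb.orig_index_x[~ds_imb.unique_x]],
            ref_y_uniq=ref.result.u_atac[ds_imb.orig_index_y[ds_imb.unique_y]],
            ref_y_share=ref.result.u_atac[ds_imb.orig_index_y[~ds_imb.unique_y]],
        )
        pair = ds_imb.pairing
        from scipy.spatial.distance import cdist as _cd
        from scipy.stats import pearsonr as _pr

        def _delta(A, B):
            return float(1.0 - _pr(np.ravel(A), np.ravel(B)).statistic)

        out["arms"][name] = {
            "within_distortion": within_distortion(di),
            "cross_distortion": cross_distortion(di),
            "foscttm_shared": foscttm(PairedEmbeddings(ux[pair[:, 0]], uy[pair[:, 1]])),
            # per-side components, useful for diagnosing which modality drives
            # the distortion
            "wd_x": _delta(_cd(di.x_uniq, di.x_share), _cd(di.ref_x_uniq, di.ref_x_share)),
            "wd_y": _delta(_cd(di.y_uniq, di.y_share), _cd(di.ref_y_uniq, di.ref_y_share)),
            "cd_xy": _delta(_cd(di.x_uniq, di.y_share), _cd(di.ref_x_uniq, di.ref_y_share)),
            "cd_yx": _delta(_cd(di.y_uniq, di.x_share), _cd(di.ref_y_uniq, di.ref_x_share)),
        }
    return out


@dataclass
class IntegrationOutput:
    """In-memory result of priors -> COOT -> training."""

    result: TrainResult
    coot: CootResult
    fp: object
    pg: object
    cell_prior: np.ndarray | None
    gene_subset: np.ndarray
    peak_subset: np.ndarray


def integrate(
    rna_counts: np.ndarray,
    atac_counts: np.ndarray,
    genes,
    peaks,
    gene_activity: np.ndarray | None = None,
    config: RunConfig | None = None,
) -> IntegrationOutput:
    """Run the full integration in memory: build the coordinate-overlap
    feature prior and (if gene activity is available) the EOT cell prior,
    solve prior-informed COOT, then train the VAEs/VGAE."""
    cfg = config or RunConfig()
    gene_ids = [g.gene_id for g in genes]
    peak_ids = [p.peak_id for p in peaks]
    fp_full = build_feature_prior(genes, peaks, cfg.upstream_ext, cfg.downstream_ext)
    g_idx, p_idx = _select_features({"rna_counts": rna_counts}, fp_full, cfg.n_hvg)
    from .priors import FeaturePrior

    fp = FeaturePrior(
        fp_full.matrix[np.ix_(g_idx, p_idx)],
        [gene_ids[i] for i in g_idx],
        [peak_ids[j] for j in p_idx],
    )
    pg = build_prior_graph(fp)
    rna = rna_counts[:, g_idx]
    atac = atac_counts[:, p_idx]

    Qs0 = None
    conf_dists = None
    if gene_activity is not None:
        ga = gene_activity[:, g_idx]
        cp = build_cell_prior(rna, ga, eps=cfg.prior_eps, random_state=cfg.seed)
        Qs0 = cp.matrix
        # alignment-confidence geometry: cross-modality distances are taken in
        # the shared gene-activity space (meaningful before any alignment),
        # within-modality distances in the updating modality's own LSI space
        from scipy.spatial.distance import cdist
        from sklearn.decomposition import PCA

        from .model import reduce_atac

        xr, xa = lognorm(rna), lognorm(ga)
        k = min(50, xr.shape[1], xr.shape[0] + xa.shape[0] - 1)
        joint = PCA(n_components=k, random_state=cfg.seed).fit_transform(
            np.vstack([xr, xa]))
        D_cross = cdist(joint[: xr.shape[0]], joint[xr.shape[0]:])
        za = reduce_atac(atac)
        conf_dists = (cdist(za, za), D_cross)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        coot = prior_coot(
            lognorm(rna), lognorm(atac),
            Qs0=Qs0, Qv0=fp.matrix.astype(float),
            eps=cfg.eps, n_outer=cfg.n_outer, n_inner=cfg.n_inner,
        )
        result = train(rna, atac, fp, coot, cfg.train_config(),
                       confidence_dists=conf_dists)
    return IntegrationOutput(result, coot, fp, pg, Qs0, g_idx, p_idx)


def run_pipeline(config: RunConfig) -> Path:
    """Execute priors -> COOT -> training -> evaluation (-> regnet) and write
    all artifacts into the run directory."""
    data = load_data_dir(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    (out / "config_hash.txt").write_text(config.digest() + "\n")

    emb_r = out / "embeddings_rna.tsv"
    emb_a = out / "embeddings_atac.tsv"
    emb_v = out / "embeddings_features.tsv"
    if config.skip_train and emb_r.exists() and emb_a.exists() and emb_v.exists():
        u_rna = read_embeddings(emb_r)[1]
        u_atac = read_embeddings(emb_a)[1]
        v = read_embeddings(emb_v)[1]
        fp = pg = None
    else:
        io_res = integrate(
            data["rna_counts"], data["atac_counts"], data["genes"], data["peaks"],
            gene_activity=data.get("gene_activity"), config=config,
        )
        result, coot, fp, pg = io_res.result, io_res.coot, io_res.fp, io_res.pg
        write_edge_list(pg, out / "prior_edges.tsv")
        if io_res.cell_prior is not None:
            spio.mmwrite(out / "cell_prior.mtx", sparse.coo_matrix(io_res.cell_prior))
        _write_plan(out / "sample_plan", coot.sample_plan,
                    {"n_outer": coot.n_outer, "objective_trace": coot.objective_trace})
        _write_plan(out / "feature_plan", coot.feature_plan, {"n_outer": coot.n_outer})
        u_rna, u_atac, v = result.u_rna, result.u_atac, result.v
        _write_embeddings(emb_r, [f"rna_cell_{i}" for i in range(len(u_rna))], u_rna)
        _write_embeddings(emb_a, [f"atac_cell_{i}" for i in range(len(u_atac))], u_atac)
        _write_embeddings(emb_v, fp.gene_index + fp.peak_index, v)
        pd.DataFrame(result.history).to_csv(out / "history.csv", index=False)
        if result.params is not None:
            flat = {f"{mod}.{name}": arr for mod, sub in result.params.items()
                    for name, arr in sub.items()}
            np.savez(out / "checkpoint.npz", config_hash=config.digest(), **flat)
        write_edge_list(pg, out / "edge_weights.tsv", weights=result.edge_weights)
        if result.anchors is not None:
            pd.DataFrame({
                "cell": np.arange(len(u_atac)),
                "is_anchor": np.isin(np.arange(len(u_atac)), result.anchors.anchors),
            }).to_csv(out / "anchors.tsv", sep="\t", index=False)

    # --- evaluation ---------------------------------------------------------
    metrics: dict = {}
    if "labels_x" in data and "labels_y" in data:
        metrics = evaluate_all(
            u_rna, u_atac, data["labels_x"], data["labels_y"],
            pairing=data.get("pairing"), k=config.knn_k, seed=config.seed,
        )
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))

    # --- regulatory inference ----------------------------------------------
    if config.run_regnet:
        if fp is None:  # skip-train path: rebuild the prior for pair lists
            gene_ids = [g.gene_id for g in data["genes"]]
            peak_ids = [p.peak_id for p in data["peaks"]]
            fp_full = build_feature_prior(data["genes"], data["peaks"],
                                          config.upstream_ext, config.downstream_ext)
            g_idx, p_idx = _select_features(data, fp_full, config.n_hvg)
            from .priors import FeaturePrior

            fp = FeaturePrior(
                fp_full.matrix[np.ix_(g_idx, p_idx)],
                [gene_ids[i] for i in g_idx],
                [peak_ids[j] for j in p_idx],
            )
            pg = build_prior_graph(fp)
        n_g = len(fp.gene_index)
        df = score_pairs(
            v[:n_g], v[n_g:], sorted(pg.edges), fp.gene_index, fp.peak_index,
            B=config.n_permutations, alpha=config.alpha, seed=config.seed,
        )
        df.to_csv(out / "regnet.tsv", sep="\t", index=False)
    return out
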