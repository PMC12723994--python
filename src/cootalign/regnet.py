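"""Gene-peak regulatory inference from learned feature embeddings.

Candidate gene-peak pairs (by default the prior-graph edges) are scored by
the cosine similarity of their feature embeddings.  Significance comes from
a permutation null that reassigns peak embeddings to peaks uniformly at
random — preserving each pair's gene — followed by Benjamini-Hochberg
correction.  An optional Fisher's exact test quantifies enrichment of the
significant pairs in an external reference set of interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairScore",
    "cosine_scores",
    "permutation_test",
    "bh_correct",
    "score_pairs",
    "enrichment_test",
]


@dataclass
class PairScore:
    gene_id: str
    peak_id: str
    cosine: float
    p_value: float | None = None
    q_value: float | None = None
    significant: bool = False


def _unit_rows(v: np.ndarray, ids: list[str], kind: str) -> tuple[np.ndarray, dict[str, int]]:
    v = np.asarray(v, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{zero.sum()} zero-norm {kind} embedding(s); their pairs are dropped",
            RuntimeWarning, stacklevel=3,
        )
    unit = np.where(zero[:, None], np.nan, v / np.where(zero, 1.0, norms)[:, None])
    return unit, {g: i for i, g in enumerate(ids)}


def cosine_scores(
    v_genes: np.ndarray,
    v_peaks: np.ndarray,
    candidate_pairs: list[tuple[str, str]],
    gene_ids: list[str],
    peak_ids: list[str],
) -> list[PairScore]:
    """Cosine similarity of the two embedding vectors per candidate pair.
    Pairs touching a zero-norm embedding are dropped with a warning."""
    ug, gidx = _unit_rows(v_genes, gene_ids, "gene")
    up, pidx = _unit_rows(v_peaks, peak_ids, "peak")
    out = []
    for g, p in candidate_pairs:
        c = float(ug[gidx[g]] @ up[pidx[p]])
        if np.isnan(c):
            continue
        out.append(PairScore(g, p, c))
    return out


def permutation_test(
    scores: list[PairScore],
    v_genes: np.ndarray,
    v_peaks: np.ndarray,
    gene_ids: list[str],
    peak_ids: list[str],
    B: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """One-sided permutation p-values for the pair scores.

    Null: peak embeddings reassigned to peaks by a uniform random permutation
    (genes fixed), preserving each pair's gene marginal.  With the +1
    smoothing, ``p = (1 + #{null >= observed}) / (1 + B)``."""
    ug, gidx = _unit_rows(v_genes, gene_ids, "gene")
    up, pidx = _unit_rows(v_peaks, peak_ids, "peak")
    rng = np.random.default_rng(seed)
    gi = np.array([gidx[s.gene_id] for s in scores])
    pj = np.array([pidx[s.peak_id] for s in scores])
    obs = np.array([s.cosine for s in scores])
    exceed = np.zeros(len(scores), dtype=int)
    n_peaks = up.shape[0]
    for _ in range(B):
        perm = rng.permutation(n_peaks)
        null = np.einsum("ij,ij->i", ug[gi], up[perm[pj]])
        exceed += null >= obs
    p = (1.0 + exceed) / (1.0 + B)
    for s, pv in zip(scores, p):
        s.p_value = float(pv)
    return p


def bh_correct(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, significant mask)."""
    p_values = np.asarray(p_values, dtype=float)
    reject, q, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return q, reject


def score_pairs(
    v_genes: np.ndarray,
    v_peaks: np.ndarray,
    candidate_pairs: list[tuple[str, str]],
    gene_ids: list[str],
    peak_ids: list[str],
    B: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Full scoring pipeline: cosine, permutation p, BH q, significance flag."""
    scores = cosine_scores(v_genes, v_peaks, candidate_pairs, gene_ids, peak_ids)
    if not scores:
        return pd.DataFrame(columns=["gene_id", "peak_id", "cosine", "p", "q", "significant"])
    p = permutation_test(scores, v_genes, v_peaks, gene_ids, peak_ids, B=B, seed=seed)
    q, sig = bh_correct(p, alpha=alpha)
    for s, qv, sv in zip(scores, q, sig):
        s.q_value = float(qv)
        s.significant = bool(sv)
    return pd.DataFrame(
        [(s.gene_id, s.peak_id, s.cosine, s.p_value, s.q_value, s.significant)
         for s in scores],
        columns=["gene_id", "peak_id", "cosine", "p", "q", "significant"],
    )


def enrichment_test(
    significant_pairs: set[tuple[str, str]],
    nonsignificant_pairs: set[tuple[str, str]],
    reference_pairs: set[tuple[str, str]],
) -> tuple[float, float]:
    """Fisher's exact test of the 2x2 table (significant x in-reference).
    Returns (odds ratio, p); the odds ratio is ``inf`` for degenerate tables
    with an empty off-diagonal."""
    a = len(significant_pairs & reference_pairs)
    b = len(significant_pairs - reference_pairs)
    c = len(nonsignificant_pairs & reference_pairs)
    d = len(nonsignificant_pairs - reference_pairs)
    res = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c else (float("inf") if a * d else float("nan"))
    return float(odds), float(res.pvalue)
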