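"""Four-layer evidence fusion: Score, Support and Confidence.

The four TF x gene evidence matrices — TFBS content {0,1,2}, annotation
kappa [0,1], expression correlation [-1,1] and curated interaction level
{0,1,2,3} — are each scaled to [0,1], summed, and the sum min-max
normalized into the integrated ``Score(Ti, Gj)`` in [0,1].  TFs and
target genes are then grouped by hierarchical clustering of their
concatenated scaled-layer profiles; ``Support`` of a (TF cluster, TG
cluster) pair is the mean Score over the block, and pairs passing a
Support threshold (0.25 by convention) are scored pair-by-pair:

``Confidence(Ti, Gj) ∝ f1 · f2 · f3 · f4 · f5``

with f1 the mean link strength of Ti to the TG cluster, f2 the mean
link strength of Gj to the TF cluster, f3 the cluster-pair Support
rescaled into [0.5, 1], f4 the link strength L(Ti,Gj) = Score rescaled
into [0.5, 1], and f5 the motif importance weight I(Ti) in [0.8, 1.2].
The factor products are min-max normalized to [0,1] and ranked.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "scale_evidence_matrix",
    "integrate_matrices",
    "tf_feature_matrix",
    "tg_feature_matrix",
    "cluster_axis",
    "compute_support",
    "select_cluster_pairs",
    "compute_confidence_table",
    "normalize_confidence",
    "rank_predictions",
]

LAYER_KINDS = ("tfbs", "kappa", "correlation", "interaction")


def scale_evidence_matrix(
    matrix: pd.DataFrame, kind: str, signed_correlation: bool = False
) -> pd.DataFrame:
    """Scale one evidence layer onto [0, 1].

    TFBS {0,1,2} maps to {0, 0.5, 1}; interaction {0..3} to {0, 1/3,
    2/3, 1}; kappa is already on [0,1]; correlation is rectified,
    ``max(r, 0)`` — a positive TF-target correlation is evidence, a
    negative one is not scored (``signed_correlation=True`` instead maps
    [-1,1] linearly onto [0,1]).  Missing entries (NaN) are imputed as 0:
    absent evidence contributes nothing.
    """
    m = matrix.astype(float)
    if kind == "tfbs":
        scaled = m / 2.0
    elif kind == "interaction":
        scaled = m / 3.0
    elif kind == "kappa":
        scaled = m.clip(0.0, 1.0)
    elif kind == "correlation":
        scaled = (m + 1.0) / 2.0 if signed_correlation else m.clip(lower=0.0)
    else:
        raise ValueError(f"unknown evidence layer kind {kind!r}; expected one of {LAYER_KINDS}")
    return scaled.fillna(0.0)


def _check_aligned(layers: dict[str, pd.DataFrame]) -> None:
    frames = list(layers.values())
    first = frames[0]
    for f in frames[1:]:
        if not f.index.equals(first.index) or not f.columns.equals(first.columns):
            raise ValueError("evidence matrices must share identical TF and gene axes")


def integrate_matrices(layers: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Sum the scaled layers and min-max rescale to the integrated Score.

    ``layers`` maps layer kind to its scaled matrix; all four matrices
    must share both axes.  The entry-wise sum is normalized over the
    full matrix so Score spans [0, 1]; a constant all-zero sum stays 0,
    a constant positive sum maps to 1 (every pair equally supported).
    """
    unknown = set(layers) - set(LAYER_KINDS)
    if unknown:
        raise ValueError(f"unknown layer kind(s) {sorted(unknown)}")
    _check_aligned(layers)
    total = sum(layers.values())
    arr = total.to_numpy(dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        scaled = np.zeros_like(arr) if hi == 0 else np.ones_like(arr)
    else:
        scaled = (arr - lo) / (hi - lo)
    return pd.DataFrame(scaled, index=total.index, columns=total.columns)


def tf_feature_matrix(layers: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """TF x (4 * n_genes) feature rows: the scaled layers side by side."""
    _check_aligned(layers)
    parts = [layers[k].add_suffix(f"::{k}") for k in LAYER_KINDS if k in layers]
    return pd.concat(parts, axis=1)


def tg_feature_matrix(layers: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Gene x (4 * n_tfs) feature rows: the scaled layers transposed."""
    _check_aligned(layers)
    parts = [layers[k].T.add_suffix(f"::{k}") for k in LAYER_KINDS if k in layers]
    return pd.concat(parts, axis=1)


def cluster_axis(
    features: pd.DataFrame,
    n_clusters: int | None = None,
    cut_height: float | None = None,
) -> pd.Series:
    """Agglomerative (average linkage, Euclidean) grouping of axis items.

    Returns integer cluster labels indexed by item.  With neither
    ``n_clusters`` nor ``cut_height`` given, the cut defaults to
    ``ceil(n_items / 8)`` clusters — small co-regulated groups.
    """
    n = len(features)
    if n < 1:
        raise ValueError("nothing to cluster")
    if n_clusters is not None and n_clusters > n:
        raise ValueError(f"requested {n_clusters} clusters for {n} items")
    if n == 1:
        return pd.Series([1], index=features.index)
    z = linkage(features.to_numpy(dtype=float), method="average", metric="euclidean")
    if cut_height is not None:
        labels = fcluster(z, t=cut_height, criterion="distance")
    else:
        if n_clusters is None:
            n_clusters = max(1, math.ceil(n / 8))
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=features.index)


def compute_support(ct: list[str], cg: list[str], score: pd.DataFrame) -> float:
    """Mean integrated Score over a TF cluster x TG cluster block."""
    ct, cg = list(ct), list(cg)
    if len(ct) == 0 or len(cg) == 0:
        raise ValueError("cluster pair has an empty side")
    rows = score.index.get_indexer(ct)
    cols = score.columns.get_indexer(cg)
    if (rows < 0).any() or (cols < 0).any():
        raise KeyError("cluster members missing from the score matrix")
    return float(score.values[np.ix_(rows, cols)].mean())


def select_cluster_pairs(
    score: pd.DataFrame,
    tf_labels: pd.Series,
    tg_labels: pd.Series,
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Support of every (TF cluster, TG cluster) pair, gated at ``threshold``."""
    rows = []
    for ct_id in sorted(tf_labels.unique()):
        ct = list(tf_labels.index[tf_labels == ct_id])
        for cg_id in sorted(tg_labels.unique()):
            cg = list(tg_labels.index[tg_labels == cg_id])
            support = compute_support(ct, cg, score)
            rows.append(
                {
                    "tf_cluster": ct_id,
                    "tg_cluster": cg_id,
                    "m": len(ct),
                    "n": len(cg),
                    "support": support,
                    "selected": support >= threshold,
                }
            )
    return pd.DataFrame(rows)


def _link_strength(score: np.ndarray) -> np.ndarray:
    """L: Score rescaled into [0.5, 1]."""
    return 0.5 + 0.5 * score


def compute_confidence_table(
    score: pd.DataFrame,
    tf_labels: pd.Series,
    tg_labels: pd.Series,
    pairs: pd.DataFrame,
    importance: pd.Series | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Confidence for every TF-TG pair inside the selected cluster pairs.

    ``importance`` maps TF -> weight I in [0.8, 1.2]; TFs without an
    entry default to the neutral 1.0 with a warning.  The five equally
    weighted factors multiply into ``confidence_raw`` which is min-max
    normalized to [0,1] over all scored pairs (an all-equal table maps
    to 1.0).  ``normalize=False`` leaves the normalization to the
    caller — the pipeline normalizes globally over the scored pairs of
    all co-expression clusters together, so confidences are comparable
    across clusters (see :func:`normalize_confidence`).
    """
    if importance is None:
        importance = pd.Series(dtype=float)
    missing_importance: set[str] = set()
    rows = []
    for pair in pairs[pairs["selected"]].itertuples():
        ct = list(tf_labels.index[tf_labels == pair.tf_cluster])
        cg = list(tg_labels.index[tg_labels == pair.tg_cluster])
        block = _link_strength(score.loc[ct, cg].to_numpy(dtype=float))
        f1 = block.mean(axis=1)  # TF connectivity to the whole TG cluster
        f2 = block.mean(axis=0)  # gene connectivity to the whole TF cluster
        f3 = 0.5 + 0.5 * pair.support
        for i, tf in enumerate(ct):
            if tf in importance.index:
                imp = float(importance[tf])
            else:
                imp = 1.0
                missing_importance.add(tf)
            for j, gene in enumerate(cg):
                f4 = block[i, j]
                raw = f1[i] * f2[j] * f3 * f4 * imp
                rows.append(
                    {
                        "tf": tf,
                        "gene": gene,
                        "tf_cluster": pair.tf_cluster,
                        "tg_cluster": pair.tg_cluster,
                        "f1": f1[i],
                        "f2": f2[j],
                        "f3": f3,
                        "f4": f4,
                        "f5": imp,
                        "confidence_raw": raw,
                    }
                )
    if missing_importance:
        warnings.warn(
            f"no importance weight for TF(s) {sorted(missing_importance)}; defaulting to 1.0"
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "tf", "gene", "tf_cluster", "tg_cluster",
            "f1", "f2", "f3", "f4", "f5", "confidence_raw",
        ],
    )
    if out.empty:
        out["confidence"] = pd.Series(dtype=float)
        return out
    if normalize:
        out = normalize_confidence(out)
    return out


def normalize_confidence(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max map ``confidence_raw`` onto a ``confidence`` column in [0,1].

    A degenerate all-equal table maps to 1.0 (every pair equally
    supported).
    """
    out = table.copy()
    if out.empty:
        out["confidence"] = pd.Series(dtype=float)
        return out
    raw = out["confidence_raw"].to_numpy(dtype=float)
    lo, hi = raw.min(), raw.max()
    out["confidence"] = 1.0 if hi == lo else (raw - lo) / (hi - lo)
    return out


def rank_predictions(confidence: pd.DataFrame, cutoff: float | None = None) -> pd.DataFrame:
    """Rank scored pairs by descending confidence (ties: TF id, gene id).

    Pairs below ``cutoff`` are excluded; ``rank`` is 1-based.
    """
    if confidence.empty:
        out = confidence.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    out = confidence.sort_values(
        ["confidence", "tf", "gene"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    if cutoff is not None:
        out = out[out["confidence"] >= cutoff].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
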