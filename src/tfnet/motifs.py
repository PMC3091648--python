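"""Promoter motif (TFBS) scoring, over-representation and importance.

Conserved motif hits in a gene's regulatory windows are condensed into a
three-level TFBS score per (motif family, gene): 0 absent, 1 a single
conserved occurrence, 2 multiple occurrences.  Per co-expression
cluster, motif families are ranked by over-representation among
hit-bearing genes in the upstream conserved-region window and in the
proximal promoter, and by their mean hit frequency; the average rank is
normalized into a heatmap score on [-2.5, 2.5] and an importance weight
I on [0.8, 1.2] that later modulates prediction confidence.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "score_tfbs_matrix",
    "test_overrepresentation",
    "compute_frequency_rank",
    "rank_motif_importance",
]

HIT_COLUMNS = ["gene", "motif", "position", "region_class", "conserved"]


def _conserved(hits: pd.DataFrame, region_class: str | None = None) -> pd.DataFrame:
    out = hits[hits["conserved"].astype(bool)]
    if region_class is not None:
        out = out[out["region_class"] == region_class]
    return out


def score_tfbs_matrix(
    hits: pd.DataFrame,
    genes: list[str],
    motifs: list[str] | None = None,
    region_class: str | None = None,
) -> pd.DataFrame:
    """Motif-family x gene TFBS matrix with entries in {0, 1, 2}.

    Only conserved hits count; 1 marks a single conserved occurrence in
    the gene's regulatory windows, 2 marks two or more.  Hits for genes
    outside ``genes`` are skipped with a warning.
    """
    genes = list(genes)
    conserved = _conserved(hits, region_class)
    unknown = set(conserved["gene"]) - set(genes)
    if unknown:
        warnings.warn(
            f"skipping motif hits for {len(unknown)} unknown gene(s), e.g. {sorted(unknown)[:3]}"
        )
        conserved = conserved[conserved["gene"].isin(genes)]
    if motifs is None:
        motifs = sorted(conserved["motif"].unique())
    counts = conserved.groupby(["motif", "gene"]).size()
    out = pd.DataFrame(0, index=list(motifs), columns=genes, dtype=int)
    for (motif, gene), c in counts.items():
        if motif in out.index:
            out.loc[motif, gene] = min(int(c), 2)
    return out


def test_overrepresentation(
    hits: pd.DataFrame,
    cluster_genes: set[str] | list[str],
    background_genes: set[str] | list[str] | None = None,
    region_class: str | None = None,
    alpha: float = 0.05,
    motifs: list[str] | None = None,
) -> pd.DataFrame:
    """Per-motif over-representation of hit-bearing genes in a cluster.

    One-sided hypergeometric test of the number of cluster genes with at
    least one conserved hit against the background (by default: every
    gene in the hit-table universe outside the cluster).  Returns a
    frame with ``p_value``, fractional ``rank`` (ascending p, ties
    averaged) and ``enriched`` (p <= alpha).  The conserved-region
    analysis is conventionally run at alpha = 0.005, the proximal
    promoter analysis at alpha = 0.05.
    """
    cluster = set(cluster_genes)
    if not cluster:
        raise ValueError("cluster is empty")
    conserved = _conserved(hits, region_class)
    if background_genes is None:
        background = set(hits["gene"].unique()) - cluster
    else:
        background = set(background_genes) - cluster
    if not background:
        raise ValueError("background gene set is empty")
    if motifs is None:
        motifs = sorted(conserved["motif"].unique())
    hit_genes = conserved.groupby("motif")["gene"].agg(set)
    n_total = len(cluster) + len(background)
    rows = []
    for motif in motifs:
        bearing = hit_genes.get(motif, set())
        k = len(bearing & cluster)
        big_k = k + len(bearing & background)
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, len(cluster)))
        rows.append({"motif": motif, "n_cluster_hit": k, "n_background_hit": big_k - k,
                     "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["rank"] = stats.rankdata(out["p_value"], method="average")
    out["enriched"] = out["p_value"] <= alpha
    return out.set_index("motif")


def compute_frequency_rank(
    hits: pd.DataFrame,
    cluster_genes: set[str] | list[str],
    promoter_enriched: set[str] | list[str],
    motifs: list[str] | None = None,
    region_class: str | None = "proximal",
) -> pd.DataFrame:
    """Mean conserved-hit frequency per cluster gene, ranked.

    Frequency is only determined (non-ND) for motifs enriched in the
    proximal promoter analysis; the rest get NaN frequency and rank and
    are excluded from the frequency ranking.  Higher frequency ranks
    better (rank 1).
    """
    cluster = set(cluster_genes)
    if not cluster:
        raise ValueError("cluster is empty")
    enriched = set(promoter_enriched)
    conserved = _conserved(hits, region_class)
    conserved = conserved[conserved["gene"].isin(cluster)]
    counts = conserved.groupby("motif").size()
    if motifs is None:
        motifs = sorted(set(hits["motif"].unique()) | enriched)
    freq = pd.Series(
        [counts.get(m, 0) / len(cluster) if m in enriched else np.nan for m in motifs],
        index=list(motifs),
        dtype=float,
    )
    out = pd.DataFrame({"frequency": freq})
    determined = out["frequency"].notna()
    ranks = stats.rankdata(-out.loc[determined, "frequency"], method="average")
    out["rank"] = np.nan
    out.loc[determined, "rank"] = ranks
    return out


def rank_motif_importance(ranks: pd.DataFrame) -> pd.DataFrame:
    """Combine the three per-motif rankings into relative importance.

    ``ranks`` has columns ``rank_ecr``, ``rank_promoter`` and
    ``rank_frequency`` (NaN = not determined).  The average of the
    available ranks is mapped linearly onto the heatmap scale [-2.5, 2.5]
    (best average rank -> 2.5) and onto the importance weight
    I in [0.8, 1.2] (best -> 1.2).  A single motif, or an all-tied set,
    sits at the midpoint (heatmap 0, I = 1.0); motifs with no determined
    rank at all are dropped with a warning.
    """
    required = {"rank_ecr", "rank_promoter", "rank_frequency"}
    missing = required - set(ranks.columns)
    if missing:
        raise ValueError(f"ranks frame missing columns: {sorted(missing)}")
    avg = ranks[["rank_ecr", "rank_promoter", "rank_frequency"]].mean(axis=1, skipna=True)
    undefined = avg.isna()
    if undefined.any():
        warnings.warn(
            f"dropping {int(undefined.sum())} motif(s) with no determined rank in any analysis"
        )
        avg = avg[~undefined]
    out = pd.DataFrame({"average_rank": avg})
    lo, hi = avg.min(), avg.max()
    if len(avg) == 0:
        out["heatmap_score"] = []
        out["weight"] = []
        return out
    if hi == lo:
        rel = pd.Series(0.5, index=avg.index)
    else:
        rel = (hi - avg) / (hi - lo)  # 1 = best (lowest average rank)
    out["heatmap_score"] = (-2.5 + 5.0 * rel).clip(-2.5, 2.5)
    out["weight"] = (0.8 + 0.4 * rel).clip(0.8, 1.2)
    return out.sort_values("average_rank", kind="stable")
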