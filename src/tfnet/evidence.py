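"""Expression-correlation and curated-interaction evidence layers."""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np
import pandas as pd

from .containers import EvidenceRecord

__all__ = ["compute_correlation_matrix", "score_interactions"]


def compute_correlation_matrix(
    tf_profiles: pd.DataFrame, gene_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation between each TF profile and each gene profile.

    Profiles must cover the same samples (>= 3).  Pairs involving a
    constant profile have no defined correlation and are flagged missing
    (NaN) rather than set to 0.
    """
    if not tf_profiles.columns.equals(gene_profiles.columns):
        raise ValueError("TF and gene profiles must cover identical sample sets")
    if tf_profiles.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    t = tf_profiles.to_numpy(dtype=float)
    g = gene_profiles.to_numpy(dtype=float)
    tc = t - t.mean(axis=1, keepdims=True)
    gc = g - g.mean(axis=1, keepdims=True)
    tn = np.sqrt((tc**2).sum(axis=1))
    gn = np.sqrt((gc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tc @ gc.T) / np.outer(tn, gn)
    r[~np.isfinite(r)] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=tf_profiles.index, columns=gene_profiles.index)


def score_interactions(
    records: list[EvidenceRecord], tfs: list[str], genes: list[str]
) -> pd.DataFrame:
    """TF x gene interaction-evidence matrix with entries in {0, 1, 2, 3}.

    Per pair, the maximum applicable level: 0 no evidence; 1 any single
    computational / high-throughput source or database co-citation <= 10;
    2 evidence from more than one resource with co-citation >= 10;
    3 direct experimental evidence, or the multi-source class (evidence
    curated from multiple resources).  Records naming unknown TFs or
    genes are skipped with a warning.
    """
    tfs, genes = list(tfs), list(genes)
    tf_set, gene_set = set(tfs), set(genes)
    by_pair: dict[tuple[str, str], list[EvidenceRecord]] = defaultdict(list)
    skipped = 0
    for rec in records:
        if rec.tf not in tf_set or rec.gene not in gene_set:
            skipped += 1
            continue
        by_pair[(rec.tf, rec.gene)].append(rec)
    if skipped:
        warnings.warn(f"skipping {skipped} evidence record(s) with unknown identifiers")
    out = pd.DataFrame(0, index=tfs, columns=genes, dtype=int)
    for (tf, gene), recs in by_pair.items():
        classes = {r.source_class for r in recs}
        resources = {r.provenance if r.provenance is not None else r.source_class for r in recs}
        max_cocite = max(r.co_citations for r in recs)
        level = 1  # any record at all is at least single-source evidence
        if len(resources) >= 2 and max_cocite >= 10:
            level = 2
        if "direct-experimental" in classes or "multi-source" in classes:
            level = 3
        out.loc[tf, gene] = level
    return out
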