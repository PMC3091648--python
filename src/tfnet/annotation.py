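"""Annotation-sharing (kappa) similarity and per-cluster term enrichment.

Two genes that share annotation terms are likely involved in similar
biological processes; Cohen's kappa over the term presence/absence
vectors quantifies that agreement, corrected for the agreement expected
by chance given how many terms each gene carries.  Cluster-level themes
are found with a one-sided Fisher exact (hypergeometric) test against
the rest of the annotated universe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationCatalog

__all__ = [
    "compute_kappa",
    "compute_kappa_matrix",
    "enrich_cluster_terms",
]


def compute_kappa(
    a: frozenset[str] | set[str],
    b: frozenset[str] | set[str],
    universe_size: int,
) -> float:
    """Cohen's kappa between two annotation term sets.

    The 2x2 agreement table counts terms annotated to both genes, to one
    only, and to neither, out of a ``universe_size``-term universe.
    Negative raw kappa (observed agreement below chance) is clamped to 0
    so the statistic ranges over [0, 1].
    """
    a, b = frozenset(a), frozenset(b)
    if not a or not b:
        raise ValueError("both genes must carry at least one annotation term")
    if universe_size < len(a | b):
        raise ValueError("universe_size smaller than the union of the two term sets")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = universe_size - len(a | b)
    n = float(universe_size)
    po = (n11 + n00) / n
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    if pe == 1.0:
        return 1.0
    kappa = (po - pe) / (1.0 - pe)
    return float(min(1.0, max(0.0, kappa)))


def compute_kappa_matrix(
    tfs: list[str], genes: list[str], catalog: AnnotationCatalog
) -> pd.DataFrame:
    """TF x gene kappa similarity matrix.

    Pairs where either side carries no annotation are recorded as
    missing (NaN), not as 0 — absence of annotation is no evidence of
    dissimilarity.
    """
    if not catalog:
        raise ValueError("annotation catalog is empty")
    universe_size = catalog.n_terms
    out = pd.DataFrame(np.nan, index=list(tfs), columns=list(genes), dtype=float)
    tf_terms = {t: catalog.terms_of(t) for t in tfs}
    gene_terms = {g: catalog.terms_of(g) for g in genes}
    for t in tfs:
        ta = tf_terms[t]
        if not ta:
            continue
        for g in genes:
            gb = gene_terms[g]
            if not gb:
                continue
            out.loc[t, g] = compute_kappa(ta, gb, universe_size)
    return out


def enrich_cluster_terms(
    cluster: set[str] | list[str],
    catalog: AnnotationCatalog,
    alpha: float = 0.01,
    min_fraction: float = 0.20,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of every term in a cluster.

    A term is ``reported`` when p < ``alpha`` and it annotates more than
    ``min_fraction`` of the cluster's genes.  The p-value is the exact
    hypergeometric upper tail P(X >= k) of drawing k term-annotated genes
    in a cluster-sized sample from the annotated universe.
    """
    cluster = set(cluster)
    if not cluster:
        return pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p_value", "cluster_fraction", "reported"]
        )
    universe = catalog.universe
    n_universe = len(universe)
    in_universe = cluster & universe
    rows = []
    for term in sorted(catalog.terms):
        term_genes = catalog.genes_of(term)
        k = len(term_genes & in_universe)
        big_k = len(term_genes)
        n = len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n))
        frac = k / len(cluster)
        rows.append(
            {
                "term": term,
                "k": k,
                "K": big_k,
                "n": n,
                "N": n_universe,
                "p_value": min(p, 1.0),
                "cluster_fraction": frac,
                "reported": (p < alpha) and (frac > min_fraction),
            }
        )
    return pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
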