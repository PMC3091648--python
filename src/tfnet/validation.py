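"""Validation of ranked predictions.

Three complementary checks: exact binomial overlap of predicted targets
with an independent perturbation-response gene list (high-confidence
predictions, score > 0.55, should overlap the response far beyond the
background rate; low-confidence ones, score < 0.45, should not), rank
percentiles of externally known TF-target pairs, and — for synthetic
runs where the planted network is known — edge-level precision/recall
and ranking AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .containers import GroundTruthNetwork

__all__ = [
    "OverlapTestResult",
    "binomial_overlap_test",
    "known_pair_rank_report",
    "recovery_metrics",
]

POSITIVE_SCORE_CUTOFF = 0.55
NEGATIVE_SCORE_CUTOFF = 0.45


@dataclass(frozen=True)
class OverlapTestResult:
    """Exact upper-tail binomial overlap test."""

    n_predicted: int
    n_overlap: int
    background_rate: float
    p_value: float


def binomial_overlap_test(
    predicted: set[str] | list[str],
    response: set[str] | list[str],
    universe: set[str] | list[str],
) -> OverlapTestResult:
    """P(X >= n_overlap) for X ~ Binomial(n_predicted, |response|/|universe|).

    The background rate is the response-set fraction of the analysis
    universe; the tail is computed exactly.  An empty predicted set, or
    an overlap of 0, gives p = 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    predicted = set(predicted) & universe
    response = set(response) & universe
    rate = len(response) / len(universe)
    n = len(predicted)
    k = len(predicted & response)
    p = 1.0 if k == 0 else float(stats.binom.sf(k - 1, n, rate))
    return OverlapTestResult(
        n_predicted=n, n_overlap=k, background_rate=rate, p_value=min(p, 1.0)
    )


def known_pair_rank_report(
    ranked_edges: pd.DataFrame, known_pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Worst rank percentile of each TF's known targets among predictions.

    ``ranked_edges`` carries columns ``tf``, ``gene`` and ``rank``
    (1-based over the prediction list).  Known pairs absent from the
    prediction set are counted per TF in ``n_missing``.
    """
    if not known_pairs:
        return pd.DataFrame(
            columns=["tf", "n_known", "n_found", "n_missing", "worst_rank", "worst_percentile"]
        )
    n_total = len(ranked_edges)
    rank_of = {(r.tf, r.gene): r.rank for r in ranked_edges.itertuples()}
    per_tf: dict[str, list[int]] = {}
    missing: dict[str, int] = {}
    for tf, gene in known_pairs:
        per_tf.setdefault(tf, [])
        missing.setdefault(tf, 0)
        if (tf, gene) in rank_of:
            per_tf[tf].append(int(rank_of[(tf, gene)]))
        else:
            missing[tf] += 1
    rows = []
    for tf in sorted(per_tf):
        ranks = per_tf[tf]
        worst = max(ranks) if ranks else None
        rows.append(
            {
                "tf": tf,
                "n_known": len(ranks) + missing[tf],
                "n_found": len(ranks),
                "n_missing": missing[tf],
                "worst_rank": worst,
                "worst_percentile": (100.0 * worst / n_total) if worst is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def recovery_metrics(
    confidence: pd.DataFrame,
    truth: GroundTruthNetwork,
    cutoffs: np.ndarray | None = None,
) -> dict:
    """Edge-level recovery of the planted network.

    Every (TF, gene) pair over the planted axes is scored with its
    maximum predicted confidence (0 when never scored) and labelled by
    planted-edge membership; returns rank AUROC plus precision/recall at
    each cutoff of the grid (default 0, 0.1, ..., 0.9).
    """
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.0, 1.0, 0.1), 10)
    known = set(truth.tfs) | set(truth.genes)
    extra = (set(confidence.get("tf", [])) | set(confidence.get("gene", []))) - known
    if extra:
        raise ValueError(f"predictions reference identifiers outside the truth: {sorted(extra)[:5]}")
    pair_score: dict[tuple[str, str], float] = {}
    if not confidence.empty:
        grouped = confidence.groupby(["tf", "gene"])["confidence"].max()
        pair_score = grouped.to_dict()
    scores, labels = [], []
    for tf in truth.tfs:
        for gene in truth.genes:
            scores.append(pair_score.get((tf, gene), 0.0))
            labels.append((tf, gene) in truth.edges)
    scores_a = np.asarray(scores)
    labels_a = np.asarray(labels)
    auroc = float(roc_auc_score(labels_a, scores_a)) if 0 < labels_a.sum() < len(labels_a) else np.nan
    pr_rows = []
    for c in cutoffs:
        pred = scores_a >= c if c > 0 else scores_a > 0
        tp = int((pred & labels_a).sum())
        fp = int((pred & ~labels_a).sum())
        fn = int((~pred & labels_a).sum())
        pr_rows.append(
            {
                "cutoff": float(c),
                "n_predicted": int(pred.sum()),
                "precision": tp / (tp + fp) if tp + fp else np.nan,
                "recall": tp / (tp + fn) if tp + fn else np.nan,
            }
        )
    return {"auroc": auroc, "precision_recall": pd.DataFrame(pr_rows)}
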