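"""Differential-expression filtering of perturbation experiments.

Candidate genes are those that respond to the perturbations: per
experiment an unpaired two-group t-test (p <= 0.05), an absolute
fold-change of at least 1.5 on the linear scale, and at least 67% Present
detection calls; genes flagged in enough distinct experiments survive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionDataset

__all__ = ["test_differential_expression", "select_candidate_genes"]


def _group_values(data: ExpressionDataset, experiment: str, group: str) -> pd.DataFrame:
    samples = data.samples_of(experiment, group)
    if len(samples) < 2:
        raise ValueError(
            f"experiment {experiment!r} has {len(samples)} {group} sample(s); need >= 2"
        )
    return data.values[samples]


def test_differential_expression(
    data: ExpressionDataset,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    present_min: float = 0.67,
    equal_var: bool = True,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Per-(gene, experiment) differential calls.

    Returns a DataFrame with columns ``gene``, ``experiment``,
    ``p_value``, ``fold_change`` (signed mutant/control ratio of linear
    group means), ``present_fraction`` (over all samples of the
    experiment) and ``flagged`` — the conjunction of the three filters.

    The t statistic uses the pooled-variance (Student) form by default;
    ``equal_var=False`` switches to Welch.  Degenerate zero-variance
    groups yield p = 0 when the group means differ and p = 1 when equal.
    """
    frames = []
    for experiment in data.experiments:
        mut = _group_values(data, experiment, "mutant")
        ctl = _group_values(data, experiment, "control")
        mut_a, ctl_a = mut.to_numpy(), ctl.to_numpy()
        t, p = stats.ttest_ind(mut_a, ctl_a, axis=1, equal_var=equal_var)
        mean_diff = mut_a.mean(axis=1) - ctl_a.mean(axis=1)
        degenerate = ~np.isfinite(p)
        p = np.where(degenerate, np.where(mean_diff == 0.0, 1.0, 0.0), p)

        lin_mut = np.power(log_base, mut_a).mean(axis=1)
        lin_ctl = np.power(log_base, ctl_a).mean(axis=1)
        fold_change = lin_mut / lin_ctl

        all_samples = data.samples_of(experiment)
        present_fraction = data.present[all_samples].to_numpy().mean(axis=1)

        abs_ratio = np.maximum(fold_change, 1.0 / fold_change)
        flagged = (p <= alpha) & (abs_ratio >= fc_min) & (present_fraction >= present_min)
        frames.append(
            pd.DataFrame(
                {
                    "gene": data.values.index,
                    "experiment": experiment,
                    "p_value": p,
                    "fold_change": fold_change,
                    "present_fraction": present_fraction,
                    "flagged": flagged,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def select_candidate_genes(calls: pd.DataFrame, min_experiments: int = 5) -> list[str]:
    """Genes flagged in at least ``min_experiments`` distinct experiments."""
    if calls.empty:
        return []
    flagged = calls[calls["flagged"]]
    counts = flagged.groupby("gene")["experiment"].nunique()
    return sorted(counts.index[counts >= min_experiments])
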