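"""Evidence fusion: scaling, Score, axis clustering, Support, Confidence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tfnet.integration import (
    cluster_axis,
    compute_confidence_table,
    compute_support,
    integrate_matrices,
    normalize_confidence,
    rank_predictions,
    scale_evidence_matrix,
    select_cluster_pairs,
    tf_feature_matrix,
    tg_feature_matrix,
)


def frame(values, tfs=None, genes=None):
    values = np.atleast_2d(values)
    tfs = tfs or [f"T{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=tfs, columns=genes, dtype=float)


def random_layers(rng, n_tf, n_gene):
    return {
        "tfbs": frame(rng.integers(0, 3, (n_tf, n_gene))),
        "kappa": frame(rng.random((n_tf, n_gene))),
        "correlation": frame(rng.uniform(-1, 1, (n_tf, n_gene))),
        "interaction": frame(rng.integers(0, 4, (n_tf, n_gene))),
    }


class TestScaling:
    def test_layer_endpoint_maps(self):
        assert scale_evidence_matrix(frame([[2]]), "tfbs").iloc[0, 0] == 1.0
        assert scale_evidence_matrix(frame([[1]]), "tfbs").iloc[0, 0] == 0.5
        assert scale_evidence_matrix(frame([[3]]), "interaction").iloc[0, 0] == 1.0
        assert scale_evidence_matrix(frame([[1]]), "interaction").iloc[0, 0] == pytest.approx(1 / 3)
        assert scale_evidence_matrix(frame([[-0.9]]), "correlation").iloc[0, 0] == 0.0
        assert scale_evidence_matrix(frame([[0.7]]), "correlation").iloc[0, 0] == 0.7

    def test_signed_correlation_mode(self):
        out = scale_evidence_matrix(frame([[-1.0, 0.0, 1.0]]), "correlation",
                                    signed_correlation=True)
        np.testing.assert_allclose(out.to_numpy()[0], [0.0, 0.5, 1.0])

    def test_missing_entries_imputed_to_zero(self):
        out = scale_evidence_matrix(frame([[np.nan, 0.5]]), "kappa")
        np.testing.assert_allclose(out.to_numpy()[0], [0.0, 0.5])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="layer kind"):
            scale_evidence_matrix(frame([[1]]), "vibes")


class TestIntegration:
    def test_maximal_pair_scores_one_and_zero_stays_zero(self):
        layers = {
            "tfbs": frame([[2, 0], [1, 0]]) / 2.0,
            "kappa": frame([[1.0, 0.0], [0.2, 0.0]]),
            "correlation": frame([[0.9, 0.0], [0.1, 0.0]]),
            "interaction": frame([[3, 0], [1, 0]]) / 3.0,
        }
        score = integrate_matrices(layers)
        assert score.loc["T0", "g0"] == 1.0
        assert score.loc["T0", "g1"] == 0.0
        assert score.to_numpy().min() >= 0 and score.to_numpy().max() <= 1

    def test_two_by_two_hand_computed(self):
        layers = {
            "tfbs": frame([[1.0, 0.0], [0.5, 0.5]]),
            "kappa": frame([[0.8, 0.2], [0.4, 0.6]]),
            "correlation": frame([[0.6, 0.0], [0.2, 0.4]]),
            "interaction": frame([[1.0, 0.0], [1 / 3, 2 / 3]]),
        }
        total = sum(layers.values()).to_numpy()  # [[3.4, 0.2], [~1.433, 2.1667]]
        expected = (total - total.min()) / (total.max() - total.min())
        np.testing.assert_allclose(integrate_matrices(layers).to_numpy(), expected, atol=1e-12)

    def test_axis_mismatch_raises(self):
        layers = {
            "tfbs": frame([[1.0]]),
            "kappa": frame([[1.0]], tfs=["other"]),
            "correlation": frame([[1.0]]),
            "interaction": frame([[1.0]]),
        }
        with pytest.raises(ValueError, match="identical TF and gene axes"):
            integrate_matrices(layers)

    def test_score_bounds_on_random_inputs(self, rng):
        for _ in range(100):
            layers = random_layers(rng, int(rng.integers(2, 6)), int(rng.integers(2, 8)))
            scaled = {k: scale_evidence_matrix(m, k) for k, m in layers.items()}
            score = integrate_matrices(scaled)
            arr = score.to_numpy()
            assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestAxisClustering:
    def test_identical_rows_cluster_together(self):
        features = frame([[1, 0, 1], [1, 0, 1], [0, 1, 0], [0, 1, 0]])
        labels = cluster_axis(features, n_clusters=2)
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[2] == labels.iloc[3]
        assert labels.iloc[0] != labels.iloc[2]

    def test_orthogonal_blocks_merge_within_block_first(self):
        features = frame([[1, 1, 0, 0], [1, 0.9, 0, 0], [0, 0, 1, 1], [0, 0, 1, 0.9]])
        labels = cluster_axis(features, n_clusters=2)
        assert labels.iloc[0] == labels.iloc[1] and labels.iloc[2] == labels.iloc[3]

    def test_singletons_when_clusters_equal_items(self):
        features = frame([[0.0, 0], [1, 0], [2, 0]])
        labels = cluster_axis(features, n_clusters=3)
        assert labels.nunique() == 3

    def test_too_many_clusters_raises(self):
        with pytest.raises(ValueError, match="clusters"):
            cluster_axis(frame([[1, 2], [3, 4]]), n_clusters=3)

    def test_feature_concatenation_axes(self, rng):
        layers = {k: scale_evidence_matrix(m, k)
                  for k, m in random_layers(rng, 3, 5).items()}
        assert tf_feature_matrix(layers).shape == (3, 20)
        assert tg_feature_matrix(layers).shape == (5, 12)


class TestSupport:
    def test_extremes(self):
        assert compute_support(["T0"], ["g0"], frame([[1.0]])) == 1.0
        assert compute_support(["T0"], ["g0"], frame([[0.0]])) == 0.0

    def test_block_mean_worked_example(self):
        score = frame([[1.0, 0.5, 0.0], [0.5, 0.5, 0.5]])
        assert compute_support(["T0", "T1"], ["g0", "g1", "g2"], score) == pytest.approx(0.5)

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError, match="empty"):
            compute_support([], ["g0"], frame([[1.0]]))

    def test_matches_bruteforce_double_sum_all_small_pairs(self, rng):
        score = frame(rng.random((5, 5)))
        tfs, genes = list(score.index), list(score.columns)
        for m in range(1, 6):
            for n in range(1, 6):
                for ct in itertools.combinations(tfs, m):
                    for cg in itertools.combinations(genes, n):
                        brute = sum(score.loc[t, g] for t in ct for g in cg) / (m * n)
                        assert compute_support(list(ct), list(cg), score) == pytest.approx(
                            brute, abs=1e-12
                        )

    @pytest.mark.parametrize("support,selected", [(0.25, True), (0.24, False)])
    def test_selection_boundary(self, support, selected):
        score = frame([[support]])
        labels_tf = pd.Series([1], index=["T0"])
        labels_tg = pd.Series([1], index=["g0"])
        pairs = select_cluster_pairs(score, labels_tf, labels_tg, threshold=0.25)
        assert bool(pairs.loc[0, "selected"]) is selected


class TestConfidence:
    def make_inputs(self, score_values, importance=None):
        score = frame(score_values)
        tf_labels = pd.Series(1, index=score.index)
        tg_labels = pd.Series(1, index=score.columns)
        pairs = select_cluster_pairs(score, tf_labels, tg_labels, threshold=0.0)
        return score, tf_labels, tg_labels, pairs, importance

    def test_saturated_scores_give_confidence_one(self):
        score, tf_l, tg_l, pairs, _ = self.make_inputs([[1.0, 1.0], [1.0, 1.0]])
        imp = pd.Series(1.2, index=score.index)
        table = compute_confidence_table(score, tf_l, tg_l, pairs, imp)
        assert (table["confidence"] == 1.0).all()
        assert (table["f4"] == 1.0).all() and (table["f5"] == 1.2).all()

    def test_zero_score_keeps_positive_floors(self):
        score, tf_l, tg_l, pairs, _ = self.make_inputs([[0.0, 1.0]])
        table = compute_confidence_table(score, tf_l, tg_l, pairs,
                                         pd.Series(1.0, index=score.index))
        zero_row = table[table["gene"] == "g0"].iloc[0]
        assert zero_row["f4"] == 0.5
        assert zero_row["confidence_raw"] > 0.0

    def test_two_by_two_hand_computed_factors(self):
        score, tf_l, tg_l, pairs, _ = self.make_inputs([[1.0, 0.5], [0.0, 0.5]])
        imp = pd.Series({"T0": 1.2, "T1": 0.8})
        table = compute_confidence_table(score, tf_l, tg_l, pairs, imp).set_index(["tf", "gene"])
        support = (1.0 + 0.5 + 0.0 + 0.5) / 4
        l = lambda s: 0.5 + 0.5 * s
        row = table.loc[("T0", "g0")]
        f1 = (l(1.0) + l(0.5)) / 2
        f2 = (l(1.0) + l(0.0)) / 2
        f3 = 0.5 + 0.5 * support
        assert row["f1"] == pytest.approx(f1)
        assert row["f2"] == pytest.approx(f2)
        assert row["f3"] == pytest.approx(f3)
        assert row["confidence_raw"] == pytest.approx(f1 * f2 * f3 * l(1.0) * 1.2)

    def test_missing_importance_warns_and_defaults(self):
        score, tf_l, tg_l, pairs, _ = self.make_inputs([[0.5, 1.0]])
        with pytest.warns(UserWarning, match="importance"):
            table = compute_confidence_table(score, tf_l, tg_l, pairs, pd.Series(dtype=float))
        assert (table["f5"] == 1.0).all()

    def test_factor_bounds_on_random_inputs(self, rng):
        for _ in range(100):
            n_tf, n_gene = int(rng.integers(1, 5)), int(rng.integers(1, 6))
            score = frame(rng.random((n_tf, n_gene)))
            tf_l = pd.Series(rng.integers(1, 3, n_tf), index=score.index)
            tg_l = pd.Series(rng.integers(1, 3, n_gene), index=score.columns)
            pairs = select_cluster_pairs(score, tf_l, tg_l, threshold=0.0)
            imp = pd.Series(rng.uniform(0.8, 1.2, n_tf), index=score.index)
            table = compute_confidence_table(score, tf_l, tg_l, pairs, imp)
            assert table["f4"].between(0.5, 1.0).all()
            assert table["f5"].between(0.8, 1.2).all()
            assert table["f1"].between(0.5, 1.0).all()
            assert table["f2"].between(0.5, 1.0).all()
            assert table["f3"].between(0.5, 1.0).all()
            assert table["confidence"].between(0.0, 1.0).all()

    def test_raising_any_evidence_never_lowers_raw_confidence(self, rng):
        layers = {k: scale_evidence_matrix(m, k) for k, m in random_layers(rng, 3, 4).items()}
        tf_l = pd.Series([1, 1, 2], index=layers["tfbs"].index)
        tg_l = pd.Series([1, 1, 2, 2], index=layers["tfbs"].columns)

        def raw_for(layers):
            score = integrate_matrices(layers)
            pairs = select_cluster_pairs(score, tf_l, tg_l, threshold=0.0)
            table = compute_confidence_table(
                score, tf_l, tg_l, pairs, pd.Series(1.0, index=score.index), normalize=False
            )
            return table.set_index(["tf", "gene"])["confidence_raw"]

        # pin one pair at the matrix maximum and one at zero so the Score
        # normalization range is fixed and the bump acts monotonically
        base_layers = {k: m.copy() for k, m in layers.items()}
        for k in base_layers:
            base_layers[k].iloc[0, 0] = 1.0
            base_layers[k].iloc[2, 3] = 0.0
        base = raw_for(base_layers)
        for kind in ("tfbs", "kappa", "correlation", "interaction"):
            bumped = {k: m.copy() for k, m in base_layers.items()}
            col = bumped[kind].columns[1]
            bumped[kind].loc[bumped[kind].index[0], col] = 1.0
            after = raw_for(bumped)
            key = (bumped[kind].index[0], col)
            assert after[key] >= base[key] - 1e-12


class TestRanking:
    def test_rank_order_and_tie_break(self):
        table = pd.DataFrame(
            {
                "tf": ["T2", "T1", "T1"],
                "gene": ["g1", "g2", "g1"],
                "confidence_raw": [0.5, 0.9, 0.5],
            }
        )
        table = normalize_confidence(table)
        ranked = rank_predictions(table)
        assert list(ranked["rank"]) == [1, 2, 3]
        assert ranked.iloc[0]["tf"] == "T1" and ranked.iloc[0]["gene"] == "g2"
        assert ranked.iloc[1]["tf"] == "T1"  # tie broken by TF then gene id

    def test_permutation_invariance(self, rng):
        table = pd.DataFrame(
            {
                "tf": [f"T{i}" for i in range(6)],
                "gene": [f"g{i}" for i in range(6)],
                "confidence_raw": rng.random(6),
            }
        )
        table = normalize_confidence(table)
        ranked = rank_predictions(table)
        shuffled = rank_predictions(table.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(
            ranked.reset_index(drop=True), shuffled.reset_index(drop=True)
        )

    def test_cutoff_above_max_empties_list(self):
        table = normalize_confidence(
            pd.DataFrame({"tf": ["T"], "gene": ["g"], "confidence_raw": [0.4]})
        )
        table["confidence"] = 0.4  # single pair: pin below the cutoff
        assert rank_predictions(table, cutoff=0.5).empty
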