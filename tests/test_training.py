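"""Focal loss, metrics, cross-validation protocol and downstream reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driverfusion import (
    AblationSpec,
    ModelConfig,
    SyntheticConfig,
    TrainConfig,
    attention_report,
    compute_metrics,
    cross_validate,
    focal_loss,
    generate,
    novel_candidates,
    prediction_table,
    preset,
    stratify_scores,
    train,
)
from driverfusion.training import _focal_loss_t, wilcoxon_fold_comparison
from driverfusion import nn


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy_at_half(self):
        assert focal_loss(np.array([0.5]), np.array([1.0]), alpha=1.0, gamma=0.0) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_perfect_prediction_vanishes(self):
        assert focal_loss(np.array([1.0 - 1e-9]), np.array([1.0])) < 1e-6

    def test_hand_evaluated_gamma_two(self):
        # (1 - 0.9)^2 * (-ln 0.9)
        expected = 0.01 * -np.log(0.9)
        assert focal_loss(np.array([0.9]), np.array([1.0]), alpha=1.0, gamma=2.0) == pytest.approx(
            expected, rel=1e-9
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=20), st.integers(0, 2**31 - 1))
    def test_gamma_zero_equals_bce_everywhere(self, probs, seed):
        p = np.asarray(probs)
        y = (np.random.default_rng(seed).random(len(p)) < 0.5).astype(float)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert focal_loss(p, y, alpha=1.0, gamma=0.0) == pytest.approx(bce, abs=1e-9)

    def test_autograd_path_matches_numpy_reference(self, rng):
        p = rng.uniform(0.05, 0.95, size=12)
        y = (rng.random(12) < 0.4).astype(float)
        t = _focal_loss_t(nn.Tensor(p), y, alpha=1.0, gamma=1.5)
        assert t.item() == pytest.approx(focal_loss(p, y, 1.0, 1.5), abs=1e-12)

    def test_empty_labeled_set_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([]), np.array([]))


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5)
        assert m == {"auroc": 1.0, "auprc": 1.0, "f1": 1.0}

    def test_inverted_ranking(self):
        assert compute_metrics([0.6, 0.4], [0, 1], 0.5)["auroc"] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0.4, 0.6], [1, 1], 0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auroc_equals_exhaustive_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # quantized scores force ties
        scores = np.round(rng.random(50), 1)
        labels = (rng.random(50) < 0.4).astype(int)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        auroc = compute_metrics(scores, labels, 0.5)["auroc"]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auroc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class TestTrain:
    def test_loss_descends_on_learnable_signal(self, tiny_model_config):
        descended = 0
        for seed in range(5):
            sd = generate(
                SyntheticConfig(n_genes=80, n_drivers=12, n_negatives=32, n_features=12,
                                n_sets=15, edge_density=0.08, seed=seed)
            )
            tm = train(sd.dataset, tiny_model_config, TrainConfig(learning_rate=0.01, epochs=8, seed=seed))
            descended += tm.history[-1] < tm.history[0]
        assert descended >= 3

    def test_determinism_same_seed_same_parameters(self, tiny_synth, tiny_model_config, fast_train_config):
        a = train(tiny_synth.dataset, tiny_model_config, fast_train_config)
        b = train(tiny_synth.dataset, tiny_model_config, fast_train_config)
        for k, v in a.model.state_arrays().items():
            np.testing.assert_array_equal(v, b.model.state_arrays()[k])
        assert a.history == b.history

    def test_eaa_ablation_zeroes_bias(self, tiny_synth, tiny_model_config, fast_train_config):
        tm = train(
            tiny_synth.dataset, tiny_model_config, fast_train_config,
            ablation=AblationSpec(frozenset({"EAA"})),
        )
        out = tm.model.forward(training=False)
        assert out["bias"] is None
        assert "edge_W" not in tm.model.params

    def test_single_class_labels_rejected(self, tiny_synth, tiny_model_config, fast_train_config):
        pos_only = tiny_synth.labels.positives
        with pytest.raises(ValueError, match="single class"):
            train(tiny_synth.dataset, tiny_model_config, fast_train_config, train_idx=pos_only)


class TestCrossValidate:
    def test_every_labeled_gene_scored_once_out_of_fold(self, tiny_synth, tiny_model_config):
        tc = TrainConfig(learning_rate=0.01, epochs=3, seed=1)
        cv = cross_validate(tiny_synth.dataset, tiny_model_config, tc, k=2, refit_full=False)
        labeled = tiny_synth.labels.labeled
        assert np.all(np.isfinite(cv.oof_scores[labeled]))
        unlabeled = tiny_synth.labels.unlabeled
        assert np.all(np.isnan(cv.oof_scores[unlabeled]))

    def test_separable_signal_reaches_perfect_auroc(self):
        sd = generate(
            SyntheticConfig(n_genes=80, n_drivers=12, n_negatives=32, n_features=12,
                            n_sets=15, edge_density=0.08, feature_shift=8.0, seed=2)
        )
        cfg = ModelConfig(d=16, n_layers=1, n_heads=2, dropout=0.0)
        tc = TrainConfig(learning_rate=0.01, epochs=40, seed=2)
        cv = cross_validate(sd.dataset, cfg, tc, k=3, refit_full=False)
        assert cv.mean["auroc"] == pytest.approx(1.0, abs=1e-9)

    def test_identical_seeds_identical_results(self, tiny_synth, tiny_model_config):
        tc = TrainConfig(learning_rate=0.01, epochs=3, seed=9)
        a = cross_validate(tiny_synth.dataset, tiny_model_config, tc, k=2, refit_full=False)
        b = cross_validate(tiny_synth.dataset, tiny_model_config, tc, k=2, refit_full=False)
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)
        np.testing.assert_array_equal(a.oof_scores, b.oof_scores)

    def test_too_small_class_suggests_smaller_k(self, tiny_synth, tiny_model_config):
        tc = TrainConfig(learning_rate=0.01, epochs=2, seed=0)
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(tiny_synth.dataset, tiny_model_config, tc, k=13)


class TestPresets:
    def test_pan_cancer_preset_values(self):
        mc, tc = preset("pan_cancer", d=128, seed=4)
        assert (mc.n_layers, mc.n_heads, mc.dropout) == (3, 4, 0.1)
        assert (tc.learning_rate, tc.epochs) == (1e-3, 30)
        assert (tc.focal_alpha, tc.focal_gamma, tc.weight_decay) == (1.0, 1.5, 1e-4)

    def test_cancer_specific_preset_values(self):
        mc, tc = preset("cancer_specific")
        assert (mc.n_layers, mc.n_heads, mc.dropout) == (2, 2, 0.2)
        assert (tc.learning_rate, tc.epochs) == (1e-4, 50)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            preset("nope")


class TestReports:
    def make_predictions(self, n, rng, scores=None):
        symbols = tuple(f"g{i:03d}" for i in range(n))
        s = scores if scores is not None else rng.random(n)
        return prediction_table(symbols, s)

    def test_ranks_are_a_permutation_with_symbol_tiebreak(self, rng):
        table = self.make_predictions(6, rng, scores=np.array([0.5, 0.9, 0.5, 0.1, 0.9, 0.5]))
        assert sorted(table["rank"]) == list(range(1, 7))
        tied_half = table[table["score"] == 0.5]["gene"].tolist()
        assert tied_half == sorted(tied_half)

    def test_novel_candidates_arithmetic(self, rng):
        table = self.make_predictions(500, rng)
        known = set(table.nsmallest(300, "rank")["gene"].iloc[:122])
        novel = novel_candidates(table, known, 300)
        assert len(novel) == 178

    def test_novel_candidates_no_known_in_top(self, rng):
        table = self.make_predictions(50, rng)
        assert len(novel_candidates(table, set(), 20)) == 20

    def test_novel_candidates_matches_sort_filter_oracle(self, rng):
        table = self.make_predictions(200, rng)
        known = set(rng.choice(table["gene"], size=40, replace=False))
        novel = novel_candidates(table, known, 80)
        ordered = table.sort_values(["score", "gene"], ascending=[False, True])
        expected = [g for g in ordered["gene"].iloc[:80] if g not in known]
        assert novel["gene"].tolist() == expected

    def test_stratification_ordering_flags(self, rng):
        n = 40
        symbols = tuple(f"g{i:03d}" for i in range(n))
        scores = np.concatenate([
            np.full(10, 0.9), np.full(10, 0.7), np.full(10, 0.2), np.full(10, 0.4),
        ])
        table = prediction_table(symbols, scores)
        cats = {
            "known_driver": symbols[:10], "potential_driver": symbols[10:20],
            "non_driver": symbols[20:30], "other": symbols[30:],
        }
        strat = stratify_scores(table, cats)
        assert strat.attrs["ordering_ok"] == {
            "known_gt_potential": True, "potential_gt_other": True, "other_gt_nondriver": True,
        }
        assert strat["n"].sum() == n

    def test_equal_scores_give_false_flags(self, rng):
        symbols = tuple(f"g{i}" for i in range(8))
        table = prediction_table(symbols, np.full(8, 0.5))
        cats = {
            "known_driver": symbols[:2], "potential_driver": symbols[2:4],
            "non_driver": symbols[4:6], "other": symbols[6:],
        }
        flags = stratify_scores(table, cats).attrs["ordering_ok"]
        assert not any(flags.values())

    def test_overlapping_categories_rejected(self, rng):
        table = self.make_predictions(4, rng)
        cats = {
            "known_driver": ["g000", "g001"], "potential_driver": ["g001"],
            "non_driver": ["g002"], "other": ["g003"],
        }
        with pytest.raises(ValueError, match="overlap"):
            stratify_scores(table, cats)

    def test_attention_clustering_recovers_archetypes(self, rng):
        # 30 genes, two planted alpha archetypes
        a1 = np.array([0.8, 0.1, 0.1])
        a2 = np.array([0.1, 0.1, 0.8])
        alpha = np.vstack([np.tile(a1, (15, 1)), np.tile(a2, (15, 1))])
        alpha += rng.normal(scale=0.01, size=alpha.shape)
        alpha = np.abs(alpha)
        alpha /= alpha.sum(axis=1, keepdims=True)
        symbols = tuple(f"g{i:02d}" for i in range(30))
        df, means = attention_report(symbols, alpha, n_clusters=2)
        first, second = df["cluster"].iloc[:15], df["cluster"].iloc[15:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]
        np.testing.assert_allclose(means.sum(), 1.0, atol=1e-6)

    def test_model_alphas_sum_to_one(self, tiny_synth, tiny_model_config, fast_train_config):
        tm = train(tiny_synth.dataset, tiny_model_config, fast_train_config)
        alpha = tm.alpha()
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    def test_wilcoxon_helper(self):
        out = wilcoxon_fold_comparison(np.arange(10.0), np.arange(10.0) + np.tile([0.1, -0.05], 5))
        assert 0.0 <= out["pvalue"] <= 1.0


def test_planted_signal_monotone_in_feature_shift(tiny_model_config):
    """End-to-end discrimination grows with the planted feature shift."""
    from sklearn.model_selection import train_test_split

    shifts = [0.0, 0.5, 1.0, 2.0]
    means = []
    for shift in shifts:
        vals = []
        for seed in range(5):
            sd = generate(
                SyntheticConfig(n_genes=80, n_drivers=12, n_negatives=32, n_features=12,
                                n_sets=15, edge_density=0.08, feature_shift=shift,
                                hub_bias=1.0, seed=seed)
            )
            labeled, y = sd.labels.y()
            tr, te = train_test_split(
                np.arange(len(labeled)), test_size=0.3, stratify=y, random_state=seed
            )
            tm = train(
                sd.dataset, tiny_model_config,
                TrainConfig(learning_rate=0.01, epochs=25, seed=seed),
                train_idx=labeled[tr],
            )
            scores = tm.scores()
            vals.append(compute_metrics(scores[labeled[te]], y[te])["auroc"])
        means.append(np.mean(vals))
    for lo, hi in zip(means, means[1:]):
        assert hi >= lo - 0.005  # Monte-Carlo slack at saturation
    assert means[-1] - means[0] > 0.25
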