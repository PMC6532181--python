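"""Classifier, LOO-on-positives protocol, ROC/AUC and operating metrics."""

import numpy as np
import pandas as pd
import pytest

from neoreact.epitope_features import FEATURE_COLUMNS, LabeledDataset
from neoreact.reactivity_model import (
    EvaluationResult,
    ModelConfig,
    ReactivityModel,
    load_results,
    loo_evaluate,
    make_loo_folds,
    operating_metrics,
    roc_auc,
)
from neoreact.synthetic_data import GeneratorConfig, generate_feature_level

FAST = ModelConfig(n_estimators=60, min_leaf_size=2, random_seed=0)


def pair_count_auc(scores, labels):
    """Oracle: P(score+ > score-) + 0.5 P(tie) over all pos/neg pairs."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def separable_dataset(n_pos=8, n_neg=24, seed=0):
    rng = np.random.default_rng(seed)
    feats = pd.DataFrame(rng.normal(size=(n_pos + n_neg, len(FEATURE_COLUMNS))),
                         columns=FEATURE_COLUMNS)
    feats.iloc[:n_pos, :] += 10.0  # wide margin on every feature
    labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
    return LabeledDataset(feats, labels, "t")


class TestModelConfig:
    def test_default_class_weights_follow_cost_matrix(self):
        cfg = ModelConfig()
        assert cfg.class_weights == {0: 0.15, 1: 1.0}

    @pytest.mark.parametrize(
        "cm", [((1.0, 0.15), (1.0, 0.0)), ((0.0, -1.0), (1.0, 0.0)), ((0.0, 0.0), (0.0, 0.0))]
    )
    def test_invalid_cost_matrices_rejected(self, cm):
        with pytest.raises(ValueError):
            ModelConfig(cost_matrix=cm)


class TestTrainPredict:
    def test_separable_data_resubstitution_auc_one(self):
        ds = separable_dataset()
        res = ReactivityModel.from_dataset(ds, FAST).fit()
        _, auc = roc_auc(res.predict_scores(ds.features), ds.labels)
        assert auc == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        ds = separable_dataset(seed=1)
        probe = generate_feature_level(GeneratorConfig(n_pos=5, n_neg=15, seed=9)).features
        s1 = ReactivityModel.from_dataset(ds, FAST).fit().predict_scores(probe)
        s2 = ReactivityModel.from_dataset(ds, FAST).fit().predict_scores(probe)
        np.testing.assert_array_equal(s1, s2)

    def test_scores_bounded_and_duplicates_identical(self):
        ds = separable_dataset(seed=2)
        res = ReactivityModel.from_dataset(ds, FAST).fit()
        probe = pd.concat([ds.features.iloc[:3]] * 2, ignore_index=True)
        s = res.predict_scores(probe)
        assert (s >= 0).all() and (s <= 1).all()
        np.testing.assert_array_equal(s[:3], s[3:])

    def test_single_class_rejected(self):
        feats = pd.DataFrame(np.zeros((5, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS)
        with pytest.raises(ValueError, match="both classes"):
            ReactivityModel(feats, np.ones(5, int), FAST)

    def test_nan_features_rejected_naming_column(self):
        feats = pd.DataFrame(np.zeros((4, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS)
        feats.loc[0, "tap"] = np.nan
        with pytest.raises(ValueError, match="tap"):
            ReactivityModel(feats, np.array([0, 1, 0, 1]), FAST)

    def test_schema_mismatch_rejected(self):
        ds = separable_dataset(seed=3)
        res = ReactivityModel.from_dataset(ds, FAST).fit()
        with pytest.raises(ValueError, match="missing=\\['tap'\\]"):
            res.predict_scores(ds.features.drop(columns=["tap"]))

    def test_generated_positives_score_higher_on_average(self):
        ds = generate_feature_level(GeneratorConfig(n_pos=30, n_neg=120, seed=5))
        res = ReactivityModel.from_dataset(ds, FAST).fit()
        s = res.predict_scores(ds.features)
        assert s[ds.labels == 1].mean() > s[ds.labels == 0].mean()

    def test_save_load_round_trip(self, tmp_path):
        ds = separable_dataset(seed=4)
        res = ReactivityModel.from_dataset(ds, FAST).fit()
        path = tmp_path / "model.joblib"
        res.save(path)
        back = load_results(path)
        np.testing.assert_array_equal(
            back.predict_scores(ds.features), res.predict_scores(ds.features)
        )
        with pytest.raises(ValueError, match="schema"):
            back.predict_scores(ds.features.rename(columns={"tap": "tapx"}))

    def test_summary_mentions_weights_and_importances(self):
        res = ReactivityModel.from_dataset(separable_dataset(), FAST).fit()
        text = res.summary()
        assert "class weights" in text and "feature importances" in text

    def test_cost_weighting_raises_tpr(self):
        """Raising the positive:negative weight ratio never lowers pooled
        TPR at threshold 0.5 (directional sanity across 3 seeds)."""
        for seed in range(3):
            ds = generate_feature_level(GeneratorConfig(n_pos=25, n_neg=150, seed=seed))
            tprs = []
            for neg_cost in (1.0, 0.15):
                cfg = ModelConfig(n_estimators=100, min_leaf_size=5, random_seed=seed,
                                  cost_matrix=((0.0, neg_cost), (1.0, 0.0)))
                ev = loo_evaluate(ds, cfg)
                pred = ev.scores["score"] >= 0.5
                tpr = (pred & (ev.scores["label"] == 1)).sum() / (ev.scores["label"] == 1).sum()
                tprs.append(tpr)
            assert tprs[1] >= tprs[0]


class TestRocAuc:
    def test_perfect_ordering(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_gives_half(self):
        _, auc = roc_auc([0.5] * 6, [1, 1, 0, 0, 0, 0])
        assert auc == 0.5

    def test_three_quarters(self):
        _, auc = roc_auc([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_trapezoid_equals_pair_counting_with_ties(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            _, auc = roc_auc(scores, labels)
            assert abs(auc - pair_count_auc(scores, labels)) < 1e-12

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        labels = np.r_[np.ones(10, int), np.zeros(30, int)]
        scores = rng.random(40)
        _, a1 = roc_auc(scores, labels)
        _, a2 = roc_auc(np.exp(3 * scores) - 1, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_endpoints(self):
        points, _ = roc_auc([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0])
        assert points.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert points.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]


class TestOperatingMetrics:
    def test_perfect_separation(self):
        m = operating_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["neg_kept_at_half_pos"] == 0.0
        assert m["pos_kept_at_half_neg"] == 1.0
        assert m["max_accuracy"] == 1.0
        assert m["max_f1"] == 1.0

    def test_all_equal_scores_no_usable_threshold(self):
        m = operating_metrics([0.4] * 8, [1, 1, 0, 0, 0, 0, 0, 0])
        assert m["neg_kept_at_half_pos"] == 1.0
        assert m["pos_kept_at_half_neg"] == 0.0

    def test_four_point_hand_example(self):
        m = operating_metrics([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0])
        assert m["pos_kept_at_half_neg"] == 1.0  # t=0.3 keeps both positives, 1/2 negatives
        assert m["neg_kept_at_half_pos"] == 0.0  # t=0.9 keeps 1/2 positives, 0 negatives

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            operating_metrics([0.1], [0])


class TestLooProtocol:
    def test_fold_partition_35_450(self):
        labels = np.r_[np.ones(35, int), np.zeros(450, int)]
        folds = make_loo_folds(labels, seed=0)
        assert len(folds) == 35
        sizes = sorted(len(f["test"]) - 1 for f in folds)
        assert set(sizes) == {12, 13}
        assert sizes.count(13) == 30 and sizes.count(12) == 5
        tested = np.concatenate([f["test"] for f in folds])
        assert len(tested) == 485 and len(set(tested)) == 485
        for f in folds:
            assert set(f["test"]).isdisjoint(f["train"])
            assert len(f["test"]) + len(f["train"]) == 485

    def test_fold_assignment_seeded(self):
        labels = np.r_[np.ones(10, int), np.zeros(100, int)]
        f0 = make_loo_folds(labels, seed=0)
        f0b = make_loo_folds(labels, seed=0)
        f1 = make_loo_folds(labels, seed=1)
        same = all((a["test"] == b["test"]).all() for a, b in zip(f0, f0b))
        diff = any(not np.array_equal(a["test"], b["test"]) for a, b in zip(f0, f1))
        assert same and diff

    def test_fewer_than_two_positives_rejected(self):
        labels = np.r_[np.ones(1, int), np.zeros(10, int)]
        with pytest.raises(ValueError, match=">= 2 positives"):
            make_loo_folds(labels, seed=0)

    def test_two_by_two_separable_pooled_auc_one(self):
        ds = separable_dataset(n_pos=2, n_neg=2)
        # each fold trains on one sample per class: leaves of size 1 needed
        ev = loo_evaluate(ds, ModelConfig(n_estimators=60, min_leaf_size=1, random_seed=0))
        assert ev.auc == pytest.approx(1.0, abs=1e-12)
        assert len(ev.scores) == 4

    def test_pooled_test_size_equals_dataset(self):
        ds = generate_feature_level(GeneratorConfig(n_pos=9, n_neg=45, seed=8))
        ev = loo_evaluate(ds, FAST)
        assert len(ev.scores) == 54
        assert sorted(ev.scores["id"]) == sorted(ds.features.index)

    def test_evaluation_result_files_and_summary(self, tmp_path):
        ds = generate_feature_level(GeneratorConfig(n_pos=6, n_neg=24, seed=8))
        ev = loo_evaluate(ds, FAST)
        paths = ev.write(tmp_path)
        assert all(p.exists() for p in paths.values())
        metrics = pd.read_csv(paths["metrics"])
        assert metrics.loc[0, "auc"] == pytest.approx(ev.auc)
        assert "AUC" in ev.summary()

    def test_shuffled_labels_give_null_auc(self):
        """Labels independent of features: held-out AUC stays in the null
        band across 5 seeds."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            feats = pd.DataFrame(rng.normal(size=(160, len(FEATURE_COLUMNS))),
                                 columns=FEATURE_COLUMNS)
            labels = np.r_[np.ones(20, int), np.zeros(140, int)]
            ds = LabeledDataset(feats, rng.permutation(labels), "t")
            ev = loo_evaluate(ds, ModelConfig(n_estimators=100, min_leaf_size=5,
                                              random_seed=seed))
            assert 0.3 < ev.auc < 0.7
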