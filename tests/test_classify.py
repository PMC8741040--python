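"""Pipeline 1, the deep-hybrid head, max-probability fusion, and split audits."""

import numpy as np
import pandas as pd
import pytest

from nucdhl.classify import (
    DHLHead,
    fuse,
    pca_reduce,
    split_hash,
    stratified_split,
    train_dense_baseline,
    train_dhl_head,
    train_pipeline1,
)
from nucdhl.encoder import TrainConfig
from nucdhl.exceptions import ArgumentError, ShapeError, TrainingError
from nucdhl.preprocessing import standard_scale
from nucdhl.types import Decision, ProbPair


class TestPCAReduce:
    def test_perfectly_correlated_columns_collapse_to_one_component(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=200)
        table, _ = standard_scale(pd.DataFrame({
            "a": base, "b": 3.0 * base + 1.0}))
        reduced, projection = pca_reduce(table, variance_retained=0.95)
        assert projection.n_components == 1
        assert projection.explained >= 0.999

    def test_full_variance_keeps_rank_components(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(50, 4))
        values[:, 3] = values[:, 0] + values[:, 1]  # rank 3
        table, _ = standard_scale(pd.DataFrame(values, columns=list("abcd")))
        _, projection = pca_reduce(table, variance_retained=1.0)
        assert projection.n_components == 3

    def test_reconstruction_error_decreases_with_components(self):
        rng = np.random.default_rng(2)
        table, _ = standard_scale(pd.DataFrame(
            rng.normal(size=(100, 5)) @ rng.normal(size=(5, 5)),
            columns=list("abcde")))
        values = table.to_numpy()
        errors = []
        for retained in (0.5, 0.8, 0.95, 1.0):
            reduced, projection = pca_reduce(values, retained)
            recon = projection.inverse_transform(reduced)
            errors.append(np.mean((values - recon) ** 2))
        assert all(x >= y - 1e-12 for x, y in zip(errors, errors[1:]))

    def test_projection_applies_to_held_out_rows(self):
        rng = np.random.default_rng(3)
        table, scaler = standard_scale(pd.DataFrame(
            rng.normal(size=(60, 3)), columns=list("abc")))
        _, projection = pca_reduce(table)
        held = scaler.transform(pd.DataFrame(rng.normal(size=(5, 3)),
                                             columns=list("abc")))
        assert projection.transform(held).shape == (5, projection.n_components)


def _two_clusters(n=200, gap=8.0, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, size=(n // 2, 4))
    x1 = rng.normal(gap, 1.0, size=(n // 2, 4))
    x = np.vstack([x0, x1])
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return x, y


class TestPipeline1:
    def test_separable_clusters_reach_perfect_cv_accuracy(self):
        x, y = _two_clusters()
        model, report = train_pipeline1(pd.DataFrame(x, columns=list("abcd")), y,
                                        folds=5, seed=0)
        assert set(report.cv_accuracy) == {"adaboost", "random_forest",
                                           "decision_tree"}
        for acc in report.cv_accuracy.values():
            assert acc == 1.0
        assert model.predict_proba(x)[:, 1].shape == (200,)

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1000, 6))
        y = rng.permutation(np.r_[np.zeros(500, int), np.ones(500, int)])
        _, report = train_pipeline1(x, y, folds=5, seed=7)
        assert 0.45 <= report.cv_accuracy["adaboost"] <= 0.55

    def test_single_class_rejected(self):
        x, _ = _two_clusters(40)
        with pytest.raises(TrainingError):
            train_pipeline1(x, np.zeros(40, int))

    def test_report_outputs_present(self):
        x, y = _two_clusters(100)
        _, report = train_pipeline1(pd.DataFrame(x, columns=list("abcd")), y)
        assert list(report.feature_importance.index)[0] in list("abcd")
        assert report.correlation.shape == (4, 4)
        assert np.allclose(np.diag(report.correlation), 1.0)


class TestDHLHead:
    @pytest.mark.parametrize("algorithm", ["gradient_boosted_trees",
                                           "random_forest"])
    def test_probability_contract_and_separable_fit(self, algorithm):
        x, y = _two_clusters(120, seed=4)
        head = train_dhl_head(x, y, algorithm=algorithm, seed=4)
        p = head.predict_proba(x)
        assert np.all((p >= 0.0) & (p <= 1.0))
        assert np.mean((p >= 0.5).astype(int) == y) == 1.0

    def test_constant_features_degenerate_to_base_rate(self):
        x = np.ones((90, 5))
        y = np.r_[np.zeros(30, int), np.ones(60, int)]  # prior 2/3 cancer
        head = train_dhl_head(x, y, seed=1)
        p = head.predict_proba(x)
        assert np.all(np.abs(p - 2.0 / 3.0) < 0.05)

    def test_feature_length_mismatch(self):
        x, y = _two_clusters(60, seed=5)
        head = train_dhl_head(x, y)
        with pytest.raises(ShapeError):
            head.predict_proba(np.zeros((3, x.shape[1] + 1)))

    def test_unknown_algorithm(self):
        with pytest.raises(ArgumentError):
            DHLHead(algorithm="svm")


class TestFusion:
    def test_examples(self):
        d = fuse(ProbPair(0.7, 0.9))
        assert d == Decision(0.9, "cancer", "pipeline2")
        d = fuse(ProbPair(0.0, 0.0))
        assert d.fused_probability == 0.0 and d.predicted_label == "normal"
        d = fuse(ProbPair(0.8, 0.3))
        assert d.source == "pipeline1" and d.predicted_label == "cancer"

    def test_max_is_commutative_and_dominates_components(self):
        rng = np.random.default_rng(6)
        for a, b in rng.random((50, 2)):
            d_ab = fuse(ProbPair(float(a), float(b)))
            d_ba = fuse(ProbPair(float(b), float(a)))
            assert d_ab.fused_probability == d_ba.fused_probability
            assert d_ab.fused_probability >= a
            assert d_ab.fused_probability >= b

    def test_tie_goes_to_pipeline2(self):
        assert fuse(ProbPair(0.6, 0.6)).source == "pipeline2"

    def test_invalid_inputs(self):
        with pytest.raises(ArgumentError):
            ProbPair(1.2, 0.5)
        with pytest.raises(ArgumentError):
            fuse(ProbPair(0.5, 0.5), threshold=0.0)


class TestSplits:
    def test_stratified_fractions_and_hash_stability(self):
        y = np.r_[np.zeros(60, int), np.ones(40, int)]
        parts = stratified_split(y, {"train": 0.6, "validation": 0.15,
                                     "test": 0.25}, seed=3)
        assert sum(len(v) for v in parts.values()) == 100
        assert len(parts["train"]) == 60
        train_labels = y[parts["train"]]
        assert (train_labels == 0).sum() == 36 and (train_labels == 1).sum() == 24
        again = stratified_split(y, {"train": 0.6, "validation": 0.15,
                                     "test": 0.25}, seed=3)
        assert split_hash(parts["train"]) == split_hash(again["train"])
        assert split_hash(parts["train"]) != split_hash(parts["test"])

    def test_partitions_are_disjoint_and_complete(self):
        y = np.random.default_rng(8).integers(0, 2, size=77)
        parts = stratified_split(y, {"train": 0.75, "validation": 0.25}, seed=0)
        merged = np.concatenate(list(parts.values()))
        assert sorted(merged.tolist()) == list(range(77))


class TestDenseBaseline:
    def test_separable_training_accuracy_and_manifest(self):
        from test_encoder import _separable_images

        x, y = _separable_images(n_per_class=16)
        model = train_dense_baseline(
            x, y, tconfig=TrainConfig(epochs=6, batch_size=8,
                                      learning_rate=1e-3, seed=2))
        p = model.predict_proba(x)
        assert np.mean((p >= 0.5).astype(int) == y) > 0.9
        assert model.run_manifest()["pretrained_weights"] == "none"
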