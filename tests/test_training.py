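"""Normalizations, losses, optimization behaviour, splits and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from d2nn.metrics import confusion_and_metrics, f1_from_precision_recall, roc_auc
from d2nn.network import DetectorLayout, DiffractiveNetwork, NetworkConfig
from d2nn.optics import GridSpec
from d2nn.training import (
    Hyperparams,
    SplitSpec,
    kfold_cases,
    loss_mse,
    loss_softmax_ce,
    normalize_classification,
    normalize_detection,
    split_cases,
    train,
)


class TestDetectionNormalization:
    @pytest.mark.parametrize("A,b,expected", [
        ((2, 2), (0, 0), (0.5, 0.5)),
        ((0, 0), (0.5, 0.5), (0.0, 0.0)),  # dark-region guard: well-defined
        ((3, 1), (0, 0), (0.75, 0.25)),
    ])
    def test_values(self, A, b, expected):
        out = normalize_detection(np.asarray(A, float), *b)
        assert np.allclose(out.A_prime, expected)

    def test_all_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            normalize_detection(np.zeros(2), 0.0, 0.0)

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = rng.uniform(0, 10, 2)
            out = normalize_detection(A, 0.3, 0.1).A_prime
            assert np.argmax(out) == np.argmax(A)


class TestSoftmaxCrossEntropy:
    def test_symmetric_readout_gives_log2(self):
        for c in (0.0, 0.5, 3.0):
            for label in ([1, 0], [0, 1]):
                assert loss_softmax_ce(np.array([c, c]), np.array(label)) == pytest.approx(np.log(2))

    def test_unit_margin_value(self):
        # softmax CE at A'=(1,0) with label (1,0): log(1 + e^-1)
        val = loss_softmax_ce(np.array([1.0, 0.0]), np.array([1, 0]))
        assert val == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-12)
        assert val == pytest.approx(0.313262, abs=1e-6)

    def test_confident_correct_approaches_zero(self):
        assert loss_softmax_ce(np.array([50.0, 0.0]), np.array([1, 0])) < 1e-20

    def test_non_one_hot_rejected(self):
        with pytest.raises(ValueError):
            loss_softmax_ce(np.array([1.0, 0.0]), np.array([1, 1]))


class TestClassificationNormalization:
    @pytest.mark.parametrize("A,alpha,expected", [
        ((4, 2), 1.0, (1.0, 0.5)),
        ((4, 2), 2.0, (2.0, 1.0)),
        ((5, 5), 0.7, (0.7, 0.7)),
    ])
    def test_values(self, A, alpha, expected):
        out = normalize_classification(np.asarray(A, float), alpha)
        assert np.allclose(out.A_prime, expected)
        assert out.A_prime.max() == pytest.approx(alpha)

    def test_zero_max_rejected(self):
        with pytest.raises(ValueError):
            normalize_classification(np.zeros(2), 1.0)


class TestMSELoss:
    def test_perfect_target_zero(self):
        for alpha in (0.5, 1.0, 2.0):
            assert loss_mse(np.array([alpha, 0.0]), np.array([1, 0]), alpha) == 0.0

    def test_direct_value(self):
        assert loss_mse(np.array([1.0, 0.5]), np.array([1, 0]), 1.0) == pytest.approx(0.25)

    def test_worst_swap(self):
        for alpha in (1.0, 2.0):
            assert loss_mse(np.array([0.0, alpha]), np.array([1, 0]), alpha) == pytest.approx(2 * alpha**2)


def _tiny_task(n_items=24, seed=0):
    """Small separable detection set on a 50×50, 2-layer network."""
    from d2nn.synthetic import PatchParams, gen_patch

    rng = np.random.default_rng(seed)
    patches = [gen_patch(PatchParams(), i % 2, rng) for i in range(n_items)]
    imgs = np.stack([p.image for p in patches])
    labels = np.array([p.label for p in patches])
    cfg = NetworkConfig(grid=GridSpec(n=50), num_layers=2,
                        detector=DetectorLayout.default(50), input_size=50)
    return imgs, labels, cfg


class TestTrainLoop:
    def test_zero_learning_rate_leaves_parameters(self):
        imgs, labels, cfg = _tiny_task()
        net = DiffractiveNetwork.initialize(cfg, seed=0)
        before = [l.phase.copy() for l in net.layers]
        hyper = Hyperparams(learning_rate=0.0, epochs=2, batch_size=8, seed=0)
        train(net, imgs, labels, None, None, hyper, "detection")
        for b, l in zip(before, net.layers):
            assert np.array_equal(b, l.phase)

    def test_seeded_training_is_bitwise_reproducible(self):
        imgs, labels, cfg = _tiny_task()
        results = []
        for _ in range(2):
            net = DiffractiveNetwork.initialize(cfg, seed=0)
            hyper = Hyperparams(learning_rate=0.005, epochs=2, batch_size=8, seed=0)
            net, hist, aux = train(net, imgs, labels, None, None, hyper, "detection")
            results.append(([l.phase.copy() for l in net.layers], hist.train_loss, aux))
        for a, b in zip(results[0][0], results[1][0]):
            assert np.array_equal(a, b)
        assert results[0][1] == results[1][1]
        assert results[0][2] == results[1][2]

    def test_loss_decreases_on_separable_task(self, reduced_training_run):
        _, history, _ = reduced_training_run
        assert history.train_loss[-1] < history.train_loss[0]

    def test_classification_training_runs_and_learns(self):
        from d2nn.synthetic import PatchParams, gen_benign_malignant

        rng = np.random.default_rng(0)
        patches = [gen_benign_malignant(PatchParams(), i % 2, rng) for i in range(48)]
        imgs = np.stack([p.image for p in patches])
        labels = np.array([p.label for p in patches])
        cfg = NetworkConfig(grid=GridSpec(n=50), num_layers=2,
                            detector=DetectorLayout.default(50), input_size=50)
        net = DiffractiveNetwork.initialize(cfg, seed=0)
        hyper = Hyperparams.for_task("classification", epochs=5, batch_size=16, seed=0)
        net, hist, _ = train(net, imgs, labels, imgs, labels, hyper, "classification")
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_empty_dataset_rejected(self):
        _, _, cfg = _tiny_task()
        net = DiffractiveNetwork.initialize(cfg, seed=0)
        with pytest.raises(ValueError):
            train(net, np.empty((0, 50, 50)), np.empty(0), None, None, Hyperparams(), "detection")


class TestSplits:
    def test_hundred_cases_split_8_17_75(self):
        val, test, tr = split_cases([f"c{i}" for i in range(100)], SplitSpec(seed=0))
        assert (len(val), len(test), len(tr)) == (8, 17, 75)

    def test_forty_cases_largest_remainder(self):
        val, test, tr = split_cases([f"c{i}" for i in range(40)], SplitSpec(seed=1))
        assert (len(val), len(test), len(tr)) == (3, 7, 30)

    def test_partition_and_determinism(self):
        ids = [f"case{i}" for i in range(37)]
        a = split_cases(ids, SplitSpec(seed=5))
        b = split_cases(ids, SplitSpec(seed=5))
        assert a == b
        merged = sorted(a[0] + a[1] + a[2])
        assert merged == sorted(ids)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            split_cases(["a", "a", "b", "c"], SplitSpec())

    def test_kfold_sizes_and_disjointness(self):
        folds = kfold_cases(list(range(101)), 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [10] * 9 + [11]
        flat = [c for f in folds for c in f]
        assert sorted(flat) == list(range(101))

    def test_kfold_equal_partition(self):
        folds = kfold_cases(list(range(100)), 10, seed=2)
        assert all(len(f) == 10 for f in folds)


class TestMetrics:
    def test_hand_computed_confusion(self):
        # TP=3, FP=1, TN=5, FN=1
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = confusion_and_metrics(y_pred, y_true)
        assert (m.tp, m.fp, m.tn, m.fn) == (3, 1, 5, 1)
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)
        assert m.mcc == pytest.approx(14 / 24)

    def test_perfect_predictions(self):
        m = confusion_and_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert m.accuracy == 1.0 and m.mcc == pytest.approx(1.0)

    def test_undefined_ratios_flagged_not_zeroed(self):
        m = confusion_and_metrics([0, 0, 0], [0, 0, 0])
        assert np.isnan(m.recall) and "recall" in m.undefined
        assert np.isnan(m.mcc) and "mcc" in m.undefined

    def test_f1_is_harmonic_mean_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            y_true = rng.integers(0, 2, 40)
            y_pred = rng.integers(0, 2, 40)
            m = confusion_and_metrics(y_pred, y_true)
            if not np.isnan(m.f1):
                assert m.f1 == pytest.approx(
                    f1_from_precision_recall(m.precision, m.recall), abs=1e-12
                )

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

        rng = np.random.default_rng(11)
        y_true = rng.integers(0, 2, 200)
        y_pred = (y_true + (rng.random(200) < 0.3)) % 2
        m = confusion_and_metrics(y_pred, y_true)
        assert m.accuracy == pytest.approx(accuracy_score(y_true, y_pred))
        assert m.f1 == pytest.approx(f1_score(y_true, y_pred))
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_mcc_positive_above_chance_on_balanced_data(self):
        y_true = np.tile([0, 1], 50)
        y_pred = y_true.copy()
        y_pred[:20] = 1 - y_pred[:20]  # 80% accuracy
        m = confusion_and_metrics(y_pred, y_true)
        assert m.accuracy > 0.5 and m.mcc > 0


class TestROC:
    def test_perfect_inverted_and_tied(self):
        labels = np.array([1, 1, 0, 0])
        assert roc_auc([0.9, 0.8, 0.3, 0.1], labels)[2] == pytest.approx(1.0)
        assert roc_auc([0.9, 0.8, 0.3, 0.1], 1 - labels)[2] == pytest.approx(0.0)
        assert roc_auc([0.5, 0.5, 0.5, 0.5], labels)[2] == pytest.approx(0.5)

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 100)
        scores = labels * 0.3 + rng.random(100)
        assert roc_auc(scores, labels)[2] == pytest.approx(roc_auc_score(labels, scores))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        scores = rng.random(20)
        base = roc_auc(scores, labels)[2]
        assert roc_auc(np.exp(3 * scores) - 2, labels)[2] == pytest.approx(base)
        assert roc_auc(np.arctan(scores) * 7 + 1, labels)[2] == pytest.approx(base)
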