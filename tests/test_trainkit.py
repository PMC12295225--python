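"""Loss, metrics, schedule, and the train/evaluate loop."""

import numpy as np
import pytest

from ilvit.model import tiny_test_config
from ilvit.tensor import Tensor
from ilvit.trainkit import (AdamW, ClassificationReport, TrainConfig,
                            confusion_matrix, cosine_lr, cross_entropy,
                            evaluate, load_checkpoint, micro_accuracy,
                            per_class_metrics, save_checkpoint, train)


class TestCrossEntropy:
    def test_certain_correct_prediction_has_zero_loss(self):
        p = np.array([[1.0, 0.0, 0.0, 0.0]])
        assert cross_entropy(p, [0], from_logits=False).item() < 1e-9

    def test_uniform_prediction_four_classes_is_ln4(self):
        logits = np.zeros((5, 4))
        assert abs(cross_entropy(logits, [0, 1, 2, 3, 0]).item()
                   - np.log(4.0)) < 1e-12

    def test_matches_explicit_loop_oracle_on_simplex_vectors(self, rng):
        p = rng.dirichlet(np.ones(5), size=8)
        y = rng.integers(0, 5, size=8)
        got = cross_entropy(p, y, from_logits=False).item()
        expected = -np.mean([np.log(p[i, y[i]]) for i in range(8)])
        assert abs(got - expected) < 1e-7

    def test_zero_probability_on_true_class_clamped_finite(self):
        p = np.array([[0.0, 1.0]])
        loss = cross_entropy(p, [0], from_logits=False).item()
        assert np.isfinite(loss) and loss > 20

    def test_logit_gradient_is_softmax_minus_onehot(self, rng):
        logits = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        cross_entropy(logits, [1, 0, 2]).backward()
        p = np.exp(logits.data - logits.data.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        onehot = np.eye(4)[[1, 0, 2]]
        np.testing.assert_allclose(logits.grad, (p - onehot) / 3, atol=1e-10)


class TestMetrics:
    def test_diagonal_confusion_is_perfect(self):
        rep = per_class_metrics(np.diag([5, 3, 2]))
        assert rep.accuracy == 1.0
        assert rep.per_class_precision == [1.0] * 3
        assert rep.per_class_recall == [1.0] * 3

    def test_hand_computed_two_class_confusion(self):
        conf = np.array([[8, 2], [1, 9]])
        rep = per_class_metrics(conf)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.per_class_precision[0] == pytest.approx(8 / 9)
        assert rep.per_class_recall[0] == pytest.approx(0.8)

    def test_micro_recall_equals_micro_accuracy_any_confusion(self, rng):
        """Micro-averaged recall (Σ TP / Σ row totals) coincides with
        trace/total on any confusion matrix."""
        for _ in range(10):
            conf = rng.integers(0, 20, size=(4, 4))
            micro_recall = np.trace(conf) / conf.sum(axis=1).sum()
            assert micro_accuracy(conf) == pytest.approx(micro_recall)

    def test_literal_error_double_counting_denominator(self):
        conf = np.array([[8, 2], [1, 9]])
        # off-diagonal errors are counted once as FP and once as FN
        assert micro_accuracy(conf, literal=True) == pytest.approx(17 / 23)

    def test_matches_scikit_learn_cross_check(self, rng):
        from sklearn.metrics import (confusion_matrix as sk_conf,
                                     precision_score, recall_score)
        y_true = rng.integers(0, 3, size=60)
        y_pred = rng.integers(0, 3, size=60)
        conf = confusion_matrix(y_true, y_pred, 3)
        np.testing.assert_array_equal(conf, sk_conf(y_true, y_pred))
        rep = per_class_metrics(conf)
        np.testing.assert_allclose(
            rep.per_class_precision,
            precision_score(y_true, y_pred, average=None, zero_division=0))
        np.testing.assert_allclose(
            rep.per_class_recall,
            recall_score(y_true, y_pred, average=None, zero_division=0))

    def test_zero_denominator_warns_and_returns_zero(self):
        conf = np.array([[5, 0], [0, 0]])
        with pytest.warns(UserWarning, match="zero-denominator"):
            rep = per_class_metrics(conf)
        assert rep.per_class_recall[1] == 0.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            micro_accuracy(np.zeros((2, 3), dtype=int))


class TestSchedule:
    def test_endpoints_match_protocol_values(self):
        cfg = TrainConfig()
        assert cosine_lr(0.0, cfg) == pytest.approx(1e-6)
        assert cosine_lr(cfg.warmup_epochs, cfg) == pytest.approx(1e-4)
        assert cosine_lr(cfg.epochs, cfg) <= 1e-6 + 1e-12

    def test_matches_closed_form_cosine_everywhere(self):
        cfg = TrainConfig(epochs=100, warmup_epochs=10)
        for e in np.linspace(10, 100, 37):
            t = (e - 10) / 90
            expected = 1e-6 + 0.5 * (1e-4 - 1e-6) * (1 + np.cos(np.pi * t))
            assert cosine_lr(e, cfg) == pytest.approx(expected, abs=1e-9)

    def test_warmup_is_linear(self):
        cfg = TrainConfig()
        lrs = [cosine_lr(e, cfg) for e in range(0, 21, 5)]
        diffs = np.diff(lrs)
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=1e-5, lr_min=1e-4)


class TestAdamW:
    def test_converges_on_quadratic(self):
        from ilvit.tensor import Parameter
        p = Parameter(np.array([5.0, -3.0]))
        opt = AdamW([p], TrainConfig(weight_decay=0.0))
        opt.lr = 0.1
        for _ in range(300):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2


class TestTrainEvaluate:
    def test_perfectly_predicted_single_class_reports_ones(self, tiny_dataset):
        """Evaluation on a one-class subset a model predicts perfectly."""
        model = tiny_test_config("baseline")
        from ilvit.model import build_model
        net = build_model(model, seed=0)
        # force the head to always output class 2
        net.head.weight.data[:] = 0.0
        net.head.bias.data[:] = 0.0
        net.head.bias.data[2] = 10.0
        from ilvit.datapipe import LabeledImageSet
        idx = [i for i, l in enumerate(tiny_dataset.labels) if l == 2]
        sub = LabeledImageSet([tiny_dataset.images[i] for i in idx],
                              [2] * len(idx), tiny_dataset.class_names)
        with pytest.warns(UserWarning):
            rep = evaluate(net, sub)
        assert rep.accuracy == 1.0
        assert rep.per_class_recall[2] == 1.0

    def test_training_is_deterministic_and_loss_decreases(self, tiny_dataset):
        cfg = tiny_test_config("V0")
        tc = TrainConfig(batch_size=32, epochs=500, seed=4, max_steps=50)
        _, h1 = train(cfg, tc, tiny_dataset)
        _, h2 = train(cfg, tc, tiny_dataset)
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]
        first = np.median([r["loss"] for r in h1[:10]])
        last = np.median([r["loss"] for r in h1[-10:]])
        assert last < first

    def test_empty_dataset_rejected(self):
        from ilvit.datapipe import LabeledImageSet
        empty = LabeledImageSet([], [], ("a",))
        with pytest.raises(ValueError, match="empty"):
            train(tiny_test_config("V0"), TrainConfig(), empty)

    def test_checkpoint_round_trip(self, tmp_path, tiny_dataset):
        from ilvit.model import build_model
        cfg = tiny_test_config("V1")
        model = build_model(cfg, seed=8)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(model, path)
        again = load_checkpoint(path)
        r1 = evaluate(model, tiny_dataset)
        r2 = evaluate(again, tiny_dataset)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_report_table_layout(self):
        rep = per_class_metrics(np.diag([3, 4]), class_names=("a", "b"))
        lines = rep.table().splitlines()
        assert lines[0] == "class,accuracy,precision,recall"
        assert lines[1].startswith("a,")
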