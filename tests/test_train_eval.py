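"""Training loop, stratified folds, ROC construction and the metric battery."""

import numpy as np
import pytest

from cceeg.ccnn_model import build_model, default_architecture
from cceeg.train_eval import (
    TrainConfig,
    evaluate,
    evaluate_probabilities,
    multiclass_roc_micro,
    stratified_kfold,
    train,
)


# --- stratified folds --------------------------------------------------------


def test_balanced_4500_labels_split_into_ten_folds_of_450():
    labels = np.repeat(np.arange(9), 500)
    folds = stratified_kfold(labels, k=10, seed=0)
    assert len(folds) == 10
    for fold in folds:
        assert fold.size == 450
        assert np.array_equal(np.bincount(labels[fold]), np.full(9, 50))


def test_folds_partition_the_index_set():
    labels = np.repeat(np.arange(9), 20)
    folds = stratified_kfold(labels, k=4, seed=1)
    joined = np.concatenate(folds)
    assert np.array_equal(np.sort(joined), np.arange(labels.size))


def test_leave_one_out_when_k_equals_n():
    labels = np.arange(5) % 5  # five singleton classes fail; use one class
    labels = np.zeros(5, dtype=int)
    folds = stratified_kfold(labels, k=5, seed=0)
    assert sorted(f.size for f in folds) == [1, 1, 1, 1, 1]


def test_fold_error_names_underpopulated_class():
    labels = np.array([0] * 10 + [7] * 2)
    with pytest.raises(ValueError, match="class 7"):
        stratified_kfold(labels, k=5, seed=0)


# --- training loop -----------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_batch():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((18, 4, 64))
    y = np.repeat(np.arange(9), 2)
    return x, y


def test_zero_learning_rate_leaves_parameters_unchanged(tiny_batch):
    x, y = tiny_batch
    model = build_model(default_architecture(), 4, 64, seed=0)
    before = [p.value.copy() for p in model.network.params()]
    train(model, x, y, TrainConfig(learning_rate=0.0, epochs=3, batch_size=6, seed=0))
    for p, orig in zip(model.network.params(), before):
        assert np.array_equal(p.value, orig)


def test_same_seed_training_is_bit_reproducible(tiny_batch):
    x, y = tiny_batch
    losses = []
    for _ in range(2):
        model = build_model(default_architecture(), 4, 64, seed=5)
        curves = train(model, x, y, TrainConfig(epochs=5, batch_size=6, seed=5,
                                                learning_rate=1e-3))
        losses.append(curves.loss)
    assert losses[0] == losses[1]


def test_training_curves_have_one_entry_per_epoch(tiny_batch):
    x, y = tiny_batch
    model = build_model(default_architecture(), 4, 64, seed=0)
    curves = train(model, x, y, TrainConfig(epochs=4, batch_size=6, seed=0))
    assert len(curves.loss) == 4 and len(curves.accuracy) == 4


def test_loss_trends_downward(tiny_batch):
    x, y = tiny_batch
    model = build_model(default_architecture(dropout_rate=0.0), 4, 64, seed=0)
    curves = train(model, x, y, TrainConfig(epochs=40, batch_size=18, seed=0,
                                            learning_rate=1e-3))
    assert np.mean(curves.loss[-5:]) < np.mean(curves.loss[:5])


# --- micro-averaged ROC ------------------------------------------------------


def _onehot(labels, k=9):
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels] = 1
    return out


def test_perfect_probabilities_give_auc_one():
    labels = np.arange(9)
    _, _, auc = multiclass_roc_micro(_onehot(labels), labels)
    assert auc == 1.0


def test_uniform_probabilities_give_auc_half():
    labels = np.repeat(np.arange(9), 3)
    probs = np.full((labels.size, 9), 1 / 9)
    _, _, auc = multiclass_roc_micro(probs, labels)
    assert auc == pytest.approx(0.5)


def test_reversed_perfect_scores_give_auc_zero():
    labels = np.arange(9)
    _, _, auc = multiclass_roc_micro(1.0 - _onehot(labels), labels)
    assert auc == 0.0


def test_roc_rejects_out_of_range_label():
    with pytest.raises(ValueError):
        multiclass_roc_micro(np.full((2, 9), 1 / 9), np.array([0, 9]))


# --- evaluation battery ------------------------------------------------------


def test_perfect_predictions_score_one_everywhere():
    labels = np.repeat(np.arange(9), 4)
    report = evaluate_probabilities(_onehot(labels), labels)
    assert (report.accuracy, report.precision, report.recall, report.f1) == (1, 1, 1, 1)
    assert report.auc == 1.0
    assert np.array_equal(report.confusion, np.diag(np.full(9, 4)))


def test_constant_predictor_on_balanced_data_scores_one_ninth():
    labels = np.repeat(np.arange(9), 5)
    probs = np.zeros((labels.size, 9))
    probs[:, 3] = 1.0
    report = evaluate_probabilities(probs, labels)
    assert report.accuracy == pytest.approx(1 / 9)


def test_confusion_matrix_totals_and_row_sums():
    rng = np.random.default_rng(1)
    labels = np.repeat(np.arange(9), 7)
    probs = rng.dirichlet(np.ones(9), size=labels.size)
    report = evaluate_probabilities(probs, labels)
    assert report.confusion.sum() == labels.size
    assert np.array_equal(report.confusion.sum(axis=1), np.full(9, 7))


def test_f1_is_harmonic_mean_per_class_before_macro_average():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 9, 120)
    probs = rng.dirichlet(np.ones(9), size=120)
    report = evaluate_probabilities(probs, labels)
    preds = probs.argmax(axis=1)
    f1s = []
    for c in range(9):
        tp = np.sum((preds == c) & (labels == c))
        p = tp / max(np.sum(preds == c), 1)
        r = tp / max(np.sum(labels == c), 1)
        f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    assert report.f1 == pytest.approx(np.mean(f1s))


def test_empty_test_set_rejected(tiny_batch):
    x, _ = tiny_batch
    model = build_model(default_architecture(), 4, 64, seed=0)
    with pytest.raises(ValueError, match="empty"):
        evaluate(model, x[:0], np.array([], dtype=int))


def test_divergence_aborts_with_diagnostics(tiny_batch):
    x, y = tiny_batch
    model = build_model(default_architecture(dropout_rate=0.0, use_batchnorm=False),
                        4, 64, seed=0)
    bad = x.copy()
    bad[0, 0, 0] = np.inf  # propagates to a non-finite loss on the first batch
    with pytest.raises(FloatingPointError, match="non-finite"):
        train(model, bad, y, TrainConfig(epochs=2, batch_size=18, seed=0))
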