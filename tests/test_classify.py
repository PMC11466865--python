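import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

import coughcount as cc


def _gaussian_clouds(n=200, d=2, delta=6.0, seed=0):
    """Two well-separated Gaussian clouds (class distance delta sigma)."""
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal((n // 2, d))
    x1 = rng.standard_normal((n - n // 2, d)) + delta
    X = np.vstack([x0, x1])
    y = np.array(["Noise"] * (n // 2) + ["Cough"] * (n - n // 2))
    return X, y


def test_separable_clouds_are_fit_perfectly():
    X, y = _gaussian_clouds()
    model = cc.CoughClassifier(random_state=0).fit(X, y)
    assert np.mean(model.predict(X) == y) == 1.0


def test_training_is_deterministic_given_seed():
    X, y = _gaussian_clouds(delta=2.0, seed=1)
    Xt, _ = _gaussian_clouds(delta=2.0, seed=2)
    p1 = cc.CoughClassifier(random_state=7).fit(X, y).predict(Xt)
    p2 = cc.CoughClassifier(random_state=7).fit(X, y).predict(Xt)
    np.testing.assert_array_equal(p1, p2)


def test_label_shuffled_data_scores_at_chance():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((400, 5))
    y = np.array(["Cough", "Noise"] * 200)
    data = cc.LabeledDataset(X, y)
    _, report = cc.cross_validated_metrics(data, seed=0)
    assert report.acc == pytest.approx(0.5, abs=0.08)


def test_single_class_training_is_an_error():
    X = np.zeros((10, 3))
    with pytest.raises(ValueError):
        cc.CoughClassifier().fit(X, np.array(["Cough"] * 10))


def test_predict_contracts():
    X, y = _gaussian_clouds()
    model = cc.CoughClassifier(random_state=0).fit(X, y)
    assert len(model.predict(np.empty((0, 2)))) == 0
    with pytest.raises(ValueError, match="2"):
        model.predict(np.zeros((5, 3)))
    perm = np.random.default_rng(0).permutation(len(X))
    np.testing.assert_array_equal(model.predict(X[perm]), model.predict(X)[perm])


def test_sklearn_estimator_interface():
    model = cc.CoughClassifier(C=2.0)
    assert model.get_params()["C"] == 2.0
    model.set_params(C=0.5)
    assert model.C == 0.5


def test_perfect_predictions_give_unit_metrics():
    y = ["Cough"] * 5 + ["Noise"] * 5
    _, report = cc.evaluate(y, y)
    for value in report.as_dict().values():
        assert value == pytest.approx(1.0)


def test_hand_worked_confusion_example():
    counts = cc.ConfusionCounts(tp=50, tn=40, fp=10, fn=0)
    report = cc.metrics_from_counts(counts)
    assert report.acc == pytest.approx(0.9)
    assert report.sen == pytest.approx(1.0)
    assert report.spe == pytest.approx(0.8)
    assert report.ppv == pytest.approx(50 / 60)
    assert report.npv == pytest.approx(1.0)
    assert report.f1 == pytest.approx(2 * (50 / 60) * 1.0 / ((50 / 60) + 1.0))
    assert report.mcc == pytest.approx(
        (50 * 40 - 10 * 0) / np.sqrt(60 * 50 * 50 * 40)
    )


def test_degenerate_all_noise_prediction():
    truth = ["Cough"] * 50 + ["Noise"] * 50
    pred = ["Noise"] * 100
    _, report = cc.evaluate(pred, truth)
    assert report.sen == 0.0
    assert report.spe == 1.0
    assert np.isnan(report.mcc)
    assert report.kappa == 0.0


def test_evaluate_rejects_length_mismatch():
    with pytest.raises(ValueError):
        cc.evaluate(["Cough"], ["Cough", "Noise"])


def test_metrics_match_independent_formulas_on_random_matrices():
    rng = np.random.default_rng(4)
    for _ in range(200):
        tp, fn, fp, tn = (int(v) for v in rng.integers(0, 200, 4))
        if tp + fn + fp + tn == 0:
            continue
        r = cc.metrics_from_counts(cc.ConfusionCounts(tp, fn, fp, tn))
        n = tp + fn + fp + tn
        assert r.acc == pytest.approx((tp + tn) / n, abs=1e-12)
        if tp + fn:
            assert r.sen == pytest.approx(tp / (tp + fn), abs=1e-12)
        if tn + fp:
            assert r.spe == pytest.approx(tn / (tn + fp), abs=1e-12)


def test_kappa_and_mcc_agree_with_sklearn():
    rng = np.random.default_rng(5)
    labels = np.array(["Cough", "Noise"])
    for _ in range(20):
        truth = labels[rng.integers(0, 2, 300)]
        pred = np.where(rng.random(300) < 0.8, truth, labels[rng.integers(0, 2, 300)])
        _, report = cc.evaluate(pred, truth)
        assert report.kappa == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-12)
        t = (truth == "Cough").astype(int)
        p = (pred == "Cough").astype(int)
        assert report.mcc == pytest.approx(matthews_corrcoef(t, p), abs=1e-12)


def test_class_swap_exchanges_sen_spe_and_ppv_npv():
    counts = cc.ConfusionCounts(tp=70, fn=10, fp=20, tn=50)
    swapped = cc.ConfusionCounts(tp=50, fn=20, fp=10, tn=70)
    a, b = cc.metrics_from_counts(counts), cc.metrics_from_counts(swapped)
    assert a.sen == pytest.approx(b.spe)
    assert a.ppv == pytest.approx(b.npv)
    assert a.acc == pytest.approx(b.acc)
    assert abs(a.mcc) == pytest.approx(abs(b.mcc))
    assert a.kappa == pytest.approx(b.kappa)


def test_mcc_and_kappa_are_scale_invariant():
    base = cc.metrics_from_counts(cc.ConfusionCounts(13, 7, 5, 25))
    scaled = cc.metrics_from_counts(cc.ConfusionCounts(39, 21, 15, 75))
    assert base.mcc == pytest.approx(scaled.mcc, abs=1e-12)
    assert base.kappa == pytest.approx(scaled.kappa, abs=1e-12)


def test_compare_feature_combinations_table(benchmark400):
    X, y = benchmark400.features, benchmark400.labels
    datasets = {
        "17-dim": cc.LabeledDataset(X, y),
        "17-dim+zero": cc.LabeledDataset(np.hstack([X, np.zeros((len(y), 1))]), y),
    }
    table = cc.compare_feature_combinations(datasets, seed=0)
    assert table.shape == (2, 8)
    assert set(table.columns) >= {"ACC (%)", "SEN (%)", "SPE (%)", "F1 (%)"}
    # an all-zero column is uninformative: metrics move by at most 2 points
    diff = (table.loc["17-dim"] - table.loc["17-dim+zero"]).abs()
    assert diff["ACC (%)"] <= 2.0
    # identical call is identical
    table2 = cc.compare_feature_combinations(datasets, seed=0)
    assert table.equals(table2)


def test_compare_rejects_mismatched_row_counts(benchmark400):
    X, y = benchmark400.features, benchmark400.labels
    with pytest.raises(ValueError):
        cc.compare_feature_combinations({
            "a": cc.LabeledDataset(X, y),
            "b": cc.LabeledDataset(X[:100], y[:100]),
        })


def test_labeled_dataset_validation():
    with pytest.raises(ValueError):
        cc.LabeledDataset(np.zeros((3, 2)), np.array(["Cough", "Bad", "Noise"]))
    with pytest.raises(ValueError):
        cc.LabeledDataset(np.full((3, 2), np.nan), np.array(["Cough"] * 3))
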