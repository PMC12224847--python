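import warnings

import numpy as np
import pytest
from sklearn.datasets import make_blobs, make_classification

from cmmnet.ml import (
    feature_importance,
    metrics_from_confusion,
    run_benchmark,
    stratified_split,
)

# ---------------------------------------------------------------------------
# stratified_split


def test_split_proportions_60_40():
    y = np.array([0] * 60 + [1] * 40)
    train, test = stratified_split(np.zeros((100, 2)), y, 0.7, seed=0)
    assert list(np.bincount(y[train])) == [42, 28]
    assert list(np.bincount(y[test])) == [18, 12]
    assert sorted(np.concatenate([train, test])) == list(range(100))
    assert set(train).isdisjoint(test)


def test_split_deterministic():
    y = np.array([0, 0, 1, 1, 0, 1, 0, 1] * 5)
    a = stratified_split(np.zeros((40, 1)), y, 0.7, seed=3)
    b = stratified_split(np.zeros((40, 1)), y, 0.7, seed=3)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_split_singleton_class_refused():
    y = np.array([0, 0, 0, 1])
    with pytest.raises(ValueError, match="single member"):
        stratified_split(np.zeros((4, 1)), y, 0.7)


def test_split_proportions_within_one_record():
    rng = np.random.default_rng(0)
    for trial in range(50):
        n = int(rng.integers(20, 200))
        k = int(rng.integers(2, 5))
        y = rng.integers(0, k, size=n)
        while np.bincount(y, minlength=k).min() < 2:
            y = rng.integers(0, k, size=n)
        train, _ = stratified_split(np.zeros((n, 1)), y, 0.7, seed=trial)
        for cls in range(k):
            n_cls = (y == cls).sum()
            expected = 0.7 * n_cls
            got = (y[train] == cls).sum()
            assert abs(got - expected) <= 1.0


# ---------------------------------------------------------------------------
# metrics_from_confusion


def test_perfect_diagonal():
    out = metrics_from_confusion(np.diag([10, 20, 30]))
    assert all(out[k] == pytest.approx(1.0) for k in ("accuracy", "precision", "recall", "f1"))


def test_two_class_reference_values():
    out = metrics_from_confusion([[50, 10], [5, 35]])
    assert out["accuracy"] == pytest.approx(0.85)
    # class-0 one-vs-rest values (checked inside the macro average below)
    cm = np.array([[50, 10], [5, 35]])
    p0 = 50 / 55
    r0 = 50 / 60
    f0 = 2 * p0 * r0 / (p0 + r0)
    assert p0 == pytest.approx(0.9091, abs=1e-4)
    assert r0 == pytest.approx(0.8333, abs=1e-4)
    assert f0 == pytest.approx(0.8696, abs=1e-4)
    p1, r1 = 35 / 45, 35 / 40
    f1 = 2 * p1 * r1 / (p1 + r1)
    assert out["precision"] == pytest.approx((p0 + p1) / 2)
    assert out["recall"] == pytest.approx((r0 + r1) / 2)
    assert out["f1"] == pytest.approx((f0 + f1) / 2)


def test_micro_identity():
    rng = np.random.default_rng(1)
    for trial in range(30):
        k = int(rng.integers(2, 6))
        cm = rng.integers(0, 40, size=(k, k))
        if cm.sum() == 0:
            continue
        out = metrics_from_confusion(cm, average="micro")
        acc = np.trace(cm) / cm.sum()
        assert out["precision"] == pytest.approx(acc, abs=1e-12)
        assert out["recall"] == pytest.approx(acc, abs=1e-12)
        assert out["accuracy"] == pytest.approx(acc, abs=1e-12)


def test_against_brute_force_one_vs_rest():
    """500 random matrices vs a from-scratch per-class reduction."""
    rng = np.random.default_rng(2)
    for trial in range(500):
        k = int(rng.integers(2, 7))
        cm = rng.integers(0, 30, size=(k, k)).astype(float)
        if cm.sum() == 0 or np.trace(cm) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = metrics_from_confusion(cm, average="macro")
        precs, recs, f1s = [], [], []
        total = cm.sum()
        for c in range(k):
            tp = cm[c, c]
            fp = cm[:, c].sum() - tp
            fn = cm[c, :].sum() - tp
            prec = tp / (tp + fp) if tp + fp > 0 else 0.0
            rec = tp / (tp + fn) if tp + fn > 0 else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
            precs.append(prec)
            recs.append(rec)
            f1s.append(f1)
        assert out["accuracy"] == pytest.approx(np.trace(cm) / total, abs=1e-12)
        assert out["precision"] == pytest.approx(np.mean(precs), abs=1e-12)
        assert out["recall"] == pytest.approx(np.mean(recs), abs=1e-12)
        assert out["f1"] == pytest.approx(np.mean(f1s), abs=1e-12)


def test_paper_literal_flag():
    cm = np.array([[50, 10], [5, 35]])
    literal = metrics_from_confusion(cm, paper_literal=True)
    standard = metrics_from_confusion(cm)
    # literal accuracy macro-averages (TP+TN)/(TP+TN+FN) per class
    total = cm.sum()
    accs = []
    for c in range(2):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        tn = total - tp - fp - fn
        accs.append((tp + tn) / (tp + tn + fn))
    assert literal["accuracy"] == pytest.approx(np.mean(accs))
    assert literal["accuracy"] != standard["accuracy"]


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        metrics_from_confusion(np.zeros((0, 0)))
    with pytest.raises(ValueError):
        metrics_from_confusion(np.zeros((3, 3)))


def test_metrics_in_unit_interval():
    rng = np.random.default_rng(3)
    for trial in range(50):
        cm = rng.integers(0, 20, size=(3, 3))
        if cm.sum() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = metrics_from_confusion(cm)
        assert all(0.0 <= v <= 1.0 for v in out.values())


# ---------------------------------------------------------------------------
# benchmark


def _bench(X, y, seed=0, models=("RandomForest", "KNN", "LogisticRegression")):
    train, test = stratified_split(X, y, 0.7, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_benchmark(
            X[train], y[train], X[test], y[test],
            feature_names=[f"f{i}" for i in range(X.shape[1])],
            models=models, seed=seed,
        )


def test_benchmark_separable_blobs():
    # reduced-seed version of the 20-seed sanity experiment
    for seed in range(3):
        X, y = make_blobs(n_samples=240, centers=3, cluster_std=0.6, random_state=seed)
        report = _bench(X, y, seed=seed, models=("RandomForest", "GradientBoosting", "SVM", "KNN", "LogisticRegression"))
        assert (report.metrics["accuracy"] >= 0.95).all(), report.metrics
        assert (report.metrics["auc_roc"] >= 0.95).all()


def test_benchmark_null_labels():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(3000, 5))
    y = rng.integers(0, 3, size=3000)
    report = _bench(X, y, models=("LogisticRegression",))
    acc = report.metrics["accuracy"].iloc[0]
    assert abs(acc - 1.0 / 3.0) < 0.05


def test_benchmark_metrics_in_unit_interval():
    X, y = make_classification(n_samples=200, n_classes=3, n_informative=4, random_state=1)
    report = _bench(X, y)
    cols = ["accuracy", "precision", "recall", "f1", "auc_roc"]
    assert ((report.metrics[cols] >= 0) & (report.metrics[cols] <= 1)).all().all()


def test_xgboost_skipped_gracefully():
    X, y = make_blobs(n_samples=60, centers=2, random_state=0)
    report = _bench(X, y, models=("LogisticRegression", "XGBoost"))
    try:
        import xgboost  # noqa: F401

        assert "XGBoost" in report.metrics["model"].tolist()
    except ImportError:
        assert "XGBoost" in report.skipped
        assert "xgboost" in report.skipped["XGBoost"]


def test_confusion_totals_match_test_size():
    X, y = make_blobs(n_samples=100, centers=3, random_state=2)
    train, test = stratified_split(X, y, 0.7, seed=2)
    report = _bench(X, y, seed=2)
    for cm in report.confusion.values():
        assert cm.sum() == len(test)


# ---------------------------------------------------------------------------
# feature importance


def test_importance_planted_signal():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(2000, 10))
    y = (X[:, 0] > 0).astype(int)
    report = _bench(X, y, models=("GradientBoosting",))
    ranked = report.importances
    assert ranked[0][0] == "f0"
    assert ranked[0][1] > 0.5


def test_importance_sums_to_one():
    X, y = make_classification(n_samples=300, n_classes=2, random_state=5)
    report = _bench(X, y, models=("GradientBoosting",))
    assert sum(v for _, v in report.importances) == pytest.approx(1.0, abs=1e-9)


def test_importance_null_features():
    # reduced-seed version (8 of 20) of the all-noise null experiment
    n_features = 20
    for seed in range(8):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(400, n_features))
        y = rng.integers(0, 2, size=400)
        report = _bench(X, y, seed=seed, models=("GradientBoosting",))
        top = report.importances[0][1]
        assert top < 3.0 / n_features


def test_importance_name_mismatch():
    from sklearn.ensemble import GradientBoostingClassifier

    X, y = make_classification(n_samples=80, random_state=0)
    model = GradientBoostingClassifier(random_state=0).fit(X, y)
    with pytest.raises(ValueError, match="feature_names"):
        feature_importance(model, ["only", "two"])


# ---------------------------------------------------------------------------
# leakage guard


def test_no_scaling_leakage(small_planted_cohort):
    """Scaling must come from training rows only; test rows only projected."""
    from cmmnet.features import build_feature_matrix

    records = small_planted_cohort
    labels = np.array([r.planted_group for r in records])
    train, test = stratified_split(np.zeros((len(records), 1)), labels, 0.7, seed=0)
    train_records = [records[i] for i in train]
    fm_train = build_feature_matrix(train_records, spec=["protein", "carbohydrate"])
    # stored scaling equals train-only statistics
    vals = np.array([r.nutrient_intakes["protein"] for r in train_records])
    mean, sd = fm_train.scaling["protein"]
    assert mean == pytest.approx(vals.mean(), abs=1e-12)
    assert sd == pytest.approx(vals.std(ddof=0), abs=1e-12)
    # projected test rows use the train statistics, not their own
    test_records = [records[i] for i in test]
    projected = fm_train.transform(test_records)
    test_vals = np.array([r.nutrient_intakes["protein"] for r in test_records])
    assert projected[:, 0] == pytest.approx((test_vals - mean) / sd, abs=1e-12)
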