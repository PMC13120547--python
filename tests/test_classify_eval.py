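import numpy as np
import pandas as pd
import pytest

from safefall.classify_eval import (
    EvalError,
    EvalProtocol,
    LeakageError,
    _assert_no_leakage,
    grouped_split,
    importance_table,
    loso_split,
    run_protocol,
)


def _subject_data(n_subjects=30, frames_per_subject=10, n_features=8,
                  separable=False, seed=0):
    """Frame-level rows for n_subjects, half labelled 'safe'."""
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for i in range(n_subjects):
        label = "safe" if i % 2 == 0 else "hazardous"
        base = rng.normal(0, 1, n_features)
        if separable:
            base[0] = 5.0 if label == "safe" else -5.0
        for _ in range(frames_per_subject):
            rows.append(base + rng.normal(0, 0.3, n_features))
            labels.append(label)
            groups.append(f"S{i:03d}")
    X = pd.DataFrame(np.array(rows), columns=[f"f{j}" for j in range(n_features)])
    return X, np.array(labels), np.array(groups)


class TestGroupedSplit:
    def test_ten_subjects_five_folds_of_two(self):
        ids = np.repeat([f"S{i}" for i in range(10)], 3)
        labels = np.repeat(["a", "b"] * 5, 3)
        folds = grouped_split(ids, labels, k=5, seed=0)
        test_subjects = [set(ids[test]) for _, test in folds]
        assert all(len(s) == 2 for s in test_subjects)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not test_subjects[i] & test_subjects[j]

    def test_zero_subject_overlap_every_fold(self):
        X, labels, groups = _subject_data(n_subjects=20)
        for train, test in grouped_split(groups, labels, k=5, seed=1):
            assert not set(groups[train]) & set(groups[test])

    def test_stratified_minority_share_at_study_sizes(self):
        """415 subjects, 285/130 labels: each fold's minority share stays
        within 5 points of the overall 31.3%."""
        ids = np.array([f"S{i:04d}" for i in range(415)])
        labels = np.array(["pre"] * 285 + ["post"] * 130)
        folds = grouped_split(ids, labels, k=5, stratified=True, seed=2)
        overall = 130 / 415
        for _, test in folds:
            share = np.mean(labels[test] == "post")
            assert abs(share - overall) < 0.05

    def test_fewer_subjects_than_folds_raises(self):
        with pytest.raises(EvalError):
            grouped_split(["a", "b", "c"], ["x", "y", "x"], k=5)

    def test_loso_one_subject_per_fold(self):
        ids = np.repeat([f"S{i}" for i in range(6)], 4)
        folds = loso_split(ids)
        assert len(folds) == 6
        for _, test in folds:
            assert len(set(ids[test])) == 1

    def test_leakage_guard_fires(self):
        ids = np.array(["A", "A", "B"])
        with pytest.raises(LeakageError):
            _assert_no_leakage(ids, np.array([0, 2]), np.array([1]))


class TestRunProtocol:
    def test_perfectly_separable_feature_gives_auc_one(self):
        X, labels, groups = _subject_data(separable=True, seed=3)
        proto = EvalProtocol(
            mode="frame_level", k=5, seed=0,
            models=("random_forest", "logistic_regression"),
        )
        report = run_protocol(X, labels, groups, proto)
        for model in ("random_forest", "logistic_regression"):
            assert report.metrics.loc[(model, "frame"), "auc_mean"] == pytest.approx(1.0)
            assert report.metrics.loc[(model, "sequence"), "auc_mean"] == pytest.approx(1.0)

    def test_reports_are_bit_identical_given_seed(self):
        X, labels, groups = _subject_data(seed=4)
        proto = EvalProtocol(mode="frame_level", k=4, seed=9,
                             models=("random_forest",))
        a = run_protocol(X, labels, groups, proto)
        b = run_protocol(X, labels, groups, proto)
        assert a.to_json() == b.to_json()

    def test_fold_manifest_covers_every_subject_once(self):
        X, labels, groups = _subject_data(n_subjects=16, seed=5)
        proto = EvalProtocol(k=4, models=("random_forest",), seed=1)
        report = run_protocol(X, labels, groups, proto)
        manifest = report.fold_manifest
        assert sorted(manifest.subject_id) == sorted(set(groups))
        assert manifest.groupby("subject_id").size().max() == 1

    def test_accuracy_within_unit_interval_and_f1_sane(self):
        X, labels, groups = _subject_data(seed=6)
        proto = EvalProtocol(models=("random_forest", "logistic_regression"), seed=2)
        report = run_protocol(X, labels, groups, proto)
        cols = [c for c in report.metrics.columns if c.endswith("_mean")]
        vals = report.metrics[cols].to_numpy()
        assert np.all(vals >= 0.0) and np.all(vals <= 1.0)

    def test_five_model_comparison_runs_and_trees_beat_linear(self):
        """All five model families evaluate under the grouped protocol; on a
        non-linearly separable frame-level task the random forest's AUC is at
        least the linear model's (the tree-vs-linear ordering of the fall-
        quality benchmark)."""
        rng = np.random.default_rng(11)
        rows, labels, groups = [], [], []
        for i in range(24):
            label = "safe" if i % 2 == 0 else "hazardous"
            center = rng.normal(0, 1, 6)
            for _ in range(12):
                x = center + rng.normal(0, 0.5, 6)
                # XOR-style nonlinear class signal on two coordinates
                x[0] = (1 if (i % 4 < 2) == (label == "safe") else -1) + rng.normal(0, 0.4)
                x[1] = (1 if (i % 4 < 2) else -1) + rng.normal(0, 0.4)
                rows.append(x)
                labels.append(label)
                groups.append(f"S{i:03d}")
        X = pd.DataFrame(np.array(rows), columns=[f"f{j}" for j in range(6)])
        proto = EvalProtocol(mode="frame_level", k=4, seed=0)
        report = run_protocol(X, np.array(labels), np.array(groups), proto)
        assert set(report.metrics.reset_index()["model"]) == {
            "random_forest", "gradient_boosting", "logistic_regression", "svm", "mlp"
        }
        rf = report.metrics.loc[("random_forest", "frame"), "auc_mean"]
        lr = report.metrics.loc[("logistic_regression", "frame"), "auc_mean"]
        assert rf >= lr

    def test_non_binary_labels_rejected(self):
        X, labels, groups = _subject_data(seed=7)
        labels = np.array(["a", "b", "c"] * (len(labels) // 3 + 1))[: len(labels)]
        with pytest.raises(EvalError):
            run_protocol(X, labels, groups, EvalProtocol(models=("random_forest",)))


class TestImportanceTable:
    def test_informative_feature_ranked_first(self):
        X, labels, groups = _subject_data(separable=True, seed=8)
        proto = EvalProtocol(models=("random_forest",), seed=3)
        report = run_protocol(X, labels, groups, proto)
        table = importance_table(report, top_n=3)
        assert table.iloc[0]["feature"] == "f0"
        assert table["importance"].sum() <= 1.0 + 1e-9

    def test_top_n_larger_than_feature_count_gives_full_table(self):
        X, labels, groups = _subject_data(n_features=5, seed=9)
        proto = EvalProtocol(models=("random_forest",), seed=4)
        report = run_protocol(X, labels, groups, proto)
        assert len(importance_table(report, top_n=99)) == 5

    def test_requires_random_forest(self):
        X, labels, groups = _subject_data(seed=10)
        proto = EvalProtocol(models=("logistic_regression",), seed=5)
        report = run_protocol(X, labels, groups, proto)
        with pytest.raises(EvalError):
            importance_table(report)


def test_protocol_validation():
    with pytest.raises(EvalError):
        EvalProtocol(mode="bogus")
    with pytest.raises(EvalError):
        EvalProtocol(k=1)
    with pytest.raises(EvalError):
        EvalProtocol(models=("random_forest", "nope"))
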