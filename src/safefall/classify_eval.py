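"""Subject-independent supervised evaluation of fall classification tasks.

Two task modes share one protocol machinery:

``subject_metrics``
    One row per subject (the 15 sequence-level metrics); e.g. pre vs post
    intervention status (skill acquisition).
``frame_level``
    Frame-level feature rows; e.g. safe vs hazardous fall quality.  Splits
    are still enforced at the subject level so no subject contributes frames
    to both sides of a fold — a hard leakage guard asserted on every fold.

Models are fitted per fold with fixed seeds; reporting uses macro-averaged
precision/recall/F1 and ROC-AUC (robust to class imbalance, which is
reported rather than resampled away).  For frame-level tasks, metrics are
reported both per frame and pooled per sequence (mean predicted score).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    GroupKFold,
    LeaveOneGroupOut,
    StratifiedGroupKFold,
)
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


class EvalError(Exception):
    pass


class LeakageError(EvalError):
    """A subject appears in both train and test of a fold."""


MODEL_NAMES = (
    "random_forest",
    "gradient_boosting",
    "logistic_regression",
    "svm",
    "mlp",
)


def make_model(name: str, seed: int):
    """Instantiate a named classifier with the package's fixed defaults."""
    if name == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, criterion="gini", random_state=seed, n_jobs=1
        )
    if name == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=100, learning_rate=0.1, random_state=seed
        )
    if name == "logistic_regression":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=seed),  # ridge (L2)
        )
    if name == "svm":
        # AUC uses decision_function margins; no probability calibration
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    if name == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(64,),
                early_stopping=True,
                max_iter=400,
                random_state=seed,
            ),
        )
    raise EvalError(f"unknown model {name!r}")


@dataclass(frozen=True)
class EvalProtocol:
    """Cross-validation protocol specification."""

    mode: str = "subject_metrics"  # or "frame_level"
    splitter: str = "grouped_kfold"  # or "loso"
    k: int = 5
    stratified: bool = True
    seed: int = 0
    models: tuple[str, ...] = MODEL_NAMES

    def __post_init__(self) -> None:
        if self.mode not in ("subject_metrics", "frame_level"):
            raise EvalError(f"unknown mode {self.mode!r}")
        if self.splitter not in ("grouped_kfold", "loso"):
            raise EvalError(f"unknown splitter {self.splitter!r}")
        if self.splitter == "grouped_kfold" and self.k < 2:
            raise EvalError("k must be >= 2")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise EvalError(f"unknown models: {sorted(unknown)}")


def grouped_split(
    subject_ids: Sequence,
    labels: Sequence,
    k: int = 5,
    stratified: bool = True,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition row indices into k folds at the subject level.

    All rows of a subject land in exactly one test fold.  With
    ``stratified``, subject-level label proportions are balanced across
    folds.  Every fold is checked for subject overlap before it is returned.
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    n_subjects = np.unique(subject_ids).size
    if n_subjects < k:
        raise EvalError(f"only {n_subjects} subjects for k={k} folds")
    if stratified:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = GroupKFold(n_splits=k, shuffle=True, random_state=seed)
    X_dummy = np.zeros((len(subject_ids), 1))
    folds = []
    for train, test in splitter.split(X_dummy, labels, groups=subject_ids):
        _assert_no_leakage(subject_ids, train, test)
        folds.append((train, test))
    return folds


def loso_split(subject_ids: Sequence) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds."""
    subject_ids = np.asarray(subject_ids)
    folds = []
    for train, test in LeaveOneGroupOut().split(
        np.zeros((len(subject_ids), 1)), groups=subject_ids
    ):
        _assert_no_leakage(subject_ids, train, test)
        folds.append((train, test))
    return folds


def _assert_no_leakage(
    subject_ids: np.ndarray, train: np.ndarray, test: np.ndarray
) -> None:
    overlap = set(subject_ids[train]) & set(subject_ids[test])
    if overlap:
        raise LeakageError(f"subjects in both train and test: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class EvalReport:
    """Cross-validated performance report."""

    metrics: pd.DataFrame  # rows: (model, pooling); mean ± sd columns
    importances: pd.Series | None  # random-forest MDI importances, sum 1
    fold_manifest: pd.DataFrame  # subject → fold mapping
    protocol: EvalProtocol
    skipped_folds: tuple[int, ...] = field(default_factory=tuple)

    def to_json(self) -> str:
        payload = {
            "protocol": {
                "mode": self.protocol.mode,
                "splitter": self.protocol.splitter,
                "k": self.protocol.k,
                "stratified": self.protocol.stratified,
                "seed": self.protocol.seed,
                "models": list(self.protocol.models),
            },
            "metrics": self.metrics.reset_index().to_dict(orient="records"),
            "importances": (
                None if self.importances is None else self.importances.to_dict()
            ),
            "fold_manifest": self.fold_manifest.to_dict(orient="records"),
            "skipped_folds": list(self.skipped_folds),
        }
        return json.dumps(payload, sort_keys=True, default=float)


_SCORES = ("accuracy", "precision", "recall", "f1", "auc")


def _fold_scores(y_true, y_pred, y_score) -> dict[str, float]:
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, average="macro", zero_division=0),
        "recall": recall_score(y_true, y_pred, average="macro", zero_division=0),
        "f1": f1_score(y_true, y_pred, average="macro", zero_division=0),
    }
    if np.unique(y_true).size < 2:
        out["auc"] = float("nan")
    else:
        out["auc"] = roc_auc_score(y_true, y_score)
    return {k: float(v) for k, v in out.items()}


def run_protocol(
    features: pd.DataFrame,
    labels: Sequence,
    subject_ids: Sequence,
    protocol: EvalProtocol,
) -> EvalReport:
    """Fit and evaluate every model of the protocol across grouped folds.

    NaNs in the feature matrix (derivative boundary rows) are imputed to 0.
    Folds whose training side contains a single class are skipped with a
    logged warning and reported in the result.  Given identical inputs and
    seeds the report is bit-identical.
    """
    X = features.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise EvalError("binary labels required")
    pos = classes[1]
    y_bin = (y == pos).astype(int)
    groups = np.asarray(subject_ids)

    if protocol.splitter == "loso":
        folds = loso_split(groups)
    else:
        folds = grouped_split(
            groups, y, k=protocol.k, stratified=protocol.stratified, seed=protocol.seed
        )

    manifest_rows = []
    for fi, (_, test) in enumerate(folds):
        for s in sorted(set(groups[test])):
            manifest_rows.append({"fold": fi, "subject_id": s})
    manifest = pd.DataFrame(manifest_rows)

    records = []
    rf_importances: list[np.ndarray] = []
    skipped: list[int] = []
    for name in protocol.models:
        per_fold: dict[str, list[dict[str, float]]] = {"frame": [], "sequence": []}
        for fi, (train, test) in enumerate(folds):
            _assert_no_leakage(groups, train, test)
            if np.unique(y_bin[train]).size < 2:
                if fi not in skipped:
                    skipped.append(fi)
                continue
            model = make_model(name, protocol.seed)
            model.fit(X[train], y_bin[train])
            if hasattr(model, "predict_proba"):
                score = model.predict_proba(X[test])[:, 1]
                threshold = 0.5
            else:
                score = model.decision_function(X[test])
                threshold = 0.0
            pred = (score >= threshold).astype(int)
            per_fold["frame"].append(_fold_scores(y_bin[test], pred, score))
            if protocol.mode == "frame_level":
                # sequence pooling: mean predicted score per subject
                df = pd.DataFrame(
                    {"g": groups[test], "y": y_bin[test], "s": score}
                )
                agg = df.groupby("g").agg(y=("y", "first"), s=("s", "mean"))
                per_fold["sequence"].append(
                    _fold_scores(
                        agg["y"], (agg["s"] >= threshold).astype(int), agg["s"]
                    )
                )
            if name == "random_forest":
                est = model if hasattr(model, "feature_importances_") else model[-1]
                rf_importances.append(est.feature_importances_)
        poolings = ("frame", "sequence") if protocol.mode == "frame_level" else ("frame",)
        for pooling in poolings:
            fold_list = per_fold[pooling]
            if not fold_list:
                continue
            rec: dict = {"model": name, "pooling": pooling, "n_folds": len(fold_list)}
            for s in _SCORES:
                vals = np.array([f[s] for f in fold_list])
                rec[f"{s}_mean"] = float(np.nanmean(vals))
                rec[f"{s}_sd"] = float(np.nanstd(vals))
            records.append(rec)

    metrics = pd.DataFrame(records).set_index(["model", "pooling"])
    importances = None
    if rf_importances:
        mean_imp = np.mean(rf_importances, axis=0)
        total = mean_imp.sum()
        if total > 0:
            mean_imp = mean_imp / total
        importances = pd.Series(mean_imp, index=list(features.columns), name="importance")
    return EvalReport(
        metrics=metrics,
        importances=importances,
        fold_manifest=manifest,
        protocol=protocol,
        skipped_folds=tuple(skipped),
    )


def importance_table(report: EvalReport, top_n: int = 10) -> pd.DataFrame:
    """Top-``top_n`` features by mean random-forest importance.

    Ties are broken lexicographically by feature name; importances sum ≤ 1.
    """
    if report.importances is None:
        raise EvalError("random forest was not among the evaluated models")
    s = report.importances
    df = pd.DataFrame({"feature": s.index, "importance": s.to_numpy()})
    df = df.sort_values(
        ["importance", "feature"], ascending=[False, True], kind="stable"
    ).head(top_n)
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)
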