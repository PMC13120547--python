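"""The hybrid Safe Fall composite score.

``S_safe = Σ_j w_j · f_j`` over a set of kinematic features that is both
hypothesis-driven and data-driven: features are first filtered by absolute
Cohen's d between safe and hazardous falls (biomechanical relevance), then
weighted by the mean-decrease-in-impurity importances of a random-forest
classifier fitted on the retained features (discriminative power).  Each
feature is min-max normalised to [0, 1] against robust percentile anchors
and orientation-flipped so that 1 always means safer; the score is their
weighted sum, in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .kinematics import MetricVector


class ScoringError(Exception):
    """Base class for scoring failures."""


class UndefinedEffectError(ScoringError):
    """Cohen's d undefined (zero pooled variance)."""


class EmptyModelError(ScoringError):
    """No feature passed the effect-size filter."""


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d = (mean_b − mean_a) / pooled sd.

    The pooled standard deviation uses the two sample variances with n−1
    denominators.  Antisymmetric under swapping the groups.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedEffectError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0 or not np.isfinite(pooled):
        raise UndefinedEffectError("zero pooled variance")
    return float((b.mean() - a.mean()) / pooled)


@dataclass(frozen=True)
class ScoreModel:
    """Fitted parameters of the composite score.

    ``direction[j] = +1`` if larger values of feature j indicate a safer
    fall, −1 otherwise; ``bounds`` are the per-feature normalisation anchors
    (low, high); ``weights`` are nonnegative and sum to 1.
    """

    selected_features: tuple[str, ...]
    direction: tuple[int, ...]
    bounds: tuple[tuple[float, float], ...]
    weights: tuple[float, ...]
    d_threshold: float
    effect_sizes: tuple[float, ...]  # Cohen's d (toward safe) per feature

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ScoringError("weights must be nonnegative and sum to 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ScoringError("normalisation bounds must satisfy low < high")

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema": "safefall-score-model",
            "version": 1,
            "selected_features": list(self.selected_features),
            "direction": list(self.direction),
            "bounds": [list(b) for b in self.bounds],
            "weights": list(self.weights),
            "d_threshold": self.d_threshold,
            "effect_sizes": list(self.effect_sizes),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoreModel":
        p = Path(source)
        payload = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            selected_features=tuple(payload["selected_features"]),
            direction=tuple(int(v) for v in payload["direction"]),
            bounds=tuple((float(lo), float(hi)) for lo, hi in payload["bounds"]),
            weights=tuple(float(v) for v in payload["weights"]),
            d_threshold=float(payload["d_threshold"]),
            effect_sizes=tuple(float(v) for v in payload["effect_sizes"]),
        )


def fit_score_model(
    metrics: pd.DataFrame,
    labels: Sequence[str],
    d_threshold: float = 0.5,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    percentile_bounds: tuple[float, float] = (2.5, 97.5),
) -> ScoreModel:
    """Fit the composite-score model from labelled metric vectors.

    ``labels`` holds ``"safe"`` / ``"hazardous"`` per row.  Features with
    |d| ≥ ``d_threshold`` are retained (d computed hazardous → safe, so its
    sign is the safety direction); weights come from the impurity importances
    of a 100-tree Gini random forest fitted on the retained features and are
    renormalised to sum to 1; bounds are robust percentiles over the fitting
    cohort.
    """
    labels = np.asarray(labels)
    if metrics.shape[0] < 10:
        raise ScoringError("need at least 10 rows to fit a score model")
    safe = labels == "safe"
    hazardous = labels == "hazardous"
    if not safe.any() or not hazardous.any():
        raise ScoringError("both 'safe' and 'hazardous' labels must be present")
    if feature_names is None:
        feature_names = [
            c for c in metrics.columns if pd.api.types.is_numeric_dtype(metrics[c])
        ]

    selected: list[str] = []
    directions: list[int] = []
    effects: list[float] = []
    for name in feature_names:
        col = metrics[name].to_numpy(dtype=float)
        try:
            d = cohens_d(col[hazardous], col[safe])
        except UndefinedEffectError:
            continue
        if abs(d) >= d_threshold:
            selected.append(name)
            directions.append(1 if d > 0 else -1)
            effects.append(d)
    if not selected:
        raise EmptyModelError(
            f"no feature reached |d| >= {d_threshold}; lower the threshold"
        )

    X = metrics[selected].to_numpy(dtype=float)
    rf = RandomForestClassifier(
        n_estimators=100, criterion="gini", random_state=seed, n_jobs=1
    )
    rf.fit(X, safe.astype(int))
    imp = rf.feature_importances_
    total = imp.sum()
    if total <= 0:
        raise ScoringError("random forest produced all-zero importances")
    weights = imp / total

    lo_q, hi_q = percentile_bounds
    bounds = []
    for j, name in enumerate(selected):
        lo, hi = np.percentile(X[:, j], [lo_q, hi_q])
        if not lo < hi:  # degenerate spread: widen minimally
            lo, hi = float(np.min(X[:, j])), float(np.max(X[:, j]))
            if not lo < hi:
                lo, hi = lo - 0.5, lo + 0.5
        bounds.append((float(lo), float(hi)))

    return ScoreModel(
        selected_features=tuple(selected),
        direction=tuple(directions),
        bounds=tuple(bounds),
        weights=tuple(float(w) for w in weights),
        d_threshold=float(d_threshold),
        effect_sizes=tuple(effects),
    )


def composite_score(
    metrics: MetricVector | Mapping[str, float], model: ScoreModel
) -> float:
    """Score one fall: weighted sum of normalised, safety-oriented features."""
    if isinstance(metrics, MetricVector):
        metrics = metrics.as_dict()
    total = 0.0
    for name, sign, (lo, hi), w in zip(
        model.selected_features, model.direction, model.bounds, model.weights
    ):
        if name not in metrics:
            raise ScoringError(f"metric {name!r} missing from input")
        f = (float(metrics[name]) - lo) / (hi - lo)
        f = min(max(f, 0.0), 1.0)
        if sign < 0:
            f = 1.0 - f
        total += w * f
    return total


def score_table(metrics: pd.DataFrame, model: ScoreModel) -> pd.Series:
    """Composite score for every row of a metric table."""
    missing = [c for c in model.selected_features if c not in metrics.columns]
    if missing:
        raise ScoringError(f"metrics missing from table: {missing}")
    X = metrics[list(model.selected_features)].to_numpy(dtype=float)
    lo = np.array([b[0] for b in model.bounds])
    hi = np.array([b[1] for b in model.bounds])
    f = np.clip((X - lo) / (hi - lo), 0.0, 1.0)
    sign = np.asarray(model.direction)
    f = np.where(sign < 0, 1.0 - f, f)
    return pd.Series(f @ np.asarray(model.weights), index=metrics.index, name="s_safe")


def cohens_kappa(annotations_a: Sequence, annotations_b: Sequence) -> float:
    """Chance-corrected agreement between two raters' labels.

    Utility for user-supplied double annotations; not used by the pipeline.
    """
    a = np.asarray(annotations_a)
    b = np.asarray(annotations_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("annotation vectors must be equal-length and non-empty")
    cats = np.union1d(a, b)
    po = float(np.mean(a == b))
    pe = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)
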