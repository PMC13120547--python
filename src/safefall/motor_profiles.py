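"""Unsupervised motor-profile analysis: PCA, k-means, cluster characterisation.

The 15 sequence-level metrics are z-standardised (unscaled pixel metrics
would dominate the objective), projected with PCA for inspection, and
partitioned with k-means (k = 3 by default, matching the three motor
profiles: chaotic high-intensity, controlled tuck-and-roll, passive
freezing).  Clusters are relabelled canonically by descending
movement-intensity centroid so cluster 0 is always the chaotic-like group,
and the cohort×cluster association is tested with a Pearson chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .kinematics import METRIC_NAMES

logger = logging.getLogger(__name__)


class ClusteringError(Exception):
    pass


def project_pca(
    metrics: pd.DataFrame,
    n_components: int = 2,
    feature_names: Sequence[str] = METRIC_NAMES,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-standardise and project onto principal components.

    Returns ``(scores, explained_variance_pct)``.  Constant columns are
    dropped with a warning before standardisation.
    """
    X, kept = _standardised(metrics, feature_names)
    if X.shape[1] < n_components:
        raise ClusteringError(
            f"only {X.shape[1]} non-degenerate columns for {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, 100.0 * pca.explained_variance_ratio_


def _standardised(
    metrics: pd.DataFrame, feature_names: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    X = metrics[list(feature_names)].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(feature_names, keep) if not k]
        logger.warning("dropping constant metric column(s): %s", dropped)
    kept = [n for n, k in zip(feature_names, keep) if k]
    if not kept:
        raise ClusteringError("all metric columns are constant")
    return StandardScaler().fit_transform(X[:, keep]), kept


def cluster_kmeans(
    metrics: pd.DataFrame,
    k: int = 3,
    n_init: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] = METRIC_NAMES,
) -> np.ndarray:
    """Best-of-``n_init`` k-means on the z-standardised metrics.

    Deterministic given ``seed``.  Cluster ids are relabelled canonically by
    descending movement-intensity centroid (chaotic-like motion first), so
    labels are stable across seeds.
    """
    if k < 2:
        raise ClusteringError("k must be >= 2")
    if len(metrics) < k:
        raise ClusteringError("need at least k rows")
    X, _ = _standardised(metrics, feature_names)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    order_key = (
        metrics["movement_intensity"].to_numpy(dtype=float)
        if "movement_intensity" in metrics.columns
        else X[:, 0]
    )
    centroid_mi = np.array([order_key[raw == c].mean() for c in range(k)])
    order = np.argsort(-centroid_mi, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]


def kmeans_inertia(
    metrics: pd.DataFrame,
    k: int = 3,
    n_init: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] = METRIC_NAMES,
) -> float:
    """Within-cluster sum of squares of the best-of-``n_init`` solution."""
    X, _ = _standardised(metrics, feature_names)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return float(km.inertia_)


def characterize_clusters(
    metrics: pd.DataFrame,
    assignments: Sequence[int],
    feature_names: Sequence[str] = METRIC_NAMES,
) -> pd.DataFrame:
    """Per-cluster centroid profiles as % deviation from the sample mean.

    ``100 · (cluster mean − sample mean) / sample mean`` per metric; NaN
    where the sample mean is zero.
    """
    assignments = np.asarray(assignments)
    rows = []
    sample_mean = metrics[list(feature_names)].mean()
    for c in sorted(np.unique(assignments)):
        sub = metrics.loc[assignments == c, list(feature_names)].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 100.0 * (sub - sample_mean) / sample_mean
        dev[sample_mean == 0] = np.nan
        row = dev.to_dict()
        row["cluster"] = int(c)
        row["n"] = int(np.sum(assignments == c))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def cohort_cluster_association(
    cohorts: Sequence[str], assignments: Sequence[int]
) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-square test of cohort × cluster independence.

    No continuity correction.  Warns when any expected count is below 5;
    degenerate margins (a single cohort or single cluster) raise.
    """
    table = pd.crosstab(pd.Series(cohorts, name="cohort"),
                        pd.Series(assignments, name="cluster"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ClusteringError("need >= 2 cohorts and >= 2 clusters")
    chi2, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if np.any(expected <= 0):
        raise ClusteringError("some expected counts are zero")
    if np.any(expected < 5):
        logger.warning("chi-square: some expected counts are below 5")
    return float(chi2), float(p), table


@dataclass(frozen=True)
class ClusterReport:
    """Full unsupervised-analysis report."""

    k: int
    assignments: np.ndarray
    explained_variance: np.ndarray  # per component, %
    pc_scores: np.ndarray
    centroid_profiles: pd.DataFrame
    cohort_table: pd.DataFrame
    chi2: float
    chi2_p: float

    def cluster_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.assignments, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def profile_clusters(
    metrics: pd.DataFrame,
    k: int = 3,
    n_init: int = 10,
    seed: int = 0,
    cohort_column: str = "cohort",
) -> ClusterReport:
    """Run the full clustering stage: PCA projection, k-means, profiles, chi²."""
    scores, ev = project_pca(metrics, n_components=2)
    assignments = cluster_kmeans(metrics, k=k, n_init=n_init, seed=seed)
    profiles = characterize_clusters(metrics, assignments)
    chi2, p, table = cohort_cluster_association(
        metrics[cohort_column].tolist(), assignments
    )
    return ClusterReport(
        k=k,
        assignments=assignments,
        explained_variance=ev,
        pc_scores=scores,
        centroid_profiles=profiles,
        cohort_table=table,
        chi2=chi2,
        chi2_p=p,
    )


def plot_clusters(report: ClusterReport, path: str) -> None:
    """2D PC1/PC2 scatter coloured by cluster, written to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for c in sorted(set(report.assignments)):
        mask = report.assignments == c
        ax.scatter(
            report.pc_scores[mask, 0],
            report.pc_scores[mask, 1],
            s=12,
            label=f"cluster {c} (n={mask.sum()})",
        )
    ax.set_xlabel(f"PC1 ({report.explained_variance[0]:.1f}% var)")
    ax.set_ylabel(f"PC2 ({report.explained_variance[1]:.1f}% var)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
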