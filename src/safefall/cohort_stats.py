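"""Pre/post cohort comparison: normality gate, Mann–Whitney U, FDR, effects.

The comparison framework mirrors a standard unpaired pre/post intervention
analysis over the 15 sequence-level kinematic metrics: a Shapiro–Wilk
normality gate per group, the non-parametric Mann–Whitney U test (exact
null when feasible), Benjamini–Hochberg FDR adjustment across metrics,
Cohen's d effect sizes, percent change (reported on both medians and means)
and a rollup of significant findings by metric category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kinematics import METRIC_CATEGORIES, METRIC_NAMES
from .scoring import UndefinedEffectError, cohens_d


class StatsInputError(Exception):
    """Invalid input to a statistical routine."""


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> bool:
    """True if Shapiro–Wilk does not reject normality at ``alpha``.

    Constant (degenerate) samples are reported as rejected.  Supported for
    3 ≤ n ≤ 5000.
    """
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise StatsInputError("Shapiro-Wilk supported for 3 <= n <= 5000")
    if np.all(x == x[0]):
        return False
    with np.errstate(all="ignore"):
        _, p = stats.shapiro(x)
    return bool(p >= alpha)


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    sides: str = "two-sided",
) -> tuple[float, float]:
    """Mann–Whitney U test (U statistic of group_a, p-value).

    Uses the exact null distribution when both groups have ≤ 20 values and
    there are no ties, and the tie-corrected normal approximation otherwise.
    If the pooled sample is constant the test is vacuous and p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=sides, method=method)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatsInputError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _percent_change(pre: float, post: float) -> float:
    if pre == 0:
        return float("nan")
    return 100.0 * (post - pre) / pre


@dataclass(frozen=True)
class CohortComparison:
    """Per-metric test results and category rollups for a pre/post contrast."""

    table: pd.DataFrame  # one row per metric
    category_summary: pd.DataFrame  # one row per category
    alpha: float
    n_pre: int
    n_post: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def to_markdown(self) -> str:
        lines = [
            f"Pre/post comparison (n_pre={self.n_pre}, n_post={self.n_post}, "
            f"alpha={self.alpha})",
            "",
            self.table.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
            "",
            "By category:",
            self.category_summary.to_string(index=False),
        ]
        return "\n".join(lines)


def compare_cohorts(
    metrics: pd.DataFrame,
    cohort_column: str = "cohort",
    alpha: float = 0.05,
    metric_names: Sequence[str] = METRIC_NAMES,
) -> CohortComparison:
    """Run the full per-metric pre/post framework on a metric table.

    For every metric: group medians and means, Shapiro–Wilk gate per group,
    Mann–Whitney U (the non-parametric path is used throughout, as the gate
    rejects for essentially all pixel-kinematic metrics), BH adjustment
    across metrics, Cohen's d, percent change on medians and means, a
    direction arrow and a significance flag at ``alpha`` (on adjusted p).
    """
    pre = metrics[metrics[cohort_column] == "pre"]
    post = metrics[metrics[cohort_column] == "post"]
    if len(pre) < 3 or len(post) < 3:
        raise StatsInputError("both cohorts need at least 3 rows")

    rows = []
    for name in metric_names:
        a = pre[name].to_numpy(dtype=float)
        b = post[name].to_numpy(dtype=float)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
        norm_a = normality_gate(a, alpha) if 3 <= a.size <= 5000 else False
        norm_b = normality_gate(b, alpha) if 3 <= b.size <= 5000 else False
        u, p = mann_whitney(a, b)
        try:
            d = cohens_d(a, b)
        except UndefinedEffectError:
            d = float("nan")
        rows.append(
            {
                "metric": name,
                "category": METRIC_CATEGORIES.get(name, "other"),
                "median_pre": med_a,
                "median_post": med_b,
                "mean_pre": mean_a,
                "mean_post": mean_b,
                "normal_pre": norm_a,
                "normal_post": norm_b,
                "U": u,
                "p_raw": p,
                "cohens_d": d,
                "pct_change_median": _percent_change(med_a, med_b),
                "pct_change_mean": _percent_change(mean_a, mean_b),
                "direction": "↑" if med_b > med_a else ("↓" if med_b < med_a else "="),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = fdr_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adjusted"] < alpha

    cats = (
        table.groupby("category", sort=False)
        .agg(total=("metric", "size"), significant=("significant", "sum"))
        .reset_index()
    )
    cats["pct_significant"] = 100.0 * cats["significant"] / cats["total"]

    return CohortComparison(
        table=table,
        category_summary=cats,
        alpha=alpha,
        n_pre=len(pre),
        n_post=len(post),
    )
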