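"""Management-strategy clustering.

Each optimal genome is summarized into four features — total mineral N,
number of non-zero applications, week of the first application and FYM
amount — which are standardized per dimension and clustered with Ward's
minimum-variance hierarchical method. Clusters are ranked by mean
profitability, and a configurable fraction of most-profitable frontier
points can be flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .surrogate import ManagementPlan, N_APPLICATIONS

__all__ = [
    "FIRST_APP_SENTINEL",
    "FEATURE_NAMES",
    "DEFAULT_BIN_EDGES",
    "StrategyFeatures",
    "ClusterResult",
    "summarize_plan",
    "features_matrix",
    "cluster_strategies",
    "rank_clusters_by_profit",
    "flag_profitable_points",
    "cluster_histograms",
    "dendrogram_gap_suggestion",
]

#: Week index reported for plans with no N application at all
#: (one past the last possible application date, keeping the feature numeric).
FIRST_APP_SENTINEL = N_APPLICATIONS + 1

FEATURE_NAMES = ("total_n", "n_apps", "first_app_week", "fym_amount")

#: Documented default histogram bin edges per feature.
DEFAULT_BIN_EDGES: dict[str, np.ndarray] = {
    "total_n": np.linspace(0.0, 900.0, 10),
    "n_apps": np.arange(-0.5, N_APPLICATIONS + 1.5),
    "first_app_week": np.arange(0.5, FIRST_APP_SENTINEL + 1.5),
    "fym_amount": np.linspace(0.0, 3.0, 7),
}


@dataclass(frozen=True)
class StrategyFeatures:
    total_n: float
    n_apps: int
    first_app_week: int
    fym_amount: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.total_n, self.n_apps, self.first_app_week, self.fym_amount]
        )


@dataclass
class ClusterResult:
    """Partition of points into k strategies plus the merge tree."""

    labels: np.ndarray  # cluster id (1..k) per point
    k: int
    linkage_matrix: np.ndarray
    dropped_features: tuple[str, ...] = ()


def summarize_plan(plan: ManagementPlan) -> StrategyFeatures:
    """Reduce the nine N genes to (total N, #applications, first week)."""
    nonzero = [i for i, r in enumerate(plan.n_rates) if r > 0]
    return StrategyFeatures(
        total_n=float(sum(plan.n_rates)),
        n_apps=len(nonzero),
        first_app_week=(nonzero[0] + 1) if nonzero else FIRST_APP_SENTINEL,
        fym_amount=plan.fym_amount,
    )


def features_matrix(features: list[StrategyFeatures]) -> np.ndarray:
    return np.array([f.to_array() for f in features])


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    return features_matrix(list(features))


def cluster_strategies(features, k: int) -> ClusterResult:
    """Ward clustering of standardized strategy features, cut at k clusters.

    Features are divided by their sample standard deviation (ddof=1)
    before Euclidean/Ward linkage — i.e. standardized Euclidean distance.
    Zero-variance dimensions are dropped with a warning. Deterministic
    given input order (scipy's linkage breaks ties by merge order).
    """
    x = _as_matrix(features)
    n = len(x)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    std = x.std(axis=0, ddof=1) if n > 1 else np.ones(x.shape[1])
    keep = std > 0
    dropped = tuple(
        FEATURE_NAMES[j] if j < len(FEATURE_NAMES) else f"feature_{j}"
        for j in np.flatnonzero(~keep)
    )
    if dropped:
        warnings.warn(
            f"dropping zero-variance feature(s) before clustering: {dropped}",
            stacklevel=2,
        )
    if not keep.any():
        # all points identical: single merge chain, all in one cluster
        z = linkage(np.zeros((n, 1)), method="ward")
        labels = fcluster(z, t=k, criterion="maxclust")
        return ClusterResult(labels=labels, k=int(labels.max()), linkage_matrix=z)
    x_std = x[:, keep] / std[keep]
    z = linkage(x_std, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(
        labels=labels, k=int(labels.max()), linkage_matrix=z, dropped_features=dropped
    )


def rank_clusters_by_profit(
    result: ClusterResult, profits, top_m: int | None = None
) -> tuple[list[int], list[int]]:
    """Order cluster ids by decreasing mean profit.

    Returns ``(ordered_ids, profitable_ids)`` where ``profitable_ids``
    are the top ``top_m`` clusters (all of them when ``top_m`` is None).
    """
    profits = np.asarray(profits, dtype=float)
    if len(profits) != len(result.labels):
        raise ValueError("profits and cluster labels have different lengths")
    ids = np.unique(result.labels)
    means = np.array([profits[result.labels == c].mean() for c in ids])
    order = np.argsort(-means, kind="stable")
    ordered = [int(ids[i]) for i in order]
    flagged = ordered if top_m is None else ordered[: max(0, top_m)]
    return ordered, list(flagged)


def flag_profitable_points(profits, fraction: float = 0.3) -> np.ndarray:
    """Boolean mask of the ``ceil(fraction * n)`` most profitable points.

    Ties are broken by stable order: among equal profits, earlier points
    are flagged first.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    profits = np.asarray(profits, dtype=float)
    n = len(profits)
    n_flag = math.ceil(fraction * n)
    order = np.argsort(-profits, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_flag]] = True
    return mask


def cluster_histograms(
    result: ClusterResult,
    features,
    bin_edges: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-cluster, per-feature binned fractions (each histogram sums to 1).

    Returns a long-format frame with columns cluster, feature, bin_lo,
    bin_hi, fraction.
    """
    x = _as_matrix(features)
    if len(x) != len(result.labels):
        raise ValueError("features and cluster labels have different lengths")
    edges = dict(DEFAULT_BIN_EDGES)
    if bin_edges:
        edges.update(bin_edges)
    rows = []
    for cluster_id in np.unique(result.labels):
        members = x[result.labels == cluster_id]
        for j, name in enumerate(FEATURE_NAMES):
            e = np.asarray(edges[name], dtype=float)
            vals = np.clip(members[:, j], e[0], e[-1])
            counts, _ = np.histogram(vals, bins=e)
            fracs = counts / counts.sum()
            for b in range(len(e) - 1):
                rows.append(
                    {
                        "cluster": int(cluster_id),
                        "feature": name,
                        "bin_lo": e[b],
                        "bin_hi": e[b + 1],
                        "fraction": fracs[b],
                    }
                )
    return pd.DataFrame(rows)


def dendrogram_gap_suggestion(linkage_matrix: np.ndarray, max_k: int = 15) -> int:
    """Suggest a cluster count from the largest relative merge-height gap.

    Advisory only — the pipeline never auto-selects k silently.
    """
    heights = linkage_matrix[:, 2]
    n = len(heights) + 1
    kmax = min(max_k, n)
    best_k, best_ratio = 1, -np.inf
    for k in range(2, kmax + 1):
        # cutting into k clusters happens between merges n-k-1 and n-k
        prev = heights[n - k - 1] if n - k - 1 >= 0 else 0.0
        ratio = heights[n - k] / max(prev, 1e-12)
        if ratio > best_ratio:
            best_ratio, best_k = ratio, k
    return best_k
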