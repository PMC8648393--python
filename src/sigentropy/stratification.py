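"""Sample and cancer-type stratification by SR/LSR.

Hierarchical clustering uses Euclidean distance with average linkage
(UPGMA); k-means selects the best of ``n_starts`` seeded initializations
by within-cluster sum of squares.  Cluster-clinical association is tested
with Pearson's chi-square on the contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans


@dataclass
class ClusterAssignment:
    """Item-to-cluster mapping with the method metadata that produced it."""

    labels: pd.Series  # item id -> cluster label in 1..k
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        uniq = np.sort(self.labels.unique())
        k = len(uniq)
        if not np.array_equal(uniq, np.arange(1, k + 1)):
            raise ValueError("cluster labels must be contiguous 1..k")

    @property
    def k(self) -> int:
        return int(self.labels.max())


def hierarchical(matrix: pd.DataFrame, k: int | None = None,
                 ) -> tuple[np.ndarray, ClusterAssignment | None]:
    """UPGMA tree on Euclidean distances between rows of ``matrix``.

    Returns the scipy linkage matrix and, when ``k`` is given, the flat
    assignment at that cut.  Ties in merge order follow scipy's
    deterministic lowest-index convention.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if matrix.isna().any().any():
        raise ValueError("missing values in clustering input")
    Z = linkage(pdist(matrix.to_numpy(float), metric="euclidean"),
                method="average")
    if k is None:
        return Z, None
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(_relabel(raw), index=matrix.index, name="cluster")
    return Z, ClusterAssignment(labels, "hierarchical",
                                {"k": k, "distance": "euclidean",
                                 "linkage": "average"})


def kmeans(matrix: pd.DataFrame, k: int, n_starts: int = 25,
           seed: int = 0) -> ClusterAssignment:
    """Best-of-``n_starts`` k-means by within-cluster sum of squares;
    reproducible given the seed."""
    if k > matrix.shape[0]:
        raise ValueError("k cannot exceed the number of items")
    if matrix.isna().any().any():
        raise ValueError("missing values in clustering input")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    raw = km.fit_predict(matrix.to_numpy(float)) + 1
    labels = pd.Series(_relabel(raw), index=matrix.index, name="cluster")
    return ClusterAssignment(labels, "kmeans",
                             {"k": k, "n_starts": n_starts, "seed": seed,
                              "wcss": float(km.inertia_)})


def _relabel(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to contiguous 1..k by first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        out[i] = mapping.setdefault(int(lab), len(mapping) + 1)
    return out


def chi_square_association(labels: ClusterAssignment,
                           factor: pd.Series) -> tuple[float, int, float]:
    """Pearson chi-square between cluster labels and a categorical factor.

    Returns (statistic, df, p).  A zero expected count makes the statistic
    undefined; merge sparse levels first.
    """
    joined = pd.concat([labels.labels, factor], axis=1, join="inner")
    joined.columns = ["cluster", "factor"]
    if joined.shape[0] == 0:
        raise ValueError("no shared items between labels and factor")
    if joined["factor"].nunique() < 2 or joined["cluster"].nunique() < 2:
        raise ValueError("need at least 2 levels in both variables")
    table = pd.crosstab(joined["cluster"], joined["factor"])
    expected = stats.contingency.expected_freq(table.to_numpy())
    if (expected == 0).any():
        raise ValueError("zero expected count in contingency table; "
                         "merge sparse levels")
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
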