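"""Hierarchical clustering of decoys on their pairwise-RMSD matrix.

The decoy set is partitioned by agglomerative clustering on the precomputed
RMSD dissimilarity matrix (average linkage by default; RMSD after
independent superpositions is not guaranteed Euclidean, so Ward-style
embeddings are deliberately not offered as defaults).  The number of
clusters is chosen by a deterministic elbow criterion on the within-cluster
dispersion curve

    W(k) = (1/n) * sum_clusters (1/n_c) * sum_{i,j in c} rmsd_ij^2

(size-weighted mean within-cluster squared RMSD): the selected k maximises
the discrete second difference W(k-1) - 2 W(k) + W(k+1), unless the
ensemble is already nearly homogeneous (W(1) below a flatness floor), in
which case k = 1.  Each cluster's representative ("centroid") is the
member with the lowest external energy, not a geometric average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .core import EnergyTable
from .geometry import RMSDMatrix

__all__ = [
    "ClusteringResult",
    "RMSDHierarchicalClustering",
    "cut_hierarchy",
    "elbow_select_k",
    "dispersion_curve",
    "select_centroids",
    "cluster_ensemble",
]

Linkage = Literal["average", "complete", "single"]

#: default mean within-cluster squared RMSD (Å^2) at k=1 below which the
#: ensemble counts as homogeneous and the elbow is skipped (k=1 returned)
FLATNESS_FLOOR = 0.25


def _as_matrix(matrix: RMSDMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, RMSDMatrix):
        return matrix.values, matrix.model_ids
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square RMSD matrix")
    return m, [str(i) for i in range(m.shape[0])]


def _renumber_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by decreasing size; ties by smallest member index."""
    sizes: dict[int, int] = {}
    first_member: dict[int, int] = {}
    for i, lab in enumerate(raw):
        sizes[lab] = sizes.get(lab, 0) + 1
        first_member.setdefault(lab, i)
    order = sorted(sizes, key=lambda lab: (-sizes[lab], first_member[lab]))
    mapping = {lab: new + 1 for new, lab in enumerate(order)}
    return np.array([mapping[lab] for lab in raw], dtype=int)


def _linkage_matrix(values: np.ndarray, linkage: Linkage) -> np.ndarray:
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    condensed = squareform(values, checks=False)
    return sch.linkage(condensed, method=linkage)


def cut_hierarchy(
    matrix: RMSDMatrix | np.ndarray,
    k: int,
    linkage: Linkage = "average",
) -> np.ndarray:
    """Cut the agglomerative dendrogram into exactly *k* clusters.

    Returns integer labels 1..k aligned with the matrix's model order,
    numbered by decreasing cluster size (ties broken by the smallest member
    index).
    """
    values, _ = _as_matrix(matrix)
    n = values.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if k == 1:
        return np.ones(n, dtype=int)
    if k == n:
        return np.arange(1, n + 1, dtype=int)
    z = _linkage_matrix(values, linkage)
    raw = sch.cut_tree(z, n_clusters=k).ravel()
    return _renumber_labels(raw)


def dispersion_curve(
    matrix: RMSDMatrix | np.ndarray,
    k_max: int,
    linkage: Linkage = "average",
) -> np.ndarray:
    """W(k) for k = 1..k_max from nested dendrogram cuts.

    W(k) is the size-weighted mean within-cluster squared RMSD (see module
    docstring); it is non-increasing along the nested cuts of one tree.
    """
    values, _ = _as_matrix(matrix)
    n = values.shape[0]
    if not 1 <= k_max <= n:
        raise ValueError(f"k_max={k_max} out of range 1..{n}")
    sq = values**2
    out = np.empty(k_max)
    z = _linkage_matrix(values, linkage) if k_max > 1 else None
    for k in range(1, k_max + 1):
        if k == 1:
            labels = np.ones(n, dtype=int)
        elif k == n:
            labels = np.arange(n)
        else:
            labels = sch.cut_tree(z, n_clusters=k).ravel()
        w = 0.0
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            block = sq[np.ix_(members, members)]
            w += block.sum() / len(members)
        out[k - 1] = w / n
    return out


def elbow_select_k(
    matrix: RMSDMatrix | np.ndarray,
    k_max: int,
    linkage: Linkage = "average",
    flatness_floor: float = FLATNESS_FLOOR,
) -> int:
    """Choose the cluster count by the maximum-curvature elbow criterion.

    Computes W(k) for k = 1..k_max; returns 1 if W(1) < *flatness_floor*
    (the ensemble is already homogeneous), else the k in 2..k_max-1
    maximising the second difference W(k-1) - 2 W(k) + W(k+1) (smallest k on
    ties).
    """
    values, _ = _as_matrix(matrix)
    n = values.shape[0]
    if n < 3:
        raise ValueError("elbow selection needs at least 3 models")
    if not (2 <= k_max < n):
        raise ValueError(f"k_max={k_max} must satisfy 2 <= k_max < n={n}")
    w = dispersion_curve(matrix, k_max, linkage)
    if w[0] < flatness_floor:
        return 1
    if k_max == 2:
        return 2
    second_diff = w[:-2] - 2 * w[1:-1] + w[2:]  # index i -> k = i + 2
    return int(np.argmax(second_diff)) + 2


def select_centroids(
    labels: Mapping[str, int] | np.ndarray,
    energies: EnergyTable,
    model_ids: Sequence[str] | None = None,
) -> dict[int, str]:
    """Per cluster, the member with minimal energy (lowest-energy centroid).

    *labels* is either a mapping model_id -> cluster index or an array of
    labels aligned with *model_ids*.  Ties in energy are broken by the
    smallest model index (position in the input order).
    """
    if isinstance(labels, Mapping):
        items = list(labels.items())
    else:
        if model_ids is None:
            raise ValueError("model_ids required when labels is an array")
        labels = np.asarray(labels)
        if len(labels) != len(model_ids):
            raise ValueError("labels and model_ids length mismatch")
        items = list(zip(model_ids, labels.tolist()))
    missing = [m for m, _ in items if m not in energies]
    if missing:
        raise KeyError(f"labeled models missing from energy table: {missing}")
    centroids: dict[int, tuple[float, int, str]] = {}
    for index, (mid, lab) in enumerate(items):
        lab = int(lab)
        cand = (energies[mid], index, mid)
        if lab not in centroids or cand < centroids[lab]:
            centroids[lab] = cand
    return {lab: mid for lab, (_, _, mid) in sorted(centroids.items())}


class RMSDHierarchicalClustering(ClusterMixin, BaseEstimator):
    """Agglomerative clustering on a precomputed pairwise-RMSD matrix.

    scikit-learn style estimator: ``fit(X)`` takes a square symmetric RMSD
    matrix (``numpy`` array or :class:`~conformens.geometry.RMSDMatrix`).
    With ``n_clusters=None`` (default) the cluster count is selected by the
    elbow criterion up to ``k_max``; otherwise the dendrogram is cut at the
    requested count.

    Parameters
    ----------
    n_clusters
        Fixed cluster count, or None for elbow selection.
    k_max
        Largest k scanned by the elbow criterion.
    linkage
        ``"average"`` (default), ``"complete"`` or ``"single"``.
    flatness_floor
        W(1) below this value (Å²) short-circuits to a single cluster.

    Attributes
    ----------
    n_clusters_ : int
        Selected or requested cluster count.
    labels_ : ndarray of int
        Cluster label (1..k) per model, numbered by decreasing cluster size.
    dispersion_curve_ : ndarray
        W(k) for k = 1..k_max (only when the elbow criterion ran).
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        k_max: int = 10,
        linkage: Linkage = "average",
        flatness_floor: float = FLATNESS_FLOOR,
    ) -> None:
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.linkage = linkage
        self.flatness_floor = flatness_floor

    def fit(self, X, y=None):
        values, ids = _as_matrix(X)
        n = values.shape[0]
        if n < 2:
            raise ValueError("clustering needs at least 2 models")
        if self.n_clusters is not None:
            k = int(self.n_clusters)
            self.dispersion_curve_ = dispersion_curve(
                values, min(self.k_max, n), self.linkage
            )
        else:
            k_max = min(self.k_max, n - 1)
            k = elbow_select_k(values, k_max, self.linkage, self.flatness_floor)
            self.dispersion_curve_ = dispersion_curve(values, k_max, self.linkage)
        self.n_clusters_ = k
        self.labels_ = cut_hierarchy(values, k, self.linkage)
        self.model_ids_ = ids
        return self

    def labels_by_id(self) -> dict[str, int]:
        return dict(zip(self.model_ids_, self.labels_.tolist()))


@dataclass
class ClusteringResult:
    """Partition of a decoy set with elbow-selected k and energy centroids."""

    k: int
    labels: dict[str, int]
    dispersion_curve: np.ndarray
    centroid_ids: dict[int, str]

    def members(self, cluster: int) -> list[str]:
        return [m for m, lab in self.labels.items() if lab == cluster]

    def to_dataframe(self, energies: EnergyTable) -> pd.DataFrame:
        ids = list(self.labels)
        return pd.DataFrame(
            {
                "model_id": ids,
                "cluster": [self.labels[m] for m in ids],
                "energy_kcal_mol": [energies[m] for m in ids],
                "is_centroid": [
                    self.centroid_ids.get(self.labels[m]) == m for m in ids
                ],
            }
        )


def cluster_ensemble(
    matrix: RMSDMatrix,
    energies: EnergyTable,
    n_clusters: int | None = None,
    k_max: int = 10,
    linkage: Linkage = "average",
    flatness_floor: float = FLATNESS_FLOOR,
) -> ClusteringResult:
    """Elbow-selected hierarchical clustering plus lowest-energy centroids."""
    est = RMSDHierarchicalClustering(
        n_clusters=n_clusters,
        k_max=k_max,
        linkage=linkage,
        flatness_floor=flatness_floor,
    ).fit(matrix)
    labels = est.labels_by_id()
    centroids = select_centroids(est.labels_, energies, matrix.model_ids)
    return ClusteringResult(
        est.n_clusters_, labels, est.dispersion_curve_, centroids
    )
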