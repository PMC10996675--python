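"""Dual clustering of the cross-ome matrix and genotype signature grouping.

Heatmap ordering comes from hierarchical clustering (average linkage,
Euclidean distance); discrete assignments come from k-means (k-means++
initialisation, best of ``restarts`` runs by within-cluster sum of squares,
seeded). Missing tau cells are treated as 0 — the null-association value —
for clustering distances only; they stay missing everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

from .correlation import CrossomeMatrix
from .io import ValidationError

__all__ = ["ClusterModel", "cluster_axis", "genotype_groups"]

AXES = ("protein", "lipid", "genotype")


@dataclass
class ClusterModel:
    """Cluster assignments plus dendrogram ordering for one axis."""

    axis: str
    k: int
    assignments: pd.Series         # feature id -> cluster id in 1..k
    dendrogram_order: tuple[str, ...]
    seed: int
    inertia: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValidationError(f"axis must be one of {AXES}")
        labels = set(self.assignments.unique())
        if labels != set(range(1, self.k + 1)):
            raise ValidationError(
                f"cluster ids must be exactly 1..{self.k} and all non-empty; got {sorted(labels)}"
            )
        if set(self.dendrogram_order) != set(self.assignments.index):
            raise ValidationError("dendrogram order must permute the clustered features")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.assignments.index)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster_id])

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"axis": self.axis, "cluster": self.assignments}
        ).rename_axis("feature_id")


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Map raw k-means labels to 1..k in order of first appearance (stable)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _cluster_matrix(
    frame: pd.DataFrame, axis: str, k: int, seed: int, restarts: int
) -> ClusterModel:
    """Cluster the rows of *frame*; index labels are the features."""
    n = frame.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range for {n} features on axis {axis!r}")
    # canonical ordering so the result is invariant to input feature order
    frame = frame.sort_index()
    x = frame.to_numpy(dtype=float)

    if n > 1:
        order_idx = leaves_list(linkage(x, method="average", metric="euclidean"))
    else:
        order_idx = np.array([0])
    dendro = tuple(frame.index[order_idx])

    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        random_state=seed % (2**32),
    ).fit(x)
    labels = _relabel_first_appearance(km.labels_)
    assignments = pd.Series(labels, index=frame.index, name="cluster")
    return ClusterModel(
        axis=axis,
        k=k,
        assignments=assignments,
        dendrogram_order=dendro,
        seed=seed,
        inertia=float(km.inertia_),
        params={"restarts": restarts, "linkage": "average", "metric": "euclidean"},
    )


def cluster_axis(
    cm: CrossomeMatrix,
    axis: str,
    k: int,
    *,
    seed: int = 0,
    restarts: int = 50,
) -> ClusterModel:
    """Cluster one axis of a (filtered) cross-ome matrix.

    Protein feature vectors are the tau profiles across all retained lipids;
    lipid vectors are the profiles across retained proteins. Missing tau
    cells are imputed as 0 for the distance computations only.
    """
    if axis not in ("protein", "lipid"):
        raise ValidationError("cluster_axis supports axes 'protein' and 'lipid'")
    filled = cm.tau.fillna(0.0)
    frame = filled.T if axis == "protein" else filled
    if frame.shape[0] == 0:
        raise ValidationError(f"no {axis} features to cluster (empty matrix)")
    return _cluster_matrix(frame, axis, k, seed, restarts)


def genotype_groups(
    signatures: pd.DataFrame,
    k: int,
    *,
    seed: int = 0,
    restarts: int = 50,
) -> ClusterModel:
    """k-means grouping of genotypes by their signature profiles.

    ``signatures`` has genotypes as rows (e.g. mean log2FC per curated
    annotation group as columns); missing entries are imputed as 0.
    """
    if signatures.shape[0] == 0:
        raise ValidationError("no genotypes to group")
    return _cluster_matrix(signatures.fillna(0.0), "genotype", k, seed, restarts)
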