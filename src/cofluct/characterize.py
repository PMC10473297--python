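"""Cluster centroids, leading activity modes, and FC/depth analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .hierarchy import HierarchyResult
from .io_masks import SystemPartition

__all__ = [
    "ClusterCentroid",
    "EigenMode",
    "cluster_centroid",
    "leading_eigenmode",
    "system_average",
    "correlate_with_fc",
    "centroid_parent_similarity",
    "hierarchical_depth",
    "depth_fc_curves",
    "cluster_composition",
]


@dataclass
class ClusterCentroid:
    """Mean co-fluctuation pattern of a community, as node x node matrix."""

    matrix: np.ndarray
    community: tuple[int, int] | None = None
    n_members: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("centroid must be symmetric")

    @property
    def vector(self) -> np.ndarray:
        """Upper-triangle edge vector of the centroid."""
        return squareform(self.matrix, checks=False)


@dataclass
class EigenMode:
    """Leading eigenvector of a centroid with its variance share."""

    vector: np.ndarray
    variance_explained: float
    eigenvalue: float

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-12:
            raise ValueError("variance explained must lie in [0, 1]")


def cluster_centroid(
    vectors: np.ndarray,
    members,
    community: tuple[int, int] | None = None,
) -> ClusterCentroid:
    """Element-wise mean of member patterns, reshaped to node x node."""
    members = np.asarray(members, dtype=int)
    if members.size == 0:
        raise ValueError("empty member set")
    mean_vec = np.asarray(vectors, dtype=float)[members].mean(axis=0)
    return ClusterCentroid(
        matrix=squareform(mean_vec, checks=False),
        community=community,
        n_members=int(members.size),
    )


def leading_eigenmode(centroid) -> EigenMode:
    """Eigenvector of the largest-|lambda| eigenvalue of a centroid.

    Variance explained is |lambda_1| / sum_k |lambda_k| (the matrices are
    indefinite).  Sign is fixed so the largest-magnitude element is
    positive.
    """
    mat = centroid.matrix if isinstance(centroid, ClusterCentroid) else centroid
    mat = np.asarray(mat, dtype=float)
    vals, vecs = np.linalg.eigh(mat)
    k = int(np.argmax(np.abs(vals)))
    v = vecs[:, k]
    if v[int(np.argmax(np.abs(v)))] < 0:
        v = -v
    total = np.abs(vals).sum()
    varexp = float(np.abs(vals[k]) / total) if total > 0 else 0.0
    return EigenMode(vector=v, variance_explained=varexp, eigenvalue=float(vals[k]))


def system_average(vec: np.ndarray, partition: SystemPartition) -> pd.Series:
    """Mean of a per-node vector within each system (no recomputation)."""
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.shape[0] != partition.n_parcels:
        raise ValueError("vector length must equal parcel count")
    return pd.Series(
        {s: float(vec[partition.indices(s)].mean())
         for s in partition.system_names}
    )


def correlate_with_fc(matrix_a: np.ndarray, matrix_b: np.ndarray) -> float:
    """Pearson r between the upper triangles of two node x node matrices."""
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must share shape")
    iu, ju = np.triu_indices(a.shape[0], k=1)
    x, y = a[iu, ju], b[iu, ju]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant upper triangle; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def centroid_parent_similarity(
    h: HierarchyResult, vectors: np.ndarray
) -> pd.DataFrame:
    """Upper-triangle correlation of every child centroid with its parent."""
    cent = {
        c.key: cluster_centroid(vectors, c.members, c.key)
        for c in h.communities
    }
    rows = []
    for c in h.communities:
        if c.parent is None:
            continue
        r = correlate_with_fc(cent[c.key].matrix, cent[c.parent].matrix)
        rows.append(
            {
                "level": c.level,
                "id": c.id,
                "parent_level": c.parent[0],
                "parent_id": c.parent[1],
                "r_parent": r,
                "size": c.size,
            }
        )
    return pd.DataFrame(rows)


def hierarchical_depth(h: HierarchyResult) -> np.ndarray:
    """Number of levels each pattern is retained in (root counts)."""
    return h.depths()


def depth_fc_curves(
    vectors: np.ndarray,
    depths: np.ndarray,
    fc: np.ndarray,
    mode: str = "level_only",
) -> pd.Series:
    """Correlation with FC of mean patterns selected by hierarchical depth.

    Per level l, patterns are selected with depth == l (``level_only``),
    depth >= l (``cumulative``), or depth <= l (``reverse_cumulative``);
    their mean edge vector is correlated with FC's upper triangle.  Levels
    with no selected pattern are NaN.
    """
    if mode not in ("level_only", "cumulative", "reverse_cumulative"):
        raise ValueError(f"unknown mode {mode!r}")
    vectors = np.asarray(vectors, dtype=float)
    depths = np.asarray(depths, dtype=int)
    iu, ju = np.triu_indices(fc.shape[0], k=1)
    fc_vec = np.asarray(fc, dtype=float)[iu, ju]
    out = {}
    for lev in range(1, int(depths.max()) + 1):
        if mode == "level_only":
            sel = depths == lev
        elif mode == "cumulative":
            sel = depths >= lev
        else:
            sel = depths <= lev
        if not sel.any():
            out[lev] = np.nan
            continue
        mean_vec = vectors[sel].mean(axis=0)
        if mean_vec.std() == 0 or fc_vec.std() == 0:
            out[lev] = np.nan
        else:
            out[lev] = float(np.corrcoef(mean_vec, fc_vec)[0, 1])
    return pd.Series(out, name=mode)


def cluster_composition(
    h: HierarchyResult,
    classes: list[str],
    rms: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amplitude-class make-up per level and mean RMS per community.

    Returns ``(level_fractions, community_stats)``: the first holds the
    fraction of assigned patterns labeled high / ns / low at every level
    (rows sum to 1); the second one row per retained community with its
    high fraction and mean RMS.
    """
    classes = np.asarray(classes)
    rms = np.asarray(rms, dtype=float)
    cats = ("high", "ns", "low")
    lev_rows = []
    for lev in range(1, h.n_levels + 1):
        row = h.level_labels(lev)
        assigned = row > 0
        n = int(assigned.sum())
        fr = {
            c: (float((classes[assigned] == c).sum()) / n if n else np.nan)
            for c in cats
        }
        lev_rows.append({"level": lev, "n_assigned": n, **fr})
    comm_rows = []
    for c in h.communities:
        cl = classes[c.members]
        comm_rows.append(
            {
                "level": c.level,
                "id": c.id,
                "size": c.size,
                "mean_rms": float(rms[c.members].mean()),
                **{f"frac_{k}": float((cl == k).mean()) for k in cats},
            }
        )
    return (
        pd.DataFrame(lev_rows).set_index("level"),
        pd.DataFrame(comm_rows),
    )
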