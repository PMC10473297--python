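"""Split-half, scan-incremental centroid-convergence analysis.

Scans are repeatedly split into two halves; one half provides reference
centroids from all of its data while the other half's centroids are
rebuilt as scans are added one at a time.  Convergence curves can be
indexed by number of scans or re-indexed by the cumulative number of
member patterns (samples), which removes apparent differences between
clusters that merely occur at different per-scan frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SplitHalfResult",
    "split_half_convergence",
    "cluster_frequency_per_scan",
    "pattern_to_centroid_similarity",
]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class SplitHalfResult:
    """Per-split convergence records.

    ``similarity`` and ``samples`` are (n_splits, n_increments, n_clusters)
    arrays; NaN marks increments where a cluster had no members yet.
    """

    clusters: np.ndarray
    similarity: np.ndarray
    samples: np.ndarray
    seeds: list[int] = field(default_factory=list)

    @property
    def n_splits(self) -> int:
        return self.similarity.shape[0]

    def scan_curve(self, cluster) -> np.ndarray:
        """Mean similarity per added scan for one cluster (NaN-aware)."""
        j = int(np.flatnonzero(self.clusters == cluster)[0])
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.similarity[:, :, j], axis=0)

    def sample_points(self, cluster) -> tuple[np.ndarray, np.ndarray]:
        """Pooled (n_samples, similarity) points across splits/increments."""
        j = int(np.flatnonzero(self.clusters == cluster)[0])
        sim = self.similarity[:, :, j].ravel()
        ns = self.samples[:, :, j].ravel()
        ok = ~np.isnan(sim) & (ns > 0)
        return ns[ok], sim[ok]

    def sample_binned_curve(self, cluster, bin_edges: np.ndarray) -> np.ndarray:
        """Mean similarity within sample-count bins (NaN where empty)."""
        ns, sim = self.sample_points(cluster)
        out = np.full(len(bin_edges) - 1, np.nan)
        which = np.digitize(ns, bin_edges) - 1
        for b in range(len(bin_edges) - 1):
            sel = which == b
            if sel.any():
                out[b] = sim[sel].mean()
        return out


def split_half_convergence(
    vectors: np.ndarray,
    scan_ids,
    labels,
    n_splits: int = 100,
    seed: int | None = None,
) -> SplitHalfResult:
    """Centroid convergence as scans accumulate in one half of a split.

    ``labels`` are cluster assignments fixed from the full-data hierarchy
    (label 0 / negative = unassigned, ignored).  For each split the scan
    list is shuffled and halved; group-1 centroids use all group-1
    patterns, group-2 centroids are recomputed after each added scan and
    compared by Pearson correlation of the centroid edge vectors.
    """
    vectors = np.asarray(vectors, dtype=float)
    scan_ids = np.asarray(scan_ids)
    labels = np.asarray(labels)
    scans = np.unique(scan_ids)
    if scans.size < 4:
        raise ValueError("need at least 4 scans to split")
    clusters = np.unique(labels[labels > 0])
    if clusters.size == 0:
        raise ValueError("no assigned clusters")
    half = scans.size // 2
    rng = np.random.default_rng(seed)
    sims = np.full((n_splits, half, clusters.size), np.nan)
    samps = np.zeros((n_splits, half, clusters.size), dtype=int)
    for s in range(n_splits):
        order = rng.permutation(scans)
        group1, group2 = order[:half], order[half : 2 * half]
        in_g1 = np.isin(scan_ids, group1)
        ref = {}
        for j, c in enumerate(clusters):
            sel = in_g1 & (labels == c)
            if sel.any():
                ref[j] = vectors[sel].mean(axis=0)
        add_order = rng.permutation(group2)
        acc = np.zeros(scan_ids.shape[0], dtype=bool)
        for k, scan in enumerate(add_order):
            acc |= scan_ids == scan
            for j, c in enumerate(clusters):
                sel = acc & (labels == c)
                n = int(sel.sum())
                samps[s, k, j] = n
                if n == 0 or j not in ref:
                    continue
                sims[s, k, j] = _pearson(vectors[sel].mean(axis=0), ref[j])
    return SplitHalfResult(
        clusters=clusters, similarity=sims, samples=samps, seeds=[seed or 0]
    )


def cluster_frequency_per_scan(labels, scan_ids) -> pd.DataFrame:
    """Mean +- sd occurrences of each cluster per scan (zeros included)."""
    labels = np.asarray(labels)
    scan_ids = np.asarray(scan_ids)
    scans = np.unique(scan_ids)
    clusters = np.unique(labels[labels > 0])
    rows = []
    for c in clusters:
        counts = np.array(
            [int(((scan_ids == s) & (labels == c)).sum()) for s in scans]
        )
        rows.append(
            {
                "cluster": int(c),
                "mean": float(counts.mean()),
                "sd": float(counts.std(ddof=1)) if scans.size > 1 else 0.0,
                "total": int(counts.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def pattern_to_centroid_similarity(
    vectors_a: np.ndarray,
    labels_a,
    centroids_b: dict,
) -> pd.Series:
    """Mean correlation of half-A member patterns with half-B centroids."""
    vectors_a = np.asarray(vectors_a, dtype=float)
    labels_a = np.asarray(labels_a)
    out = {}
    for c, cent in centroids_b.items():
        sel = labels_a == c
        if not sel.any():
            out[c] = np.nan
            continue
        cent = np.asarray(cent, dtype=float).ravel()
        rs = [_pearson(v, cent) for v in vectors_a[sel]]
        out[c] = float(np.nanmean(rs))
    return pd.Series(out)
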