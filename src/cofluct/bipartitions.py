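"""Sign bipartitions of activity frames and system-template matching.

At any single frame the co-fluctuation pattern splits the nodes into at
most two groups by the sign of their activity; r_ij(t) > 0 exactly when i
and j fall on the same side.  System-level bipartitions over S systems
number 2^(S-1) - 1 once complements and trivial splits are removed; each
expands to a node-level template whose co-assignment matrix can be
compared against empirical frame bipartitions via normalized mutual
information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_masks import SystemPartition

__all__ = [
    "TemplateSet",
    "MatchResult",
    "frame_bipartition",
    "is_degenerate_bipartition",
    "coassignment_from_bipartitions",
    "enumerate_system_templates",
    "nmi_bipartitions",
    "match_to_templates",
]

log = logging.getLogger(__name__)

MAX_SYSTEMS = 20


def frame_bipartition(z_frame: np.ndarray) -> np.ndarray:
    """Binary labels: 1 where activity is above its mean (z > 0), else 0."""
    z_frame = np.asarray(z_frame, dtype=float).ravel()
    labels = (z_frame > 0).astype(np.uint8)
    if labels.all() or not labels.any():
        log.info("degenerate bipartition: all nodes on one side")
    return labels


def is_degenerate_bipartition(labels: np.ndarray) -> bool:
    labels = np.asarray(labels)
    return bool(labels.all() or not labels.any())


def coassignment_from_bipartitions(bipartitions: np.ndarray) -> np.ndarray:
    """Fraction of frames in which each node pair shares a side.

    ``bipartitions`` is frames x nodes binary; the result is node x node in
    [0, 1] with unit diagonal.
    """
    m = np.atleast_2d(np.asarray(bipartitions, dtype=float))
    t = m.shape[0]
    if t < 1:
        raise ValueError("need at least one frame")
    co = (m.T @ m + (1 - m).T @ (1 - m)) / t
    np.fill_diagonal(co, 1.0)
    return co


@dataclass
class TemplateSet:
    """All nontrivial system bipartitions, canonicalized up to complement.

    ``system_labels`` is n_templates x S binary with the first system
    always on side 1 (the canonical form that removes complements).
    Node-level expansions are produced lazily to keep S = 14 (8,191
    templates) tractable.
    """

    system_labels: np.ndarray
    partition: SystemPartition

    def __len__(self) -> int:
        return self.system_labels.shape[0]

    def node_labels(self, index: int) -> np.ndarray:
        """Template ``index`` expanded to a node-level bipartition."""
        codes = self.partition.label_codes()
        return self.system_labels[index][codes]

    def node_label_matrix(self) -> np.ndarray:
        """All templates expanded to node level (n_templates x N)."""
        codes = self.partition.label_codes()
        return self.system_labels[:, codes]

    def node_coassignment(self, index: int) -> np.ndarray:
        lab = self.node_labels(index).astype(float)
        return coassignment_from_bipartitions(lab[None, :])


def enumerate_system_templates(partition: SystemPartition) -> TemplateSet:
    """Every split of the S systems into two nonempty groups.

    Complement duplicates are removed by fixing the first system to side 1,
    leaving exactly 2^(S-1) - 1 templates.
    """
    s = partition.n_systems
    if s > MAX_SYSTEMS:
        raise ValueError(
            f"S={s} systems would enumerate 2^{s - 1}-1 templates; "
            f"restrict to <= {MAX_SYSTEMS} systems"
        )
    n_templates = 2 ** (s - 1) - 1
    labels = np.zeros((n_templates, s), dtype=np.uint8)
    labels[:, 0] = 1
    # mask m in [0, 2^(S-1) - 2] sets membership of systems 1..S-1;
    # the all-ones mask (trivial split) is excluded by the range.
    masks = np.arange(n_templates, dtype=np.int64)
    for j in range(1, s):
        labels[:, j] = (masks >> (j - 1)) & 1
    return TemplateSet(system_labels=labels, partition=partition)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def nmi_bipartitions(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized mutual information of two node bipartitions.

    Normalization is by the arithmetic mean of the two entropies, which
    makes the measure invariant to complementing either side.  Degenerate
    single-group partitions yield 0 by convention.
    """
    a = np.asarray(a).astype(int).ravel()
    b = np.asarray(b).astype(int).ravel()
    if a.shape != b.shape:
        raise ValueError("bipartitions must share length")
    n = a.shape[0]
    joint = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            joint[i, j] = ((a == i) & (b == j)).sum()
    ha = _entropy(joint.sum(axis=1))
    hb = _entropy(joint.sum(axis=0))
    if ha == 0.0 or hb == 0.0:
        return 0.0
    pj = joint / n
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    mi = 0.0
    for i in (0, 1):
        for j in (0, 1):
            if pj[i, j] > 0:
                mi += pj[i, j] * np.log(pj[i, j] / (pa[i] * pb[j]))
    return float(np.clip(mi / ((ha + hb) / 2.0), 0.0, 1.0))


def _nmi_matrix(bips: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Pairwise NMI between P frame bipartitions and T templates (P x T)."""
    a = bips.astype(np.float64)
    b = templates.astype(np.float64)
    n = a.shape[1]
    n11 = a @ b.T
    a1 = a.sum(axis=1)[:, None]
    b1 = b.sum(axis=1)[None, :]
    n10 = a1 - n11
    n01 = b1 - n11
    n00 = n - a1 - b1 + n11

    def xlogx(x):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(x > 0, x * np.log(x), 0.0)

    def ent(p):  # p is probability of one side
        return -(xlogx(p) + xlogx(1 - p))

    ha = ent(a1 / n)
    hb = ent(b1 / n)
    hj = -(
        xlogx(n11 / n) + xlogx(n10 / n) + xlogx(n01 / n) + xlogx(n00 / n)
    )
    mi = ha + hb - hj
    denom = (ha + hb) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nmi = np.where(denom > 0, mi / denom, 0.0)
    return np.clip(nmi, 0.0, 1.0)


@dataclass
class MatchResult:
    """Template assignment of a pattern set."""

    best_index: np.ndarray
    frequencies: np.ndarray
    weighted: np.ndarray
    weighted_z: np.ndarray


def match_to_templates(
    bipartitions: np.ndarray, templates: TemplateSet
) -> MatchResult:
    """Assign each frame bipartition its maximum-NMI template.

    Ties go to the lowest template index (logged).  The weighted template
    is the frequency-weighted sum of matched templates' co-assignment
    matrices; ``weighted_z`` standardizes its off-diagonal entries.
    """
    bips = np.atleast_2d(np.asarray(bipartitions))
    if len(templates) == 0:
        raise ValueError("empty template set")
    tmpl_nodes = templates.node_label_matrix()
    nmi = _nmi_matrix(bips, tmpl_nodes)
    best = nmi.argmax(axis=1)
    ties = (nmi == nmi.max(axis=1, keepdims=True)).sum(axis=1)
    if (ties > 1).any():
        log.info(
            "%d patterns had tied template matches; lowest index kept",
            int((ties > 1).sum()),
        )
    freq = np.bincount(best, minlength=len(templates)).astype(float)
    freq /= freq.sum()
    n = templates.partition.n_parcels
    weighted = np.zeros((n, n))
    for t in np.flatnonzero(freq):
        weighted += freq[t] * templates.node_coassignment(int(t))
    iu, ju = np.triu_indices(n, k=1)
    off = weighted[iu, ju]
    wz = np.zeros_like(weighted)
    sd = off.std()
    zvals = (off - off.mean()) / sd if sd > 0 else np.zeros_like(off)
    wz[iu, ju] = zvals
    wz[ju, iu] = zvals
    return MatchResult(
        best_index=best, frequencies=freq, weighted=weighted, weighted_z=wz
    )
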