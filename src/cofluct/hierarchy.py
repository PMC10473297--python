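"""Recursive, significance-gated modularity maximization on concordance.

The expected weight of every pattern pair is the uniform mean of the
concordance matrix's upper triangle, so the signed modularity matrix
B = C - P_exp sums to zero over its upper triangle at every recursion
node.  A bespoke Louvain generalization optimizes Q on B; an ensemble of
runs is reconciled by permutation-null consensus clustering; each
consensus community's local modularity q_c is tested against a
size-preserving permutation null, and only communities passing the
p-value, minimum-size, and multi-scan rules are recursed into.  The
recursion bottoms out with one final (possibly empty) level in which no
community survives.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ModularityMatrix",
    "CommunityRecord",
    "HierarchyResult",
    "modularity_matrix",
    "partition_modularity",
    "louvain_partition",
    "consensus_partition",
    "community_contribution",
    "significance_test",
    "recursive_cluster",
    "hierarchy_coassignment",
]

log = logging.getLogger(__name__)

_GAIN_TOL = 1e-12


@dataclass
class ModularityMatrix:
    """Signed modularity matrix B = C - P_exp (off-diagonal), zero diagonal."""

    values: np.ndarray
    expected: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self):
        return self.values.shape


def _as_b(b) -> np.ndarray:
    arr = b.values if isinstance(b, ModularityMatrix) else np.asarray(b, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("modularity matrix must be square")
    return arr


def modularity_matrix(c: np.ndarray) -> ModularityMatrix:
    """Observed concordance minus the uniform upper-triangle mean."""
    c = np.asarray(c, dtype=float)
    p = c.shape[0]
    if p < 2:
        raise ValueError("need at least 2 patterns")
    iu, ju = np.triu_indices(p, k=1)
    p_exp = float(c[iu, ju].mean())
    b = c - p_exp
    np.fill_diagonal(b, 0.0)
    return ModularityMatrix(b, p_exp)


def partition_modularity(b, labels: np.ndarray) -> float:
    """Q = sum of B over ordered same-community pairs (double count)."""
    arr = _as_b(b)
    labels = np.asarray(labels)
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        sub = arr[np.ix_(idx, idx)]
        q += sub.sum() - np.trace(sub)
    return float(q)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..K-1 in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def _local_move(
    b: np.ndarray,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Phase-1 greedy node moves; returns labels (arbitrary ints)."""
    n = b.shape[0]
    labels = np.arange(n) if init is None else init.copy()
    counts = np.bincount(labels, minlength=n + 1)
    tol = 1e-12 * (1.0 + np.abs(b).max() * n) + _GAIN_TOL
    moved = True
    sweeps = 0
    while moved and sweeps < 200:
        moved = False
        sweeps += 1
        for i in rng.permutation(n):
            gains = np.bincount(labels, weights=b[i], minlength=n + 1)
            cur = labels[i]
            best = int(np.argmax(gains))
            target = best
            # escaping to a fresh singleton community has gain 0, which can
            # beat every existing community when B is signed
            if gains[best] < 0.0 and counts[cur] > 1:
                free = np.flatnonzero(counts == 0)
                if free.size:
                    target = int(free[0])
                    gains[target] = 0.0
            if gains[target] > gains[cur] + tol:
                counts[cur] -= 1
                counts[target] += 1
                labels[i] = target
                moved = True
    return labels


def _kl_refine(b: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Kernighan-Lin style refinement of a partition on signed B.

    Repeatedly builds a chain of single-node moves (each node moved at most
    once per pass, moves may be locally worsening) and keeps the best
    configuration seen, escaping local optima that pure greedy moves
    cannot leave.  Gains are maintained incrementally, O(n^2) per step.
    """
    n = b.shape[0]
    labels = labels.copy()
    # improvement threshold scaled to the matrix magnitude, else float
    # round-off (~1e-12 relative) masquerades as gain and passes cycle
    eps = 1e-10 * np.abs(b).sum() + _GAIN_TOL
    max_chain = min(n, 50)  # long chains add cost, rarely quality
    for _ in range(20):
        work = labels.copy()
        gains = np.zeros((n, n + 1))
        for lab in range(int(work.max()) + 1):
            members = work == lab
            if members.any():
                gains[:, lab] = b[:, members].sum(axis=1)
        counts = np.bincount(work, minlength=n + 1)
        moved = np.zeros(n, dtype=bool)
        rel_q = 0.0
        best_rel = 0.0
        best_state: np.ndarray | None = None
        for _ in range(max_chain):
            delta = gains - gains[np.arange(n), work][:, None]
            delta[np.arange(n), work] = -np.inf
            empty = counts == 0
            if empty.any():
                first_free = int(np.flatnonzero(empty)[0])
                empty[first_free] = False  # keep one escape target open
            delta[:, empty] = -np.inf
            delta[moved] = -np.inf
            flat = int(np.argmax(delta))
            i, t = divmod(flat, n + 1)
            if not np.isfinite(delta[i, t]):
                break
            src = work[i]
            work[i] = t
            moved[i] = True
            counts[src] -= 1
            counts[t] += 1
            gains[:, src] -= b[:, i]
            gains[:, t] += b[:, i]
            rel_q += 2.0 * delta[i, t]
            if rel_q > best_rel + eps:
                best_rel = rel_q
                best_state = work.copy()
        if best_state is None:
            return labels
        labels = best_state
    return labels


def louvain_partition(b, seed=None) -> np.ndarray:
    """Signed-modularity Louvain: local moves plus graph aggregation.

    The move gain for node i joining community c is 2 * sum_{j in c} B_ij;
    aggregation sums B over community blocks (self-weight is a constant and
    is excluded from gains).  Visit order is randomized by ``seed``; the
    result is a local optimum whose Q never decreases across passes.
    """
    arr = _as_b(b).copy()
    np.fill_diagonal(arr, 0.0)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = arr.shape[0]
    membership = np.arange(n)
    while True:
        labels = _canonical(_local_move(arr, rng))
        k = labels.max() + 1
        membership = labels[membership]
        if k == arr.shape[0]:  # no merge happened; converged
            break
        onehot = np.zeros((arr.shape[0], k))
        onehot[np.arange(arr.shape[0]), labels] = 1.0
        arr = onehot.T @ arr @ onehot
        np.fill_diagonal(arr, 0.0)
    # node-level refinement on the full matrix: greedy single moves seeded
    # from the coarse solution, then KL move chains to escape the local
    # optima that single-move dynamics cannot leave
    full = _as_b(b).copy()
    np.fill_diagonal(full, 0.0)
    membership = _local_move(full, rng, init=membership)
    membership = _kl_refine(full, _canonical(membership))
    return _canonical(membership)


def _coclass(parts: list[np.ndarray]) -> np.ndarray:
    p = parts[0].shape[0]
    d = np.zeros((p, p))
    for lab in parts:
        d += lab[:, None] == lab[None, :]
    return d / len(parts)


def _perm_null_coclass(parts: list[np.ndarray]) -> float:
    """Expected off-diagonal co-classification under label permutations."""
    p = parts[0].shape[0]
    vals = []
    for lab in parts:
        sizes = np.bincount(lab)
        vals.append((sizes * (sizes - 1)).sum() / (p * (p - 1)))
    return float(np.mean(vals))


def consensus_partition(
    b, n_runs: int = 1000, seed=None, max_iter: int = 50
) -> np.ndarray:
    """Reconcile a Louvain ensemble into a single partition.

    Repeatedly clusters the co-classification frequency matrix minus its
    permutation-null expectation until all runs in the ensemble agree.
    Deterministic given the master seed; falls back to the modal partition
    (with a warning) if agreement is not reached within ``max_iter``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    arr = _as_b(b)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mat = arr
    parts: list[np.ndarray] = []
    for _ in range(max_iter):
        parts = [louvain_partition(mat, rng) for _ in range(n_runs)]
        first = parts[0]
        if all(np.array_equal(first, q) for q in parts[1:]):
            return first
        d = _coclass(parts)
        mat = d - _perm_null_coclass(parts)
        np.fill_diagonal(mat, 0.0)
    warnings.warn(
        f"consensus did not converge in {max_iter} iterations; "
        "returning modal partition",
        RuntimeWarning,
        stacklevel=2,
    )
    keys = [tuple(q.tolist()) for q in parts]
    modal = max(set(keys), key=keys.count)
    return np.array(modal)


def community_contribution(b, labels: np.ndarray, c: int) -> float:
    """q_c: sum of B over ordered pairs within community ``c``."""
    arr = _as_b(b)
    idx = np.flatnonzero(np.asarray(labels) == c)
    if idx.size == 0:
        raise ValueError(f"community {c} is empty")
    sub = arr[np.ix_(idx, idx)]
    return float(sub.sum() - np.trace(sub))


def significance_test(
    b, labels: np.ndarray, n_perm: int = 10000, seed=None
) -> dict[int, float]:
    """Permutation p-value for each community's local modularity.

    The null permutes pattern indices while preserving community sizes;
    p_c is the raw fraction of permutations whose null q_c >= the observed
    q_c (ties count as exceeding; no pseudocount).
    """
    arr = _as_b(b)
    labels = np.asarray(labels)
    p = arr.shape[0]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    comms = np.unique(labels)
    k = comms.size
    onehot = np.zeros((p, k))
    for j, c in enumerate(comms):
        onehot[labels == c, j] = 1.0
    observed = ((arr @ onehot) * onehot).sum(axis=0)  # diag(S^T B S); diag(B)=0
    exceed = np.zeros(k)
    for _ in range(n_perm):
        perm = rng.permutation(p)
        sp = onehot[perm]
        null_q = ((arr @ sp) * sp).sum(axis=0)
        exceed += null_q >= observed
    pvals = exceed / n_perm
    return {int(c): float(pvals[j]) for j, c in enumerate(comms)}


@dataclass
class CommunityRecord:
    """One retained community in the hierarchy."""

    level: int
    id: int
    members: np.ndarray
    q: float
    p: float | None
    n_scans: int
    parent: tuple[int, int] | None = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.level, self.id)

    @property
    def size(self) -> int:
        return self.members.shape[0]


@dataclass
class HierarchyResult:
    """Nested multiscale clustering of patterns.

    ``labels`` is an L x P matrix; row 0 is the all-inclusive root level
    (level 1), label 0 means pruned/unassigned, and the last row is the
    terminal level in which no community survived.  Community ids restart
    from 1 within each level.
    """

    labels: np.ndarray
    communities: list[CommunityRecord]
    scan_ids: np.ndarray

    @property
    def n_levels(self) -> int:
        return self.labels.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.labels.shape[1]

    def level_labels(self, level: int) -> np.ndarray:
        """Per-pattern labels at 1-based ``level``."""
        return self.labels[level - 1]

    def communities_at(self, level: int) -> list[CommunityRecord]:
        return [c for c in self.communities if c.level == level]

    def children(self, level: int, cid: int) -> list[CommunityRecord]:
        return [c for c in self.communities if c.parent == (level, cid)]

    def depths(self) -> np.ndarray:
        """Per-pattern count of levels retained (root counts; >= 1)."""
        return (self.labels > 0).sum(axis=0)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "labels": self.labels.tolist(),
            "scan_ids": [str(s) for s in self.scan_ids],
            "communities": [
                {
                    "level": c.level,
                    "id": c.id,
                    "members": c.members.tolist(),
                    "q": c.q,
                    "p": c.p,
                    "n_scans": c.n_scans,
                    "parent": list(c.parent) if c.parent else None,
                }
                for c in self.communities
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HierarchyResult":
        if isinstance(source, Path) or Path(str(source)).exists():
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        comms = [
            CommunityRecord(
                level=c["level"],
                id=c["id"],
                members=np.array(c["members"], dtype=int),
                q=c["q"],
                p=c["p"],
                n_scans=c["n_scans"],
                parent=tuple(c["parent"]) if c["parent"] else None,
            )
            for c in payload["communities"]
        ]
        return cls(
            labels=np.array(payload["labels"], dtype=int),
            communities=comms,
            scan_ids=np.array(payload["scan_ids"]),
        )


def recursive_cluster(
    c: np.ndarray,
    scan_ids,
    alpha: float = 0.05,
    min_size: int = 5,
    min_scans: int = 2,
    n_runs: int = 1000,
    n_perm: int = 10000,
    seed: int | None = None,
) -> HierarchyResult:
    """Recursively partition the concordance matrix into nested communities.

    Level 1 is the trivial all-inclusive root.  At each deeper level every
    surviving community's concordance submatrix gets its own modularity
    matrix (expected weight recomputed on the submatrix), a consensus
    partition, and a permutation test; children failing p < alpha,
    size >= min_size, or >= min_scans distinct scans are pruned and never
    reappear.  Recursion stops when a level retains nothing, and that empty
    level is included, so a structureless input yields exactly 2 levels.
    """
    c = np.asarray(c, dtype=float)
    scan_ids = np.asarray(scan_ids)
    p = c.shape[0]
    if scan_ids.shape[0] != p:
        raise ValueError("scan_ids must align with the concordance matrix")
    ss = np.random.SeedSequence(seed)
    root = CommunityRecord(
        level=1,
        id=1,
        members=np.arange(p),
        q=0.0,
        p=None,
        n_scans=int(np.unique(scan_ids).size),
    )
    levels = [np.ones(p, dtype=int)]
    communities = [root]
    if p < max(min_size, 2):
        # nothing can ever satisfy the size rule: root plus an empty level
        log.info("only %d patterns (< min_size=%d); trivial hierarchy",
                 p, min_size)
        levels.append(np.zeros(p, dtype=int))
        return HierarchyResult(
            labels=np.vstack(levels),
            communities=communities,
            scan_ids=scan_ids,
        )
    frontier = [root]
    while frontier:
        nxt_labels = np.zeros(p, dtype=int)
        nxt_frontier: list[CommunityRecord] = []
        next_id = 0
        level = len(levels) + 1
        for parent in frontier:
            members = parent.members
            if members.size < 2:
                continue
            sub_c = c[np.ix_(members, members)]
            b = modularity_matrix(sub_c)
            s_cons, s_perm = ss.spawn(2)
            labs = consensus_partition(b, n_runs=n_runs, seed=s_cons)
            pvals = significance_test(b, labs, n_perm=n_perm, seed=s_perm)
            for cid in np.unique(labs):
                mask = labs == cid
                midx = members[mask]
                n_scans = int(np.unique(scan_ids[midx]).size)
                q = community_contribution(b, labs, int(cid))
                pv = pvals[int(cid)]
                if pv >= alpha or midx.size < min_size or n_scans < min_scans:
                    continue
                next_id += 1
                rec = CommunityRecord(
                    level=level,
                    id=next_id,
                    members=midx,
                    q=q,
                    p=pv,
                    n_scans=n_scans,
                    parent=parent.key,
                )
                nxt_labels[midx] = next_id
                communities.append(rec)
                nxt_frontier.append(rec)
        levels.append(nxt_labels)
        frontier = nxt_frontier
    return HierarchyResult(
        labels=np.vstack(levels),
        communities=communities,
        scan_ids=scan_ids,
    )


def hierarchy_coassignment(h: HierarchyResult) -> np.ndarray:
    """Fraction of levels (where both patterns are assigned) shared.

    Entry (i, j) counts only the levels at which both i and j carry a
    nonzero label; the root level guarantees a denominator >= 1.
    """
    p = h.n_patterns
    num = np.zeros((p, p))
    den = np.zeros((p, p))
    for row in h.labels:
        assigned = row > 0
        both = assigned[:, None] & assigned[None, :]
        den += both
        num += both & (row[:, None] == row[None, :])
    return num / den
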