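"""Signed-weighted community detection and temporal co-occurrence.

Community structure is found on the complete, unthresholded, signed and
weighted connectivity matrix by Louvain-style greedy optimization of the
asymmetric signed quality

    Q* = (1/v+) sum_ij (w+_ij - e+_ij) d(c_i, c_j)
       - (1/(v+ + v-)) sum_ij (w-_ij - e-_ij) d(c_i, c_j),

where ``w+``/``w-`` are the positive/negative parts of the matrix,
``e+-_ij = s+-_i s+-_j / v+-`` the chance-expected weights, ``v+-`` the total
positive/negative weight and ``d`` the same-community indicator. Positive
weights inside a community are rewarded at full scale while intramodular
negative weights are penalized at a scale shrunk by the total negative
strength relative to total strength — the standard asymmetric signed
modularity convention for correlation networks. The diagonal never
contributes.

Because Q* is linear in the same-community indicator, the whole objective
collapses to one symmetric gain matrix ``B`` with
``Q*(partition) = sum_{ij} B_ij d(c_i, c_j)``; Louvain local moving and
graph aggregation are exact on ``B``, which the numba kernels below exploit.

The per-window partitions feed the temporal co-occurrence (module
allegiance) matrix ``C_ij``: the fraction of windows in which nodes i and j
share a community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "Partition",
    "CoOccurrence",
    "signed_modularity_matrix",
    "partition_quality",
    "detect_communities",
    "detect_communities_stack",
    "reference_partition",
    "window_allegiance",
    "co_occurrence",
]


@dataclass(frozen=True)
class Partition:
    """Node -> community assignment with its Q* value.

    Labels are contiguous integers 0..m-1 in order of first appearance.
    """

    labels: np.ndarray
    quality: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", _canonical(labels))
        self.labels.setflags(write=False)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def n_nodes(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class CoOccurrence:
    """Symmetric node x node same-community frequency matrix for one subject."""

    C: np.ndarray
    subject: str | None = None
    n_windows: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be square")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("C must be symmetric")
        if C.size and (np.nanmin(C) < -1e-12 or np.nanmax(C) > 1 + 1e-12):
            raise ValueError("C entries must lie in [0, 1]")
        object.__setattr__(self, "C", C)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities as 0..m-1 in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def signed_modularity_matrix(w: np.ndarray) -> np.ndarray:
    """Gain matrix B of the asymmetric signed quality Q* (diagonal zero)."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if not np.isfinite(w).all():
        raise ValueError("connectivity matrix contains non-finite entries")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("connectivity matrix must be symmetric")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    wp = np.clip(w, 0.0, None)
    wn = np.clip(-w, 0.0, None)
    vp = wp.sum()
    vn = wn.sum()
    b = np.zeros_like(w)
    if vp > 0:
        sp = wp.sum(axis=1)
        b += (wp - np.outer(sp, sp) / vp) / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        b -= (wn - np.outer(sn, sn) / vn) / (vp + vn)
    np.fill_diagonal(b, 0.0)
    return b


def partition_quality(w: np.ndarray, labels: np.ndarray) -> float:
    """Evaluate Q* of a given assignment on a signed matrix by direct summation."""
    b = signed_modularity_matrix(w)
    return _quality_from_b(b, np.asarray(labels))


def _quality_from_b(b: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum())


@njit(cache=True)
def _louvain_level(b, labels):  # pragma: no cover - numba
    """One Louvain level: greedy local moving on gain matrix b. In place."""
    n = b.shape[0]
    improved = False
    moved = True
    while moved:
        moved = False
        order = np.random.permutation(n)
        for oi in range(n):
            i = order[oi]
            cur = labels[i]
            # gain of node i to every community
            gain = np.zeros(n)
            for j in range(n):
                if j != i:
                    gain[labels[j]] += b[i, j]
            best, best_gain = cur, gain[cur]
            for c in range(n):
                if gain[c] > best_gain + 1e-12:
                    best, best_gain = c, gain[c]
            if best != cur:
                labels[i] = best
                moved = True
                improved = True
    return improved


@njit(cache=True)
def _aggregate(b, labels, k):  # pragma: no cover - numba
    n = b.shape[0]
    out = np.zeros((k, k))
    for i in range(n):
        for j in range(n):
            out[labels[i], labels[j]] += b[i, j]
    return out


@njit(cache=True)
def _louvain_once(b0, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n0 = b0.shape[0]
    node_comm = np.arange(n0)
    b = b0.copy()
    while True:
        n = b.shape[0]
        labels = np.arange(n)
        improved = _louvain_level(b, labels)
        if not improved:
            break
        # compact labels
        k = 0
        remap = -np.ones(n, dtype=np.int64)
        for i in range(n):
            if remap[labels[i]] < 0:
                remap[labels[i]] = k
                k += 1
        for i in range(n0):
            node_comm[i] = remap[labels[node_comm[i]]]
        if k == n:
            break
        b = _aggregate(b, remap[labels], k)
    return node_comm


def _init_seeds(seed: int, n_init: int, stream: tuple[int, ...] = ()) -> np.ndarray:
    """Counter-derived per-init seeds: reproducible and order-independent."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(stream))
    return ss.generate_state(n_init, dtype=np.uint32)


def detect_communities(w: np.ndarray, n_init: int = 100, seed: int = 0) -> Partition:
    """Best-of-``n_init`` signed Louvain partition of one connectivity matrix.

    Each initialization uses a seeded random node order; the run with the
    maximal Q* is returned. An all-zero matrix yields a single community
    with Q* = 0.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    w = np.asarray(w, dtype=float)
    b = signed_modularity_matrix(w)
    if not b.any() and not np.clip(w, 0, None).sum() and not np.clip(-w, 0, None).sum():
        return Partition(np.zeros(w.shape[0], dtype=np.int64), 0.0)
    best_labels, best_q = None, -np.inf
    for s in _init_seeds(seed, n_init):
        labels = _louvain_once(b, np.int64(s % np.int64(2**31)))
        q = _quality_from_b(b, labels)
        if q > best_q:
            best_labels, best_q = labels, q
    return Partition(best_labels, best_q)


def reference_partition(group_static: np.ndarray, n_init: int = 100, seed: int = 0) -> Partition:
    """Static reference partition: communities of the group-averaged matrix.

    Each node's label here is its *native* community u_i, the baseline for
    all node-level dynamics metrics.
    """
    return detect_communities(group_static, n_init=n_init, seed=seed)


def detect_communities_stack(
    stack: np.ndarray, n_init: int = 100, seed: int = 0
) -> list[Partition]:
    """Per-window community detection on a (n_windows, n, n) stack.

    Window t uses seeds derived from (seed, t) by counter, so results do
    not depend on evaluation order.
    """
    out = []
    for t, w in enumerate(stack):
        b = signed_modularity_matrix(w)
        best_labels, best_q = None, -np.inf
        for s in _init_seeds(seed, n_init, stream=(t,)):
            labels = _louvain_once(b, np.int64(s % np.int64(2**31)))
            q = _quality_from_b(b, labels)
            if q > best_q:
                best_labels, best_q = labels, q
        out.append(Partition(best_labels, best_q))
    return out


def window_allegiance(partition: Partition) -> np.ndarray:
    """Binary same-community adjacency A for one window (diagonal 1)."""
    lab = partition.labels
    return (lab[:, None] == lab[None, :]).astype(float)


def co_occurrence(
    partitions: list[Partition], subject: str | None = None
) -> CoOccurrence:
    """Temporal mean of the per-window allegiance matrices."""
    if not partitions:
        raise ValueError("need at least one window partition")
    n = partitions[0].n_nodes
    acc = np.zeros((n, n))
    for p in partitions:
        if p.n_nodes != n:
            raise ValueError("partitions differ in node count")
        acc += window_allegiance(p)
    return CoOccurrence(acc / len(partitions), subject=subject, n_windows=len(partitions))
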