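"""Null-model controls: phase-randomized surrogates and random-graph nulls.

Two complementary controls:

* **Phase randomization** ("noise model"): each node's series is Fourier
  transformed, an i.i.d. uniform [0, 2pi) phase is added independently at
  every frequency (conjugate-symmetric, so the inverse transform is real),
  and the series is inverted back. Per-node amplitude spectra — hence means,
  variances and autocorrelations — are preserved exactly, while all
  cross-correlations between nodes are destroyed.

* **Degree/strength/weight-preserving random graphs**: the positive and
  negative subnetworks are randomized separately; topology is rewired by
  degree-preserving edge swaps (10 swaps per edge; a no-op on complete
  graphs) and the original weight multiset is then reassigned to edges by
  stochastic rank-matching against the expected strength product, so the
  weight multiset and degree sequence are preserved exactly and node
  strengths approximately.

The structure test compares the variance fraction of the first principal
component of a co-occurrence matrix against such nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .community import CoOccurrence
from .io import SignalSet

__all__ = [
    "SurrogateSpec",
    "phase_randomize",
    "surrogate_node_metrics",
    "random_graph_null",
    "pc1_variance_fraction",
    "pc1_structure_test",
]


@dataclass(frozen=True)
class SurrogateSpec:
    n_surrogates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")


def _phase_randomize_matrix(mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomize each row of a (nodes, frames) matrix independently."""
    n = mat.shape[1]
    spec = np.fft.rfft(mat, axis=1)
    n_bins = spec.shape[1]
    rot = np.ones((mat.shape[0], n_bins), dtype=complex)
    # bins strictly between DC and (for even n) Nyquist get free phases
    hi = n_bins - 1 if n % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(mat.shape[0], hi - 1))
    rot[:, 1:hi] = np.exp(1j * phases)
    if n % 2 == 0:
        # Nyquist coefficient must stay real: random sign keeps |.| intact
        rot[:, -1] = rng.choice([-1.0, 1.0], size=mat.shape[0])
    return np.fft.irfft(spec * rot, n=n, axis=1)


def phase_randomize(s: SignalSet, spec: SurrogateSpec = SurrogateSpec()) -> list[SignalSet]:
    """Surrogate SignalSets with per-node spectra preserved, cross-spectra destroyed."""
    out = []
    for k in range(spec.n_surrogates):
        ss = np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(k,))
        rng = np.random.default_rng(ss)
        mats = tuple(_phase_randomize_matrix(m, rng) for m in s.data)
        out.append(SignalSet(s.subjects, mats, s.node_ids, s.dt))
    return out


def surrogate_node_metrics(
    s: SignalSet,
    window_spec=None,
    n_init: int = 20,
    seed: int = 0,
) -> "pd.DataFrame":
    """Node dynamics metrics of phase-randomized surrogates ("noise model").

    Each subject's (already preprocessed) signals are phase-randomized and
    pushed through the windowed connectivity -> community -> co-occurrence
    -> metrics chain. Because surrogates carry no shared structure, a group
    reference partition would be arbitrary — yet shared across subjects, so
    its community-size offsets masquerade as consistent node effects in
    paired across-subject tests. Each subject's metrics are therefore
    computed against a reference detected from that subject's own surrogate
    static connectivity, which restores exchangeability under the null.
    """
    import pandas as pd  # local: keep module import light

    from .community import co_occurrence as _cooc
    from .community import detect_communities, detect_communities_stack
    from .connectivity import WindowSpec, fisher_z, sliding_connectivity
    from .metrics import (spatiotemporal_diversity, temporal_flexibility,
                          within_community_centrality)

    if window_spec is None:
        window_spec = WindowSpec()
    sur = phase_randomize(s, SurrogateSpec(1, seed=seed))[0]
    stacks = sliding_connectivity(sur, window_spec)
    rows = []
    for j, (subj, stack) in enumerate(zip(sur.subjects, stacks)):
        static_j = fisher_z(np.corrcoef(sur.data[j]))
        ref_j = detect_communities(static_j, n_init=n_init, seed=seed + 7919 * (j + 1))
        parts = detect_communities_stack(stack, n_init=n_init, seed=seed + 104729 * (j + 1))
        C = _cooc(parts, subject=subj)
        rows.append(
            pd.DataFrame(
                {
                    "subject": subj,
                    "node": list(sur.node_ids),
                    "flexibility": temporal_flexibility(C, ref_j),
                    "diversity": spatiotemporal_diversity(C, ref_j),
                    "centrality": within_community_centrality(C, ref_j),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@njit(cache=True)
def _rewire(ei, ej, adj, blocked, n_swaps, seed):  # pragma: no cover - numba
    """Degree-preserving Maslov-Sneppen swaps on an undirected edge list.

    ``adj`` is the (mutated) boolean adjacency of this subnetwork;
    ``blocked`` marks slots occupied by the opposite-sign subnetwork, which
    proposed edges must avoid so the merged matrix keeps both multisets.
    """
    np.random.seed(seed)
    n_e = len(ei)
    done = 0
    attempts = 0
    max_attempts = 20 * n_swaps + 100
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        a = np.random.randint(n_e)
        b = np.random.randint(n_e)
        if a == b:
            continue
        ia, ja = ei[a], ej[a]
        ib, jb = ei[b], ej[b]
        if np.random.randint(2) == 1:
            ib, jb = jb, ib
        # proposed: (ia, jb), (ib, ja)
        if ia == jb or ib == ja or ia == ib or ja == jb:
            continue
        if adj[ia, jb] or adj[ib, ja] or blocked[ia, jb] or blocked[ib, ja]:
            continue
        adj[ia, ja] = adj[ja, ia] = False
        adj[ib, jb] = adj[jb, ib] = False
        adj[ia, jb] = adj[jb, ia] = True
        adj[ib, ja] = adj[ja, ib] = True
        ej[a] = jb
        ei[b] = ib
        ej[b] = ja
        done += 1


@njit(cache=True)
def _assign_weights(ei, ej, w_sorted, strengths, seed):  # pragma: no cover - numba
    """Stochastic rank-matched reassignment of a weight multiset to edges.

    Repeatedly picks a random unassigned edge, ranks its expected-strength
    product among the remaining edges and gives it the weight of the same
    rank from the remaining (ascending) weight list; residual strengths are
    decremented so later picks adapt.
    """
    np.random.seed(seed)
    n_e = len(ei)
    out = np.empty(n_e)
    alive = np.ones(n_e, dtype=np.bool_)
    w_used = np.zeros(n_e, dtype=np.bool_)
    s = strengths.copy()
    for step in range(n_e):
        n_left = n_e - step
        pick = np.random.randint(n_left)
        idx = -1
        seen = 0
        for e in range(n_e):
            if alive[e]:
                if seen == pick:
                    idx = e
                    break
                seen += 1
        p_idx = s[ei[idx]] * s[ej[idx]]
        rank = 0
        for e in range(n_e):
            if alive[e] and e != idx and s[ei[e]] * s[ej[e]] < p_idx:
                rank += 1
        # weight with the same ascending rank among unused weights
        seen = 0
        w_pick = 0.0
        for q in range(n_e):
            if not w_used[q]:
                if seen == rank:
                    w_used[q] = True
                    w_pick = w_sorted[q]
                    break
                seen += 1
        out[idx] = w_pick
        alive[idx] = False
        s[ei[idx]] -= w_pick
        s[ej[idx]] -= w_pick
    return out


def _null_one_sign(
    w: np.ndarray,
    swaps_per_edge: int,
    rng: np.random.Generator,
    blocked: np.ndarray | None = None,
) -> np.ndarray:
    """Null for a nonnegative weighted subnetwork (upper-triangle edges)."""
    n = w.shape[0]
    iu, ju = np.nonzero(np.triu(w, 1))
    if len(iu) == 0:
        return np.zeros_like(w)
    if len(iu) < 2:
        raise ValueError("matrix too sparse to rewire (fewer than 2 edges)")
    ei = iu.astype(np.int64).copy()
    ej = ju.astype(np.int64).copy()
    seed1, seed2 = rng.integers(0, 2**31, size=2)
    if blocked is None:
        blocked = np.zeros((n, n), dtype=bool)
    if len(iu) < n * (n - 1) // 2:  # complete graphs admit no swaps
        adj = w > 0
        _rewire(ei, ej, adj, blocked, swaps_per_edge * len(ei), seed1)
    weights = np.sort(w[iu, ju])
    strengths = w.sum(axis=1)
    assigned = _assign_weights(ei, ej, weights, strengths, seed2)
    out = np.zeros_like(w)
    out[ei, ej] = assigned
    out[ej, ei] = assigned
    return out


def random_graph_null(
    w: np.ndarray, n_graphs: int = 1, seed: int = 0, swaps_per_edge: int = 10
) -> list[np.ndarray]:
    """Random graphs with the same weight, degree and strength distributions.

    Positive and negative subnetworks are randomized separately and merged,
    preserving both signed degree sequences and weight multisets exactly and
    node strengths approximately. The diagonal is carried over unchanged.
    """
    w = np.asarray(w, dtype=float)
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    diag = np.diag(w).copy()
    wz = w.copy()
    np.fill_diagonal(wz, 0.0)
    wp = np.clip(wz, 0.0, None)
    wn = np.clip(-wz, 0.0, None)
    out = []
    for k in range(n_graphs):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(k,)))
        pos = _null_one_sign(wp, swaps_per_edge, rng, blocked=wn != 0)
        neg = _null_one_sign(wn, swaps_per_edge, rng, blocked=pos != 0)
        null = pos - neg
        np.fill_diagonal(null, diag)
        out.append(null)
    return out


def pc1_variance_fraction(C: np.ndarray) -> float:
    """Variance fraction of PC1: lambda_1 / sum(lambda) of the column-centered matrix."""
    x = np.asarray(C, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(x, compute_uv=False)
    total = (sv**2).sum()
    if total == 0:
        return float("nan")
    return float(sv[0] ** 2 / total)


def pc1_structure_test(
    C: CoOccurrence | np.ndarray, n_graphs: int = 1000, seed: int = 0
) -> dict:
    """Is a co-occurrence matrix more one-dimensional than chance?

    Compares the observed PC1 variance fraction against nulls with matched
    weight/degree/strength distributions; empirical one-sided p with the +1
    permutation correction.
    """
    if n_graphs < 19:
        raise ValueError("n_graphs < 19 gives too coarse a p-value grid")
    mat = C.C if isinstance(C, CoOccurrence) else np.asarray(C, dtype=float)
    observed = pc1_variance_fraction(mat)
    null = np.array(
        [pc1_variance_fraction(g) for g in random_graph_null(mat, n_graphs, seed=seed)]
    )
    p = (1 + int((null >= observed).sum())) / (1 + n_graphs)
    return {
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)),
        "p": p,
        "null": null,
    }
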