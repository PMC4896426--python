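"""Synthetic cohorts with planted static communities and planted flexibility.

The generator emulates the statistical structure that sliding-window
community analysis of parcellated resting-state recordings assumes:
segregated node communities whose members are mutually correlated, plus a
small set of *flexible* nodes that transiently couple to other communities.

Signals are piecewise-stationary: time is cut into epochs of
``switch_period`` frames and within each epoch every node's signal is drawn
from a zero-mean multivariate normal whose correlation is ``within_corr``
inside each community block and ``between_corr`` elsewhere. Flexible nodes
are reassigned to a different community each epoch, round-robin over the
communities other than their native one. Flexible nodes sharing a native
community move together (a coherent coalition with a shared, seeded
round-robin phase), so the coalition itself is the static ground-truth
cluster for its members: averaged over the run they correlate more strongly
with each other than with any fixed community.

White observation noise of standard deviation ``noise_sd`` is added; the
epoch correlation target is pre-scaled by ``1 + noise_sd**2`` so the
*emitted* data realize ``within_corr`` / ``between_corr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SignalSet

__all__ = [
    "SimSpec",
    "BehaviorSpec",
    "simulate_subject",
    "simulate_cohort",
    "simulate_behavior",
    "make_atlas",
    "DEFAULT_MEASURES",
]

_EIG_FLOOR = 1e-6
DEFAULT_MEASURES = ("processing_speed", "card_sort", "flanker")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the planted-structure signal generator.

    Defaults describe the cohort condition used throughout the analyses:
    40 nodes in 4 communities at 1,200 frames, TR 0.72 s, within/between
    community correlation 0.5 / 0.05, mild white observation noise. The
    fourth community is a small 4-node coalition whose members are all
    flexible — a salience-network-like subsystem that couples to a
    different host community every 100 frames — while the three 12-node
    host communities are purely stable.
    """

    n_nodes: int = 40
    n_communities: int = 4
    community_sizes: tuple[int, ...] = (12, 12, 12, 4)
    n_frames: int = 1200
    dt: float = 0.72
    within_corr: float = 0.5
    between_corr: float = 0.05
    flexible_nodes: tuple[int, ...] = (36, 37, 38, 39)
    switch_period: int = 100
    noise_sd: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        object.__setattr__(self, "community_sizes", tuple(self.community_sizes))
        object.__setattr__(self, "flexible_nodes", tuple(self.flexible_nodes))
        if sum(self.community_sizes) != self.n_nodes:
            raise ValueError(
                f"community_sizes sum {sum(self.community_sizes)} != n_nodes {self.n_nodes}"
            )
        if len(self.community_sizes) != self.n_communities:
            raise ValueError("community_sizes length must equal n_communities")
        if not (0 <= self.between_corr < self.within_corr < 1 or self.within_corr == 1):
            if not (self.within_corr > self.between_corr >= 0):
                raise ValueError(
                    f"need within_corr > between_corr >= 0, got "
                    f"{self.within_corr}, {self.between_corr}"
                )
        if any(i < 0 or i >= self.n_nodes for i in self.flexible_nodes):
            raise ValueError("flexible_nodes outside node range")
        if self.flexible_nodes and self.n_communities < 2:
            raise ValueError("flexible nodes need at least 2 communities")
        if self.switch_period < 2:
            raise ValueError("switch_period must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # noise compensation must keep the target correlation below 1
        scale = 1.0 + self.noise_sd**2
        if self.within_corr < 1 and self.within_corr * scale >= 1.0:
            raise ValueError(
                "non-positive-definite target: within_corr="
                f"{self.within_corr} with noise_sd={self.noise_sd} requires an "
                f"epoch correlation of {self.within_corr * scale:.3f} >= 1"
            )

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(f"n{i:03d}" for i in range(self.n_nodes))

    def native_labels(self) -> np.ndarray:
        """Community of each node by block layout (flexible nodes: their home)."""
        labels = np.repeat(np.arange(self.n_communities), self.community_sizes)
        return labels

    def static_truth_labels(self) -> np.ndarray:
        """Planted *static* community labels.

        Stable nodes keep their block label; flexible nodes form one extra
        "transient coalition" label (``n_communities``), because statically
        they correlate most strongly with each other, not with any block.
        With no flexible nodes this equals :meth:`native_labels`.
        """
        labels = self.native_labels().copy()
        if self.flexible_nodes:
            labels[list(self.flexible_nodes)] = self.n_communities
        return labels


def _epoch_labels(spec: SimSpec, n_epochs: int, rng: np.random.Generator) -> np.ndarray:
    """(n_epochs, n_nodes) community membership per epoch.

    Flexible nodes cycle round-robin over the non-native communities; all
    flexible nodes sharing a native community share one seeded phase.
    """
    native = spec.native_labels()
    labels = np.tile(native, (n_epochs, 1))
    phases = {c: int(rng.integers(spec.n_communities - 1))
              for c in sorted({int(native[i]) for i in spec.flexible_nodes})}
    for i in spec.flexible_nodes:
        home = int(native[i])
        others = [c for c in range(spec.n_communities) if c != home]
        for e in range(n_epochs):
            labels[e, i] = others[(phases[home] + e) % len(others)]
    return labels


def _epoch_correlation(spec: SimSpec, labels: np.ndarray) -> np.ndarray:
    """Target correlation matrix for one epoch given node labels."""
    same = labels[:, None] == labels[None, :]
    r = np.where(same, spec.within_corr, spec.between_corr).astype(float)
    np.fill_diagonal(r, 1.0)
    return r


def _nearest_pd(corr: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to the nearest PD matrix (eigenvalue floor)."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= floor:
        return corr
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def simulate_subject(spec: SimSpec, subject_seed: int) -> np.ndarray:
    """One subject's ``(n_nodes, n_frames)`` signal matrix.

    Each epoch draws from a multivariate normal whose correlation realizes
    the planted block structure of that epoch; independent white noise of
    sd ``noise_sd`` is added on top. Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(int(subject_seed))
    n_epochs = -(-spec.n_frames // spec.switch_period)
    labels = _epoch_labels(spec, n_epochs, rng)
    comp = 1.0 + spec.noise_sd**2
    out = np.empty((spec.n_nodes, spec.n_frames))
    chol_cache: dict[bytes, np.ndarray] = {}
    for e in range(n_epochs):
        start = e * spec.switch_period
        stop = min(start + spec.switch_period, spec.n_frames)
        width = stop - start
        if spec.within_corr == 1.0 and spec.noise_sd == 0.0 and spec.between_corr == 0.0:
            # degenerate: every node of a community carries the same series
            shared = rng.standard_normal((spec.n_communities, width))
            out[:, start:stop] = shared[labels[e]]
            continue
        key = labels[e].tobytes()
        if key not in chol_cache:
            target = _epoch_correlation(spec, labels[e])
            off = ~np.eye(spec.n_nodes, dtype=bool)
            target[off] *= comp
            chol_cache[key] = np.linalg.cholesky(_nearest_pd(target))
        out[:, start:stop] = chol_cache[key] @ rng.standard_normal((spec.n_nodes, width))
    if spec.noise_sd > 0:
        out += spec.noise_sd * rng.standard_normal(out.shape)
    return out


def subject_seed(spec: SimSpec, session: int, subject: int) -> int:
    """Deterministic per-(session, subject) seed fanned out from spec.seed."""
    ss = np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(session, subject))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate_cohort(spec: SimSpec, n_subjects: int, sessions: int = 1) -> list[SignalSet]:
    """Simulate ``n_subjects`` subjects for ``sessions`` sessions.

    Sessions share every subject's flexible-node identities (fixed in the
    spec) but use independent noise and sample paths, emulating a
    test-retest design. Returns one :class:`SignalSet` per session.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if sessions < 1:
        raise ValueError("sessions must be >= 1")
    subjects = tuple(f"sub{j:03d}" for j in range(n_subjects))
    out = []
    for sess in range(sessions):
        mats = tuple(
            simulate_subject(spec, subject_seed(spec, sess, j)) for j in range(n_subjects)
        )
        out.append(SignalSet(subjects, mats, spec.node_ids, spec.dt))
    return out


def make_atlas(spec: SimSpec, flexible_label: str = "SN") -> pd.DataFrame:
    """Atlas table for a simulated cohort.

    Stable communities get generic network names; flexible nodes are grouped
    under ``flexible_label`` (by analogy with a salience-network-like set of
    transiently coupling nodes). Coordinates are arbitrary community-wise
    offsets, present only to satisfy the table schema.
    """
    labels = spec.static_truth_labels()
    names = [f"net{c}" for c in range(spec.n_communities)] + [flexible_label]
    rng = np.random.default_rng(spec.seed)
    coords = rng.uniform(-60, 60, size=(spec.n_nodes, 3)).round(1)
    return pd.DataFrame(
        {
            "node_id": list(spec.node_ids),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "network_label": [names[c] for c in labels],
        }
    )


@dataclass(frozen=True)
class BehaviorSpec:
    """Planted linear brain-behavior link.

    ``coupling_r`` is the correlation between subjects' flexibility summary
    and the behavioral composite ``measures @ true_weights``. Three measures
    emulate speeded/executive-function scores (processing speed, card-sort
    switching, flanker inhibition).
    """

    n_measures: int = 3
    true_weights: tuple[float, ...] = (0.2, 1.0, 0.4)
    coupling_r: float = 0.45
    seed: int = 11
    residual: float = 0.9  # fraction of off-composite measure variance, in [0, 1]

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_weights", tuple(self.true_weights))
        if len(self.true_weights) != self.n_measures:
            raise ValueError("true_weights length must equal n_measures")
        if not np.any(np.asarray(self.true_weights)):
            raise ValueError("true_weights must not be all zero")
        if not -1.0 <= self.coupling_r <= 1.0:
            raise ValueError("coupling_r must be in [-1, 1]")
        if not 0 <= self.residual <= 1:
            raise ValueError("residual must be in [0, 1]")


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant vector cannot be standardized")
    return (v - v.mean()) / sd


def simulate_behavior(
    bspec: BehaviorSpec,
    flex_scores: np.ndarray | "pd.Series",
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Subject x measure behavioral table with a planted composite link.

    The latent composite direction ``g = r*z + sqrt(1-r^2)*eta`` (``z`` the
    standardized flexibility scores, ``eta`` an independent standard-normal
    draw) carries the planted coupling; measure ``j`` loads on ``g`` with
    ``b_j = sign(w_j) sqrt(1 - residual (1 - u_j^2))`` (``u = w/|w|``) and
    residual noise confined to the null space of ``true_weights``, so the
    population correlation between ``measures @ true_weights`` and
    ``flex_scores`` is ``coupling_r`` while the sample correlation carries
    ordinary sampling variability. Columns are standardized to mean 0,
    sd 1 exactly; with ``residual = 0`` every measure (hence the composite)
    is an exact affine image of ``g``.
    """
    if isinstance(flex_scores, pd.Series):
        if subjects is None:
            subjects = list(flex_scores.index.astype(str))
        flex_scores = flex_scores.to_numpy()
    flex = np.asarray(flex_scores, dtype=float)
    n, m = len(flex), bspec.n_measures
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if n <= m:
        raise ValueError(f"fewer subjects ({n}) than behavioral measures+1 ({m + 1})")
    rng = np.random.default_rng(bspec.seed)
    z = _standardize(flex)
    r = bspec.coupling_r
    eta = rng.standard_normal(n)
    g = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eta

    w = np.asarray(bspec.true_weights, dtype=float)
    u = w / np.linalg.norm(w)
    proj = np.eye(m) - np.outer(u, u)  # noise stays in the null space of w
    kappa = bspec.residual
    b = np.sqrt(1.0 - kappa * (1.0 - u**2))
    b[w < 0] *= -1.0
    table = np.outer(g, b) + np.sqrt(kappa) * (rng.standard_normal((n, m)) @ proj)

    # exact column standardization (perturbs the composite only at O(1/n))
    table -= table.mean(axis=0)
    sds = table.std(axis=0)
    if (sds == 0).any():
        raise ValueError("degenerate behavioral measure (zero variance)")
    table /= sds
    if subjects is None:
        subjects = [f"sub{j:03d}" for j in range(n)]
    cols = list(DEFAULT_MEASURES) if m == 3 else [f"measure_{j}" for j in range(m)]
    return pd.DataFrame(table, index=pd.Index(subjects, name="subject"), columns=cols)
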