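"""Node-level metrics of dynamic functional connectivity.

All three dynamics metrics are computed from a subject's temporal
co-occurrence matrix ``C`` and the static reference partition (each node's
native community ``u_i``); strength sums always exclude the diagonal
(``C_ii = 1`` is a self-allegiance artifact):

* temporal flexibility  ``f_i = sum_{j not in u_i} C_ij / sum_{j != i} C_ij``
  — the fraction of a node's co-occurrence mass spent outside its native
  community;
* spatiotemporal diversity
  ``h_i = -(1/log m) sum_u p_i(u) log p_i(u)``, ``p_i(u) = s_i(u)/s_i``
  — normalized entropy of the node's co-occurrence strength over the m
  reference communities (its own included, as in the diversity
  coefficient);
* within-community centrality
  ``z_i = (s_i(u_i) - mean) / sd`` — z-score of the node's within-native-
  community strength over that community's nodes (sample sd).

Static analogues (node strength and participation coefficient of the
positive static connectivity) allow the dynamic/static comparison, and a
2-means clustering of the group-mean (flexibility, diversity) plane isolates
the high-flexibility node set.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .community import CoOccurrence, Partition

__all__ = [
    "temporal_flexibility",
    "spatiotemporal_diversity",
    "within_community_centrality",
    "static_node_metrics",
    "node_dynamics_table",
    "aggregate_by_network",
    "network_contrasts",
    "high_flex_cluster",
    "session_overlap",
]


def _cmat(C: CoOccurrence | np.ndarray) -> np.ndarray:
    m = C.C if isinstance(C, CoOccurrence) else np.asarray(C, dtype=float)
    m = m.copy()
    np.fill_diagonal(m, 0.0)  # self-allegiance never contributes
    return m


def _check_nodes(mat: np.ndarray, ref: Partition) -> None:
    if mat.shape[0] != ref.n_nodes:
        raise ValueError(f"C has {mat.shape[0]} nodes, partition {ref.n_nodes}")


def _community_strengths(mat: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(n_nodes, m) strength of each node into each community, diagonal excluded."""
    m = int(labels.max()) + 1
    onehot = np.eye(m)[labels]
    return mat @ onehot


def temporal_flexibility(C: CoOccurrence | np.ndarray, ref: Partition) -> np.ndarray:
    """Per-node temporal flexibility f in [0, 1]; NaN where total strength is 0."""
    mat = _cmat(C)
    _check_nodes(mat, ref)
    s_by_comm = _community_strengths(mat, ref.labels)
    total = s_by_comm.sum(axis=1)
    own = s_by_comm[np.arange(len(total)), ref.labels]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, (total - own) / total, np.nan)
    if np.isnan(f).any():
        warnings.warn("flexibility undefined for nodes with zero co-occurrence strength")
    return f


def spatiotemporal_diversity(C: CoOccurrence | np.ndarray, ref: Partition) -> np.ndarray:
    """Per-node diversity h in [0, 1]: entropy of strength over communities."""
    mat = _cmat(C)
    _check_nodes(mat, ref)
    m = ref.n_communities
    if m < 2:
        raise ValueError("diversity needs at least 2 reference communities")
    s_by_comm = _community_strengths(mat, ref.labels)
    total = s_by_comm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = s_by_comm / total
        terms = np.where(p > 0, p * np.log(p), 0.0)
        h = -terms.sum(axis=1) / np.log(m)
    h = np.where(total[:, 0] > 0, h, np.nan)
    if np.isnan(h).any():
        warnings.warn("diversity undefined for nodes with zero co-occurrence strength")
    return h


def within_community_centrality(C: CoOccurrence | np.ndarray, ref: Partition) -> np.ndarray:
    """Per-node within-community centrality z (z-scored native-community strength).

    Singleton communities or zero within-community spread yield a flagged 0.
    """
    mat = _cmat(C)
    _check_nodes(mat, ref)
    labels = ref.labels
    s_by_comm = _community_strengths(mat, labels)
    s_own = s_by_comm[np.arange(len(labels)), labels]
    z = np.zeros(len(labels))
    degenerate = False
    for c in range(ref.n_communities):
        members = np.flatnonzero(labels == c)
        vals = s_own[members]
        if len(members) < 2 or np.ptp(vals) == 0:
            degenerate = True
            continue  # z stays 0 (flagged)
        z[members] = (vals - vals.mean()) / vals.std(ddof=1)
    if degenerate:
        warnings.warn("centrality set to 0 for singleton/constant-strength communities")
    return z


def static_node_metrics(
    w_static: np.ndarray, ref: Partition
) -> tuple[np.ndarray, np.ndarray]:
    """Static node strength and participation coefficient (positive weights).

    strength_i = sum_{j != i} max(w_ij, 0);
    participation_i = 1 - sum_u (s_i(u)/s_i)^2. Zero-strength nodes get
    strength 0 and a flagged NaN participation.
    """
    w = np.clip(np.asarray(w_static, dtype=float), 0.0, None)
    np.fill_diagonal(w, 0.0)
    _check_nodes(w, ref)
    s_by_comm = _community_strengths(w, ref.labels)
    strength = s_by_comm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = s_by_comm / strength[:, None]
        participation = np.where(strength > 0, 1.0 - (frac**2).sum(axis=1), np.nan)
    if np.isnan(participation).any():
        warnings.warn("participation undefined for zero-strength nodes")
    return strength, participation


def node_dynamics_table(
    cooccurrences: dict[str, CoOccurrence],
    ref: Partition,
    static_w: np.ndarray,
    node_ids: list[str],
    atlas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tidy per-subject, per-node metric table.

    Columns: subject, node, network (if an atlas is given), flexibility,
    diversity, centrality, strength, participation.
    """
    strength, participation = static_node_metrics(static_w, ref)
    net = None
    if atlas is not None:
        net = atlas.set_index("node_id")["network_label"].reindex([str(n) for n in node_ids])
    rows = []
    for subj, C in cooccurrences.items():
        f = temporal_flexibility(C, ref)
        h = spatiotemporal_diversity(C, ref)
        z = within_community_centrality(C, ref)
        df = pd.DataFrame(
            {
                "subject": subj,
                "node": [str(n) for n in node_ids],
                "flexibility": f,
                "diversity": h,
                "centrality": z,
                "strength": strength,
                "participation": participation,
            }
        )
        if net is not None:
            df.insert(2, "network", net.to_numpy())
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def aggregate_by_network(
    nd: pd.DataFrame, metric: str = "flexibility"
) -> pd.DataFrame:
    """Per-subject mean of ``metric`` over the nodes of each network.

    Returns a subject x network table. Networks without nodes are simply
    absent; empty groups in the input raise nothing but are warned about by
    pandas-level emptiness upstream.
    """
    if "network" not in nd.columns:
        raise ValueError("node table has no network column (no atlas given)")
    table = nd.pivot_table(index="subject", columns="network", values=metric, aggfunc="mean")
    empty = [c for c in table.columns if table[c].isna().all()]
    if empty:
        warnings.warn(f"networks without nodes excluded: {empty}")
        table = table.drop(columns=empty)
    return table


def network_contrasts(per_network: pd.DataFrame) -> pd.DataFrame:
    """All pairwise cross-network contrasts of per-subject means.

    Paired two-sided Wilcoxon signed-rank across subjects, Holm-corrected.
    """
    nets = list(per_network.columns)
    rows = []
    for i, a in enumerate(nets):
        for b_ in nets[i + 1:]:
            diff = per_network[a] - per_network[b_]
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = stats.wilcoxon(per_network[a], per_network[b_]).pvalue
            rows.append({"network_a": a, "network_b": b_,
                         "mean_diff": diff.mean(), "p_raw": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def high_flex_cluster(
    nd: pd.DataFrame,
    method: str = "kmeans",
    percentile: float = 85.0,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """High-flexibility node set from the group-mean (flexibility, diversity) plane.

    ``method='kmeans'``: standardize both axes, 2-means with 50 seeded
    restarts, return the component with higher mean flexibility. Degenerate
    clustering (a component would be empty, or zero spread) falls back to
    the percentile rule with a warning. ``method='threshold'``: nodes above
    the given flexibility percentile (default top 15%).
    """
    grp = nd.groupby("node", sort=False)[["flexibility", "diversity"]].mean()
    x = grp.to_numpy()
    nodes = grp.index.to_numpy()
    summary = grp.copy()
    if method not in ("kmeans", "threshold"):
        raise ValueError(f"unknown method {method!r}")
    if method == "kmeans":
        sd = x.std(axis=0)
        if (sd == 0).any() or np.isnan(x).any():
            warnings.warn("degenerate flexibility-diversity plane; falling back to threshold rule")
            method = "threshold"
        else:
            xs = (x - x.mean(axis=0)) / sd
            km = KMeans(n_clusters=2, n_init=50, random_state=seed).fit(xs)
            lab = km.labels_
            if len(np.unique(lab)) < 2:
                warnings.warn("empty k-means component; falling back to threshold rule")
                method = "threshold"
            else:
                mean_f = [x[lab == c, 0].mean() for c in (0, 1)]
                chosen = int(np.argmax(mean_f))
                summary["high_flex"] = lab == chosen
                return [str(n) for n in nodes[lab == chosen]], summary
    cut = np.nanpercentile(x[:, 0], percentile)
    mask = x[:, 0] > cut
    summary["high_flex"] = mask
    return [str(n) for n in nodes[mask]], summary


def session_overlap(cluster_a, cluster_b) -> tuple[float, float]:
    """Bidirectional overlap percentages |A&B|/|A| and |A&B|/|B| (in %)."""
    a, b = set(cluster_a), set(cluster_b)
    if not a or not b:
        warnings.warn("empty cluster in overlap computation")
        return float("nan"), float("nan")
    inter = len(a & b)
    return 100.0 * inter / len(a), 100.0 * inter / len(b)
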