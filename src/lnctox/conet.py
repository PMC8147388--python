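"""Guilt-by-association lncRNA-mRNA co-expression network.

Differentially expressed lncRNAs are associated to differentially
expressed mRNAs through Pearson correlation of their log2 fold-change
profiles across all exposure contrasts. Edges must satisfy |R| > 0.8 and
p < 0.05 (both strict); a lncRNA stays in the network only if it is
correlated to at least 15 mRNAs, and an mRNA only if it keeps at least
one edge to a retained lncRNA. The retained correlation matrix is then
bi-clustered hierarchically (Euclidean distance, average linkage) on
each axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.cluster.vq import kmeans2

from .core import LnctoxError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetThresholds:
    """Edge and connectivity cutoffs: |R| > 0.8, p < 0.05, degree >= 15."""

    min_abs_r: float = 0.8
    max_p: float = 0.05
    min_degree: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.min_abs_r <= 1):
            raise LnctoxError("min_abs_r must be in (0, 1]")
        if self.min_degree < 1:
            raise LnctoxError("min_degree must be >= 1")


def correlation_profiles(
    contrasts: dict[str, pd.DataFrame],
    de_lnc: set[str],
    de_mrna: set[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-transcript log2FC vectors across all exposure contrasts.

    A transcript enters the profile matrix if it is DE in at least one
    contrast; its profile uses the log2FC from every contrast (complete
    vectors are required for Pearson correlation).
    """
    if len(contrasts) < 3:
        raise LnctoxError(
            f"need >=3 contrasts for meaningful correlation p-values, got {len(contrasts)}"
        )
    groups = list(contrasts)
    lfc = pd.DataFrame({g: contrasts[g]["log2fc"] for g in groups})
    lnc = lfc.loc[sorted(de_lnc & set(lfc.index))]
    mrna = lfc.loc[sorted(de_mrna & set(lfc.index))]
    return lnc, mrna


def pearson_edges(
    lnc_profiles: pd.DataFrame,
    mrna_profiles: pd.DataFrame,
    th: NetThresholds = NetThresholds(),
) -> pd.DataFrame:
    """All lncRNA-mRNA Pearson edges passing |R| > min_abs_r and p < max_p.

    p comes from the exact t transform t = r sqrt((n-2)/(1-r^2)) on n-2
    degrees of freedom, two-sided. Zero-variance profiles contribute no
    edges (logged). Returns columns lnc_id, mrna_id, r, p, n.
    """
    n = lnc_profiles.shape[1]
    if n < 3:
        raise LnctoxError("profiles must span >=3 contrasts")
    if mrna_profiles.shape[1] != n:
        raise LnctoxError("lncRNA and mRNA profiles span different contrast sets")
    empty = pd.DataFrame(columns=["lnc_id", "mrna_id", "r", "p", "n"])
    if lnc_profiles.empty or mrna_profiles.empty:
        return empty
    L = lnc_profiles.to_numpy(dtype=float)
    M = mrna_profiles.to_numpy(dtype=float)
    Lc = L - L.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    lnorm = np.linalg.norm(Lc, axis=1)
    mnorm = np.linalg.norm(Mc, axis=1)
    lok, mok = lnorm > 0, mnorm > 0
    for ids, ok, axis in ((lnc_profiles.index, lok, "lncRNA"), (mrna_profiles.index, mok, "mRNA")):
        if not ok.all():
            log.warning(
                "%d %s profile(s) have zero variance and contribute no edges "
                "(e.g. %r)", int((~ok).sum()), axis, ids[~ok][0]
            )
    R = (Lc[lok] @ Mc[mok].T) / np.outer(lnorm[lok], mnorm[mok])
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - R**2
        tstat = np.abs(R) * np.sqrt((n - 2) / np.where(denom > 0, denom, 1.0))
        tstat = np.where(denom > 0, tstat, np.inf)
    p = 2.0 * stats.t.sf(tstat, n - 2)
    keep = (np.abs(R) > th.min_abs_r) & (p < th.max_p)
    li, mi = np.nonzero(keep)
    lnc_ids = lnc_profiles.index[lok]
    mrna_ids = mrna_profiles.index[mok]
    return pd.DataFrame(
        {
            "lnc_id": lnc_ids[li],
            "mrna_id": mrna_ids[mi],
            "r": R[li, mi],
            "p": p[li, mi],
            "n": n,
        }
    ).reset_index(drop=True)


def degree_filter(
    edges: pd.DataFrame, th: NetThresholds = NetThresholds()
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Connectivity rule: lncRNA degree >= min_degree, then cascade to mRNAs.

    lncRNAs correlated to at least ``min_degree`` mRNAs are kept; mRNAs
    are kept iff they retain at least one edge to a kept lncRNA; the
    edge table is restricted accordingly.
    """
    if edges.empty:
        return set(), set(), edges.copy()
    deg = edges.groupby("lnc_id").size()
    kept_lnc = set(deg.index[deg >= th.min_degree])
    sub = edges[edges["lnc_id"].isin(kept_lnc)]
    kept_mrna = set(sub["mrna_id"])
    return kept_lnc, kept_mrna, sub.reset_index(drop=True)


@dataclass
class ClusterAssignment:
    """Cluster labels over one axis, ids ranked by size (1 = largest).

    Ties in size are broken by the height at which the cluster's members
    finish merging in the dendrogram: lower height (tighter cluster)
    wins the lower id.
    """

    labels: pd.Series  # item_id -> cluster_id (1-based)
    axis: str
    linkage: np.ndarray | None = None
    heights: dict[int, float] = field(default_factory=dict)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _cluster_heights(Z: np.ndarray, flat: np.ndarray) -> dict[int, float]:
    """Max merge height fully inside each flat cluster (singletons: 0)."""
    n = len(flat)
    # leaves under each internal node, built bottom-up
    node_cluster: dict[int, int | None] = {i: int(flat[i]) for i in range(n)}
    heights = {int(c): 0.0 for c in np.unique(flat)}
    for k, (a, b, h, _) in enumerate(Z):
        ca, cb = node_cluster.get(int(a)), node_cluster.get(int(b))
        same = ca is not None and ca == cb
        node_cluster[n + k] = ca if same else None
        if same:
            heights[ca] = max(heights[ca], float(h))
    return heights


def _rank_clusters(items: pd.Index, flat: np.ndarray, Z: np.ndarray, axis: str) -> ClusterAssignment:
    heights = _cluster_heights(Z, flat)
    sizes = pd.Series(flat).value_counts()
    order = sorted(
        sizes.index,
        key=lambda c: (-sizes[c], heights[int(c)], min(np.nonzero(flat == c)[0])),
    )
    remap = {int(c): i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[int(c)] for c in flat], index=items)
    return ClusterAssignment(
        labels=labels,
        axis=axis,
        linkage=Z,
        heights={remap[c]: h for c, h in heights.items()},
    )


def _hcluster(X: np.ndarray, items: pd.Index, k: int, axis: str, kmeans_k: int | None = None) -> ClusterAssignment:
    if k > len(items):
        raise LnctoxError(f"k={k} exceeds {axis} item count {len(items)}")
    if len(items) == 1:
        return ClusterAssignment(pd.Series([1], index=items), axis, None, {1: 0.0})
    if kmeans_k is not None and kmeans_k < len(items):
        # optional pre-partitioning: cluster k-means centroids, then map
        # items through their centroid's label
        _, pre = kmeans2(X, kmeans_k, seed=0, minit="++")
        centroids = np.vstack([X[pre == c].mean(axis=0) for c in np.unique(pre)])
        Z = hierarchy.linkage(centroids, method="average", metric="euclidean")
        cent_flat = hierarchy.fcluster(Z, t=min(k, len(centroids)), criterion="maxclust")
        lut = dict(zip(np.unique(pre), cent_flat))
        flat = np.array([lut[c] for c in pre])
        return _rank_clusters(items, flat, Z, axis)
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return _rank_clusters(items, flat, Z, axis)


def edge_matrix(edges: pd.DataFrame, kept_lnc: set[str], kept_mrna: set[str]) -> pd.DataFrame:
    """Dense lncRNA x mRNA correlation matrix; 0 where no edge survived."""
    mat = pd.DataFrame(0.0, index=sorted(kept_lnc), columns=sorted(kept_mrna))
    for row in edges.itertuples(index=False):
        if row.lnc_id in mat.index and row.mrna_id in mat.columns:
            mat.loc[row.lnc_id, row.mrna_id] = row.r
    return mat


def bicluster_network(
    edges: pd.DataFrame,
    kept_lnc: set[str],
    kept_mrna: set[str],
    k_lnc: int = 5,
    k_mrna: int = 2,
    kmeans_k: int | None = None,
) -> tuple[ClusterAssignment, ClusterAssignment]:
    """Hierarchical bi-clustering of the retained correlation matrix.

    Rows (lncRNAs) and columns (mRNAs) are clustered independently with
    Euclidean distance and average linkage; each tree is cut to the
    requested number of clusters, labelled by descending size.
    """
    if not kept_lnc or not kept_mrna:
        raise LnctoxError("cannot bicluster an empty network")
    mat = edge_matrix(edges, kept_lnc, kept_mrna)
    lnc_cl = _hcluster(mat.to_numpy(), mat.index, k_lnc, "lncRNA", kmeans_k)
    mrna_cl = _hcluster(mat.to_numpy().T, mat.columns, k_mrna, "mRNA", kmeans_k)
    return lnc_cl, mrna_cl


def select_top_clusters(clusters: ClusterAssignment, n_top: int = 2) -> list[int]:
    """The n largest clusters by member count (ids are already size-ranked)."""
    available = sorted(clusters.labels.unique())
    if len(available) < n_top:
        warnings.warn(
            f"requested top {n_top} clusters but only {len(available)} exist",
            stacklevel=2,
        )
    return available[:n_top]


def linked_mrna_cluster(
    lnc_cluster_members: list[str],
    edges: pd.DataFrame,
    mrna_clusters: ClusterAssignment,
) -> int:
    """The mRNA cluster most connected to a given lncRNA cluster."""
    sub = edges[edges["lnc_id"].isin(lnc_cluster_members)]
    if sub.empty:
        raise LnctoxError("lncRNA cluster has no surviving edges")
    counts = mrna_clusters.labels.loc[
        [m for m in sub["mrna_id"] if m in mrna_clusters.labels.index]
    ].value_counts()
    return int(counts.idxmax())
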