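"""Exposure ranking from panel-lncRNA expression.

The panel is the set of lncRNAs with at least ``min_degree`` surviving
correlation edges into a chosen mRNA cluster. Panel probes are Z-scored
across all samples, averaged per exposure group, hierarchically
clustered (Euclidean, average linkage) over groups, and the clusters are
ordered by mean panel expression into toxicity tiers. The cluster
containing the control groups must be the lowest tier — a ranking
inversion is an error, not a silent relabeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core import ExpressionMatrix, LnctoxError, is_control_group

TIER_NAMES_K3 = ("control_low", "medium", "high")


@dataclass
class ToxicityRanking:
    """Per-group panel DE counts and tier labels, plus the panel itself."""

    tiers: pd.Series  # group -> tier label
    counts: pd.Series  # group -> n DE panel lncRNAs
    panel: set[str]
    linkage: np.ndarray | None = None
    tier_order: tuple[str, ...] = ()

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_de_lnc_in_panel": self.counts, "tier": self.tiers}
        ).rename_axis("group")


def panel_filter(
    edges: pd.DataFrame, target_mrna_cluster: set[str], min_degree: int = 15
) -> set[str]:
    """lncRNAs with >= min_degree edges into the target mRNA cluster."""
    if not target_mrna_cluster:
        raise LnctoxError("target mRNA cluster is empty")
    if edges.empty:
        return set()
    sub = edges[edges["mrna_id"].isin(target_mrna_cluster)]
    deg = sub.groupby("lnc_id").size()
    return set(deg.index[deg >= min_degree])


def zscore_group_matrix(
    m: ExpressionMatrix, design: pd.DataFrame, panel: set[str]
) -> pd.DataFrame:
    """Groups x panel matrix of per-probe Z-scores averaged within group.

    Each panel probe is Z-scored across all samples (sample SD, ddof=1);
    constant probes have no Z-score and are dropped with a warning. Rows
    cover every group in the design, controls included.
    """
    if m.scale != "log2":
        raise LnctoxError("zscore_group_matrix expects a log2-scale matrix")
    probes = [p for p in sorted(panel) if p in m.values.index]
    X = m.values.loc[probes]
    sd = X.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant panel probe(s) with "
            f"undefined Z-score (e.g. {X.index[constant][0]!r})",
            stacklevel=2,
        )
        X, sd = X[~constant], sd[~constant]
    Z = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
    groups = design.set_index("sample_id")["group"]
    return Z.T.groupby(groups).mean().rename_axis("group")[Z.index]


def tier_exposures(z: pd.DataFrame, k: int = 3) -> tuple[pd.Series, tuple[str, ...], np.ndarray | None]:
    """Cluster group rows and order clusters into toxicity tiers.

    Returns (group -> tier label, tier order low-to-high, linkage).
    Tiers are named control_low / medium / high for k=3, tier_1..tier_k
    otherwise. The cluster holding the control groups must have the
    lowest mean panel expression; otherwise the ranking is invalid and
    an error is raised.
    """
    groups = z.index
    if k < 1:
        raise LnctoxError("k must be >= 1")
    if k > len(groups):
        raise LnctoxError(f"k={k} exceeds number of groups {len(groups)}")
    X = z.to_numpy(dtype=float)
    if k == 1 or len(groups) == 1:
        labels = np.ones(len(groups), dtype=int)
        Z = None
    else:
        if np.allclose(X, X[0]):
            warnings.warn("all group profiles identical; single degenerate tier", stacklevel=2)
            labels = np.ones(len(groups), dtype=int)
            Z = None
        else:
            Z = hierarchy.linkage(X, method="average", metric="euclidean")
            labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    uniq = np.unique(labels)
    if len(uniq) < k and Z is not None:
        warnings.warn(
            f"clustering produced {len(uniq)} cluster(s) for k={k}", stacklevel=2
        )
    means = {c: X[labels == c].mean() for c in uniq}
    order = sorted(uniq, key=lambda c: means[c])
    names = TIER_NAMES_K3 if len(uniq) == 3 else tuple(f"tier_{i+1}" for i in range(len(uniq)))
    tier_of = {c: names[i] for i, c in enumerate(order)}
    tiers = pd.Series([tier_of[c] for c in labels], index=groups, name="tier")
    controls = [g for g in groups if is_control_group(g)]
    lowest = {g for g, c in zip(groups, labels) if c == order[0]}
    inverted = [g for g in controls if g not in lowest]
    if inverted:
        raise LnctoxError(
            f"ranking inversion: control group {inverted[0]!r} is not in the "
            "lowest-expression cluster"
        )
    return tiers, names, Z


def panel_de_counts(gated: dict[str, tuple[set, set]], panel: set[str]) -> pd.Series:
    """Per-group count of panel lncRNAs that pass the DE gates."""
    return pd.Series(
        {g: len(lnc & panel) for g, (lnc, _mrna) in gated.items()}, name="n_de_lnc_in_panel"
    ).rename_axis("group")


def rank_exposures(
    m: ExpressionMatrix,
    design: pd.DataFrame,
    edges: pd.DataFrame,
    target_mrna_cluster: set[str],
    gated: dict[str, tuple[set, set]],
    min_degree: int = 15,
    k: int = 3,
) -> ToxicityRanking:
    """Full ranking: panel filter -> Z-score matrix -> tiers -> DE counts."""
    panel = panel_filter(edges, target_mrna_cluster, min_degree)
    if not panel:
        warnings.warn("empty lncRNA panel: no group can be ranked", stacklevel=2)
        groups = list(dict.fromkeys(design["group"]))
        return ToxicityRanking(
            tiers=pd.Series(["control_low"] * len(groups), index=groups, name="tier"),
            counts=pd.Series(0, index=pd.Index(groups, name="group")),
            panel=set(),
        )
    z = zscore_group_matrix(m, design, panel)
    tiers, order, Z = tier_exposures(z, k=k)
    counts = panel_de_counts(gated, panel).reindex(tiers.index, fill_value=0)
    return ToxicityRanking(tiers=tiers, counts=counts, panel=panel, linkage=Z, tier_order=order)
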