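"""Core containers shared by every pipeline stage.

The central object is :class:`ExpressionMatrix`: a probes x samples
intensity matrix carrying its probe annotation (accession, biotype) and a
scale flag distinguishing raw foreground intensities from log2 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BIOTYPES = ("lncRNA", "mRNA", "negative_control")
MATERIALS = ("CuO", "MWCNT", "TiO2p", "TiO2r")
SURFACES = ("Core", "COOH", "NH2", "PEG")
CONTROL_MATERIAL = "control"

ANNOTATION_COLUMNS = ("probe_id", "accession", "biotype")
DESIGN_COLUMNS = (
    "sample_id",
    "material",
    "surface",
    "dispersant",
    "batch_label",
    "batch_array",
    "replicate",
    "group",
)


class LnctoxError(ValueError):
    """Base class for domain validation errors."""


def group_name(material: str, surface: str, dispersant: str = "PBS") -> str:
    """Canonical group label: ``CuO-NH2`` for exposures, ``control-PBS`` for controls."""
    if material == CONTROL_MATERIAL:
        return f"{CONTROL_MATERIAL}-{dispersant}"
    return f"{material}-{surface}"


def is_control_group(group: str) -> bool:
    return group.startswith(CONTROL_MATERIAL + "-")


@dataclass
class ExpressionMatrix:
    """Probes x samples expression with biotype-aware probe index.

    Parameters
    ----------
    values
        DataFrame indexed by probe_id, columns are sample_ids. No NA
        values are permitted anywhere (the array platform reports an
        intensity for every feature, and the workflow has no imputation
        step).
    annotation
        DataFrame indexed by probe_id with columns ``accession`` and
        ``biotype``; must cover every probe in ``values``.
    scale
        ``"raw"`` for foreground intensities, ``"log2"`` after transform.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise LnctoxError(f"unknown scale {self.scale!r}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise LnctoxError(f"duplicate probe id {dup!r} in expression matrix")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise LnctoxError(f"duplicate sample id {dup!r} in expression matrix")
        if self.values.isna().any().any():
            col = self.values.columns[self.values.isna().any()][0]
            probe = self.values.index[self.values[col].isna()][0]
            raise LnctoxError(
                f"missing value at probe {probe!r}, sample {col!r}: "
                "NA cells are not permitted in expression input"
            )
        missing = self.values.index.difference(self.annotation.index)
        if len(missing) > 0:
            raise LnctoxError(
                f"probe {missing[0]!r} has no annotation row "
                f"({len(missing)} unannotated probes in total)"
            )
        bad = set(self.annotation["biotype"]) - set(BIOTYPES)
        if bad:
            raise LnctoxError(f"unknown biotype(s) {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def biotype(self) -> pd.Series:
        """Biotype per probe, aligned to the matrix row order."""
        return self.annotation.loc[self.values.index, "biotype"]

    @property
    def accession(self) -> pd.Series:
        return self.annotation.loc[self.values.index, "accession"]

    def probes_of_biotype(self, biotype: str) -> pd.Index:
        return self.values.index[self.biotype.to_numpy() == biotype]

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(probe_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values[list(sample_ids)])

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return replace(self, values=values, scale=scale or self.scale)


def validate_design(design: pd.DataFrame) -> None:
    """Check the design table invariants.

    sample_ids unique; every exposed group has a dispersant-matched
    control group; every group has at least 2 replicates (required for
    differential expression).
    """
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise LnctoxError(f"design table missing column(s) {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise LnctoxError(f"duplicate sample id {dup!r} in design table")
    control_disp = set(
        design.loc[design["material"] == CONTROL_MATERIAL, "dispersant"]
    )
    exposed = design[design["material"] != CONTROL_MATERIAL]
    for disp in exposed["dispersant"].unique():
        if disp not in control_disp:
            grp = exposed.loc[exposed["dispersant"] == disp, "group"].iloc[0]
            raise LnctoxError(
                f"group {grp!r} has dispersant {disp!r} but no matched control group"
            )
    sizes = design.groupby("group").size()
    small = sizes[sizes < 2]
    if len(small) > 0:
        raise LnctoxError(
            f"group {small.index[0]!r} has {small.iloc[0]} sample(s); >=2 replicates required"
        )


def exposure_groups(design: pd.DataFrame) -> list[str]:
    """Exposed (non-control) group labels in design-table order."""
    mask = design["material"] != CONTROL_MATERIAL
    return list(dict.fromkeys(design.loc[mask, "group"]))


def control_group_for(design: pd.DataFrame, group: str) -> str:
    """The dispersant-matched control group for an exposed group."""
    rows = design[design["group"] == group]
    if rows.empty:
        raise LnctoxError(f"group {group!r} not present in design table")
    disp = rows["dispersant"].iloc[0]
    ctrl = design[
        (design["material"] == CONTROL_MATERIAL) & (design["dispersant"] == disp)
    ]
    if ctrl.empty:
        raise LnctoxError(f"no control group with dispersant {disp!r} for group {group!r}")
    return ctrl["group"].iloc[0]


def samples_of_group(design: pd.DataFrame, group: str) -> list[str]:
    return list(design.loc[design["group"] == group, "sample_id"])
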