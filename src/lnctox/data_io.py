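"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated UTF-8 with ``.`` as the decimal
separator: expression (probes x samples), probe annotation (probe_id,
accession, biotype), sample design, and gene sets in the standard GMT
dialect. Cross-file consistency (probes vs annotation, samples vs design)
is validated on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ANNOTATION_COLUMNS,
    BIOTYPES,
    DESIGN_COLUMNS,
    ExpressionMatrix,
    LnctoxError,
    validate_design,
)


@dataclass(frozen=True)
class GeneSet:
    """One gene set: id, human-readable name, ordered unique members."""

    set_id: str
    set_name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise LnctoxError(f"gene set {self.set_id!r} has no members")


def read_annotation(path) -> pd.DataFrame:
    """Read a 3-column probe annotation TSV (header required).

    Returns a DataFrame indexed by probe_id with columns ``accession``
    and ``biotype``.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise LnctoxError(f"annotation {path} missing column(s) {sorted(missing)}")
    if ann["probe_id"].duplicated().any():
        dup = ann.loc[ann["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise LnctoxError(f"duplicate probe id {dup!r} in annotation {path}")
    bad = set(ann["biotype"]) - set(BIOTYPES)
    if bad:
        raise LnctoxError(f"annotation {path} has unknown biotype(s) {sorted(bad)}")
    return ann.set_index("probe_id")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.reset_index().to_csv(path, sep="\t", index=False)


def read_expression(path, annotation: pd.DataFrame, scale: str = "raw") -> ExpressionMatrix:
    """Read an expression TSV (first column probe_id, then one column per sample).

    Every probe must be annotated; any non-numeric or missing cell is a
    hard error naming the offending probe and sample.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    for col in raw.columns:
        if not np.issubdtype(raw[col].dtype, np.number):
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = raw.index[coerced.isna() & raw[col].notna()]
            probe = bad[0] if len(bad) else raw.index[raw[col].isna()][0]
            raise LnctoxError(
                f"non-numeric cell in {path} at probe {probe!r}, sample {col!r}"
            )
    unknown = raw.index.difference(annotation.index)
    if len(unknown) > 0:
        raise LnctoxError(
            f"expression {path} contains probe {unknown[0]!r} absent from annotation"
        )
    return ExpressionMatrix(values=raw.astype(float), annotation=annotation, scale=scale)


def write_expression(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise LnctoxError(f"design {path} missing column(s) {sorted(missing)}")
    validate_design(design)
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: ``set_id TAB description TAB member...`` per line.

    Duplicate members within a set are removed, preserving first
    occurrence; set order follows file order.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LnctoxError(
                    f"GMT {path} line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            members = tuple(dict.fromkeys(f for f in fields[2:] if f))
            sets.append(GeneSet(set_id=fields[0], set_name=fields[1], members=members))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.set_name, *s.members]) + "\n")


def validate_consistency(
    m: ExpressionMatrix, annotation: pd.DataFrame, design: pd.DataFrame
) -> None:
    """Reject any expression/annotation/design triple with mismatched ids."""
    extra = m.values.index.difference(annotation.index)
    if len(extra) > 0:
        raise LnctoxError(f"probe {extra[0]!r} in expression but not annotation")
    design_samples = pd.Index(design["sample_id"])
    unmatched = m.values.columns.difference(design_samples)
    if len(unmatched) > 0:
        raise LnctoxError(f"sample {unmatched[0]!r} in expression but not design")
    missing = design_samples.difference(m.values.columns)
    if len(missing) > 0:
        raise LnctoxError(f"sample {missing[0]!r} in design but not expression")


def load_experiment(expression_path, annotation_path, design_path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Convenience loader that reads and cross-validates the input triple."""
    ann = read_annotation(annotation_path)
    design = read_design(design_path)
    m = read_expression(expression_path, ann)
    validate_consistency(m, ann, design)
    return m, design
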