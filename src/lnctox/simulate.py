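"""Synthetic microarray experiments with planted ground truth.

The generator emulates a 16-exposure nanomaterial inhalation study read
out on a two-biotype array: 4 core materials (CuO, MWCNT, TiO2p, TiO2r)
x 4 surface chemistries (Core, COOH, NH2, PEG), each with a
dispersant-matched control group (PBS, or PBS + BSA for MWCNT) and 3
replicates per group. Probes are lncRNA (systematically lower intensity),
mRNA, and negative controls that define per-sample background.

Signal model (log2 scale, per probe i and sample s of group g):

    y_is = b_i + e_ig + gamma_i[label(s)] + delta_i[array(s)] + eps_is

with probe baseline b_i, planted group effect e_ig, additive mean-zero
batch shifts on two batch variables (labeling and array), and Gaussian
noise. Raw intensities are 2**y. Group effects come from two sources:

* co-regulated modules: each module has one group-activity vector; every
  member's effect is that vector times a per-member sign (lncRNA members
  +1, mRNA members +/-1), so member log2FC profiles across contrasts are
  exactly proportional (correlation +/-1 before noise);
* independent per-group differential expression: a fraction ``frac_de``
  of non-module probes per group receives an effect of +/-
  ``effect_size_log2``.

Negative-control probes are pure background draws. The returned
:class:`GroundTruth` records every planted effect, every within-module
lncRNA-mRNA pair, and the module assignment, so downstream recovery is
measurable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CONTROL_MATERIAL,
    ExpressionMatrix,
    LnctoxError,
    MATERIALS,
    SURFACES,
    group_name,
)
from .data_io import GeneSet


def _dispersant(material: str) -> str:
    return "PBS_BSA" if material == "MWCNT" else "PBS"


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic experiment.

    Counts default to the array-like scale (2000 lncRNA, 8000 mRNA, 200
    negative-control probes); the biotype intensity offset, batch SD and
    noise SD are in log2 units.
    """

    n_lnc: int = 2000
    n_mrna: int = 8000
    n_negctrl: int = 200
    materials: tuple[str, ...] = MATERIALS
    surfaces: tuple[str, ...] = SURFACES
    reps_per_group: int = 3
    lnc_mean_offset: float = -2.0
    batch_sd: float = 0.5
    noise_sd: float = 0.3
    baseline_mean: float = 10.0
    baseline_sd: float = 1.2
    background_mean: float = 6.9
    background_sd: float = 0.4
    n_modules: int = 2
    module_size: tuple[int, int] = (40, 120)  # (lncRNA, mRNA) members per module
    effect_size_log2: float = 2.0
    frac_de: float = 0.05
    mrna_negative_frac: float = 0.5
    module_active_prob: float = 0.5
    # Optional explicit per-module group-activity vectors: list (one dict
    # per module) mapping group name -> signed effect multiplier. When
    # None, activity is Bernoulli(module_active_prob) with effect
    # +effect_size_log2.
    module_activity: list[dict[str, float]] | None = None
    # Optional per-group scaling of independent DE effect magnitudes.
    group_effect_scale: dict[str, float] | None = None
    seed: int = 0

    @property
    def exposed_groups(self) -> list[str]:
        return [group_name(m, s) for m in self.materials for s in self.surfaces]

    @property
    def control_groups(self) -> list[str]:
        disps = list(dict.fromkeys(_dispersant(m) for m in self.materials))
        return [group_name(CONTROL_MATERIAL, "none", d) for d in disps]

    def validate(self) -> None:
        for name in ("n_lnc", "n_mrna", "n_negctrl", "reps_per_group", "n_modules"):
            if getattr(self, name) < (0 if name == "n_modules" else 1):
                raise LnctoxError(f"{name} must be positive")
        if not (0 <= self.frac_de < 1):
            raise LnctoxError("frac_de must be in [0, 1)")
        n_mod_lnc = self.n_modules * self.module_size[0]
        n_mod_mrna = self.n_modules * self.module_size[1]
        if n_mod_lnc > self.n_lnc or n_mod_mrna > self.n_mrna:
            raise LnctoxError(
                f"module sizes infeasible: {self.n_modules} modules x "
                f"{self.module_size} members exceed probe counts "
                f"({self.n_lnc} lncRNA, {self.n_mrna} mRNA)"
            )
        if self.module_activity is not None and len(self.module_activity) != self.n_modules:
            raise LnctoxError("module_activity must have one entry per module")


@dataclass
class GroundTruth:
    """Planted structure of one simulated experiment.

    de_probes maps each exposed group to {probe_id: true log2FC} for
    every probe with a non-zero planted effect in that group; true_edges
    is the set of within-module (lncRNA, mRNA) pairs; module_assignment
    maps member probes to their module index (0-based).
    """

    de_probes: dict[str, dict[str, float]]
    true_edges: set[tuple[str, str]]
    module_assignment: dict[str, int]

    def de_set(self, group: str, min_abs_log2fc: float = 0.0) -> set[str]:
        return {
            p
            for p, fc in self.de_probes.get(group, {}).items()
            if abs(fc) >= min_abs_log2fc
        }


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named child RNG streams off one global seed (stable under refactoring)."""
    names = ("probe-effects", "batch", "noise", "background")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _build_design(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    i = 0
    groups = [(m, s) for m in cfg.materials for s in cfg.surfaces]
    groups += [(CONTROL_MATERIAL, "none")]
    # one control block per dispersant
    disps = list(dict.fromkeys(_dispersant(m) for m in cfg.materials))
    expanded = []
    for m, s in groups:
        if m == CONTROL_MATERIAL:
            for d in disps:
                expanded.append((m, s, d))
        else:
            expanded.append((m, s, _dispersant(m)))
    for m, s, d in expanded:
        g = group_name(m, s, d)
        for rep in range(1, cfg.reps_per_group + 1):
            rows.append(
                {
                    "sample_id": f"{g}_r{rep}",
                    "material": m,
                    "surface": s,
                    "dispersant": d,
                    "batch_label": f"L{i % 2 + 1}",
                    "batch_array": f"A{(i // 2) % 2 + 1}",
                    "replicate": rep,
                    "group": g,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def _build_annotation(cfg: SimulationConfig) -> pd.DataFrame:
    probes, accs, biotypes = [], [], []
    for i in range(cfg.n_lnc):
        probes.append(f"lnc_{i:05d}")
        accs.append(f"NR_{100000 + i}")
        biotypes.append("lncRNA")
    for i in range(cfg.n_mrna):
        probes.append(f"mrna_{i:05d}")
        accs.append(f"NM_{100000 + i}")
        biotypes.append("mRNA")
    for i in range(cfg.n_negctrl):
        probes.append(f"neg_{i:04d}")
        accs.append(f"CTRL_{i:04d}")
        biotypes.append("negative_control")
    return pd.DataFrame(
        {"probe_id": probes, "accession": accs, "biotype": biotypes}
    ).set_index("probe_id")


def _plant_effects(
    cfg: SimulationConfig, annotation: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Build the probes x exposed-groups effect matrix and its ground truth."""
    groups = cfg.exposed_groups
    lnc_ids = [p for p, b in annotation["biotype"].items() if b == "lncRNA"]
    mrna_ids = [p for p, b in annotation["biotype"].items() if b == "mRNA"]
    effects = pd.DataFrame(
        0.0, index=list(annotation.index), columns=groups
    )

    module_assignment: dict[str, int] = {}
    true_edges: set[tuple[str, str]] = set()

    mod_lnc = rng.choice(lnc_ids, size=cfg.n_modules * cfg.module_size[0], replace=False)
    mod_mrna = rng.choice(mrna_ids, size=cfg.n_modules * cfg.module_size[1], replace=False)
    for m in range(cfg.n_modules):
        lmembers = mod_lnc[m * cfg.module_size[0] : (m + 1) * cfg.module_size[0]]
        gmembers = mod_mrna[m * cfg.module_size[1] : (m + 1) * cfg.module_size[1]]
        if cfg.module_activity is not None:
            activity = np.array(
                [cfg.module_activity[m].get(g, 0.0) for g in groups]
            ) * cfg.effect_size_log2
        else:
            active = rng.random(len(groups)) < cfg.module_active_prob
            if not active.any():  # a silent module is untestable
                active[rng.integers(len(groups))] = True
            activity = np.where(active, cfg.effect_size_log2, 0.0)
        # lncRNA members drive the module: +1 proportionality (panel
        # lncRNAs are upregulated relative to controls); mRNA members
        # follow with +/-1 signs, producing opposing correlation blocks.
        signs_m = np.where(
            rng.random(len(gmembers)) < cfg.mrna_negative_frac, -1.0, 1.0
        )
        for p in lmembers:
            effects.loc[p, :] = activity
            module_assignment[p] = m
        for p, c in zip(gmembers, signs_m):
            effects.loc[p, :] = c * activity
            module_assignment[p] = m
        for lp in lmembers:
            for gp in gmembers:
                true_edges.add((lp, gp))

    free_lnc = [p for p in lnc_ids if p not in module_assignment]
    free_mrna = [p for p in mrna_ids if p not in module_assignment]
    scale = cfg.group_effect_scale or {}
    for g in groups:
        s = scale.get(g, 1.0)
        for pool in (free_lnc, free_mrna):
            n_de = int(round(cfg.frac_de * len(pool)))
            if n_de == 0:
                continue
            chosen = rng.choice(pool, size=n_de, replace=False)
            signs = np.where(rng.random(n_de) < 0.5, -1.0, 1.0)
            effects.loc[chosen, g] += signs * cfg.effect_size_log2 * s

    de_probes = {
        g: {
            p: float(fc)
            for p, fc in effects[g].items()
            if fc != 0.0
        }
        for g in groups
    }
    truth = GroundTruth(
        de_probes=de_probes,
        true_edges=true_edges,
        module_assignment=module_assignment,
    )
    return effects, truth


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one raw-scale experiment plus design, annotation and truth.

    Identical config (including seed) always yields identical output.
    """
    cfg.validate()
    rngs = _streams(cfg.seed)
    design = _build_design(cfg)
    annotation = _build_annotation(cfg)
    effects, truth = _plant_effects(cfg, annotation, rngs["probe-effects"])

    probes = list(annotation.index)
    n_probes, n_samples = len(probes), len(design)
    biotype = annotation["biotype"].to_numpy()
    is_neg = biotype == "negative_control"

    baseline = rngs["probe-effects"].normal(cfg.baseline_mean, cfg.baseline_sd, n_probes)
    baseline[biotype == "lncRNA"] += cfg.lnc_mean_offset

    # per-probe, mean-zero-across-levels batch shifts on two variables
    gamma_label = rngs["batch"].normal(0.0, cfg.batch_sd, n_probes)
    gamma_array = rngs["batch"].normal(0.0, cfg.batch_sd, n_probes)
    label_sign = np.where(design["batch_label"].to_numpy() == "L1", 1.0, -1.0)
    array_sign = np.where(design["batch_array"].to_numpy() == "A1", 1.0, -1.0)

    group_of_sample = design["group"].to_numpy()
    eff = np.zeros((n_probes, n_samples))
    for j, g in enumerate(group_of_sample):
        if g in effects.columns:
            eff[:, j] = effects[g].to_numpy()

    log2sig = (
        baseline[:, None]
        + eff
        + np.outer(gamma_label, label_sign)
        + np.outer(gamma_array, array_sign)
        + rngs["noise"].normal(0.0, cfg.noise_sd, (n_probes, n_samples))
    )
    # negative controls: background distribution only
    log2sig[is_neg, :] = rngs["background"].normal(
        cfg.background_mean, cfg.background_sd, (int(is_neg.sum()), n_samples)
    )

    values = pd.DataFrame(
        np.power(2.0, log2sig),
        index=pd.Index(probes, name="probe_id"),
        columns=list(design["sample_id"]),
    )
    m = ExpressionMatrix(values=values, annotation=annotation, scale="raw")
    return m, design, annotation, truth


def simulate_null(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Same generative model with every group effect forced to zero."""
    null_cfg = replace(cfg, frac_de=0.0, n_modules=0, module_activity=None)
    m, design, annotation, truth = simulate_experiment(null_cfg)
    return m, design, annotation, truth


def simulate_gene_sets(
    annotation: pd.DataFrame,
    truth: GroundTruth,
    seed: int,
    n_random: int = 30,
    random_size: tuple[int, int] = (10, 60),
) -> list[GeneSet]:
    """Gene-set collection over the mRNA accession universe.

    One set per planted module (its mRNA members' accessions) plus
    ``n_random`` uniformly drawn decoy sets, so enrichment of recovered
    network clusters has a known answer.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    acc = annotation["accession"]
    mrna_acc = acc[annotation["biotype"] == "mRNA"]
    sets: list[GeneSet] = []
    modules: dict[int, list[str]] = {}
    for p, mid in truth.module_assignment.items():
        if annotation.loc[p, "biotype"] == "mRNA":
            modules.setdefault(mid, []).append(acc.loc[p])
    for mid in sorted(modules):
        sets.append(
            GeneSet(
                set_id=f"MODULE_{mid}",
                set_name=f"planted co-regulated module {mid}",
                members=tuple(sorted(modules[mid])),
            )
        )
    universe = list(mrna_acc)
    for i in range(n_random):
        size = int(rng.integers(random_size[0], random_size[1] + 1))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        sets.append(
            GeneSet(
                set_id=f"RANDOM_{i:03d}",
                set_name=f"random decoy set {i}",
                members=tuple(members),
            )
        )
    return sets


# --- ground-truth serialization (TSV) ---------------------------------


def write_truth(truth: GroundTruth, directory) -> None:
    directory = Path(directory)
    rows = [
        {"group": g, "probe_id": p, "true_log2fc": fc}
        for g, d in truth.de_probes.items()
        for p, fc in d.items()
    ]
    pd.DataFrame(rows, columns=["group", "probe_id", "true_log2fc"]).to_csv(
        directory / "truth_de.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(truth.true_edges), columns=["lnc_id", "mrna_id"]
    ).to_csv(directory / "truth_edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.module_assignment.items()), columns=["probe_id", "module_id"]
    ).to_csv(directory / "truth_modules.tsv", sep="\t", index=False)


def read_truth(directory) -> GroundTruth:
    directory = Path(directory)
    de = pd.read_csv(directory / "truth_de.tsv", sep="\t")
    edges = pd.read_csv(directory / "truth_edges.tsv", sep="\t")
    modules = pd.read_csv(directory / "truth_modules.tsv", sep="\t")
    de_probes: dict[str, dict[str, float]] = {}
    for row in de.itertuples(index=False):
        de_probes.setdefault(row.group, {})[row.probe_id] = float(row.true_log2fc)
    return GroundTruth(
        de_probes=de_probes,
        true_edges=set(map(tuple, edges.to_numpy())),
        module_assignment=dict(
            zip(modules["probe_id"], modules["module_id"].astype(int))
        ),
    )
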