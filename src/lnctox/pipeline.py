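"""End-to-end orchestration: simulate -> preprocess -> DE -> network ->
enrichment -> ranking, with every stage output written as TSV/JSON into
one output directory and a checksum manifest for determinism checks.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import conet, data_io, diffexpr, enrich, preprocess, simulate, toxicity
from .core import LnctoxError

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "lnctox_out",
    "paths": {
        "expression": None,
        "annotation": None,
        "design": None,
        "gmt": None,
    },
    "simulate": {},  # overrides for SimulationConfig fields
    "background": {"method": "mean_sd", "k": 2.0, "q": 0.95},
    "batch": {"batch_vars": ["batch_label", "batch_array"], "preserve": "group"},
    "de": {"min_abs_log2fc": 0.58, "max_q": 0.05, "prior_df": None},
    "network": {
        "min_abs_r": 0.8,
        "max_p": 0.05,
        "min_degree": 15,
        "k_lnc": 5,
        "k_mrna": 2,
        "n_top": 2,
        "kmeans_k": None,
        "profile_mode": "contrast_log2fc",  # or "sample_log2"
    },
    "enrich": {"max_q": 0.05},
    "rank": {"min_degree": 15, "k": 3, "target_cluster": None},
}


def make_config(overrides: dict | None = None) -> dict:
    """Deep-merge user overrides onto the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for key, val in src.items():
            if isinstance(val, dict) and isinstance(dst.get(key), dict):
                merge(dst[key], val)
            else:
                dst[key] = val

    if overrides:
        merge(cfg, overrides)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(config: dict, outdir: Path) -> dict[str, Path]:
    """Generate a synthetic experiment and write every input file."""
    outdir.mkdir(parents=True, exist_ok=True)
    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs.setdefault("seed", config["seed"])
    if "module_size" in sim_kwargs:
        sim_kwargs["module_size"] = tuple(sim_kwargs["module_size"])
    cfg = simulate.SimulationConfig(**sim_kwargs)
    m, design, annotation, truth = simulate.simulate_experiment(cfg)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "design": outdir / "design.tsv",
        "gmt": outdir / "genesets.gmt",
    }
    data_io.write_expression(m, paths["expression"])
    data_io.write_annotation(annotation, paths["annotation"])
    data_io.write_design(design, paths["design"])
    sets = simulate.simulate_gene_sets(annotation, truth, seed=cfg.seed)
    data_io.write_gmt(sets, paths["gmt"])
    simulate.write_truth(truth, outdir)
    return paths


def run_pipeline(config: dict) -> dict:
    """Run every stage on the configured inputs; return the manifest.

    Degenerate results (e.g. an empty network under an extreme degree
    cutoff) produce empty downstream artifacts and warnings, not errors;
    the manifest records checksums of every written file so identical
    config + seed yields identical manifests.
    """
    config = make_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    paths = config["paths"]
    for key in ("expression", "annotation", "design"):
        if not paths.get(key):
            raise LnctoxError(f"config paths.{key} is required")
    m_raw, design = data_io.load_experiment(
        paths["expression"], paths["annotation"], paths["design"]
    )

    bg = config["background"]
    rule = preprocess.BackgroundRule(method=bg["method"], k=bg["k"], q=bg["q"])
    try:
        m = preprocess.preprocess_chain(
            m_raw,
            design,
            rule=rule,
            batch_vars=tuple(config["batch"]["batch_vars"]),
            preserve=config["batch"]["preserve"],
        )
    except LnctoxError as err:
        raise LnctoxError(f"stage preprocess failed: {err}") from err
    data_io.write_expression(m, outdir / "preprocessed.tsv")

    de_cfg = config["de"]
    gates = diffexpr.DEGates(
        min_abs_log2fc=de_cfg["min_abs_log2fc"], max_q=de_cfg["max_q"]
    )
    try:
        contrasts = diffexpr.run_contrasts(m, design, prior_df=de_cfg["prior_df"])
    except LnctoxError as err:
        raise LnctoxError(f"stage de failed: {err}") from err
    de_dir = outdir / "de"
    de_dir.mkdir(exist_ok=True)
    gated: dict[str, tuple[set, set]] = {}
    all_de_lnc: set = set()
    all_de_mrna: set = set()
    for g, res in contrasts.items():
        lnc, mrna = diffexpr.gate_de(res, gates)
        gated[g] = (lnc, mrna)
        all_de_lnc |= lnc
        all_de_mrna |= mrna
        out = res.copy()
        out["passes_gate"] = out.index.isin(lnc | mrna)
        out.to_csv(de_dir / f"{g}.tsv", sep="\t", float_format="%.8g")
    diffexpr.de_count_table(gated).to_csv(outdir / "de_counts.tsv", sep="\t")

    net_cfg = config["network"]
    th = conet.NetThresholds(
        min_abs_r=net_cfg["min_abs_r"],
        max_p=net_cfg["max_p"],
        min_degree=net_cfg["min_degree"],
    )
    if net_cfg["profile_mode"] == "sample_log2":
        lnc_prof = m.values.loc[sorted(all_de_lnc & set(m.values.index))]
        mrna_prof = m.values.loc[sorted(all_de_mrna & set(m.values.index))]
    else:
        lnc_prof, mrna_prof = conet.correlation_profiles(
            contrasts, all_de_lnc, all_de_mrna
        )
    edges = conet.pearson_edges(lnc_prof, mrna_prof, th)
    kept_lnc, kept_mrna, edges = conet.degree_filter(edges, th)
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False, float_format="%.8g")

    cluster_rows = []
    enrich_results: dict[int, pd.DataFrame] = {}
    ranking = None
    if kept_lnc and kept_mrna:
        lnc_cl, mrna_cl = conet.bicluster_network(
            edges,
            kept_lnc,
            kept_mrna,
            k_lnc=min(net_cfg["k_lnc"], len(kept_lnc)),
            k_mrna=min(net_cfg["k_mrna"], len(kept_mrna)),
            kmeans_k=net_cfg["kmeans_k"],
        )
        for cl in (lnc_cl, mrna_cl):
            for item, cid in cl.labels.items():
                cluster_rows.append({"item_id": item, "axis": cl.axis, "cluster_id": int(cid)})

        if paths.get("gmt"):
            sets = data_io.read_gmt(paths["gmt"])
            acc = m.accession
            universe = set(acc[m.biotype == "mRNA"])
            enrich_results = enrich.enrich_clusters(
                mrna_cl, sets, universe, accession_of=acc, max_q=config["enrich"]["max_q"]
            )
            enr_dir = outdir / "enrichment"
            enr_dir.mkdir(exist_ok=True)
            for cid, res in enrich_results.items():
                res.to_csv(
                    enr_dir / f"mrna_cluster_{cid}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.8g",
                )

        rank_cfg = config["rank"]
        target_cid = rank_cfg["target_cluster"] or 1  # 1 = largest mRNA cluster
        target = set(mrna_cl.members(int(target_cid)))
        ranking = toxicity.rank_exposures(
            m,
            design,
            edges,
            target,
            gated,
            min_degree=rank_cfg["min_degree"],
            k=rank_cfg["k"],
        )
        panel = ranking.panel
        if panel:
            z = toxicity.zscore_group_matrix(m, design, panel)
            z.to_csv(outdir / "zscore_matrix.tsv", sep="\t", float_format="%.8g")
        ranking_table = ranking.table()
        meta = design.drop_duplicates("group").set_index("group")[["material", "surface"]]
        ranking_table.join(meta).to_csv(outdir / "ranking.tsv", sep="\t")
    else:
        log.warning("empty network after degree filter; downstream stages skipped")
        pd.DataFrame(columns=["item_id", "axis", "cluster_id"]).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            columns=["group", "n_de_lnc_in_panel", "tier", "material", "surface"]
        ).to_csv(outdir / "ranking.tsv", sep="\t", index=False)

    if cluster_rows:
        pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    artifacts = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
        "seed": config["seed"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
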