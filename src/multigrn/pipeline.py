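"""Pipeline driver: configuration, stage orchestration, run manifest.

Stages run in a fixed order — simulate → qc → activity → features →
links → grn → subgrn → keytfs — each consuming in-memory state from its
predecessors and writing tab-separated outputs (floats at 6 significant
digits) into the output directory, so a repeated run with the same seed
produces byte-identical text artifacts.
"""
from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as ft
from . import grn as grnmod
from . import io as mio
from . import links as lk
from . import motifs as mt
from . import qc as qcmod
from .synthetic import (ConfigurationError, SimConfig, simulate_cells,
                        simulate_grn, write_fixture)

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "qc", "activity", "features", "links", "grn",
               "subgrn", "keytfs"]


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, defaulting to the study's values."""

    sim: SimConfig = field(default_factory=SimConfig)
    qc_thresholds: qcmod.QCThresholds = field(
        default_factory=qcmod.QCThresholds)
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER})
    seed: int = 0
    out_dir: str = "multigrn_out"
    write_matrices: bool = False

    # motif activity
    p_cutoff: float = 5e-5
    n_background: int = 50
    # feature calls
    deg_log2fc_min: float = 0.25
    adj_p_max: float = 0.05
    dar_log2fc_min: float = 0.25
    dar_p_max: float = 0.05
    atac_ceiling: int = 4
    mg_groups: tuple[str, ...] = ("restMG", "actMG", "MGPC")
    # links
    promoter_bp: int = 500
    distal_bp: int = 200_000
    n_aggregates: int = 100
    cells_per_aggregate: int = 100
    n_pcs: int = 30
    r_min: float = 0.25
    fdr_max: float = 0.01
    footprint_min: float = 0.1
    expressed_min_fraction: float = 0.05
    # grn
    importance_quantile: float = 0.95
    edge_r_pos: float = 0.03
    edge_r_neg: float = -0.03
    # trajectories / key TFs
    n_bins: int = 30
    smooth_window: int = 3
    kmeans_k: int = 4
    kmeans_n_init: int = 10
    key_p_max: float = 0.001
    key_coverage_min: float = 0.01

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        for s in STAGE_ORDER:
            self.stages.setdefault(s, True)

    def validate_dependencies(self) -> None:
        enabled = [s for s in STAGE_ORDER if self.stages[s]]
        for s in enabled:
            needed = STAGE_ORDER[:STAGE_ORDER.index(s)]
            missing = [d for d in needed if not self.stages[d]]
            if missing:
                raise ConfigurationError(
                    f"stage {s!r} requires disabled stage(s) {missing}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        sim = SimConfig(**_checked(d.pop("sim", {}), SimConfig))
        qc_th = qcmod.QCThresholds(
            **_checked(d.pop("qc_thresholds", {}), qcmod.QCThresholds))
        own = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - own
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        if "conditions" in d.get("sim", {}):
            d["sim"]["conditions"] = tuple(d["sim"]["conditions"])
        return cls(sim=sim, qc_thresholds=qc_th, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["conditions"] = list(d["sim"]["conditions"])
        d["sim"]["cell_groups"] = list(d["sim"]["cell_groups"])
        d["mg_groups"] = list(self.mg_groups)
        return d


def _checked(d: dict, cls) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ConfigurationError(
            f"unknown {cls.__name__} keys {sorted(unknown)}")
    for key in ("conditions", "cell_groups"):
        if key in d:
            d[key] = tuple(d[key])
    return d


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: dict, seconds: float,
               info: dict | None = None) -> None:
        self.stages[stage] = {
            "outputs": outputs, "seconds": round(seconds, 3),
            "info": info or {}}

    @property
    def completed_stages(self) -> list[str]:
        return list(self.stages)


def _hash_outputs(paths: dict[str, Path]) -> dict:
    return {name: {"path": str(Path(p).name), "sha256": mio.sha256_file(p)}
            for name, p in paths.items()}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order; halt on the first failure."""
    return run_pipeline_with_state(config)[0]


def run_pipeline_with_state(config: PipelineConfig):
    """Like :func:`run_pipeline` but also returns the in-memory stage
    state (datasets, call sets, networks) for downstream evaluation."""
    config.validate_dependencies()
    outdir = mio.ensure_dir(config.out_dir)
    manifest = RunManifest(seed=config.seed, config=config.to_dict())
    state: dict = {"config": config}

    runners = {
        "simulate": _stage_simulate, "qc": _stage_qc,
        "activity": _stage_activity, "features": _stage_features,
        "links": _stage_links, "grn": _stage_grn,
        "subgrn": _stage_subgrn, "keytfs": _stage_keytfs,
    }
    for stage in STAGE_ORDER:
        if not config.stages[stage]:
            log.info("stage %s disabled; skipped", stage)
            continue
        t0 = time.time()
        try:
            outputs, info = runners[stage](state, config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, _hash_outputs(outputs), time.time() - t0, info)
        log.info("stage %-9s done in %.1fs", stage, time.time() - t0)

    mio.write_json({"seed": manifest.seed, "stages": manifest.stages,
                    "config": manifest.config}, outdir / "manifest.json")
    return manifest, state


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(state, config: PipelineConfig, outdir: Path):
    grn = simulate_grn(config.sim)
    ds = simulate_cells(grn, config.sim)
    state["grn_truth"], state["dataset_raw"] = grn, ds
    outputs = {}
    if config.write_matrices:
        fx = write_fixture(ds, grn, outdir / "fixture")
        outputs = {f"fixture_{k}": outdir / "fixture" / v["path"]
                   for k, v in fx["files"].items()}
    else:
        mio.write_table(ds.cells, outdir / "cells.tsv")
        bed = ds.peaks.rename(columns={"peak_id": "name"})
        mio.write_bed(bed[["chrom", "start", "end", "name"]],
                      outdir / "peaks.bed")
        mio.write_gene_models(ds.genes, outdir / "genes.tsv")
        motif_tf = {m: tf for tf, m in grn.motif_of_tf.items()}
        mio.write_pwms_jaspar(grn.pwms, motif_tf, outdir / "pwms.jaspar")
        outputs = {"cells": outdir / "cells.tsv",
                   "peaks": outdir / "peaks.bed",
                   "genes": outdir / "genes.tsv",
                   "pwms": outdir / "pwms.jaspar"}
    return outputs, {"n_cells": ds.n_cells, "n_triples": len(grn.triples)}


def _stage_qc(state, config: PipelineConfig, outdir: Path):
    ds = state["dataset_raw"]
    filtered, report = qcmod.apply_qc(ds, config.qc_thresholds)
    state["dataset"] = filtered
    # ArchR-style ceiling on the peak matrix for downstream comparisons;
    # the deviation stage keeps the raw counts
    capped = filtered.atac.copy()
    capped.data = np.minimum(capped.data, config.atac_ceiling)
    state["atac_capped"] = capped
    mio.write_table(report.per_cell, outdir / "qc_report.tsv")
    return ({"qc_report": outdir / "qc_report.tsv"}, report.summary)


def _stage_activity(state, config: PipelineConfig, outdir: Path):
    ds = state["dataset"]
    truth = state["grn_truth"]
    motif_tf = {m: tf for tf, m in truth.motif_of_tf.items()}
    motif_set = mt.MotifSet.from_pwms(truth.pwms, motif_tf)
    matches = mt.match_motifs(motif_set, ds.peak_sequences, config.p_cutoff)
    bias = mt.compute_expected_and_bias(ds.atac, ds.peak_sequences,
                                        ds.peak_ids)
    activity = mt.compute_deviations(
        ds.atac, matches, bias, n_background=config.n_background,
        seed=config.seed, motif_tf=motif_set.motif_tf,
        cell_ids=ds.cells["cell_id"])
    state["matches"], state["bias"], state["activity"] = matches, bias, activity
    state["motif_set"] = motif_set

    # step 1: activator/repressor classification lives with the activity
    # matrix — TF expression vs motif z over all filtered cells
    norm = ft.normalize_log1p_cpm(ds.rna)
    state["norm_rna"] = norm
    tf_ids = [tf for tf, _ in truth.tfs]
    gidx = {g: i for i, g in enumerate(ds.gene_ids)}
    tf_expr = pd.DataFrame({t: norm[:, gidx[t]] for t in tf_ids})
    roles = lk.classify_tf_motifs(tf_expr, activity.z.reset_index(drop=True),
                                  activity.motif_tf)
    state["roles"] = roles
    state["tf_motif_corr"] = {r.motif_id: r.pearson_r for r in roles}

    mio.write_table(matches.records, outdir / "motif_matches.tsv")
    zout = activity.z.copy()
    zout.insert(0, "cell_id", list(ds.cells["cell_id"]))
    mio.write_table(zout, outdir / "motif_activity.tsv")
    roles_df = pd.DataFrame([r.__dict__ for r in roles])
    mio.write_table(roles_df, outdir / "tf_motif_roles.tsv")
    return ({"matches": outdir / "motif_matches.tsv",
             "activity": outdir / "motif_activity.tsv",
             "roles": outdir / "tf_motif_roles.tsv"},
            {"n_matches": len(matches.records), "n_roles": len(roles)})


def _split(state):
    ds = state["dataset"]
    config: PipelineConfig = state["config"]
    conds = config.sim.conditions
    mask_a = (ds.cells["condition"] == conds[0]).to_numpy()
    mask_b = (ds.cells["condition"] == conds[1]).to_numpy()
    return ds, conds, mask_a, mask_b


def _stage_features(state, config: PipelineConfig, outdir: Path):
    ds, conds, mask_a, mask_b = _split(state)
    norm = state["norm_rna"]
    groups = ds.cells["cell_group"]
    ga, gb = groups[mask_a], groups[mask_b]
    contrast = f"{conds[0]}-vs-{conds[1]}"

    degs = ft.find_degs(norm[mask_a], norm[mask_b], ga, gb, ds.gene_ids,
                        cell_groups=config.mg_groups,
                        log2fc_min=config.deg_log2fc_min,
                        adj_p_max=config.adj_p_max, contrast=contrast)
    cegs = ft.find_cegs(norm[mask_a], norm[mask_b], ga, gb, ds.gene_ids,
                        trajectory_groups=config.sim.cell_groups)

    # per-group peak statistics; DAR/CAR calls finalized after linking
    norm_atac = ft.normalize_log1p_cpm(state["atac_capped"])
    state["norm_atac"] = norm_atac
    peak_stats = []
    for g in config.mg_groups:
        tab = ft._group_test(norm_atac[mask_a][ga.to_numpy() == g],
                             norm_atac[mask_b][gb.to_numpy() == g],
                             ds.peak_ids, g)
        peak_stats.append(tab)
    peak_stats = pd.concat(peak_stats, ignore_index=True)
    state["peak_stats"] = peak_stats

    act = state["activity"]
    z = act.z.reset_index(drop=True)
    za, zb = z[mask_a], z[mask_b]
    dms = ft.find_dms(za, zb, ga, gb, degs, act.motif_tf,
                      state["tf_motif_corr"], cell_groups=config.mg_groups)
    cms = ft.find_cms(za, zb, ga, gb, cegs, act.motif_tf,
                      state["tf_motif_corr"],
                      trajectory_groups=config.sim.cell_groups)
    state.update(degs=degs, cegs=cegs, dms=dms, cms=cms)

    outputs = {}
    for name, call in (("degs", degs), ("cegs", cegs), ("dms", dms),
                       ("cms", cms)):
        mio.write_table(call.table, outdir / f"{name}.tsv")
        outputs[name] = outdir / f"{name}.tsv"
    mio.write_table(peak_stats, outdir / "peak_stats.tsv")
    outputs["peak_stats"] = outdir / "peak_stats.tsv"
    return outputs, {
        "n_degs": len(degs.all_features()), "n_cegs": len(cegs.all_features()),
        "n_dms": len(dms.all_features()), "n_cms": len(cms.all_features())}


def _stage_links(state, config: PipelineConfig, outdir: Path):
    ds, conds, mask_a, mask_b = _split(state)
    cats, candidates = lk.categorize_peaks(
        ds.peaks, ds.genes, promoter_window=config.promoter_bp,
        distal_window=config.distal_bp)
    agg_rna, agg_atac, _ = lk.aggregate_cells(
        ds, n_aggregates=config.n_aggregates,
        cells_per_aggregate=config.cells_per_aggregate,
        n_pcs=config.n_pcs, seed=config.seed,
        atac_counts=state["atac_capped"])
    links = lk.peak_to_gene(agg_rna, agg_atac, candidates,
                            r_min=config.r_min, fdr_max=config.fdr_max)
    state["links"] = links

    expressed = lk.expressed_tf_ids(ds, groups=config.mg_groups,
                                    min_fraction=config.expressed_min_fraction)
    motif_widths = {m.motif_id: m.width for m in state["motif_set"].motifs}
    sites = lk.footprint_sites(
        state["matches"], set(ds.peak_ids), ds.insertion_signal,
        expressed, state["activity"].motif_tf, motif_widths,
        score_min=config.footprint_min)
    state["sites"] = sites

    # DAR/CAR calls need the links, so they are finalized here
    groups = ds.cells["cell_group"]
    live = links[links["retained"]]
    dars = ft.find_dars(
        state["norm_atac"][mask_a], state["norm_atac"][mask_b],
        groups[mask_a], groups[mask_b], ds.peak_ids,
        deg_genes=state["degs"].all_features(), peak_links=live,
        cell_groups=config.mg_groups, log2fc_min=config.dar_log2fc_min,
        p_max=config.dar_p_max,
        contrast=f"{conds[0]}-vs-{conds[1]}")
    cars = ft.find_cars(
        state["norm_atac"][mask_a], state["norm_atac"][mask_b],
        groups[mask_a], groups[mask_b], ds.peak_ids,
        ceg_genes=state["cegs"].all_features(), peak_links=live,
        trajectory_groups=config.sim.cell_groups)
    state.update(dars=dars, cars=cars)

    mio.write_table(cats, outdir / "peak_categories.tsv")
    mio.write_table(links, outdir / "peak_gene_links.tsv")
    sites_df = lk.sites_to_frame(sites)
    mio.write_table(sites_df, outdir / "footprint_sites.tsv")
    mio.write_table(dars.table, outdir / "dars.tsv")
    mio.write_table(cars.table, outdir / "cars.tsv")
    return ({"categories": outdir / "peak_categories.tsv",
             "links": outdir / "peak_gene_links.tsv",
             "sites": outdir / "footprint_sites.tsv",
             "dars": outdir / "dars.tsv", "cars": outdir / "cars.tsv"},
            {"n_links": int(links["retained"].sum()),
             "n_sites": len(sites),
             "n_dars": len(dars.all_features()),
             "n_cars": len(cars.all_features())})


def _stage_grn(state, config: PipelineConfig, outdir: Path):
    ds = state["dataset"]
    truth = state["grn_truth"]
    norm = state["norm_rna"]
    tf_ids = [tf for tf, _ in truth.tfs]
    expr = pd.DataFrame(norm, columns=ds.gene_ids)
    target_ids = [g for g in ds.gene_ids
                  if not g.startswith("mt-")]
    edges = grnmod.tf_target_importance(
        expr, tf_ids, target_ids=target_ids,
        quantile_cut=config.importance_quantile,
        r_pos=config.edge_r_pos, r_neg=config.edge_r_neg, seed=config.seed)
    state["edges"] = edges
    mg_tfs = grnmod.mg_enriched_tfs(norm, ds.gene_ids, tf_ids,
                                    ds.cells["cell_group"],
                                    groups=config.mg_groups)
    state["mg_tfs"] = mg_tfs
    total = grnmod.assemble_triples(state["sites"], state["links"],
                                    state["roles"], edges, mg_tfs)
    state["total_grn"] = total
    mio.write_table(edges, outdir / "tf_gene_edges.tsv")
    mio.write_table(total, outdir / "grn.tsv")
    return ({"edges": outdir / "tf_gene_edges.tsv",
             "grn": outdir / "grn.tsv"},
            {"n_edges": int(edges["retained"].sum()),
             "n_triples": len(total), "n_mg_tfs": len(mg_tfs)})


def _stage_subgrn(state, config: PipelineConfig, outdir: Path):
    conds = config.sim.conditions
    subs = {}
    outputs = {}
    for cond in conds:
        sub = grnmod.extract_enriched_subgrn(
            state["total_grn"], state["degs"], state["peak_stats"], cond,
            conditions=conds, groups=config.mg_groups)
        subs[cond] = sub
        path = outdir / f"subgrn_{cond}.tsv"
        mio.write_table(sub.triples, path)
        outputs[f"subgrn_{cond}"] = path
    state["subgrns"] = subs
    return outputs, {f"n_{c}": len(s.triples) for c, s in subs.items()}


def _stage_keytfs(state, config: PipelineConfig, outdir: Path):
    ds, conds, mask_a, mask_b = _split(state)
    degs: ft.FeatureCallSet = state["degs"]
    deg_genes = sorted(degs.all_features())
    results_all = []
    clusters: dict[str, set[str]] = {}
    if deg_genes:
        # k-means on DEG pseudotime profiles, both conditions concatenated
        gidx = {g: i for i, g in enumerate(ds.gene_ids)}
        cols = [gidx[g] for g in deg_genes]
        mg_mask = ds.cells["cell_group"].isin(config.mg_groups).to_numpy()
        profs = []
        for mask in (mask_a, mask_b):
            m = mask & mg_mask
            mat = pd.DataFrame(state["norm_rna"][m][:, cols],
                               columns=deg_genes)
            binned = ft.bin_pseudotime(
                ds.cells.loc[m, "pseudotime"], {"expr": mat},
                n_bins=config.n_bins, smooth_window=config.smooth_window)
            profs.append(binned.matrices["expr"])
        profiles = pd.concat(profs, axis=1)
        k = min(config.kmeans_k, len(deg_genes))
        labels = ft.cluster_profiles_kmeans(profiles, k, seed=config.seed,
                                            n_init=config.kmeans_n_init)
        clusters = {f"c{c}": set(labels.index[labels == c])
                    for c in sorted(labels.unique())}
        state["deg_clusters"] = clusters
        for cond in conds:
            res = grnmod.key_activators(
                state["subgrns"][cond], state["total_grn"], clusters,
                p_max=config.key_p_max,
                coverage_min=config.key_coverage_min)
            df = grnmod.key_results_frame(res)
            if len(df):
                df.insert(0, "condition", cond)
            results_all.append(df)
    out = pd.concat(results_all, ignore_index=True) if results_all \
        else pd.DataFrame()
    state["key_results"] = out
    mio.write_table(out, outdir / "key_tfs.tsv")
    cl = pd.DataFrame(sorted(
        (cid, g) for cid, gs in clusters.items() for g in gs),
        columns=["cluster", "gene_id"])
    mio.write_table(cl, outdir / "deg_clusters.tsv")
    n_key = int(out["is_key"].sum()) if len(out) else 0
    return ({"key_tfs": outdir / "key_tfs.tsv",
             "clusters": outdir / "deg_clusters.tsv"},
            {"n_key": n_key, "n_clusters": len(clusters)})
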