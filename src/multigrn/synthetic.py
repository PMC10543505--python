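"""Seeded synthetic paired RNA+ATAC single-cell data with a planted GRN.

The generator emulates the statistical structure the downstream stages
rely on, so that every stage has a recoverable ground truth:

* two injury-like conditions (default "LD", "NMDA");
* an ordered lineage (resting MG → activated MG → MGPC → neuron
  precursors) laid out along a pseudotime in [0, 1];
* per-TF latent activity = a narrow Gaussian bump in pseudotime plus a
  per-cell idiosyncratic term that is shared between the TF's own
  expression and everything it regulates (this is what makes regulator
  attribution identifiable when many TFs peak at similar times);
* negative-binomial RNA counts whose means are multiplied up (activators)
  or down (repressors) by the latent activity of the planted regulators;
* Poisson peak counts driven the same way for the planted regulatory
  peaks, flat for decoy peaks;
* motif placements (the motif's consensus word written into the peak
  sequence) for every planted site, and center-depleted, footprint-shaped
  insertion signal at bound sites versus flat noise at unbound sites;
* a small planted fraction of QC-failing cells so filtering is testable.

Condition-specific regulation is planted per triple but grouped by TF, and
two "master" activator TFs carry many targets of which half are
condition-specific — these are the planted key regulators the
hypergeometric key-TF test must rediscover.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as mio
from .datatypes import (GENE_COLUMNS, GroundTruthGRN, MotifSite,
                        MultiomeDataset, Triple)

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic multiome.

    Defaults are the scale at which planted structure is recoverable by
    the pipeline: 30 TFs × 300 candidate targets × 1500 fixed-width peaks,
    150 planted TF→peak→target triples, 2000 cells per condition.
    """

    n_tfs: int = 30
    n_targets: int = 300
    n_peaks: int = 1500
    n_cells_per_condition: int = 2000
    conditions: tuple[str, ...] = ("LD", "NMDA")
    cell_groups: tuple[str, ...] = ("restMG", "actMG", "MGPC",
                                    "precursor1", "precursor2")
    activator_fraction: float = 0.7
    effect_size: float = 1.5          # multiplier exponent on regulated means
    tf_expr_beta: float = 3.0         # amplitude of a TF's own expression
    footprint_depth: float = 1.0      # signal units removed at bound centers
    nb_dispersion: float = 0.3        # NB var = mu + disp * mu^2
    peak_rate: float = 2.0            # mean counts per peak per cell
    fraction_condition_specific: float = 0.3
    seed: int = 0

    # planted-network shape
    n_triples: int = 150
    n_master_tfs: int = 2             # planted key activators
    master_targets: int = 20          # targets per master TF
    decoy_sites_per_tf: int = 5       # unbound motif placements per TF
    motif_width: int = 8

    # genome / signal scale
    chrom: str = "chrS1"
    chrom_length: int = 35_000_000
    peak_width: int = 501
    signal_noise_sd: float = 0.05     # per-base insertion-signal noise

    # nuisance structure
    n_mito_genes: int = 5
    plant_qc_failures: bool = True
    qc_failure_rate: float = 0.02

    def validate(self) -> None:
        counts = {
            "n_tfs": self.n_tfs, "n_targets": self.n_targets,
            "n_peaks": self.n_peaks,
            "n_cells_per_condition": self.n_cells_per_condition,
            "n_triples": self.n_triples, "peak_width": self.peak_width,
            "motif_width": self.motif_width,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {v}")
        if not 0.0 <= self.activator_fraction <= 1.0:
            raise ConfigurationError("activator_fraction must be in [0, 1]")
        if not 0.0 <= self.fraction_condition_specific <= 1.0:
            raise ConfigurationError(
                "fraction_condition_specific must be in [0, 1]")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition labels must be distinct")
        if len(self.conditions) != 2:
            raise ConfigurationError("exactly two conditions are supported")
        if self.n_peaks < self.n_tfs:
            raise ConfigurationError(
                f"n_peaks ({self.n_peaks}) < n_tfs ({self.n_tfs}): cannot "
                "place one motif site per TF")
        if self.n_triples < self.n_tfs:
            raise ConfigurationError("n_triples must be >= n_tfs so every TF "
                                     "regulates at least one target")
        if self.n_triples > min(self.n_targets, self.n_peaks):
            raise ConfigurationError(
                "n_triples exceeds the available targets or peaks")
        if self.motif_width < 4:
            raise ConfigurationError("motif_width must be >= 4")


# ---------------------------------------------------------------------------
# planted network

def simulate_grn(config: SimConfig) -> GroundTruthGRN:
    """Draw the planted TF/peak/target network for ``config``.

    Deterministic for a fixed seed. Exactly
    ``floor(activator_fraction * n_tfs)`` TFs are activators; activator
    triples carry sign "+", repressor triples "-";
    ``round(fraction_condition_specific * n_triples)`` triples are
    assigned to a single condition (grouped by TF so a TF's specific
    triples share one condition).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    tf_ids = [f"TF{i:03d}" for i in range(config.n_tfs)]
    n_act = int(np.floor(config.activator_fraction * config.n_tfs))
    act_idx = np.sort(rng.choice(config.n_tfs, size=n_act, replace=False))
    roles = np.array(["repressor"] * config.n_tfs, dtype=object)
    roles[act_idx] = "activator"
    tfs = list(zip(tf_ids, roles))

    n_master = min(config.n_master_tfs, n_act)
    masters = [tf_ids[i] for i in act_idx[:n_master]]

    # triples per TF: masters get master_targets each, the rest round-robin
    n_rest = config.n_tfs - n_master
    master_quota = min(config.master_targets,
                       max(1, (config.n_triples - n_rest) // max(n_master, 1))) \
        if n_master else 0
    remaining = config.n_triples - n_master * master_quota
    per_tf = {}
    for tf in masters:
        per_tf[tf] = master_quota
    rest = [tf for tf in tf_ids if tf not in masters]
    if rest:
        base, extra = divmod(remaining, len(rest))
        for i, tf in enumerate(rest):
            per_tf[tf] = base + (1 if i < extra else 0)
    if min(per_tf.values()) < 1:
        raise ConfigurationError("n_triples too small: a TF got no target")

    target_ids = [f"T{i:04d}" for i in range(config.n_targets)]
    peak_ids = [f"P{i:05d}" for i in range(config.n_peaks)]
    target_pool = [str(x) for x in rng.permutation(target_ids)]
    peak_pool = [str(x) for x in rng.permutation(peak_ids)]

    # per-TF designated condition for its specific triples
    cond_of_tf = {}
    for i, tf in enumerate(masters):
        cond_of_tf[tf] = config.conditions[i % len(config.conditions)]
    for i, tf in enumerate(rest):
        cond_of_tf[tf] = config.conditions[i % len(config.conditions)]

    # fill the condition-specific quota: masters half-and-half first,
    # then whole non-master TFs in order
    n_specific = int(round(config.fraction_condition_specific
                           * config.n_triples))
    spec_count = {tf: 0 for tf in tf_ids}
    quota = n_specific
    for tf in masters:
        take = min(per_tf[tf] // 2, quota)
        spec_count[tf] = take
        quota -= take
    for tf in rest:
        if quota <= 0:
            break
        take = min(per_tf[tf], quota)
        spec_count[tf] = take
        quota -= take
    if quota > 0:
        log.warning("condition-specific quota not fully assignable: %d left",
                    quota)

    role_of = dict(tfs)
    triples: list[Triple] = []
    for tf in tf_ids:
        sign = "+" if role_of[tf] == "activator" else "-"
        for j in range(per_tf[tf]):
            spec = (cond_of_tf[tf] if j < spec_count[tf] else "shared")
            triples.append(Triple(tf, peak_pool.pop(), target_pool.pop(),
                                  sign, spec))

    # motifs: one per TF, a strong random consensus PWM
    motif_of_tf = {tf: f"M_{tf}" for tf in tf_ids}
    pwms = {}
    for tf in tf_ids:
        consensus = rng.integers(0, 4, size=config.motif_width)
        mat = np.full((config.motif_width, 4), 0.02)
        mat[np.arange(config.motif_width), consensus] = 0.94
        pwms[motif_of_tf[tf]] = mat

    # bound sites inside every triple peak; unbound decoys in unused peaks
    w = config.motif_width
    lo, hi = 3 * w, config.peak_width - 4 * w
    sites: list[MotifSite] = []
    for t in triples:
        offset = int(rng.integers(lo, hi))
        sites.append(MotifSite(motif_of_tf[t.tf_id], t.peak_id, offset, w,
                               bound=True))
    unused_peaks = peak_pool  # peaks never used by a triple
    for tf in tf_ids:
        n_decoy = min(config.decoy_sites_per_tf, len(unused_peaks))
        if n_decoy == 0:
            break
        chosen = rng.choice(len(unused_peaks), size=n_decoy, replace=False)
        for ci in chosen:
            offset = int(rng.integers(lo, hi))
            sites.append(MotifSite(motif_of_tf[tf], unused_peaks[ci], offset,
                                   w, bound=False))

    key_tfs = {cond: [tf for tf in masters if cond_of_tf[tf] == cond]
               for cond in config.conditions}

    grn = GroundTruthGRN(tfs=tfs, triples=triples, motif_sites=sites,
                         key_tfs_per_cluster=key_tfs,
                         motif_of_tf=motif_of_tf, pwms=pwms)
    grn.cond_of_tf = cond_of_tf            # type: ignore[attr-defined]
    grn.spec_fraction_of_tf = {            # type: ignore[attr-defined]
        tf: spec_count[tf] / per_tf[tf] for tf in tf_ids}
    return grn


# ---------------------------------------------------------------------------
# genome layout

def _interleaved_locus_order(triples: list[Triple],
                             centers: dict[str, float]) -> list:
    """Order triples so genomic neighbours carry TFs with distant bump
    centers (keeps cross-locus peak↔gene correlations low).

    Triples are sorted by their TF's pseudotime bump center, split into a
    low and a high half at a TF boundary, and alternated; ``None`` entries
    pad the shorter half and become empty loci.
    """
    order = sorted(range(len(triples)),
                   key=lambda i: (centers[triples[i].tf_id], triples[i].tf_id, i))
    n = len(order)
    # split at a TF boundary nearest the middle
    half = n // 2
    cut = half
    while 0 < cut < n and (triples[order[cut]].tf_id
                           == triples[order[cut - 1]].tf_id):
        cut += 1
    low, high = order[:cut], order[cut:]
    m = max(len(low), len(high))
    interleaved: list = []
    for i in range(m):
        interleaved.append(low[i] if i < len(low) else None)
        interleaved.append(high[i] if i < len(high) else None)
    return interleaved


def _layout_genome(grn: GroundTruthGRN, config: SimConfig,
                   centers: dict[str, float], rng: np.random.Generator):
    """Place genes and peaks on the synthetic chromosome.

    Regulated loci (one per triple: target gene + its peak) are spaced so
    at most the two flanking loci fall inside the distal linking window;
    TF and mito genes live in a peak-free tail region so they acquire no
    candidate links; decoy genes and decoy peaks fill the bands between
    loci.
    """
    n_triples = len(grn.triples)
    order = _interleaved_locus_order(grn.triples, centers)
    n_cells_layout = len(order)
    tail = max(1_200_000, config.chrom_length // 10)
    span = config.chrom_length - tail
    S = span / max(n_cells_layout, 1)

    gene_rows = []
    peak_pos: dict[str, int] = {}      # peak_id -> start
    pw = config.peak_width

    regulated_targets = {t.target_id for t in grn.triples}
    category_cycle = ["promoter", "gene_body", "intergenic", "intergenic",
                      "intergenic"]
    for k, tri_idx in enumerate(order):
        if tri_idx is None:
            continue
        t = grn.triples[tri_idx]
        c = int((k + 0.5) * S)
        tss = c
        gene_rows.append((t.target_id, config.chrom, "+", tss, tss,
                          tss + 2500, False, False))
        cat = category_cycle[tri_idx % len(category_cycle)]
        if cat == "promoter":
            start = tss - pw // 2
        elif cat == "gene_body":
            start = tss + 900
        else:
            frac = rng.uniform(0.12, 0.33)
            offset = max(3000, int(frac * S))
            side = 1 if tri_idx % 2 == 0 else -1
            start = tss + side * offset
        peak_pos[t.peak_id] = max(0, start)

    # decoy peaks + decoy genes in the outer band of each layout cell
    decoy_peaks = [p for p in (f"P{i:05d}" for i in range(config.n_peaks))
                   if p not in peak_pos]
    decoy_genes = [g for g in (f"T{i:04d}" for i in range(config.n_targets))
                   if g not in regulated_targets]
    band_lo, band_hi = 0.37, 0.985
    items: list[tuple[str, str]] = (
        [("peak", p) for p in decoy_peaks] + [("gene", g) for g in decoy_genes])
    per_band = int(np.ceil(len(items) / max(n_cells_layout, 1)))
    it = iter(items)
    done = False
    for k in range(n_cells_layout):
        base = k * S
        slots = np.linspace(band_lo, band_hi, per_band + 1)[:-1]
        for s in slots:
            try:
                kind, name = next(it)
            except StopIteration:
                done = True
                break
            pos = int(base + s * S)
            if kind == "peak":
                peak_pos[name] = pos
            else:
                gene_rows.append((name, config.chrom, "+", pos, pos,
                                  pos + 1200, False, False))
        if done:
            break

    # TF genes and mito genes in the peak-free tail
    cursor = config.chrom_length - tail + 50_000
    for tf in (tf for tf, _ in grn.tfs):
        gene_rows.append((tf, config.chrom, "+", cursor, cursor,
                          cursor + 2000, True, False))
        cursor += 8000
    for i in range(config.n_mito_genes):
        gene_rows.append((f"mt-{i + 1}", config.chrom, "+", cursor, cursor,
                          cursor + 1000, False, True))
        cursor += 6000

    genes = pd.DataFrame(gene_rows, columns=GENE_COLUMNS)

    peaks = pd.DataFrame({
        "peak_id": list(peak_pos),
        "chrom": config.chrom,
        "start": [peak_pos[p] for p in peak_pos],
    })
    peaks["end"] = peaks["start"] + pw
    peaks = peaks.sort_values(["start", "peak_id"],
                              kind="mergesort").reset_index(drop=True)
    # resolve any residual overlap (possible only in very dense configs)
    starts = peaks["start"].to_numpy().copy()
    for i in range(1, len(starts)):
        if starts[i] < starts[i - 1] + pw:
            starts[i] = starts[i - 1] + pw
    peaks["start"], peaks["end"] = starts, starts + pw
    peaks = peaks[["peak_id", "chrom", "start", "end"]]
    return genes, peaks


def _peak_sequences(grn: GroundTruthGRN, peaks: pd.DataFrame,
                    config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """I.i.d. nucleotides with per-peak GC ~ Beta(5, 5); planted motif
    sites overwrite the sequence with the motif's consensus word."""
    gc = rng.beta(5.0, 5.0, size=len(peaks))
    seqs = []
    for j in range(len(peaks)):
        p = np.array([(1 - gc[j]) / 2, gc[j] / 2, gc[j] / 2, (1 - gc[j]) / 2])
        codes = rng.choice(4, size=config.peak_width, p=p)
        seqs.append(codes)
    seq_by_peak = dict(zip(peaks["peak_id"], seqs))
    for site in grn.motif_sites:
        consensus = np.argmax(grn.pwms[site.motif_id], axis=1)
        seq_by_peak[site.peak_id][site.offset:site.offset + site.width] = \
            consensus
    return pd.Series(
        {pid: "".join(BASES[c] for c in codes)
         for pid, codes in seq_by_peak.items()},
        name="sequence",
    ).loc[peaks["peak_id"]]


# ---------------------------------------------------------------------------
# cells

def _tf_parameters(grn: GroundTruthGRN, config: SimConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Per-TF latent-activity parameters.

    Bump centers are confined to the MG span of pseudotime (restMG
    through MGPC under the default five groups) so every planted TF is
    MG-enriched; off-condition expression gates shrink with the TF's
    planted condition specificity.
    """
    tf_ids = [tf for tf, _ in grn.tfs]
    n = len(tf_ids)
    # bump centers sit at the midpoints of the MG-lineage groups (the
    # first three cell groups span pseudotime [0, 0.6] by construction),
    # so each TF's active window lies inside one group and its group-wise
    # enrichment is detectable; jitter keeps profiles distinguishable
    n_groups = max(len(config.cell_groups), 1)
    mg_mids = np.array([(i + 0.5) / n_groups for i in range(3)])
    centers = mg_mids[np.arange(n) % 3] + rng.uniform(-0.04, 0.04, n)
    centers = centers[rng.permutation(n)]
    widths = rng.uniform(0.05, 0.09, n)
    baseline = np.exp(rng.normal(np.log(5.0), 0.3, n))
    spec_frac = np.array([grn.spec_fraction_of_tf[tf] for tf in tf_ids])
    gate_off = np.where(spec_frac >= 1.0, 0.15,
                        np.where(spec_frac > 0.0, 0.3, 1.0))
    return pd.DataFrame({
        "tf_id": tf_ids,
        "role": [r for _, r in grn.tfs],
        "condition": [grn.cond_of_tf[tf] for tf in tf_ids],
        "bump_center": centers,
        "bump_width": widths,
        "baseline": baseline,
        "gate_off": gate_off,
        "spec_fraction": spec_frac,
    }).set_index("tf_id", drop=False)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu**2 (Poisson when
    dispersion == 0)."""
    mu = np.maximum(mu, 1e-9)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_cells(grn: GroundTruthGRN, config: SimConfig) -> MultiomeDataset:
    """Sample the paired count matrices, metadata and insertion signal."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    n_cond = len(config.conditions)
    n_cells = config.n_cells_per_condition * n_cond
    condition = np.repeat(list(config.conditions),
                          config.n_cells_per_condition)
    t = rng.uniform(0.0, 1.0, n_cells)
    groups = np.asarray(config.cell_groups, dtype=object)
    group_idx = np.minimum((t * len(groups)).astype(int), len(groups) - 1)
    cell_group = groups[group_idx]
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    tf_params = _tf_parameters(grn, config, rng)
    tf_ids = list(tf_params["tf_id"])
    tf_index = {tf: i for i, tf in enumerate(tf_ids)}

    # latent activity per cell×TF: bump + idiosyncratic term
    bump = np.exp(
        -(t[:, None] - tf_params["bump_center"].to_numpy()[None, :]) ** 2
        / (2.0 * tf_params["bump_width"].to_numpy()[None, :] ** 2))
    eta = rng.normal(0.0, 0.5, size=(n_cells, len(tf_ids)))
    z = 0.05 + bump + eta

    # expression gate: 1 in the TF's designated condition, gate_off elsewhere
    gate = np.ones_like(z)
    for i, tf in enumerate(tf_ids):
        off = tf_params.loc[tf, "gate_off"]
        if off < 1.0:
            gate[condition != tf_params.loc[tf, "condition"], i] = off

    # --- gene model table and coordinates
    genes, peaks = _layout_genome(
        grn, config, dict(zip(tf_params["tf_id"], tf_params["bump_center"])),
        rng)
    gene_ids = list(genes["gene_id"])
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    peak_index = {p: i for i, p in enumerate(peaks["peak_id"])}

    # --- RNA means
    beta = config.effect_size
    depth_rna = np.exp(rng.normal(0.0, 0.25, n_cells))
    baseline_gene = np.exp(rng.normal(np.log(3.0), 0.5, len(gene_ids)))
    for i in range(config.n_mito_genes):
        baseline_gene[gene_index[f"mt-{i + 1}"]] = 2.0
    log_mu = np.zeros((n_cells, len(gene_ids)))
    # TF own expression (its own amplitude so enrichment calls are not
    # starved by the log-scale compression of modest fold changes)
    for tf in tf_ids:
        gi, ti = gene_index[tf], tf_index[tf]
        baseline_gene[gi] = tf_params.loc[tf, "baseline"]
        # clip the idiosyncratic tail so no single TF dominates a cell's
        # library; targets keep the unclipped latent
        log_mu[:, gi] = config.tf_expr_beta \
            * np.minimum(z[:, ti], 1.6) * gate[:, ti]
    # planted target effects
    sign_num = {"+": 1.0, "-": -1.0}
    for tri in grn.triples:
        gi, ti = gene_index[tri.target_id], tf_index[tri.tf_id]
        eff = beta * sign_num[tri.sign] * z[:, ti]
        if tri.condition_specificity != "shared":
            eff = eff * (condition == tri.condition_specificity)
        log_mu[:, gi] += eff
    # depth floor: tiny configurations (few genes/peaks) would otherwise
    # put every cell under the fixed QC count minima; rescale expected
    # totals to a safe margin when they fall below twice the threshold
    from .qc import QCThresholds
    th = QCThresholds()
    exp_rna = float(baseline_gene.sum())
    if exp_rna < 2.0 * th.min_rna:
        baseline_gene *= 3.0 * th.min_rna / exp_rna
    mu_rna = baseline_gene[None, :] * np.exp(log_mu) * depth_rna[:, None]

    # --- ATAC rates
    depth_atac = np.exp(rng.normal(0.0, 0.25, n_cells))
    base_peak = config.peak_rate * np.exp(
        rng.normal(0.0, 0.4, len(peak_index)))
    exp_atac = float(base_peak.sum())
    if exp_atac < 2.0 * QCThresholds().min_atac:
        base_peak *= 3.0 * QCThresholds().min_atac / exp_atac
    log_lam = np.zeros((n_cells, len(peak_index)))
    for tri in grn.triples:
        pi, ti = peak_index[tri.peak_id], tf_index[tri.tf_id]
        eff = beta * sign_num[tri.sign] * z[:, ti]
        if tri.condition_specificity != "shared":
            eff = eff * (condition == tri.condition_specificity)
        log_lam[:, pi] += eff
    lam = base_peak[None, :] * np.exp(log_lam) * depth_atac[:, None]

    # --- planted QC failures
    qc_fail_mode = np.array([""] * n_cells, dtype=object)
    if config.plant_qc_failures and config.qc_failure_rate > 0:
        n_fail = int(round(config.qc_failure_rate * n_cells))
        fail_cells = rng.choice(n_cells, size=n_fail, replace=False)
        modes = ["low_rna", "low_atac", "high_mito", "doublet_rna",
                 "doublet_atac", "low_tss"]
        mito_cols = [gene_index[f"mt-{i + 1}"]
                     for i in range(config.n_mito_genes)]
        for k, ci in enumerate(fail_cells):
            mode = modes[k % len(modes)]
            qc_fail_mode[ci] = mode
            if mode == "low_rna":
                mu_rna[ci] *= 0.15
            elif mode == "low_atac":
                lam[ci] *= 0.15
            elif mode == "high_mito" and mito_cols:
                mu_rna[ci, mito_cols] *= 60.0

    rna = _nb_sample(rng, mu_rna, config.nb_dispersion)
    atac = rng.poisson(lam)

    # --- metadata
    tss_enr = rng.uniform(6.0, 12.0, n_cells)
    tss_enr[qc_fail_mode == "low_tss"] = 2.0
    dbl_rna = np.zeros(n_cells)
    dbl_rna[qc_fail_mode == "doublet_rna"] = 0.6
    dbl_atac = rng.uniform(0.0, 1.8, n_cells)
    dbl_atac[qc_fail_mode == "doublet_atac"] = 3.5
    n_rna = rna.sum(axis=1)
    n_atac = atac.sum(axis=1)
    mito_cols = [gene_index[f"mt-{i + 1}"] for i in range(config.n_mito_genes)]
    mito_counts = rna[:, mito_cols].sum(axis=1) if mito_cols else \
        np.zeros(n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_rna > 0, mito_counts / np.maximum(n_rna, 1), 0.0)

    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "condition": condition,
        "cell_group": cell_group,
        "pseudotime": t,
        "nCount_RNA": n_rna,
        "nCount_ATAC": n_atac,
        "tss_enrichment": tss_enr,
        "mito_fraction": mito_frac,
        "doublet_score_rna": dbl_rna,
        "doublet_enrichment_atac": dbl_atac,
        "qc_fail_mode": qc_fail_mode,
    })

    # --- footprint-shaped insertion signal per planted motif site
    w = config.motif_width
    vec_len = 7 * w
    sig_rows = []
    for site in grn.motif_sites:
        v = 1.0 + rng.normal(0.0, config.signal_noise_sd, vec_len)
        if site.bound:
            v[3 * w:4 * w] -= config.footprint_depth
        sig_rows.append((site.motif_id, site.peak_id, site.offset, *v))
    signal = pd.DataFrame(
        sig_rows,
        columns=["motif_id", "peak_id", "offset"]
        + [f"s{i}" for i in range(vec_len)])

    seqs = _peak_sequences(grn, peaks, config, rng)

    # reorder matrix columns to the peak table's coordinate order
    atac = atac[:, [peak_index[p] for p in peaks["peak_id"]]]

    ds = MultiomeDataset(
        rna=sp.csr_matrix(rna), atac=sp.csr_matrix(atac), cells=cells,
        genes=genes, peaks=peaks, peak_sequences=seqs,
        insertion_signal=signal)
    ds.tf_params = tf_params          # type: ignore[attr-defined]
    return ds


# ---------------------------------------------------------------------------
# fixture writer

def write_fixture(dataset: MultiomeDataset, grn: GroundTruthGRN,
                  directory) -> dict:
    """Write the dataset + ground truth as plain-text files.

    Emits MTX+TSV matrices, BED peaks, the gene-model TSV, cell metadata,
    the per-site insertion-signal TSV, JASPAR PWMs and the ground-truth
    JSON; returns a manifest listing every file with its row/column
    counts and sha256. Stable row order makes re-runs byte-identical.
    """
    outdir = mio.ensure_dir(directory)
    files: dict[str, dict] = {}

    def record(name, path, rows, cols):
        files[name] = {"path": str(Path(path).name), "rows": int(rows),
                       "cols": int(cols), "sha256": mio.sha256_file(path)}

    barcodes = list(dataset.cells["cell_id"])
    mio.write_counts_mtx(dataset.rna, barcodes, dataset.gene_ids,
                         outdir / "rna.mtx", outdir / "rna_barcodes.tsv",
                         outdir / "rna_features.tsv")
    record("rna", outdir / "rna.mtx", *dataset.rna.shape)
    mio.write_counts_mtx(dataset.atac, barcodes, dataset.peak_ids,
                         outdir / "atac.mtx", outdir / "atac_barcodes.tsv",
                         outdir / "atac_features.tsv")
    record("atac", outdir / "atac.mtx", *dataset.atac.shape)

    bed = dataset.peaks.rename(columns={"peak_id": "name"})
    mio.write_bed(bed[["chrom", "start", "end", "name"]],
                  outdir / "peaks.bed")
    record("peaks", outdir / "peaks.bed", len(bed), 4)

    mio.write_gene_models(dataset.genes, outdir / "genes.tsv")
    record("genes", outdir / "genes.tsv", len(dataset.genes),
           len(dataset.genes.columns))

    mio.write_table(dataset.cells, outdir / "cells.tsv")
    record("cells", outdir / "cells.tsv", len(dataset.cells),
           len(dataset.cells.columns))

    if dataset.peak_sequences is not None:
        mio.write_sequences_tsv(dataset.peak_sequences,
                                outdir / "peak_sequences.tsv")
        record("peak_sequences", outdir / "peak_sequences.tsv",
               len(dataset.peak_sequences), 2)
    if dataset.insertion_signal is not None:
        mio.write_table(dataset.insertion_signal,
                        outdir / "insertion_signal.tsv")
        record("insertion_signal", outdir / "insertion_signal.tsv",
               len(dataset.insertion_signal),
               len(dataset.insertion_signal.columns))

    motif_tf = {m: tf for tf, m in grn.motif_of_tf.items()}
    mio.write_pwms_jaspar(grn.pwms, motif_tf, outdir / "pwms.jaspar")
    record("pwms", outdir / "pwms.jaspar", len(grn.pwms), 4)

    gt = {
        "tfs": [list(x) for x in grn.tfs],
        "triples": [[t.tf_id, t.peak_id, t.target_id, t.sign,
                     t.condition_specificity] for t in grn.triples],
        "motif_sites": [[s.motif_id, s.peak_id, s.offset, s.width,
                         bool(s.bound)] for s in grn.motif_sites],
        "key_tfs_per_cluster": grn.key_tfs_per_cluster,
        "motif_of_tf": grn.motif_of_tf,
    }
    mio.write_json(gt, outdir / "ground_truth.json")
    record("ground_truth", outdir / "ground_truth.json", len(grn.triples), 0)

    manifest = {"files": files}
    mio.write_json(manifest, outdir / "manifest.json")
    return manifest


def read_ground_truth(path) -> GroundTruthGRN:
    gt = mio.read_json(path)
    return GroundTruthGRN(
        tfs=[tuple(x) for x in gt["tfs"]],
        triples=[Triple(*x) for x in gt["triples"]],
        motif_sites=[MotifSite(*x) for x in gt["motif_sites"]],
        key_tfs_per_cluster=gt["key_tfs_per_cluster"],
        motif_of_tf=gt["motif_of_tf"],
    )


def read_fixture(directory) -> MultiomeDataset:
    """Round-trip reader for :func:`write_fixture` output."""
    d = Path(directory)
    rna, barcodes, gene_ids = mio.read_counts_mtx(
        d / "rna.mtx", d / "rna_barcodes.tsv", d / "rna_features.tsv")
    atac, barcodes2, peak_ids = mio.read_counts_mtx(
        d / "atac.mtx", d / "atac_barcodes.tsv", d / "atac_features.tsv")
    if barcodes != barcodes2:
        raise ValueError("RNA and ATAC barcode files disagree")
    peaks = mio.read_bed(d / "peaks.bed").rename(columns={"name": "peak_id"})
    peaks = peaks[["peak_id", "chrom", "start", "end"]]
    genes = mio.read_gene_models(d / "genes.tsv")
    cells = mio.read_table(d / "cells.tsv")
    seqs = mio.read_sequences_tsv(d / "peak_sequences.tsv") \
        if (d / "peak_sequences.tsv").exists() else None
    signal = mio.read_table(d / "insertion_signal.tsv") \
        if (d / "insertion_signal.tsv").exists() else None
    return MultiomeDataset(rna=rna, atac=atac, cells=cells, genes=genes,
                           peaks=peaks, peak_sequences=seqs,
                           insertion_signal=signal)
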