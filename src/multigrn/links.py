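"""GRN construction steps 1–3: TF-motif roles, cis-element links, footprints.

Step 1 classifies each TF-motif pair as activator or repressor from the
single-cell Pearson correlation between TF expression and motif activity
(> 0.05 activator, < −0.05 repressor, dead zone dropped). Step 2
categorizes peaks (promoter / gene body / intergenic), builds candidate
peak→gene pairs, and retains links whose accessibility↔expression
correlation across pseudo-bulk aggregates passes |r| > 0.25 at FDR < 0.01.
Step 3 scores motif matches with the footprint statistic
NL + NR − 2·NC on corrected Tn5 insertion signal (flanks triple the motif
width) and keeps protected sites (score > 0.1) of expressed TFs inside
retained peaks.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .datatypes import MultiomeDataset
from .features import bh_adjust, normalize_log1p_cpm

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# step 1: activators and repressors

@dataclass(frozen=True)
class TFMotifRole:
    tf_id: str
    motif_id: str
    pearson_r: float
    role: str            # "activator" | "repressor"


def classify_tf_motifs(tf_expression: pd.DataFrame, motif_z: pd.DataFrame,
                       motif_tf: dict[str, str],
                       dead_zone: float = 0.05) -> list[TFMotifRole]:
    """Pearson r between TF expression and motif activity over all cells.

    r > dead_zone → activator; r < −dead_zone → repressor; pairs inside
    [−dead_zone, dead_zone] are dropped (logged), as are zero-variance
    vectors for which r is undefined.
    """
    if len(tf_expression) != len(motif_z):
        raise ValueError("expression and activity matrices disagree on cells")
    roles: list[TFMotifRole] = []
    for motif_id in motif_z.columns:
        tf_id = motif_tf.get(motif_id)
        if tf_id is None or tf_id not in tf_expression.columns:
            log.warning("motif %s: TF not in expression matrix; dropped",
                        motif_id)
            continue
        x = tf_expression[tf_id].to_numpy(dtype=float)
        y = motif_z[motif_id].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            log.warning("pair (%s, %s): zero variance; dropped", tf_id,
                        motif_id)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > dead_zone:
            roles.append(TFMotifRole(tf_id, motif_id, r, "activator"))
        elif r < -dead_zone:
            roles.append(TFMotifRole(tf_id, motif_id, r, "repressor"))
        else:
            log.info("pair (%s, %s): r=%.3f inside dead zone; dropped",
                     tf_id, motif_id, r)
    return roles


# ---------------------------------------------------------------------------
# step 2: cis-regulatory elements

def categorize_peaks(peaks: pd.DataFrame, gene_models: pd.DataFrame,
                     promoter_window: int = 500,
                     distal_window: int = 200_000):
    """Assign each peak a category and its candidate target genes.

    Promoter: the peak overlaps [tss − w, tss + w] of some gene (those
    genes are the candidates). Else gene body: the peak overlaps a gene
    body (overlapped genes are candidates). Else intergenic: candidates
    are all genes whose TSS lies within ``distal_window`` of the peak
    center. Precedence promoter > gene_body > intergenic. Returns
    ``(categories, candidates)``.
    """
    cats = []
    cand_rows = []
    for chrom, pk in peaks.groupby("chrom", sort=False):
        gm = gene_models[gene_models["chrom"] == chrom]
        if gm.empty:
            for pid in pk["peak_id"]:
                cats.append((pid, "intergenic"))
            log.info("chrom %s absent from gene models: %d peaks intergenic "
                     "with no candidates", chrom, len(pk))
            continue
        tss = gm["tss"].to_numpy()
        b0 = gm["body_start"].to_numpy()
        b1 = gm["body_end"].to_numpy()
        gids = gm["gene_id"].to_numpy()
        for pid, s, e in zip(pk["peak_id"], pk["start"], pk["end"]):
            prom = (s < tss + promoter_window + 1) & (e > tss - promoter_window)
            if prom.any():
                cats.append((pid, "promoter"))
                cand_rows += [(pid, g, "promoter") for g in gids[prom]]
                continue
            body = (s < b1) & (e > b0)
            if body.any():
                cats.append((pid, "gene_body"))
                cand_rows += [(pid, g, "gene_body") for g in gids[body]]
                continue
            center = (s + e) // 2
            near = np.abs(tss - center) <= distal_window
            cats.append((pid, "intergenic"))
            cand_rows += [(pid, g, "intergenic") for g in gids[near]]
    categories = pd.DataFrame(cats, columns=["peak_id", "category"])
    candidates = pd.DataFrame(cand_rows,
                              columns=["peak_id", "gene_id", "category"])
    return categories, candidates


def aggregate_cells(dataset: MultiomeDataset, n_aggregates: int = 100,
                    cells_per_aggregate: int = 100, n_pcs: int = 30,
                    seed: int = 0, atac_counts=None):
    """K-nearest-neighbour pseudo-bulk aggregates in a joint PCA space.

    Both modalities are log-normalized, concatenated and reduced to
    ``n_pcs`` components; each aggregate sums the raw counts of the
    ``cells_per_aggregate`` nearest neighbours of a random seed cell
    (with replacement across aggregates), then log-normalizes the sums.
    When the dataset holds fewer than 10,000 cells the neighbourhood size
    is scaled down proportionally. Returns
    ``(agg_rna, agg_atac, membership)``.
    """
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    n_cells = dataset.n_cells
    if n_cells < 10_000:
        cells_per_aggregate = max(10, int(round(
            cells_per_aggregate * n_cells / 10_000)))
    cells_per_aggregate = min(cells_per_aggregate, n_cells)
    n_aggregates = min(n_aggregates, n_cells)

    atac = dataset.atac if atac_counts is None else sp.csr_matrix(atac_counts)
    norm_rna = normalize_log1p_cpm(dataset.rna)
    norm_atac = normalize_log1p_cpm(atac)
    joint = np.hstack([norm_rna, norm_atac])
    n_pcs = min(n_pcs, joint.shape[1] - 1, n_cells - 1)
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    emb = pca.fit_transform(joint)

    rng = np.random.default_rng(seed)
    seeds = rng.choice(n_cells, size=n_aggregates, replace=False)
    nn = NearestNeighbors(n_neighbors=cells_per_aggregate).fit(emb)
    _, members = nn.kneighbors(emb[seeds])

    agg_rna = np.vstack([
        np.asarray(dataset.rna[m].sum(axis=0)).ravel() for m in members])
    agg_atac = np.vstack([
        np.asarray(atac[m].sum(axis=0)).ravel() for m in members])
    # aggregates pool the same number of cells, so summed counts are
    # depth-homogeneous already; a per-aggregate CPM rescaling would
    # couple unrelated features through the library total (regulated
    # features drag every flat feature's fraction down), so the sums are
    # log-transformed directly
    agg_rna = np.log1p(agg_rna)
    agg_atac = np.log1p(agg_atac)
    return (pd.DataFrame(agg_rna, columns=dataset.gene_ids),
            pd.DataFrame(agg_atac, columns=dataset.peak_ids),
            members)


def peak_to_gene(agg_rna: pd.DataFrame, agg_atac: pd.DataFrame,
                 candidates: pd.DataFrame, r_min: float = 0.25,
                 fdr_max: float = 0.01) -> pd.DataFrame:
    """Correlate peak accessibility with gene expression across aggregates.

    p-values come from the t-distribution transform of r with n − 2
    degrees of freedom; BH runs across ALL tested candidate pairs;
    retained links satisfy |r| > ``r_min`` and FDR < ``fdr_max``.
    """
    n = len(agg_rna)
    if n != len(agg_atac):
        raise ValueError("aggregate matrices disagree on rows")
    pairs = candidates[
        candidates["peak_id"].isin(agg_atac.columns)
        & candidates["gene_id"].isin(agg_rna.columns)].drop_duplicates(
            ["peak_id", "gene_id"]).reset_index(drop=True)

    X = agg_atac[pairs["peak_id"]].to_numpy(dtype=float)
    Y = agg_rna[pairs["gene_id"]].to_numpy(dtype=float)
    sx = X.std(axis=0, ddof=0)
    sy = Y.std(axis=0, ddof=0)
    const = (sx == 0) | (sy == 0)
    if const.any():
        log.warning("peak_to_gene: %d constant pairs dropped",
                    int(const.sum()))
    Xc = (X - X.mean(axis=0)) / np.where(sx == 0, 1.0, sx)
    Yc = (Y - Y.mean(axis=0)) / np.where(sy == 0, 1.0, sy)
    r = (Xc * Yc).mean(axis=0)
    r = np.clip(r, -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    out = pairs.copy()
    out["r"] = r
    out["p"] = p
    out = out[~const].reset_index(drop=True)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["retained"] = (out["r"].abs() > r_min) & (out["fdr"] < fdr_max)
    return out


# ---------------------------------------------------------------------------
# step 3: footprint-scored binding sites

@dataclass(frozen=True)
class FootprintSite:
    tf_id: str
    motif_id: str
    peak_id: str
    offset: int
    strand: str
    nc: float
    nl: float
    nr: float

    @property
    def score(self) -> float:
        return self.nl + self.nr - 2.0 * self.nc


def footprint_stats(signal: np.ndarray, width: int):
    """(NC, NL, NR) means over the center window and the two flanks.

    The signal vector spans [left flank | center | right flank] with
    flanks triple the motif width, hence length 7 × width.
    """
    v = np.asarray(signal, dtype=float)
    if v.size != 7 * width:
        raise ValueError(
            f"signal length {v.size} != 7 x width ({7 * width})")
    nl = float(v[:3 * width].mean())
    nc = float(v[3 * width:4 * width].mean())
    nr = float(v[4 * width:].mean())
    return nc, nl, nr


def footprint_sites(matches, retained_peaks: set[str],
                    insertion_signal: pd.DataFrame,
                    expressed_tfs: set[str], motif_tf: dict[str, str],
                    motif_widths: dict[str, int],
                    score_min: float = 0.1) -> list[FootprintSite]:
    """Retain protected binding sites of expressed TFs in retained peaks.

    A site passes when NL + NR − 2·NC > ``score_min``. ``insertion_signal``
    is the per-site corrected Tn5 track (columns motif_id/peak_id/offset
    then per-base values); matches with no signal record are skipped with
    a log message, a signal vector of the wrong length is an error naming
    the site.
    """
    sig_cols = [c for c in insertion_signal.columns
                if c not in ("motif_id", "peak_id", "offset")]
    sig_index = {
        (m, p, int(o)): i for i, (m, p, o) in enumerate(zip(
            insertion_signal["motif_id"], insertion_signal["peak_id"],
            insertion_signal["offset"]))}
    sig_values = insertion_signal[sig_cols].to_numpy(dtype=float)

    records = matches.records if hasattr(matches, "records") else matches
    sites: list[FootprintSite] = []
    n_missing = 0
    for row in records.itertuples(index=False):
        key = (row.motif_id, row.peak_id, int(row.offset))
        tf = motif_tf.get(row.motif_id)
        if tf is None:
            continue
        if row.peak_id not in retained_peaks:
            continue
        i = sig_index.get(key)
        if i is None:
            n_missing += 1
            continue
        width = motif_widths[row.motif_id]
        v = sig_values[i]
        v = v[~np.isnan(v)] if np.isnan(v).any() else v
        if v.size != 7 * width:
            raise ValueError(
                f"site {key}: signal length {v.size} != {7 * width}")
        nc, nl, nr = footprint_stats(v, width)
        if nl + nr - 2.0 * nc > score_min and tf in expressed_tfs:
            strand = getattr(row, "strand", "+")
            sites.append(FootprintSite(tf, row.motif_id, row.peak_id,
                                       int(row.offset), strand, nc, nl, nr))
    if n_missing:
        log.info("footprint_sites: %d matches had no signal record; skipped",
                 n_missing)
    return sites


def expressed_tf_ids(dataset: MultiomeDataset,
                     groups=("restMG", "actMG", "MGPC"),
                     min_fraction: float = 0.05) -> set[str]:
    """TFs detected (count > 0) in at least ``min_fraction`` of the cells
    of the pooled MG-lineage groups."""
    mask = dataset.cells["cell_group"].isin(groups).to_numpy()
    if mask.sum() == 0:
        return set()
    tf_cols = np.flatnonzero(dataset.genes["is_tf"].to_numpy()) \
        if "is_tf" in dataset.genes.columns else np.arange(len(dataset.genes))
    sub = dataset.rna[mask][:, tf_cols]
    frac = np.asarray((sub > 0).sum(axis=0)).ravel() / mask.sum()
    gids = np.asarray(dataset.gene_ids)[tf_cols]
    return {g for g, f in zip(gids, frac) if f >= min_fraction}


def sites_to_frame(sites: list[FootprintSite]) -> pd.DataFrame:
    return pd.DataFrame([{
        "tf_id": s.tf_id, "motif_id": s.motif_id, "peak_id": s.peak_id,
        "offset": s.offset, "strand": s.strand, "nc": s.nc, "nl": s.nl,
        "nr": s.nr, "score": s.score} for s in sites])
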