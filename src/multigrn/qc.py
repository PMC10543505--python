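"""Per-cell quality control and fixed-width peak merging.

Filtering applies the study's exact cut-offs, all strict inequalities:
multiome cells are removed when the RNA doublet score exceeds 0, the ATAC
doublet enrichment exceeds 2, nCount_RNA < 500, nCount_ATAC < 1000,
nCount_RNA > 50000, nCount_ATAC > 100000, or TSS enrichment < 4; RNA-only
cells when nCount_RNA < 500 or > 50000, the mitochondrial fraction
exceeds 15%, or the cell is a doublet. Doublet scores are consumed as
inputs — the scoring algorithms themselves are external tools.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MultiomeDataset

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_rna: float = 500.0
    min_atac: float = 1000.0
    max_rna: float = 50_000.0
    max_atac: float = 100_000.0
    min_tss_enrichment: float = 4.0
    max_mito_fraction: float = 0.15
    doublet_rna_cut: float = 0.0      # exclusive: score > cut removes
    doublet_atac_cut: float = 2.0     # exclusive

    def __post_init__(self) -> None:
        if self.min_rna >= self.max_rna:
            raise ValueError("min_rna must be < max_rna")
        if self.min_atac >= self.max_atac:
            raise ValueError("min_atac must be < max_atac")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    per_cell: pd.DataFrame          # metrics + pass flag + failure reasons
    summary: dict = field(default_factory=dict)

    @property
    def kept_ids(self) -> list[str]:
        return list(self.per_cell.loc[self.per_cell["pass"], "cell_id"])

    @property
    def pass_mask(self) -> np.ndarray:
        return self.per_cell["pass"].to_numpy()


def compute_qc_metrics(dataset: MultiomeDataset,
                       mito_genes: set[str] | None = None) -> pd.DataFrame:
    """Row-sum count metrics and the mitochondrial fraction per cell.

    ``mito_fraction`` is mito counts / nCount_RNA (0 for empty cells).
    Unknown mito gene ids raise with the offenders listed.
    """
    if dataset.rna.shape[0] == 0 or dataset.rna.shape[1] == 0:
        raise ValueError("empty RNA matrix")
    mito_genes = set(mito_genes or ())
    known = set(dataset.gene_ids)
    unknown = sorted(mito_genes - known)
    if unknown:
        raise ValueError(f"unknown mito gene ids: {unknown}")

    n_rna = np.asarray(dataset.rna.sum(axis=1)).ravel()
    n_atac = np.asarray(dataset.atac.sum(axis=1)).ravel()
    cols = [i for i, g in enumerate(dataset.gene_ids) if g in mito_genes]
    if cols:
        mito = np.asarray(dataset.rna[:, cols].sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(n_rna, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(n_rna > 0, mito / np.maximum(n_rna, 1), 0.0)

    out = pd.DataFrame({
        "cell_id": dataset.cells["cell_id"].to_numpy(),
        "nCount_RNA": n_rna,
        "nCount_ATAC": n_atac,
        "mito_fraction": mito_frac,
    })
    if "tss_enrichment" in dataset.cells.columns:
        out["tss_enrichment"] = dataset.cells["tss_enrichment"].to_numpy()
    return out


_MULTIOME_RULES = [
    # (rule name, required column, predicate factory)
    ("doublet_rna", "doublet_score_rna",
     lambda v, th: v > th.doublet_rna_cut),
    ("doublet_atac", "doublet_enrichment_atac",
     lambda v, th: v > th.doublet_atac_cut),
    ("min_rna", "nCount_RNA", lambda v, th: v < th.min_rna),
    ("min_atac", "nCount_ATAC", lambda v, th: v < th.min_atac),
    ("max_rna", "nCount_RNA", lambda v, th: v > th.max_rna),
    ("max_atac", "nCount_ATAC", lambda v, th: v > th.max_atac),
    ("min_tss", "tss_enrichment", lambda v, th: v < th.min_tss_enrichment),
]

_RNA_ONLY_RULES = [
    ("min_rna", "nCount_RNA", lambda v, th: v < th.min_rna),
    ("max_rna", "nCount_RNA", lambda v, th: v > th.max_rna),
    ("max_mito", "mito_fraction", lambda v, th: v > th.max_mito_fraction),
    ("doublet_rna", "doublet_score_rna",
     lambda v, th: v > th.doublet_rna_cut),
]


def filter_cells(metrics: pd.DataFrame,
                 doublet_scores: pd.DataFrame | None,
                 thresholds: QCThresholds | None = None,
                 modality: str = "multiome") -> QCReport:
    """Apply the threshold rules for ``modality`` and report per-rule counts.

    ``doublet_scores`` must provide ``doublet_score_rna`` (and, for
    multiome, ``doublet_enrichment_atac``) aligned with ``metrics`` by
    ``cell_id`` — the scores are required inputs for multiome filtering.
    A cell failing k rules lists exactly k reasons. Filtering is
    idempotent: re-filtering the kept cells removes nothing.
    """
    thresholds = thresholds or QCThresholds()
    if modality not in ("multiome", "rna_only"):
        raise ValueError(f"unknown modality {modality!r}")
    rules = _MULTIOME_RULES if modality == "multiome" else _RNA_ONLY_RULES

    table = metrics.copy()
    if doublet_scores is not None:
        dcols = [c for c in ("doublet_score_rna", "doublet_enrichment_atac")
                 if c in doublet_scores.columns]
        ds = doublet_scores.set_index("cell_id")[dcols] \
            if "cell_id" in doublet_scores.columns else doublet_scores[dcols]
        table = table.join(ds, on="cell_id")

    needed = {col for _, col, _ in rules}
    missing = sorted(needed - set(table.columns))
    if missing:
        raise ValueError(
            f"{modality} filtering requires columns {missing} "
            "(doublet scores are required inputs)")
    if table[sorted(needed)].isna().any().any():
        bad = table.columns[table[sorted(needed)].isna().any().to_numpy()]
        raise ValueError(f"missing metric values in columns {list(bad)}")

    n = len(table)
    fail = np.zeros(n, dtype=bool)
    reasons = [[] for _ in range(n)]
    removed_per_rule = {}
    for name, col, pred in rules:
        hit = pred(table[col].to_numpy(), thresholds)
        removed_per_rule[name] = int(hit.sum())
        fail |= hit
        for i in np.flatnonzero(hit):
            reasons[i].append(name)
        log.info("qc rule %-12s flagged %d cells", name, int(hit.sum()))

    table["pass"] = ~fail
    table["failure_reasons"] = [",".join(r) for r in reasons]
    summary = {
        "n_input": n,
        "n_kept": int((~fail).sum()),
        "n_removed": int(fail.sum()),
        "removed_per_rule": removed_per_rule,
        "modality": modality,
    }
    return QCReport(per_cell=table, summary=summary)


def apply_qc(dataset: MultiomeDataset,
             thresholds: QCThresholds | None = None) -> tuple[MultiomeDataset, QCReport]:
    """Convenience wrapper: metrics + multiome filtering + subsetting."""
    mito = set(dataset.genes.loc[dataset.genes.get("is_mito", False).astype(bool),
                                 "gene_id"]) if "is_mito" in dataset.genes else set()
    metrics = compute_qc_metrics(dataset, mito)
    report = filter_cells(
        metrics,
        dataset.cells[["cell_id", "doublet_score_rna",
                       "doublet_enrichment_atac"]],
        thresholds, modality="multiome")
    return dataset.subset_cells(report.pass_mask), report


def merge_fixed_width_peaks(candidates: pd.DataFrame,
                            width: int = 501) -> pd.DataFrame:
    """Iteratively retain the most significant peak among overlapping ones.

    ``candidates`` needs chrom/start/end/score columns and every interval
    must have the fixed ``width``. Greedy rule: keep the highest-score
    remaining candidate (ties broken by smaller start, then chrom),
    discard everything overlapping it, repeat. Output is coordinate
    sorted and pairwise non-overlapping.
    """
    df = candidates.reset_index(drop=True)
    widths = (df["end"] - df["start"]).to_numpy()
    if np.any(widths != width):
        bad = df.index[widths != width][:5].tolist()
        raise ValueError(
            f"candidates at rows {bad} do not have width {width}")

    order = df.sort_values(["score", "start", "chrom"],
                           ascending=[False, True, True],
                           kind="mergesort").index.to_numpy()
    kept: list[int] = []
    discarded = np.zeros(len(df), dtype=bool)
    chrom = df["chrom"].to_numpy()
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    for i in order:
        if discarded[i]:
            continue
        kept.append(i)
        overlap = (chrom == chrom[i]) & (start < end[i]) & (end > start[i])
        discarded |= overlap
    out = df.loc[sorted(kept)].sort_values(
        ["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out
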