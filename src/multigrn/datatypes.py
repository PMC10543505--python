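"""Shared in-memory containers for the multiome GRN pipeline.

Coordinates are 0-based half-open throughout. The paired count matrices are
stored sparse with cells as rows; per-cell metadata, gene models and peak
intervals travel with them so every stage can subset consistently.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

CELL_META_COLUMNS = [
    "cell_id", "condition", "cell_group", "pseudotime",
    "nCount_RNA", "nCount_ATAC", "tss_enrichment", "mito_fraction",
    "doublet_score_rna", "doublet_enrichment_atac",
]

GENE_COLUMNS = [
    "gene_id", "chrom", "strand", "tss", "body_start", "body_end",
    "is_tf", "is_mito",
]


@dataclass
class MultiomeDataset:
    """Paired cell×gene and cell×peak counts plus cell/peak/gene annotation.

    ``insertion_signal`` carries the bias-corrected per-base Tn5 insertion
    track for each assayed motif site: one row per site with identifying
    columns (motif_id, peak_id, offset) followed by ``7 × width`` signal
    values (left flank | center | right flank, flanks triple the motif
    width).
    """

    rna: sp.csr_matrix                 # cells × genes, raw counts
    atac: sp.csr_matrix                # cells × peaks, raw counts
    cells: pd.DataFrame                # one row per cell, CELL_META_COLUMNS
    genes: pd.DataFrame                # one row per gene, GENE_COLUMNS
    peaks: pd.DataFrame                # peak_id, chrom, start, end (sorted)
    peak_sequences: Optional[pd.Series] = None       # peak_id -> str
    insertion_signal: Optional[pd.DataFrame] = None  # site table, see above

    def __post_init__(self) -> None:
        self.rna = sp.csr_matrix(self.rna)
        self.atac = sp.csr_matrix(self.atac)
        if self.rna.shape[0] != self.atac.shape[0]:
            raise ValueError(
                f"RNA ({self.rna.shape[0]}) and ATAC ({self.atac.shape[0]}) "
                "matrices disagree on cell count"
            )
        if self.rna.shape[0] != len(self.cells):
            raise ValueError("cell metadata rows != matrix rows")
        if self.rna.shape[1] != len(self.genes):
            raise ValueError("gene table rows != RNA columns")
        if self.atac.shape[1] != len(self.peaks):
            raise ValueError("peak table rows != ATAC columns")

    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    @property
    def peak_ids(self) -> list[str]:
        return list(self.peaks["peak_id"])

    def subset_cells(self, mask: np.ndarray) -> "MultiomeDataset":
        """Return a dataset restricted to the cells where ``mask`` is true."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            rna=self.rna[idx],
            atac=self.atac[idx],
            cells=self.cells.iloc[idx].reset_index(drop=True),
        )

    def split_by_condition(self) -> dict[str, "MultiomeDataset"]:
        return {
            cond: self.subset_cells((self.cells["condition"] == cond).to_numpy())
            for cond in pd.unique(self.cells["condition"])
        }


@dataclass(frozen=True)
class Triple:
    """One planted or inferred TF → peak → target edge."""

    tf_id: str
    peak_id: str
    target_id: str
    sign: str                      # "+" or "-"
    condition_specificity: str     # "shared" or a condition label


@dataclass(frozen=True)
class MotifSite:
    motif_id: str
    peak_id: str
    offset: int
    width: int
    bound: bool


@dataclass
class GroundTruthGRN:
    """Planted regulatory network used for parameter-recovery testing."""

    tfs: list[tuple[str, str]]                  # (tf_id, "activator"/"repressor")
    triples: list[Triple]
    motif_sites: list[MotifSite]
    key_tfs_per_cluster: dict[str, list[str]]   # planted cluster id -> TFs
    motif_of_tf: dict[str, str] = field(default_factory=dict)
    pwms: dict[str, np.ndarray] = field(default_factory=dict)  # motif_id -> w×4

    @property
    def role_of(self) -> dict[str, str]:
        return dict(self.tfs)

    def planted_links(self) -> set[tuple[str, str]]:
        return {(t.peak_id, t.target_id) for t in self.triples}

    def planted_edges(self) -> set[tuple[str, str]]:
        return {(t.tf_id, t.target_id) for t in self.triples}

    def planted_triples(self) -> set[tuple[str, str, str]]:
        return {(t.tf_id, t.peak_id, t.target_id) for t in self.triples}

    @staticmethod
    def expected_subgrn_condition(triple: Triple,
                                  conditions) -> str | None:
        """Condition whose enriched sub-network should carry ``triple``.

        A condition-specific activator belongs to its own condition's
        sub-network. A condition-specific repressor acts in its own
        condition but its regulatory consequence — targets de-repressed,
        TF comparatively down — is the signature of the *other*
        condition's expression state, which is where the directional
        enrichment rules place it. Shared triples belong to neither.
        """
        if triple.condition_specificity == "shared":
            return None
        if triple.sign == "+":
            return triple.condition_specificity
        others = [c for c in conditions if c != triple.condition_specificity]
        return others[0] if others else None
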