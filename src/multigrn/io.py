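"""Readers and writers for the external formats the pipeline touches.

Formats: MatrixMarket (counts), TSV (tables, signal tracks), BED3/6 (peaks,
binding sites), JASPAR text (PWMs), JSON (ground truth, manifests). All
genomic coordinates are 0-based half-open; text output uses tab separators
and floats at 6 significant digits so repeated runs hash identically.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"

BASES = "ACGT"


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket + barcode/feature TSVs)

def read_counts_mtx(matrix_path, barcodes_path, features_path):
    """Read a cell×feature count matrix (cells as rows).

    Returns ``(csr_matrix, barcodes, features)``. Raises ``ValueError``
    when the barcode/feature row counts disagree with the matrix header.
    """
    mat = sp.csr_matrix(sio.mmread(matrix_path))
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    if mat.shape[0] != len(barcodes):
        raise ValueError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has "
            f"{mat.shape[0]} rows"
        )
    if mat.shape[1] != len(features):
        raise ValueError(
            f"{features_path}: {len(features)} features but matrix has "
            f"{mat.shape[1]} columns"
        )
    return mat, barcodes, features


def write_counts_mtx(matrix, barcodes: Sequence[str], features: Sequence[str],
                     matrix_path, barcodes_path, features_path) -> None:
    matrix = sp.coo_matrix(matrix)
    if len(barcodes) != matrix.shape[0] or len(features) != matrix.shape[1]:
        raise ValueError("barcode/feature counts do not match matrix shape")
    sio.mmwrite(str(matrix_path), matrix, field="integer")
    _write_id_column(barcodes, barcodes_path)
    _write_id_column(features, features_path)


def _read_id_column(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _write_id_column(ids: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for x in ids:
            fh.write(f"{x}\n")


# ---------------------------------------------------------------------------
# BED intervals

def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a coordinate-sorted DataFrame (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
            rec = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 4:
                rec["name"] = parts[3]
            if len(parts) >= 5:
                rec["score"] = float(parts[4])
            if len(parts) >= 6:
                rec["strand"] = parts[5]
            rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        df = df.reset_index(drop=True)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    for extra in ("name", "score", "strand"):
        if extra in df.columns:
            cols.append(extra)
        else:
            break
    out = df[cols].copy()
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# plain TSV tables

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_gene_models(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open; tss is a point coordinate\n")
        genes.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_gene_models(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"gene_id", "chrom", "strand", "tss", "body_start", "body_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing gene-model columns {sorted(missing)}")
    return df


def write_sequences_tsv(seqs: pd.Series, path) -> None:
    df = pd.DataFrame({"peak_id": seqs.index, "sequence": seqs.values})
    df.to_csv(path, sep="\t", index=False)


def read_sequences_tsv(path) -> pd.Series:
    df = read_table(path, dtype=str)
    return pd.Series(df["sequence"].values, index=df["peak_id"].values,
                     name="sequence")


# ---------------------------------------------------------------------------
# JASPAR-format PWMs

def write_pwms_jaspar(pwms: dict[str, np.ndarray],
                      motif_tf: dict[str, str], path) -> None:
    """Write probability matrices in JASPAR text layout.

    One block per motif: a ``>motif_id tf_id`` header then four labelled
    rows (A, C, G, T) of per-position probabilities.
    """
    with open(path, "w") as fh:
        for motif_id in pwms:
            mat = np.asarray(pwms[motif_id], dtype=float)
            fh.write(f">{motif_id} {motif_tf.get(motif_id, motif_id)}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:.6f}" for v in mat[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


def read_pwms_jaspar(path):
    """Parse JASPAR text into ``(pwms, motif_tf)``.

    ``pwms`` maps motif_id to a width×4 matrix in A,C,G,T column order.
    Accepts both raw JASPAR counts and probability rows; rows are
    renormalized per position.
    """
    pwms: dict[str, np.ndarray] = {}
    motif_tf: dict[str, str] = {}
    name = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines.append(">")  # sentinel to flush the last block

    def flush():
        if name is None:
            return
        if set(rows) != set(BASES):
            raise ValueError(f"motif {name}: expected rows A,C,G,T, got {sorted(rows)}")
        mat = np.column_stack([rows[b] for b in BASES]).astype(float)
        sums = mat.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError(f"motif {name}: zero column sum")
        pwms[name] = mat / sums

    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            rows = {}
            parts = line[1:].split()
            name = parts[0] if parts else None
            if name:
                motif_tf[name] = parts[1] if len(parts) > 1 else name
            continue
        base = line[0].upper()
        if base not in BASES:
            raise ValueError(f"unexpected PWM row: {line[:40]!r}")
        body = line[1:].replace("[", " ").replace("]", " ")
        rows[base] = [float(tok) for tok in body.split()]
    return pwms, motif_tf


# ---------------------------------------------------------------------------
# JSON helpers

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
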