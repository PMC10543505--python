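"""Motif matching and per-cell motif deviation z-scores.

Matching scores each window with the PWM log-odds against an i.i.d.
background; the score threshold for the stated p-value cut-off (default
5e-5) is computed exactly by dynamic programming over the discretized
per-position score distribution, so it agrees with exhaustive
enumeration of all 4^w words. Deviations follow the chromVAR model: the
fragment-count deviation of each motif's matched peak set from its
expected fraction, standardized against background peak sets matched on
GC content and mean accessibility.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

BASE_ORDER = "ACGT"
PROB_FLOOR = 1e-4       # PWM probabilities floored before log
SCORE_GRAIN = 1e-3      # DP score discretization


@dataclass
class Motif:
    motif_id: str
    tf_id: str
    pwm: np.ndarray      # width × 4 probability matrix (A,C,G,T)

    @property
    def width(self) -> int:
        return self.pwm.shape[0]


@dataclass
class MotifSet:
    motifs: list[Motif]
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        seen = {}
        for m in self.motifs:
            m.pwm = np.asarray(m.pwm, dtype=float)
            if m.width < 4:
                raise ValueError(f"motif {m.motif_id}: width must be >= 4")
            if not np.allclose(m.pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"motif {m.motif_id}: PWM rows must sum to 1")
            if m.motif_id in seen:
                raise ValueError(f"duplicate motif id {m.motif_id}")
            seen[m.motif_id] = m.tf_id

    @property
    def motif_ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs]

    @property
    def motif_tf(self) -> dict[str, str]:
        return {m.motif_id: m.tf_id for m in self.motifs}

    @classmethod
    def from_pwms(cls, pwms: dict[str, np.ndarray],
                  motif_tf: dict[str, str],
                  background=None) -> "MotifSet":
        motifs = [Motif(mid, motif_tf.get(mid, mid), mat)
                  for mid, mat in pwms.items()]
        if background is None:
            return cls(motifs)
        return cls(motifs, background)


@dataclass
class MotifMatchMatrix:
    """Boolean peak×motif matrix plus the individual match records."""

    matrix: pd.DataFrame                 # peaks × motifs, bool
    records: pd.DataFrame                # peak_id, motif_id, offset, strand, score

    @property
    def peak_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def matched_peaks(self, motif_id: str) -> list[str]:
        col = self.matrix[motif_id]
        return list(col.index[col.to_numpy()])


def _int_scores(pwm: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Discretized log-odds matrix (width × 4, integers in SCORE_GRAIN units)."""
    lo = np.log(np.maximum(pwm, PROB_FLOOR)) - np.log(background)
    return np.rint(lo / SCORE_GRAIN).astype(np.int64)


def score_threshold(pwm: np.ndarray, background: np.ndarray,
                    p_cutoff: float) -> int:
    """Smallest integer score T with P(score >= T) <= p_cutoff under the
    i.i.d. background model, by exact DP over the discretized scores."""
    if not 0.0 < p_cutoff < 1.0:
        raise ValueError("p_cutoff must be in (0, 1)")
    ints = _int_scores(pwm, background)
    # convolve the per-position score distributions
    dist = np.array([1.0])
    offset = 0
    for i in range(ints.shape[0]):
        row = ints[i]
        rmin, rmax = int(row.min()), int(row.max())
        pos = np.zeros(rmax - rmin + 1)
        for b in range(4):
            pos[row[b] - rmin] += background[b]
        dist = np.convolve(dist, pos)
        offset += rmin
    # dist[k] = P(total == offset + k); upper tail from the top
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.flatnonzero(tail <= p_cutoff)
    if len(ok) == 0:
        return offset + len(dist)        # unattainable: nothing matches
    return offset + int(ok[0])


def score_threshold_bruteforce(pwm: np.ndarray, background: np.ndarray,
                               p_cutoff: float) -> int:
    """Exhaustive-enumeration oracle over all 4**w words (w <= ~10)."""
    w = pwm.shape[0]
    ints = _int_scores(pwm, background)
    scores = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for i in range(w):
        scores = (scores[:, None] + ints[i][None, :]).ravel()
        probs = (probs[:, None] * background[None, :]).ravel()
    uniq = np.unique(scores)[::-1]                    # descending
    tails = np.array([probs[scores >= s].sum() for s in uniq])
    bad = uniq[tails > p_cutoff]                      # scores whose tail fails
    if len(bad) == 0:
        return int(uniq[-1])                          # everything matches
    # smallest integer T with P(S >= T) <= p_cutoff
    return int(bad[0]) + 1


_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASE_ORDER):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def match_motifs(motif_set: MotifSet, peak_sequences: pd.Series,
                 p_cutoff: float = 5e-5) -> MotifMatchMatrix:
    """Scan every peak sequence with every motif on both strands.

    A position matches when its discretized log-odds score reaches the
    exact DP threshold for ``p_cutoff``; per position only the better
    strand is reported. Windows containing non-ACGT characters are
    skipped (logged), not errors.
    """
    peak_ids = list(peak_sequences.index)
    encoded = [_encode(s) for s in peak_sequences.to_numpy()]
    n_skipped = 0

    all_records = []
    bool_cols = {}
    for motif in motif_set.motifs:
        w = motif.width
        ints_f = _int_scores(motif.pwm, motif_set.background)
        # reverse strand == reverse-complemented PWM scanned forward
        ints_r = ints_f[::-1, ::-1]
        big_neg = np.full((w, 1), np.iinfo(np.int32).min // w, dtype=np.int64)
        ints_f = np.hstack([ints_f, big_neg])   # column 4 = non-ACGT
        ints_r = np.hstack([ints_r, big_neg])
        thresh = score_threshold(motif.pwm, motif_set.background, p_cutoff)
        hits_bool = np.zeros(len(peak_ids), dtype=bool)
        for pi, codes in enumerate(encoded):
            L = len(codes)
            if L < w:
                continue
            n_win = L - w + 1
            idx = np.arange(n_win)[:, None] + np.arange(w)[None, :]
            win = codes[idx]
            valid = ~(win == 4).any(axis=1)
            if not valid.all():
                n_skipped += int((~valid).sum())
            pos_range = np.arange(w)
            sf = ints_f[pos_range, win].sum(axis=1)
            sr = ints_r[pos_range, win].sum(axis=1)
            best = np.maximum(sf, sr)
            hit = valid & (best >= thresh)
            if not hit.any():
                continue
            hits_bool[pi] = True
            for off in np.flatnonzero(hit):
                strand = "+" if sf[off] >= sr[off] else "-"
                all_records.append((peak_ids[pi], motif.motif_id, int(off),
                                    strand, float(best[off] * SCORE_GRAIN)))
        bool_cols[motif.motif_id] = hits_bool

    if n_skipped:
        log.info("match_motifs: skipped %d windows containing N", n_skipped)
    matrix = pd.DataFrame(bool_cols, index=pd.Index(peak_ids, name="peak_id"))
    records = pd.DataFrame(
        all_records,
        columns=["peak_id", "motif_id", "offset", "strand", "score"])
    return MotifMatchMatrix(matrix=matrix, records=records)


# ---------------------------------------------------------------------------
# chromVAR-style deviations

def compute_expected_and_bias(peak_counts, peak_sequences: pd.Series,
                              peak_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-peak expected accessibility fraction and GC content.

    ``expected_fraction_j`` = total counts in peak j / grand total;
    ``gc_content`` = fraction of G/C bases in the peak's sequence.
    """
    counts = sp.csr_matrix(peak_counts)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("zero grand total in peak counts")
    if peak_ids is None:
        peak_ids = list(peak_sequences.index)
    seqs = peak_sequences.loc[peak_ids]
    gc = np.array([
        (s.count("G") + s.count("C") + s.count("g") + s.count("c")) / len(s)
        if len(s) else 0.0
        for s in seqs.to_numpy()])
    return pd.DataFrame({
        "peak_id": peak_ids,
        "expected_fraction": totals / grand,
        "gc_content": gc,
    }).set_index("peak_id")


@dataclass
class MotifActivity:
    """Cell × motif deviation z-scores with the motif↔TF map."""

    z: pd.DataFrame                       # cells × motifs
    motif_tf: dict[str, str]
    n_background: int = 50
    n_bins: tuple[int, int] = (10, 10)
    dropped_motifs: list[str] = field(default_factory=list)


def _background_bins(bias: pd.DataFrame, n_bins: int = 10) -> np.ndarray:
    """Joint (gc, expected_fraction) quantile-bin label per peak."""
    def codes(v):
        ranks = pd.Series(v).rank(method="first")
        q = np.ceil(ranks / len(ranks) * n_bins).astype(int) - 1
        return q.to_numpy()

    g = codes(bias["gc_content"].to_numpy())
    e = codes(bias["expected_fraction"].to_numpy())
    return g * n_bins + e


def compute_deviations(peak_counts, matches: MotifMatchMatrix,
                       bias: pd.DataFrame, n_background: int = 50,
                       seed: int = 0, n_bins: int = 10,
                       motif_tf: dict[str, str] | None = None,
                       cell_ids=None) -> MotifActivity:
    """Per-cell motif deviation z-scores against matched backgrounds.

    Raw deviation Y_im = (X_im - E_im) / E_im with X_im the cell's counts
    in the motif's matched peaks and E_im = nCount_i * sum of matched
    expected fractions. Each of the B background sets replaces every
    matched peak with a random peak from the same (GC, expected fraction)
    bin; z = (Y - mean_b Y^b) / sd_b Y^b. Motifs with zero matched peaks
    are dropped with a warning; zero background sd yields z = 0.
    """
    if n_background < 2:
        raise ValueError("n_background must be >= 2")
    counts = sp.csr_matrix(peak_counts).astype(float)
    n_cells, n_peaks = counts.shape
    peak_ids = matches.peak_ids
    if len(peak_ids) != n_peaks:
        raise ValueError("match matrix and count matrix disagree on peaks")
    bias = bias.loc[peak_ids]
    ef = bias["expected_fraction"].to_numpy()
    ncount = np.asarray(counts.sum(axis=1)).ravel()

    rng = np.random.default_rng(seed)
    bins = _background_bins(bias, n_bins)
    members = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    # background peak draw for every peak × background set
    bg_draw = np.empty((n_peaks, n_background), dtype=np.int64)
    for b, idx in members.items():
        take = rng.integers(0, len(idx), size=(len(idx), n_background))
        bg_draw[idx] = idx[take]

    M = matches.matrix.to_numpy()          # peaks × motifs bool
    kept = M.any(axis=0)
    dropped = [m for m, k in zip(matches.motif_ids, kept) if not k]
    for m in dropped:
        log.warning("motif %s has no matched peaks; column dropped", m)
    motif_ids = [m for m, k in zip(matches.motif_ids, kept) if k]
    M = M[:, kept].astype(float)

    X = counts @ M                                     # cells × motifs
    E = np.outer(ncount, ef @ M)
    with np.errstate(divide="ignore", invalid="ignore"):
        Y = np.where(E > 0, (X - E) / E, 0.0)

    mean_b = np.zeros_like(Y)
    m2_b = np.zeros_like(Y)
    for b in range(n_background):
        # substitute every matched peak with its drawn background peak
        sub = bg_draw[:, b]
        Xb = np.zeros_like(Y)
        Eb = np.zeros_like(Y)
        for k in range(M.shape[1]):
            mp = np.flatnonzero(M[:, k] > 0)
            bp = sub[mp]
            Xb[:, k] = np.asarray(counts[:, bp].sum(axis=1)).ravel()
            Eb[:, k] = ncount * ef[bp].sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            Yb = np.where(Eb > 0, (Xb - Eb) / Eb, 0.0)
        delta = Yb - mean_b
        mean_b += delta / (b + 1)
        m2_b += delta * (Yb - mean_b)
    sd_b = np.sqrt(m2_b / (n_background - 1))
    # deviations are dimensionless; sd at float-jitter scale means the
    # backgrounds are degenerate and the z-score is 0 by convention
    zero_sd = sd_b <= 1e-8
    if zero_sd.any():
        log.warning("compute_deviations: %d (cell, motif) entries had zero "
                    "background sd; z set to 0", int(zero_sd.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(zero_sd, 0.0, (Y - mean_b) / np.where(zero_sd, 1.0, sd_b))

    zdf = pd.DataFrame(z, columns=motif_ids)
    if cell_ids is not None:
        zdf.index = pd.Index(cell_ids, name="cell_id")
    tf_map = {m: (motif_tf or {}).get(m, m) for m in motif_ids}
    return MotifActivity(z=zdf, motif_tf=tf_map, n_background=n_background,
                         n_bins=(n_bins, n_bins), dropped_motifs=dropped)
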