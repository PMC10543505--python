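"""Normalization, two-group tests, differential/consensus feature calls,
pseudotime binning and profile clustering.

Call types follow the study's vocabulary: DEG/CEG for genes, DAR/CAR for
accessible regions, DM/CM for motif activities; "differential" contrasts
the two conditions inside each cell group, "consensus" contrasts each
trajectory group against the others in both conditions independently.
Gene and peak effects are log2 fold changes of group means on the
log-normalized scale; motif z-scores can be negative, so motif effects
are differences of group mean z against the same 0.25 threshold.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

log = logging.getLogger(__name__)

EPS = 1e-9


# ---------------------------------------------------------------------------
# primitives

def normalize_log1p_cpm(counts, scale: float = 1e4) -> np.ndarray:
    """ln(1 + scale * x / rowsum); zero rows map to zeros (warned)."""
    X = sp.csr_matrix(counts, dtype=float)
    rs = np.asarray(X.sum(axis=1)).ravel()
    zero = rs <= 0
    if zero.any():
        log.warning("normalize_log1p_cpm: %d all-zero rows", int(zero.sum()))
    inv = np.where(zero, 0.0, scale / np.maximum(rs, 1.0))
    X = sp.diags(inv) @ X
    X = X.toarray()
    return np.log1p(X)


def rank_test(group_a: np.ndarray, group_b: np.ndarray):
    """Two-sided Wilcoxon rank-sum plus a log2 fold change of means.

    Inputs are value vectors (1-D) or value matrices (observations ×
    features). The p-value uses the exact null for small tie-free samples
    and the tie-corrected normal approximation otherwise; the fold change
    is log2((mean_a + eps) / (mean_b + eps)) on whatever scale the values
    are given.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if np.asarray(group_a).ndim == 1:
        a, b = a.T, b.T
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("each group needs n >= 3")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                                 method="auto")
    p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        # undefined (NaN) for sign-mixed scales such as motif z, where
        # callers use the mean difference instead
        lfc = np.log2((a.mean(axis=0) + EPS) / (b.mean(axis=0) + EPS))
    if np.asarray(group_a).ndim == 1:
        return float(lfc[0]), float(p[0])
    return lfc, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up with monotonicity enforcement, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class FeatureCallSet:
    """Per-group retained features with the full statistics table."""

    call_type: str                      # DEG | CEG | DAR | CAR | DM | CM
    contrast: str
    groups: dict[str, list[str]]        # cell group -> retained feature ids
    table: pd.DataFrame                 # feature_id, group, effect, p, adj_p, ...
    filters: list[str] = field(default_factory=list)

    def all_features(self) -> set[str]:
        return set().union(*map(set, self.groups.values())) if self.groups \
            else set()

    def retained_in(self, group: str) -> set[str]:
        return set(self.groups.get(group, []))


def seurat_log2fc(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Fold change on the de-logged expression scale.

    log2((mean(expm1(a)) + 1) / (mean(expm1(b)) + 1)) — the convention of
    the single-cell toolkits whose thresholds (0.25 / 0.5 / 2) the calls
    use; a ratio of log-scale means would compress real fold changes so
    far that those thresholds could never fire.
    """
    ea = np.expm1(np.atleast_2d(norm_a)).mean(axis=0) + 1.0
    eb = np.expm1(np.atleast_2d(norm_b)).mean(axis=0) + 1.0
    return np.log2(ea / eb)


def _group_test(values_a: np.ndarray, values_b: np.ndarray,
                feature_ids, group: str, effect: str = "log2fc",
                min_n: int = 3) -> pd.DataFrame:
    """Feature-wise rank tests between two cell sets; BH within the batch."""
    if values_a.shape[0] < min_n or values_b.shape[0] < min_n:
        log.warning("group %s skipped: fewer than %d cells", group, min_n)
        return pd.DataFrame(
            columns=["feature_id", "group", "effect", "p", "adj_p"])
    if effect == "log2fc":
        _, p = rank_test(values_a, values_b)
        eff = seurat_log2fc(values_a, values_b)
    else:  # delta_z: difference of group means on the z scale
        _, p = rank_test(values_a, values_b)
        eff = values_a.mean(axis=0) - values_b.mean(axis=0)
    return pd.DataFrame({
        "feature_id": list(feature_ids),
        "group": group,
        "effect": np.asarray(eff, dtype=float),
        "p": np.asarray(p, dtype=float),
        "adj_p": bh_adjust(p),
    })


# ---------------------------------------------------------------------------
# gene calls

def mature_marker_genes(control_norm: np.ndarray, gene_ids,
                        cell_types: pd.Series,
                        mature_types: list[str],
                        log2fc_min: float = 2.0,
                        adj_p_max: float = 0.05) -> set[str]:
    """Markers of mature cell types in control data (log2FC > 2, adj p < .05).

    Used downstream to purge ambient-RNA-driven genes from MG DEG lists;
    returns the union over the listed mature types.
    """
    markers: set[str] = set()
    types = cell_types.to_numpy()
    for ct in mature_types:
        mask = types == ct
        if mask.sum() < 3 or (~mask).sum() < 3:
            log.warning("mature type %s skipped (too few cells)", ct)
            continue
        tab = _group_test(control_norm[mask], control_norm[~mask],
                          gene_ids, ct)
        hit = (tab["effect"] > log2fc_min) & (tab["adj_p"] < adj_p_max)
        markers |= set(tab.loc[hit, "feature_id"])
    return markers


def find_degs(norm_a: np.ndarray, norm_b: np.ndarray,
              groups_a: pd.Series, groups_b: pd.Series, gene_ids,
              cell_groups=("restMG", "actMG", "MGPC"),
              log2fc_min: float = 0.25, adj_p_max: float = 0.05,
              mature_markers: set[str] | None = None,
              contrast: str = "A-vs-B") -> FeatureCallSet:
    """Condition-vs-condition differential genes per MG cell group.

    Genes pass with |log2FC| > ``log2fc_min`` (0.25 for the within-injury
    contrast, 0.5 for injury-vs-development) and BH-adjusted p < 0.05;
    mature-neuron markers are excluded from the lists.
    """
    mature_markers = mature_markers or set()
    tables, retained = [], {}
    ga, gb = groups_a.to_numpy(), groups_b.to_numpy()
    for g in cell_groups:
        tab = _group_test(norm_a[ga == g], norm_b[gb == g], gene_ids, g)
        if tab.empty:
            retained[g] = []
            continue
        hit = (tab["effect"].abs() > log2fc_min) & (tab["adj_p"] < adj_p_max)
        is_mature = tab["feature_id"].isin(mature_markers)
        tab["retained"] = hit & ~is_mature
        tab.loc[hit & is_mature, "excluded_by"] = "mature_marker"
        tables.append(tab)
        retained[g] = list(tab.loc[tab["retained"], "feature_id"])
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return FeatureCallSet("DEG", contrast, retained, table,
                          filters=[f"abs_log2fc>{log2fc_min}",
                                   f"adj_p<{adj_p_max}", "mature_excluded"])


def find_cegs(norm_a: np.ndarray, norm_b: np.ndarray,
              groups_a: pd.Series, groups_b: pd.Series, gene_ids,
              trajectory_groups, log2fc_min: float = 0.5,
              adj_p_max: float = 0.05) -> FeatureCallSet:
    """Consensus genes: enriched in a trajectory group vs the others, with
    log2FC > 0.5 and adj p < 0.05 in BOTH conditions independently."""
    tables, retained = [], {}
    for g in trajectory_groups:
        per_cond = []
        for norm, grp, cond in ((norm_a, groups_a, "A"), (norm_b, groups_b, "B")):
            mask = grp.to_numpy() == g
            tab = _group_test(norm[mask], norm[~mask], gene_ids, g)
            if tab.empty:
                per_cond = []
                break
            tab["condition"] = cond
            tab["hit"] = (tab["effect"] > log2fc_min) \
                & (tab["adj_p"] < adj_p_max)
            per_cond.append(tab)
        if not per_cond:
            retained[g] = []
            continue
        both = set(per_cond[0].loc[per_cond[0]["hit"], "feature_id"]) \
            & set(per_cond[1].loc[per_cond[1]["hit"], "feature_id"])
        retained[g] = sorted(both)
        tables.extend(per_cond)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return FeatureCallSet("CEG", "group-vs-rest in both conditions",
                          retained, table,
                          filters=[f"log2fc>{log2fc_min}",
                                   f"adj_p<{adj_p_max}", "both_conditions"])


# ---------------------------------------------------------------------------
# peak calls

def _linked_targets(peak_links: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for pid, gid in zip(peak_links["peak_id"], peak_links["gene_id"]):
        out.setdefault(pid, set()).add(gid)
    return out


def find_dars(norm_atac_a: np.ndarray, norm_atac_b: np.ndarray,
              groups_a: pd.Series, groups_b: pd.Series, peak_ids,
              deg_genes: set[str], peak_links: pd.DataFrame,
              cell_groups=("restMG", "actMG", "MGPC"),
              log2fc_min: float = 0.25, p_max: float = 0.05,
              contrast: str = "A-vs-B") -> FeatureCallSet:
    """Differential peaks per group: |log2FC| > 0.25 and raw p < 0.05
    (raw p, unlike the gene calls), then peaks whose linked target genes
    include no DEG are removed."""
    links = _linked_targets(peak_links)
    tables, retained = [], {}
    ga, gb = groups_a.to_numpy(), groups_b.to_numpy()
    for g in cell_groups:
        tab = _group_test(norm_atac_a[ga == g], norm_atac_b[gb == g],
                          peak_ids, g)
        if tab.empty:
            retained[g] = []
            continue
        hit = (tab["effect"].abs() > log2fc_min) & (tab["p"] < p_max)
        linked_deg = tab["feature_id"].map(
            lambda p: bool(links.get(p, set()) & deg_genes))
        tab["retained"] = hit & linked_deg
        tab.loc[hit & ~linked_deg, "excluded_by"] = "no_deg_target"
        tables.append(tab)
        retained[g] = list(tab.loc[tab["retained"], "feature_id"])
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return FeatureCallSet("DAR", contrast, retained, table,
                          filters=[f"abs_log2fc>{log2fc_min}",
                                   f"raw_p<{p_max}", "target_is_deg"])


def find_cars(norm_atac_a: np.ndarray, norm_atac_b: np.ndarray,
              groups_a: pd.Series, groups_b: pd.Series, peak_ids,
              ceg_genes: set[str], peak_links: pd.DataFrame,
              trajectory_groups, log2fc_min: float = 0.25,
              p_max: float = 0.05) -> FeatureCallSet:
    """Consensus peaks: group-vs-rest log2FC > 0.25 and p < 0.05 in both
    conditions; peaks unrelated to any CEG are excluded."""
    links = _linked_targets(peak_links)
    tables, retained = [], {}
    for g in trajectory_groups:
        per_cond_hits = []
        for norm, grp in ((norm_atac_a, groups_a), (norm_atac_b, groups_b)):
            mask = grp.to_numpy() == g
            tab = _group_test(norm[mask], norm[~mask], peak_ids, g)
            if tab.empty:
                per_cond_hits = []
                break
            hits = set(tab.loc[(tab["effect"] > log2fc_min)
                               & (tab["p"] < p_max), "feature_id"])
            per_cond_hits.append(hits)
            tables.append(tab)
        if not per_cond_hits:
            retained[g] = []
            continue
        both = per_cond_hits[0] & per_cond_hits[1]
        retained[g] = sorted(p for p in both
                             if links.get(p, set()) & ceg_genes)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return FeatureCallSet("CAR", "group-vs-rest in both conditions",
                          retained, table,
                          filters=[f"log2fc>{log2fc_min}", f"p<{p_max}",
                                   "both_conditions", "target_is_ceg"])


# ---------------------------------------------------------------------------
# motif calls

def _lr_test_pvalues(z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Likelihood-ratio p for logistic regression of membership on one
    motif's z (vs intercept only); falls back to the rank test under
    perfect separation."""
    import statsmodels.api as sm
    n_feat = z.shape[1]
    pvals = np.empty(n_feat)
    y = labels.astype(float)
    for j in range(n_feat):
        x = sm.add_constant(z[:, j])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            llf, llnull = fit.llf, fit.llnull
            stat = max(2.0 * (llf - llnull), 0.0)
            p = float(stats.chi2.sf(stat, df=1))
            if not np.isfinite(p):
                raise ValueError("non-finite LR p")
            pvals[j] = p
        except Exception:
            log.warning("LR test failed (perfect separation?); "
                        "falling back to rank test for one motif")
            _, p = rank_test(z[labels, j], z[~labels, j])
            pvals[j] = p
    return pvals


def _best_motif_per_tf(candidates: list[str], motif_tf: dict[str, str],
                       tf_motif_corr: dict[str, float]) -> list[str]:
    """Keep, per TF, only the motif with maximal |TF-expression ↔ motif
    activity| correlation."""
    best: dict[str, tuple[float, str]] = {}
    for m in candidates:
        tf = motif_tf.get(m, m)
        score = abs(tf_motif_corr.get(m, 0.0))
        if tf not in best or score > best[tf][0]:
            best[tf] = (score, m)
    keep = {m for _, m in best.values()}
    return [m for m in candidates if m in keep]


def find_dms(z_a: pd.DataFrame, z_b: pd.DataFrame,
             groups_a: pd.Series, groups_b: pd.Series,
             deg_calls: FeatureCallSet, motif_tf: dict[str, str],
             tf_motif_corr: dict[str, float],
             cell_groups=("restMG", "actMG", "MGPC"),
             delta_min: float = 0.25, adj_p_max: float = 0.05) -> FeatureCallSet:
    """Differential motifs per group via the logistic LR test.

    Effect is the difference in group mean z (|Δz| > 0.25, adj p < 0.05);
    motifs whose TF is not a DEG in the same direction are dropped, and
    for TFs with several motifs only the best-correlated motif is kept.
    """
    motif_ids = list(z_a.columns)
    tables, retained = [], {}
    ga, gb = groups_a.to_numpy(), groups_b.to_numpy()
    deg_tab = deg_calls.table
    for g in cell_groups:
        za, zb = z_a.to_numpy()[ga == g], z_b.to_numpy()[gb == g]
        if za.shape[0] < 3 or zb.shape[0] < 3:
            retained[g] = []
            continue
        z = np.vstack([za, zb])
        labels = np.zeros(len(z), dtype=bool)
        labels[:len(za)] = True
        p = _lr_test_pvalues(z, labels)
        delta = za.mean(axis=0) - zb.mean(axis=0)
        tab = pd.DataFrame({"feature_id": motif_ids, "group": g,
                            "effect": delta, "p": p, "adj_p": bh_adjust(p)})
        hit = (np.abs(delta) > delta_min) & (tab["adj_p"] < adj_p_max)
        # TF must be a DEG in this group with matching direction
        deg_g = deg_tab[(deg_tab["group"] == g) & deg_tab["retained"]] \
            if len(deg_tab) else deg_tab
        deg_dir = dict(zip(deg_g["feature_id"], np.sign(deg_g["effect"]))) \
            if len(deg_g) else {}
        consistent = np.array([
            deg_dir.get(motif_tf.get(m, m), 0.0) == np.sign(d) and d != 0
            for m, d in zip(motif_ids, delta)])
        tab["retained"] = hit & consistent
        cand = list(tab.loc[tab["retained"], "feature_id"])
        keep = set(_best_motif_per_tf(cand, motif_tf, tf_motif_corr))
        tab.loc[~tab["feature_id"].isin(keep), "retained"] = False
        tables.append(tab)
        retained[g] = list(tab.loc[tab["retained"], "feature_id"])
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return FeatureCallSet("DM", deg_calls.contrast, retained, table,
                          filters=[f"abs_delta_z>{delta_min}",
                                   f"adj_p<{adj_p_max}",
                                   "tf_is_deg_same_direction", "best_motif"])


def find_cms(z_a: pd.DataFrame, z_b: pd.DataFrame,
             groups_a: pd.Series, groups_b: pd.Series,
             ceg_calls: FeatureCallSet, motif_tf: dict[str, str],
             tf_motif_corr: dict[str, float], trajectory_groups,
             delta_min: float = 0.25, adj_p_max: float = 0.05) -> FeatureCallSet:
    """Consensus motifs: group-vs-rest |Δ mean z| > 0.25 and adj p < 0.05
    in both conditions, CEG-consistent, best motif per TF."""
    motif_ids = list(z_a.columns)
    tables, retained = [], {}
    for g in trajectory_groups:
        hits_per_cond, delta_sign = [], None
        for z, grp in ((z_a, groups_a), (z_b, groups_b)):
            mask = grp.to_numpy() == g
            if mask.sum() < 3 or (~mask).sum() < 3:
                hits_per_cond = []
                break
            delta = z.to_numpy()[mask].mean(axis=0) \
                - z.to_numpy()[~mask].mean(axis=0)
            _, p = rank_test(z.to_numpy()[mask], z.to_numpy()[~mask])
            adj = bh_adjust(p)
            tab = pd.DataFrame({"feature_id": motif_ids, "group": g,
                                "effect": delta, "p": p, "adj_p": adj})
            tables.append(tab)
            hits = {m for m, d, a in zip(motif_ids, delta, adj)
                    if abs(d) > delta_min and a < adj_p_max}
            hits_per_cond.append((hits, dict(zip(motif_ids, delta))))
        if not hits_per_cond:
            retained[g] = []
            continue
        both = hits_per_cond[0][0] & hits_per_cond[1][0]
        ceg_g = ceg_calls.retained_in(g)
        cand = [m for m in motif_ids if m in both
                and motif_tf.get(m, m) in ceg_g
                and hits_per_cond[0][1][m] > 0]
        retained[g] = _best_motif_per_tf(cand, motif_tf, tf_motif_corr)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    return FeatureCallSet("CM", "group-vs-rest in both conditions",
                          retained, table,
                          filters=[f"abs_delta_z>{delta_min}",
                                   f"adj_p<{adj_p_max}", "both_conditions",
                                   "tf_is_ceg", "best_motif"])


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class BinnedTrajectory:
    trajectory_id: str
    n_bins: int
    bin_counts: np.ndarray                  # cells per bin
    matrices: dict[str, pd.DataFrame]       # name -> features × bins (scaled)
    flagged: dict[str, list] = field(default_factory=dict)


def bin_pseudotime(pseudotime: pd.Series, matrices: dict[str, pd.DataFrame],
                   n_bins: int = 30, smooth_window: int = 3,
                   trajectory_id: str = "traj") -> BinnedTrajectory:
    """Average features over equal-width pseudotime bins, smooth, z-scale.

    ``matrices`` maps a name to a cells × features frame aligned with
    ``pseudotime``. Bins span [min t, max t]; empty bins are filled by
    linear interpolation from neighbouring bins (flagged); smoothing is a
    centered rolling mean of odd width (edges truncated); each feature
    row is z-scaled across bins (constant rows become zeros, flagged).
    """
    if not 20 <= n_bins <= 50:
        raise ValueError(
            f"n_bins must be within the supported 20–50 range, got {n_bins}")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    t = pseudotime.to_numpy(dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("pseudotime must be finite")
    lo, hi = t.min(), t.max()
    width = (hi - lo) / n_bins or 1.0
    bins = np.minimum(((t - lo) / width).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)

    out, flagged = {}, {}
    centers = (np.arange(n_bins) + 0.5)
    for name, mat in matrices.items():
        X = mat.to_numpy(dtype=float)
        sums = np.zeros((n_bins, X.shape[1]))
        np.add.at(sums, bins, X)
        with np.errstate(invalid="ignore"):
            means = sums / np.maximum(counts[:, None], 1)
        empty = counts == 0
        if empty.any():
            filled = np.flatnonzero(~empty)
            for j in range(means.shape[1]):
                means[empty, j] = np.interp(centers[empty], centers[filled],
                                            means[filled, j])
            flagged.setdefault("empty_bins", []).append(
                (name, np.flatnonzero(empty).tolist()))
        if smooth_window > 1:
            k = smooth_window // 2
            sm = np.empty_like(means)
            for i in range(n_bins):
                a, b = max(0, i - k), min(n_bins, i + k + 1)
                sm[i] = means[a:b].mean(axis=0)
            means = sm
        mu = means.mean(axis=0)
        sd = means.std(axis=0, ddof=0)
        const = sd <= 0
        if const.any():
            flagged.setdefault("constant_features", []).append(
                (name, list(np.asarray(mat.columns)[const])))
        scaled = np.where(const[None, :], 0.0,
                          (means - mu[None, :]) / np.where(const, 1.0, sd))
        out[name] = pd.DataFrame(scaled.T, index=mat.columns,
                                 columns=[f"bin{i}" for i in range(n_bins)])
    return BinnedTrajectory(trajectory_id, n_bins, counts, out, flagged)


def cluster_profiles_kmeans(profiles: pd.DataFrame, k: int, seed: int = 0,
                            n_init: int = 10) -> pd.Series:
    """K-means (Euclidean, ``n_init`` restarts, best inertia) on scaled
    bin profiles; deterministic given the seed."""
    from sklearn.cluster import KMeans
    X = profiles.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return pd.Series(labels, index=profiles.index, name="cluster")
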