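"""GRN construction steps 4–7: importance edges, triples, sub-networks,
key activators.

Step 4 fits a stochastic gradient-boosted regression per target gene on
all TF expression columns; per-target gain importances are normalized to
sum to 1, pairs below the global 95th-percentile cut are discarded, and
the surviving edges are signed by Pearson correlation (±0.03 dead zone).
Step 5 joins footprint-scored binding sites, peak→gene links and TF→gene
edges into TF-peak-target triples with direction-consistency,
MG-enrichment and best-footprint dedup filters. Step 6 extracts the
condition-enriched sub-network from the directional DEG/DAR evidence and
step 7 tests each TF's sub-network targets against DEG clusters with the
hypergeometric upper tail (key activators: p < 0.001 and coverage > 0.01).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom, pearsonr

from .features import FeatureCallSet
from .links import FootprintSite, TFMotifRole

log = logging.getLogger(__name__)

GRN_COLUMNS = ["tf_id", "motif_id", "peak_id", "target_id", "role", "sign",
               "footprint_score", "ptg_r", "importance"]


# ---------------------------------------------------------------------------
# step 4: TF -> target importance

def tf_target_importance(expression: pd.DataFrame, tf_ids: list[str],
                         target_ids: list[str] | None = None,
                         quantile_cut: float = 0.95,
                         r_pos: float = 0.03, r_neg: float = -0.03,
                         seed: int = 0, per_target_cut: bool = False,
                         n_estimators: int = 100, max_depth: int = 3,
                         learning_rate: float = 0.1,
                         subsample: float = 0.9) -> pd.DataFrame:
    """Gradient-boosted TF→gene importances with correlation signs.

    ``expression`` is a cells × genes frame of normalized values. Each
    target is regressed on all TF columns (a TF never predicts itself);
    importance is the total split gain per TF, normalized to sum to 1
    within each target. Pairs below the 95th percentile of all importances
    (global by default; per target behind ``per_target_cut``) are
    discarded; retained pairs are annotated positive (r > 0.03) or
    negative (r < −0.03), dead-zone pairs dropped.
    """
    import lightgbm as lgb

    if len(tf_ids) < 2:
        raise ValueError("need at least 2 TFs")
    tf_ids = [t for t in tf_ids if t in expression.columns]
    if target_ids is None:
        target_ids = [g for g in expression.columns]
    X_all = expression[tf_ids].to_numpy(dtype=float)
    rows = []
    rng = np.random.default_rng(seed)
    for target in target_ids:
        y = expression[target].to_numpy(dtype=float)
        if y.std() == 0:
            log.warning("target %s constant; skipped", target)
            continue
        if target in tf_ids:
            keep = [i for i, t in enumerate(tf_ids) if t != target]
            X = X_all[:, keep]
            preds = [tf_ids[i] for i in keep]
        else:
            X, preds = X_all, tf_ids
        model = lgb.LGBMRegressor(
            n_estimators=n_estimators, max_depth=max_depth,
            num_leaves=2 ** max_depth, learning_rate=learning_rate,
            subsample=subsample, subsample_freq=1,
            random_state=int(rng.integers(0, 2 ** 31 - 1)),
            n_jobs=1, deterministic=True, force_row_wise=True,
            verbosity=-1, min_child_samples=10)
        model.fit(X, y)
        gain = model.booster_.feature_importance(importance_type="gain")
        total = gain.sum()
        if total <= 0:
            log.warning("target %s: no splits; skipped", target)
            continue
        imp = gain / total
        for tf, v in zip(preds, imp):
            rows.append((tf, target, float(v)))
    edges = pd.DataFrame(rows, columns=["tf_id", "gene_id", "importance"])
    if edges.empty:
        edges["r"] = edges["sign"] = edges["retained"] = []
        return edges

    if per_target_cut:
        cut = edges.groupby("gene_id")["importance"].transform(
            lambda v: np.quantile(v, quantile_cut))
    else:
        cut = np.quantile(edges["importance"].to_numpy(), quantile_cut)
    edges["retained"] = edges["importance"] >= cut

    # sign retained edges by Pearson correlation
    r_vals = np.full(len(edges), np.nan)
    idx = {g: expression[g].to_numpy(dtype=float) for g in expression.columns}
    for i, row in enumerate(edges.itertuples(index=False)):
        if not row.retained:
            continue
        r_vals[i] = pearsonr(idx[row.tf_id], idx[row.gene_id])[0]
    edges["r"] = r_vals
    sign = np.where(r_vals > r_pos, "positive",
                    np.where(r_vals < r_neg, "negative", "none"))
    edges["sign"] = sign
    edges.loc[edges["retained"] & (edges["sign"] == "none"),
              "retained"] = False
    return edges


# ---------------------------------------------------------------------------
# step 5: triple assembly

def assemble_triples(binding_sites: list[FootprintSite] | pd.DataFrame,
                     links: pd.DataFrame, roles: list[TFMotifRole],
                     edges: pd.DataFrame,
                     mg_enriched: set[str]) -> pd.DataFrame:
    """Join sites, links and edges into the total GRN.

    A candidate (tf, peak, target) exists when a retained binding site
    for the TF lies in the peak, a retained link joins the peak to the
    target, and a retained edge joins the TF to the target. Retention:
    (1) role and edge sign agree (activator ↔ positive), (2) the TF is
    MG-enriched, (3) one record per (tf, peak, target) keeping the
    maximal footprint score.
    """
    if isinstance(binding_sites, pd.DataFrame):
        sites = binding_sites
    else:
        from .links import sites_to_frame
        sites = sites_to_frame(binding_sites)
    if sites.empty:
        return pd.DataFrame(columns=GRN_COLUMNS)

    role_of = {(r.tf_id, r.motif_id): r.role for r in roles}
    known_tfs = {r.tf_id for r in roles}
    missing = sorted(set(sites["tf_id"]) - known_tfs)
    if missing:
        log.warning("TFs present in sites but absent from roles "
                    "(candidates dropped): %s", missing)
    sites = sites[sites["tf_id"].isin(known_tfs)].copy()
    sites["role"] = [role_of.get((t, m))
                     for t, m in zip(sites["tf_id"], sites["motif_id"])]
    sites = sites[sites["role"].notna()]

    live_links = links[links["retained"]][["peak_id", "gene_id", "r"]] \
        .rename(columns={"gene_id": "target_id", "r": "ptg_r"})
    live_edges = edges[edges["retained"]][
        ["tf_id", "gene_id", "importance", "sign"]] \
        .rename(columns={"gene_id": "target_id"})

    cand = sites.merge(live_links, on="peak_id")
    cand = cand.merge(live_edges, on=["tf_id", "target_id"])
    # rule 1: direction consistency
    consistent = ((cand["role"] == "activator") & (cand["sign"] == "positive")) \
        | ((cand["role"] == "repressor") & (cand["sign"] == "negative"))
    dropped = (~consistent).sum()
    if dropped:
        log.info("assemble_triples: %d candidates dropped (direction)",
                 int(dropped))
    cand = cand[consistent]
    # rule 2: TF enriched in MG cell groups
    cand = cand[cand["tf_id"].isin(mg_enriched)]
    # rule 3: dedupe on max footprint score
    cand = cand.sort_values("score", ascending=False, kind="mergesort")
    cand = cand.drop_duplicates(["tf_id", "peak_id", "target_id"],
                                keep="first")
    out = cand.rename(columns={"score": "footprint_score"})[GRN_COLUMNS]
    return out.sort_values(["tf_id", "peak_id", "target_id"],
                           kind="mergesort").reset_index(drop=True)


def mg_enriched_tfs(norm_rna: np.ndarray, gene_ids, tf_ids: list[str],
                    cell_groups: pd.Series,
                    groups=("restMG", "actMG", "MGPC"),
                    log2fc_min: float = 0.25,
                    adj_p_max: float = 0.05) -> set[str]:
    """TFs up-regulated (rank test vs all other cells) in at least one MG
    cell group."""
    from .features import _group_test

    gi = {g: i for i, g in enumerate(gene_ids)}
    cols = [gi[t] for t in tf_ids if t in gi]
    ids = [t for t in tf_ids if t in gi]
    sub = norm_rna[:, cols]
    labels = cell_groups.to_numpy()
    enriched: set[str] = set()
    for g in groups:
        mask = labels == g
        if mask.sum() < 3 or (~mask).sum() < 3:
            log.warning("group %s too small; skipped", g)
            continue
        tab = _group_test(sub[mask], sub[~mask], ids, g)
        hit = (tab["effect"] > log2fc_min) & (tab["adj_p"] < adj_p_max)
        enriched |= set(tab.loc[hit, "feature_id"])
    return enriched


# ---------------------------------------------------------------------------
# step 6: enriched sub-networks

@dataclass
class SubGRN:
    condition: str
    triples: pd.DataFrame           # GRN rows + evidence columns
    n_parent: int = 0

    def triple_keys(self) -> set[tuple[str, str, str]]:
        return {(r.tf_id, r.peak_id, r.target_id)
                for r in self.triples.itertuples(index=False)}


def extract_enriched_subgrn(grn: pd.DataFrame, deg_calls: FeatureCallSet,
                            dar_stats: pd.DataFrame, condition: str,
                            conditions: tuple[str, str],
                            groups=("restMG", "actMG", "MGPC"),
                            peak_rule: str = "significant",
                            peak_log2fc_min: float = 0.25,
                            peak_p_max: float = 0.05) -> SubGRN:
    """Condition-enriched triples from the total GRN.

    With the DEG/DAR contrast oriented as conditions[0] vs conditions[1]:
    (1) the TF is an up-DEG in ``condition`` (down for repressors) in at
    least one MG group; (2) the peak is NOT significantly less accessible
    in ``condition`` in any group (``peak_rule="sign"`` instead excludes
    any negative point estimate); (3) the target is an up-DEG in at least
    one group. Evidence is recorded per triple.
    """
    if condition not in conditions:
        raise ValueError(f"condition {condition!r} not in {conditions}")
    orient = 1.0 if condition == conditions[0] else -1.0

    deg_tab = deg_calls.table
    deg_tab = deg_tab[deg_tab.get("retained", True)] if len(deg_tab) else deg_tab

    def up_groups(feature: str, direction: float) -> list[str]:
        if not len(deg_tab):
            return []
        rows = deg_tab[(deg_tab["feature_id"] == feature)
                       & (deg_tab["group"].isin(groups))
                       & (np.sign(deg_tab["effect"]) * orient == direction)]
        return list(rows["group"])

    # peaks significantly depleted in `condition` in any group
    bad_peaks: set[str] = set()
    if len(dar_stats):
        d = dar_stats[dar_stats["group"].isin(groups)]
        if peak_rule == "significant":
            hit = (d["effect"] * orient < -peak_log2fc_min) \
                & (d["p"] < peak_p_max)
        elif peak_rule == "sign":
            hit = d["effect"] * orient < 0
        else:
            raise ValueError(f"unknown peak_rule {peak_rule!r}")
        bad_peaks = set(d.loc[hit, "feature_id"])

    rows = []
    for r in grn.itertuples(index=False):
        tf_dir = 1.0 if r.role == "activator" else -1.0
        tf_g = up_groups(r.tf_id, tf_dir)
        if not tf_g:
            continue
        if r.peak_id in bad_peaks:
            continue
        tgt_g = up_groups(r.target_id, 1.0)
        if not tgt_g:
            continue
        rec = r._asdict()
        rec["evidence_tf_groups"] = ",".join(tf_g)
        rec["evidence_peak_ok"] = True
        rec["evidence_target_groups"] = ",".join(tgt_g)
        rows.append(rec)
    sub = pd.DataFrame(rows, columns=list(grn.columns)
                       + ["evidence_tf_groups", "evidence_peak_ok",
                          "evidence_target_groups"])
    return SubGRN(condition=condition, triples=sub, n_parent=len(grn))


# ---------------------------------------------------------------------------
# step 7: key activators

def hypergeom_upper_tail(N: int, K: int, n: int, k_obs: int) -> float:
    """P(X >= k_obs) for X ~ Hypergeometric(N, K, n), computed in log space."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k_obs):
        raise ValueError(f"inconsistent arguments N={N} K={K} n={n} "
                         f"k_obs={k_obs}")
    if k_obs > min(K, n):
        raise ValueError(f"k_obs={k_obs} exceeds min(K, n)={min(K, n)}")
    if k_obs == 0:
        return 1.0
    ks = np.arange(k_obs, min(K, n) + 1)
    if len(ks) == 0:
        return 0.0
    return float(np.exp(logsumexp(hypergeom.logpmf(ks, N, K, n))))


@dataclass
class KeyTFResult:
    tf_id: str
    cluster_id: str
    n_overlap: int
    n_cluster: int
    coverage: float
    p: float
    is_key: bool
    n_total_targets: int = 0
    n_sub_targets: int = 0


def key_activators(subgrn: SubGRN, total_grn: pd.DataFrame,
                   deg_clusters: dict[str, set[str]],
                   p_max: float = 0.001,
                   coverage_min: float = 0.01) -> list[KeyTFResult]:
    """Hypergeometric key-regulator test per (TF, DEG cluster).

    Triples are reduced to unique (tf, target) pairs. Population = the
    TF's targets in the total GRN, successes = those targets inside the
    cluster, sample = the TF's targets in the sub-GRN, observed = sample ∩
    cluster. Coverage = overlap / cluster size; key TFs pass p < 0.001
    and coverage > 0.01.
    """
    for cid, genes in deg_clusters.items():
        if not genes:
            raise ValueError(f"cluster {cid!r} is empty")
    total_targets = total_grn.groupby("tf_id")["target_id"].agg(set)
    sub_targets = subgrn.triples.groupby("tf_id")["target_id"].agg(set) \
        if len(subgrn.triples) else pd.Series(dtype=object)

    results: list[KeyTFResult] = []
    for tf, sub_t in sub_targets.items():
        tot_t = total_targets.get(tf, set())
        n = len(sub_t)
        if n == 0:
            continue
        N = len(tot_t)
        for cid, cluster in deg_clusters.items():
            K = len(tot_t & cluster)
            k_obs = len(sub_t & cluster)
            p = hypergeom_upper_tail(N, K, n, k_obs)
            coverage = k_obs / len(cluster)
            results.append(KeyTFResult(
                tf_id=tf, cluster_id=str(cid), n_overlap=k_obs,
                n_cluster=len(cluster), coverage=coverage, p=p,
                is_key=bool(p < p_max and coverage > coverage_min),
                n_total_targets=N, n_sub_targets=n))
    return results


def key_results_frame(results: list[KeyTFResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
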