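"""Parameter-recovery evaluation against the planted ground truth, plus
null-calibration checks of the statistical machinery.

These functions compare a completed pipeline run (the in-memory state
from :func:`multigrn.pipeline.run_pipeline_with_state`) with the
GroundTruthGRN the run was simulated from, and quantify how much of the
planted structure each stage recovered.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GroundTruthGRN
from .features import bh_adjust, normalize_log1p_cpm, rank_test, seurat_log2fc
from .links import footprint_stats
from .motifs import (MotifMatchMatrix, compute_deviations,
                     compute_expected_and_bias)


def _prf(got: set, truth: set) -> dict:
    tp = len(got & truth)
    precision = tp / len(got) if got else 0.0
    recall = tp / len(truth) if truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_called": len(got), "n_planted": len(truth)}


def recovery_metrics(state: dict, config) -> dict:
    """All criterion-level recovery quantities for one completed run."""
    truth: GroundTruthGRN = state["grn_truth"]
    role_of = truth.role_of

    # activator/repressor classification over planted TF-motif pairs
    roles = state["roles"]
    called = {r.tf_id: r.role for r in roles}
    role_acc = np.mean([called.get(tf) == role for tf, role in truth.tfs])

    # peak-to-gene links
    live = state["links"][state["links"]["retained"]]
    got_links = set(zip(live["peak_id"], live["gene_id"]))
    links = _prf(got_links, truth.planted_links())

    # footprint separation: classify every planted site by its score
    ds = state["dataset_raw"]
    w = config.sim.motif_width
    sig_cols = [f"s{i}" for i in range(7 * w)]
    sig = ds.insertion_signal
    key_of = {(m, p, int(o)): i for i, (m, p, o) in enumerate(
        zip(sig["motif_id"], sig["peak_id"], sig["offset"]))}
    correct = 0
    for site in truth.motif_sites:
        v = sig.loc[key_of[(site.motif_id, site.peak_id, site.offset)],
                    sig_cols].to_numpy(dtype=float)
        nc, nl, nr = footprint_stats(v, w)
        predicted_bound = (nl + nr - 2 * nc) > config.footprint_min
        correct += int(predicted_bound == site.bound)
    footprint_acc = correct / len(truth.motif_sites)

    # assembled GRN triples
    got_triples = set(map(tuple,
                          state["total_grn"][["tf_id", "peak_id",
                                              "target_id"]].values))
    triples = _prf(got_triples, truth.planted_triples())

    # condition assignment of recovered condition-specific triples
    conds = config.sim.conditions
    expected = {}
    for t in truth.triples:
        c = GroundTruthGRN.expected_subgrn_condition(t, conds)
        if c is not None:
            expected[(t.tf_id, t.peak_id, t.target_id)] = c
    sub_keys = {c: state["subgrns"][c].triple_keys() for c in conds}
    recovered_specific = [k for k in expected if k in got_triples]
    n_correct = sum(
        1 for k in recovered_specific
        if k in sub_keys[expected[k]]
        and all(k not in sub_keys[c] for c in conds if c != expected[k]))
    assignment_acc = (n_correct / len(recovered_specific)
                      if recovered_specific else 0.0)

    # planted key TFs flagged is_key in their condition
    kr = state["key_results"]
    recovered_keys = 0
    n_planted_keys = 0
    for cond, tfs in truth.key_tfs_per_cluster.items():
        for tf in tfs:
            n_planted_keys += 1
            if len(kr):
                hit = kr[(kr["condition"] == cond) & (kr["tf_id"] == tf)
                         & kr["is_key"]]
                recovered_keys += int(len(hit) > 0)
    key_recovery = (recovered_keys / n_planted_keys
                    if n_planted_keys else 1.0)

    return {
        "role_accuracy": float(role_acc),
        "link_precision": links["precision"],
        "link_recall": links["recall"],
        "footprint_accuracy": float(footprint_acc),
        "triple_precision": triples["precision"],
        "triple_recall": triples["recall"],
        "triple_f1": triples["f1"],
        "subgrn_assignment_accuracy": float(assignment_acc),
        "key_tf_recovery": float(key_recovery),
        "n_triples_called": triples["n_called"],
        "n_triples_planted": triples["n_planted"],
        "n_specific_recovered": len(recovered_specific),
    }


# ---------------------------------------------------------------------------
# null calibration

def null_rank_test_calibration(seed: int, n_features: int = 2000,
                               n_per_group: int = 150,
                               log2fc_min: float = 0.25,
                               adj_p_max: float = 0.05) -> dict:
    """Rank-test behaviour on no-effect negative-binomial counts.

    Returns the fraction of raw p < 0.05 (should sit near the nominal
    level) and the fraction surviving the DEG thresholds (should be
    ~none).
    """
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(np.log(3.0), 0.5, n_features))
    r = 1.0 / 0.3
    counts = rng.negative_binomial(
        r, r / (r + mu[None, :]), size=(2 * n_per_group, n_features))
    norm = normalize_log1p_cpm(counts)
    a, b = norm[:n_per_group], norm[n_per_group:]
    _, p = rank_test(a, b)
    lfc = seurat_log2fc(a, b)
    adj = bh_adjust(p)
    return {
        "frac_raw_p_below_05": float(np.mean(p < 0.05)),
        "frac_pass_deg_thresholds": float(np.mean(
            (np.abs(lfc) > log2fc_min) & (adj < adj_p_max))),
        "n_features": n_features,
    }


def null_motif_z_calibration(seed: int, n_cells: int = 600,
                             n_peaks: int = 400, n_motifs: int = 20,
                             n_background: int = 50) -> dict:
    """Motif z-score calibration on counts with no planted motif effect.

    Per-motif z across cells should be centred (|mean| < 0.1) with sd
    near 1; returns the fraction of motifs inside the calibration band.
    """
    rng = np.random.default_rng(seed)
    depth = np.exp(rng.normal(0, 0.3, n_cells))
    rates = 2.0 * np.exp(rng.normal(0, 0.4, n_peaks))
    counts = rng.poisson(np.outer(depth, rates))
    gc = rng.beta(5, 5, n_peaks)
    seqs = pd.Series({
        f"p{j}": "".join(rng.choice(
            list("ACGT"), 20,
            p=[(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]))
        for j, g in enumerate(gc)})
    mat = pd.DataFrame(
        {f"m{k}": np.isin(np.arange(n_peaks),
                          rng.choice(n_peaks, 40, replace=False))
         for k in range(n_motifs)}, index=seqs.index)
    matches = MotifMatchMatrix(matrix=mat, records=pd.DataFrame(
        columns=["peak_id", "motif_id", "offset", "strand", "score"]))
    bias = compute_expected_and_bias(counts, seqs)
    act = compute_deviations(counts, matches, bias,
                             n_background=n_background, seed=seed)
    means = act.z.mean(axis=0).to_numpy()
    sds = act.z.std(axis=0, ddof=1).to_numpy()
    ok = (np.abs(means) < 0.1) & (sds > 0.8) & (sds < 1.2)
    return {
        "frac_motifs_calibrated": float(np.mean(ok)),
        "max_abs_mean": float(np.max(np.abs(means))),
        "n_motifs": n_motifs,
    }
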