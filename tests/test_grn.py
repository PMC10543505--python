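"""Importance edges, triple assembly, sub-networks, key activators."""
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from multigrn import (FootprintSite, TFMotifRole, assemble_triples,
                      extract_enriched_subgrn, hypergeom_upper_tail,
                      key_activators, tf_target_importance)
from multigrn.features import FeatureCallSet
from multigrn.grn import SubGRN, key_results_frame


def hypergeom_tail_exact(N, K, n, k_obs):
    total = Fraction(0)
    for k in range(k_obs, min(K, n) + 1):
        total += Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))
    return float(total)


class TestHypergeom:
    def test_worked_example(self):
        # C(4,4) C(6,1) / C(10,5) = 6/252
        assert hypergeom_upper_tail(10, 4, 5, 4) == \
            pytest.approx(6 / 252, abs=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_tail(50, 10, 5, 0) == 1.0

    def test_all_successes_population(self):
        assert hypergeom_upper_tail(8, 8, 3, 2) == pytest.approx(1.0)

    def test_inconsistent_arguments_error(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 6, 2, 1)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(5, 2, 2, 3)

    def test_matches_exact_enumeration_small_populations(self):
        for N in range(1, 16):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(0, min(K, n) + 1, 2):
                        assert hypergeom_upper_tail(N, K, n, k) == \
                            pytest.approx(hypergeom_tail_exact(N, K, n, k),
                                          abs=1e-9)


def _expression(seed=1, n=2000, n_tfs=8):
    rng = np.random.default_rng(seed)
    tfs = {f"TF{i}": rng.normal(0, 1, n) for i in range(n_tfs)}
    df = pd.DataFrame(tfs)
    df["t_pos"] = 2.0 * df["TF0"] + rng.normal(0, 0.3, n)
    df["t_neg"] = -1.0 * df["TF1"] + rng.normal(0, 0.3, n)
    df["t_noise"] = rng.normal(0, 1, n)
    return df


class TestImportance:
    def test_planted_drivers_found_with_signs(self):
        df = _expression()
        edges = tf_target_importance(df, [f"TF{i}" for i in range(8)],
                                     target_ids=["t_pos", "t_neg", "t_noise"],
                                     seed=1)
        pos = edges[edges["gene_id"] == "t_pos"].sort_values(
            "importance", ascending=False)
        assert pos.iloc[0]["tf_id"] == "TF0"
        assert pos.iloc[0]["retained"] and pos.iloc[0]["sign"] == "positive"
        neg = edges[edges["gene_id"] == "t_neg"].sort_values(
            "importance", ascending=False)
        assert neg.iloc[0]["tf_id"] == "TF1"
        assert neg.iloc[0]["retained"] and neg.iloc[0]["sign"] == "negative"

    def test_importances_sum_to_one_per_target(self):
        df = _expression(seed=2)
        edges = tf_target_importance(df, [f"TF{i}" for i in range(8)],
                                     target_ids=["t_pos", "t_neg", "t_noise"],
                                     seed=2)
        sums = edges.groupby("gene_id")["importance"].sum()
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_noise_target_falls_below_global_cut(self):
        misses = 0
        for seed in range(1, 11):
            df = _expression(seed=seed)
            edges = tf_target_importance(
                df, [f"TF{i}" for i in range(8)],
                target_ids=["t_pos", "t_neg", "t_noise"], seed=seed)
            noise = edges[edges["gene_id"] == "t_noise"]
            if noise["retained"].any():
                misses += 1
        assert misses <= 1

    def test_deterministic_given_seed(self):
        df = _expression(seed=3, n=500)
        e1 = tf_target_importance(df, [f"TF{i}" for i in range(8)],
                                  target_ids=["t_pos"], seed=9)
        e2 = tf_target_importance(df, [f"TF{i}" for i in range(8)],
                                  target_ids=["t_pos"], seed=9)
        assert e1.equals(e2)

    def test_needs_two_tfs(self):
        with pytest.raises(ValueError, match="2 TFs"):
            tf_target_importance(pd.DataFrame({"a": [1.0, 2]}), ["a"])


def _site(tf, peak, score, motif=None):
    return FootprintSite(tf, motif or f"M_{tf}", peak, 10, "+",
                         nc=0.1, nl=0.1 + score / 2, nr=0.1 + score / 2)


def _links(pairs):
    return pd.DataFrame([{"peak_id": p, "gene_id": g, "r": r,
                          "retained": True} for p, g, r in pairs])


def _edges(rows):
    return pd.DataFrame([{"tf_id": t, "gene_id": g, "importance": i,
                          "sign": s, "retained": True}
                         for t, g, i, s in rows])


class TestAssembly:
    def test_consistent_activator_triple_retained(self):
        grn = assemble_triples(
            [_site("tfA", "pk1", 0.4)],
            _links([("pk1", "g1", 0.5)]),
            [TFMotifRole("tfA", "M_tfA", 0.3, "activator")],
            _edges([("tfA", "g1", 0.2, "positive")]),
            {"tfA"})
        assert len(grn) == 1
        row = grn.iloc[0]
        assert (row["tf_id"], row["peak_id"], row["target_id"]) == \
            ("tfA", "pk1", "g1")
        assert row["role"] == "activator" and row["sign"] == "positive"

    def test_direction_mismatch_dropped(self):
        grn = assemble_triples(
            [_site("tfA", "pk1", 0.4)],
            _links([("pk1", "g1", -0.5)]),
            [TFMotifRole("tfA", "M_tfA", 0.3, "activator")],
            _edges([("tfA", "g1", 0.2, "negative")]),
            {"tfA"})
        assert grn.empty

    def test_non_mg_tf_dropped(self):
        grn = assemble_triples(
            [_site("tfA", "pk1", 0.4)],
            _links([("pk1", "g1", 0.5)]),
            [TFMotifRole("tfA", "M_tfA", 0.3, "activator")],
            _edges([("tfA", "g1", 0.2, "positive")]),
            set())
        assert grn.empty

    def test_duplicate_sites_keep_max_footprint(self):
        grn = assemble_triples(
            [_site("tfA", "pk1", 0.2), _site("tfA", "pk1", 0.5)],
            _links([("pk1", "g1", 0.5)]),
            [TFMotifRole("tfA", "M_tfA", 0.3, "activator")],
            _edges([("tfA", "g1", 0.2, "positive")]),
            {"tfA"})
        assert len(grn) == 1
        assert grn.iloc[0]["footprint_score"] == pytest.approx(0.5)


def _deg_calls(rows):
    tab = pd.DataFrame(rows, columns=["feature_id", "group", "effect", "p",
                                      "adj_p"])
    tab["retained"] = True
    groups = {g: list(tab.loc[tab["group"] == g, "feature_id"])
              for g in tab["group"].unique()}
    return FeatureCallSet("DEG", "A-vs-B", groups, tab)


def _grn_frame(rows):
    return pd.DataFrame(rows, columns=["tf_id", "motif_id", "peak_id",
                                       "target_id", "role", "sign",
                                       "footprint_score", "ptg_r",
                                       "importance"])


class TestSubGRN:
    GRN = _grn_frame([
        ("tfA", "mA", "pk1", "g1", "activator", "positive", 0.5, 0.6, 0.2),
        ("tfR", "mR", "pk2", "g2", "repressor", "negative", 0.4, 0.5, 0.1),
    ])

    def test_up_tf_and_target_in_condition_a(self):
        degs = _deg_calls([("tfA", "actMG", 1.0, 1e-9, 1e-8),
                           ("g1", "actMG", 0.8, 1e-9, 1e-8)])
        sub = extract_enriched_subgrn(self.GRN, degs, pd.DataFrame(), "LD",
                                      ("LD", "NMDA"))
        assert sub.triple_keys() == {("tfA", "pk1", "g1")}

    def test_repressor_down_with_up_target(self):
        degs = _deg_calls([("tfR", "MGPC", -1.0, 1e-9, 1e-8),
                           ("g2", "MGPC", 0.9, 1e-9, 1e-8)])
        sub = extract_enriched_subgrn(self.GRN, degs, pd.DataFrame(), "LD",
                                      ("LD", "NMDA"))
        assert sub.triple_keys() == {("tfR", "pk2", "g2")}

    def test_significantly_closed_peak_excluded(self):
        degs = _deg_calls([("tfA", "actMG", 1.0, 1e-9, 1e-8),
                           ("g1", "actMG", 0.8, 1e-9, 1e-8)])
        dar = pd.DataFrame({"feature_id": ["pk1"], "group": ["MGPC"],
                            "effect": [-0.6], "p": [0.001]})
        sub = extract_enriched_subgrn(self.GRN, degs, dar, "LD",
                                      ("LD", "NMDA"))
        assert sub.triples.empty
        # under the point-estimate rule variant a negative but
        # non-significant effect also excludes
        dar2 = pd.DataFrame({"feature_id": ["pk1"], "group": ["MGPC"],
                             "effect": [-0.05], "p": [0.9]})
        sub2 = extract_enriched_subgrn(self.GRN, degs, dar2, "LD",
                                       ("LD", "NMDA"), peak_rule="sign")
        assert sub2.triples.empty
        sub3 = extract_enriched_subgrn(self.GRN, degs, dar2, "LD",
                                       ("LD", "NMDA"))
        assert len(sub3.triples) == 1

    def test_subgrn_is_subset_and_idempotent(self):
        degs = _deg_calls([("tfA", "actMG", 1.0, 1e-9, 1e-8),
                           ("g1", "actMG", 0.8, 1e-9, 1e-8)])
        sub = extract_enriched_subgrn(self.GRN, degs, pd.DataFrame(), "LD",
                                      ("LD", "NMDA"))
        assert sub.triple_keys() <= {
            (r.tf_id, r.peak_id, r.target_id)
            for r in self.GRN.itertuples(index=False)}
        again = extract_enriched_subgrn(
            sub.triples[self.GRN.columns], degs, pd.DataFrame(), "LD",
            ("LD", "NMDA"))
        assert again.triple_keys() == sub.triple_keys()


class TestKeyActivators:
    def _nets(self, total_pairs, sub_pairs):
        total = _grn_frame([
            (tf, "m", f"pk_{tf}_{g}", g, "activator", "positive", 0.5, 0.5,
             0.1) for tf, g in total_pairs])
        sub = SubGRN("LD", _grn_frame([
            (tf, "m", f"pk_{tf}_{g}", g, "activator", "positive", 0.5, 0.5,
             0.1) for tf, g in sub_pairs]))
        return total, sub

    def test_master_regulator_is_key(self):
        cluster = {f"g{i}" for i in range(10)}
        total_pairs = [("tf", f"g{i}") for i in range(20)]
        sub_pairs = [("tf", f"g{i}") for i in range(10)]     # all in cluster
        total, sub = self._nets(total_pairs, sub_pairs)
        res = key_activators(sub, total, {"c0": cluster})
        assert len(res) == 1
        r = res[0]
        assert r.is_key and r.p < 0.001
        assert r.p == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_coverage_arithmetic(self):
        cluster = {f"g{i}" for i in range(100)}
        total_pairs = [("tf", f"g{i}") for i in range(30)]
        sub_pairs = [("tf", "g0"), ("tf", "g1"), ("tf", "g2")]
        total, sub = self._nets(total_pairs, sub_pairs)
        res = key_activators(sub, total, {"c0": cluster})
        assert res[0].coverage == pytest.approx(0.03)

    def test_zero_overlap_not_key(self):
        cluster = {"x1", "x2"}
        total_pairs = [("tf", f"g{i}") for i in range(5)]
        sub_pairs = [("tf", "g0")]
        total, sub = self._nets(total_pairs, sub_pairs)
        res = key_activators(sub, total, {"c0": cluster})
        assert res[0].p == 1.0 and not res[0].is_key

    def test_empty_cluster_is_error(self):
        total, sub = self._nets([("tf", "g0")], [("tf", "g0")])
        with pytest.raises(ValueError, match="empty"):
            key_activators(sub, total, {"c0": set()})

    def test_results_frame_columns(self):
        total, sub = self._nets([("tf", "g0")], [("tf", "g0")])
        res = key_activators(sub, total, {"c0": {"g0"}})
        df = key_results_frame(res)
        assert {"tf_id", "cluster_id", "coverage", "p", "is_key"} \
            <= set(df.columns)
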