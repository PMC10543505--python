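"""Normalization, rank tests, BH, feature calls, binning, clustering."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from multigrn import (bh_adjust, bin_pseudotime, cluster_profiles_kmeans,
                      find_cegs, find_degs, find_dms, mature_marker_genes,
                      normalize_log1p_cpm, rank_test)
from multigrn.features import FeatureCallSet, find_dars


class TestNormalize:
    def test_zero_row_maps_to_zeros(self):
        out = normalize_log1p_cpm(np.array([[0, 0, 0], [1, 1, 0]]))
        assert np.all(out[0] == 0)

    def test_single_nonzero_entry(self):
        out = normalize_log1p_cpm(np.array([[0, 7, 0]]), scale=1e4)
        assert out[0, 1] == pytest.approx(np.log1p(1e4))

    def test_scale_invariance_under_doubling(self):
        x = np.array([[3, 5, 2]])
        assert np.allclose(normalize_log1p_cpm(x), normalize_log1p_cpm(2 * x))


class TestRankTest:
    def test_null_case_identical_groups(self):
        lfc, p = rank_test(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
        assert lfc == pytest.approx(0.0)
        assert p >= 0.99

    def test_exact_small_sample_p(self):
        # fully separated n=3 vs 3: exact two-sided p = 2/20
        lfc, p = rank_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1)

    def test_log2fc_of_doubled_mean(self):
        a = np.array([2.0, 2, 2, 2])
        b = np.array([1.0, 1, 1, 1])
        lfc, _ = rank_test(a, b)
        assert lfc == pytest.approx(1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            rank_test(np.array([1.0, 2]), np.array([1.0, 2, 3]))


class TestBH:
    def test_hand_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_agrees_with_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests
        p = np.random.default_rng(seed).uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(bh_adjust(p) - ref)) < 1e-12

    def test_preserves_ordering_and_dominates_p(self):
        p = np.random.default_rng(0).uniform(size=500)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _two_group_norm(n=60, n_genes=30, shift_gene=0, shift=3.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.poisson(5.0, size=(n, n_genes)).astype(float)
    b = rng.poisson(5.0, size=(n, n_genes)).astype(float)
    a[:, shift_gene] *= np.exp(shift)
    return normalize_log1p_cpm(a), normalize_log1p_cpm(b)


class TestMatureMarkers:
    def test_exclusive_gene_is_marker_uniform_is_not(self):
        rng = np.random.default_rng(0)
        n = 120
        counts = rng.poisson(4.0, size=(n, 10)).astype(float)
        types = pd.Series(["rod"] * 40 + ["other"] * 80)
        counts[:40, 0] *= 40.0          # rod-only gene
        norm = normalize_log1p_cpm(counts)
        markers = mature_marker_genes(norm, [f"g{i}" for i in range(10)],
                                      types, ["rod"])
        assert "g0" in markers
        assert "g1" not in markers

    def test_empty_type_list_gives_empty_set(self):
        norm = normalize_log1p_cpm(np.ones((10, 3)))
        assert mature_marker_genes(norm, ["a", "b", "c"],
                                   pd.Series(["x"] * 10), []) == set()


class TestDegCalls:
    def _groups(self, n):
        return pd.Series(["actMG"] * n)

    def test_planted_shift_called_and_marker_excluded(self):
        na, nb = _two_group_norm(shift_gene=2, shift=2.0, seed=1)
        ids = [f"g{i}" for i in range(na.shape[1])]
        calls = find_degs(na, nb, self._groups(len(na)), self._groups(len(nb)),
                          ids, cell_groups=("actMG",))
        assert "g2" in calls.retained_in("actMG")
        calls2 = find_degs(na, nb, self._groups(len(na)),
                           self._groups(len(nb)), ids,
                           cell_groups=("actMG",), mature_markers={"g2"})
        assert "g2" not in calls2.retained_in("actMG")
        excl = calls2.table
        assert (excl.loc[excl["feature_id"] == "g2", "excluded_by"]
                == "mature_marker").any()

    def test_threshold_boundary_is_strict(self):
        # construct a fold change of exactly 0.25 on the tested
        # (de-logged) scale: mean(expm1(b)) + 1 = 2, mean(expm1(a)) + 1
        # = 2^1.25
        a = np.full((50, 1), np.log(2.0 ** 1.25))
        b = np.full((50, 1), np.log(2.0))
        calls = find_degs(a, b, pd.Series(["g"] * 50), pd.Series(["g"] * 50),
                          ["x"], cell_groups=("g",))
        row = calls.table.iloc[0]
        assert row["effect"] == pytest.approx(0.25, abs=1e-9)
        assert not row["retained"]

    def test_ceg_requires_both_conditions(self):
        rng = np.random.default_rng(2)
        n = 150
        groups = pd.Series(["MGPC"] * 50 + ["other"] * 100)
        base_a = rng.poisson(5.0, size=(n, 6)).astype(float)
        base_b = rng.poisson(5.0, size=(n, 6)).astype(float)
        base_a[:50, 0] *= 8; base_b[:50, 0] *= 8      # both conditions
        base_a[:50, 1] *= 8                           # condition A only
        ids = [f"g{i}" for i in range(6)]
        calls = find_cegs(normalize_log1p_cpm(base_a),
                          normalize_log1p_cpm(base_b),
                          groups, groups, ids, trajectory_groups=("MGPC",))
        kept = calls.retained_in("MGPC")
        assert "g0" in kept and "g1" not in kept and "g5" not in kept


class TestDarCalls:
    def test_link_filter_removes_unlinked_differential_peak(self):
        na, nb = _two_group_norm(n=80, n_genes=4, shift_gene=0, shift=2.0,
                                 seed=3)
        na2, nb2 = _two_group_norm(n=80, n_genes=4, shift_gene=1, shift=2.0,
                                   seed=4)
        # peaks p0 (linked to a DEG) and p1 (linked to a non-DEG)
        links = pd.DataFrame({"peak_id": ["p0", "p1"],
                              "gene_id": ["deg1", "boring"]})
        groups = pd.Series(["actMG"] * 80)
        calls = find_dars(na, nb, groups, groups,
                          [f"p{i}" for i in range(4)],
                          deg_genes={"deg1"}, peak_links=links,
                          cell_groups=("actMG",))
        kept = calls.retained_in("actMG")
        assert "p0" in kept
        assert "p1" not in kept
        tab = calls.table
        assert (tab.loc[tab["feature_id"] == "p1", "excluded_by"]
                == "no_deg_target").any()


class TestDmCalls:
    def _setup(self):
        rng = np.random.default_rng(5)
        n = 100
        motifs = ["mA", "mA2", "mB"]
        za = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=motifs)
        zb = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=motifs)
        za["mA"] += 1.0; za["mA2"] += 1.0; za["mB"] += 1.0
        groups = pd.Series(["actMG"] * n)
        deg_tab = pd.DataFrame({
            "feature_id": ["TFA"], "group": ["actMG"], "effect": [1.0],
            "p": [1e-6], "adj_p": [1e-5], "retained": [True]})
        degs = FeatureCallSet("DEG", "A-vs-B", {"actMG": ["TFA"]}, deg_tab)
        motif_tf = {"mA": "TFA", "mA2": "TFA", "mB": "TFB"}
        corr = {"mA": 0.4, "mA2": 0.2, "mB": 0.5}
        return za, zb, groups, degs, motif_tf, corr

    def test_consistency_and_best_motif_rules(self):
        za, zb, groups, degs, motif_tf, corr = self._setup()
        calls = find_dms(za, zb, groups, groups, degs, motif_tf, corr,
                         cell_groups=("actMG",))
        kept = calls.retained_in("actMG")
        assert kept == {"mA"}          # mB: TF not a DEG; mA2: lower |corr|


class TestBinning:
    def test_uniform_cells_fill_bins_evenly(self):
        t = pd.Series(np.repeat(np.linspace(0, 1, 20), 5))
        mat = pd.DataFrame({"f": np.ones(100)})
        out = bin_pseudotime(t, {"m": mat}, n_bins=20, smooth_window=1)
        assert np.all(out.bin_counts == 5)

    def test_constant_feature_flagged_zero(self):
        t = pd.Series(np.linspace(0, 1, 100))
        mat = pd.DataFrame({"const": np.ones(100), "lin": np.arange(100.0)})
        out = bin_pseudotime(t, {"m": mat}, n_bins=25, smooth_window=1)
        prof = out.matrices["m"]
        assert np.all(prof.loc["const"].to_numpy() == 0)
        assert ("m", ["const"]) in out.flagged["constant_features"]
        assert np.all(np.diff(prof.loc["lin"].to_numpy()) > 0)

    def test_bin_range_enforced(self):
        t = pd.Series(np.linspace(0, 1, 30))
        with pytest.raises(ValueError, match="20"):
            bin_pseudotime(t, {}, n_bins=10)

    def test_empty_bins_interpolated_and_flagged(self):
        t = pd.Series(np.concatenate([np.linspace(0, 0.4, 50),
                                      np.linspace(0.8, 1.0, 50)]))
        mat = pd.DataFrame({"f": t.to_numpy()})
        out = bin_pseudotime(t, {"m": mat}, n_bins=20, smooth_window=1)
        assert "empty_bins" in out.flagged
        assert np.isfinite(out.matrices["m"].to_numpy()).all()


class TestKmeans:
    def test_recovers_two_planted_shapes(self):
        rng = np.random.default_rng(0)
        early = np.exp(-((np.linspace(0, 1, 30) - 0.2) ** 2) / 0.02)
        late = np.exp(-((np.linspace(0, 1, 30) - 0.8) ** 2) / 0.02)
        rows, truth = [], []
        for i in range(40):
            shape = early if i % 2 == 0 else late
            rows.append(shape + rng.normal(0, 0.05, 30))
            truth.append(i % 2)
        profiles = pd.DataFrame(rows)
        labels = cluster_profiles_kmeans(profiles, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_zero_inertia(self):
        profiles = pd.DataFrame(np.eye(5))
        labels = cluster_profiles_kmeans(profiles, k=5, seed=0)
        assert labels.nunique() == 5

    def test_deterministic_given_seed(self):
        profiles = pd.DataFrame(np.random.default_rng(3).normal(size=(30, 10)))
        l1 = cluster_profiles_kmeans(profiles, k=3, seed=7)
        l2 = cluster_profiles_kmeans(profiles, k=3, seed=7)
        assert l1.equals(l2)
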