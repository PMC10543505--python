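"""TF-motif roles, peak categorization, aggregates, links, footprints."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multigrn import (aggregate_cells, categorize_peaks, classify_tf_motifs,
                      footprint_sites, footprint_stats, peak_to_gene)
from multigrn.motifs import MotifMatchMatrix


class TestRoles:
    def _frames(self, r_target, n=4000, seed=0):
        # mixture construction: corr(x, y) == weight on the shared part
        rng = np.random.default_rng(seed)
        shared = rng.normal(size=n)
        x = shared
        y = r_target * shared + np.sqrt(1 - r_target ** 2) \
            * rng.normal(size=n)
        return (pd.DataFrame({"tf1": x}), pd.DataFrame({"m1": y}),
                {"m1": "tf1"})

    def test_positive_correlation_is_activator(self):
        expr, z, m2t = self._frames(0.3)
        roles = classify_tf_motifs(expr, z, m2t)
        assert len(roles) == 1 and roles[0].role == "activator"
        assert roles[0].pearson_r > 0.05

    def test_negative_correlation_is_repressor(self):
        expr, z, m2t = self._frames(-0.3)
        roles = classify_tf_motifs(expr, z, m2t)
        assert roles[0].role == "repressor"

    def test_dead_zone_dropped(self):
        expr, z, m2t = self._frames(0.0, seed=3)
        assert classify_tf_motifs(expr, z, m2t) == []

    def test_negating_activity_flips_role_and_r(self):
        expr, z, m2t = self._frames(0.4, seed=5)
        fwd = classify_tf_motifs(expr, z, m2t)[0]
        rev = classify_tf_motifs(expr, -z, m2t)[0]
        assert fwd.role == "activator" and rev.role == "repressor"
        assert rev.pearson_r == pytest.approx(-fwd.pearson_r)

    def test_zero_variance_dropped(self):
        expr = pd.DataFrame({"tf1": np.ones(10)})
        z = pd.DataFrame({"m1": np.arange(10.0)})
        assert classify_tf_motifs(expr, z, {"m1": "tf1"}) == []


def _gene_models():
    return pd.DataFrame({
        "gene_id": ["gA", "gB"], "chrom": ["chr1", "chr1"],
        "strand": ["+", "+"], "tss": [1000, 60_000],
        "body_start": [1000, 60_000], "body_end": [8000, 65_000],
        "is_tf": [False, False], "is_mito": [False, False]})


class TestCategorize:
    def test_promoter_overlap(self):
        peaks = pd.DataFrame({"peak_id": ["p"], "chrom": ["chr1"],
                              "start": [900], "end": [1401]})
        cats, cand = categorize_peaks(peaks, _gene_models())
        assert cats.loc[0, "category"] == "promoter"
        assert set(cand["gene_id"]) == {"gA"}

    def test_gene_body_without_promoter_contact(self):
        peaks = pd.DataFrame({"peak_id": ["p"], "chrom": ["chr1"],
                              "start": [3000], "end": [3501]})
        cats, cand = categorize_peaks(peaks, _gene_models())
        assert cats.loc[0, "category"] == "gene_body"
        assert set(cand["gene_id"]) == {"gA"}

    def test_intergenic_within_window(self):
        peaks = pd.DataFrame({"peak_id": ["p"], "chrom": ["chr1"],
                              "start": [150_000 + 60_000 - 250],
                              "end": [150_000 + 60_000 + 251]})
        cats, cand = categorize_peaks(peaks, _gene_models())
        assert cats.loc[0, "category"] == "intergenic"
        assert set(cand["gene_id"]) == {"gB"}   # 150 kb < 200 kb from gB only

    def test_unknown_chromosome_has_no_candidates(self):
        peaks = pd.DataFrame({"peak_id": ["p"], "chrom": ["chrZ"],
                              "start": [0], "end": [501]})
        cats, cand = categorize_peaks(peaks, _gene_models())
        assert cats.loc[0, "category"] == "intergenic"
        assert cand.empty


class TestAggregates:
    def test_shapes_and_determinism(self, small_sim):
        _, _, ds = small_sim
        r1, a1, m1 = aggregate_cells(ds, n_aggregates=20, seed=3)
        r2, a2, m2 = aggregate_cells(ds, n_aggregates=20, seed=3)
        assert r1.shape[0] == 20 and a1.shape == (20, len(ds.peak_ids))
        assert np.array_equal(m1, m2)
        assert r1.equals(r2)
        # neighbourhood scaled down for small datasets
        assert m1.shape[1] == max(10, int(round(100 * ds.n_cells / 10_000)))

    def test_aggregate_sums_conserve_member_counts(self, small_sim):
        _, _, ds = small_sim
        _, _, members = aggregate_cells(ds, n_aggregates=5, seed=1)
        raw = np.vstack([np.asarray(ds.rna[m].sum(axis=0)).ravel()
                         for m in members])
        expected = np.vstack([
            np.asarray(ds.rna[m].sum(axis=0)).ravel() for m in members])
        assert np.array_equal(raw, expected)


class TestPeakToGene:
    def _aggregates(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=n)
        atac = pd.DataFrame({
            "pk_true": 2 + latent + rng.normal(0, 0.8, n),
            "pk_null": rng.normal(size=n),
        })
        rna = pd.DataFrame({
            "g_true": 1 + latent + rng.normal(0, 0.8, n),
            "g_null": rng.normal(size=n),
        })
        cand = pd.DataFrame({
            "peak_id": ["pk_true", "pk_null"],
            "gene_id": ["g_true", "g_null"],
            "category": ["intergenic", "intergenic"]})
        return rna, atac, cand

    def test_planted_pair_retained_null_dropped(self):
        rna, atac, cand = self._aggregates()
        links = peak_to_gene(rna, atac, cand)
        by_peak = links.set_index("peak_id")
        assert by_peak.loc["pk_true", "retained"]
        assert not by_peak.loc["pk_null", "retained"]

    def test_decoy_rejected_across_seeds(self):
        hits = 0
        for seed in range(20):
            rna, atac, cand = self._aggregates(seed=seed)
            links = peak_to_gene(rna, atac, cand)
            hits += int(links.set_index("peak_id").loc["pk_null", "retained"])
        assert hits <= 1

    def test_sub_threshold_r_dropped_regardless_of_p(self):
        # r ~ 0.2 with n=5000 aggregates: p is tiny but |r| <= 0.25
        n = 5000
        rng = np.random.default_rng(1)
        latent = rng.normal(size=n)
        atac = pd.DataFrame({"pk": 0.2 * latent
                             + np.sqrt(1 - 0.04) * rng.normal(size=n)})
        rna = pd.DataFrame({"g": latent})
        cand = pd.DataFrame({"peak_id": ["pk"], "gene_id": ["g"],
                             "category": ["intergenic"]})
        links = peak_to_gene(rna, atac, cand)
        assert links.loc[0, "p"] < 1e-10
        assert not links.loc[0, "retained"]

    def test_p_matches_t_transform_oracle(self):
        from scipy import stats
        rna, atac, cand = self._aggregates(seed=5)
        links = peak_to_gene(rna, atac, cand)
        r = links.loc[0, "r"]
        n = len(rna)
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        assert links.loc[0, "p"] == pytest.approx(
            2 * stats.t.sf(abs(t), df=n - 2))


def _match_records(rows):
    rec = pd.DataFrame(rows, columns=["peak_id", "motif_id", "offset",
                                      "strand", "score"])
    mat = pd.DataFrame(index=rec["peak_id"].unique())
    return MotifMatchMatrix(matrix=mat, records=rec)


def _signal_frame(vectors):
    w = 4
    rows = []
    for (motif, peak, off), v in vectors.items():
        rows.append((motif, peak, off, *v))
    return pd.DataFrame(rows, columns=["motif_id", "peak_id", "offset"]
                        + [f"s{i}" for i in range(7 * w)])


class TestFootprints:
    W = 4

    def _vector(self, nl, nc, nr):
        w = self.W
        return np.concatenate([np.full(3 * w, nl), np.full(w, nc),
                               np.full(3 * w, nr)])

    def _run(self, vec, expressed=("tf1",)):
        matches = _match_records([("pk", "m1", 10, "+", 5.0)])
        signal = _signal_frame({("m1", "pk", 10): vec})
        return footprint_sites(matches, {"pk"}, signal, set(expressed),
                               {"m1": "tf1"}, {"m1": self.W})

    def test_protected_site_retained_with_score(self):
        sites = self._run(self._vector(0.6, 0.2, 0.5))
        assert len(sites) == 1
        assert sites[0].score == pytest.approx(0.7)

    def test_flat_signal_dropped(self):
        assert self._run(self._vector(0.4, 0.4, 0.4)) == []

    def test_boundary_score_not_retained(self):
        # NL=0.3, NR=0.2, NC=0.25 -> score exactly 0.0
        assert self._run(self._vector(0.3, 0.25, 0.2)) == []

    def test_unexpressed_tf_dropped(self):
        assert self._run(self._vector(0.6, 0.2, 0.5), expressed=()) == []

    def test_stats_match_bruteforce_index_ranges(self, rng):
        for w in (4, 6, 8):
            v = rng.normal(size=7 * w)
            nc, nl, nr = footprint_stats(v, w)
            assert nl == pytest.approx(v[:3 * w].mean())
            assert nc == pytest.approx(v[3 * w:4 * w].mean())
            assert nr == pytest.approx(v[4 * w:].mean())

    def test_wrong_length_is_error_naming_site(self):
        matches = _match_records([("pk", "m1", 10, "+", 5.0)])
        signal = _signal_frame({("m1", "pk", 10): np.ones(28)})
        with pytest.raises(ValueError, match="pk"):
            footprint_sites(matches, {"pk"}, signal, {"tf1"},
                            {"m1": "tf1"}, {"m1": 8})

    @settings(max_examples=30, deadline=None)
    @given(st.floats(-50, 50), st.integers(0, 2 ** 31 - 1))
    def test_score_invariant_under_constant_shift(self, c, seed):
        w = 6
        v = np.random.default_rng(seed).normal(size=7 * w)
        nc1, nl1, nr1 = footprint_stats(v, w)
        nc2, nl2, nr2 = footprint_stats(v + c, w)
        s1 = nl1 + nr1 - 2 * nc1
        s2 = nl2 + nr2 - 2 * nc2
        assert s1 == pytest.approx(s2, abs=1e-9)
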