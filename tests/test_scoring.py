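"""Signature scoring, classification, and interval-overlap tests against
quadratic brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import plasticore as pc
from conftest import random_fragments, random_intervals
from plasticore.io import merge_intervals
from plasticore.normalize import NormalizedMatrix
from plasticore.scoring import (
    aggregate_gene_accessibility,
    gene_activity_matrix,
    gene_window,
    lineage_specific_sets,
    mean_expression_score,
    per_cell_region_score,
    rank_classifier,
    region_set_fragment_counts,
    tss_window,
    tss_window_signal,
)


def _norm(dense):
    nf, nc = np.asarray(dense).shape
    return NormalizedMatrix(
        sp.csr_matrix(np.asarray(dense, dtype=float)),
        [f"g{i}" for i in range(nf)],
        [f"c{j}" for j in range(nc)],
        "none",
    )


def overlap_oracle(fragments, regions, cell_ids):
    """O(n^2) half-open overlap counter over merged regions."""
    merged = merge_intervals(regions)
    out = np.zeros((len(merged), len(cell_ids)), dtype=int)
    cell_idx = {c: i for i, c in enumerate(cell_ids)}
    for f in fragments:
        if f.barcode not in cell_idx:
            continue
        for ri, r in enumerate(merged):
            if f.chrom == r.chrom and max(f.start, r.start) < min(f.end, r.end):
                out[ri, cell_idx[f.barcode]] += f.count
    return merged, out


class TestMeanExpressionScore:
    def test_single_gene_signature(self):
        norm = _norm([[1.0, 2.0], [5.0, 7.0]])
        scores, frac = mean_expression_score(norm, pc.SignatureSet("s", ["g1"]))
        assert list(scores) == [5.0, 7.0] and frac == 1.0

    def test_all_zero_matrix(self):
        norm = _norm(np.zeros((3, 4)))
        scores, _ = mean_expression_score(norm, pc.SignatureSet("s", ["g0", "g2"]))
        assert (scores == 0).all()

    def test_matches_mean_oracle_and_reports_missing(self, rng):
        dense = rng.random((50, 10))
        norm = _norm(dense)
        genes = [f"g{i}" for i in rng.choice(50, size=20, replace=False)]
        sig = pc.SignatureSet("s", genes + ["absent_gene"])
        scores, frac = mean_expression_score(norm, sig)
        rows = [int(g[1:]) for g in genes]
        np.testing.assert_allclose(scores, dense[rows].mean(axis=0), atol=1e-12)
        assert frac == pytest.approx(20 / 21)

    def test_no_gene_present_rejected(self):
        with pytest.raises(ValueError):
            mean_expression_score(_norm(np.ones((2, 2))), pc.SignatureSet("s", ["nope"]))


class TestRegionFragmentCounts:
    def test_half_open_boundary(self):
        region = [pc.GenomicInterval("chr1", 200, 300)]
        touch = [pc.FragmentRecord("chr1", 100, 200, "c")]
        cross = [pc.FragmentRecord("chr1", 150, 250, "c")]
        assert region_set_fragment_counts(touch, region, ["c"]).to_dense().sum() == 0
        assert region_set_fragment_counts(cross, region, ["c"]).to_dense().sum() == 1

    def test_matches_quadratic_oracle(self, rng):
        cells = [f"c{i}" for i in range(4)]
        for _ in range(10):
            regions = random_intervals(rng, 50)
            frags = random_fragments(rng, 1000, cells)
            merged, expected = overlap_oracle(frags, regions, cells)
            got = region_set_fragment_counts(frags, regions, cells)
            assert got.feature_ids == [r.key() for r in merged]
            np.testing.assert_array_equal(got.to_dense(), expected)

    def test_fragment_spanning_two_regions_counts_in_each(self):
        regions = [
            pc.GenomicInterval("chr1", 100, 200),
            pc.GenomicInterval("chr1", 300, 400),
        ]
        frags = [pc.FragmentRecord("chr1", 150, 350, "c")]
        out = region_set_fragment_counts(frags, regions, ["c"])
        assert out.to_dense().ravel().tolist() == [1, 1]


class TestPerCellRegionScore:
    def test_uniform_counts_equal_scores(self):
        mat = pc.CellFeatureMatrix(
            sp.csr_matrix(np.ones((3, 4))), ["r0", "r1", "r2"], list("abcd"), "atac_peak"
        )
        s = per_cell_region_score(mat)
        assert s.nunique() == 1

    def test_enriched_nucleus_scores_higher(self):
        dense = np.array([[1, 4], [1, 4], [2, 2]])  # cell 2 doubles set proportions
        mat = pc.CellFeatureMatrix(sp.csr_matrix(dense), ["r0", "r1", "r2"], ["a", "b"], "atac_peak")
        s = per_cell_region_score(mat)
        assert s["b"] > s["a"]

    def test_none_normalization_is_column_mean(self):
        dense = np.array([[1, 2], [3, 4], [5, 6]])
        mat = pc.CellFeatureMatrix(sp.csr_matrix(dense), ["r0", "r1", "r2"], ["a", "b"], "atac_peak")
        s = per_cell_region_score(mat, normalize="none")
        np.testing.assert_allclose(s, [3.0, 4.0])


class TestGeneWindows:
    def test_plus_strand_window_clipped(self):
        g = pc.GenomicInterval("chr1", 1000, 2000, "+", "gA")
        w = gene_window(g, flank=2000)
        assert (w.start, w.end) == (0, 2000)
        frag = pc.FragmentRecord("chr1", 500, 600, "c")
        mat = gene_activity_matrix([frag], [g], ["c"])
        assert mat.to_dense()[0, 0] == 1

    def test_minus_strand_downstream_flank(self):
        g = pc.GenomicInterval("chr1", 1000, 2000, "-", "gA")
        w = gene_window(g, flank=2000)
        assert (w.start, w.end) == (1000, 4000)
        frag = pc.FragmentRecord("chr1", 2100, 2200, "c")
        assert gene_activity_matrix([frag], [g], ["c"]).to_dense()[0, 0] == 1

    def test_outside_window_contributes_zero(self):
        g = pc.GenomicInterval("chr1", 1000, 2000, "+", "gA")
        frag = pc.FragmentRecord("chr2", 1500, 1600, "c")
        assert gene_activity_matrix([frag], [g], ["c"]).to_dense().sum() == 0

    def test_unstranded_gene_rejected(self):
        g = pc.GenomicInterval("chr1", 1000, 2000, ".", "gA")
        with pytest.raises(ValueError, match="strand"):
            gene_activity_matrix([], [g], ["c"])

    def test_matches_quadratic_oracle(self, rng):
        cells = ["c0", "c1", "c2"]
        genes = [
            pc.GenomicInterval(
                "chr1", int(s), int(s) + 800, "+" if i % 2 == 0 else "-", f"g{i}"
            )
            for i, s in enumerate(rng.integers(2100, 4000, size=20))
        ]
        frags = random_fragments(rng, 400, cells, chroms=("chr1",))
        got = gene_activity_matrix(frags, genes, cells, flank=2000)
        cell_idx = {c: i for i, c in enumerate(cells)}
        expected = np.zeros((len(genes), 3), dtype=int)
        for gi, g in enumerate(genes):
            w = gene_window(g, 2000)
            for f in frags:
                if f.chrom == w.chrom and max(f.start, w.start) < min(f.end, w.end):
                    expected[gi, cell_idx[f.barcode]] += f.count
        np.testing.assert_array_equal(got.to_dense(), expected)

    def test_per_sample_pooling(self, rng):
        genes = [pc.GenomicInterval("chr1", 1000, 2000, "+", "gA")]
        frags = [
            pc.FragmentRecord("chr1", 1100, 1200, "x", 2),
            pc.FragmentRecord("chr1", 1300, 1400, "y", 1),
        ]
        mat = gene_activity_matrix(
            frags, genes, per="sample", sample_of_barcode={"x": "s1", "y": "s1"}
        )
        assert mat.cell_ids == ["s1"] and mat.to_dense()[0, 0] == 3


class TestTssWindow:
    def test_plus_strand_window(self):
        g = pc.GenomicInterval("chr1", 1000, 5000, "+", "gA")
        w = tss_window(g)
        assert (w.start, w.end) == (700, 1500)

    def test_minus_strand_window(self):
        g = pc.GenomicInterval("chr1", 1000, 2000, "-", "gA")
        w = tss_window(g)
        assert (w.start, w.end) == (1500, 2300)

    def test_uniform_coverage_proportional_to_width(self):
        genes = [
            pc.GenomicInterval("chr1", 5000, 9000, "+", "gA"),
            pc.GenomicInterval("chr1", 20000, 24000, "-", "gB"),
        ]
        frags = [
            pc.FragmentRecord("chr1", s, s + 1, "c") for s in range(0, 30000)
        ]
        sig = tss_window_signal(frags, genes)
        assert sig["gA"] == 800 and sig["gB"] == 800


class TestRankClassifier:
    def test_exclusive_expression(self):
        dense = np.array([[5.0, 0.0], [4.0, 0.0], [0.0, 3.0], [0.0, 2.0], [0.1, 0.1]])
        norm = _norm(dense)
        sigs = [pc.SignatureSet("T2", ["g0", "g1"]), pc.SignatureSet("T1", ["g2", "g3"])]
        out = rank_classifier(norm, sigs)
        assert list(out["label"]) == ["T2", "T1"]

    def test_symmetric_expression_is_undetermined(self):
        dense = np.array([[2.0], [2.0], [2.0], [2.0], [1.0]])
        norm = _norm(dense)
        sigs = [pc.SignatureSet("A", ["g0", "g1"]), pc.SignatureSet("B", ["g2", "g3"])]
        out = rank_classifier(norm, sigs)
        assert out["label"].iloc[0] == "Undetermined"

    def test_matches_midrank_oracle(self, rng):
        from scipy.stats import rankdata

        dense = rng.integers(0, 6, size=(40, 100)).astype(float)
        norm = _norm(dense)
        sigs = [
            pc.SignatureSet("A", [f"g{i}" for i in range(0, 8)]),
            pc.SignatureSet("B", [f"g{i}" for i in range(8, 16)]),
            pc.SignatureSet("C", [f"g{i}" for i in range(16, 24)]),
        ]
        out = rank_classifier(norm, sigs)
        for j in range(100):
            r = rankdata(dense[:, j])
            means = {s.name: np.mean([r[int(g[1:])] for g in s.members]) for s in sigs}
            best = max(means.values())
            tied = [k for k, v in means.items() if abs(v - best) <= 1e-12]
            expected = tied[0] if len(tied) == 1 else "Undetermined"
            assert out["label"].iloc[j] == expected

    def test_monotone_transform_invariance(self, rng):
        dense = rng.random((30, 20))
        sigs = [
            pc.SignatureSet("A", [f"g{i}" for i in range(5)]),
            pc.SignatureSet("B", [f"g{i}" for i in range(5, 10)]),
        ]
        a = rank_classifier(_norm(dense), sigs)["label"]
        b = rank_classifier(_norm(np.expm1(dense * 3)), sigs)["label"]
        assert (a == b).all()


class TestAggregateGeneAccessibility:
    def test_composition_identity(self, rng):
        cells = ["c0", "c1"]
        regions = random_intervals(rng, 10)
        frags = random_fragments(rng, 200, cells)
        a = aggregate_gene_accessibility(frags, regions, cells)
        counts = region_set_fragment_counts(frags, regions, cells)
        b = per_cell_region_score(counts)
        pd.testing.assert_series_equal(a, b, check_names=False)

    def test_signature_cells_score_higher(self, multiome):
        truth = multiome["truth"]
        sig_regions = [
            s for s in multiome["signatures"]["regions"] if s.name == "ILC2"
        ][0].members
        cells = multiome["rna"].cell_ids
        scores = aggregate_gene_accessibility(multiome["fragments"], sig_regions, cells)
        ilc2 = truth.labels == "ILC2"
        _, auc, _ = pc.rank_sum_auc(scores[ilc2.values], scores[~ilc2.values], "greater")
        assert auc > 0.95


class TestLineageSpecificSets:
    def test_block_matrix_recovery(self):
        rng = np.random.default_rng(0)
        block1 = np.hstack([np.full((10, 2), 5.0), np.full((10, 2), 0.0)])
        block2 = np.hstack([np.full((10, 2), 0.0), np.full((10, 2), 5.0)])
        signal = pd.DataFrame(
            np.vstack([block1, block2]) + rng.normal(0, 0.01, size=(20, 4)),
            index=[f"p{i}" for i in range(20)],
            columns=["ILC1_a", "ILC1_b", "ILC2_a", "ILC2_b"],
        )
        sets = lineage_specific_sets(signal, k_clusters=2)
        assert sorted(sets) == ["ILC1_a", "ILC2_a"] or len(sets) == 2
        members = {name: set(s.members) for name, s in sets.items()}
        groups = list(members.values())
        assert {f"p{i}" for i in range(10)} in groups
        assert {f"p{i}" for i in range(10, 20)} in groups

    def test_zero_variance_rows_rejected(self):
        signal = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="zero variance"):
            lineage_specific_sets(signal, 2)

    def test_permutation_invariance(self, rng):
        signal = pd.DataFrame(
            rng.random((15, 3)) + np.repeat([[0], [3], [6]], 5, axis=0),
            index=[f"p{i}" for i in range(15)],
            columns=list("abc"),
        )
        sets_a = lineage_specific_sets(signal, 3)
        perm = rng.permutation(15)
        sets_b = lineage_specific_sets(signal.iloc[perm], 3)
        for name in sets_a:
            assert set(sets_a[name].members) == set(sets_b[name].members)

    def test_k_exceeds_features_rejected(self):
        signal = pd.DataFrame(np.random.default_rng(0).random((3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="exceeds"):
            lineage_specific_sets(signal, 5)
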