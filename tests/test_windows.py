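import numpy as np
import pandas as pd
import pytest

from sweepscan.datatypes import Feature, FeatureSet, Region, RegionSet, ScoreTrack
from sweepscan.io_formats import RegionTableFixture, load_region_table_fixture
from sweepscan.windows import (annotate_regions, classify_windows,
                               consensus_regions, count_region_genes,
                               make_windows, merge_windows_to_regions)

from _oracles import brute_classify, brute_consensus


def track(test, positions, mlog10p, contrast=None, chrom="1"):
    n = len(positions)
    return ScoreTrack(test, contrast, pd.DataFrame({
        "chrom": chrom, "pos_bp": positions,
        "marker_id": [f"m{i}" for i in range(n)],
        "raw": 0.0, "score": 0.0, "mlog10p": mlog10p}))


class TestMakeWindows:
    @pytest.mark.parametrize("length,expected", [
        (2_000_000, 101), (1_000_000, 1), (900_000, 0)])
    def test_window_counts(self, length, expected):
        assert len(make_windows({"1": length})) == expected

    def test_grid_alignment(self):
        ws = make_windows({"1": 1_500_000})
        assert all(w.start_bp % 10_000 == 0 for w in ws)
        assert all(w.end_bp - w.start_bp == 1_000_000 for w in ws)

    def test_size_step_mismatch(self):
        with pytest.raises(ValueError):
            make_windows({"1": 2_000_000}, size=1_000_000, step=30_000)


class TestClassifyWindows:
    def test_per_test_marker_minima(self):
        ws = make_windows({"1": 1_000_000})
        pos = [100_000, 200_000, 300_000]
        ihs = classify_windows(ws, track("iHS", pos, [3.1, 3.5, 4.2]))
        assert ihs[0].significant and ihs[0].n_significant == 3
        rsb = classify_windows(ws, track("Rsb", pos, [3.1, 3.5, 4.2]))
        assert not rsb[0].significant  # Rsb needs 4 markers
        empty = classify_windows(ws, track("Rsb", [], []))
        assert not empty[0].significant

    def test_threshold_inclusive(self):
        ws = make_windows({"1": 1_000_000})
        t = track("iHS", [10_000, 20_000, 30_000], [3.0, 3.0, 3.0])
        assert classify_windows(ws, t)[0].significant

    def test_unknown_test_label(self):
        ws = make_windows({"1": 1_000_000})
        t = track("iHS", [1], [5.0])
        t.test = "nSL"  # bypass ScoreTrack validation deliberately
        with pytest.raises(ValueError, match="unknown test"):
            classify_windows(ws, t)

    def test_matches_naive_rescan(self, rng):
        ws = make_windows({"1": 3_000_000})
        pos = np.sort(rng.choice(np.arange(1, 3_000_001), 400, replace=False))
        p = rng.exponential(1.2, 400)
        t = track("Rsb", pos, p)
        out = classify_windows(ws, t)
        for w in out:
            n, sig = brute_classify(pos, p, w.start_bp, w.end_bp, 3.0, 4)
            assert (w.n_significant, w.significant) == (n, sig)


class TestMergeWindows:
    def test_single_window_region(self):
        ws = make_windows({"1": 2_000_000})
        t = track("iHS", [500_000, 500_500, 501_000], [4, 4, 4])
        regions = merge_windows_to_regions(classify_windows(ws, t), "iHS")
        assert len(regions) == 1
        r = list(regions)[0]
        assert r.length_bp >= 1_000_000
        assert r.start_bp % 10_000 == 0 and r.end_bp % 10_000 == 0

    def test_run_of_windows_gives_printed_granularity(self):
        # significant windows at starts 0..550k merge to one 1.55-Mb region
        ws = [w for w in make_windows({"1": 3_000_000})]
        for w in ws:
            w.significant = w.start_bp <= 550_000
        regions = merge_windows_to_regions(ws, "iHS")
        assert len(regions) == 1
        r = list(regions)[0]
        assert (r.start_bp, r.end_bp) == (0, 1_550_000)
        assert (r.end_bp - r.start_bp) / 1e6 == pytest.approx(1.55)

    def test_distant_windows_stay_apart(self):
        ws = [w for w in make_windows({"1": 5_000_000})]
        for w in ws:
            w.significant = w.start_bp in (0, 3_000_000)
        regions = merge_windows_to_regions(ws, "Rsb", "AFT")
        assert len(regions) == 2


class TestConsensus:
    def _regions(self, triplets, test, contrast="AFT"):
        return RegionSet([Region(c, s, e, frozenset({(test, contrast)}))
                          for c, s, e in triplets])

    def test_disjoint_intervals_no_consensus(self):
        a = self._regions([("1", 0, 1_000_000)], "Rsb")
        b = self._regions([("1", 2_000_000, 3_000_000)], "XPEHH")
        assert len(consensus_regions([a, b], 2)) == 0

    def test_same_test_does_not_count_twice(self):
        a = self._regions([("1", 0, 1_000_000)], "Rsb", "AFT")
        b = self._regions([("1", 500_000, 1_500_000)], "Rsb", "EUT")
        assert len(consensus_regions([a, b], 2)) == 0
        c = self._regions([("1", 500_000, 1_500_000)], "XPEHH", "AFT")
        assert len(consensus_regions([a, c], 2)) == 1

    def test_idempotent_and_order_invariant(self, rng):
        sets = []
        for test in ("iHS", "Rsb", "XPEHH"):
            starts = rng.integers(0, 50, 12) * 100_000
            sets.append(RegionSet([
                Region("1", int(s), int(s) + 1_000_000,
                       frozenset({(test, "AFT")})) for s in starts]))
        merged = consensus_regions(sets, 1)
        again = consensus_regions([merged], 1)
        assert [(r.chrom, r.start_bp, r.end_bp) for r in merged.sorted()] == \
            [(r.chrom, r.start_bp, r.end_bp) for r in again.sorted()]
        reordered = consensus_regions(sets[::-1], 1)
        assert [(r.chrom, r.start_bp, r.end_bp, r.methods)
                for r in merged.sorted()] == \
            [(r.chrom, r.start_bp, r.end_bp, r.methods)
             for r in reordered.sorted()]

    def test_matches_union_find_oracle_on_random_intervals(self, rng):
        tests = ["iHS", "Rsb", "XPEHH"]
        intervals = []
        for _ in range(1000):
            chrom = str(rng.integers(1, 6))
            start = int(rng.integers(0, 400)) * 10_000
            length = int(rng.integers(1, 40)) * 10_000
            intervals.append((chrom, start, start + length,
                              tests[rng.integers(0, 3)]))
        sets = [RegionSet([Region(c, s, e, frozenset({(t, "AFT")}))
                           for c, s, e, t in intervals if t == test])
                for test in tests]
        for min_methods in (1, 2, 3):
            ours = consensus_regions(sets, min_methods)
            expected = brute_consensus(intervals, min_methods)
            got = sorted((r.chrom, r.start_bp, r.end_bp,
                          frozenset(t for t, _ in r.methods)) for r in ours)
            assert got == expected


class TestAnnotate:
    def _region(self, start, end):
        return RegionSet([Region("1", start, end, frozenset({("iHS", None)}))])

    def test_gene_inside_listed(self):
        regions = self._region(1_000_000, 2_000_000)
        feats = FeatureSet([Feature("1", 1_200_000, 1_300_000, "geneA", "gene")])
        ann = annotate_regions(regions, feats)
        assert [f.name for f in list(ann.values())[0]] == ["geneA"]

    def test_large_sv_excluded_smaller_kept(self):
        regions = self._region(1_000_000, 2_000_000)
        feats = FeatureSet([
            Feature("1", 0, 9_000_000, "sv9Mb", "SV", sv_length_bp=9_000_000),
            Feature("1", 1_100_000, 1_150_000, "sv50kb", "SV", sv_length_bp=50_000)])
        ann = annotate_regions(regions, feats)
        assert [f.name for f in list(ann.values())[0]] == ["sv50kb"]

    def test_abutting_feature_not_listed(self):
        regions = self._region(1_000_000, 2_000_000)
        feats = FeatureSet([Feature("1", 2_000_000, 2_100_000, "after", "gene"),
                            Feature("1", 900_000, 1_000_000, "before", "gene"),
                            Feature("1", 999_999, 1_000_001, "straddle", "gene")])
        ann = annotate_regions(regions, feats)
        assert [f.name for f in list(ann.values())[0]] == ["straddle"]


class TestRegionGeneCounts:
    def test_fixture_ihs_gene_count(self):
        fx = load_region_table_fixture()
        assert count_region_genes(fx, "iHS") == 57

    def test_duplicates_counted_once_and_empty_zero(self):
        fx = RegionTableFixture(pd.DataFrame({
            "test": ["Rsb", "Rsb", "XPEHH"], "contrast": ["AFT"] * 3,
            "chrom": ["1", "1", "2"],
            "start_bp": [0, 2_000_000, 0],
            "end_bp": [1_000_000, 3_000_000, 1_000_000],
            "length_mb": [1.0, 1.0, 1.0],
            "genes": [["A", "B"], ["B", "C"], []]}))
        assert count_region_genes(fx, "Rsb") == 3
        assert count_region_genes(fx, "XPEHH") == 0

    def test_unknown_test_errors(self):
        fx = load_region_table_fixture()
        with pytest.raises(ValueError, match="unknown test"):
            count_region_genes(fx, "nSL")
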