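import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from sweepscan import ehh
from sweepscan.ehh import (EHHProfile, ehh_decay, ies_scan, ihs_scan,
                           integrate_ihh, p_transform, rsb_scan, xpehh_scan)

from conftest import build_matrix
from _oracles import brute_ehh_profile, brute_integrate


class TestEhhDecay:
    def test_identical_carriers_stay_at_one(self):
        haps = np.zeros((6, 5), dtype=np.uint8)
        haps[:4, 2] = 1  # derived carriers identical elsewhere
        m = build_matrix(haps)
        prof = ehh_decay(m, 2, "derived")
        assert prof.n_carriers == 4
        np.testing.assert_allclose(prof.left_ehh, 1.0)
        np.testing.assert_allclose(prof.right_ehh, 1.0)
        assert prof.truncation_right == "chrom_end"

    def test_two_classes_of_two(self):
        # 4 carriers split 2/2 one step right of the core:
        # EHH = (C(2,2)+C(2,2)) / C(4,2) = 2/6
        haps = np.zeros((4, 3), dtype=np.uint8)
        haps[:, 1] = 1
        haps[2:, 2] = 1
        m = build_matrix(haps)
        prof = ehh_decay(m, 1, "derived")
        assert prof.right_ehh[1] == pytest.approx(1 / 3)

    def test_all_distinct_hits_cutoff(self, rng):
        haps = np.vstack([np.eye(4, 6, k=1, dtype=np.uint8)])
        haps[:, 0] = 1
        m = build_matrix(haps)
        prof = ehh_decay(m, 0, "derived")
        assert prof.right_ehh[-1] < 0.05
        assert prof.truncation_right == "cutoff"

    def test_max_gap_truncates_before_gap(self):
        haps = np.zeros((4, 4), dtype=np.uint8)
        haps[:, 0] = 1
        m = build_matrix(haps, positions=[1000, 2000, 700_000, 701_000])
        prof = ehh_decay(m, 0, "derived", max_gap_bp=500_000)
        assert prof.truncation_right == "maxgap"
        assert prof.right_pos[-1] == 2000  # profile ends before the gap

    def test_single_carrier_is_flagged_not_raised(self):
        haps = np.zeros((4, 3), dtype=np.uint8)
        haps[0, 1] = 1
        m = build_matrix(haps)
        prof = ehh_decay(m, 1, "derived")
        assert not prof.defined
        assert np.isnan(integrate_ihh(prof))

    @pytest.mark.parametrize("allele", ["ancestral", "derived", "all"])
    def test_matches_bruteforce_pair_enumeration(self, random_panel, allele):
        m = random_panel
        for core in range(m.n_markers):
            col = m.haplotypes[:, core]
            if allele == "all":
                carriers = np.arange(m.n_haplotypes)
            else:
                carriers = np.flatnonzero(col == (1 if allele == "derived" else 0))
            if len(carriers) < 2:
                continue
            prof = ehh_decay(m, core, allele)
            lp, le, rp, re_ = brute_ehh_profile(
                m.haplotypes, m.positions(), core, carriers, 500_000, 0.05)
            np.testing.assert_allclose(prof.left_ehh, le, atol=1e-10)
            np.testing.assert_allclose(prof.right_ehh, re_, atol=1e-10)
            np.testing.assert_array_equal(prof.left_pos, lp)
            np.testing.assert_array_equal(prof.right_pos, rp)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_nonincreasing_outward(self, seed):
        rng = np.random.default_rng(seed)
        haps = rng.integers(0, 2, (8, 12)).astype(np.uint8)
        m = build_matrix(haps)
        core = int(rng.integers(0, 12))
        prof = ehh_decay(m, core, "all")
        assert (np.diff(prof.left_ehh) <= 1e-12).all()
        assert (np.diff(prof.right_ehh) <= 1e-12).all()


class TestIntegration:
    def test_rectangle_and_triangle(self):
        prof = EHHProfile(0, 1000, "derived",
                          np.array([1000]), np.array([1.0]),
                          np.array([1000, 1000 + 500]), np.array([1.0, 1.0]),
                          "chrom_end", "cutoff", 4)
        assert integrate_ihh(prof) == pytest.approx(500)  # constant 1 over d
        prof.right_ehh = np.array([1.0, 0.0])
        assert integrate_ihh(prof) == pytest.approx(250)  # linear 1 -> 0

    def test_arbitrary_profile_matches_hand_sum(self, rng):
        pos = np.array([10_000, 12_000, 15_000, 19_000, 24_000])
        vals = np.array([1.0, 0.8, 0.5, 0.2, 0.1])
        prof = EHHProfile(0, 10_000, "all", np.array([10_000]),
                          np.array([1.0]), pos, vals, "chrom_end", "cutoff", 6)
        assert integrate_ihh(prof) == pytest.approx(
            brute_integrate(pos, vals, 10_000), abs=1e-10)


class TestIhsScan:
    def test_symmetric_alleles_give_zero_raw(self):
        # ancestral and derived carriers with mirror-image backgrounds
        haps = np.array([[1, 1, 0, 1, 1],
                         [1, 1, 0, 0, 1],
                         [0, 0, 1, 1, 0],
                         [0, 0, 1, 0, 0]], dtype=np.uint8)
        m = build_matrix(haps)
        track = ihs_scan(m)
        row = track.table[track.table["marker_id"] == "m2"]
        assert row["raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_swapping_labels_flips_raw_sign(self, random_panel):
        m = random_panel
        flipped = build_matrix(1 - m.haplotypes, m.positions())
        t1 = ihs_scan(m).table.set_index("marker_id")
        t2 = ihs_scan(flipped).table.set_index("marker_id")
        common = t1.index.intersection(t2.index)
        assert len(common) > 0
        np.testing.assert_allclose(t1.loc[common, "raw"],
                                   -t2.loc[common, "raw"], atol=1e-10)

    def test_bin_standardization_is_exact(self, rng):
        haps = rng.integers(0, 2, (20, 120)).astype(np.uint8)
        m = build_matrix(haps, positions=np.arange(1, 121) * 2000)
        track = ihs_scan(m)
        meta = track.standardization
        assert meta["kind"] == "freq_bins"
        df = track.table.copy()
        freq = m.derived_freq()[m.markers["marker_id"].isin(df["marker_id"]).to_numpy()]
        # reconstruct bins exactly as the scan assigns them
        bins = ehh._frequency_bins(freq, meta["n_bins"], meta["min_bin_count"])
        for b in np.unique(bins):
            scores = df["score"].to_numpy()[bins == b]
            if scores.std() > 0:
                assert abs(scores.mean()) < 1e-6
                assert abs(scores.std() - 1) < 1e-6


class TestBetweenPopulationScans:
    def test_identical_pools_give_zero_raw(self, random_panel):
        ies = ies_scan(random_panel)
        track = rsb_scan(ies, ies.copy())
        np.testing.assert_allclose(track.table["raw"], 0.0, atol=1e-12)

    def test_swapping_pools_flips_raw(self, rng):
        a = build_matrix(rng.integers(0, 2, (8, 15)))
        b = build_matrix(rng.integers(0, 2, (8, 15)))
        ia, ib = ies_scan(a), ies_scan(b)
        t12 = xpehh_scan(ia, ib).table.set_index("marker_id")["raw"]
        t21 = xpehh_scan(ib, ia).table.set_index("marker_id")["raw"]
        np.testing.assert_allclose(t12, -t21.loc[t12.index], atol=1e-12)

    def test_ies_extremes(self):
        same = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.uint8), (6, 1))
        m = build_matrix(same, positions=[1000, 3000, 5000, 7000, 9000])
        ies = ies_scan(m)
        # all haplotypes identical: iES equals the full support span
        assert ies["ies"].iloc[0] == pytest.approx(8000)
        # columns right of the core binary-encode the row index: all 8
        # haplotypes become distinct after three extensions
        bits = ((np.arange(8)[:, None] >> np.arange(3)[None, :]) & 1)
        distinct = np.concatenate(
            [np.zeros((8, 1), dtype=np.uint8), bits.astype(np.uint8)], axis=1)
        m2 = build_matrix(distinct, positions=[1000, 3000, 5000, 7000])
        ies2 = ies_scan(m2)
        # EHH decays 1, 0.428, 0.143, 0 -> iES ~ the inter-marker scale
        assert ies2["ies"].iloc[0] == pytest.approx(
            ((1 + 3 / 7) + (3 / 7 + 1 / 7) + (1 / 7 + 0)) * 1000, abs=1e-9)

    def test_standardization_centres(self, rng):
        a = build_matrix(rng.integers(0, 2, (10, 40)))
        b = build_matrix(rng.integers(0, 2, (10, 40)))
        ia, ib = ies_scan(a), ies_scan(b)
        rsb = rsb_scan(ia, ib).table
        xp = xpehh_scan(ia, ib).table
        assert np.median(rsb["score"]) == pytest.approx(0.0, abs=1e-9)
        assert xp["score"].mean() == pytest.approx(0.0, abs=1e-9)
        assert xp["score"].to_numpy().std() == pytest.approx(1.0, abs=1e-6)


class TestPTransform:
    def test_zero_and_symmetry(self):
        assert p_transform(0.0) == 0.0
        x = np.linspace(-6, 6, 41)
        np.testing.assert_allclose(p_transform(x), p_transform(-x))

    def test_threshold_crossing_score(self):
        # the score magnitude mapping to exactly -log10 p = 3, located by
        # bisection against an independently coded error-function series
        def erf_series(z, terms=60):
            total, term = z, z
            for n in range(1, terms):
                term *= -z * z / n
                total += term / (2 * n + 1)
            return 2 / np.sqrt(np.pi) * total

        def two_sided_mlog10p(x):
            phi = 0.5 * (1 + erf_series(x / np.sqrt(2)))
            return -np.log10(2 * (1 - phi))

        root = brentq(lambda x: two_sided_mlog10p(x) - 3.0, 2.0, 4.0,
                      xtol=1e-10)
        assert root == pytest.approx(3.29053, abs=1e-5)
        assert p_transform(root) == pytest.approx(3.0, abs=1e-9)

    def test_large_scores_stay_finite(self):
        out = p_transform(np.array([10.0, 40.0, 100.0]))
        assert np.isfinite(out).all()
        assert (np.diff(out) > 0).all()

    def test_positive_iff_nonzero(self):
        assert (p_transform(np.array([1e-9, 0.5, 9.0])) > 0).all()
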