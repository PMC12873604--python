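import io

import numpy as np
import pytest

from telocus.annotation import GenomicInterval
from telocus.peaks import (
    Peak,
    PeakSet,
    SignalMatrix,
    SignalTrack,
    assign_peak_classes,
    compute_signal_matrix,
    filter_peaks,
    intersect_sets,
    kmeans_rows,
    overlap_length,
    peak_retention,
    promoter_peak_confidence,
    rpkm_normalize,
)
from telocus.synthetic_data import young_fl_l1_ids


def peakset(spans, condition="control"):
    return PeakSet(condition, "rep1",
                   [Peak(GenomicInterval(c, s, e)) for c, s, e in spans])


def brute_force_pairs(A, B):
    out = set()
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            ov = overlap_length(a, b)
            if ov > 0:
                out.add((i, j, ov))
    return out


class TestFilterPeaks:
    def test_strictly_longer_than_cutoff_kept(self):
        ps = peakset([("chr1", 0, 400), ("chr1", 1000, 1500),
                      ("chr1", 3000, 3501), ("chr1", 9000, 9600)])
        kept = filter_peaks(ps, 500)
        assert [len(p.interval) for p in kept] == [501, 600]

    def test_non_reference_chrom_dropped(self):
        ps = peakset([("chrM", 0, 10_000)])
        assert len(filter_peaks(ps, 500)) == 0

    def test_empty_and_idempotent(self):
        assert len(filter_peaks(peakset([]), 500)) == 0
        ps = peakset([("chr1", 0, 700), ("chr2", 0, 300)])
        once = filter_peaks(ps, 500)
        twice = filter_peaks(once, 500)
        assert once.peaks == twice.peaks


class TestOverlapAndIntersect:
    @pytest.mark.parametrize("a, b, expected", [
        (("chr1", 0, 10), ("chr1", 0, 10), 10),
        (("chr1", 0, 10), ("chr1", 10, 20), 0),   # half-open adjacency
        (("chr1", 5, 15), ("chr1", 10, 30), 5),
        (("chr1", 0, 10), ("chr2", 0, 10), 0),
    ])
    def test_overlap_length(self, a, b, expected):
        assert overlap_length(GenomicInterval(*a), GenomicInterval(*b)) == expected

    def test_simple_pair(self):
        A = [GenomicInterval("chr1", 0, 100)]
        B = [GenomicInterval("chr1", 50, 60), GenomicInterval("chr1", 200, 300)]
        assert intersect_sets(A, B) == [(0, 0, 10)]

    def test_disjoint_chromosomes(self):
        A = [GenomicInterval("chr1", 0, 100)]
        B = [GenomicInterval("chr2", 0, 100)]
        assert intersect_sets(A, B) == []

    def test_unsorted_input_rejected(self):
        A = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 0, 50)]
        with pytest.raises(ValueError, match="sorted"):
            intersect_sets(A, A[:1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        chroms = ["chr1", "chr2", "chr3"]
        for _ in range(1000):
            def draw(n):
                ivs = []
                for _ in range(n):
                    s = int(rng.integers(0, 500))
                    ivs.append(GenomicInterval(chroms[rng.integers(3)],
                                               s, s + int(rng.integers(1, 60))))
                return sorted(ivs, key=lambda iv: (iv.chrom, iv.start))
            A, B = draw(int(rng.integers(0, 25))), draw(int(rng.integers(0, 25)))
            assert set(intersect_sets(A, B)) == brute_force_pairs(A, B)


class TestAssignPeakClasses:
    def test_peak_inside_l1(self, tiny_catalog):
        labels, _ = assign_peak_classes(peakset([("chr1", 2000, 3000)]), tiny_catalog)
        assert labels == ["L1"]

    def test_max_overlap_wins(self, tiny_catalog):
        # overlaps AluY_1 (chr1:40000-40300) by 20 bp, L1PA2_1 by 300 bp
        ps = peakset([("chr1", 26_700, 40_020)])
        labels, _ = assign_peak_classes(ps, tiny_catalog)
        assert labels == ["L1"]

    def test_fractions_match_hand_count(self, tiny_catalog):
        # 10 peaks: 4 over L1s, 2 over Alus, 1 over SVA, 3 over nothing
        spans = [("chr1", 1_500, 2_500), ("chr1", 7_500, 8_200),
                 ("chr1", 21_000, 22_000), ("chr2", 5_200, 6_000),
                 ("chr1", 40_100, 40_200), ("chr2", 1_000, 1_200),
                 ("chr2", 50_500, 51_000),
                 ("chr1", 100_000, 101_000), ("chr2", 80_000, 80_800),
                 ("chr2", 200_000, 201_000)]
        labels, summary = assign_peak_classes(peakset(spans), tiny_catalog)
        assert summary["n_peaks"] == 10
        assert summary["fraction_te"] == pytest.approx(0.7)
        assert summary["te_class_fractions"] == pytest.approx(
            {"L1": 4 / 7, "Alu": 2 / 7, "SVA": 1 / 7})
        assert labels.count("non-TE") == 3


class TestPeakRetention:
    def test_identical_sets_lose_nothing(self):
        ps = peakset([("chr1", 0, 1000), ("chr2", 50, 800)])
        n, lost, frac = peak_retention(ps, ps)
        assert (n, lost, frac) == (2, 0, 0.0)

    def test_empty_treatment_loses_everything(self):
        ps = peakset([("chr1", 0, 1000), ("chr2", 50, 800)])
        n, lost, frac = peak_retention(ps, peakset([], "treatment"))
        assert (n, lost, frac) == (2, 2, 1.0)

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            peak_retention(peakset([]), peakset([("chr1", 0, 10)]))

    def test_fraction_bounds_on_fixture(self, bundle):
        ctrl = filter_peaks(bundle.control_peaks)
        treat = filter_peaks(bundle.treatment_peaks)
        _, _, frac = peak_retention(ctrl, treat)
        assert 0.0 <= frac <= 1.0


class TestSignalMatrix:
    def test_constant_track_fills_matrix(self):
        track = SignalTrack.from_rows([("chr1", 0, 100_000, 2.5)])
        regions = [GenomicInterval("chr1", 10_000, 20_000, "+")]
        m = compute_signal_matrix(track, regions, bin_size_bp=100,
                                  upstream_bp=500, downstream_bp=500)
        assert np.allclose(m.values, 2.5)

    def test_step_track_bins_match_hand_computation(self):
        # three segments: [0,150)=1, [150,250)=3, [250,400)=0 (absent)
        track = SignalTrack.from_rows([("chr1", 0, 150, 1.0),
                                       ("chr1", 150, 250, 3.0)])
        regions = [GenomicInterval("chr1", 100, 300, "+")]
        m = compute_signal_matrix(track, regions, bin_size_bp=100,
                                  upstream_bp=0, downstream_bp=200)
        # bin [100,200): 50bp of 1 + 50bp of 3 -> 2.0; bin [200,300): 50bp of 3 -> 1.5
        assert m.values[0] == pytest.approx([2.0, 1.5])

    def test_minus_strand_row_is_mirror_of_plus(self):
        rng = np.random.default_rng(0)
        segs = [("chr1", i * 50, (i + 1) * 50, float(v))
                for i, v in enumerate(rng.uniform(0, 5, 200))]
        track = SignalTrack.from_rows(segs)
        plus = GenomicInterval("chr1", 3000, 6000, "+")
        m_plus = compute_signal_matrix(track, [plus], bin_size_bp=100,
                                       upstream_bp=1000, downstream_bp=1000)
        # mirrored track around the element: compute on the minus strand of a
        # region whose 5' anchor sits at the old anchor reflected
        minus = GenomicInterval("chr1", 3000, 6000, "-")
        m_minus = compute_signal_matrix(track, [minus], bin_size_bp=100,
                                        upstream_bp=1000, downstream_bp=1000)
        # minus-strand bins walk leftward from the region end: row equals the
        # reversed window around the end anchor
        window = [track.mean_over("chr1", s, s + 100)
                  for s in range(6000 - 1000, 6000 + 1000, 100)]
        assert m_minus.values[0] == pytest.approx(window[::-1])
        assert m_plus.values.shape == m_minus.values.shape

    def test_scale_regions_resizes_body(self):
        track = SignalTrack.from_rows([("chr1", 1000, 2000, 4.0)])
        regions = [GenomicInterval("chr1", 1000, 2000, "+")]
        m = compute_signal_matrix(track, regions, mode="scale-regions",
                                  bin_size_bp=100, upstream_bp=200,
                                  downstream_bp=200, body_bins=10)
        assert m.values.shape == (1, 2 + 10 + 2)
        assert m.values[0, 2:12] == pytest.approx(np.full(10, 4.0))
        assert m.values[0, :2] == pytest.approx([0.0, 0.0])

    def test_tsv_round_trip(self):
        m = SignalMatrix(["r1", "r2"], "reference-point", 100, 300, 200, 0,
                         np.arange(10.0).reshape(2, 5))
        buf = io.StringIO()
        m.to_tsv(buf)
        buf.seek(0)
        m2 = SignalMatrix.from_tsv(buf)
        assert m2.region_ids == m.region_ids
        assert np.allclose(m2.values, m.values)
        assert (m2.mode, m2.bin_size_bp) == (m.mode, m.bin_size_bp)


class TestRpkm:
    def test_reference_value(self):
        assert rpkm_normalize(10, 10_000_000, 1000) == pytest.approx(1.0)

    def test_depth_invariance_and_zero(self):
        a = rpkm_normalize([4, 0], 1_000_000, 500)
        b = rpkm_normalize([8, 0], 2_000_000, 500)
        assert np.allclose(a, b)
        assert a[1] == 0.0


class TestKmeans:
    def _matrix(self, rows):
        rows = np.asarray(rows, dtype=float)
        return SignalMatrix([f"r{i}" for i in range(len(rows))],
                            "reference-point", 100, 0, 100 * rows.shape[1], 0,
                            rows)

    def test_three_well_separated_pairs(self):
        m = self._matrix([[0.0], [0.1], [5.0], [5.1], [10.0], [10.2]])
        res = kmeans_rows(m, 3, seed=0)
        a = res.assignments
        assert a["r0"] == a["r1"]
        assert a["r2"] == a["r3"]
        assert a["r4"] == a["r5"]
        assert len({a["r0"], a["r2"], a["r4"]}) == 3

    def test_k1_centroid_is_column_mean(self):
        m = self._matrix(np.random.default_rng(0).uniform(0, 1, (20, 4)))
        res = kmeans_rows(m, 1, seed=0)
        assert np.allclose(res.centroids[0], m.values.mean(axis=0))

    def test_deterministic_given_seed(self):
        m = self._matrix(np.random.default_rng(1).uniform(0, 1, (30, 5)))
        r1 = kmeans_rows(m, 3, seed=7)
        r2 = kmeans_rows(m, 3, seed=7)
        assert r1.assignments == r2.assignments
        assert np.allclose(r1.centroids, r2.centroids)

    def test_inertia_never_increases_across_iterations(self):
        m = self._matrix(np.random.default_rng(2).uniform(0, 1, (60, 6)))
        res = kmeans_rows(m, 4, seed=3)
        trace = res.inertia_trace
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_k_larger_than_rows_rejected(self):
        m = self._matrix([[0.0], [1.0]])
        with pytest.raises(ValueError):
            kmeans_rows(m, 3, seed=0)

    def test_matches_sklearn_inertia(self):
        sklearn = pytest.importorskip("sklearn.cluster")
        m = self._matrix(np.random.default_rng(5).uniform(0, 1, (80, 4)))
        ours = kmeans_rows(m, 3, seed=0, n_init=10)
        ref = sklearn.KMeans(n_clusters=3, n_init=10, random_state=0).fit(m.values)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=0.05)


class TestPromoterConfidence:
    def _matrix(self, rows):
        rows = np.asarray(rows, dtype=float)
        return SignalMatrix([f"r{i}" for i in range(len(rows))],
                            "reference-point", 100, 500,
                            100 * rows.shape[1] - 500, 0, rows)

    def test_all_zero_row_is_none(self):
        rows = np.zeros((4, 10))
        rows[1:] = 1.0  # others give nonzero background
        calls = promoter_peak_confidence(self._matrix(rows))
        assert calls["r0"] == "none"

    def test_strong_promoter_is_high(self):
        rows = np.full((10, 10), 1.0)
        rows[0, 5:] = 50.0
        calls = promoter_peak_confidence(self._matrix(rows))
        assert calls["r0"] == "high"

    def test_recovers_planted_tiers(self, bundle):
        track = SignalTrack.from_rows(bundle.signal_tracks["h3k4me3_treatment"])
        young = young_fl_l1_ids(bundle.catalog)
        regions = [bundle.catalog.by_id(i).interval for i in young]
        m = compute_signal_matrix(track, regions, region_ids=young,
                                  bin_size_bp=100, upstream_bp=1000,
                                  downstream_bp=1000)
        calls = promoter_peak_confidence(m)
        accuracy = np.mean([calls[i] == bundle.promoter_tiers[i] for i in young])
        assert accuracy >= 0.9

    def test_clusters_separate_planted_tiers(self, bundle):
        track = SignalTrack.from_rows(bundle.signal_tracks["h3k4me3_treatment"])
        young = young_fl_l1_ids(bundle.catalog)
        regions = [bundle.catalog.by_id(i).interval for i in young]
        m = compute_signal_matrix(track, regions, region_ids=young,
                                  bin_size_bp=100, upstream_bp=1000,
                                  downstream_bp=1000)
        res = kmeans_rows(m, 3, seed=0)
        # the cluster holding most "high" elements should be mostly planted
        high = [i for i in young if bundle.promoter_tiers[i] == "high"]
        labels = [res.assignments[i] for i in high]
        majority = max(set(labels), key=labels.count)
        members = [i for i in young if res.assignments[i] == majority]
        frac_high = np.mean([bundle.promoter_tiers[i] == "high" for i in members])
        assert frac_high >= 0.9
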