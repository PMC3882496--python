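"""Coverage construction, binned promoter matrices and metagene profiles."""

import numpy as np
import pytest

from luatscan.signal import (
    Anchor,
    antisense_score,
    binned_promoter_signal,
    coverage_from_reads,
    feature_fraction_profile,
    meta_profile,
    rescaled_region_profile,
)
from luatscan.types import FeatureIntervals

from conftest import make_reads, make_tx


class TestCoverage:
    def test_single_read_mass(self, flat_genome):
        cov = coverage_from_reads(make_reads([("chr1", 100, 150, "+")]), flat_genome)
        vec = cov.get("chr1", "+")
        assert vec[100] == 1 and vec[149] == 1 and vec[99] == 0 and vec[150] == 0
        assert int(vec.sum()) == 50

    def test_empty_reads_zero_coverage(self, flat_genome):
        cov = coverage_from_reads(make_reads([]), flat_genome)
        assert cov.total_mass() == 0

    def test_duplicate_reads_double_coverage(self, flat_genome):
        r = [("chr1", 100, 150, "+")]
        c1 = coverage_from_reads(make_reads(r), flat_genome)
        c2 = coverage_from_reads(make_reads(r * 2), flat_genome)
        np.testing.assert_array_equal(2 * c1.get("chr1", "+"), c2.get("chr1", "+"))

    def test_mass_conservation_random_reads(self, flat_genome, rng):
        starts = rng.integers(0, 99_000, 500)
        lens = rng.integers(1, 300, 500)
        strands = rng.choice(["+", "-"], 500)
        reads = make_reads(
            [("chr1", int(s), int(s + l), str(st)) for s, l, st in zip(starts, lens, strands)]
        )
        cov = coverage_from_reads(reads, flat_genome)
        assert cov.total_mass() == reads.total_fragment_bp()

    def test_out_of_bounds_errors(self, flat_genome):
        with pytest.raises(ValueError, match="out of bounds"):
            coverage_from_reads(make_reads([("chr1", 99_990, 100_010, "+")]), flat_genome)


class TestBinnedPromoterSignal:
    def test_constant_coverage_log_transform(self, flat_genome):
        # 3 overlapping fragments everywhere on the + strand around the anchor
        reads = make_reads([("chr1", 40_000, 60_000, "+")] * 3)
        cov = coverage_from_reads(reads, flat_genome)
        t = make_tx("A.t1", [(50_000, 51_000)], "+")
        sense, anti = binned_promoter_signal(cov, [t], flank=5000, bin_bp=100)
        np.testing.assert_allclose(sense.values[0], np.log2(301), rtol=1e-12)
        np.testing.assert_array_equal(anti.values[0], 0.0)

    def test_zero_coverage_all_zero_bins(self, flat_genome):
        cov = coverage_from_reads(make_reads([]), flat_genome)
        t = make_tx("A.t1", [(50_000, 51_000)], "+")
        sense, anti = binned_promoter_signal(cov, [t])
        assert not sense.values.any() and not anti.values.any()

    def test_raw_row_sum_equals_window_coverage(self, flat_genome, rng):
        starts = rng.integers(30_000, 70_000, 300)
        reads = make_reads([("chr1", int(s), int(s) + 100, "+") for s in starts])
        cov = coverage_from_reads(reads, flat_genome)
        t = make_tx("A.t1", [(50_000, 51_000)], "+")
        sense, _ = binned_promoter_signal(cov, [t], transform="raw")
        window_sum = cov.get("chr1", "+")[45_000:55_000].sum()
        assert sense.values[0].sum() == window_sum

    def test_read_strand_swap_exchanges_channels(self, flat_genome):
        recs = [("chr1", 46_000, 46_200, "+"), ("chr1", 53_000, 53_400, "-")]
        cov = coverage_from_reads(make_reads(recs), flat_genome)
        cov_sw = coverage_from_reads(
            make_reads([(c, s, e, "+" if st == "-" else "-") for c, s, e, st in recs]),
            flat_genome,
        )
        t_plus = make_tx("A.t1", [(50_000, 51_000)], "+")
        s1, a1 = binned_promoter_signal(cov, [t_plus])
        s2, a2 = binned_promoter_signal(cov_sw, [t_plus])
        np.testing.assert_allclose(s1.values, a2.values)
        np.testing.assert_allclose(a1.values, s2.values)

    def test_orientation_involution(self, flat_genome, rng):
        starts = rng.integers(30_000, 70_000, 200)
        strands = rng.choice(["+", "-"], 200)
        recs = [("chr1", int(s), int(s) + 80, str(st)) for s, st in zip(starts, strands)]
        cov = coverage_from_reads(make_reads(recs), flat_genome)
        flipped = [(c, s, e, "+" if st == "-" else "-") for c, s, e, st in recs]
        cov2 = coverage_from_reads(
            make_reads([(c, s, e, "+" if st == "-" else "-") for c, s, e, st in flipped]),
            flat_genome,
        )
        t = make_tx("A.t1", [(50_000, 51_000)], "+")
        for m1, m2 in zip(binned_promoter_signal(cov, [t]), binned_promoter_signal(cov2, [t])):
            np.testing.assert_array_equal(m1.values, m2.values)

    def test_edge_anchor_dropped_with_warning(self, flat_genome, caplog):
        cov = coverage_from_reads(make_reads([]), flat_genome)
        t = make_tx("A.t1", [(2_000, 3_000)], "+")
        with caplog.at_level("WARNING"):
            sense, _ = binned_promoter_signal(cov, [t])
        assert sense.values.shape[0] == 0
        assert "dropped" in caplog.text


class TestAntisenseScore:
    @pytest.mark.parametrize(
        "row,expected",
        [
            (np.ones(100), 50.0),
            (np.zeros(100), 0.0),
            (np.array([2.0] + [0.0] * 99), 2.0),
        ],
    )
    def test_sum_of_upstream_bins(self, row, expected):
        assert antisense_score(row, 50) == expected

    def test_short_row_errors(self):
        with pytest.raises(ValueError):
            antisense_score(np.ones(10), 50)


class TestMetaProfile:
    def test_single_region_identity(self, flat_genome):
        reads = make_reads([("chr1", 50_000, 50_300, "+")])
        cov = coverage_from_reads(reads, flat_genome)
        t = make_tx("A.t1", [(50_000, 51_000)], "+")
        prof = meta_profile(cov, [t], transform="raw")
        sense, _ = binned_promoter_signal(cov, [t], transform="raw")
        np.testing.assert_array_equal(prof.values, sense.values[0])
        assert prof.n_regions == 1

    def test_mean_of_two_rows(self, flat_genome):
        # gene A sees signal downstream only, gene B upstream only
        reads = make_reads(
            [("chr1", 30_000, 30_100, "+"), ("chr1", 59_900, 60_000, "+")]
        )
        cov = coverage_from_reads(reads, flat_genome)
        a = make_tx("A.t1", [(29_900, 30_900)], "+", gene="A")
        b = make_tx("B.t1", [(60_100, 61_000)], "+", gene="B")
        prof = meta_profile(cov, [a, b], transform="raw")
        single_a = meta_profile(cov, [a], transform="raw")
        single_b = meta_profile(cov, [b], transform="raw")
        np.testing.assert_allclose(prof.values, (single_a.values + single_b.values) / 2)

    def test_n_copies_equal_single(self, flat_genome):
        reads = make_reads([("chr1", 50_000, 50_500, "+")])
        cov = coverage_from_reads(reads, flat_genome)
        t = make_tx("A.t1", [(50_000, 51_000)], "+")
        one = meta_profile(cov, [t], transform="raw")
        five = meta_profile(cov, [t] * 5, transform="raw")
        np.testing.assert_allclose(one.values, five.values)

    def test_no_usable_anchor_errors(self, flat_genome):
        cov = coverage_from_reads(make_reads([]), flat_genome)
        with pytest.raises(ValueError):
            meta_profile(cov, [make_tx("A.t1", [(1_000, 2_000)], "+")])


class TestRescaledRegionProfile:
    def test_constant_coverage_flat(self, flat_genome):
        reads = make_reads([("chr1", 10_000, 20_000, "+")] * 3)
        cov = coverage_from_reads(reads, flat_genome)
        prof = rescaled_region_profile(cov, [("chr1", 12_000, 15_000, "+")])
        np.testing.assert_allclose(prof.values, 3.0)

    def test_linear_ramp(self, flat_genome):
        # stack of nested reads makes a staircase ramp
        reads = make_reads([("chr1", 10_000, 10_000 + 100 * (i + 1), "+") for i in range(50)])
        cov = coverage_from_reads(reads, flat_genome)
        prof = rescaled_region_profile(cov, [("chr1", 10_000, 15_000, "+")], n_bins=50)
        diffs = np.diff(prof.values)
        assert np.all(diffs <= 0)  # monotone decreasing ramp
        assert prof.values[0] == 50 and prof.values[-1] == 1

    def test_minus_strand_reverses(self, flat_genome):
        reads = make_reads(
            [("chr1", 10_000, 10_500, "+"), ("chr1", 10_000, 10_500, "-")]
        )
        cov = coverage_from_reads(reads, flat_genome)
        plus = rescaled_region_profile(cov, [("chr1", 10_000, 11_000, "+")], n_bins=10)
        minus = rescaled_region_profile(cov, [("chr1", 10_000, 11_000, "-")], n_bins=10)
        np.testing.assert_allclose(minus.values, plus.values[::-1])

    def test_short_region_dropped(self, flat_genome):
        cov = coverage_from_reads(make_reads([]), flat_genome)
        with pytest.raises(ValueError):
            rescaled_region_profile(cov, [("chr1", 0, 50, "+")], n_bins=100)


class TestFeatureFractionProfile:
    def test_full_cover_is_one(self):
        anchors = [Anchor("a", "chr1", 50_000, "+"), Anchor("b", "chr1", 60_000, "+")]
        feats = FeatureIntervals("x", [("chr1", 0, 100_000)])
        prof = feature_fraction_profile(feats, anchors, flank=1000, step=100)
        np.testing.assert_array_equal(prof.values, 1.0)

    def test_no_features_zero(self):
        anchors = [Anchor("a", "chr1", 50_000, "+")]
        prof = feature_fraction_profile(FeatureIntervals("x"), anchors, flank=1000)
        np.testing.assert_array_equal(prof.values, 0.0)

    def test_half_covered_at_anchor(self):
        anchors = [Anchor("a", "chr1", 50_000, "+"), Anchor("b", "chr1", 80_000, "+")]
        feats = FeatureIntervals("x", [("chr1", 49_990, 50_010)])
        prof = feature_fraction_profile(feats, anchors, flank=500, step=10)
        at_zero = prof.values[np.where(prof.positions == 0)[0][0]]
        assert at_zero == 0.5
        assert prof.values.min() >= 0 and prof.values.max() <= 1
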