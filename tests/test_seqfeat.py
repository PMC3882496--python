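"""Promoter sequence features: GC skew, CpG islands, PWM scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from luatscan.seqfeat import (
    PWM,
    detect_cpg_islands,
    gc_content_profile,
    gc_skew,
    gc_skew_profile,
    promoter_cpg_summary,
    pwm_max_score,
    reverse_complement,
    splice_site_accumulation,
)
from luatscan.types import FeatureIntervals, GenomeAssembly

from conftest import make_tx

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


class TestGcSkew:
    @pytest.mark.parametrize(
        "seq,expected", [("GGGG", 1.0), ("GCGC", 0.0), ("GGC", 1 / 3), ("CCCC", -1.0)]
    )
    def test_values(self, seq, expected):
        assert gc_skew(seq) == pytest.approx(expected)

    def test_no_gc_is_nan(self):
        assert np.isnan(gc_skew("ATAT"))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gc_skew("")

    @given(dna)
    @settings(deadline=None, max_examples=100)
    def test_reverse_complement_negates(self, seq):
        sk = gc_skew(seq)
        rc = gc_skew(reverse_complement(seq))
        if np.isnan(sk):
            assert np.isnan(rc)
        else:
            assert rc == pytest.approx(-sk)


class TestGcProfiles:
    def _genome(self, seq):
        return GenomeAssembly({"chr1": seq})

    def test_all_gc_content_one(self):
        g = self._genome("GC" * 5_000)
        t = make_tx("A.t1", [(5_000, 6_000)], "+")
        prof = gc_content_profile(g, [t], flank=1000, bin_bp=100)
        np.testing.assert_allclose(prof.values, 1.0)

    def test_all_at_content_zero(self):
        g = self._genome("AT" * 5_000)
        t = make_tx("A.t1", [(5_000, 6_000)], "+")
        prof = gc_content_profile(g, [t], flank=1000, bin_bp=100)
        np.testing.assert_allclose(prof.values, 0.0)

    def test_alternating_acgt_is_half(self):
        g = self._genome("ACGT" * 2_500)
        t = make_tx("A.t1", [(5_000, 6_000)], "+")
        prof = gc_content_profile(g, [t], flank=1000, bin_bp=100)
        np.testing.assert_allclose(prof.values, 0.5)

    def test_skew_profile_involution_under_revcomp(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 20_000, p=[0.2, 0.35, 0.25, 0.2]))
        g = self._genome(seq)
        g_rc = self._genome(reverse_complement(seq))
        t = make_tx("A.t1", [(10_000, 11_000)], "+")
        # same genomic locus read from the opposite assembly orientation
        t_rc = make_tx("A.t1", [(len(seq) - 11_000, len(seq) - 10_000)], "-")
        p1 = gc_skew_profile(g, [t], flank=2000, bin_bp=100)
        p2 = gc_skew_profile(g_rc, [t_rc], flank=2000, bin_bp=100)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-12)

    def test_skew_free_genome_near_zero(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 40_000))
        g = self._genome(seq)
        anchors = [make_tx(f"A{i}.t1", [(5_000 + 3_000 * i, 5_500 + 3_000 * i)], "+")
                   for i in range(10)]
        prof = gc_skew_profile(g, anchors, flank=2000, bin_bp=100)
        assert abs(np.nanmean(prof.values)) < 0.03


class TestCpgIslands:
    def test_cg_repeat_detected_with_expected_oe(self):
        seq = "A" * 2_000 + "CG" * 150 + "A" * 2_000
        g = GenomeAssembly({"chr1": seq})
        islands = detect_cpg_islands(g)
        assert len(islands) == 1
        chrom, s, e = next(iter(islands))
        # the island spans the repeat (plus at most one flanking window)
        assert s <= 2_000 and e >= 2_300
        assert s >= 1_900 and e <= 2_400
        # recomputed on the pure repeat, observed/expected CpG is ~2
        core = seq[2_000:2_300]
        oe = core.count("CG") * len(core) / (core.count("C") * core.count("G"))
        assert oe == pytest.approx(2.0, abs=0.05)
        # and the reported island itself re-satisfies both thresholds
        sub = seq[s:e]
        assert (sub.count("G") + sub.count("C")) / len(sub) >= 0.5
        assert sub.count("CG") * len(sub) / (sub.count("C") * sub.count("G")) >= 0.6

    def test_poly_a_has_no_island(self):
        g = GenomeAssembly({"chr1": "A" * 1_000})
        assert len(detect_cpg_islands(g)) == 0

    def test_reported_islands_resatisfy_thresholds(self):
        rng = np.random.default_rng(3)
        parts = []
        for _ in range(20):
            parts.append("".join(rng.choice(list("ACGT"), 1_000, p=[0.3, 0.2, 0.2, 0.3])))
            parts.append("CG" * rng.integers(50, 200))
        g = GenomeAssembly({"chr1": "".join(parts)})
        islands = detect_cpg_islands(g)
        assert len(islands) > 0
        seq = g.sequence("chr1", 0, g.length("chr1"))
        prev_end = -1
        for _, s, e in islands:
            assert s >= prev_end  # disjoint
            prev_end = e
            sub = seq[s:e]
            L = e - s
            assert L >= 200
            gc = (sub.count("G") + sub.count("C")) / L
            oe = sub.count("CG") * L / max(1, sub.count("C") * sub.count("G"))
            assert gc >= 0.5 and oe >= 0.6

    def test_promoter_summary_sums_island_lengths(self):
        t = make_tx("A.t1", [(10_000, 12_000)], "+")
        islands = FeatureIntervals(
            "cpg", [("chr1", 9_700, 10_200), ("chr1", 10_400, 10_800)]
        )
        out = promoter_cpg_summary(islands, [t])
        covered, total = out["A.t1"]
        assert covered is True and total == 900

    def test_promoter_summary_empty(self):
        t = make_tx("A.t1", [(10_000, 12_000)], "+")
        out = promoter_cpg_summary(FeatureIntervals("cpg"), [t])
        assert out["A.t1"] == (False, 0)

    def test_edge_overlapping_island_counts_full_length(self):
        t = make_tx("A.t1", [(10_000, 12_000)], "+")
        islands = FeatureIntervals("cpg", [("chr1", 10_800, 11_600)])  # crosses +1 kb edge
        covered, total = promoter_cpg_summary(islands, [t])["A.t1"]
        assert covered is False and total == 800
        _, clipped = promoter_cpg_summary(islands, [t], clip=True)["A.t1"]
        assert clipped == 200


class TestPwm:
    def _pwm(self):
        counts = np.array(
            [[8, 0, 0, 1], [0, 0, 8, 1], [0, 0, 0, 6], [0, 8, 0, 0]], dtype=float
        )  # consensus ATCG... rows are A,C,G,T: consensus = A,T,C,G
        return PWM.from_counts("toy", counts)

    def test_consensus_scores_column_max_sum(self):
        pwm = self._pwm()
        g = GenomeAssembly({"chr1": "AAAA" + "ATCG" + "AAAA" * 30})
        t = make_tx("A.t1", [(60, 80)], "+")
        score = pwm_max_score(g, t, pwm, window=120)
        assert score == pytest.approx(pwm.consensus_score())

    def test_scan_matches_bruteforce(self, rng):
        pwm = self._pwm()
        lookup = {b: i for i, b in enumerate("ACGT")}
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 1_000))
            scores = pwm.scan(seq)
            L = pwm.length
            brute = [
                sum(pwm.matrix[lookup[seq[p + j]], j] for j in range(L))
                for p in range(len(seq) - L + 1)
            ]
            np.testing.assert_allclose(scores, brute, atol=1e-10)

    def test_all_n_window_scores_column_minimum(self):
        pwm = self._pwm()
        g = GenomeAssembly({"chr1": "N" * 400})
        t = make_tx("A.t1", [(200, 300)], "+")
        score = pwm_max_score(g, t, pwm, window=100)
        assert score == pytest.approx(pwm.matrix.min(axis=0).sum())

    def test_locality_outside_window(self):
        pwm = self._pwm()
        base = "A" * 1_000
        spiked = "ATCG" + "A" * 996  # consensus far outside the scan window
        t = make_tx("A.t1", [(500, 600)], "+")
        s1 = pwm_max_score(GenomeAssembly({"chr1": base}), t, pwm, window=100)
        s2 = pwm_max_score(GenomeAssembly({"chr1": spiked}), t, pwm, window=100)
        assert s1 == s2


class TestSpliceSiteAccumulation:
    def _pwm(self):
        counts = np.zeros((4, 4))
        for j, b in enumerate("GTAG"):
            counts["ACGT".index(b), j] = 10
        return PWM.from_counts("ss", counts)

    def test_planted_consensus_steps_at_expected_x(self):
        pwm = self._pwm()
        # consensus occupies 1-based downstream positions 10..13
        seq = "A" * 1_000 + "A" * 9 + "GTAG" + "A" * 500
        g = GenomeAssembly({"chr1": seq})
        genes = [make_tx("A.t1", [(1_000, 1_400)], "+")]
        curve = splice_site_accumulation(g, genes, pwm, span=100,
                                         threshold=pwm.consensus_score())
        step_x = 10 + pwm.length - 1
        assert curve.values[step_x - 2] == 0.0
        assert curve.values[step_x - 1] == 1.0
        assert curve.values[-1] == 1.0

    def test_no_hits_flat_zero(self):
        g = GenomeAssembly({"chr1": "A" * 2_000})
        genes = [make_tx("A.t1", [(1_000, 1_400)], "+")]
        curve = splice_site_accumulation(g, genes, self._pwm(), span=100, threshold=1.0)
        assert not curve.values.any()

    def test_monotone_nondecreasing_and_bounded(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        g = GenomeAssembly({"chr1": seq})
        genes = [make_tx(f"G{i}.t1", [(1_000 + 600 * i, 1_400 + 600 * i)], "+")
                 for i in range(20)]
        curve = splice_site_accumulation(g, genes, self._pwm(), span=200, threshold=2.0)
        assert np.all(np.diff(curve.values) >= 0)
        assert curve.values[-1] <= 1.0
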