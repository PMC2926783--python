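"""Selection filters and element-overlap statistics against brute force."""

import numpy as np
import pytest

from conftest import make_tx, random_tx
from oracles import brute_filter, brute_overlap_fraction

from lincons.core import ConservedElement, GenomicInterval
from lincons.filtering import (
    FilterReport,
    filter_noncoding,
    overlap_fraction,
    summarize_overlap,
)


def el(chrom, start, end, score=500):
    return ConservedElement(GenomicInterval(chrom, start, end), score)


class TestFilterNoncoding:
    def test_empty_coding_keeps_all(self, rng):
        lnc = [random_tx(rng, f"l{i}", "chr1", 1000 * (i + 1)) for i in range(3)]
        reports = filter_noncoding(lnc, [])
        assert all(r.kept and r.nearest_coding_distance is None for r in reports)

    def test_proximity_strict_inequality(self):
        coding = [make_tx("g", "chr1", [(0, 100), (200, 300)], biotype="coding")]
        at_5000 = make_tx("ok", "chr1", [(5300, 5400), (5500, 5600)])
        at_4999 = make_tx("near", "chr1", [(5299, 5399), (5500, 5600)])
        r_ok, r_near = filter_noncoding([at_5000, at_4999], coding)
        assert r_ok.kept and r_ok.nearest_coding_distance == 5000
        assert not r_near.kept and r_near.reason == "within_proximity"
        assert r_near.nearest_coding_distance == 4999

    def test_exon_overlap_trumps_proximity(self):
        coding = [make_tx("g", "chr1", [(0, 100), (200, 300)], biotype="coding")]
        lnc = make_tx("l", "chr1", [(250, 350), (400, 500)])
        (r,) = filter_noncoding([lnc], coding)
        assert r.reason == "overlaps_coding" and r.nearest_coding_distance == 0

    def test_intron_only_overlap_is_proximity_not_exon_overlap(self):
        # lncRNA exon inside the coding gene's intron: no exon-exon overlap,
        # but the loci overlap so the gap is 0
        coding = [make_tx("g", "chr1", [(0, 100), (900, 1000)], biotype="coding")]
        lnc = make_tx("l", "chr1", [(300, 400), (500, 600)])
        (r,) = filter_noncoding([lnc], coding)
        assert r.reason == "within_proximity"

    def test_matches_brute_force_on_random_loci(self, rng):
        coding = [
            random_tx(rng, f"g{i}", f"chr{1 + i % 2}", int(rng.integers(0, 40000)))
            for i in range(20)
        ]
        lnc = [
            random_tx(rng, f"l{i}", f"chr{1 + i % 2}", int(rng.integers(0, 40000)))
            for i in range(50)
        ]
        got = filter_noncoding(lnc, coding, 3000)
        expected = brute_filter(lnc, coding, 3000)
        for r, (eid, ereason, edist) in zip(got, expected):
            assert (r.id, r.reason, r.nearest_coding_distance) == (eid, ereason, edist)

    def test_order_independence(self, rng):
        coding = [random_tx(rng, f"g{i}", "chr1", 9000 * (i + 1)) for i in range(5)]
        lnc = [random_tx(rng, f"l{i}", "chr1", 4000 * (i + 1)) for i in range(8)]
        fwd = {r.id: r.reason for r in filter_noncoding(lnc, coding)}
        rev = {r.id: r.reason for r in filter_noncoding(lnc[::-1], coding[::-1])}
        assert fwd == rev

    def test_tss_distance_mode(self):
        coding = [make_tx("g", "chr1", [(0, 100), (200, 300)], biotype="coding")]
        # locus gap 700 but TSS-to-TSS distance 1000
        lnc = make_tx("l", "chr1", [(1000, 1100), (1200, 1300)])
        (by_gap,) = filter_noncoding([lnc], coding, 800, distance_mode="gap")
        (by_tss,) = filter_noncoding([lnc], coding, 800, distance_mode="tss")
        assert by_gap.nearest_coding_distance == 700 and not by_gap.kept
        assert by_tss.nearest_coding_distance == 1000 and by_tss.kept

    def test_unknown_distance_mode_rejected(self):
        with pytest.raises(ValueError, match="distance_mode"):
            filter_noncoding([], [], 5000, distance_mode="midpoint")

    def test_report_consistency_enforced(self):
        with pytest.raises(ValueError):
            FilterReport("x", kept=True, reason="overlaps_coding",
                         nearest_coding_distance=None)


class TestOverlapFraction:
    def test_no_elements(self):
        tx = make_tx("t", "chr1", [(0, 100), (200, 300)])
        s = overlap_fraction(tx, [])
        assert s.exonic_fraction == 0 and s.genic_fraction == 0
        assert not s.has_constrained

    def test_full_span_element(self):
        tx = make_tx("t", "chr1", [(0, 100), (200, 300)])
        s = overlap_fraction(tx, [el("chr1", 0, 300)])
        assert s.exonic_fraction == 1.0 and s.genic_fraction == 1.0

    def test_partial_overlap_hand_counted(self):
        tx = make_tx("t", "chr1", [(0, 100), (200, 300)])
        s = overlap_fraction(tx, [el("chr1", 50, 250)])
        assert s.exonic_fraction == pytest.approx(0.5)
        assert s.genic_fraction == pytest.approx(200 / 300)

    def test_duplicated_elements_change_nothing(self, rng):
        tx = random_tx(rng, "t", "chr1", 100)
        els = [
            el("chr1", int(s), int(s) + int(rng.integers(10, 80)))
            for s in rng.integers(50, 800, size=10)
        ]
        s1 = overlap_fraction(tx, els)
        s2 = overlap_fraction(tx, els + els)
        assert s1 == s2

    def test_matches_per_base_oracle(self, rng):
        for trial in range(20):
            tx = random_tx(rng, "t", "chr1", int(rng.integers(0, 500)))
            els = [
                el("chr1", int(s), int(s) + int(rng.integers(5, 120)))
                for s in rng.integers(0, 1200, size=int(rng.integers(0, 8)))
            ]
            s = overlap_fraction(tx, els)
            ex, gen = brute_overlap_fraction(tx, els)
            assert s.exonic_fraction == pytest.approx(ex)
            assert s.genic_fraction == pytest.approx(gen)


class TestSummarize:
    def test_two_transcripts_arithmetic(self):
        tx1 = make_tx("a", "chr1", [(0, 100)])
        tx2 = make_tx("b", "chr1", [(0, 100)])
        s1 = overlap_fraction(tx1, [el("chr1", 0, 20)])
        s2 = overlap_fraction(tx2, [el("chr1", 0, 40)])
        stats = summarize_overlap([s1, s2])
        assert stats["mean_genic_fraction"] == pytest.approx(0.3)
        assert stats["n_constrained"] == 2
        assert stats["pct_constrained"] == 100.0

    def test_all_zero(self):
        tx = make_tx("a", "chr1", [(0, 100)])
        stats = summarize_overlap([overlap_fraction(tx, [])])
        assert stats["n_constrained"] == 0
        assert stats["mean_exonic_fraction"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_overlap([])

    def test_histogram_bins(self):
        tx = make_tx("a", "chr1", [(0, 100)])
        stats = summarize_overlap([overlap_fraction(tx, [el("chr1", 0, 5)])])
        hist = stats["histogram"]
        assert hist["count"].sum() == 1
        assert np.isclose(hist["bin_hi"].iloc[0] - hist["bin_lo"].iloc[0], 0.02)
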