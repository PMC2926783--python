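"""Locus partitioning, even-spacing sampler, metagene averaging, peak call."""

import numpy as np
import pytest

from conftest import make_tx

from lincons.core import GenomicInterval, ScoreTrack
from lincons.metagene import (
    MetageneProfile,
    RegionSchema,
    build_metagene,
    call_peak,
    partition_locus,
    sample_region,
)


def const_track(chrom="chr1", n=2000, value=0.5):
    t = ScoreTrack()
    t.set_array(chrom, np.full(n, value))
    return t


def pos_track(chrom="chr1", n=2000):
    """Score encodes position/n so sampled values identify sampled bases."""
    t = ScoreTrack()
    t.set_array(chrom, np.arange(n) / n)
    return t


class TestPartition:
    def test_two_exon_plus(self):
        tx = make_tx("t", "chr1", [(500, 600), (800, 900)])
        parts = partition_locus(tx)
        assert parts["middle_exons"] == []
        assert [(i.start, i.end) for i in parts["introns"]] == [(600, 800)]
        assert parts["upstream200"][0].start == 300
        assert parts["downstream200"][0].end == 1100

    def test_minus_strand_upstream_at_higher_coords(self):
        tx = make_tx("t", "chr1", [(500, 600), (700, 800), (900, 1000)], strand="-")
        parts = partition_locus(tx)
        up = parts["upstream200"][0]
        assert (up.start, up.end) == (1000, 1200)
        assert parts["first_exon"][0].start == 900
        assert parts["last_exon"][0].start == 500
        # introns in transcript order: the genomically-last intron first
        assert [i.start for i in parts["introns"]] == [800, 600]

    def test_three_exon_transcript_order(self):
        tx = make_tx("t", "chr1", [(1000, 1100), (1200, 1250), (1300, 1380)])
        parts = partition_locus(tx)
        assert parts["first_exon"][0].length == 100
        assert parts["middle_exons"][0].length == 50
        assert parts["last_exon"][0].length == 80

    def test_single_exon_rejected(self):
        tx = make_tx("t", "chr1", [(500, 600)])
        with pytest.raises(ValueError, match="single-exon"):
            partition_locus(tx)


class TestSampleRegion:
    def test_length_equals_k_constant(self):
        iv = [GenomicInterval("chr1", 100, 300)]
        vec = sample_region(const_track(value=0.7), iv, 200)
        assert np.allclose(vec, 0.7)

    def test_short_region_slot_formula(self):
        t = ScoreTrack()
        t.set_array("chr1", np.array([0.1, 0.2, 0.3]))
        vec = sample_region(t, [GenomicInterval("chr1", 0, 3)], 5)
        assert vec[0] == pytest.approx(0.1)
        assert vec[2] == pytest.approx(0.2)
        assert vec[4] == pytest.approx(0.3)
        assert np.isnan(vec[1]) and np.isnan(vec[3])

    def test_long_region_positions_increasing_and_cover_ends(self):
        vec = sample_region(pos_track(), [GenomicInterval("chr1", 0, 399)], 200)
        sampled = np.round(vec * 2000).astype(int)
        assert sampled[0] == 0 and sampled[-1] == 398
        assert (np.diff(sampled) > 0).all()

    def test_k_equals_length_no_interpolation(self):
        vec = sample_region(pos_track(), [GenomicInterval("chr1", 10, 60)], 50)
        assert np.allclose(vec, np.arange(10, 60) / 2000)

    def test_empty_intervals_all_missing(self):
        vec = sample_region(const_track(), [], 10)
        assert np.isnan(vec).all()

    def test_minus_strand_reads_backwards(self):
        vec = sample_region(
            pos_track(), [GenomicInterval("chr1", 10, 60, "-")], 50
        )
        assert np.allclose(vec, np.arange(59, 9, -1) / 2000)

    def test_impute_zero_convention(self):
        t = ScoreTrack()
        arr = np.full(100, np.nan)
        arr[:50] = 0.4
        t.set_array("chr1", arr)
        vec = sample_region(
            t, [GenomicInterval("chr1", 0, 100)], 100, impute_zero=True
        )
        assert np.allclose(vec[50:], 0.0)
        assert np.allclose(vec[:50], 0.4)

    def test_missing_positions_excluded(self):
        t = ScoreTrack()
        arr = np.full(100, np.nan)
        arr[:50] = 0.4
        t.set_array("chr1", arr)
        vec = sample_region(t, [GenomicInterval("chr1", 0, 100)], 100)
        assert np.isnan(vec[50:]).all()
        assert np.allclose(vec[:50], 0.4)


class TestBuildMetagene:
    def test_constant_track_everywhere(self):
        txs = [
            make_tx("a", "chr1", [(400, 500), (700, 800)]),
            make_tx("b", "chr1", [(1000, 1100), (1200, 1400)]),
        ]
        prof = build_metagene(txs, const_track(value=0.6))
        for region in prof.schema.regions:
            vals = prof.values[region]
            assert np.allclose(vals[~np.isnan(vals)], 0.6)

    def test_single_locus_identity(self):
        tx = make_tx("a", "chr1", [(400, 500), (700, 800)])
        schema = RegionSchema(samples_per_region=50)
        prof = build_metagene([tx], pos_track(), schema)
        vec = sample_region(pos_track(), partition_locus(tx, schema)["first_exon"], 50)
        assert np.allclose(prof.values["first_exon"], vec, equal_nan=True)

    def test_locus_weighting_independent_of_intron_length(self):
        # both introns longer than the slot grid, so every slot is sampled
        short = make_tx("a", "chr1", [(400, 500), (800, 900)])
        long = make_tx("b", "chr1", [(400, 500), (1200, 1300)])
        p1 = build_metagene([short], const_track(value=0.3))
        p2 = build_metagene([long], const_track(value=0.3))
        assert (p1.counts["introns"] == p2.counts["introns"]).all()

    def test_profile_bounded_by_track(self, rng):
        t = ScoreTrack()
        arr = rng.uniform(0.2, 0.8, 3000)
        t.set_array("chr1", arr)
        txs = [make_tx("a", "chr1", [(500, 700), (900, 1100), (1300, 1500)])]
        prof = build_metagene(txs, t)
        for region in prof.schema.regions:
            vals = prof.values[region]
            ok = vals[~np.isnan(vals)]
            assert (ok >= arr.min()).all() and (ok <= arr.max()).all()

    def test_no_multi_exon_transcripts_rejected(self):
        tx = make_tx("a", "chr1", [(400, 500)])
        with pytest.raises(ValueError, match="multi-exon"):
            build_metagene([tx], const_track())


class TestCallPeak:
    def _profile_with_upstream(self, values):
        schema = RegionSchema(samples_per_region=len(values))
        vals = {r: np.full(len(values), np.nan) for r in schema.regions}
        counts = {r: np.zeros(len(values), dtype=int) for r in schema.regions}
        vals["upstream200"] = np.asarray(values, dtype=float)
        counts["upstream200"] = np.ones(len(values), dtype=int)
        return MetageneProfile(
            schema=schema, values=vals, counts=counts,
            region_mean_length={r: 200.0 for r in schema.regions},
        )

    def test_monotone_increasing_peaks_at_tss(self):
        prof = self._profile_with_upstream(np.linspace(0.1, 0.9, 200))
        peak = call_peak(prof, "upstream200")
        assert peak.slot == 199 and peak.offset == -1

    def test_flat_ties_resolve_to_anchor(self):
        prof = self._profile_with_upstream(np.full(200, 0.5))
        peak = call_peak(prof, "upstream200")
        assert peak.slot == 199  # TSS-proximal for the upstream flank

    def test_offset_scale(self):
        values = np.full(200, 0.1)
        values[157] = 0.9  # 200-slot grid over 200 bp: slot 157 = TSS-43
        prof = self._profile_with_upstream(values)
        peak = call_peak(prof, "upstream200")
        assert peak.offset == -43 and peak.height == pytest.approx(0.9)

    def test_all_missing_region_rejected(self):
        prof = self._profile_with_upstream(np.full(200, 0.5))
        with pytest.raises(ValueError, match="no defined slots"):
            call_peak(prof, "introns")


class TestPeakRecoveryEndToEnd:
    def test_planted_bump_recovered(self):
        from lincons.simulate import (
            SyntheticConfig, generate_annotation, generate_score_track,
        )

        cfg = SyntheticConfig(
            seed=9, n_chroms=2, chrom_length=1_200_000, n_coding=10,
            n_lncrna=80, frac_proximal=0.0, frac_overlapping=0.0,
        )
        _, lnc, _ = generate_annotation(cfg)
        track, _ = generate_score_track(cfg, lnc)
        prof = build_metagene(lnc, track)
        peak = call_peak(prof, "upstream200")
        assert abs(peak.offset - (-43)) <= 5
        expected = cfg.background_score_mean + cfg.promoter_peak_height
        assert abs(peak.height - expected) <= 0.03
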