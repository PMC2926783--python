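"""The synthetic-data generator: determinism, planted structure, ground truth."""

import io

import numpy as np
import pytest

from lincons import io as fio
from lincons.ecr import column_identity
from lincons.simulate import (
    SyntheticConfig,
    generate_alignment,
    generate_annotation,
    generate_ortholog_pair,
    generate_score_track,
)


def _bed_bytes(txs):
    buf = io.StringIO()
    fio.write_bed12(txs, buf)
    return buf.getvalue()


class TestAnnotation:
    def test_deterministic_under_seed(self, small_cfg):
        a = generate_annotation(small_cfg)
        b = generate_annotation(small_cfg)
        assert _bed_bytes(a[0]) == _bed_bytes(b[0])
        assert _bed_bytes(a[1]) == _bed_bytes(b[1])

    def test_seed_changes_output(self, small_cfg):
        a = generate_annotation(small_cfg)
        small_cfg2 = SyntheticConfig(**{**small_cfg.__dict__, "seed": 43})
        b = generate_annotation(small_cfg2)
        assert _bed_bytes(a[1]) != _bed_bytes(b[1])

    def test_no_lncrnas(self, small_cfg):
        small_cfg.n_lncrna = 0
        _, lnc, truth = generate_annotation(small_cfg)
        assert lnc == [] and truth.empty

    def test_forced_gaps_straddling_threshold(self):
        """4,999 bp from a coding gene removes; 5,001 bp keeps (strict <5 kb)."""
        cfg = SyntheticConfig(
            seed=1, n_chroms=1, chrom_length=400_000, n_coding=2, n_lncrna=2,
            frac_overlapping=0.0, frac_proximal=0.0, forced_gaps=[4999, 5001],
        )
        _, _, truth = generate_annotation(cfg)
        labels = dict(zip(truth["id"], truth["label"]))
        assert labels == {"lnc1": "within_proximity", "lnc2": "kept"}
        dists = dict(zip(truth["id"], truth["nearest_coding_distance"]))
        assert dists["lnc1"] == 4999 and dists["lnc2"] == 5001

    def test_too_small_genome_raises(self, small_cfg):
        small_cfg.chrom_length = 2000
        with pytest.raises(ValueError, match="chrom_length"):
            generate_annotation(small_cfg)


class TestScoreTrack:
    def test_flat_when_nothing_planted(self, small_cfg):
        small_cfg.promoter_peak_height = 0.0
        small_cfg.splice_peak_height = 0.0
        small_cfg.exon_conserved_prob = 0.0
        small_cfg.element_exonic_coverage = 0.0
        _, lnc, _ = generate_annotation(small_cfg)
        track, elements = generate_score_track(small_cfg, lnc)
        assert elements == []
        arr = track.array("chr1")
        lo = small_cfg.background_score_mean - small_cfg.background_jitter
        hi = small_cfg.background_score_mean + small_cfg.background_jitter
        assert arr.min() >= lo - 1e-9 and arr.max() <= hi + 1e-9

    def test_planted_promoter_peak_position(self, small_cfg):
        """argmax of the upstream 200 bp window sits at TSS-43 (+- smoothing)."""
        _, lnc, _ = generate_annotation(small_cfg)
        track, _ = generate_score_track(small_cfg, lnc)
        for tx in lnc[:4]:
            arr = track.array(tx.chrom)
            if tx.strand == "+":
                window = arr[tx.tss - 200 : tx.tss]
                offset = 200 - int(np.argmax(window))
            else:
                window = arr[tx.tss + 1 : tx.tss + 201]
                offset = int(np.argmax(window)) + 1
            assert abs(offset - small_cfg.promoter_peak_offset) <= 10

    def test_element_coverage_near_target(self, small_cfg):
        _, lnc, _ = generate_annotation(small_cfg)
        _, elements = generate_score_track(small_cfg, lnc)
        covered = set()
        for el in elements:
            covered.update(range(el.interval.start, el.interval.end))
        exonic = [p for tx in lnc for e in tx.exons for p in range(e.start, e.end)]
        frac = sum(1 for p in exonic if p in covered) / len(exonic)
        assert abs(frac - small_cfg.element_exonic_coverage) <= 0.05

    def test_scores_bounded(self, small_cfg):
        _, lnc, _ = generate_annotation(small_cfg)
        track, _ = generate_score_track(small_cfg, lnc)
        arr = track.array("chr1")
        assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestAlignment:
    def test_perfect_identity_no_gaps(self, small_cfg):
        small_cfg.background_identity = 1.0
        small_cfg.gap_rate = 0.0
        small_cfg.ecr_specs = []
        (block,), _ = generate_alignment(small_cfg)
        assert column_identity(block).all()

    def test_ground_truth_coordinates(self, small_cfg):
        _, truth = generate_alignment(small_cfg)
        (iv,) = truth
        start, length, _ = small_cfg.ecr_specs[0]
        assert iv.start == small_cfg.ref_offset + start
        assert iv.end == iv.start + length

    def test_deterministic(self, small_cfg):
        (a,), _ = generate_alignment(small_cfg)
        (b,), _ = generate_alignment(small_cfg)
        assert a.rows[1].text == b.rows[1].text

    def test_planted_segment_identity(self, small_cfg):
        small_cfg.ecr_specs = [(200, 400, 0.9)]
        (block,), _ = generate_alignment(small_cfg)
        flags = column_identity(block)
        planted = flags[200:600]
        assert abs(planted.mean() - 0.9) < 0.06  # binomial noise at n=400


class TestOrthologPair:
    def test_identity_one_gives_identical(self, small_cfg):
        small_cfg.ortholog_identity = 1.0
        q, s = generate_ortholog_pair(small_cfg)
        assert q.seq == s.seq

    def test_identity_zero_gives_unrelated(self, small_cfg):
        small_cfg.ortholog_identity = 0.0
        q, s = generate_ortholog_pair(small_cfg)
        assert q.seq != s.seq

    def test_polya_planted_at_30(self, small_cfg):
        """Independent string search finds ATAAA exactly 30 nt from both
        3' ends."""
        q, s = generate_ortholog_pair(small_cfg)
        for rec in (q, s):
            pos = rec.seq.rfind("ATAAA")
            assert len(rec.seq) - pos == 30

    def test_deterministic_and_index_varies(self, small_cfg):
        q1, _ = generate_ortholog_pair(small_cfg, index=0)
        q2, _ = generate_ortholog_pair(small_cfg, index=0)
        q3, _ = generate_ortholog_pair(small_cfg, index=1)
        assert q1.seq == q2.seq
        assert q1.seq != q3.seq


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("background_identity", 1.5),
            ("element_exonic_coverage", -0.1),
            ("exon_count_range", (5, 2)),
            ("ecr_specs", [(1900, 400, 0.9)]),
        ],
    )
    def test_invalid_config_rejected(self, small_cfg, field, value):
        setattr(small_cfg, field, value)
        with pytest.raises(ValueError):
            small_cfg.validate()
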