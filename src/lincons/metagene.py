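"""Generic-locus ("metagene") conservation profile and promoter peak call.

Every multi-exon locus is partitioned into six strand-aware regions —
200 bp upstream of the TSS, first exon, introns, middle exons, last exon,
and 200 bp downstream — and each region is rescaled to a fixed number of
sample slots. Scores are sampled (a slot holds a real track value or is
missing), never interpolated, and averaging is locus-weighted: each locus
contributes once per slot regardless of its length. The promoter peak is
the argmax of the upstream segment, reported as bp upstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, ScoreTrack, TranscriptModel

DEFAULT_REGIONS = (
    "upstream200",
    "first_exon",
    "introns",
    "middle_exons",
    "last_exon",
    "downstream200",
)

# regions whose features are rescaled individually then averaged within a locus
POOLED_REGIONS = ("introns", "middle_exons")


@dataclass
class RegionSchema:
    regions: tuple[str, ...] = DEFAULT_REGIONS
    samples_per_region: int = 200
    flank_length: int = 200

    def __post_init__(self) -> None:
        if self.samples_per_region < 2:
            raise ValueError("samples_per_region must be >= 2")
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region names must be unique")
        if self.flank_length < 1:
            raise ValueError("flank_length must be >= 1")


@dataclass
class MetageneProfile:
    schema: RegionSchema
    values: dict[str, np.ndarray]  # per-region mean score, NaN where no data
    counts: dict[str, np.ndarray]  # contributing loci per slot
    region_mean_length: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in self.schema.regions:
            for j in range(self.schema.samples_per_region):
                rows.append(
                    {
                        "region": region,
                        "slot": j,
                        "mean_score": self.values[region][j],
                        "n_loci": int(self.counts[region][j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class PeakCall:
    region: str
    offset: int  # bp relative to the region anchor; negative = upstream of TSS
    height: float
    slot: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.height <= 1.0):
            raise ValueError("peak height outside [0, 1]")


def partition_locus(
    tx: TranscriptModel, schema: RegionSchema | None = None
) -> dict[str, list[GenomicInterval]]:
    """Split a multi-exon locus into the six schema regions, strand-aware.

    Intervals are returned in transcript (5'->3') order; on the minus strand
    the upstream flank therefore lies at higher genomic coordinates than the
    transcript. Middle exons may be empty for two-exon loci. Single-exon
    transcripts are rejected (the profile cohort is multi-exon by design).
    """
    schema = schema or RegionSchema()
    if tx.n_exons < 2:
        raise ValueError(f"transcript {tx.id}: single-exon locus excluded")
    flank = schema.flank_length
    iv = tx.interval
    chrom, strand = tx.chrom, tx.strand
    left_flank_start = max(0, iv.start - flank)
    left = (
        [GenomicInterval(chrom, left_flank_start, iv.start, strand)]
        if iv.start > 0
        else []
    )
    right = [GenomicInterval(chrom, iv.end, iv.end + flank, strand)]
    introns = tx.introns
    if strand == "-":
        return {
            "upstream200": right,
            "first_exon": [tx.exons[-1]],
            "introns": introns[::-1],
            "middle_exons": tx.exons[1:-1][::-1],
            "last_exon": [tx.exons[0]],
            "downstream200": left,
        }
    return {
        "upstream200": left,
        "first_exon": [tx.exons[0]],
        "introns": introns,
        "middle_exons": tx.exons[1:-1],
        "last_exon": [tx.exons[-1]],
        "downstream200": right,
    }


def _positions(intervals: list[GenomicInterval]) -> tuple[str | None, np.ndarray]:
    """Concatenated per-base genome positions in transcript order."""
    if not intervals:
        return None, np.empty(0, dtype=np.int64)
    chrom = intervals[0].chrom
    parts = []
    for iv in intervals:
        pos = np.arange(iv.start, iv.end, dtype=np.int64)
        if iv.strand == "-":
            pos = pos[::-1]
        parts.append(pos)
    return chrom, np.concatenate(parts)


def sample_region(
    track: ScoreTrack,
    intervals: list[GenomicInterval],
    k: int,
    impute_zero: bool = False,
) -> np.ndarray:
    """Sample ``k`` evenly spaced bases across a (virtual) region.

    The intervals are concatenated into a virtual sequence of length L. When
    L >= k, slot i holds the score at base round(i*(L-1)/(k-1)); when L < k,
    each base lands in slot round(pos*(k-1)/(L-1)) and slots may receive
    several bases (averaged) or none (missing). Bases absent from the track
    are missing and never averaged in by default; ``impute_zero`` treats
    them as score 0 instead (the convention appropriate for element-derived
    tracks, where absence means "not conserved" rather than "unalignable").
    Returns a length-k vector with NaN for missing slots.
    """
    if k < 2:
        raise ValueError("k must be >= 2")

    def _lookup(positions):
        s = track.scores(chrom, positions)
        return np.nan_to_num(s) if impute_zero else s

    chrom, pos = _positions(intervals)
    out = np.full(k, np.nan)
    L = pos.size
    if L == 0:
        return out
    if L >= k:
        idx = np.round(np.arange(k) * (L - 1) / (k - 1)).astype(np.int64)
        out[:] = _lookup(pos[idx])
        return out
    if L == 1:
        out[0] = _lookup(pos)[0]
        return out
    slots = np.round(np.arange(L) * (k - 1) / (L - 1)).astype(np.int64)
    scores = _lookup(pos)
    ok = ~np.isnan(scores)
    if ok.any():
        sums = np.bincount(slots[ok], weights=scores[ok], minlength=k)
        cnts = np.bincount(slots[ok], minlength=k)
        filled = cnts > 0
        out[filled] = sums[filled] / cnts[filled]
    return out


def build_metagene(
    txs: list[TranscriptModel],
    track: ScoreTrack,
    schema: RegionSchema | None = None,
    impute_zero: bool = False,
) -> MetageneProfile:
    """Average sampled conservation vectors over all multi-exon loci.

    For the pooled regions (introns, middle exons) each feature is rescaled
    to the slot grid individually and the features of one locus are averaged
    first, so a locus with many introns still counts once. Loci lacking a
    region contribute nothing to it. Raises when no multi-exon transcript
    is supplied.
    """
    schema = schema or RegionSchema()
    k = schema.samples_per_region
    eligible = [tx for tx in txs if tx.n_exons >= 2]
    if not eligible:
        raise ValueError("no multi-exon transcripts to profile")
    sums = {r: np.zeros(k) for r in schema.regions}
    counts = {r: np.zeros(k, dtype=np.int64) for r in schema.regions}
    len_sum = {r: 0.0 for r in schema.regions}
    len_n = {r: 0 for r in schema.regions}
    for tx in eligible:
        parts = partition_locus(tx, schema)
        for region in schema.regions:
            intervals = parts[region]
            if not intervals:
                continue
            if region in POOLED_REGIONS:
                vecs = [
                    sample_region(track, [iv], k, impute_zero)
                    for iv in intervals
                ]
                stacked = np.vstack(vecs)
                ok_counts = (~np.isnan(stacked)).sum(axis=0)
                vec = np.where(
                    ok_counts > 0,
                    np.nansum(stacked, axis=0) / np.maximum(ok_counts, 1),
                    np.nan,
                )
                mean_len = float(np.mean([iv.length for iv in intervals]))
            else:
                vec = sample_region(track, intervals, k, impute_zero)
                mean_len = float(sum(iv.length for iv in intervals))
            ok = ~np.isnan(vec)
            sums[region][ok] += vec[ok]
            counts[region][ok] += 1
            len_sum[region] += mean_len
            len_n[region] += 1
    values = {}
    for region in schema.regions:
        with np.errstate(invalid="ignore"):
            values[region] = np.where(
                counts[region] > 0, sums[region] / np.maximum(counts[region], 1), np.nan
            )
    mean_length = {
        r: (len_sum[r] / len_n[r] if len_n[r] else float("nan"))
        for r in schema.regions
    }
    return MetageneProfile(
        schema=schema, values=values, counts=counts, region_mean_length=mean_length
    )


def call_peak(profile: MetageneProfile, region: str = "upstream200") -> PeakCall:
    """Locate the maximum of a region's profile segment.

    The slot index is converted to bp with the region's base-per-slot scale
    (mean region length across contributing loci; the flank length for the
    upstream/downstream flanks). For the upstream flank the anchor is the
    TSS at the region's 3' edge, so offsets are negative (bp upstream); for
    all other regions the anchor is the region's 5' start. Ties go to the
    anchor-proximal slot.
    """
    if region not in profile.schema.regions:
        raise ValueError(f"unknown region {region!r}")
    v = profile.values[region]
    defined = np.flatnonzero(~np.isnan(v))
    if defined.size == 0:
        raise ValueError(f"region {region!r} has no defined slots")
    vmax = np.nanmax(v)
    candidates = defined[v[defined] == vmax]
    anchored_at_end = region == "upstream200"
    slot = int(candidates.max() if anchored_at_end else candidates.min())
    k = profile.schema.samples_per_region
    if region in ("upstream200", "downstream200"):
        L = profile.schema.flank_length
    else:
        L = max(1, int(round(profile.region_mean_length.get(region) or 1)))
    x = int(round(slot * (L - 1) / (k - 1))) if L > 1 else 0
    offset = x - L if anchored_at_end else x
    return PeakCall(region=region, offset=offset, height=float(vmax), slot=slot)
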