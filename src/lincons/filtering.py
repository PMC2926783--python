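"""lncRNA selection filters and conserved-element overlap statistics.

Candidate lncRNAs are removed when any of their exons overlaps a
protein-coding exon, or when their locus lies closer than ``min_distance``
(default 5 kb, strict inequality) to the nearest coding locus — the latter
guards against mistaking UTRs or alternative transcripts of coding genes for
independent noncoding loci, so proximity is strand-ignored. Overlap with
discrete conserved elements is then summarized per transcript, with elements
unioned first so no base is counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConservedElement, TranscriptModel


@dataclass
class FilterReport:
    id: str
    kept: bool
    reason: str  # kept | overlaps_coding | within_proximity
    nearest_coding_distance: int | None

    def __post_init__(self) -> None:
        if (self.reason == "kept") != self.kept:
            raise ValueError("reason 'kept' must match the kept flag")


@dataclass
class OverlapSummary:
    id: str
    exonic_fraction: float
    genic_fraction: float
    has_constrained: bool


def _union_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def filter_noncoding(
    lncrnas: list[TranscriptModel],
    coding: list[TranscriptModel],
    min_distance: int = 5000,
    distance_mode: str = "gap",
) -> list[FilterReport]:
    """Apply the exon-overlap and <``min_distance`` proximity filters.

    A transcript is removed if any of its exons overlaps any coding exon
    (reason ``overlaps_coding``), else if its distance to the nearest coding
    locus is strictly less than ``min_distance`` (reason
    ``within_proximity``). A distance of exactly ``min_distance`` keeps the
    transcript. ``distance_mode`` selects the distance definition: ``gap``
    (default) measures the bases between the two locus intervals; ``tss``
    measures |TSS - TSS|. Distances are reported for all transcripts (None
    when no coding locus shares the chromosome). Output order follows the
    input.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    if distance_mode not in ("gap", "tss"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for cg in coding:
        by_chrom.setdefault(cg.chrom, []).append(cg)

    reports = []
    for tx in lncrnas:
        neighbors = by_chrom.get(tx.chrom, [])
        exon_overlap = any(
            e.overlaps(ce) for cg in neighbors for e in tx.exons for ce in cg.exons
        )
        if distance_mode == "tss":
            dists = [abs(tx.tss - cg.tss) for cg in neighbors]
        else:
            dists = [tx.interval.gap_to(cg.interval) for cg in neighbors]
        nearest = min(dists) if dists else None
        if exon_overlap:
            kept, reason = False, "overlaps_coding"
        elif nearest is not None and nearest < min_distance:
            kept, reason = False, "within_proximity"
        else:
            kept, reason = True, "kept"
        reports.append(FilterReport(tx.id, kept, reason, nearest))
    return reports


def overlap_fraction(
    tx: TranscriptModel, elements: list[ConservedElement]
) -> OverlapSummary:
    """Fraction of a transcript covered by conserved elements.

    ``exonic_fraction`` counts covered exonic bases over total exonic bases;
    ``genic_fraction`` counts covered locus bases (exons plus introns) over
    locus length. Overlapping elements are unioned before counting.
    """
    union = _union_intervals(
        [
            (el.interval.start, el.interval.end)
            for el in elements
            if el.interval.chrom == tx.chrom
        ]
    )
    locus = (tx.interval.start, tx.interval.end)
    genic_cov = sum(_overlap_len(locus, u) for u in union)
    exonic_cov = sum(
        _overlap_len((e.start, e.end), u) for e in tx.exons for u in union
    )
    genic_fraction = genic_cov / tx.interval.length
    exonic_fraction = exonic_cov / tx.exonic_length
    return OverlapSummary(
        id=tx.id,
        exonic_fraction=exonic_fraction,
        genic_fraction=genic_fraction,
        has_constrained=genic_cov > 0,
    )


def summarize_overlap(
    summaries: list[OverlapSummary], bin_width: float = 0.02
) -> dict:
    """Population statistics over per-transcript overlap summaries.

    Returns the count and percentage of transcripts with any constrained
    sequence, the mean exonic and genic covered fractions, and a histogram
    of genic fraction in ``bin_width``-wide bins (a DataFrame with bin_lo,
    bin_hi, count).
    """
    if not summaries:
        raise ValueError("no overlap summaries to aggregate")
    n = len(summaries)
    n_constrained = sum(s.has_constrained for s in summaries)
    genic = np.array([s.genic_fraction for s in summaries])
    exonic = np.array([s.exonic_fraction for s in summaries])
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(genic, bins=edges)
    hist = pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    )
    return {
        "n": n,
        "n_constrained": n_constrained,
        "pct_constrained": 100.0 * n_constrained / n,
        "mean_exonic_fraction": float(exonic.mean()),
        "mean_genic_fraction": float(genic.mean()),
        "histogram": hist,
    }


def reports_to_frame(reports: list[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in reports],
            "kept": [r.kept for r in reports],
            "reason": [r.reason for r in reports],
            "nearest_coding_distance": [
                r.nearest_coding_distance for r in reports
            ],
        }
    )


def summaries_to_frame(summaries: list[OverlapSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [s.id for s in summaries],
            "exonic_fraction": [s.exonic_fraction for s in summaries],
            "genic_fraction": [s.genic_fraction for s in summaries],
            "has_constrained": [s.has_constrained for s in summaries],
        }
    )
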