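"""Evolutionarily conserved region (ECR) detection in pairwise alignments.

An ECR is a reference-genome segment of at least ``min_length`` bases
(default 100 bp) whose identity with the aligned second species is at least
``min_identity`` (default 70%). Windows are measured in reference bases,
not alignment columns; every window offset is tested and overlapping
qualifying windows are merged into maximal intervals, whose identity is
recomputed over the merge (and may legitimately dip below the per-window
threshold — ``n_windows`` is reported for transparency). A reference base
aligned to a gap or to N counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlignmentBlock, GenomicInterval


@dataclass
class Ecr:
    ref_interval: GenomicInterval
    other_species: str
    identity: float  # percent over the merged interval
    n_windows: int


def column_identity(
    block: AlignmentBlock, row_a: int = 0, row_b: int = 1
) -> np.ndarray:
    """Per-reference-base match flags between two rows of a block.

    ``row_a`` is the reference. One flag per non-gap reference base: True
    iff both characters are non-gap, non-N, and equal case-insensitively
    (soft-masking is not identity-relevant).
    """
    n = len(block.rows)
    if not (0 <= row_a < n and 0 <= row_b < n):
        raise IndexError("row index out of range")
    a = np.frombuffer(block.rows[row_a].text.upper().encode(), dtype="S1")
    b = np.frombuffer(block.rows[row_b].text.upper().encode(), dtype="S1")
    ref_base = a != b"-"
    match = (a == b) & ref_base & (b != b"-") & (a != b"N") & (b != b"N")
    return match[ref_base]


def scan_ecrs(
    block: AlignmentBlock,
    min_length: int = 100,
    min_identity: float = 0.70,
    row_b: int | None = None,
) -> list[Ecr]:
    """Scan one alignment block for ECRs against one non-reference row.

    Every window of exactly ``min_length`` consecutive reference bases with
    match fraction >= ``min_identity`` qualifies; overlapping or adjacent
    qualifying windows are merged. Coordinates are reference-genome space
    (the block's src_start offset applied). Returns merged intervals sorted
    by start; empty when the reference row is shorter than ``min_length``.
    """
    if len(block.rows) < 2:
        raise ValueError("alignment block needs >= 2 rows")
    if row_b is None:
        row_b = 1 if block.reference == 0 else 0
    flags = column_identity(block, block.reference, row_b)
    n = flags.size
    w = min_length
    if n < w:
        return []
    from fractions import Fraction

    # threshold as a rational: all comparisons in exact integer arithmetic
    ratio = Fraction(str(min_identity)).limit_denominator(10**6)
    num, den = ratio.numerator, ratio.denominator
    csum = np.concatenate([[0], np.cumsum(flags)])
    window_matches = csum[w:] - csum[:-w]  # matches in window starting at i
    qualifying = np.flatnonzero(window_matches * den >= num * w)
    if qualifying.size == 0:
        return []
    ref = block.ref
    other = block.rows[row_b]
    out: list[Ecr] = []
    run_start = prev = int(qualifying[0])
    n_win = 1

    def _trim(s: int, e: int) -> tuple[int, int]:
        """Trim a merged cluster to its best-scoring subsegment of length
        >= w, scoring each base match - min_identity. Union-of-windows
        boundaries systematically overshoot into background by up to half
        a window; the maximal-surplus subsegment ends at the identity
        transition instead. Ties prefer the longer, then leftmost segment.
        Integer arithmetic (threshold as a rational) keeps ties exact."""
        p = csum[s : e + 1] * den - num * np.arange(s, e + 1)
        best = None  # (score, length, -start, end)
        min_p, min_i = int(p[0]), 0
        for j in range(w, e - s + 1):
            if p[j - w] < min_p:
                min_p, min_i = int(p[j - w]), j - w
            cand = (int(p[j]) - min_p, j - min_i, -min_i)
            if best is None or cand > best[:3]:
                best = (*cand, j)
        s2, e2 = s - best[2], s + best[3]
        return s2, e2

    def _emit(start_i: int, end_i: int, count: int) -> None:
        s, e = _trim(start_i, end_i + w)
        ident = 100.0 * float(csum[e] - csum[s]) / (e - s)
        out.append(
            Ecr(
                ref_interval=GenomicInterval(
                    ref.src_chrom, ref.src_start + s, ref.src_start + e
                ),
                other_species=other.species,
                identity=ident,
                n_windows=count,
            )
        )

    for i in qualifying[1:]:
        i = int(i)
        if i <= prev + w:  # windows overlap or abut -> same merged interval
            prev = i
            n_win += 1
        else:
            _emit(run_start, prev, n_win)
            run_start = prev = i
            n_win = 1
    _emit(run_start, prev, n_win)
    return out


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint or cross-chrom."""
    if a.chrom != b.chrom:
        return 0.0
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return min(ov / a.length, ov / b.length)
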