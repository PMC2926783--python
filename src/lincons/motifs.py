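"""Poly(A)-signal and splice-site consensus annotation.

Poly(A) signals (AATAAA, or the ATAAA variant) are scanned near transcript
3' ends; the reported ``offset_3p`` counts from the motif's first base to
the 3' terminus, so a signal whose first base is 30 nt from the end has
offset 30. Splice donors are matched against the U2-type consensus
MAG|GTRAG spanning the exon|intron junction (last 3 exonic + first 5
intronic bases), and intron-terminal dinucleotides are checked for the
canonical GT..AG, strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import CdnaRecord, TranscriptModel, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DONOR_CONSENSUS = "MAG|GTRAG"
POLYA_PATTERNS = ("AATAAA", "ATAAA")


@dataclass
class MotifHit:
    motif: str
    pattern: str
    position: int  # 0-based start on the transcript
    offset_3p: int  # bases from the motif's first base to the 3' terminus
    context: str  # +-5 nt around the match


def _clean_pattern(pattern: str) -> str:
    """Strip annotation '|' and validate IUPAC codes."""
    cleaned = pattern.replace("|", "").upper()
    for i, ch in enumerate(cleaned):
        if ch not in IUPAC:
            raise ValueError(f"illegal IUPAC code {ch!r} at pattern position {i}")
    return cleaned


def iupac_match(seq: str, pattern: str) -> bool:
    """Does ``seq`` (plain nucleotides) match the cleaned IUPAC pattern?"""
    if len(seq) != len(pattern):
        return False
    return all(base in IUPAC[sym] for base, sym in zip(seq.upper(), pattern))


def scan_iupac(seq: str, pattern: str, name: str | None = None) -> list[MotifHit]:
    """All forward-strand occurrences of an IUPAC pattern (overlaps allowed,
    case-insensitive). '|' in the pattern is annotation only."""
    cleaned = _clean_pattern(pattern)
    seq_u = seq.upper()
    m = len(cleaned)
    hits = []
    for i in range(len(seq_u) - m + 1):
        if iupac_match(seq_u[i : i + m], cleaned):
            hits.append(
                MotifHit(
                    motif=name or pattern,
                    pattern=pattern,
                    position=i,
                    offset_3p=len(seq_u) - i,
                    context=seq_u[max(0, i - 5) : i + m + 5],
                )
            )
    return hits


def polya_offset(
    tx: CdnaRecord,
    patterns: tuple[str, ...] = POLYA_PATTERNS,
    measure_from: str = "start",
) -> MotifHit | None:
    """The poly(A) signal nearest the 3' end, or None.

    Patterns are tried in priority order; a lower-priority hit that lies
    entirely inside a higher-priority hit is suppressed (the ATAAA inside
    every AATAAA never outranks it), and at equal distance from the 3' end
    the earlier pattern wins. ``measure_from`` selects the offset
    convention: ``start`` (default) counts from the motif's first base to
    the 3' terminus; ``end`` counts from the base after the motif's last.
    """
    if measure_from not in ("start", "end"):
        raise ValueError(f"unknown measure_from {measure_from!r}")
    best: MotifHit | None = None
    claimed: list[tuple[int, int]] = []
    for pattern in patterns:
        plen = len(pattern.replace("|", ""))
        hits = [
            h
            for h in scan_iupac(tx.seq, pattern)
            if not any(
                s <= h.position and h.position + plen <= e for s, e in claimed
            )
        ]
        claimed.extend((h.position, h.position + plen) for h in hits)
        if not hits:
            continue
        if measure_from == "end":
            for h in hits:
                h.offset_3p -= plen
        cand = min(hits, key=lambda h: h.offset_3p)
        if best is None or cand.offset_3p < best.offset_3p:
            best = cand
    return best


@dataclass
class IntronReport:
    intron_index: int  # 0-based, transcript order
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    gt_ag: bool
    donor_consensus: bool
    too_short: bool


def splice_consensus_report(
    tx: TranscriptModel, genome: dict[str, str]
) -> list[IntronReport]:
    """Per-intron splice-site table for a transcript model.

    ``genome`` maps chromosome name to forward-strand sequence. All bases
    are read in transcript orientation (reverse-complemented for minus-
    strand transcripts). Introns shorter than 4 nt are flagged, not scored.
    """
    chrom_seq = genome[tx.chrom]
    introns = tx.introns
    exons = tx.exons
    minus = tx.strand == "-"
    order = range(len(introns))
    reports = []
    for out_idx, gi in enumerate(reversed(order) if minus else order):
        intron = introns[gi]
        if intron.length < 4:
            reports.append(
                IntronReport(out_idx, "", "", False, False, too_short=True)
            )
            continue
        iseq = chrom_seq[intron.start : intron.end]
        # last 3 bases of the upstream exon (transcript orientation)
        if minus:
            iseq = revcomp(iseq)
            exon_up = chrom_seq[exons[gi + 1].start : exons[gi + 1].end]
            exon_tail = revcomp(exon_up)[-3:]
        else:
            exon_tail = chrom_seq[exons[gi].end - 3 : exons[gi].end]
        donor = iseq[:2].upper()
        acceptor = iseq[-2:].upper()
        junction = (exon_tail + iseq[:5]).upper()
        donor_ok = len(junction) == 8 and iupac_match(
            junction, _clean_pattern(DONOR_CONSENSUS)
        )
        reports.append(
            IntronReport(
                intron_index=out_idx,
                donor_dinucleotide=donor,
                acceptor_dinucleotide=acceptor,
                gt_ag=(donor == "GT" and acceptor == "AG"),
                donor_consensus=donor_ok,
                too_short=False,
            )
        )
    return reports


def introns_to_frame(reports: list[IntronReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in hits])
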