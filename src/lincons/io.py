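"""Readers and writers for the standard formats the pipeline touches.

FASTA and MAF go through Biopython; BED6/BED12 and bedGraph are parsed
directly with strict validation. All parsers reject rather than repair
invalid input, and every error names the offending line or record.
Writers emit a commented header line with tool name and version.
"""

from __future__ import annotations

import io as _stdio
from typing import Iterable, TextIO

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .core import (
    AlignmentBlock,
    AlignmentRow,
    CdnaRecord,
    ConservedElement,
    GenomicInterval,
    ScoreTrack,
    TranscriptModel,
)


class ParseError(ValueError):
    """Raised for malformed input; the message names the line or record."""


def _as_handle(stream) -> TextIO:
    if isinstance(stream, str):
        return _stdio.StringIO(stream)
    return stream


def tool_header() -> str:
    return f"# lincons v{__version__}"


# ---------------------------------------------------------------------------
# BED12 / BED6
# ---------------------------------------------------------------------------

def parse_bed12(stream, biotype: str = "other") -> list[TranscriptModel]:
    """Parse BED12 lines into transcript models.

    thickStart/thickEnd are ignored; ``biotype`` is assigned to every
    transcript (BED carries no biotype column). Blocks extending past
    chromEnd are rejected; lines whose last block ends short of chromEnd
    are accepted, with the locus interval taken from the block span.
    """
    out: list[TranscriptModel] = []
    for lineno, raw in enumerate(_as_handle(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(
                f"line {lineno}: expected >=12 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name = fields[3]
            strand = fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ParseError(
                f"line {lineno}: blockCount {n_blocks} does not match "
                f"blockSizes/blockStarts lengths"
            )
        if starts[0] != 0:
            raise ParseError(f"line {lineno}: blockStarts[0] must be 0")
        block_end = start + starts[-1] + sizes[-1]
        if block_end > end:
            raise ParseError(
                f"line {lineno}: blocks extend past chromEnd ({block_end} > {end})"
            )
        try:
            exons = [
                GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                for bs, sz in zip(starts, sizes)
            ]
            tx = TranscriptModel(
                id=name,
                interval=GenomicInterval(chrom, start, block_end, strand),
                exons=exons,
                biotype=biotype,
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        out.append(tx)
    return out


def write_bed12(txs: Iterable[TranscriptModel], handle: TextIO) -> None:
    handle.write(tool_header() + " BED12\n")
    for tx in txs:
        iv = tx.interval
        sizes = ",".join(str(e.length) for e in tx.exons)
        starts = ",".join(str(e.start - iv.start) for e in tx.exons)
        handle.write(
            "\t".join(
                [
                    iv.chrom,
                    str(iv.start),
                    str(iv.end),
                    tx.id,
                    "0",
                    iv.strand,
                    str(iv.start),
                    str(iv.end),
                    "0",
                    str(tx.n_exons),
                    sizes,
                    starts,
                ]
            )
            + "\n"
        )


def parse_bed6_elements(stream) -> list[ConservedElement]:
    """Parse BED6 (or BED5) lines into conserved elements; column 5 is the
    integer log-odds score (1-1000)."""
    out: list[ConservedElement] = []
    for lineno, raw in enumerate(_as_handle(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"line {lineno}: expected >=5 fields")
        try:
            iv = GenomicInterval(
                fields[0],
                int(fields[1]),
                int(fields[2]),
                fields[5] if len(fields) > 5 else ".",
            )
            out.append(ConservedElement(iv, int(fields[4])))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return out


def write_bed6(
    records: Iterable[tuple[GenomicInterval, str, int]], handle: TextIO
) -> None:
    """Write (interval, name, score) triples as BED6."""
    handle.write(tool_header() + " BED6\n")
    for iv, name, score in records:
        handle.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
        )


# ---------------------------------------------------------------------------
# bedGraph / wiggle
# ---------------------------------------------------------------------------

def parse_bedgraph(stream) -> ScoreTrack:
    """Parse a bedGraph of conservation scores into a dense track.

    Intervals must be non-overlapping and every value must lie in [0, 1];
    violations raise rather than being repaired.
    """
    track = ScoreTrack()
    for lineno, raw in enumerate(_as_handle(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(f"line {lineno}: expected 4 fields")
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        if not (0 <= start < end):
            raise ParseError(f"line {lineno}: invalid interval {start}-{end}")
        try:
            track.set_range(chrom, start, end, value)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return track


def write_bedgraph(track: ScoreTrack, handle: TextIO, decimals: int = 6) -> None:
    """Write a track as bedGraph, merging runs of equal value."""
    import numpy as np

    handle.write(tool_header() + " bedGraph\n")
    for chrom in track.chroms:
        vals = np.round(track.array(chrom), decimals)
        n = vals.size
        # run boundaries: value changes or NaN-ness changes
        nan = np.isnan(vals)
        same = (vals[1:] == vals[:-1]) | (nan[1:] & nan[:-1])
        starts = np.concatenate([[0], np.flatnonzero(~same) + 1])
        ends = np.concatenate([starts[1:], [n]])
        for s, e in zip(starts, ends):
            if nan[s]:
                continue
            handle.write(f"{chrom}\t{s}\t{e}\t{vals[s]:.{decimals}g}\n")


def wiggle_to_bedgraph(stream, out: TextIO) -> None:
    """Convert fixedStep wiggle to bedGraph (the single internal track form)."""
    chrom = None
    pos = step = span = None
    for lineno, raw in enumerate(_as_handle(stream), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        if line.startswith("fixedStep"):
            kv = dict(tok.split("=") for tok in line.split()[1:])
            try:
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"line {lineno}: bad fixedStep header") from exc
            continue
        if chrom is None:
            raise ParseError(f"line {lineno}: data before fixedStep header")
        try:
            value = float(line)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        out.write(f"{chrom}\t{pos}\t{pos + span}\t{value:g}\n")
        pos += step


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        species, chrom = src.split(".", 1)
    else:
        species, chrom = src, src
    return species, chrom


def parse_maf(stream) -> list[AlignmentBlock]:
    """Parse MAF alignment blocks; the first 's' row of each block is the
    reference. Soft-masked (lower-case) bases are preserved."""
    blocks: list[AlignmentBlock] = []
    try:
        for i, msa in enumerate(AlignIO.parse(_as_handle(stream), "maf"), 1):
            rows = []
            for rec in msa:
                ann = rec.annotations
                species, chrom = _split_src(rec.id)
                try:
                    rows.append(
                        AlignmentRow(
                            species=species,
                            src_chrom=chrom,
                            src_start=int(ann["start"]),
                            src_size=int(ann["size"]),
                            strand="+" if int(ann["strand"]) >= 0 else "-",
                            src_length=int(ann["srcSize"]),
                            text=str(rec.seq),
                        )
                    )
                except ValueError as exc:
                    raise ParseError(f"block {i}, row {rec.id}: {exc}") from exc
            try:
                blocks.append(AlignmentBlock(rows=rows))
            except ValueError as exc:
                raise ParseError(f"block {i}: {exc}") from exc
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"malformed MAF: {exc}") from exc
    return blocks


def write_maf(blocks: Iterable[AlignmentBlock], handle: TextIO) -> None:
    msas = []
    from Bio.Align import MultipleSeqAlignment

    for block in blocks:
        recs = []
        for row in block.rows:
            rec = SeqRecord(Seq(row.text), id=row.src, description="")
            rec.annotations = {
                "start": row.src_start,
                "size": row.src_size,
                "strand": 1 if row.strand == "+" else -1,
                "srcSize": row.src_length,
            }
            recs.append(rec)
        msas.append(MultipleSeqAlignment(recs))
    AlignIO.write(msas, handle, "maf")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(stream) -> list[CdnaRecord]:
    """Parse FASTA into cDNA records: sequences uppercased, U mapped to T."""
    out: list[CdnaRecord] = []
    for rec in SeqIO.parse(_as_handle(stream), "fasta"):
        try:
            out.append(
                CdnaRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
            )
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
    if not out:
        raise ParseError("no FASTA records found")
    return out


def write_fasta(records: Iterable[CdnaRecord], handle: TextIO) -> None:
    SeqIO.write(
        (
            SeqRecord(Seq(r.seq), id=r.id, description=r.description)
            for r in records
        ),
        handle,
        "fasta",
    )
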