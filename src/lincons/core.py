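"""Core domain types shared across the pipeline.

Coordinates are uniformly 0-based half-open; 1-based coordinates appear
only in human-readable reports. Strand is one of ``+``, ``-``, ``.``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int | None:
        """Bases strictly between the two intervals; 0 when they touch or
        overlap; None when on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        return max(other.start - self.end, self.start - other.end, 0)


@dataclass
class TranscriptModel:
    """A stranded, multi-exon locus with BED12 semantics.

    Exons are sorted by genomic start, non-overlapping, and flush with the
    locus interval at both ends. ``biotype`` is one of
    {"lncRNA", "coding", "other"}.
    """

    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: needs at least one exon")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"transcript {self.id}: exon on wrong chrom")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"transcript {self.id}: exon {ex.start}-{ex.end} outside "
                    f"locus {self.interval.start}-{self.interval.end}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"transcript {self.id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        if self.exons[0].start != self.interval.start:
            raise ValueError(f"transcript {self.id}: first exon not at locus start")
        if self.exons[-1].end != self.interval.end:
            raise ValueError(f"transcript {self.id}: last exon not at locus end")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        """Strand-aware 5' end. For '-' transcripts this is interval.end - 1
        expressed as the position of the first transcribed base."""
        if self.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.chrom, a.end, b.start, self.strand)
                )
        return out

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


class ScoreTrack:
    """Per-base conservation scores in [0, 1], keyed by chromosome.

    Internally a dense float array per chromosome with NaN marking positions
    absent from the track (e.g. unalignable bases in a phastCons track).
    """

    def __init__(self) -> None:
        self._data: dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def _ensure(self, chrom: str, end: int) -> np.ndarray:
        arr = self._data.get(chrom)
        if arr is None:
            arr = np.full(end, np.nan)
            self._data[chrom] = arr
        elif arr.size < end:
            # geometric growth: amortized O(1) per appended interval
            grown = np.full(max(end, 2 * arr.size), np.nan)
            grown[: arr.size] = arr
            arr = grown
            self._data[chrom] = arr
        return arr

    def set_range(self, chrom: str, start: int, end: int, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"score {value} outside [0, 1]")
        arr = self._ensure(chrom, end)
        if np.any(~np.isnan(arr[start:end])):
            raise ValueError(
                f"overlapping score assignment on {chrom}:{start}-{end}"
            )
        arr[start:end] = value

    def set_array(self, chrom: str, values: np.ndarray) -> None:
        """Install a full per-base array (NaN = undefined) for a chromosome."""
        values = np.asarray(values, dtype=float)
        defined = values[~np.isnan(values)]
        if defined.size and (defined.min() < 0 or defined.max() > 1):
            raise ValueError("scores outside [0, 1]")
        self._data[chrom] = values

    def array(self, chrom: str) -> np.ndarray:
        return self._data[chrom]

    def scores(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Scores at the given positions; NaN for undefined or out-of-range."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, np.nan)
        arr = self._data.get(chrom)
        if arr is None:
            return out
        ok = (positions >= 0) & (positions < arr.size)
        out[ok] = arr[positions[ok]]
        return out

    def score(self, chrom: str, pos: int) -> float:
        return float(self.scores(chrom, np.array([pos]))[0])


@dataclass(frozen=True)
class ConservedElement:
    """A discrete conserved element with an integer log-odds score (1-1000)."""

    interval: GenomicInterval
    score: int

    def __post_init__(self) -> None:
        if not (1 <= self.score <= 1000):
            raise ValueError(f"element score {self.score} outside [1, 1000]")


@dataclass
class AlignmentRow:
    """One gapped row of an alignment block (MAF 's' line semantics)."""

    species: str
    src_chrom: str
    src_start: int
    src_size: int
    strand: str
    src_length: int
    text: str

    def __post_init__(self) -> None:
        ungapped = len(self.text) - self.text.count("-")
        if ungapped != self.src_size:
            raise ValueError(
                f"row {self.species}.{self.src_chrom}: src_size {self.src_size} "
                f"!= {ungapped} non-gap characters"
            )
        if self.src_start + self.src_size > self.src_length:
            raise ValueError(
                f"row {self.species}.{self.src_chrom}: start+size exceeds "
                f"source length {self.src_length}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def src(self) -> str:
        return f"{self.species}.{self.src_chrom}"


@dataclass
class AlignmentBlock:
    """Gapped aligned rows with reference coordinates (MAF semantics)."""

    rows: list[AlignmentRow]
    reference: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment block has no rows")
        width = len(self.rows[0].text)
        for row in self.rows:
            if len(row.text) != width:
                raise ValueError(
                    f"row {row.src}: text length {len(row.text)} != {width}"
                )
        if not (0 <= self.reference < len(self.rows)):
            raise ValueError("reference row index out of range")

    @property
    def width(self) -> int:
        return len(self.rows[0].text)

    @property
    def ref(self) -> AlignmentRow:
        return self.rows[self.reference]


VALID_NT = set("ACGTN")


@dataclass
class CdnaRecord:
    """A cDNA (or genomic) nucleotide sequence record."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id}: empty sequence")
        self.seq = self.seq.upper().replace("U", "T")
        bad = set(self.seq) - VALID_NT
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"record {self.id}: illegal character {self.seq[pos]!r} at "
                f"position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]
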