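"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the features the pipeline measures on
real data: a genome with protein-coding genes and interleaved multi-exon
lncRNA loci; a conservation track whose score rises in a smooth bump inside
the 200 bp promoter window (centered a configurable distance upstream of the
TSS) and near splice sites; discrete conserved elements covering a target
fraction of exonic bases; pairwise alignments with planted high-identity
segments (ECRs) on a lower-identity background; and ortholog cDNA pairs whose
expected identical-aligned fraction is set by configuration.

Every generator is fully deterministic under (seed, config) and emits
machine-readable ground truth sufficient to score recovery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AlignmentBlock,
    AlignmentRow,
    CdnaRecord,
    ConservedElement,
    GenomicInterval,
    ScoreTrack,
    TranscriptModel,
)

NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic genome, with study-condition defaults.

    The promoter bump defaults (height 0.19 over a 0.05 background, centered
    43 bp upstream of the TSS) and the ECR regime (planted segments >= 100 bp
    at >= 70% identity) mirror the conservation structure the analysis is
    designed to detect.
    """

    seed: int = 0
    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 600_000
    n_coding: int = 30
    n_lncrna: int = 30
    exon_count_range: tuple[int, int] = (2, 5)
    exon_len_range: tuple[int, int] = (80, 300)
    intron_len_range: tuple[int, int] = (200, 1500)
    min_distance: int = 5000
    frac_proximal: float = 0.2
    frac_overlapping: float = 0.1
    proximal_gap_range: tuple[int, int] = (500, 4500)
    distal_gap_range: tuple[int, int] = (7000, 20000)
    forced_gaps: list[int] | None = None
    # conservation track
    promoter_peak_offset: int = 43
    promoter_peak_height: float = 0.19
    promoter_peak_sigma: float = 10.0
    splice_peak_height: float = 0.12
    splice_peak_halfwidth: int = 20
    background_score_mean: float = 0.05
    background_jitter: float = 0.03
    element_exonic_coverage: float = 0.30
    exon_conserved_prob: float = 0.6
    exon_conserved_height: float = 0.25
    # pairwise alignment / ECRs
    alignment_length: int = 2000
    background_identity: float = 0.5
    gap_rate: float = 0.02
    ecr_specs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(500, 150, 0.9)]
    )
    ref_offset: int = 1000
    # ortholog cDNA pairs
    ortholog_length: int = 2000
    ortholog_identity: float = 0.5
    ortholog_block_identity: float = 0.95
    ortholog_block_len: int = 160
    conserved_3p_block: int = 120
    n_indels: int = 4
    indel_len_range: tuple[int, int] = (1, 10)
    plant_polya: bool = True
    polya_offset_3p: int = 30

    def validate(self) -> None:
        for name in (
            "frac_proximal",
            "frac_overlapping",
            "background_identity",
            "gap_rate",
            "element_exonic_coverage",
            "promoter_peak_height",
            "splice_peak_height",
            "background_score_mean",
            "ortholog_identity",
            "ortholog_block_identity",
            "exon_conserved_prob",
            "exon_conserved_height",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("exon_count_range", "exon_len_range", "intron_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} is empty or non-positive")
        for start, length, ident in self.ecr_specs:
            if start < 0 or start + length > self.alignment_length:
                raise ValueError("planted ECR segment outside alignment bounds")
            if not (0.0 <= ident <= 1.0):
                raise ValueError("planted ECR identity outside [0, 1]")


def _rng(cfg: SyntheticConfig, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage, index])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _make_locus(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    strand: str,
    name: str,
    biotype: str,
    cfg: SyntheticConfig,
) -> TranscriptModel:
    n_ex = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
    exons = []
    pos = start
    for i in range(n_ex):
        ex_len = int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + ex_len, strand))
        pos += ex_len
        if i < n_ex - 1:
            pos += int(
                rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1)
            )
    return TranscriptModel(
        id=name,
        interval=GenomicInterval(chrom, start, pos, strand),
        exons=exons,
        biotype=biotype,
    )


def _brute_force_labels(
    lncrnas: list[TranscriptModel],
    coding: list[TranscriptModel],
    min_distance: int,
) -> pd.DataFrame:
    """Ground-truth filter labels by exhaustive pairwise scan (independent of
    the production filter implementation)."""
    rows = []
    for tx in lncrnas:
        exon_overlap = any(
            e.overlaps(ce)
            for cg in coding
            if cg.chrom == tx.chrom
            for e in tx.exons
            for ce in cg.exons
        )
        dists = [
            tx.interval.gap_to(cg.interval)
            for cg in coding
            if cg.chrom == tx.chrom
        ]
        nearest = min(dists) if dists else None
        if exon_overlap:
            label = "overlaps_coding"
        elif nearest is not None and nearest < min_distance:
            label = "within_proximity"
        else:
            label = "kept"
        rows.append(
            {"id": tx.id, "label": label, "nearest_coding_distance": nearest}
        )
    return pd.DataFrame(rows)


def generate_annotation(
    cfg: SyntheticConfig,
) -> tuple[list[TranscriptModel], list[TranscriptModel], pd.DataFrame]:
    """Place coding genes and interleaved lncRNA loci on synthetic chromosomes.

    Coding and lncRNA loci alternate along each chromosome. A configurable
    fraction of lncRNAs is deliberately placed closer than ``min_distance``
    to the preceding coding gene, and another fraction with its first exon
    overlapping a coding exon, so the selection filters have true positives
    to find. Returns (coding, lncrna, truth) where ``truth`` holds per-lncRNA
    ground-truth filter labels computed by brute-force pairwise scan.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    coding: list[TranscriptModel] = []
    lncrnas: list[TranscriptModel] = []
    per_chrom = [[] for _ in range(cfg.n_chroms)]
    order = []
    for i in range(max(cfg.n_coding, cfg.n_lncrna)):
        if i < cfg.n_coding:
            order.append(("coding", i))
        if i < cfg.n_lncrna:
            order.append(("lncRNA", i))
    # contiguous chunks per chromosome, preserving coding/lncRNA alternation
    for k, item in enumerate(order):
        per_chrom[k * cfg.n_chroms // len(order)].append(item)

    n_lnc_seen = 0
    for ci, items in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(1000, 3000))
        prev: TranscriptModel | None = None
        for kind, idx in items:
            strand = "+" if rng.random() < 0.5 else "-"
            if kind == "coding":
                gap = int(rng.integers(*cfg.distal_gap_range))
                start = cursor + gap if prev is not None else cursor
                tx = _make_locus(
                    rng, chrom, start, strand, f"gene{idx + 1}", "coding", cfg
                )
                coding.append(tx)
            else:
                forced = (
                    cfg.forced_gaps[n_lnc_seen]
                    if cfg.forced_gaps is not None
                    and n_lnc_seen < len(cfg.forced_gaps)
                    else None
                )
                u = rng.random()
                if forced is not None:
                    gap = forced
                elif prev is not None and u < cfg.frac_overlapping:
                    # overlap the previous coding gene's last exon
                    gap = -int(rng.integers(10, min(50, prev.exons[-1].length)))
                elif u < cfg.frac_overlapping + cfg.frac_proximal:
                    gap = int(rng.integers(*cfg.proximal_gap_range))
                else:
                    gap = int(rng.integers(*cfg.distal_gap_range))
                start = cursor + gap if prev is not None else cursor
                tx = _make_locus(
                    rng, chrom, start, strand, f"lnc{idx + 1}", "lncRNA", cfg
                )
                lncrnas.append(tx)
                n_lnc_seen += 1
            cursor = tx.interval.end
            prev = tx
            if cursor > cfg.chrom_length:
                raise ValueError(
                    f"loci do not fit on {chrom} (cursor {cursor} > "
                    f"chrom_length {cfg.chrom_length}); increase chrom_length "
                    "or n_chroms"
                )
    truth = _brute_force_labels(lncrnas, coding, cfg.min_distance)
    return coding, lncrnas, truth


# ---------------------------------------------------------------------------
# Conservation track + conserved elements
# ---------------------------------------------------------------------------

def _add_bump(
    arr: np.ndarray, center: int, height: float, sigma: float, halfwidth: int
) -> None:
    lo = max(0, center - halfwidth)
    hi = min(arr.size, center + halfwidth + 1)
    if lo >= hi:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] += height * np.exp(-((x - center) ** 2) / (2 * sigma**2))


def generate_score_track(
    cfg: SyntheticConfig, lncrnas: list[TranscriptModel]
) -> tuple[ScoreTrack, list[ConservedElement]]:
    """Synthesize a per-base conservation track and discrete elements.

    Background scores are independent uniform jitter around
    ``background_score_mean``. A Gaussian bump (sigma 10 bp) of height
    ``promoter_peak_height`` is centered ``promoter_peak_offset`` bases 5' of
    each lncRNA TSS, strand-aware; bumps of ``splice_peak_height`` span each
    internal splice site. Elements are maximal runs above the score threshold
    that makes the covered fraction of lncRNA exonic bases hit
    ``element_exonic_coverage`` (+- 0.05, else an error).
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    chroms = sorted({tx.chrom for tx in lncrnas}) or [
        f"chr{i + 1}" for i in range(cfg.n_chroms)
    ]
    track = ScoreTrack()
    arrays: dict[str, np.ndarray] = {}
    for chrom in chroms:
        arr = cfg.background_score_mean + rng.uniform(
            -cfg.background_jitter, cfg.background_jitter, cfg.chrom_length
        )
        arrays[chrom] = arr
    for tx in lncrnas:
        arr = arrays[tx.chrom]
        if tx.strand == "-":
            center = tx.tss + cfg.promoter_peak_offset
        else:
            center = tx.tss - cfg.promoter_peak_offset
        _add_bump(
            arr,
            center,
            cfg.promoter_peak_height,
            cfg.promoter_peak_sigma,
            int(4 * cfg.promoter_peak_sigma),
        )
        for a, b in zip(tx.exons, tx.exons[1:]):
            for site in (a.end, b.start):
                _add_bump(
                    arr,
                    site,
                    cfg.splice_peak_height,
                    cfg.splice_peak_halfwidth / 2.5,
                    cfg.splice_peak_halfwidth,
                )
        # conserved exonic segments: the discrete-element substrate
        for ex in tx.exons:
            if rng.random() >= cfg.exon_conserved_prob:
                continue
            seg_len = max(10, int(ex.length * rng.uniform(0.2, 0.8)))
            seg_len = min(seg_len, ex.length)
            s = ex.start + int(rng.integers(0, ex.length - seg_len + 1))
            arr[s : s + seg_len] += cfg.exon_conserved_height
    for chrom in chroms:
        arrays[chrom] = np.clip(arrays[chrom], 0.0, 1.0)
        track.set_array(chrom, arrays[chrom])

    elements: list[ConservedElement] = []
    if cfg.element_exonic_coverage == 0:
        return track, elements
    exonic = np.concatenate(
        [
            arrays[tx.chrom][e.start : e.end]
            for tx in lncrnas
            for e in tx.exons
        ]
    )
    threshold = float(np.quantile(exonic, 1.0 - cfg.element_exonic_coverage))
    achieved = float(np.mean(exonic > threshold))
    if abs(achieved - cfg.element_exonic_coverage) > 0.05:
        raise ValueError(
            f"element coverage {cfg.element_exonic_coverage} unreachable at the "
            f"configured peak heights (achieved {achieved:.3f}); raise the peak "
            "heights or lower the target"
        )
    for chrom in chroms:
        above = arrays[chrom] > threshold
        padded = np.concatenate([[False], above, [False]])
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for s, e in zip(run_starts, run_ends):
            score = int(round(1 + 999 * float(np.mean(arrays[chrom][s:e]))))
            elements.append(
                ConservedElement(
                    GenomicInterval(chrom, int(s), int(e)),
                    min(1000, max(1, score)),
                )
            )
    return track, elements


# ---------------------------------------------------------------------------
# Pairwise alignments with planted ECRs
# ---------------------------------------------------------------------------

def generate_alignment(
    cfg: SyntheticConfig, index: int = 0
) -> tuple[list[AlignmentBlock], list[GenomicInterval]]:
    """One two-species alignment block with planted high-identity segments.

    Per-column match probability equals ``background_identity`` outside the
    planted segments and the segment's own identity inside it. Gap columns
    (deletions or insertions in the second species) occur at ``gap_rate``
    outside planted segments only, so planted identities are exact by
    construction. Returns (blocks, truth) where truth lists the planted
    segments in reference-genome coordinates.
    """
    cfg.validate()
    rng = _rng(cfg, 2, index)
    L = cfg.alignment_length
    planted = np.zeros(L, dtype=bool)
    p_match = np.full(L, cfg.background_identity)
    truth: list[GenomicInterval] = []
    for start, length, ident in cfg.ecr_specs:
        planted[start : start + length] = True
        p_match[start : start + length] = ident
        truth.append(
            GenomicInterval(
                "chr1", cfg.ref_offset + start, cfg.ref_offset + start + length
            )
        )
    bases = np.array(list("ACGT"))
    ref_seq = bases[rng.integers(0, 4, L)]
    ref_cols: list[str] = []
    oth_cols: list[str] = []
    for i in range(L):
        if not planted[i] and rng.random() < cfg.gap_rate:
            if rng.random() < 0.5:  # deletion in other species
                ref_cols.append(ref_seq[i])
                oth_cols.append("-")
                continue
            else:  # insertion column before this base
                ref_cols.append("-")
                oth_cols.append(str(bases[rng.integers(0, 4)]))
        ref_cols.append(ref_seq[i])
        if rng.random() < p_match[i]:
            oth_cols.append(ref_seq[i])
        else:
            choices = [b for b in "ACGT" if b != ref_seq[i]]
            oth_cols.append(choices[rng.integers(0, 3)])
    ref_text = "".join(ref_cols)
    oth_text = "".join(oth_cols)
    oth_size = len(oth_text) - oth_text.count("-")
    ref_size = len(ref_text) - ref_text.count("-")
    block = AlignmentBlock(
        rows=[
            AlignmentRow(
                "mouse", "chr1", cfg.ref_offset, ref_size, "+",
                cfg.ref_offset + ref_size + 1000, ref_text,
            ),
            AlignmentRow(
                "chicken", "chr2", 0, oth_size, "+", oth_size + 1000, oth_text
            ),
        ]
    )
    return [block], truth


# ---------------------------------------------------------------------------
# Ortholog cDNA pairs
# ---------------------------------------------------------------------------

def generate_ortholog_pair(
    cfg: SyntheticConfig, index: int = 0
) -> tuple[CdnaRecord, CdnaRecord]:
    """A mouse-like query cDNA and a diverged ortholog.

    Homology is block-structured, as in real ortholog pairs: conserved blocks
    (within-block identity ``ortholog_block_identity``) cover just enough of
    the query that the expected identical-aligned fraction equals
    ``ortholog_identity``; sequence between blocks is unrelated. When the
    requested identity exceeds the block identity the whole sequence becomes
    one block with per-base identity equal to the request. Short indels
    (1-10 bp) fall only between conserved blocks, and the conserved 3' block
    (with its ATAAA signal 30 bp from the 3' end when ``plant_polya``) is
    copied exactly, so planted quantities are exact by construction.
    """
    cfg.validate()
    rng = _rng(cfg, 3, index)
    L = cfg.ortholog_length
    f = cfg.ortholog_identity
    query = list(_random_seq(rng, L))
    polya_start = L - cfg.polya_offset_3p
    if cfg.plant_polya:
        query[polya_start : polya_start + 5] = list("ATAAA")
        if polya_start >= 1 and query[polya_start - 1] == "A":
            query[polya_start - 1] = "C"  # avoid an accidental AATAAA hexamer
        # scrub chance poly(A) signals downstream of the planted one
        for i in range(polya_start + 1, L - 4):
            if "".join(query[i : i + 5]) == "ATAAA":
                query[i + 2] = "C"

    if f >= cfg.ortholog_block_identity or f == 0.0:
        blocks = [(0, L)] if f > 0 else []
        within = f
    else:
        within = cfg.ortholog_block_identity
        target = int(round(f * L / within))
        blocks = []
        b3 = min(cfg.conserved_3p_block, L, target) if target else 0
        remaining = max(0, target - b3)
        if b3:
            blocks.append((L - b3, L))
        # scatter the rest upstream of the 3' block; random offsets are capped
        # by the spare room so the full target coverage always fits
        avail_end = L - b3 if b3 else L
        cursor = 0
        while remaining > 0 and cursor < avail_end:
            blen = min(cfg.ortholog_block_len, remaining, avail_end - cursor)
            spare = avail_end - cursor - remaining
            off = int(rng.integers(0, min(max(spare, 0), 200) + 1))
            start = cursor + off
            blocks.append((start, start + blen))
            gap = min(20, max(0, avail_end - (start + blen) - (remaining - blen)))
            cursor = start + blen + gap
            remaining -= blen
        blocks.sort()

    # The subject is the ordered concatenation of mutated copies of the
    # query's homology blocks, joined by short unrelated spacers. Sequence
    # outside the blocks is simply absent from the ortholog (real ortholog
    # pairs differ in length), so non-homologous bases never sit on the
    # query diagonal and cannot inflate recovered identity by chance.
    ends_with_3p = bool(blocks) and blocks[-1][1] == L
    exact_3p_from = L - cfg.conserved_3p_block if cfg.plant_polya else L
    subject: list[str] = []
    for bi, (s, e) in enumerate(blocks):
        if bi > 0 or s > 0:
            spacer = int(rng.integers(8, 20))
            subject.extend(_random_seq(rng, spacer))
        copy = []
        for i in range(s, e):
            base = query[i]
            keep_exact = ends_with_3p and bi == len(blocks) - 1 and i >= exact_3p_from
            if not keep_exact and rng.random() >= within:
                base = [b for b in "ACGT" if b != base][rng.integers(0, 3)]
            copy.append(base)
        # short indels inside non-3' blocks only
        if f < 1.0 and cfg.n_indels > 0 and not (ends_with_3p and bi == len(blocks) - 1):
            for _ in range(max(1, cfg.n_indels // max(1, len(blocks) - 1)) if len(blocks) > 1 else cfg.n_indels):
                if len(copy) < 30:
                    break
                ilen = int(
                    rng.integers(cfg.indel_len_range[0], cfg.indel_len_range[1] + 1)
                )
                site = int(rng.integers(5, len(copy) - 5))
                if rng.random() < 0.5:
                    del copy[site : site + ilen]
                else:
                    copy[site:site] = list(_random_seq(rng, ilen))
        subject.extend(copy)
    if not blocks:
        subject = list(_random_seq(rng, L))

    qid = f"query{index + 1}"
    sid = f"ortholog{index + 1}"
    return (
        CdnaRecord(qid, "".join(query), "synthetic reference cDNA"),
        CdnaRecord(sid, "".join(subject), "synthetic ortholog cDNA"),
    )


# ---------------------------------------------------------------------------
# Neutral codon-pair simulation (dN/dS calibration regime)
# ---------------------------------------------------------------------------

def neutral_codon_pair(
    rng: np.random.Generator, n_codons: int = 300, mu: float = 0.1
) -> tuple[str, str]:
    """Simulate an ORF codon pair under equal per-site substitution pressure.

    Each nucleotide site of the derived copy mutates with probability ``mu``
    uniformly to one of the other three bases, with no selection on the
    protein; codons that would become stops are redrawn. The dN/dS of such
    pairs is ~1, the neutral regime.
    """
    a_codons = [NON_STOP_CODONS[i] for i in rng.integers(0, len(NON_STOP_CODONS), n_codons)]
    b_codons = []
    for codon in a_codons:
        for _ in range(100):
            out = []
            for ch in codon:
                if rng.random() < mu:
                    out.append([b for b in "ACGT" if b != ch][rng.integers(0, 3)])
                else:
                    out.append(ch)
            cand = "".join(out)
            if cand not in ("TAA", "TAG", "TGA"):
                break
        else:
            cand = codon
        b_codons.append(cand)
    return "".join(a_codons), "".join(b_codons)
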