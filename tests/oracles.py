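"""Independent brute-force reference implementations used to validate the
production code. Everything here favours obviousness over speed: per-base
counting, exhaustive window enumeration, O(n*m) dynamic programming, and
explicit codon enumeration via Biopython's translation table.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Seq import Seq

from lincons.core import AlignmentBlock, ConservedElement, TranscriptModel

# ---------------------------------------------------------------------------
# locus_filter oracles
# ---------------------------------------------------------------------------

def brute_filter(
    lncrnas: list[TranscriptModel],
    coding: list[TranscriptModel],
    min_distance: int,
) -> list[tuple[str, str, int | None]]:
    """(id, reason, nearest_distance) by all-pairs interval scanning."""
    out = []
    for tx in lncrnas:
        overlap = False
        for cg in coding:
            if cg.chrom != tx.chrom:
                continue
            for e in tx.exons:
                for ce in cg.exons:
                    if max(e.start, ce.start) < min(e.end, ce.end):
                        overlap = True
        dists = []
        for cg in coding:
            if cg.chrom != tx.chrom:
                continue
            a, b = tx.interval, cg.interval
            if max(a.start, b.start) < min(a.end, b.end):
                dists.append(0)
            else:
                dists.append(max(b.start - a.end, a.start - b.end))
        nearest = min(dists) if dists else None
        if overlap:
            reason = "overlaps_coding"
        elif nearest is not None and nearest < min_distance:
            reason = "within_proximity"
        else:
            reason = "kept"
        out.append((tx.id, reason, nearest))
    return out


def brute_overlap_fraction(
    tx: TranscriptModel, elements: list[ConservedElement]
) -> tuple[float, float]:
    """(exonic_fraction, genic_fraction) by per-base membership testing."""
    covered = set()
    for el in elements:
        if el.interval.chrom == tx.chrom:
            covered.update(range(el.interval.start, el.interval.end))
    exonic = [p for e in tx.exons for p in range(e.start, e.end)]
    genic = range(tx.interval.start, tx.interval.end)
    n_ex = sum(1 for p in exonic if p in covered)
    n_gen = sum(1 for p in genic if p in covered)
    return n_ex / len(exonic), n_gen / tx.interval.length


# ---------------------------------------------------------------------------
# ecr_detect oracle
# ---------------------------------------------------------------------------

def brute_scan_ecrs(
    block: AlignmentBlock, min_length: int, min_identity: float
) -> list[tuple[int, int, float, int]]:
    """(ref_start, ref_end, identity_pct, n_windows) by exhaustive window
    enumeration, union merging, and O(n^2) boundary trimming."""
    ref = block.ref.text.upper()
    oth = block.rows[1 if block.reference == 0 else 0].text.upper()
    flags = []
    for a, b in zip(ref, oth):
        if a == "-":
            continue
        flags.append(a == b and b != "-" and a != "N" and b != "N")
    from fractions import Fraction

    ratio = Fraction(str(min_identity)).limit_denominator(10**6)
    num, den = ratio.numerator, ratio.denominator
    n = len(flags)
    w = min_length
    qual = [
        i
        for i in range(0, n - w + 1)
        if sum(flags[i : i + w]) * den >= num * w
    ]
    if not qual:
        return []
    clusters = []
    cur = [qual[0]]
    for i in qual[1:]:
        if i <= cur[-1] + w:
            cur.append(i)
        else:
            clusters.append(cur)
            cur = [i]
    clusters.append(cur)
    out = []
    src = block.ref.src_start
    pre = [0]
    for f in flags:
        pre.append(pre[-1] + f)
    for cluster in clusters:
        s, e = cluster[0], cluster[-1] + w
        best = None  # (score, length, -start, s2, e2)
        for s2 in range(s, e - w + 1):
            for e2 in range(s2 + w, e + 1):
                score = (pre[e2] - pre[s2]) * den - num * (e2 - s2)
                key = (score, e2 - s2, -s2)
                if best is None or key > best[:3]:
                    best = (*key, s2, e2)
        s2, e2 = best[3], best[4]
        ident = 100.0 * (pre[e2] - pre[s2]) / (e2 - s2)
        out.append((src + s2, src + e2, ident, len(cluster)))
    return out


# ---------------------------------------------------------------------------
# windowed identity oracle
# ---------------------------------------------------------------------------

def brute_windowed_identity(
    block: AlignmentBlock, window: int, step: int
) -> list[tuple[str, int, int, float]]:
    ref_row = block.ref
    out = []
    for ri, row in enumerate(block.rows):
        if ri == block.reference:
            continue
        for c in range(0, block.width - window + 1, step):
            ref_bases_before = sum(
                1 for ch in ref_row.text[:c] if ch != "-"
            )
            n_ref = sum(1 for ch in ref_row.text[c : c + window] if ch != "-")
            if n_ref == 0:
                continue
            matches = 0
            for a, b in zip(
                ref_row.text[c : c + window].upper(),
                row.text[c : c + window].upper(),
            ):
                if a == b and a not in "-N" and b not in "-N":
                    matches += 1
            out.append(
                (
                    row.species,
                    ref_row.src_start + ref_bases_before,
                    ref_row.src_start + ref_bases_before + n_ref,
                    100.0 * matches / window,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Smith-Waterman affine-gap oracle (Gotoh), BLAST gap convention
# ---------------------------------------------------------------------------

def sw_affine_score(
    a: str,
    b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> float:
    """Best local alignment score; a gap of length k costs open + k*extend."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    first_gap = -(gap_open + gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + first_gap, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] + first_gap, F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return float(H.max())


# ---------------------------------------------------------------------------
# IUPAC scan oracle
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_iupac_positions(seq: str, pattern: str) -> list[int]:
    pattern = pattern.replace("|", "").upper()
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        ok = True
        for k, sym in enumerate(pattern):
            if seq[i + k] not in _IUPAC[sym]:
                ok = False
                break
        if ok:
            hits.append(i)
    return hits


# ---------------------------------------------------------------------------
# NG86 oracle (independent path: Biopython translation, explicit enumeration)
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_ng86(seq_a: str, seq_b: str) -> tuple[float, float, float, float]:
    """(N, S, Nd, Sd) by direct enumeration over codon pairs."""
    N = S = Nd = Sd = 0.0
    for k in range(len(seq_a) // 3):
        c1, c2 = seq_a[3 * k : 3 * k + 3], seq_b[3 * k : 3 * k + 3]
        if "-" in c1 + c2 or c1 in _STOPS or c2 in _STOPS:
            continue
        diff = [i for i in range(3) if c1[i] != c2[i]]
        paths = []
        for order in permutations(diff):
            cur, nd, sd, ok = c1, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if nxt in _STOPS:
                    ok = False
                    break
                if _aa(nxt) == _aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                paths.append((nd, sd))
        if diff and not paths:
            continue  # stop-blocked pair: dropped entirely (sites excluded)
        for codon in (c1, c2):
            syn = tot = 0
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    mut = codon[:pos] + base + codon[pos + 1 :]
                    if mut in _STOPS:
                        continue
                    tot += 1
                    if _aa(mut) == _aa(codon):
                        syn += 1
            S += 0.5 * 3 * syn / tot
            N += 0.5 * (3 - 3 * syn / tot)
        if paths:
            Nd += sum(p[0] for p in paths) / len(paths)
            Sd += sum(p[1] for p in paths) / len(paths)
    return N, S, Nd, Sd
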