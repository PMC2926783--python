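"""Coding-potential screening: longest-ORF detection and Nei-Gojobori dN/dS.

Transcripts with no ORF longer than 100 amino acids and with dN/dS near 1
on their longest ORF show no sign of protein-level selective constraint —
the expected signature of a noncoding RNA. dN/dS is computed by the
Nei-Gojobori (1986) counting method with Jukes-Cantor multiple-hit
correction: synonymous/nonsynonymous *sites* are counted per codon from the
nine single-nucleotide mutants (stop mutants excluded, counts rescaled so
n + s = 3), and *differences* between a codon pair are classified by
averaging over all substitution orderings that avoid stop-codon
intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log

from Bio.Data.CodonTable import standard_dna_table

from .core import CdnaRecord

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)  # TAA, TAG, TGA


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    if codon in STOP_CODONS:
        return None
    return CODON_TABLE[codon]


# ---------------------------------------------------------------------------
# ORF detection
# ---------------------------------------------------------------------------

@dataclass
class OrfRecord:
    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int  # half-open; includes the stop codon when complete
    aa_length: int  # codons excluding the stop
    complete: bool  # has both ATG and in-frame stop

    @property
    def long_orf(self) -> bool:
        """True when the ORF exceeds 100 amino acids (strict)."""
        return self.aa_length > 100


def find_longest_orf(tx: CdnaRecord, aa_threshold: int = 100) -> OrfRecord | None:
    """Longest forward-strand ORF across all three frames.

    ATG to the first in-frame stop; an ATG with no downstream stop yields an
    incomplete ORF counted by its current codon length (cDNA truncation is
    common). ORFs containing N are skipped. Ties go to the 5'-most start.
    Returns None when no ORF exists.
    """
    seq = tx.seq
    best: OrfRecord | None = None
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] != "ATG":
                i += 3
                continue
            j = i
            complete = False
            has_n = False
            while j + 3 <= len(seq):
                codon = seq[j : j + 3]
                if "N" in codon:
                    has_n = True
                if codon in STOP_CODONS:
                    complete = True
                    break
                j += 3
            if complete:
                nt_end = j + 3
                aa_len = (j - i) // 3
            else:
                nt_end = i + ((len(seq) - i) // 3) * 3
                aa_len = (nt_end - i) // 3
            if not has_n and aa_len > 0:
                cand = OrfRecord(tx.id, frame, i, nt_end, aa_len, complete)
                if (
                    best is None
                    or cand.aa_length > best.aa_length
                    or (cand.aa_length == best.aa_length and cand.nt_start < best.nt_start)
                ):
                    best = cand
            # next ATG in this frame strictly after this one
            i += 3
    return best


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986
# ---------------------------------------------------------------------------

def ng86_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon.

    Enumerates the nine single-nucleotide mutants; mutants that are stop
    codons are excluded and the counts rescaled so n + s = 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no NG86 site counts")
    aa = CODON_TABLE[codon]
    syn = 0
    counted = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            counted += 1
            if CODON_TABLE[mut] == aa:
                syn += 1
    if counted == 0:
        raise ValueError(f"codon {codon}: all mutants are stops")
    s = 3.0 * syn / counted
    return 3.0 - s, s


def _pathway_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """(nonsyn, syn) difference counts for one codon pair, averaged over all
    substitution orderings that avoid stop intermediates; None when every
    pathway crosses a stop."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff_pos):
        cur = c1
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((nd, sd))
    if not totals:
        return None
    nd = sum(t[0] for t in totals) / len(totals)
    sd = sum(t[1] for t in totals) / len(totals)
    return nd, sd


@dataclass
class DnDsEstimate:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None  # None when the Jukes-Cantor correction is undefined
    dS: float | None
    ratio: float | None  # None when dS is 0 or undefined
    codons_compared: int
    codons_dropped: int  # gapped or stop-blocked codon pairs (QC)


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(seq_a: str, seq_b: str) -> DnDsEstimate:
    """NG86 dN/dS for a pre-aligned codon pair (gaps as ``-``).

    Both sequences must have equal length divisible by 3. Codon pairs
    containing a gap are dropped; an internal stop codon raises (a trailing
    stop pair is tolerated and excluded from the counts). Codon pairs whose
    every substitution pathway crosses a stop are dropped and counted in
    ``codons_dropped``. The estimate is symmetric in its two arguments.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("aligned length not divisible by 3")
    n_codons = len(seq_a) // 3
    N = S = Nd = Sd = 0.0
    compared = dropped = 0
    for k in range(n_codons):
        c1 = seq_a[3 * k : 3 * k + 3]
        c2 = seq_b[3 * k : 3 * k + 3]
        if "-" in c1 or "-" in c2:
            dropped += 1
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            if k == n_codons - 1:  # trailing stop: not compared
                dropped += 1
                continue
            raise ValueError(f"internal stop codon at codon index {k}")
        diffs = _pathway_differences(c1, c2)
        if diffs is None:
            dropped += 1
            continue
        n1, s1 = ng86_sites(c1)
        n2, s2 = ng86_sites(c2)
        N += (n1 + n2) / 2.0
        S += (s1 + s2) / 2.0
        Nd += diffs[0]
        Sd += diffs[1]
        compared += 1
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    dN = _jc(pN)
    dS = _jc(pS)
    ratio = None
    if dN is not None and dS is not None and dS > 0:
        ratio = dN / dS
    return DnDsEstimate(
        N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, dN=dN, dS=dS, ratio=ratio,
        codons_compared=compared, codons_dropped=dropped,
    )
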