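"""Ortholog percent identity from local alignments, and windowed identity
profiles across alignment blocks.

Overall identity between a reference cDNA and an ortholog is computed the
way BLASTn-based summaries are usually read: the best-scoring local
alignment (affine gaps, +2/-3 match/mismatch, gap open 5 extend 2 — the
BLASTn nucleotide defaults) is found by exact dynamic programming, its
query span is masked, and the search repeats until no hit reaches
``min_score``. The percent is 100 x (summed identities over the accepted,
query-disjoint hits) / query length, so it is deliberately asymmetric: the
denominator is always the reference transcript length. Query-masking
guarantees the summed identities can never exceed that denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from .core import AlignmentBlock, CdnaRecord

DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": 5, "gap_extend": 2}
_MASK = "X"
_ALPHABET = "ACGTN" + _MASK


@dataclass
class LocalHit:
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    score: float
    identities: int
    aligned_len: int

    def __post_init__(self) -> None:
        if self.identities > self.aligned_len:
            raise ValueError("identities cannot exceed aligned columns")


@dataclass
class IdentitySummary:
    query_id: str
    subject_id: str
    total_identities: int
    query_length: int
    percent: float
    n_hits: int


def _make_aligner(scoring: dict) -> Align.PairwiseAligner:
    matrix = Align.substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == _MASK or b == _MASK:
                matrix[a, b] = -1_000_000.0
            elif a == "N" or b == "N":
                matrix[a, b] = scoring["mismatch"]
            else:
                matrix[a, b] = (
                    scoring["match"] if a == b else scoring["mismatch"]
                )
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: a gap of length k costs open + k*extend
    aligner.open_gap_score = -(scoring["gap_open"] + scoring["gap_extend"])
    aligner.extend_gap_score = -scoring["gap_extend"]
    return aligner


def _best_alignment(alignments, max_enumerate: int = 64):
    """Deterministic tie-break among equal-scoring optimal alignments:
    smallest query start, then smallest subject start."""
    best = None
    best_key = None
    for i, aln in enumerate(alignments):
        qb, sb = aln.aligned
        key = (int(qb[0][0]), int(sb[0][0]))
        if best_key is None or key < best_key:
            best, best_key = aln, key
        if i + 1 >= max_enumerate:
            break
    return best


def _hit_from_alignment(aln, query: str, subject: str, score: float) -> LocalHit:
    qblocks, sblocks = aln.aligned
    identities = 0
    aligned_len = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        if prev_q is not None:
            aligned_len += (qs - prev_q) + (ss - prev_s)  # gap columns
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if a == b and a != "N":
                identities += 1
        aligned_len += qe - qs
        prev_q, prev_s = qe, se
    return LocalHit(
        query_start=int(qblocks[0][0]),
        query_end=int(qblocks[-1][1]),
        subject_start=int(sblocks[0][0]),
        subject_end=int(sblocks[-1][1]),
        score=float(score),
        identities=identities,
        aligned_len=aligned_len,
    )


def local_align(
    query: CdnaRecord,
    subject: CdnaRecord,
    scoring: dict | None = None,
    min_score: float = 30,
) -> list[LocalHit]:
    """Iterated masked local alignment (affine gaps, exact DP).

    Finds the best local alignment, records it, masks its query span, and
    repeats until the best score drops below ``min_score``. Hits are
    returned sorted by score descending and are disjoint on the query.
    """
    if min_score <= 0:
        raise ValueError("min_score must be positive")
    scoring = scoring or DEFAULT_SCORING
    aligner = _make_aligner(scoring)
    q = list(query.seq)
    s = subject.seq
    hits: list[LocalHit] = []
    while True:
        masked = "".join(q)
        alignments = aligner.align(masked, s)
        try:
            score = alignments.score
        except (ValueError, AttributeError):
            break
        if score < min_score:
            break
        aln = _best_alignment(alignments)
        hit = _hit_from_alignment(aln, masked, s, score)
        hits.append(hit)
        for i in range(hit.query_start, hit.query_end):
            q[i] = _MASK
    hits.sort(key=lambda h: (-h.score, h.query_start, h.subject_start))
    return hits


def overall_identity(
    query: CdnaRecord,
    subject: CdnaRecord,
    scoring: dict | None = None,
    min_score: float = 30,
) -> IdentitySummary:
    """Overall percent identity of an ortholog pair.

    percent = 100 x (summed identities over accepted query-disjoint hits)
    / len(query). Not symmetric: the query is the reference-species
    transcript and its length is the denominator.
    """
    hits = local_align(query, subject, scoring, min_score)
    total = sum(h.identities for h in hits)
    return IdentitySummary(
        query_id=query.id,
        subject_id=subject.id,
        total_identities=total,
        query_length=len(query),
        percent=100.0 * total / len(query),
        n_hits=len(hits),
    )


def hits_to_frame(hits: list[LocalHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_start": h.query_start,
                "query_end": h.query_end,
                "subject_start": h.subject_start,
                "subject_end": h.subject_end,
                "score": h.score,
                "identities": h.identities,
                "aligned_len": h.aligned_len,
            }
            for h in hits
        ]
    )


# ---------------------------------------------------------------------------
# Windowed identity along alignment blocks
# ---------------------------------------------------------------------------

@dataclass
class IdentityWindowRow:
    species: str
    window_start: int  # reference coords of first reference base in window
    window_end: int  # one past the last reference base in window
    percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent <= 100.0):
            raise ValueError("percent outside [0, 100]")


def windowed_identity_profile(
    blocks: list[AlignmentBlock], window: int = 100, step: int = 10
) -> list[IdentityWindowRow]:
    """Percent identity of each non-reference row in sliding column windows.

    Identity is matches / window columns, a match being equal, non-gap,
    non-N characters (case-insensitive). Window bounds are mapped to
    reference coordinates of the window's first and last reference bases;
    windows containing no reference base are skipped.
    """
    if window < 2:
        raise ValueError("window must be >= 2 columns")
    if step < 1:
        raise ValueError("step must be >= 1")
    out: list[IdentityWindowRow] = []
    for block in blocks:
        ref = block.ref
        a = np.frombuffer(ref.text.upper().encode(), dtype="S1")
        ref_nongap = a != b"-"
        # reference coordinate of each column's base (for non-gap columns)
        ref_idx = np.cumsum(ref_nongap) - 1  # index among ref bases
        for ri, row in enumerate(block.rows):
            if ri == block.reference:
                continue
            b = np.frombuffer(row.text.upper().encode(), dtype="S1")
            match = (
                (a == b) & ref_nongap & (b != b"-") & (a != b"N") & (b != b"N")
            )
            csum_m = np.concatenate([[0], np.cumsum(match)])
            csum_r = np.concatenate([[0], np.cumsum(ref_nongap)])
            for c in range(0, block.width - window + 1, step):
                n_ref = csum_r[c + window] - csum_r[c]
                if n_ref == 0:
                    continue
                matches = csum_m[c + window] - csum_m[c]
                first_ref = int(csum_r[c])  # ref bases before the window
                out.append(
                    IdentityWindowRow(
                        species=row.species,
                        window_start=ref.src_start + first_ref,
                        window_end=ref.src_start + first_ref + int(n_ref),
                        percent=100.0 * float(matches) / window,
                    )
                )
    return out


def windows_to_frame(rows: list[IdentityWindowRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "window_start": r.window_start,
                "window_end": r.window_end,
                "percent": r.percent,
            }
            for r in rows
        ]
    )
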