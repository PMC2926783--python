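import numpy as np
import pytest

from lincons.core import GenomicInterval, TranscriptModel
from lincons.simulate import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """A small genome that every generator stage can populate quickly."""
    return SyntheticConfig(
        seed=42,
        n_chroms=1,
        chrom_length=250_000,
        n_coding=6,
        n_lncrna=6,
        alignment_length=800,
        ecr_specs=[(200, 150, 0.9)],
        ortholog_length=600,
    )


def make_tx(
    id: str,
    chrom: str,
    exon_bounds: list[tuple[int, int]],
    strand: str = "+",
    biotype: str = "lncRNA",
) -> TranscriptModel:
    """Build a transcript model from explicit exon coordinates."""
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_bounds]
    return TranscriptModel(
        id=id,
        interval=GenomicInterval(chrom, exon_bounds[0][0], exon_bounds[-1][1], strand),
        exons=exons,
        biotype=biotype,
    )


def random_tx(rng, id: str, chrom: str, origin: int, strand: str = "+"):
    """A random multi-exon transcript starting at ``origin``."""
    n_ex = int(rng.integers(2, 5))
    bounds = []
    pos = origin
    for i in range(n_ex):
        length = int(rng.integers(30, 120))
        bounds.append((pos, pos + length))
        pos += length + (int(rng.integers(40, 300)) if i < n_ex - 1 else 0)
    return make_tx(id, chrom, bounds, strand)
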