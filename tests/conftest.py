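import numpy as np
import pytest

from retmap.models import GeneModel, GenomicInterval, RegionSequence, revcomp
from retmap.simulate import STOP_CODONS, demo_gene, demo_gene_plus, demo_models

BASES = "ACGT"


@pytest.fixture(scope="session")
def demo():
    """(model, region, variant) for the minus-strand demonstration gene."""
    return demo_gene(0)


@pytest.fixture(scope="session")
def demo_plus():
    """(model, region) for the small plus-strand gene."""
    return demo_gene_plus(0)


@pytest.fixture(scope="session")
def both_models():
    return demo_models(0)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _rand_codon(rng: np.random.Generator) -> str:
    while True:
        c = _rand_seq(rng, 3)
        if c not in STOP_CODONS:
            return c


def make_toy_gene(rng: np.random.Generator, strand: str | None = None,
                  n_exons: int | None = None):
    """Random small multi-exon gene with a valid ORF and full region sequence.

    Returns (model, region).  Intron interiors are unconstrained (they may
    contain in-frame stops), UTRs are random; the CDS is a valid ORF.
    """
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    n_exons = n_exons or int(rng.integers(3, 6))
    exon_lens = [int(rng.integers(30, 91)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(20, 61)) for _ in range(n_exons - 1)]
    total_exonic = sum(exon_lens)
    utr5 = int(rng.integers(0, 8))
    max_codons = (total_exonic - utr5 - 6) // 3
    n_codons = int(rng.integers(max(4, max_codons - 10), max_codons + 1))
    cds_len = 3 * n_codons
    utr3 = total_exonic - utr5 - cds_len
    assert utr3 >= 0

    cds = "ATG" + "".join(_rand_codon(rng) for _ in range(n_codons - 2)) + "TAA"
    tx_exonic = _rand_seq(rng, utr5) + cds + _rand_seq(rng, utr3)
    pieces, pos = [], 0
    for i, elen in enumerate(exon_lens):
        pieces.append(tx_exonic[pos : pos + elen])
        pos += elen
        if i < len(intron_lens):
            pieces.append(_rand_seq(rng, intron_lens[i]))
    pre = "".join(pieces)

    origin = 100_000
    if strand == "+":
        region = RegionSequence("toy", origin, pre)
        exons, lo = [], origin
        for i, elen in enumerate(exon_lens):
            exons.append(GenomicInterval("toy", lo, lo + elen - 1, "+"))
            lo += elen
            if i < len(intron_lens):
                lo += intron_lens[i]
    else:
        region = RegionSequence("toy", origin, revcomp(pre))
        top = origin + len(pre) - 1
        exons, hi = [], top
        for i, elen in enumerate(exon_lens):
            exons.append(GenomicInterval("toy", hi - elen + 1, hi, "-"))
            hi -= elen
            if i < len(intron_lens):
                hi -= intron_lens[i]

    def tx_to_genomic(t: int) -> int:
        off = 0
        for e in exons:
            if t <= off + e.length_bp:
                w = t - off
                return e.start + w - 1 if strand == "+" else e.end - w + 1
            off += e.length_bp
        raise ValueError(t)

    model = GeneModel(
        "TOY", "toy", strand, exons,
        tx_to_genomic(utr5 + 1), tx_to_genomic(utr5 + cds_len),
    )
    return model, region


@pytest.fixture
def toy_gene_factory():
    return make_toy_gene
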