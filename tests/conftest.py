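import numpy as np
import pytest

from rnadx.formats import GeneModel, SpliceJunction, Transcript


def make_junction(
    chrom="chr1",
    start=1000,
    end=2000,
    strand="+",
    unique=10,
    annotated=False,
    motif=1,
):
    return SpliceJunction(
        chrom=chrom,
        intron_start=start,
        intron_end=end,
        strand=strand,
        motif=motif,
        annotated=annotated,
        unique_reads=unique,
    )


@pytest.fixture
def toy_gene():
    """+ strand, 5 exons of 90 nt separated by 500-nt introns, coding.

    CDS runs from base 31 of exon 1 to base 60 of exon 5, so the CDS
    length is 90*5 - 30 - 30 = 390 nt (a codon multiple).
    """
    exons = tuple((1000 + i * 590, 1000 + i * 590 + 89) for i in range(5))
    cds_start = exons[0][0] + 30
    cds_end = exons[-1][1] - 30
    tx = Transcript("TX1", exons, cds_start, cds_end)
    return GeneModel("G1", "GeneOne", "chr1", "+", (tx,))


@pytest.fixture
def toy_gene_minus(toy_gene):
    """Mirror of toy_gene on the - strand (same coordinates)."""
    tx = toy_gene.transcripts[0]
    return GeneModel(
        "G1m", "GeneOneMinus", "chr1", "-",
        (Transcript("TX1m", tx.exons, tx.cds_start, tx.cds_end),),
    )


def random_gene_with_sequence(rng: np.random.Generator, n_exons=None, strand=None):
    """A random coding gene plus the nucleotide sequence of its chromosome.

    Exon/intron lengths are small so brute-force string splicing stays
    cheap.  Returns (GeneModel, chrom_sequence_str).
    """
    n_exons = n_exons or int(rng.integers(3, 7))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    pos = int(rng.integers(50, 200))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(30, 120))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(50, 200))
    utr5 = int(rng.integers(3, 20))
    utr3 = int(rng.integers(3, 20))
    if strand == "+":
        cds_start = exons[0][0] + utr5
        cds_end = exons[-1][1] - utr3
    else:
        cds_start = exons[0][0] + utr3
        cds_end = exons[-1][1] - utr5
    tx = Transcript("TXr", tuple(exons), cds_start, cds_end)
    excess = tx.cds_length() % 3
    if excess:
        if strand == "+":
            cds_end -= excess
        else:
            cds_start += excess
        tx = Transcript("TXr", tuple(exons), cds_start, cds_end)
    gene = GeneModel("Gr", "RandGene", "chrR", strand, (tx,))
    seq_len = exons[-1][1] + 50
    seq = "".join(rng.choice(list("ACGT"), size=seq_len))
    return gene, seq
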