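import pytest

from trfcall.mapping import CollapsedRead, ReadAlignment
from trfcall.reference import (
    SEG_MATURE,
    SEG_TRAILER,
    Genome,
    ReferenceEntry,
    TRFReference,
    TRNAGene,
    build_reference,
)


def brute_force_map(read: CollapsedRead, ref: TRFReference) -> list[ReadAlignment]:
    """Independent oracle: slice-compare the read at every position of every segment."""
    out = []
    k = len(read.sequence)
    for entry in ref.entries:
        for segment, seq in ((SEG_MATURE, entry.mature_plus_cca), (SEG_TRAILER, entry.trailer)):
            for i in range(len(seq) - k + 1):
                if seq[i : i + k] == read.sequence:
                    out.append(
                        ReadAlignment(
                            sequence=read.sequence,
                            count=read.count,
                            gene=entry.name,
                            segment=segment,
                            offset=i,
                        )
                    )
    return out


def make_entry(name="g1", mature="ACGTACGTACGTACGTACGT", trailer="TTTTGGGGCCCCAAAA"):
    return ReferenceEntry(
        name=name,
        mature_plus_cca=mature + "CCA",
        trailer=trailer,
        chrom="chr1",
        start=100,
        end=100 + len(mature),
        strand="+",
    )


@pytest.fixture
def toy_genome():
    #          0         1         2         3         4         5
    #          0123456789012345678901234567890123456789012345678901234567890
    contig = "TTTTTTTTTTACGTACGTACGTACGTACGTGGGGGAAAAATTCCTTCCTTGGAACCGGAAGGTTTTTTTT"
    return Genome({"chr1": contig})


@pytest.fixture
def toy_genes():
    return [
        TRNAGene(name="plusG", chrom="chr1", start=10, end=30, strand="+"),
        TRNAGene(name="minusG", chrom="chr1", start=40, end=60, strand="-"),
    ]


@pytest.fixture
def toy_reference(toy_genome, toy_genes):
    return build_reference(toy_genome, toy_genes, species="toy", trailer_len=8)
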