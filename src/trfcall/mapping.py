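"""Read collapsing, exact full-length placement and genome-exclusivity filtering.

Reads are matched with the strictest possible criterion: the whole read must
occur verbatim (100 % of its length, 100 % identity) inside a reference
segment.  Reads that additionally occur in the genome outside annotated tRNA
loci (padded by the trailer length downstream) are discarded as ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .reference import (
    SEG_MATURE,
    SEG_TRAILER,
    Genome,
    TRFReference,
    TRNAGene,
    normalize_seq,
    revcomp,
)

logger = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN")
MAPPABLE_CHARS = frozenset("ACGT")

#: default small-RNA insert-length window for mapping
DEFAULT_MIN_LEN = 14
DEFAULT_MAX_LEN = 40


class ReadParseError(ValueError):
    """Unreadable or invalid read record."""


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence and its occurrence count in one library."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class ReadAlignment:
    """Exact full-length placement of a collapsed read on a reference segment."""

    sequence: str
    count: int
    gene: str
    segment: str  # SEG_MATURE or SEG_TRAILER
    offset: int

    @property
    def end_offset(self) -> int:
        return self.offset + len(self.sequence)


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".tsv", ".txt", ".counts"):
        return "counts"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return "fasta"
    if first.startswith("@"):
        return "fastq"
    return "counts"


def _iter_counts_file(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ReadParseError(f"{path}, line {lineno}: expected 'sequence<TAB>count'")
            try:
                count = int(parts[1])
            except ValueError as exc:
                raise ReadParseError(f"{path}, line {lineno}: bad count {parts[1]!r}") from exc
            if count < 1:
                raise ReadParseError(f"{path}, line {lineno}: count must be >= 1")
            yield parts[0], count


def collapse_reads(
    path: str | Path,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    fmt: str | None = None,
) -> tuple[list[CollapsedRead], int]:
    """Collapse a read library to unique sequences with counts.

    Accepts FASTA, FASTQ (qualities ignored) or a 2-column
    ``sequence<TAB>count`` file; the format is sniffed from the file suffix
    or content unless ``fmt`` is given.  Returns the collapsed, mappable
    reads plus ``library_total``: the total number of input reads, which
    includes reads outside ``[min_len, max_len]`` and reads containing N
    even though those are excluded from the returned list (exact matching
    is impossible for them).

    Sequences are normalized (uppercase, U->T); characters outside
    A/C/G/T/N raise :class:`ReadParseError`.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    counts: dict[str, int] = {}
    library_total = 0
    if fmt == "counts":
        records: Iterable[tuple[str, int]] = _iter_counts_file(path)
    else:
        records = ((str(rec.seq), 1) for rec in SeqIO.parse(str(path), fmt))
    for idx, (raw_seq, n) in enumerate(records, start=1):
        seq = normalize_seq(raw_seq)
        if not set(seq) <= VALID_CHARS:
            bad = sorted(set(seq) - VALID_CHARS)
            raise ReadParseError(f"{path}, record {idx}: invalid characters {bad}")
        library_total += n
        if not (min_len <= len(seq) <= max_len):
            continue
        if not set(seq) <= MAPPABLE_CHARS:
            continue  # N cannot exact-match
        counts[seq] = counts.get(seq, 0) + n
    reads = [CollapsedRead(sequence=s, count=c) for s, c in counts.items()]
    return reads, library_total


def find_all(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) start offsets of ``needle`` in ``haystack``."""
    offsets = []
    pos = haystack.find(needle)
    while pos != -1:
        offsets.append(pos)
        pos = haystack.find(needle, pos + 1)
    return offsets


def map_exact(read: CollapsedRead, ref: TRFReference) -> list[ReadAlignment]:
    """Every exact full-length occurrence of the read in the reference.

    Output order is deterministic: reference entry order, mature+CCA before
    trailer, ascending offset.
    """
    alignments: list[ReadAlignment] = []
    for entry in ref.entries:
        for segment, seq in ((SEG_MATURE, entry.mature_plus_cca), (SEG_TRAILER, entry.trailer)):
            for offset in find_all(read.sequence, seq):
                alignments.append(
                    ReadAlignment(
                        sequence=read.sequence,
                        count=read.count,
                        gene=entry.name,
                        segment=segment,
                        offset=offset,
                    )
                )
    return alignments


def _allowed_intervals(
    trna_loci: Sequence[TRNAGene], pad_down: int, pad_up: int
) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome tRNA locus intervals padded in transcription orientation."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in trna_loci:
        if g.strand == "+":
            lo, hi = g.start - pad_up, g.end + pad_down
        else:
            lo, hi = g.start - pad_down, g.end + pad_up
        by_chrom.setdefault(g.chrom, []).append((max(lo, 0), hi))
    return by_chrom


def genome_occurrences(sequence: str, genome: Genome) -> list[tuple[str, int, int]]:
    """Exact occurrences of ``sequence`` or its reverse complement in the genome.

    Returned as (chrom, start, end) intervals on the forward strand.
    """
    hits = []
    rc = revcomp(sequence)
    queries = {sequence, rc}
    for chrom, contig in genome.contigs.items():
        for query in queries:
            for pos in find_all(query, contig):
                hits.append((chrom, pos, pos + len(query)))
    return sorted(set(hits))


def genome_exclusivity_filter(
    read: CollapsedRead,
    genome: Genome,
    trna_loci: Sequence[TRNAGene],
    pad: int = 50,
    pad_upstream: int = 0,
) -> bool:
    """True iff the read maps exclusively to (padded) tRNA loci.

    The read is dropped when it (or its reverse complement) occurs exactly
    anywhere in the genome outside the union of tRNA loci extended by
    ``pad`` bases downstream in transcription orientation (so trailer hits
    are not self-hits) and ``pad_upstream`` bases upstream.
    """
    allowed = _allowed_intervals(trna_loci, pad_down=pad, pad_up=pad_upstream)
    for chrom, start, end in genome_occurrences(read.sequence, genome):
        inside = any(lo <= start and end <= hi for lo, hi in allowed.get(chrom, ()))
        if not inside:
            return False
    return True


def map_library(
    reads: Sequence[CollapsedRead],
    ref: TRFReference,
    genome: Genome | None = None,
    trna_loci: Sequence[TRNAGene] | None = None,
    pad: int | None = None,
    pad_upstream: int = 0,
) -> list[ReadAlignment]:
    """Map a collapsed library: exact placement plus optional exclusivity filter.

    When ``genome`` is provided, reads with at least one reference alignment
    that also occur in the genome outside padded tRNA loci are discarded
    entirely.  ``pad`` defaults to the reference trailer length.
    """
    if genome is not None and trna_loci is None:
        trna_loci = [
            TRNAGene(name=e.name, chrom=e.chrom, start=e.start, end=e.end, strand=e.strand)
            for e in ref.entries
        ]
    if pad is None:
        pad = ref.trailer_len
    alignments: list[ReadAlignment] = []
    n_dropped = 0
    for read in reads:
        alns = map_exact(read, ref)
        if not alns:
            continue
        if genome is not None and not genome_exclusivity_filter(
            read, genome, trna_loci, pad=pad, pad_upstream=pad_upstream
        ):
            n_dropped += 1
            continue
        alignments.extend(alns)
    if n_dropped:
        logger.info("exclusivity filter dropped %d read(s)", n_dropped)
    return alignments


ALIGNMENT_COLUMNS = ("sequence", "count", "gene", "segment", "offset", "end_offset")


def write_alignments(alignments: Iterable[ReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
        for a in alignments:
            fh.write(f"{a.sequence}\t{a.count}\t{a.gene}\t{a.segment}\t{a.offset}\t{a.end_offset}\n")


def read_alignments(path: str | Path) -> list[ReadAlignment]:
    alignments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ALIGNMENT_COLUMNS:
            raise ReadParseError(f"{path}: unexpected alignment header {header}")
        for line in fh:
            seq, count, gene, segment, offset, _end = line.rstrip("\n").split("\t")
            alignments.append(
                ReadAlignment(
                    sequence=seq, count=int(count), gene=gene, segment=segment, offset=int(offset)
                )
            )
    return alignments
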