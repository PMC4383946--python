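"""Build the tRF search space: mature tRNA sequences (+CCA) and 3' trailers.

The search space for fragment calling consists, per annotated tRNA gene, of

* the mature tRNA sequence (genomic span, introns spliced out, strand
  applied, ``CCA`` appended), and
* the trailer: the ``n`` bases (default 50) immediately downstream of the
  gene in transcription orientation.

Coordinates are stored 0-based half-open internally; input files may use
either the BED convention (0-based half-open) or the gtRNAdb convention
(1-based inclusive), selected by a dialect flag.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: segment labels used throughout the package
SEG_MATURE = "mature_plus_cca"
SEG_TRAILER = "trailer"


class AnnotationError(ValueError):
    """Malformed or inconsistent tRNA annotation input."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class TRNAGene:
    """An annotated tRNA locus.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``introns``
    is a tuple of (start, end) pairs in the same convention, each lying
    strictly inside the gene span.
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"gene {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.name!r}: strand must be '+' or '-', got {self.strand!r}")
        for istart, iend in self.introns:
            if not (self.start < istart < iend < self.end):
                raise AnnotationError(
                    f"gene {self.name!r}: intron ({istart}, {iend}) not strictly inside gene span"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


class Genome:
    """In-memory multi-contig sequence store backed by plain strings."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: normalize_seq(seq) for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not contigs:
            raise AnnotationError(f"no sequences found in {path}")
        return cls(contigs)

    @property
    def contigs(self) -> dict[str, str]:
        return self._contigs

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._contigs

    def contig_length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._contigs:
            raise KeyError(f"unknown contig {chrom!r}")
        contig = self._contigs[chrom]
        if start < 0 or end > len(contig):
            raise IndexError(
                f"coordinates [{start}, {end}) exceed contig {chrom!r} (length {len(contig)})"
            )
        return contig[start:end]

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _parse_introns(text: str, dialect: str) -> tuple[tuple[int, int], ...]:
    introns = []
    for token in text.split(","):
        token = token.strip()
        if not token or token in (".", "-", "NA"):
            continue
        lo, _, hi = token.partition("-")
        istart, iend = int(lo), int(hi)
        if dialect == "gtrnadb":
            istart -= 1
        introns.append((istart, iend))
    return tuple(introns)


def load_trna_annotation(path: str | Path, dialect: str = "bed") -> list[TRNAGene]:
    """Load tRNA gene annotations from a BED6 file or a gtRNAdb-style table.

    ``dialect='bed'`` expects ``chrom start end name score strand`` with
    0-based half-open coordinates.  ``dialect='gtrnadb'`` expects
    ``name chrom start end strand [introns]`` with 1-based inclusive
    coordinates (start > end tolerated and swapped); the optional intron
    column holds comma-separated ``start-end`` pairs in the same convention.

    Genes are returned in file order; duplicate names are rejected.
    """
    if dialect not in ("bed", "gtrnadb"):
        raise ValueError(f"unknown coordinate dialect {dialect!r}")
    genes: list[TRNAGene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed":
                    if len(fields) < 6:
                        raise AnnotationError("BED6 requires at least 6 columns")
                    chrom, start_s, end_s, name, _score, strand = fields[:6]
                    start, end = int(start_s), int(end_s)
                    introns: tuple[tuple[int, int], ...] = ()
                else:
                    if len(fields) < 5:
                        raise AnnotationError("gtRNAdb table requires at least 5 columns")
                    name, chrom, start_s, end_s, strand = fields[:5]
                    start, end = int(start_s), int(end_s)
                    if start > end:
                        start, end = end, start
                    start -= 1  # to 0-based half-open
                    introns = _parse_introns(fields[5], "gtrnadb") if len(fields) > 5 else ()
                if name in seen:
                    raise AnnotationError(f"duplicate gene name {name!r}")
                gene = TRNAGene(
                    name=name, chrom=chrom, start=start, end=end, strand=strand, introns=introns
                )
            except (ValueError, IndexError) as exc:
                raise AnnotationError(f"{path}, line {lineno}: {exc}") from exc
            seen.add(name)
            genes.append(gene)
    return genes


def write_trna_annotation(genes: Iterable[TRNAGene], path: str | Path, dialect: str = "bed") -> None:
    """Render genes back to an annotation file (inverse of :func:`load_trna_annotation`)."""
    with open(path, "w") as fh:
        for g in genes:
            if dialect == "bed":
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
            elif dialect == "gtrnadb":
                introns = ",".join(f"{s + 1}-{e}" for s, e in g.introns)
                fh.write(f"{g.name}\t{g.chrom}\t{g.start + 1}\t{g.end}\t{g.strand}\t{introns}\n")
            else:
                raise ValueError(f"unknown coordinate dialect {dialect!r}")


def extract_mature_sequence(genome: Genome, gene: TRNAGene) -> str:
    """Extract the mature tRNA body: gene span, introns spliced, strand applied.

    Returns an uppercase DNA string; does NOT append CCA (see
    :func:`build_reference`).
    """
    span = genome.fetch(gene.chrom, gene.start, gene.end)
    if gene.introns:
        pieces = []
        cursor = gene.start
        for istart, iend in sorted(gene.introns):
            pieces.append(span[cursor - gene.start : istart - gene.start])
            cursor = iend
        pieces.append(span[cursor - gene.start :])
        span = "".join(pieces)
    if gene.strand == "-":
        span = revcomp(span)
    return normalize_seq(span)


def extract_trailer(genome: Genome, gene: TRNAGene, n: int = 50) -> str:
    """The ``n`` bases immediately 3' of the gene in transcription orientation.

    For plus-strand genes this is the slice downstream of ``end``; for
    minus-strand genes the reverse complement of the slice upstream of
    ``start``.  Truncated silently (with a log message) at contig boundaries.
    """
    if n < 1:
        raise ValueError("trailer length must be >= 1")
    clen = genome.contig_length(gene.chrom)
    if gene.strand == "+":
        hi = min(gene.end + n, clen)
        seq = genome.fetch(gene.chrom, gene.end, hi)
    else:
        lo = max(gene.start - n, 0)
        seq = revcomp(genome.fetch(gene.chrom, lo, gene.start))
    if len(seq) < n:
        logger.info("trailer of %s truncated to %d nt at contig boundary", gene.name, len(seq))
    return normalize_seq(seq)


@dataclass(frozen=True)
class ReferenceEntry:
    name: str
    mature_plus_cca: str
    trailer: str
    chrom: str
    start: int
    end: int
    strand: str

    def segment(self, label: str) -> str:
        if label == SEG_MATURE:
            return self.mature_plus_cca
        if label == SEG_TRAILER:
            return self.trailer
        raise KeyError(label)


@dataclass
class TRFReference:
    """Immutable per-species search space of mature+CCA and trailer sequences."""

    species: str
    entries: tuple[ReferenceEntry, ...]
    trailer_len: int = 50

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.mature_plus_cca.endswith("CCA"):
                raise ValueError(f"entry {e.name!r} does not end with CCA")

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, name: str) -> ReferenceEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": self.species,
            "trailer_len": self.trailer_len,
            "entries": [
                {
                    "name": e.name,
                    "mature_plus_cca": e.mature_plus_cca,
                    "trailer": e.trailer,
                    "chrom": e.chrom,
                    "start": e.start + 1,  # rendered 1-based inclusive
                    "end": e.end,
                    "strand": e.strand,
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TRFReference":
        with open(path) as fh:
            payload = json.load(fh)
        entries = tuple(
            ReferenceEntry(
                name=d["name"],
                mature_plus_cca=d["mature_plus_cca"],
                trailer=d["trailer"],
                chrom=d["chrom"],
                start=d["start"] - 1,
                end=d["end"],
                strand=d["strand"],
            )
            for d in payload["entries"]
        )
        return cls(
            species=payload["species"], entries=entries, trailer_len=payload.get("trailer_len", 50)
        )


def build_reference(
    genome: Genome,
    genes: Sequence[TRNAGene],
    species: str = "unnamed",
    trailer_len: int = 50,
) -> TRFReference:
    """Assemble the search space: one (mature+CCA, trailer) entry per gene.

    A per-gene warning is emitted when the genomic mature sequence already
    ends in CCA (appending then duplicates a genomically encoded CCA, as in
    some bacterial tRNAs).
    """
    if not genes:
        warnings.warn("building an empty reference: no tRNA genes supplied", stacklevel=2)
    entries = []
    for gene in genes:
        mature = extract_mature_sequence(genome, gene)
        if mature.endswith("CCA"):
            logger.warning(
                "gene %s: genomic 3' end already reads CCA; appended CCA may be duplicated",
                gene.name,
            )
        entries.append(
            ReferenceEntry(
                name=gene.name,
                mature_plus_cca=mature + "CCA",
                trailer=extract_trailer(genome, gene, trailer_len),
                chrom=gene.chrom,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
            )
        )
    return TRFReference(species=species, entries=tuple(entries), trailer_len=trailer_len)
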