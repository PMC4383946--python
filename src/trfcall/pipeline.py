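"""End-to-end orchestration: reads -> alignments -> called fragments -> RPM."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .classify import (
    DEFAULT_DOMINANT_THRESHOLD,
    DEFAULT_MIN_SITE_COUNT,
    TRFRecord,
    TRFRegistry,
    call_trfs,
)
from .mapping import (
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    CollapsedRead,
    ReadAlignment,
    collapse_reads,
    map_library,
)
from .quantify import LibraryProfile, quantify_library
from .reference import Genome, TRFReference, TRNAGene


@dataclass
class LibraryResult:
    library_id: str
    library_total: int
    alignments: list[ReadAlignment]
    trfs: list[TRFRecord]
    concentration: dict[str, float]
    profile: LibraryProfile


def run_library(
    ref: TRFReference,
    read_counts: Mapping[str, int],
    library_total: int,
    library_id: str = "lib",
    group: str = "",
    genome: Genome | None = None,
    trna_loci: Sequence[TRNAGene] | None = None,
    registry: TRFRegistry | None = None,
    dominant_threshold: float = DEFAULT_DOMINANT_THRESHOLD,
    min_site_count: int = DEFAULT_MIN_SITE_COUNT,
    rpm_denominator: str = "total",
) -> LibraryResult:
    """Process one collapsed library against a reference.

    ``read_counts`` maps sequence to count (the output of
    :func:`trfcall.mapping.collapse_reads`, or a simulator library).  When a
    genome is supplied the exclusivity filter is applied.  A shared
    ``registry`` keeps fragment IDs stable across libraries.
    """
    reads = [CollapsedRead(sequence=s, count=c) for s, c in read_counts.items()]
    alignments = map_library(reads, ref, genome=genome, trna_loci=trna_loci)
    trfs, concentration = call_trfs(
        alignments,
        ref,
        registry=registry,
        dominant_threshold=dominant_threshold,
        min_site_count=min_site_count,
    )
    profile = quantify_library(
        trfs,
        read_counts,
        library_total=library_total,
        library_id=library_id,
        group=group,
        denominator=rpm_denominator,
    )
    return LibraryResult(
        library_id=library_id,
        library_total=library_total,
        alignments=alignments,
        trfs=trfs,
        concentration=concentration,
        profile=profile,
    )


def run_library_from_file(
    ref: TRFReference,
    reads_path: str | Path,
    library_id: str | None = None,
    genome: Genome | None = None,
    trna_loci: Sequence[TRNAGene] | None = None,
    registry: TRFRegistry | None = None,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    **kwargs,
) -> LibraryResult:
    reads, library_total = collapse_reads(reads_path, min_len=min_len, max_len=max_len)
    read_counts = {r.sequence: r.count for r in reads}
    return run_library(
        ref,
        read_counts,
        library_total=library_total,
        library_id=library_id or Path(reads_path).stem,
        genome=genome,
        trna_loci=trna_loci,
        registry=registry,
        **kwargs,
    )


def merge_trfs(results: Sequence[LibraryResult]) -> list[TRFRecord]:
    """Union of called fragments across libraries, de-duplicated by ID."""
    by_id: dict[str, TRFRecord] = {}
    for res in results:
        for t in res.trfs:
            by_id.setdefault(t.trf_id, t)
    type_order = {"tRF-5": 0, "tRF-3": 1, "tRF-1": 2}
    return sorted(by_id.values(), key=lambda r: (type_order[r.trf_type], r.numeric_id))
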