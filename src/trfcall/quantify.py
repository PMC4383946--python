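"""Per-library RPM quantification, expression matrices, pileup views.

RPM (reads per million) scales a fragment's read count by 10^6 over the
library total.  The denominator is the total number of reads in the trimmed
input library by default; ``denominator='mapped'`` restricts it to reads
with at least one reference alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import TRFRecord
from .mapping import ReadAlignment
from .reference import SEG_MATURE, SEG_TRAILER, ReferenceEntry


def rpm(count: int, library_total: int) -> float:
    """Reads-per-million normalization: count x 10^6 / library_total."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1_000_000 / library_total


@dataclass
class LibraryProfile:
    """Quantified abundances of called fragments in one library."""

    library_id: str
    library_total: int
    source: str = ""
    group: str = ""
    counts: dict[str, int] = field(default_factory=dict)  # trf_id -> raw count

    def rpm_of(self, trf_id: str) -> float:
        return rpm(self.counts.get(trf_id, 0), self.library_total)

    @property
    def rpms(self) -> dict[str, float]:
        return {trf_id: self.rpm_of(trf_id) for trf_id in self.counts}


def quantify_library(
    trfs: Sequence[TRFRecord],
    read_counts: Mapping[str, int],
    library_total: int,
    library_id: str,
    source: str = "",
    group: str = "",
    denominator: str = "total",
) -> LibraryProfile:
    """Count each called fragment's exact sequence in a collapsed library.

    ``read_counts`` maps read sequence to occurrence count.  A fragment that
    is multi-parent still contributes a single record whose count is the
    read count (not split across parents).
    """
    if denominator not in ("total", "mapped"):
        raise ValueError(f"unknown RPM denominator {denominator!r}")
    if denominator == "mapped":
        library_total = sum(read_counts.values())
    counts = {t.trf_id: read_counts.get(t.sequence, 0) for t in trfs}
    return LibraryProfile(
        library_id=library_id,
        library_total=library_total,
        source=source,
        group=group,
        counts=counts,
    )


def build_matrix(trfs: Sequence[TRFRecord], profiles: Sequence[LibraryProfile]) -> pd.DataFrame:
    """RPM matrix, one row per fragment (sorted by ID), one column per library.

    Fragments absent from a library get 0.  Column order follows the input
    profile order; cell values do not depend on it.
    """
    index = sorted({t.trf_id for t in trfs}, key=_id_sort_key)
    data = {
        p.library_id: [rpm(p.counts.get(trf_id, 0), p.library_total) for trf_id in index]
        for p in profiles
    }
    return pd.DataFrame(data, index=pd.Index(index, name="trf_id"))


def _id_sort_key(trf_id: str):
    digits = "".join(ch for ch in trf_id if ch.isdigit())
    return (int(digits), trf_id)


def write_matrix(
    matrix: pd.DataFrame, path: str | Path, profiles: Sequence[LibraryProfile] | None = None
) -> None:
    """Write the RPM matrix as TSV (2 decimals) with a JSON metadata sidecar."""
    matrix.to_csv(path, sep="\t", float_format="%.2f")
    if profiles is not None:
        sidecar = Path(str(path) + ".json")
        meta = [
            {
                "library_id": p.library_id,
                "source": p.source,
                "group": p.group,
                "library_total": p.library_total,
            }
            for p in profiles
        ]
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=1)
            fh.write("\n")


def _segment_offset(entry: ReferenceEntry, aln: ReadAlignment) -> int:
    """Offset of an alignment on the concatenated mature+CCA||trailer axis."""
    if aln.segment == SEG_MATURE:
        return aln.offset
    if aln.segment == SEG_TRAILER:
        return len(entry.mature_plus_cca) + aln.offset
    raise ValueError(f"unknown segment {aln.segment!r}")


def alignment_view(
    entry: ReferenceEntry,
    alignments: Sequence[ReadAlignment],
    library_total: int | None = None,
    dominant: Iterable[str] = (),
) -> str:
    """Text pileup of all reads on one gene (mature+CCA then trailer).

    First line is the gene axis; each read follows on its own line, padded
    to its offset and annotated with count (and RPM when ``library_total``
    is given).  Dominant sequences are flagged with ``*``.  Reads are
    ordered by count descending, then sequence.
    """
    dominant = set(dominant)
    axis = entry.mature_plus_cca + "|" + entry.trailer
    lines = [f"{axis}  {entry.name}"]
    mine = [a for a in alignments if a.gene == entry.name]
    for a in sorted(mine, key=lambda a: (-a.count, a.sequence)):
        pos = _segment_offset(entry, a)
        if a.segment == SEG_TRAILER:
            pos += 1  # axis has a '|' separator between segments
        note = f"  x{a.count}"
        if library_total:
            note += f" ({rpm(a.count, library_total):.2f} RPM)"
        if a.sequence in dominant:
            note += " *"
        lines.append(" " * pos + a.sequence + note)
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base read depth over mature+CCA followed by trailer."""

    gene: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")


def coverage_histogram(entry: ReferenceEntry, alignments: Sequence[ReadAlignment]) -> CoverageTrack:
    """depth[i] = sum of counts of alignments covering base i.

    Conservation: sum(depth) equals the sum over alignments of
    count x read length.
    """
    n = len(entry.mature_plus_cca) + len(entry.trailer)
    depth = np.zeros(n, dtype=np.int64)
    for a in alignments:
        if a.gene != entry.name:
            continue
        start = _segment_offset(entry, a)
        depth[start : start + len(a.sequence)] += a.count
    return CoverageTrack(gene=entry.name, depth=depth)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """BedGraph-style TSV: gene, 1-based base index, depth."""
    with open(path, "w") as fh:
        fh.write("gene\tposition\tdepth\n")
        for i, d in enumerate(track.depth, start=1):
            fh.write(f"{track.gene}\t{i}\t{d}\n")
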