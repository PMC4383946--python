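"""Fragment calling: positional typing, dominance filtering, naming.

A filtered alignment set is reduced to called fragments in four steps:

1. each alignment is assigned a region — extreme 5' end of the mature tRNA
   (offset 0), extreme 3' end (read ends at the appended CCA), start of the
   trailer, or "internal" (everything else, treated as degradation);
2. per (gene, region) site, the one or two most abundant read sequences
   must account for more than a threshold fraction (default 0.80) of the
   site's reads, otherwise no fragment is called there;
3. dominant sequences become fragment records typed tRF-5 / tRF-3 / tRF-1
   by region, with all genes carrying the identical sequence at the same
   region listed as parents;
4. records receive sequential IDs per type (5001..., 3001..., 1001...) from
   a persistent registry, plus a/b/c length-subclass letters when two or
   more fragments of the same type share a parent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .mapping import ReadAlignment
from .reference import SEG_MATURE, SEG_TRAILER, TRFReference

REGION_FIVE = "five_prime"
REGION_THREE = "three_prime"
REGION_TRAILER = "trailer"
REGION_INTERNAL = "internal"

#: region -> fragment type
REGION_TO_TYPE = {REGION_FIVE: "tRF-5", REGION_THREE: "tRF-3", REGION_TRAILER: "tRF-1"}
TYPE_TO_REGION = {v: k for k, v in REGION_TO_TYPE.items()}

#: first ID per type
ID_BASE = {"tRF-5": 5001, "tRF-3": 3001, "tRF-1": 1001}

#: canonical subclass lengths and bin edges (midpoints, upper-inclusive)
SUBCLASS_BINS = {
    "tRF-5": (("a", 18), ("b", 26), ("c", None)),  # ~15 / ~22 / ~31 nt
    "tRF-3": (("a", 20), ("b", None)),  # ~18 / ~22 nt
}

DEFAULT_DOMINANT_THRESHOLD = 0.80
DEFAULT_MIN_SITE_COUNT = 2


class RegistryError(ValueError):
    """Inconsistent ID registry state."""


def assign_region(aln: ReadAlignment, ref: TRFReference) -> str:
    """Positional region of an alignment on its reference entry."""
    if aln.segment == SEG_MATURE:
        if aln.offset == 0:
            return REGION_FIVE
        if aln.end_offset == len(ref.entry(aln.gene).mature_plus_cca):
            return REGION_THREE
        return REGION_INTERNAL
    if aln.segment == SEG_TRAILER:
        return REGION_TRAILER if aln.offset == 0 else REGION_INTERNAL
    raise ValueError(f"unknown segment {aln.segment!r}")


@dataclass(frozen=True)
class SiteSummary:
    """Read-count summary for one (gene, region) site."""

    gene: str
    region: str
    counts: tuple[tuple[str, int], ...]  # (sequence, count), dominance order
    dominant_reads: tuple[str, ...]
    dominant_fraction: float

    @property
    def total(self) -> int:
        return sum(c for _, c in self.counts)


def _dominance_order(counts: Mapping[str, int]) -> list[tuple[str, int]]:
    # count desc, then longer sequence, then lexicographic
    return sorted(counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))


def summarize_site(
    gene: str,
    region: str,
    alignments: Iterable[ReadAlignment],
    threshold: float = DEFAULT_DOMINANT_THRESHOLD,
) -> SiteSummary:
    """Apply the dominant-read rule at one site.

    The single most abundant sequence is dominant if its count fraction is
    >= ``threshold``; failing that, the top two together; failing that the
    site yields no dominant reads (degradation-like pileup).
    """
    counts: dict[str, int] = {}
    for a in alignments:
        counts[a.sequence] = counts.get(a.sequence, 0) + a.count
    if not counts:
        raise ValueError("summarize_site requires at least one alignment")
    ordered = _dominance_order(counts)
    total = sum(counts.values())
    top1 = ordered[0][1] / total
    if top1 >= threshold:
        dominant = (ordered[0][0],)
        fraction = top1
    elif len(ordered) >= 2 and (ordered[0][1] + ordered[1][1]) / total >= threshold:
        dominant = (ordered[0][0], ordered[1][0])
        fraction = (ordered[0][1] + ordered[1][1]) / total
    else:
        dominant = ()
        fraction = top1
    return SiteSummary(
        gene=gene,
        region=region,
        counts=tuple(ordered),
        dominant_reads=dominant,
        dominant_fraction=fraction,
    )


def region_concentration(regions_and_counts: Iterable[tuple[str, int]]) -> float:
    """Fraction of a gene's read counts falling on the three fragment regions.

    Advisory QC metric: values below 0.90 flag a gene whose pileup looks
    degradation-dominated rather than fragment-dominated.
    """
    total = 0
    on_region = 0
    for region, count in regions_and_counts:
        total += count
        if region in REGION_TO_TYPE:
            on_region += count
    if total == 0:
        raise ValueError("region_concentration requires at least one alignment")
    return on_region / total


def assign_subclass(trf_type: str, length: int) -> str | None:
    """Raw length-bin letter for a fragment type; None for tRF-1.

    Whether the letter is actually emitted depends on siblings (see
    :func:`call_trfs`): a solitary fragment carries no letter.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    bins = SUBCLASS_BINS.get(trf_type)
    if bins is None:
        return None
    for letter, upper in bins:
        if upper is None or length <= upper:
            return letter
    raise AssertionError("unreachable")


def check_terminator(trailer: str, end_offset: int) -> bool:
    """Whether a poly-U (encoded poly-T) tract overlaps the fragment's 3' end.

    True iff a run of >= 4 consecutive T in the trailer intersects the
    inclusive position window [end_offset - 4, end_offset + 2].
    """
    lo, hi = end_offset - 4, end_offset + 2
    run_start = None
    for i, base in enumerate(trailer + "$"):  # sentinel flushes the last run
        if base == "T":
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= 4:
                if run_start <= hi and i - 1 >= lo:
                    return True
            run_start = None
    return False


@dataclass(frozen=True)
class TRFRecord:
    """A called tRNA-derived fragment."""

    trf_id: str
    trf_type: str
    subclass: str | None
    sequence: str
    parents: tuple[str, ...]
    terminator: bool | None = None  # tRF-1 only

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def numeric_id(self) -> int:
        return int("".join(ch for ch in self.trf_id if ch.isdigit()))


class TRFRegistry:
    """Persistent per-species sequence -> numeric-ID map, sequential per type."""

    def __init__(self) -> None:
        self._ids: dict[str, dict[str, int]] = {t: {} for t in ID_BASE}
        self._next: dict[str, int] = dict(ID_BASE)

    def assign(self, trf_type: str, sequence: str) -> int:
        """Return the existing ID for a sequence or mint the next one."""
        pool = self._ids[trf_type]
        if sequence in pool:
            return pool[sequence]
        number = self._next[trf_type]
        pool[sequence] = number
        self._next[trf_type] = number + 1
        return number

    def lookup(self, trf_type: str, sequence: str) -> int | None:
        return self._ids[trf_type].get(sequence)

    def __len__(self) -> int:
        return sum(len(pool) for pool in self._ids.values())

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"ids": self._ids, "next": self._next}, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TRFRegistry":
        with open(path) as fh:
            payload = json.load(fh)
        reg = cls()
        for trf_type, pool in payload["ids"].items():
            seen: dict[int, str] = {}
            for seq, number in pool.items():
                if number in seen:
                    raise RegistryError(
                        f"{path}: ID {number} assigned to both {seen[number]!r} and {seq!r}"
                    )
                seen[number] = seq
            reg._ids[trf_type] = dict(pool)
        reg._next.update(payload["next"])
        return reg


def _label_alignments(
    alignments: Sequence[ReadAlignment], ref: TRFReference
) -> list[tuple[ReadAlignment, str]]:
    return [(a, assign_region(a, ref)) for a in alignments]


def call_trfs(
    alignments: Sequence[ReadAlignment],
    ref: TRFReference,
    registry: TRFRegistry | None = None,
    dominant_threshold: float = DEFAULT_DOMINANT_THRESHOLD,
    min_site_count: int = DEFAULT_MIN_SITE_COUNT,
) -> tuple[list[TRFRecord], dict[str, float]]:
    """Call fragments from a filtered alignment set.

    Returns the called records (ordered by type then numeric ID) and the
    per-gene region-concentration QC map.  Discovery order — and hence ID
    assignment order for novel sequences — is reference entry order, then
    region (5', 3', trailer), then dominance rank; this is deterministic
    given the reference and the registry.
    """
    registry = registry if registry is not None else TRFRegistry()
    labelled = _label_alignments(alignments, ref)

    concentration: dict[str, float] = {}
    by_gene: dict[str, list[tuple[ReadAlignment, str]]] = {}
    for a, region in labelled:
        by_gene.setdefault(a.gene, []).append((a, region))
    for gene, pairs in by_gene.items():
        concentration[gene] = region_concentration((r, a.count) for a, r in pairs)

    # parents: genes where a sequence aligns at the matching region
    parents_of: dict[tuple[str, str], set[str]] = {}
    for a, region in labelled:
        if region in REGION_TO_TYPE:
            parents_of.setdefault((REGION_TO_TYPE[region], a.sequence), set()).add(a.gene)

    # discovery pass: gene order, then region order, then dominance rank
    called: dict[tuple[str, str], int] = {}  # (type, sequence) -> numeric id
    for entry in ref.entries:
        pairs = by_gene.get(entry.name, [])
        for region in (REGION_FIVE, REGION_THREE, REGION_TRAILER):
            site_alns = [a for a, r in pairs if r == region]
            if not site_alns:
                continue
            summary = summarize_site(entry.name, region, site_alns, threshold=dominant_threshold)
            if summary.total < min_site_count:
                continue
            trf_type = REGION_TO_TYPE[region]
            for seq in summary.dominant_reads:
                key = (trf_type, seq)
                if key not in called:
                    called[key] = registry.assign(trf_type, seq)

    # subclass letters: only when >=2 distinct fragments of a type share a parent
    records: list[TRFRecord] = []
    for (trf_type, seq), number in called.items():
        parents = tuple(sorted(parents_of[(trf_type, seq)]))
        siblings = [
            (t2, s2)
            for (t2, s2) in called
            if t2 == trf_type and s2 != seq and parents_of[(t2, s2)] & set(parents)
        ]
        letter = assign_subclass(trf_type, len(seq)) if siblings else None
        terminator: bool | None = None
        if trf_type == "tRF-1":
            terminator = any(
                check_terminator(ref.entry(p).trailer, len(seq)) for p in parents
            )
        records.append(
            TRFRecord(
                trf_id=f"{number}{letter or ''}",
                trf_type=trf_type,
                subclass=letter,
                sequence=seq,
                parents=parents,
                terminator=terminator,
            )
        )

    type_order = {"tRF-5": 0, "tRF-3": 1, "tRF-1": 2}
    records.sort(key=lambda r: (type_order[r.trf_type], r.numeric_id))
    _check_record_invariants(records, ref)
    return records, concentration


def _check_record_invariants(records: Sequence[TRFRecord], ref: TRFReference) -> None:
    seen_ids: dict[str, str] = {}
    for r in records:
        if r.trf_type == "tRF-3" and not r.sequence.endswith("CCA"):
            raise AssertionError(f"tRF-3 {r.trf_id} does not end with CCA")
        for parent in r.parents:
            entry = ref.entry(parent)
            if r.trf_type == "tRF-5" and not entry.mature_plus_cca.startswith(r.sequence):
                raise AssertionError(f"tRF-5 {r.trf_id} is not a prefix of {parent}")
            if r.trf_type == "tRF-1" and not entry.trailer.startswith(r.sequence):
                raise AssertionError(f"tRF-1 {r.trf_id} is not a trailer prefix of {parent}")
        if r.trf_id in seen_ids and seen_ids[r.trf_id] != r.sequence:
            raise RegistryError(f"ID {r.trf_id} assigned to two different sequences")
        seen_ids[r.trf_id] = r.sequence


def assign_ids(
    trfs: Sequence[TRFRecord], registry: TRFRegistry
) -> list[TRFRecord]:
    """(Re-)assign IDs to records from a registry; known sequences keep theirs."""
    out = []
    for r in trfs:
        existing = registry.lookup(r.trf_type, r.sequence)
        number = existing if existing is not None else registry.assign(r.trf_type, r.sequence)
        out.append(replace(r, trf_id=f"{number}{r.subclass or ''}"))
    return out


TRF_COLUMNS = ("trf_id", "type", "subclass", "sequence", "length", "parents", "terminator_flag")


def write_trfs(records: Iterable[TRFRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRF_COLUMNS) + "\n")
        for r in records:
            term = "" if r.terminator is None else str(int(r.terminator))
            fh.write(
                f"{r.trf_id}\t{r.trf_type}\t{r.subclass or ''}\t{r.sequence}\t{r.length}\t"
                f"{','.join(r.parents)}\t{term}\n"
            )


def read_trfs(path: str | Path) -> list[TRFRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRF_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            trf_id, trf_type, sub, seq, _length, parents, term = line.rstrip("\n").split("\t")
            records.append(
                TRFRecord(
                    trf_id=trf_id,
                    trf_type=trf_type,
                    subclass=sub or None,
                    sequence=seq,
                    parents=tuple(p for p in parents.split(",") if p),
                    terminator=None if term == "" else bool(int(term)),
                )
            )
    return records
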