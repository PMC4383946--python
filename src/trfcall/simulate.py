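"""Synthetic genomes, tRNA annotations and small RNA libraries with planted truth.

The simulator builds a random genome carrying non-overlapping synthetic
tRNA genes, plants fragment reads at the three canonical sites (5' end of
the mature body, 3' end including the appended CCA, trailer start), and
adds two noise channels shaped like real pileups:

* ``trim_fraction``: copies of a planted read shortened by 1-3 nt at the
  3' end (nuclease nibbling of the main fragment);
* ``noise_fraction``: fragments drawn uniformly from internal positions of
  the mature bodies (random degradation).

Optionally, decoy copies of planted read sequences are written into
intergenic background to exercise the genome-exclusivity filter.  Every
library comes with a ground-truth table whose counts sum to the library
depth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .classify import REGION_FIVE, REGION_THREE, REGION_TRAILER, REGION_TO_TYPE, assign_subclass
from .mapping import find_all
from .reference import Genome, TRFReference, TRNAGene, build_reference, revcomp, write_trna_annotation

BASES = np.array(list("ACGT"))

NOISE_MIN_LEN = 14
NOISE_MAX_LEN = 30


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedTRF:
    """One fragment to plant: which gene, which site, how long, how abundant."""

    gene_index: int
    region: str  # five_prime / three_prime / trailer
    length: int
    abundance: float  # relative weight within a library

    def __post_init__(self) -> None:
        if self.region not in REGION_TO_TYPE:
            raise SimulationError(f"cannot plant in region {self.region!r}")
        if self.length < 1 or self.abundance <= 0:
            raise SimulationError("length must be >= 1 and abundance > 0")


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    group: str
    depth: int
    # per-library override of planted abundances (by index into cfg.planted)
    abundance_scale: tuple[float, ...] | None = None


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_genes: int = 6
    gene_len: int = 72
    trailer_len: int = 50
    libraries: tuple[LibrarySpec, ...] = ()
    planted: tuple[PlantedTRF, ...] = ()
    noise_fraction: float = 0.05
    trim_fraction: float = 0.10
    decoys: int = 0
    intergenic_gap: int = 120
    contig_name: str = "chrS"

    def __post_init__(self) -> None:
        for p in self.planted:
            if not 0 <= p.gene_index < self.n_genes:
                raise SimulationError(f"planted gene index {p.gene_index} out of range")
            limit = self.trailer_len if p.region == REGION_TRAILER else self.gene_len + 3
            if p.length > limit:
                raise SimulationError(f"planted length {p.length} exceeds segment ({limit})")
        if self.noise_fraction + self.trim_fraction >= 1:
            raise SimulationError("noise_fraction + trim_fraction must be < 1")


@dataclass
class SyntheticReference:
    genome: Genome
    genes: list[TRNAGene]
    reference: TRFReference
    planted_reads: list[tuple[PlantedTRF, str]]  # (spec, read sequence)
    decoy_sequences: list[str]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _planted_sequence(planted: PlantedTRF, mature: str, trailer: str) -> str:
    if planted.region == REGION_FIVE:
        return mature[: planted.length]
    if planted.region == REGION_THREE:
        return (mature + "CCA")[-planted.length :]
    return trailer[: planted.length]


def generate_reference(cfg: SimulationConfig, max_attempts: int = 10) -> SyntheticReference:
    """Build genome FASTA-equivalent, annotations and search space, deterministically.

    Genes are placed non-overlapping on random background, alternating
    strands.  Trailers of genes carrying a planted trailer fragment get an
    encoded poly-T tract at the fragment's 3' end so the terminator
    annotation is exercised.  The construction is retried (fresh random
    background) in the astronomically unlikely event that a planted read
    collides with background sequence outside its locus.
    """
    rng = np.random.default_rng(cfg.seed)
    for _ in range(max_attempts):
        result = _generate_once(cfg, rng)
        if result is not None:
            return result
    raise SimulationError("could not place planted reads without background collisions")


def _generate_once(cfg: SimulationConfig, rng: np.random.Generator) -> SyntheticReference | None:
    gap, glen, tlen = cfg.intergenic_gap, cfg.gene_len, cfg.trailer_len
    matures = [_random_seq(rng, glen) for _ in range(cfg.n_genes)]
    trailers = [_random_seq(rng, tlen) for _ in range(cfg.n_genes)]
    for p in cfg.planted:
        if p.region == REGION_TRAILER:
            t = trailers[p.gene_index]
            lo = max(p.length - 4, 0)
            trailers[p.gene_index] = t[:lo] + "T" * (p.length - lo) + t[p.length :]

    planted_reads = [
        (p, _planted_sequence(p, matures[p.gene_index], trailers[p.gene_index]))
        for p in cfg.planted
    ]
    decoy_sequences = [seq for _, seq in planted_reads[: cfg.decoys]]
    if cfg.decoys > len(planted_reads):
        raise SimulationError("more decoys requested than planted reads")

    unit = glen + tlen + gap
    tail = sum(len(s) + gap for s in decoy_sequences) + gap
    contig_len = gap + tlen + cfg.n_genes * unit + tail
    contig = list(_random_seq(rng, contig_len))

    genes: list[TRNAGene] = []
    cursor = gap + tlen
    for i, (mature, trailer) in enumerate(zip(matures, trailers)):
        strand = "+" if i % 2 == 0 else "-"
        start, end = cursor, cursor + glen
        if strand == "+":
            contig[start:end] = mature
            contig[end : end + tlen] = trailer
        else:
            contig[start:end] = revcomp(mature)
            contig[start - tlen : start] = revcomp(trailer)
        genes.append(
            TRNAGene(name=f"syn.trna{i + 1}", chrom=cfg.contig_name, start=start, end=end, strand=strand)
        )
        cursor += unit

    decoy_cursor = cursor + gap
    for seq in decoy_sequences:
        contig[decoy_cursor : decoy_cursor + len(seq)] = seq
        decoy_cursor += len(seq) + gap

    genome = Genome({cfg.contig_name: "".join(contig)})
    reference = build_reference(genome, genes, species="synthetic", trailer_len=tlen)

    if not _placement_is_clean(cfg, genome, genes, planted_reads, decoy_sequences):
        return None
    return SyntheticReference(
        genome=genome,
        genes=genes,
        reference=reference,
        planted_reads=planted_reads,
        decoy_sequences=decoy_sequences,
    )


def _placement_is_clean(cfg, genome, genes, planted_reads, decoy_sequences) -> bool:
    """No planted read may occur in the genome outside its padded locus,
    except for its deliberate decoy copies."""
    contig = genome.contigs[cfg.contig_name]
    allowed = []
    for g in genes:
        if g.strand == "+":
            allowed.append((g.start, g.end + cfg.trailer_len))
        else:
            allowed.append((g.start - cfg.trailer_len, g.end))
    for _, seq in planted_reads:
        outside = 0
        for query in {seq, revcomp(seq)}:
            for pos in find_all(query, contig):
                if not any(lo <= pos and pos + len(query) <= hi for lo, hi in allowed):
                    outside += 1
        # expected hits: occurrences inside the decoy copies themselves
        # (a decoy copy of a longer planted read can embed a shorter one)
        expected = sum(
            len(find_all(seq, d)) + len(find_all(revcomp(seq), d)) for d in decoy_sequences
        )
        if outside != expected:
            return False
    return True


def _library_weights(cfg: SimulationConfig, lib: LibrarySpec) -> np.ndarray:
    weights = np.array([p.abundance for p in cfg.planted], dtype=float)
    if lib.abundance_scale is not None:
        if len(lib.abundance_scale) != len(cfg.planted):
            raise SimulationError("abundance_scale length mismatch")
        weights = weights * np.asarray(lib.abundance_scale, dtype=float)
    return weights / weights.sum()


def simulate_library(
    cfg: SimulationConfig,
    synref: SyntheticReference,
    lib: LibrarySpec,
    lib_index: int = 0,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Draw one library: collapsed sequence counts plus a ground-truth table.

    Reads are drawn by a single multinomial over planted reads (weight
    ``1 - noise - trim`` of the library), their 1-3 nt 3'-trimmed copies
    (``trim_fraction``, split equally over the three trim depths) and a
    degradation bucket (``noise_fraction``, expanded into uniform internal
    fragments of 14-30 nt).  Truth counts sum exactly to the library depth.
    """
    rng = np.random.default_rng([cfg.seed, lib_index])
    weights = _library_weights(cfg, lib)
    main_frac = 1.0 - cfg.noise_fraction - cfg.trim_fraction

    categories: list[tuple[str, str, str, str]] = []  # sequence, gene, region, kind
    probs: list[float] = []
    for (p, seq), w in zip(synref.planted_reads, weights):
        gene = synref.genes[p.gene_index].name
        categories.append((seq, gene, p.region, "planted"))
        probs.append(w * main_frac)
        for delta in (1, 2, 3):
            if len(seq) - delta < 1:
                continue
            categories.append((seq[:-delta], gene, p.region, "trim"))
            probs.append(w * cfg.trim_fraction / 3)
    categories.append(("", "", "", "noise"))
    probs.append(cfg.noise_fraction)

    prob_arr = np.array(probs)
    prob_arr = prob_arr / prob_arr.sum()
    draws = rng.multinomial(lib.depth, prob_arr)

    truth_rows: list[dict] = []
    counts: dict[str, int] = {}
    for (seq, gene, region, kind), n in zip(categories, draws):
        if n == 0 or kind == "noise":
            continue
        counts[seq] = counts.get(seq, 0) + int(n)
        truth_rows.append(
            {"sequence": seq, "gene": gene, "region": region, "kind": kind, "count": int(n)}
        )

    n_noise = int(draws[-1])
    noise_counts: dict[tuple[str, str], int] = {}
    for _ in range(n_noise):
        gi = int(rng.integers(cfg.n_genes))
        mature = synref.reference.entries[gi].mature_plus_cca[:-3]
        length = int(rng.integers(NOISE_MIN_LEN, NOISE_MAX_LEN + 1))
        length = min(length, len(mature) - 1)
        offset = int(rng.integers(1, len(mature) - length + 1))
        seq = mature[offset : offset + length]
        counts[seq] = counts.get(seq, 0) + 1
        noise_counts[(seq, synref.genes[gi].name)] = noise_counts.get((seq, synref.genes[gi].name), 0) + 1
    for (seq, gene), n in sorted(noise_counts.items()):
        truth_rows.append(
            {"sequence": seq, "gene": gene, "region": "internal", "kind": "noise", "count": n}
        )

    truth = pd.DataFrame(truth_rows, columns=["sequence", "gene", "region", "kind", "count"])
    assert int(truth["count"].sum()) == lib.depth
    return counts, truth


def planted_records(synref: SyntheticReference) -> list[tuple[str, str, tuple[str, ...], str | None]]:
    """Expected (type, sequence, parents, subclass) for the planted fragment set.

    Parents are all reference entries carrying the identical sequence at the
    matching site; subclass letters follow the sibling rule (emitted only
    when two or more planted fragments of a type share a parent).
    """
    ref = synref.reference
    expected: dict[tuple[str, str], set[str]] = {}
    for p, seq in synref.planted_reads:
        trf_type = REGION_TO_TYPE[p.region]
        parents = set()
        for e in ref.entries:
            if p.region == REGION_FIVE and e.mature_plus_cca.startswith(seq):
                parents.add(e.name)
            elif p.region == REGION_THREE and e.mature_plus_cca.endswith(seq):
                parents.add(e.name)
            elif p.region == REGION_TRAILER and e.trailer.startswith(seq):
                parents.add(e.name)
        expected[(trf_type, seq)] = parents
    out = []
    for (trf_type, seq), parents in expected.items():
        has_sibling = any(
            t2 == trf_type and s2 != seq and (parents & p2)
            for (t2, s2), p2 in expected.items()
        )
        letter = assign_subclass(trf_type, len(seq)) if has_sibling else None
        out.append((trf_type, seq, tuple(sorted(parents)), letter))
    return out


def write_simulation(
    cfg: SimulationConfig, synref: SyntheticReference, outdir: str | Path
) -> dict[str, Path]:
    """Emit genome.fa, trna.bed, per-library collapsed counts, truth tables
    and a manifest; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    synref.genome.to_fasta(paths["genome"])
    paths["annotation"] = outdir / "trna.bed"
    write_trna_annotation(synref.genes, paths["annotation"], dialect="bed")
    for i, lib in enumerate(cfg.libraries):
        counts, truth = simulate_library(cfg, synref, lib, lib_index=i)
        lib_path = outdir / f"lib_{lib.library_id}.tsv"
        with open(lib_path, "w") as fh:
            for seq, n in sorted(counts.items()):
                fh.write(f"{seq}\t{n}\n")
        truth.to_csv(outdir / f"truth_{lib.library_id}.tsv", sep="\t", index=False)
        paths[f"library:{lib.library_id}"] = lib_path
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "decoy_sequences": synref.decoy_sequences,
        "planted": [
            {"gene": synref.genes[p.gene_index].name, "region": p.region, "sequence": seq}
            for p, seq in synref.planted_reads
        ],
    }
    paths["manifest"] = outdir / "sim-manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return paths


def default_recovery_config(
    seed: int = 7,
    depth: int = 200_000,
    noise_fraction: float = 0.05,
    trim_fraction: float = 0.10,
    decoys: int = 0,
) -> SimulationConfig:
    """The standard six-gene recovery scenario: fragments of all three types,
    sibling pairs on two genes (so subclass letters are exercised), plus the
    two noise channels."""
    planted = (
        PlantedTRF(0, REGION_FIVE, 15, 0.18),
        PlantedTRF(0, REGION_FIVE, 22, 0.12),
        PlantedTRF(1, REGION_THREE, 18, 0.15),
        PlantedTRF(1, REGION_THREE, 22, 0.10),
        PlantedTRF(2, REGION_TRAILER, 19, 0.15),
        PlantedTRF(3, REGION_FIVE, 31, 0.10),
        PlantedTRF(4, REGION_THREE, 22, 0.10),
        PlantedTRF(5, REGION_TRAILER, 25, 0.20),
    )
    return SimulationConfig(
        seed=seed,
        n_genes=6,
        libraries=(LibrarySpec("sim1", "default", depth),),
        planted=planted,
        noise_fraction=noise_fraction,
        trim_fraction=trim_fraction,
        decoys=decoys,
    )


def differential_config(
    seed: int = 11,
    n_genes: int = 12,
    depth: int = 200_000,
    fold_low: float = 150.0,
    fold_high: float = 600.0,
    replicates: int = 2,
) -> SimulationConfig:
    """Two-group scenario: trailer fragments induced ``fold_low``-``fold_high``x
    in group B, 5'/3' fragments flat.

    Group-A trailer weights are tiny (a few dozen reads at default depth)
    so the induction spans orders of magnitude without shifting the
    normalizer enough to distort the flat classes.
    """
    rng = np.random.default_rng(seed)
    planted = []
    for i in range(n_genes):
        planted.append(PlantedTRF(i, REGION_FIVE, int(rng.integers(15, 23)), 0.04))
        planted.append(PlantedTRF(i, REGION_THREE, int(rng.integers(18, 23)), 0.04))
        planted.append(PlantedTRF(i, REGION_TRAILER, int(rng.integers(16, 26)), 4e-5))
    folds = rng.uniform(fold_low, fold_high, size=n_genes)
    scale_b = []
    for i in range(n_genes):
        scale_b.extend([1.0, 1.0, float(folds[i])])
    libraries = []
    for r in range(replicates):
        libraries.append(LibrarySpec(f"normal{r + 1}", "A", depth))
    for r in range(replicates):
        libraries.append(
            LibrarySpec(f"tumor{r + 1}", "B", depth, abundance_scale=tuple(scale_b))
        )
    return SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        libraries=tuple(libraries),
        planted=tuple(planted),
        noise_fraction=0.05,
        trim_fraction=0.10,
    )
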