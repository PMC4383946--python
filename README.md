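# trfcall

Identification, classification, naming and quantification of tRNA-derived
fragments (tRFs) from small RNA-seq libraries, as a reusable Python library
and CLI, plus a synthetic-data generator for planted-truth testing.

The pipeline:

1. **Reference building** — extract mature tRNA sequences from a genome
   (strand-aware, introns spliced) and append `CCA`; extract the 50-nt 3'
   trailer of each gene. These two segments per gene form the search space.
2. **Mapping** — collapse a read library to unique sequences with counts and
   place each read by *exact full-length* matching (100 % length, 100 %
   identity — implemented as deterministic substring search). Reads that
   also occur in the genome outside padded tRNA loci are discarded
   (genome-exclusivity filter).
3. **Calling** — reads are typed by position: tRF-5 (starts at mature base
   1), tRF-3 (ends at the appended CCA), tRF-1 (starts at trailer base 1).
   At each site the one or two most abundant sequences must account for
   ≥ 80 % of the site's reads, separating genuine fragments from
   degradation pileups. Fragments get sequential IDs per type (5001…,
   3001…, 1001…) from a persistent registry, with a/b/c length-subclass
   letters when siblings share a parent gene, and tRF-1s are annotated for
   an encoded poly-U terminator at their 3' end.
4. **Quantification** — reads-per-million (RPM) per library, a multi-library
   expression matrix, text pileup views and per-base coverage tracks.
5. **Differential abundance** — two-group comparison with a > 20 RPM
   detection filter, pseudocount-stabilized log2 fold changes, and
   per-class (tRF-5/-3/-1) summaries. Descriptive only: no p-values.
6. **Simulation** — synthetic genomes with non-overlapping tRNA genes,
   planted fragments at the three canonical sites, 3'-trimming and
   internal-degradation noise channels, optional intergenic decoy copies,
   and ground-truth tables.

## CLI

```bash
# generate a synthetic dataset (or bring your own genome + BED/gtRNAdb table)
trfcall simulate --seed 7 -o sim/

# build the search space
trfcall build-ref --genome sim/genome.fa --trna sim/trna.bed --coord bed -o ref.json

# map a library (exclusivity filter enabled when --genome is given)
trfcall map --ref ref.json --reads sim/lib_sim1.tsv \
    --genome sim/genome.fa --trna sim/trna.bed -o aln.tsv

# call fragments (registry keeps IDs stable across libraries)
trfcall call --alignments aln.tsv --ref ref.json --registry reg.json -o trfs.tsv

# RPM matrix across libraries
trfcall quantify --trfs trfs.tsv --alignments aln.tsv -o matrix.tsv

# two-group comparison
trfcall diff --matrix matrix.tsv --trfs trfs.tsv \
    --group-a normal1,normal2 --group-b tumor1,tumor2 -o diff.tsv
```

Read input may be FASTA, FASTQ (qualities ignored) or a two-column
`sequence<TAB>count` file. Annotations may be BED6 (`--coord bed`) or a
gtRNAdb-style 1-based table (`--coord gtrnadb`).

## Layout

```
src/trfcall/
  reference.py   genome/annotation IO, mature+CCA and trailer extraction
  mapping.py     read collapsing, exact placement, exclusivity filter
  classify.py    region typing, dominance filter, subclasses, ID registry
  quantify.py    RPM, expression matrix, pileup view, coverage track
  diff.py        two-group comparison and class summaries
  simulate.py    synthetic references/libraries with planted ground truth
  pipeline.py    end-to-end orchestration helpers
  cli.py         `trfcall` command group
```
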