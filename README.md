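# tripscan

Detection, typing, locus mapping and rearrangement analysis of the **TRIP1
repeat family** in *Escherichia coli* genome assemblies.

TRIP1 repeats are 146–273 bp GC-rich interspersed repeats of the *E. coli*
chromosome.  Five types (TRIP1a–e) are known, each tied to a canonical
chromosomal locus defined by its two flanking genes (e.g. TRIP1a sits 70 bp
downstream of the *aqpZ* stop codon and 158 bp upstream of the *ybjE* start
codon).  Because the copies are long and highly similar, they act as
substrates for homologous recombination: an exchange between two copies at
different loci inverts or deletes the intervening chromosome segment and
leaves *hybrid junctions* — repeat copies whose flanking genes come from two
different canonical loci.  This package implements the full survey pipeline
for genome collections:

1. **scan** — find all copies of each reference type on both strands by
   affine-gap Smith–Waterman/Gotoh local alignment (match +2, mismatch −3,
   gap open 5, gap extend 2; exact 12-mer seeding with full DP in candidate
   windows), keeping alignments that cover ≥ 80% of the reference length;
2. **type** — where several types match one position, keep only the
   highest-scoring one, and orient each copy relative to its reference;
3. **locate** — label each copy by its two flanking genes from a GFF3
   annotation: canonical locus (A–E), hybrid junction, or unplaced;
4. **rearrange** — call one rearrangement event per hybrid junction, classify
   it by locus pair and junction gene pair, pair reciprocal junctions of an
   inversion, and compute the affected span;
5. **summarize** — per-genome copy numbers, per-type presence and
   orientation tallies, integer-percent shares.

A first-class synthetic-genome simulator (`tripscan.simulate`) generates
annotated genomes with planted repeat loci, controlled divergence, simulated
inversions/deletions and draft-style fragmentation, together with exhaustive
truth tables — the test bed for the whole pipeline.

## Worked example

Simulate a genome with three planted loci (A forward, B reverse, C reverse)
and one inversion between the A and C copies, then run the pipeline:

```python
from tripscan.simulate import simulate_genome, SimulationConfig, LocusSpec, write_genome
cfg = SimulationConfig(seed=42, genome_id="demo", genome_length=120_000,
    loci=(LocusSpec("A", 20_000, strand="+", divergence=0.03),
          LocusSpec("B", 50_000, strand="-", divergence=0.02),
          LocusSpec("C", 90_000, strand="-", divergence=0.01)),
    inversions=(("A", "C"),))
paths = write_genome(simulate_genome(cfg), "demo_dir")
```

```sh
tripscan scan demo_dir/demo.fasta --out hits.tsv
# 3 repeat copies -> hits.tsv
tripscan locate --hits hits.tsv --annotations demo_dir/demo.gff3 --out calls.tsv
# 3 locus calls (2 hybrid) -> calls.tsv
tripscan rearrange --calls calls.tsv --out events.tsv
# 2 events (2 paired) -> events.tsv
```

`hits.tsv`:

```text
genome_id  contig  start  end    strand  type  score  identity  coverage  final_type  orientation
demo       chr     20000  20268  +       A     466    0.948     1.0       A           forward
demo       chr     60123  60268  +       B     277    0.9795    1.0       B           forward
demo       chr     90003  90272  -       C     454    0.9341    1.0       C           reverse
```

The inversion turned the A and C copies into two chimeric junction repeats
(detected at their exact planted intervals) and carried the B copy — which
lay inside the inverted segment — to position 60 123 on the opposite strand.
`events.tsv` shows the two reciprocal junctions with the new flanking-gene
permutations and the affected span (inclusive of both junction repeats):

```text
genome_id  contig  junction_pair  locus_pair  repeat_type  orientation  repeat_start  repeat_end  paired  span
demo       chr     aqpZ/yohI      A/C         A            forward      20000         20268       True    70273
demo       chr     ybjE/yohG      A/C         C            reverse      90003         90272       True    70273
```

An end-to-end run over a directory of genomes (`tripscan run --genomes d/
--annotations d/ --out out/`) additionally writes the census tables
(copy-number histogram, per-type presence/orientation, event tally with
integer-percent shares).

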