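# Methods

## Coordinate convention

All intervals are 1-based and fully inclusive; this is the only convention
under which the canonical copy coordinates reproduce the published lengths
(915281 − 915016 + 1 = 266 for TRIP1a; 146, 273, 264 and 265 bp for types
b–e).  The 0-based half-open conversion happens only when writing BED.

## Reference registry

The registry holds the five canonical types with their source coordinates,
strand, and canonical flanking genes with boundary offsets:
A {aqpZ 70 / ybjE 158}, B {putP 41 / ycdN 355}, C {yohI 43 / yohG 363},
D {alx 96 / sstT 255}, E {copA 38 / ybaP 124}.  The bundled sequences are
**synthetic stand-ins** (built deterministically from a frozen seed), not the
genomic sequences: they have the published lengths, GC richness (≥ 62%), and
the family's identity structure — B is A with a 120 bp internal block
deletion plus ~16% divergence, C/E diverge ~6% from A, D ~11%.  One published
statement gives the B deletion as 125 bp; the printed lengths require
266 − 146 = 120, and the lengths are taken as authoritative.  Users can
substitute real sequences through `load_registry` (FASTA + TSV); every
sequence length is validated against its declared interval.

All five synthetic types share identical 10 bp termini.  Conserved ends are
a common feature of interspersed repeat families, and here they serve a
numerical purpose: together with the simulator's policy of never mutating
the terminal 10 bp of a planted copy, they make the planted boundaries the
unique optimum of the local alignment, so detected intervals — and therefore
inversion spans — are exact rather than fuzzed by terminal mismatch clipping.
Real data offers no such guarantee; on real genomes reported intervals may be
clipped by a few bases where copy ends have decayed.

## Detection

The scan is an explicit re-implementation of a BLASTN-style search as
Smith–Waterman/Gotoh DP: substitution scores +2/−3, affine gaps costing
`gap_open + k·gap_extend` with defaults 5 and 2.  Only the gap costs are
inherited from the original search protocol; the substitution scores are the
standard nucleotide-search defaults that accompany them and are
configurable.  Candidate regions come from exact 12-mer seeding (seed
positions clustered by subject proximity; clusters padded by one reference
length on each side); each window is then aligned with the full DP matrix,
and accepted spans are masked and the window re-aligned so that several
copies merged into one window are all recovered.  Reported scores are
therefore true full-matrix optima, a property enforced by an oracle test
against an independent pure-Python Gotoh implementation.

Filters: length coverage (aligned query columns, gaps excluded, over the
full reference length) ≥ 0.80 — "greater than 80%" implemented as ≥ —
and a default minimum score of half the maximum attainable score of the
shortest reference (0.5 × 2 × 146 = 146), which suppresses spurious
background alignments while passing every ≤ 5% diverged copy.  Identity is
matching columns over all alignment columns, gaps counting as non-matching.
Ambiguous bases (N) mismatch everything, including N.  Chromosomes are
treated as linear; a copy spanning the origin of a circular chromosome
would be missed (known limitation).

## Type resolution and orientation

Hits of different types at "the same position" — reciprocal overlap above
50% of the shorter hit (the original protocol gives no threshold; 50% is
this package's documented choice) — form connected groups, and only the
highest-raw-score hit of each group survives; ties break on higher identity,
then on type order A<B<C<D<E so runs are reproducible.  Nearly adjacent hits
of the same type with ≤ 50% overlap are treated as distinct copies.
Orientation is *forward* when the hit strand equals the stored reference
strand of the assigned type; the antisense placement of the canonical
TRIP1c copy relative to TRIP1a is a property of the reference table, not of
this operation.

## Locus mapping

Flanks of 1000 bp (the annotation window of the original protocol) define
the context: the nearest gene ending before the repeat and the nearest gene
starting after it, within the window, drawn from the GFF3 `gene` features
(`Name`/`gene` attribute, falling back to `locus_tag`).  Genes overlapping
the repeat count as flanking at distance 0; genes straddling the window edge
count if any part lies inside.  Both flanks from one canonical pair → that
locus; flanks from two different canonical pairs → hybrid (junction pair
recorded); a missing flank or an unknown gene → unplaced.  Copies at contig
ends in draft assemblies therefore end up unplaced and are excluded from
event detection — how the original survey counted such copies is not
recorded, and this is the package's explicit choice.

## Rearrangement events

One hybrid locus call is one event.  This junction-level counting is what
reconciles per-gene-pair tallies in which the two reciprocal subtypes of a
locus pair appear with *unequal* counts (68 vs 58 for A/C) — inversions
counted once could not produce that.  Within a genome and contig, two events
with the same locus pair and complementary junction pairs (jointly covering
all four canonical genes) are reciprocal and get paired; more than two
candidates trigger a warning and greedy nearest pairing.  The affected span
is inclusive of both junction repeats by default (configurable to the inner
distance).  A deletion between direct repeats leaves a single unpaired
junction; the default report does not distinguish deletion junctions beyond
the unpaired flag.

## Census

Copy-number histogram bins 0,1,2,3,4,5+; a genome "has" a type when ≥ 1
resolved copy remains.  Shares are integer percent with exact half-up
rounding computed in integer arithmetic, `(200·n + d) // (2·d)`, the
convention that reproduces published shares (96, 36, 46, 88).  The
complete/draft flag is user-supplied metadata; no assembly-quality inference
is attempted.

## Simulator

Backgrounds are i.i.d. bases at a requested GC (default 0.508, the *E. coli*
chromosomal average; planted repeats are GC-rich against it).  A locus plant
is `left gene — offset — repeat — offset — right gene` with the canonical
offsets above; flanking genes are synthetic ORF-like sequences (default
900 bp, a typical bacterial gene) whose *names* drive all locus logic.
Divergence applies an exact `round(d · n_interior)` count of substitutions
at distinct interior positions (termini protected, see above); substitutions
only, so planted intervals are exact.  Realized divergence over the whole
copy is accordingly about `d · (L−20)/L`.

Inversion places both recombination breakpoints at the repeat midpoints (a
fixed, reproducible choice; real breakpoints vary within the repeat),
requires the two copies in inverted relative orientation, reverse-complements
the enclosed segment, remaps every feature and repeat inside it, and yields
two chimeric junction repeats.  Direct-orientation pairs route to deletion
mode, which excises the segment between the midpoints and leaves one
junction.  Fragmentation cuts at uniform random positions, never inside a
planted repeat by default; a severed gene is dropped from the annotation, so
the truth call for a repeat whose flank was severed becomes unplaced.

Expected calls and events are re-derived from the final feature/hit tables
by an independent exhaustive scan at generation time, so truth is consistent
with the emitted FASTA/GFF3 under any operation sequence.  Identical
configurations produce byte-identical outputs.

The default cohort generator (20 genomes in the acceptance run) plants 3–5
loci per genome with strand frequencies matching the survey's orientation
tallies (B always reverse, D/E always forward, A forward ~73%, C ~51%),
divergence uniform on [0, 0.05], and 0–2 inversions drawn from the
inversion-eligible locus pairs weighted by the survey's event-class counts
(A/C dominant).  Pairs involving type B are not drawn: a junction chimera of
the internally deleted 146 bp type with a full-length type aligns to every
reference with a large structural gap and falls below the default score
threshold, so such junctions are only detectable with a lowered
`min_score` — a documented limitation of single-alignment scoring shared, in
spirit, with any coverage-thresholded search.

## What the synthetic tests do and do not show

Passing the round trip shows the pipeline recovers exactly what was planted
under the stated conditions: substitution-only divergence ≤ 5%, conserved
copy termini, complete and correct gene annotations, and well-separated
loci.  It does not certify behaviour on real assemblies with indel
divergence, decayed copies, annotation errors, misassemblies, or copies
spanning contig ends; the unplaced category and the configurable thresholds
are the designed escape hatches for those cases.  Problem sizes (200 kb
genomes, 20-genome cohorts) are the package's default test scale and are
configurable.
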