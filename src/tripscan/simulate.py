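"""Synthetic annotated genomes with planted repeat loci and known truth.

The simulator emulates the genome population a repeat-family survey runs on:
GC-controlled background sequence, canonical loci planted as
left gene / gap / repeat copy / gap / right gene cassettes at the family's
published flank offsets, controlled substitution divergence, repeat-mediated
inversions and deletions (recombination breakpoints fixed at the repeat
midpoints), and draft-style fragmentation into contigs.

Every emitted genome carries an exhaustive truth table: the planted repeat
intervals (exact, because mutations are substitutions only and the terminal
10 bp of each copy — the family's conserved termini — are never mutated, so
copy boundaries are the unique local-alignment optimum), the expected locus
calls, and the expected rearrangement events with their subtypes and spans.
Expected calls and events are re-derived from the emitted feature table by a
simple independent scan, so truth stays consistent with the FASTA/GFF3 under
any combination of operations.

Junction repeats created by recombination between types X and Y are chimeric;
they have no single true type and truth records ``allowed_types={X, Y}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tripscan.align import reverse_complement
from tripscan.loci import GeneFeature
from tripscan.reference import (
    CANONICAL_FLANKS,
    CANONICAL_PAIRS,
    GENE_TO_LOCUS,
    RepeatRef,
    builtin_registry,
)

__all__ = [
    "LocusSpec",
    "SimulationConfig",
    "TruthHit",
    "TruthCall",
    "TruthEvent",
    "SyntheticTruth",
    "SimulatedGenome",
    "generate_background",
    "simulate_genome",
    "simulate_cohort",
    "write_genome",
]

_PROTECTED_END = 10  # conserved family termini, never mutated in planted copies
_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusSpec:
    """One planted locus: label, repeat type, strand, repeat start, divergence."""

    label: str
    position: int  # 1-based start of the repeat copy
    repeat_type: str | None = None  # defaults to the label
    strand: str = "+"
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 0.15:
            raise ValueError("divergence must be in [0, 0.15]")

    @property
    def type_id(self) -> str:
        return self.repeat_type or self.label


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_id: str = "sim"
    genome_length: int = 200_000
    background_gc: float = 0.508  # E. coli chromosomal GC
    loci: tuple = ()
    inversions: tuple = ()  # pairs of locus labels, applied in order
    deletions: tuple = ()  # pairs of locus labels (direct-repeat recombination)
    n_contigs: int = 1
    flank_gene_length: int = 900
    avoid_repeats_when_fragmenting: bool = True


@dataclass
class TruthHit:
    contig_id: str
    start: int
    end: int
    strand: str
    allowed_types: frozenset
    orientation: str
    origin: str  # planted locus label, or 'junction'


@dataclass(frozen=True)
class TruthCall:
    hit_index: int
    left_gene: str | None
    right_gene: str | None
    left_distance: int | None
    right_distance: int | None
    locus_label: str
    junction_pair: frozenset | None


@dataclass(frozen=True)
class TruthEvent:
    contig_id: str
    junction_pair: frozenset
    locus_pair: frozenset
    repeat_start: int
    repeat_end: int
    paired: bool
    span: int | None


@dataclass(frozen=True)
class SyntheticTruth:
    hits: list
    calls: list
    events: list
    contig_lengths: dict


@dataclass(frozen=True)
class SimulatedGenome:
    genome_id: str
    contigs: dict
    features: list
    truth: SyntheticTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------


def generate_background(length: int, gc: float, seed: int | np.random.Generator) -> str:
    """i.i.d. background with P(G)+P(C) = gc, split evenly within each pair."""
    if length <= 0:
        raise ValueError("length must be > 0")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _mutate_copy(sequence: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute an exact round(divergence * n_interior) count of interior bases.

    The terminal ``_PROTECTED_END`` bases on each side stay untouched.
    """
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    interior = np.arange(_PROTECTED_END, len(arr) - _PROTECTED_END)
    k = int(round(divergence * interior.size))
    if k:
        for p in rng.choice(interior, size=k, replace=False):
            choices = [b for b in (b"A", b"C", b"G", b"T") if b != arr[p]]
            arr[p] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def _gene_sequence(length: int, rng: np.random.Generator) -> str:
    seq = generate_background(length, 0.5, rng)
    return "ATG" + seq[3:-3] + "TAA"


# ---------------------------------------------------------------------------
# Construction primitives (operate on a single linear chromosome)
# ---------------------------------------------------------------------------


class _Builder:
    """Mutable single-chromosome genome under construction."""

    def __init__(self, config: SimulationConfig, registry: dict, rng: np.random.Generator):
        self.config = config
        self.registry = registry
        self.rng = rng
        self.seq = bytearray(generate_background(config.genome_length, config.background_gc, rng).encode())
        self.features: list[GeneFeature] = []
        self.hits: list[TruthHit] = []
        self.occupied: list[tuple[int, int]] = []

    # -- low-level helpers -------------------------------------------------

    def _write(self, start: int, text: str) -> None:
        """Overwrite genome bases at 1-based ``start``."""
        self.seq[start - 1 : start - 1 + len(text)] = text.encode()

    def _claim(self, start: int, end: int) -> None:
        for s, e in self.occupied:
            if start <= e and s <= end:
                raise ValueError(f"planted region [{start}, {end}] overlaps existing plant [{s}, {e}]")
        if start < 1 or end > len(self.seq):
            raise ValueError(f"planted region [{start}, {end}] outside genome of length {len(self.seq)}")
        self.occupied.append((start, end))

    # -- planting ----------------------------------------------------------

    def plant_locus(self, spec: LocusSpec) -> TruthHit:
        ref: RepeatRef = self.registry[spec.type_id]
        left_gene, left_off, right_gene, right_off = CANONICAL_FLANKS[spec.label]
        glen = self.config.flank_gene_length
        rep_start = spec.position
        rep_end = rep_start + len(ref) - 1
        lg_start = rep_start - left_off - glen
        rg_end = rep_end + right_off + glen
        self._claim(lg_start, rg_end)

        copy = _mutate_copy(ref.sequence, spec.divergence, self.rng)
        placed = copy if spec.strand == "+" else reverse_complement(copy)
        self._write(lg_start, _gene_sequence(glen, self.rng))
        self._write(rep_start, placed)
        self._write(rep_end + right_off + 1, _gene_sequence(glen, self.rng))
        self.features.append(GeneFeature("chr", lg_start, rep_start - left_off - 1, "+", left_gene))
        self.features.append(GeneFeature("chr", rep_end + right_off + 1, rg_end, "+", right_gene))
        hit = TruthHit(
            contig_id="chr",
            start=rep_start,
            end=rep_end,
            strand=spec.strand,
            allowed_types=frozenset({spec.type_id}),
            orientation="forward" if spec.strand == "+" else "reverse",
            origin=spec.label,
        )
        self.hits.append(hit)
        return hit

    # -- locating current loci --------------------------------------------

    def _locate(self, label_x: str, label_y: str) -> tuple[int, int]:
        """Indices of the current truth hits carrying loci ``label_x`` and ``label_y``.

        Canonical labels resolve via the derived call labels; hybrid junctions
        qualify for either of their two loci (needed to re-invert a pair).
        """
        calls = derive_calls(self.hits, self.features)

        def candidates(label: str) -> list[int]:
            out = []
            for c in calls:
                if c.locus_label == label:
                    out.append(c.hit_index)
                elif c.locus_label == "hybrid" and label in {GENE_TO_LOCUS[g] for g in c.junction_pair}:
                    out.append(c.hit_index)
            return out

        cx, cy = candidates(label_x), candidates(label_y)
        pairs = sorted(
            (self.hits[i].start, self.hits[j].start, i, j) for i in cx for j in cy if i != j
        )
        if not pairs:
            raise ValueError(f"no repeat pair found for loci {label_x}/{label_y}")
        _, _, i, j = pairs[0]
        return (i, j) if self.hits[i].start < self.hits[j].start else (j, i)

    # -- recombination operations -----------------------------------------

    def apply_inversion(self, label_x: str, label_y: str) -> None:
        """Invert the region between two repeats lying in inverted orientation.

        Breakpoints sit at the repeat midpoints, so the two resulting junction
        repeats are chimeras of the two originals and two reciprocal hybrid
        gene permutations appear.
        """
        ix, iy = self._locate(label_x, label_y)
        hx, hy = self.hits[ix], self.hits[iy]
        if hx.strand == hy.strand:
            raise ValueError(
                f"loci {label_x}/{label_y} are in direct orientation; use apply_deletion"
            )
        lx, ly = hx.end - hx.start + 1, hy.end - hy.start + 1
        s = hx.start + lx // 2  # first inverted position
        e = hy.start + ly // 2 - 1  # last inverted position
        self.seq[s - 1 : e] = reverse_complement(self.seq[s - 1 : e].decode()).encode()

        def remap(pos: int) -> int:
            return s + e - pos

        new_features = []
        for f in self.features:
            if f.start >= s and f.end <= e:
                new_features.append(
                    GeneFeature(f.contig_id, remap(f.end), remap(f.start), "-" if f.strand == "+" else "+", f.gene_name)
                )
            elif f.end < s or f.start > e:
                new_features.append(f)
            else:  # pragma: no cover - breakpoints are inside repeats
                raise AssertionError("gene straddles inversion breakpoint")
        self.features = new_features

        allowed = hx.allowed_types | hy.allowed_types
        j1 = TruthHit("chr", hx.start, s + ly // 2 - 1, hx.strand, allowed,
                      "forward" if hx.strand == "+" else "reverse", "junction")
        j2 = TruthHit("chr", s + e - hx.end, hy.end, hy.strand, allowed,
                      "forward" if hy.strand == "+" else "reverse", "junction")
        survivors = []
        for k, h in enumerate(self.hits):
            if k in (ix, iy):
                continue
            if h.start >= s and h.end <= e:
                survivors.append(
                    TruthHit(h.contig_id, remap(h.end), remap(h.start),
                             "-" if h.strand == "+" else "+", h.allowed_types,
                             "reverse" if h.orientation == "forward" else "forward", h.origin)
                )
            else:
                survivors.append(h)
        self.hits = survivors + [j1, j2]
        self.occupied = []  # regions already materialized; further planting unsupported

    def apply_deletion(self, label_x: str, label_y: str) -> None:
        """Excise the region between two direct-orientation repeats.

        Recombination between direct repeats removes one locus and the
        intervening sequence, leaving a single chimeric junction repeat.
        """
        ix, iy = self._locate(label_x, label_y)
        hx, hy = self.hits[ix], self.hits[iy]
        if hx.strand != hy.strand:
            raise ValueError(
                f"loci {label_x}/{label_y} are in inverted orientation; use apply_inversion"
            )
        lx, ly = hx.end - hx.start + 1, hy.end - hy.start + 1
        s = hx.start + lx // 2
        e = hy.start + ly // 2 - 1
        removed = e - s + 1
        del self.seq[s - 1 : e]

        def shift(pos: int) -> int:
            return pos - removed if pos > e else pos

        self.features = [
            GeneFeature(f.contig_id, shift(f.start), shift(f.end), f.strand, f.gene_name)
            for f in self.features
            if f.end < s or f.start > e
        ]
        allowed = hx.allowed_types | hy.allowed_types
        junction = TruthHit("chr", hx.start, hx.start + (lx // 2) + (ly - ly // 2) - 1,
                            hx.strand, allowed, hx.orientation, "junction")
        survivors = []
        for k, h in enumerate(self.hits):
            if k in (ix, iy) or (h.start >= s and h.end <= e):
                continue
            survivors.append(replace_hit_coords(h, shift(h.start), shift(h.end)))
        self.hits = survivors + [junction]
        self.occupied = []


def replace_hit_coords(h: TruthHit, start: int, end: int) -> TruthHit:
    return TruthHit(h.contig_id, start, end, h.strand, h.allowed_types, h.orientation, h.origin)


# ---------------------------------------------------------------------------
# Truth derivation (independent re-scan of the emitted annotation)
# ---------------------------------------------------------------------------


def derive_calls(hits: list, features: list, window: int = 1000) -> list:
    """Expected locus call for every truth hit, from the current feature table.

    A plain exhaustive scan: nearest gene end before the repeat / gene start
    after it, within the flank window; the label follows from whether the two
    gene names form one canonical pair, two different ones (hybrid), or
    neither (unplaced).
    """
    calls = []
    for idx, h in enumerate(hits):
        same = [f for f in features if f.contig_id == h.contig_id]
        lefts = [f for f in same if f.start < h.start]
        rights = [f for f in same if f.end > h.end]
        left = max(lefts, key=lambda f: f.end) if lefts else None
        right = min(rights, key=lambda f: f.start) if rights else None
        lg = ld = rg = rd = None
        if left is not None:
            d = max(0, h.start - left.end - 1)
            if d <= window:
                lg, ld = left.gene_name, d
        if right is not None:
            d = max(0, right.start - h.end - 1)
            if d <= window:
                rg, rd = right.gene_name, d
        label, pair = "unplaced", None
        if lg in GENE_TO_LOCUS and rg in GENE_TO_LOCUS:
            gene_pair = frozenset({lg, rg})
            matching = [t for t, p in CANONICAL_PAIRS.items() if p == gene_pair]
            if matching:
                label = matching[0]
            elif GENE_TO_LOCUS[lg] != GENE_TO_LOCUS[rg]:
                label, pair = "hybrid", gene_pair
        calls.append(TruthCall(idx, lg, rg, ld, rd, label, pair))
    return calls


def derive_events(hits: list, calls: list) -> list:
    """Expected events from the hybrid truth calls, with reciprocal pairing.

    Two hybrids on one contig with the same locus pair and disjoint gene pairs
    covering all four canonical genes are reciprocal; their span is inclusive
    of both junction repeats.
    """
    raw = []
    for c in calls:
        if c.locus_label != "hybrid":
            continue
        h = hits[c.hit_index]
        raw.append(
            {
                "contig": h.contig_id,
                "pair": c.junction_pair,
                "loci": frozenset(GENE_TO_LOCUS[g] for g in c.junction_pair),
                "start": h.start,
                "end": h.end,
                "paired": False,
                "span": None,
            }
        )
    for i in range(len(raw)):
        for j in range(i + 1, len(raw)):
            a, b = raw[i], raw[j]
            if a["paired"] or b["paired"] or a["contig"] != b["contig"] or a["loci"] != b["loci"]:
                continue
            four = set().union(*(CANONICAL_PAIRS[t] for t in a["loci"]))
            if not (a["pair"] & b["pair"]) and (a["pair"] | b["pair"] == four):
                up, down = (a, b) if a["start"] <= b["start"] else (b, a)
                span = down["end"] - up["start"] + 1
                a["paired"] = b["paired"] = True
                a["span"] = b["span"] = span
    return [
        TruthEvent(r["contig"], r["pair"], r["loci"], r["start"], r["end"], r["paired"], r["span"])
        for r in raw
    ]


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------


def _fragment(
    seq: str,
    features: list,
    hits: list,
    n_contigs: int,
    rng: np.random.Generator,
    avoid_repeats: bool = True,
) -> tuple[dict, list, list]:
    """Cut the chromosome into ``n_contigs`` pieces at uniform random positions.

    A cut after position p splits any feature spanning (p, p+1); cut positions
    inside planted repeat intervals are excluded by default.  Genes severed by
    a cut are dropped from the annotation (their locus calls become unplaced).
    """
    L = len(seq)
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if n_contigs == 1:
        return {"chr": seq}, list(features), [replace_hit_coords(h, h.start, h.end) for h in hits]
    forbidden = np.zeros(L, dtype=bool)  # forbidden[p-1]: may not cut between p and p+1
    if avoid_repeats:
        for h in hits:
            forbidden[h.start - 1 : h.end] = True
    allowed = np.flatnonzero(~forbidden[: L - 1]) + 1  # cut after position p
    if allowed.size < n_contigs - 1:
        raise ValueError("not enough cut space for the requested contig count")
    cuts = sorted(int(p) for p in rng.choice(allowed, size=n_contigs - 1, replace=False))
    bounds = [0] + cuts + [L]
    contigs = {}
    new_features: list[GeneFeature] = []
    new_hits: list[TruthHit] = []
    for k in range(n_contigs):
        lo, hi = bounds[k], bounds[k + 1]  # 0-based half-open
        name = f"contig_{k + 1}"
        contigs[name] = seq[lo:hi]
        for f in features:
            if f.start > lo and f.end <= hi:
                new_features.append(GeneFeature(name, f.start - lo, f.end - lo, f.strand, f.gene_name))
        for h in hits:
            if h.start > lo and h.end <= hi:
                new_hits.append(
                    TruthHit(name, h.start - lo, h.end - lo, h.strand, h.allowed_types, h.orientation, h.origin)
                )
    return contigs, new_features, new_hits


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig, registry: dict | None = None) -> SimulatedGenome:
    """Build one annotated genome with its truth tables from a config."""
    registry = registry or builtin_registry()
    rng = np.random.default_rng(config.seed)
    builder = _Builder(config, registry, rng)
    for spec in config.loci:
        builder.plant_locus(spec)
    for x, y in config.inversions:
        builder.apply_inversion(x, y)
    for x, y in config.deletions:
        builder.apply_deletion(x, y)
    contigs, features, hits = _fragment(
        builder.seq.decode(),
        builder.features,
        builder.hits,
        config.n_contigs,
        rng,
        config.avoid_repeats_when_fragmenting,
    )
    # generation-time consistency check: planted termini must sit at the
    # recorded truth coordinates on the recorded strand
    for h in hits:
        seg = contigs[h.contig_id][h.start - 1 : h.end]
        if h.strand == "-":
            seg = reverse_complement(seg)
        ref_term = next(iter(h.allowed_types))
        assert seg[:_PROTECTED_END] == registry[ref_term].sequence[:_PROTECTED_END]
        assert seg[-_PROTECTED_END:] == registry[ref_term].sequence[-_PROTECTED_END:]
    calls = derive_calls(hits, features)
    events = derive_events(hits, calls)
    truth = SyntheticTruth(
        hits=hits,
        calls=calls,
        events=events,
        contig_lengths={k: len(v) for k, v in contigs.items()},
    )
    return SimulatedGenome(config.genome_id, contigs, features, truth, config)


# strand draw probabilities per type, matching the observed orientation
# tallies of the family survey (B always reverse; D and E always forward;
# A forward in 3448/4703 genomes; C forward in 2952/5741)
_STRAND_P_FORWARD = {"A": 3448 / 4703, "B": 0.0, "C": 2952 / 5741, "D": 1.0, "E": 1.0}

#: inversion-eligible locus pairs weighted by the survey's event-class counts
#: (A/C dominates at 88%); pairs involving the internally deleted type B are
#: excluded because their chimeric junctions fall below the default score
#: threshold (see methods note)
_INVERSION_WEIGHTS = {frozenset("AC"): 137, frozenset("AE"): 6, frozenset("AD"): 2, frozenset("CE"): 1}


def _cohort_config(i: int, rng: np.random.Generator, genome_length: int,
                   max_divergence: float, n_contigs: int) -> SimulationConfig:
    labels = list("ABCDE")
    k = int(rng.integers(3, 6))
    chosen = sorted(rng.choice(labels, size=k, replace=False).tolist())
    strands = {
        t: "+" if rng.random() < _STRAND_P_FORWARD[t] else "-" for t in chosen
    }
    order = list(chosen)
    rng.shuffle(order)
    margin = 5_000
    slot = (genome_length - 2 * margin) // k
    positions = {}
    for j, label in enumerate(order):
        lo = margin + j * slot + 1500  # room for the left gene + offset
        hi = margin + (j + 1) * slot - 2500
        positions[label] = int(rng.integers(lo, hi))
    specs = tuple(
        LocusSpec(
            label=t,
            position=positions[t],
            strand=strands[t],
            divergence=float(rng.uniform(0.0, max_divergence)),
        )
        for t in order
    )
    n_inv = int(rng.integers(0, 3))
    inversions = []
    used: set[str] = set()
    candidates = [
        (pair, w)
        for pair, w in _INVERSION_WEIGHTS.items()
        if pair <= set(chosen) and len({strands[t] for t in pair}) == 2
    ]
    candidates.sort(key=lambda item: -item[1])
    for pair, _ in candidates:
        if len(inversions) >= n_inv or pair & used:
            continue
        # segments of distinct locus pairs must not interleave
        span = sorted(positions[t] for t in pair)
        clash = any(
            (span[0] < sorted(positions[t] for t in prev)[1]) and (sorted(positions[t] for t in prev)[0] < span[1])
            for prev in inversions
        )
        if clash:
            continue
        inversions.append(tuple(sorted(pair)))
        used |= pair
    return SimulationConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        genome_id=f"sim_{i:03d}",
        genome_length=genome_length,
        loci=specs,
        inversions=tuple(inversions),
        n_contigs=n_contigs,
    )


def simulate_cohort(
    n_genomes: int,
    seed: int,
    genome_length: int = 200_000,
    max_divergence: float = 0.05,
    n_contigs: int = 1,
    registry: dict | None = None,
) -> list[SimulatedGenome]:
    """A seeded cohort of genomes with 3-5 planted loci and 0-2 inversions each.

    Strand draws and inversion-class weights follow the family survey's
    observed tallies; divergence is uniform on [0, ``max_divergence``].
    """
    registry = registry or builtin_registry()
    rng = np.random.default_rng(seed)
    sims = []
    for i in range(n_genomes):
        config = _cohort_config(i, rng, genome_length, max_divergence, n_contigs)
        sims.append(simulate_genome(config, registry))
    return sims


def write_genome(sim: SimulatedGenome, out_dir) -> dict:
    """Emit FASTA, GFF3 and truth TSVs for one simulated genome; returns the paths."""
    from pathlib import Path

    import pandas as pd

    from tripscan.io import write_fasta, write_gff3

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / f"{sim.genome_id}.fasta",
        "gff3": out / f"{sim.genome_id}.gff3",
        "hits": out / f"{sim.genome_id}.truth_hits.tsv",
        "calls": out / f"{sim.genome_id}.truth_calls.tsv",
        "events": out / f"{sim.genome_id}.truth_events.tsv",
    }
    write_fasta(sim.contigs, paths["fasta"])
    write_gff3(sim.features, paths["gff3"], sim.truth.contig_lengths)
    pd.DataFrame(
        [
            {
                "contig": h.contig_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "allowed_types": "/".join(sorted(h.allowed_types)),
                "orientation": h.orientation,
                "origin": h.origin,
            }
            for h in sim.truth.hits
        ]
    ).to_csv(paths["hits"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "hit_index": c.hit_index,
                "left_gene": c.left_gene or "",
                "right_gene": c.right_gene or "",
                "left_distance": "" if c.left_distance is None else c.left_distance,
                "right_distance": "" if c.right_distance is None else c.right_distance,
                "locus_label": c.locus_label,
                "junction_pair": "/".join(sorted(c.junction_pair)) if c.junction_pair else "",
            }
            for c in sim.truth.calls
        ]
    ).to_csv(paths["calls"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "contig": e.contig_id,
                "junction_pair": "/".join(sorted(e.junction_pair)),
                "locus_pair": "/".join(sorted(e.locus_pair)),
                "repeat_start": e.repeat_start,
                "repeat_end": e.repeat_end,
                "paired": e.paired,
                "span": "" if e.span is None else e.span,
            }
            for e in sim.truth.events
        ]
    ).to_csv(paths["events"], sep="\t", index=False)
    return paths
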