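"""Registry of canonical TRIP1 repeat types.

The TRIP1 family comprises five GC-rich interspersed repeat types (A-E) found
in *Escherichia coli* chromosomes.  Each type has a canonical chromosomal
locus defined by its two flanking genes.  This module fixes the coordinate
convention for the whole package: **1-based, fully inclusive** intervals,
the only convention under which the published coordinates reproduce the
published lengths (e.g. 915281 - 915016 + 1 = 266).

A self-consistent synthetic reference family is bundled (:func:`builtin_registry`)
so that nothing here requires downloading the source genome records; users may
substitute the real sequences via :func:`load_registry`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "RepeatRef",
    "InvalidIntervalError",
    "RegistryLoadError",
    "TYPE_IDS",
    "CANONICAL_COORDS",
    "CANONICAL_FLANKS",
    "CANONICAL_PAIRS",
    "GENE_TO_LOCUS",
    "coords_to_length",
    "gc_fraction",
    "builtin_registry",
    "load_registry",
    "write_registry",
]

TYPE_IDS = ("A", "B", "C", "D", "E")

#: source record and 1-based inclusive coordinates of each canonical copy
CANONICAL_COORDS = {
    "A": ("NC_000913.3", 915016, 915281, "+"),
    "B": ("NC_000913.3", 1080855, 1081000, "+"),
    "C": ("NC_000913.3", 2229122, 2229394, "+"),
    "D": ("CP027440.1", 2251149, 2251412, "+"),
    "E": ("CP057178.1", 1232542, 1232806, "+"),
}

#: (upstream/left gene, left gap bp, downstream/right gene, right gap bp)
#: gaps are measured from the repeat boundary to the nearest gene boundary
CANONICAL_FLANKS = {
    "A": ("aqpZ", 70, "ybjE", 158),
    "B": ("putP", 41, "ycdN", 355),
    "C": ("yohI", 43, "yohG", 363),
    "D": ("alx", 96, "sstT", 255),
    "E": ("copA", 38, "ybaP", 124),
}

#: unordered canonical gene pair per locus
CANONICAL_PAIRS = {t: frozenset({CANONICAL_FLANKS[t][0], CANONICAL_FLANKS[t][2]}) for t in TYPE_IDS}

#: inverse map gene name -> locus label
GENE_TO_LOCUS = {g: t for t, pair in CANONICAL_PAIRS.items() for g in pair}


class InvalidIntervalError(ValueError):
    """Raised for 1-based intervals with start > end or positions < 1."""


class RegistryLoadError(ValueError):
    """Raised when a reference FASTA/table pair is inconsistent."""


@dataclass(frozen=True)
class RepeatRef:
    """One canonical repeat type.

    Coordinates are 1-based inclusive on ``source_record``; the stored
    ``sequence`` is the repeat read on ``source_strand``.
    """

    type_id: str
    sequence: str
    source_record: str
    source_start: int
    source_end: int
    source_strand: str
    upstream_gene: str
    downstream_gene: str
    upstream_offset: int
    downstream_offset: int

    def __post_init__(self) -> None:
        expected = coords_to_length(self.source_start, self.source_end)
        if len(self.sequence) != expected:
            raise RegistryLoadError(
                f"type {self.type_id}: sequence length {len(self.sequence)} "
                f"does not match declared interval length {expected}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def coords_to_length(start: int, end: int) -> int:
    """Length in bp of the 1-based inclusive interval [start, end]."""
    if start < 1 or end < 1:
        raise InvalidIntervalError(f"positions must be >= 1, got ({start}, {end})")
    if start > end:
        raise InvalidIntervalError(f"start {start} > end {end}")
    return end - start + 1


def gc_fraction(sequence: str) -> float:
    """(G + C) / (A + C + G + T); ambiguity codes excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# Bundled synthetic reference family
# ---------------------------------------------------------------------------

#: conserved family termini (10 bp each) shared by all five types; interspersed
#: repeat families typically carry conserved ends, and the simulator keeps
#: planted-copy termini unmutated so that copy boundaries are exact alignment
#: optima.
_TERM5 = "GGCGCTGGCG"
_TERM3 = "CGCCAGCGCC"
_FAMILY_SEED = 91528  # arbitrary fixed seed; the family is frozen, not tunable

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_gc_string(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _mutate_interior(rng: np.random.Generator, seq: str, frac: float) -> str:
    """Substitute ``frac`` of positions outside the conserved 10 bp termini."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    interior = np.arange(10, len(arr) - 10)
    k = int(round(frac * interior.size))
    pos = rng.choice(interior, size=k, replace=False)
    for p in pos:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[p]]
        arr[p] = bytes([rng.choice(choices)])
    return arr.tobytes().decode()


def _delete_interior(rng: np.random.Generator, seq: str, n: int, block: bool = False) -> str:
    interior = np.arange(10, len(seq) - 10)
    if block:
        start = int(rng.integers(interior[0], interior[-1] - n + 1))
        keep = [i for i in range(len(seq)) if not (start <= i < start + n)]
    else:
        drop = set(int(i) for i in rng.choice(interior, size=n, replace=False))
        keep = [i for i in range(len(seq)) if i not in drop]
    return "".join(seq[i] for i in keep)


def _insert_interior(rng: np.random.Generator, seq: str, n: int, gc: float) -> str:
    pos = int(rng.integers(10, len(seq) - 10))
    return seq[:pos] + _random_gc_string(rng, n, gc) + seq[pos:]


def _build_family() -> dict[str, str]:
    """Deterministically build the synthetic five-type family.

    Lengths match the published family exactly (A 266, B 146, C 273, D 264,
    E 265) and the derivation mirrors its identity structure: B is A with a
    large internal deletion plus heavy divergence (~84% identity to A), C/E
    diverge ~6% from A, D ~11%.
    """
    rng = np.random.default_rng(_FAMILY_SEED)
    gc = 0.635
    a = _TERM5 + _random_gc_string(rng, 266 - 20, gc) + _TERM3
    b = _mutate_interior(rng, _delete_interior(rng, a, 120, block=True), 0.16)
    c = _insert_interior(rng, _mutate_interior(rng, a, 0.06), 7, gc)
    d = _delete_interior(rng, _mutate_interior(rng, a, 0.11), 2)
    e = _delete_interior(rng, _mutate_interior(rng, a, 0.06), 1)
    fam = {"A": a, "B": b, "C": c, "D": d, "E": e}
    assert {t: len(s) for t, s in fam.items()} == {"A": 266, "B": 146, "C": 273, "D": 264, "E": 265}
    return fam


def builtin_registry() -> dict[str, RepeatRef]:
    """The bundled synthetic reference family keyed by type id.

    Sequences are synthetic stand-ins built with the published lengths,
    GC content and pairwise-identity structure; coordinates and flanking-gene
    metadata are the published canonical values.
    """
    fam = _build_family()
    registry: dict[str, RepeatRef] = {}
    for t in TYPE_IDS:
        rec, start, end, strand = CANONICAL_COORDS[t]
        up, up_off, down, down_off = CANONICAL_FLANKS[t]
        registry[t] = RepeatRef(
            type_id=t,
            sequence=fam[t],
            source_record=rec,
            source_start=start,
            source_end=end,
            source_strand=strand,
            upstream_gene=up,
            downstream_gene=down,
            upstream_offset=up_off,
            downstream_offset=down_off,
        )
    return registry


# ---------------------------------------------------------------------------
# File-based registries
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "type_id",
    "accession",
    "start",
    "end",
    "strand",
    "upstream_gene",
    "downstream_gene",
    "upstream_offset",
    "downstream_offset",
]


def load_registry(reference_fasta: str | Path, coordinate_table: str | Path) -> dict[str, RepeatRef]:
    """Load a registry from a FASTA (records named by type id) and a TSV table.

    Every sequence length is verified against the declared interval; a
    mismatch or a missing type raises :class:`RegistryLoadError` naming it.
    """
    from tripscan.io import read_fasta

    seqs = read_fasta(reference_fasta)
    registry: dict[str, RepeatRef] = {}
    with open(coordinate_table, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing_cols = set(_TABLE_COLUMNS) - set(reader.fieldnames or [])
        if missing_cols:
            raise RegistryLoadError(f"coordinate table missing columns: {sorted(missing_cols)}")
        for row in reader:
            t = row["type_id"]
            if t not in seqs:
                raise RegistryLoadError(f"type {t}: no FASTA record named {t!r}")
            try:
                registry[t] = RepeatRef(
                    type_id=t,
                    sequence=seqs[t],
                    source_record=row["accession"],
                    source_start=int(row["start"]),
                    source_end=int(row["end"]),
                    source_strand=row["strand"],
                    upstream_gene=row["upstream_gene"],
                    downstream_gene=row["downstream_gene"],
                    upstream_offset=int(row["upstream_offset"]),
                    downstream_offset=int(row["downstream_offset"]),
                )
            except InvalidIntervalError as exc:
                raise RegistryLoadError(f"type {t}: {exc}") from exc
    if len(set(registry)) != len(registry):
        raise RegistryLoadError("duplicate type ids in coordinate table")
    return registry


def write_registry(registry: dict[str, RepeatRef], reference_fasta: str | Path, coordinate_table: str | Path) -> None:
    """Materialize a registry as the FASTA + TSV pair consumed by :func:`load_registry`."""
    from tripscan.io import write_fasta

    write_fasta({t: r.sequence for t, r in registry.items()}, reference_fasta)
    with open(coordinate_table, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for t, r in registry.items():
            writer.writerow(
                [
                    t,
                    r.source_record,
                    r.source_start,
                    r.source_end,
                    r.source_strand,
                    r.upstream_gene,
                    r.downstream_gene,
                    r.upstream_offset,
                    r.downstream_offset,
                ]
            )
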