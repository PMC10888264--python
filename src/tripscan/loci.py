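"""Locus assignment from flanking-gene context.

Each resolved repeat copy is localized by the two annotated genes flanking it
within a window (default 1000 bp, the flank size used for annotation).  A copy
whose two flanks are the canonical gene pair of a locus gets that locus label
(A-E); flanks drawn from two *different* canonical pairs mark a hybrid
junction — the signature of an intra-chromosomal rearrangement; anything else
is unplaced.

Left/right are defined on the contig forward strand.  Canonical pairs:
A {aqpZ, ybjE}, B {putP, ycdN}, C {yohI, yohG}, D {alx, sstT}, E {copA, ybaP}.
"""

from __future__ import annotations

from dataclasses import dataclass

from tripscan.reference import CANONICAL_PAIRS, GENE_TO_LOCUS
from tripscan.resolve import TypedHit

__all__ = ["GeneFeature", "LocusCall", "extract_flanks", "nearest_genes", "assign_locus", "map_loci"]


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene (1-based inclusive coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_name: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_name}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class LocusCall:
    """A typed hit with its flanking-gene context and locus label."""

    hit: TypedHit
    left_gene: str | None
    right_gene: str | None
    left_distance: int | None
    right_distance: int | None
    locus_label: str  # A..E, 'hybrid', or 'unplaced'
    junction_pair: frozenset | None = None


def extract_flanks(contig: str, hit: TypedHit, window: int = 1000) -> tuple[str, str]:
    """The up-to-``window`` bp sequences flanking the hit, truncated at contig edges."""
    L = len(contig)
    if not (1 <= hit.start <= hit.end <= L):
        raise ValueError(f"hit [{hit.start}, {hit.end}] outside contig of length {L}")
    left = contig[max(0, hit.start - 1 - window) : hit.start - 1]
    right = contig[hit.end : hit.end + window]
    return left, right


def nearest_genes(
    hit: TypedHit, features: list[GeneFeature], window: int = 1000
) -> tuple[tuple[str, int] | None, tuple[str, int] | None]:
    """Nearest annotated gene on each side of the hit, with its gap in bp.

    The left gene is the one with the greatest end before the hit, the right
    gene the one with the smallest start after it; the gap is 0 for abutting
    or overlapping genes, and sides with no gene within ``window`` return
    ``None``.  A gene straddling the window edge counts if any part of it lies
    within the window.
    """
    left_best: GeneFeature | None = None
    right_best: GeneFeature | None = None
    for f in features:
        if f.contig_id != hit.contig_id:
            continue
        if f.start < hit.start:  # candidate left flank (may overlap the hit)
            if left_best is None or f.end > left_best.end or (f.end == left_best.end and f.start > left_best.start):
                left_best = f
        if f.end > hit.end:  # candidate right flank
            if right_best is None or f.start < right_best.start or (
                f.start == right_best.start and f.end < right_best.end
            ):
                right_best = f
    left = None
    if left_best is not None:
        gap = max(0, hit.start - left_best.end - 1)
        if gap <= window:
            left = (left_best.gene_name, gap)
    right = None
    if right_best is not None:
        gap = max(0, right_best.start - hit.end - 1)
        if gap <= window:
            right = (right_best.gene_name, gap)
    return left, right


def assign_locus(
    left_gene: str | None, right_gene: str | None, canonical_pairs: dict | None = None
) -> tuple[str, frozenset | None]:
    """Locus label from the unordered flanking-gene pair.

    Both genes from one canonical pair -> that locus; genes from two different
    pairs -> ``('hybrid', junction_pair)``; a missing flank or a gene outside
    the canonical table -> ``('unplaced', None)``.  Symmetric in its two gene
    arguments.
    """
    pairs = canonical_pairs if canonical_pairs is not None else CANONICAL_PAIRS
    gene_to_locus = (
        GENE_TO_LOCUS
        if canonical_pairs is None
        else {g: t for t, p in pairs.items() for g in p}
    )
    if left_gene is None or right_gene is None:
        return "unplaced", None
    if left_gene not in gene_to_locus or right_gene not in gene_to_locus:
        return "unplaced", None
    pair = frozenset({left_gene, right_gene})
    for label, canonical in pairs.items():
        if pair == canonical:
            return label, None
    if gene_to_locus[left_gene] != gene_to_locus[right_gene]:
        return "hybrid", pair
    # two distinct genes of the same locus cannot flank one repeat copy in a
    # canonical arrangement unless they equal the canonical pair (handled
    # above); same gene on both sides is likewise unplaced
    return "unplaced", None


def map_loci(
    typed_hits: list[TypedHit], features: list[GeneFeature], window: int = 1000
) -> list[LocusCall]:
    """Locus calls for every typed hit."""
    calls = []
    for hit in typed_hits:
        left, right = nearest_genes(hit, features, window)
        label, pair = assign_locus(
            left[0] if left else None, right[0] if right else None
        )
        calls.append(
            LocusCall(
                hit=hit,
                left_gene=left[0] if left else None,
                right_gene=right[0] if right else None,
                left_distance=left[1] if left else None,
                right_distance=right[1] if right else None,
                locus_label=label,
                junction_pair=pair,
            )
        )
    return calls
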