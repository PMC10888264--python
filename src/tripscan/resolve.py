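"""Overlap resolution and orientation assignment.

When copies of several repeat types match the same genomic position, only the
highest-scoring type is kept for downstream analysis.  "Same position" is
operationalized as reciprocal overlap greater than a threshold fraction
(default 0.5) of the shorter hit; overlapping hits form connected groups and
one survivor is kept per group.

Orientation is defined per type: a hit is *forward* when its aligned strand
equals the strand on which the reference sequence of its assigned type is
stored, *reverse* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from tripscan.align import RepeatHit

__all__ = ["TypedHit", "resolve_overlaps", "assign_orientation", "type_hits"]

_TYPE_ORDER = {t: i for i, t in enumerate("ABCDE")}


@dataclass(frozen=True)
class TypedHit(RepeatHit):
    """A resolved hit with its final type and reference-relative orientation."""

    final_type: str = ""
    orientation: str = ""


def _reciprocal_overlap(a: RepeatHit, b: RepeatHit, threshold: float) -> bool:
    ov = a.overlap(b)
    return ov > threshold * min(len(a), len(b))


def resolve_overlaps(hits: list[RepeatHit], overlap_threshold: float = 0.5) -> list[RepeatHit]:
    """Keep one hit per connected group of reciprocally overlapping hits.

    The survivor is the highest raw score; ties break on higher identity, then
    on type order A < B < C < D < E.  Survivors keep their coordinates; the
    operation is idempotent and never invents hits.
    """
    by_contig: dict[str, list[RepeatHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    survivors: list[RepeatHit] = []
    for contig_hits in by_contig.values():
        contig_hits.sort(key=lambda h: (h.start, h.end))
        n = len(contig_hits)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if contig_hits[j].start > contig_hits[i].end:
                    break
                if _reciprocal_overlap(contig_hits[i], contig_hits[j], overlap_threshold):
                    parent[find(i)] = find(j)
        groups: dict[int, list[RepeatHit]] = {}
        for i, h in enumerate(contig_hits):
            groups.setdefault(find(i), []).append(h)
        for group in groups.values():
            survivors.append(
                max(group, key=lambda h: (h.raw_score, h.identity, -_TYPE_ORDER[h.candidate_type]))
            )
    return sorted(survivors, key=lambda h: (h.contig_id, h.start, h.end))


def assign_orientation(hit: RepeatHit | TypedHit, registry: dict) -> str:
    """``forward`` iff the hit strand equals the stored reference strand of its type."""
    type_id = getattr(hit, "final_type", "") or hit.candidate_type
    if type_id not in registry:
        raise KeyError(f"unknown repeat type {type_id!r}")
    return "forward" if hit.strand == registry[type_id].source_strand else "reverse"


def type_hits(
    hits: list[RepeatHit], registry: dict, overlap_threshold: float = 0.5
) -> list[TypedHit]:
    """Resolve overlaps and attach final type and orientation to each survivor."""
    typed = []
    for h in resolve_overlaps(hits, overlap_threshold):
        t = TypedHit(
            genome_id=h.genome_id,
            contig_id=h.contig_id,
            start=h.start,
            end=h.end,
            strand=h.strand,
            raw_score=h.raw_score,
            identity=h.identity,
            coverage=h.coverage,
            candidate_type=h.candidate_type,
            final_type=h.candidate_type,
            orientation="",
        )
        typed.append(
            TypedHit(
                **{**t.__dict__, "orientation": assign_orientation(t, registry)}
            )
        )
    return typed
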