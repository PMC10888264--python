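"""Per-genome copy-number census and per-type presence/orientation tallies.

Reproduces the survey-style summaries of a repeat-family screen: how many
copies each genome carries (0 to 5+), which types are present in how many
genomes, and forward/reverse orientation splits, with shares reported as
integer percent rounded half-up (the convention that reproduces printed
shares such as 6454/6725 -> 96).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from tripscan.reference import TYPE_IDS
from tripscan.resolve import TypedHit

__all__ = [
    "GenomeSummary",
    "summarize_genome",
    "copy_number_histogram",
    "integer_percent",
    "type_presence_table",
]


@dataclass(frozen=True)
class GenomeSummary:
    """Copy-number and per-type orientation tallies for one genome."""

    genome_id: str
    completeness: str = "draft"  # {'complete', 'draft'}
    copy_number: int = 0
    types_present: frozenset = frozenset()
    orientation_counts: dict = field(default_factory=dict)  # type -> (fwd, rev)


def summarize_genome(
    genome_id: str, typed_hits: list[TypedHit], completeness: str = "draft"
) -> GenomeSummary:
    counts: dict[str, list[int]] = {}
    for h in typed_hits:
        fwd_rev = counts.setdefault(h.final_type, [0, 0])
        fwd_rev[0 if h.orientation == "forward" else 1] += 1
    return GenomeSummary(
        genome_id=genome_id,
        completeness=completeness,
        copy_number=len(typed_hits),
        types_present=frozenset(counts),
        orientation_counts={t: tuple(v) for t, v in counts.items()},
    )


def copy_number_histogram(summaries: list[GenomeSummary]) -> dict[str, int]:
    """Genome counts per copy-number bin 0,1,2,3,4,5+ (bins sum to the genome count)."""
    ids = [s.genome_id for s in summaries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in summaries")
    bins = {str(i): 0 for i in range(5)}
    bins["5+"] = 0
    for s in summaries:
        bins["5+" if s.copy_number >= 5 else str(s.copy_number)] += 1
    return bins


def integer_percent(numerator: int, denominator: int) -> int:
    """round(100 * n / d) with exact half-up rounding (no float involved)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    return (200 * numerator + denominator) // (2 * denominator)


def type_presence_table(summaries: list[GenomeSummary]) -> pd.DataFrame:
    """Per type: genomes containing >=1 copy, and forward/reverse copy counts.

    Indexed by type id with columns ``genomes``, ``forward``, ``reverse``.
    """
    rows = []
    for t in TYPE_IDS:
        genomes = sum(1 for s in summaries if t in s.types_present)
        fwd = sum(s.orientation_counts.get(t, (0, 0))[0] for s in summaries)
        rev = sum(s.orientation_counts.get(t, (0, 0))[1] for s in summaries)
        rows.append({"type": t, "genomes": genomes, "forward": fwd, "reverse": rev})
    return pd.DataFrame(rows).set_index("type")
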