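"""Rearrangement-event calling from hybrid junctions.

A hybrid locus call — a repeat copy whose two flanking genes come from two
different canonical loci — is one rearrangement event (one junction).  A
single inversion between two repeat copies produces two *reciprocal* hybrid
junctions that together carry all four flanking genes of the two original
loci; such pairs are matched within a contig and the affected span computed.
Deletion-type recombination between direct repeats leaves a single unpaired
junction.

Events are counted per junction, which matches tallies in which the two
reciprocal subtypes of one locus pair are reported separately.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

from tripscan.loci import LocusCall
from tripscan.reference import CANONICAL_PAIRS, GENE_TO_LOCUS
from tripscan.census import integer_percent

logger = logging.getLogger(__name__)

__all__ = ["RearrangementEvent", "EventTally", "detect_junctions", "pair_events", "tally_events"]


@dataclass(frozen=True)
class RearrangementEvent:
    """One hybrid junction."""

    genome_id: str
    contig_id: str
    junction_pair: frozenset
    locus_pair: frozenset
    repeat_type: str
    orientation: str
    repeat_start: int
    repeat_end: int
    paired: bool = False
    partner_index: int | None = None
    span: int | None = None


@dataclass(frozen=True)
class EventTally:
    """Grouped event counts with integer-percent shares per locus pair."""

    total: int
    n_genomes: int
    by_locus_pair: dict
    by_junction_pair: dict
    share_percent: dict


def detect_junctions(locus_calls: list[LocusCall]) -> list[RearrangementEvent]:
    """One event per hybrid locus call; canonical and unplaced calls yield none."""
    events = []
    for call in locus_calls:
        if call.locus_label != "hybrid":
            continue
        locus_pair = frozenset(GENE_TO_LOCUS[g] for g in call.junction_pair)
        events.append(
            RearrangementEvent(
                genome_id=call.hit.genome_id,
                contig_id=call.hit.contig_id,
                junction_pair=call.junction_pair,
                locus_pair=locus_pair,
                repeat_type=call.hit.final_type,
                orientation=call.hit.orientation,
                repeat_start=call.hit.start,
                repeat_end=call.hit.end,
            )
        )
    return events


def _complementary(a: RearrangementEvent, b: RearrangementEvent) -> bool:
    """True when the two junction pairs together carry all four canonical genes."""
    if a.locus_pair != b.locus_pair or a.junction_pair & b.junction_pair:
        return False
    four = set().union(*(CANONICAL_PAIRS[t] for t in a.locus_pair))
    return a.junction_pair | b.junction_pair == four


def pair_events(
    events: list[RearrangementEvent], inclusive_span: bool = True
) -> list[RearrangementEvent]:
    """Match reciprocal junctions within each contig and compute affected spans.

    The span covers the region between the two junction repeats, by default
    inclusive of both repeats; with ``inclusive_span=False`` it is the inner
    distance only.  More than two mutually complementary candidates trigger a
    warning and greedy nearest pairing.  Unpaired events keep ``span=None``.
    """
    out = list(events)
    by_group: dict[tuple, list[int]] = {}
    for i, ev in enumerate(out):
        by_group.setdefault((ev.genome_id, ev.contig_id, ev.locus_pair), []).append(i)
    for group in by_group.values():
        candidates = [
            (abs(out[i].repeat_start - out[j].repeat_start), i, j)
            for ki, i in enumerate(group)
            for j in group[ki + 1 :]
            if _complementary(out[i], out[j])
        ]
        if len(candidates) > 1:
            logger.warning(
                "ambiguous junction pairing in %s (%d candidate pairs); pairing greedily by proximity",
                out[group[0]].genome_id,
                len(candidates),
            )
        used: set[int] = set()
        for _, i, j in sorted(candidates):
            if i in used or j in used:
                continue
            used.update((i, j))
            up, down = (i, j) if out[i].repeat_start <= out[j].repeat_start else (j, i)
            if inclusive_span:
                span = out[down].repeat_end - out[up].repeat_start + 1
            else:
                span = out[down].repeat_start - out[up].repeat_end - 1
            out[i] = replace(out[i], paired=True, partner_index=j, span=span)
            out[j] = replace(out[j], paired=True, partner_index=i, span=span)
    return out


def tally_events(events: list[RearrangementEvent]) -> EventTally:
    """Counts per locus pair and per junction-gene-pair subtype, plus shares.

    Shares are integer percent (half-up) of the total event count per locus
    pair; genomes are counted once however many events they carry.
    """
    by_locus = Counter(ev.locus_pair for ev in events)
    by_junction = Counter(ev.junction_pair for ev in events)
    total = len(events)
    shares = {
        pair: integer_percent(count, total) for pair, count in by_locus.items()
    }
    return EventTally(
        total=total,
        n_genomes=len({ev.genome_id for ev in events}),
        by_locus_pair=dict(by_locus),
        by_junction_pair=dict(by_junction),
        share_percent=shares,
    )
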