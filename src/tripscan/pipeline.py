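"""End-to-end analysis: scan -> type -> localize -> rearrangements -> census.

Also provides the round-trip evaluation used to validate the whole pipeline
against simulator truth (recall, type/orientation/locus agreement, event
subtype and span recovery).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from tripscan.align import AlignmentParams, find_repeats
from tripscan.census import (
    GenomeSummary,
    copy_number_histogram,
    summarize_genome,
    type_presence_table,
)
from tripscan.loci import map_loci
from tripscan.rearrange import detect_junctions, pair_events, tally_events
from tripscan.reference import builtin_registry
from tripscan.resolve import type_hits
from tripscan.simulate import SimulatedGenome

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "GenomeResult", "PipelineReport", "analyze_genome", "run_pipeline", "roundtrip_metrics"]


@dataclass(frozen=True)
class RunConfig:
    """Inputs and knobs for an end-to-end run over a genome collection."""

    genome_fastas: tuple = ()
    annotation_dir: str | Path | None = None
    reference_fasta: str | Path | None = None
    reference_table: str | Path | None = None
    out_dir: str | Path = "tripscan_out"
    params: AlignmentParams = field(default_factory=AlignmentParams)
    flank_window: int = 1000
    overlap_threshold: float = 0.5
    completeness: dict = field(default_factory=dict)  # genome_id -> complete/draft


@dataclass
class GenomeResult:
    genome_id: str
    typed_hits: list
    calls: list
    events: list
    summary: GenomeSummary


@dataclass
class PipelineReport:
    results: list
    tally: object
    histogram: dict
    presence: object
    n_failed: int = 0


def analyze_genome(
    genome_id: str,
    contigs: dict,
    features: list,
    registry: dict,
    params: AlignmentParams | None = None,
    flank_window: int = 1000,
    overlap_threshold: float = 0.5,
    completeness: str = "draft",
) -> GenomeResult:
    """Run the full per-genome analysis on in-memory inputs."""
    raw_hits = find_repeats(contigs, registry, params, genome_id=genome_id)
    typed = type_hits(raw_hits, registry, overlap_threshold)
    calls = map_loci(typed, features, flank_window)
    events = pair_events(detect_junctions(calls))
    summary = summarize_genome(genome_id, typed, completeness)
    return GenomeResult(genome_id, typed, calls, events, summary)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Analyze every genome FASTA in the config and aggregate the survey tables.

    Per-genome failures are logged and skipped (counted in the report); all
    genomes failing raises.  Outputs are written as TSVs under ``out_dir``.
    """
    from tripscan.io import (
        read_fasta,
        read_gff3,
        write_calls_tsv,
        write_events_tsv,
        write_hits_tsv,
    )
    from tripscan.reference import load_registry

    if config.reference_fasta and config.reference_table:
        registry = load_registry(config.reference_fasta, config.reference_table)
    else:
        registry = builtin_registry()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: list[GenomeResult] = []
    n_failed = 0
    for fasta in config.genome_fastas:
        fasta = Path(fasta)
        genome_id = fasta.stem
        try:
            contigs = read_fasta(fasta)
            features = []
            if config.annotation_dir is not None:
                ann_dir = Path(config.annotation_dir)
                gff = ann_dir / f"{genome_id}.gff3"
                if not gff.exists():
                    gff = ann_dir / f"{genome_id}.gff"
                if gff.exists():
                    features = read_gff3(gff)
                else:
                    logger.warning("%s: no annotation found, locus calls will be unplaced", genome_id)
            result = analyze_genome(
                genome_id,
                contigs,
                features,
                registry,
                config.params,
                config.flank_window,
                config.overlap_threshold,
                config.completeness.get(genome_id, "draft"),
            )
        except Exception:
            logger.exception("%s: analysis failed, skipping", genome_id)
            n_failed += 1
            continue
        results.append(result)
        write_hits_tsv(result.typed_hits, out_dir / f"{genome_id}.hits.tsv")
        write_calls_tsv(result.calls, out_dir / f"{genome_id}.calls.tsv")
        write_events_tsv(result.events, out_dir / f"{genome_id}.events.tsv")
        logger.info(
            "%s: %d copies, %d events", genome_id, len(result.typed_hits), len(result.events)
        )
    if config.genome_fastas and not results:
        raise RuntimeError("all genomes failed")
    if not config.genome_fastas:
        logger.warning("no genome FASTAs supplied; empty report")
    all_events = [e for r in results for e in r.events]
    summaries = [r.summary for r in results]
    report = PipelineReport(
        results=results,
        tally=tally_events(all_events),
        histogram=copy_number_histogram(summaries),
        presence=type_presence_table(summaries),
        n_failed=n_failed,
    )
    _write_aggregate(report, out_dir)
    return report


def _write_aggregate(report: PipelineReport, out_dir: Path) -> None:
    import pandas as pd

    rows = [
        {
            "genome_id": r.summary.genome_id,
            "completeness": r.summary.completeness,
            "copy_number": r.summary.copy_number,
            "types_present": "".join(sorted(r.summary.types_present)),
            "n_events": len(r.events),
        }
        for r in report.results
    ]
    pd.DataFrame(
        rows, columns=["genome_id", "completeness", "copy_number", "types_present", "n_events"]
    ).to_csv(out_dir / "genomes.tsv", sep="\t", index=False)
    pd.DataFrame([report.histogram]).to_csv(out_dir / "copy_number_histogram.tsv", sep="\t", index=False)
    report.presence.to_csv(out_dir / "type_presence.tsv", sep="\t")
    tally = report.tally
    pd.DataFrame(
        [
            {
                "locus_pair": "/".join(sorted(pair)),
                "events": count,
                "share_percent": tally.share_percent[pair],
            }
            for pair, count in sorted(tally.by_locus_pair.items(), key=lambda kv: -kv[1])
        ],
        columns=["locus_pair", "events", "share_percent"],
    ).to_csv(out_dir / "event_tally.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Round-trip evaluation against simulator truth
# ---------------------------------------------------------------------------


def roundtrip_metrics(
    sims: list[SimulatedGenome],
    registry: dict | None = None,
    params: AlignmentParams | None = None,
    interval_tolerance: int = 2,
) -> dict:
    """Run the pipeline on simulated genomes and score it against the truth.

    A truth hit is recovered when a resolved hit matches its contig, strand
    and interval (within ``interval_tolerance`` bp).  Type agreement accepts
    any member of the truth's allowed types (chimeric junction repeats have
    two defensible types).  Events match on junction gene pair; spans must be
    exact.
    """
    registry = registry or builtin_registry()
    totals = {
        "n_genomes": len(sims),
        "truth_hits": 0,
        "recovered_hits": 0,
        "type_correct": 0,
        "orientation_correct": 0,
        "locus_correct": 0,
        "false_hits": 0,
        "truth_events": 0,
        "recovered_events": 0,
        "false_events": 0,
        "truth_spans": 0,
        "exact_spans": 0,
    }
    for sim in sims:
        result = analyze_genome(sim.genome_id, sim.contigs, sim.features, registry, params)
        truth = sim.truth
        matched_detected: set[int] = set()
        for t_idx, th in enumerate(truth.hits):
            totals["truth_hits"] += 1
            match = None
            for d_idx, dh in enumerate(result.typed_hits):
                if d_idx in matched_detected:
                    continue
                if (
                    dh.contig_id == th.contig_id
                    and dh.strand == th.strand
                    and abs(dh.start - th.start) <= interval_tolerance
                    and abs(dh.end - th.end) <= interval_tolerance
                ):
                    match = d_idx
                    break
            if match is None:
                continue
            matched_detected.add(match)
            dh = result.typed_hits[match]
            totals["recovered_hits"] += 1
            if dh.final_type in th.allowed_types:
                totals["type_correct"] += 1
            if dh.orientation == th.orientation:
                totals["orientation_correct"] += 1
            truth_call = truth.calls[t_idx]
            det_call = result.calls[match]
            if det_call.locus_label == truth_call.locus_label and (
                det_call.junction_pair == truth_call.junction_pair
            ):
                totals["locus_correct"] += 1
        totals["false_hits"] += len(result.typed_hits) - len(matched_detected)

        truth_ev = {(e.contig_id, e.junction_pair): e for e in truth.events}
        det_ev = {(e.contig_id, e.junction_pair): e for e in result.events}
        totals["truth_events"] += len(truth.events)
        for key, te in truth_ev.items():
            de = det_ev.get(key)
            if de is None:
                continue
            totals["recovered_events"] += 1
            if te.span is not None:
                totals["truth_spans"] += 1
                if de.span == te.span:
                    totals["exact_spans"] += 1
        totals["false_events"] += len([k for k in det_ev if k not in truth_ev])
    return totals
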