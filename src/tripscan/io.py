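"""File formats: FASTA, GFF3, BED6 and the package's headered TSV schemas.

All in-memory coordinates are 1-based inclusive; the 0-based half-open
conversion happens only at the BED boundary.  TSVs are tab-separated,
headered, UTF-8, unquoted, with a fixed column order per schema.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tripscan.loci import GeneFeature
from tripscan.resolve import TypedHit

__all__ = [
    "FastaParseError",
    "GffParseError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_hits_tsv",
    "read_hits_tsv",
    "hits_to_bed",
    "write_calls_tsv",
    "write_events_tsv",
]


class FastaParseError(ValueError):
    pass


class GffParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequences from a FASTA file, uppercased; empty file -> empty dict."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(f"{path}:{lineno}: expected '>' header, got {line.strip()[:30]!r}")
                break
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 80 columns; round-trips through :func:`read_fasta`."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Gene features from a GFF3 file (coordinates kept 1-based inclusive).

    Gene names come from the ``Name`` or ``gene`` attribute, falling back to
    ``locus_tag``.  Non-gene features are ignored; a file with CDS records but
    no gene records triggers a warning and yields an empty list.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    seen_types = set()
    for f in db.all_features():
        seen_types.add(f.featuretype)
        if f.start > f.end:
            raise GffParseError(f"{path}: feature {f.id} has start {f.start} > end {f.end}")
        if f.featuretype != "gene":
            continue
        name = (
            f.attributes.get("Name", [None])[0]
            or f.attributes.get("gene", [None])[0]
            or f.attributes.get("locus_tag", [None])[0]
        )
        if name is None:
            continue
        features.append(GeneFeature(f.seqid, f.start, f.end, f.strand, name))
    if not features and "CDS" in seen_types:
        warnings.warn(f"{path}: no gene features found (CDS-only annotation)", stacklevel=2)
    return features


def write_gff3(features: list[GeneFeature], path: str | Path, contig_lengths: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"##sequence-region {contig} 1 {length}\n")
        for i, f in enumerate(features):
            attrs = f"ID=gene{i:04d};Name={f.gene_name};locus_tag={f.gene_name}"
            fh.write(
                f"{f.contig_id}\ttripscan\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# TSV schemas
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "genome_id",
    "contig",
    "start",
    "end",
    "strand",
    "type",
    "score",
    "identity",
    "coverage",
    "final_type",
    "orientation",
]


def write_hits_tsv(hits: list, path: str | Path) -> None:
    """Hits or typed hits; the two trailing columns are empty for raw hits."""
    rows = []
    for h in hits:
        rows.append(
            {
                "genome_id": h.genome_id,
                "contig": h.contig_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "type": h.candidate_type,
                "score": h.raw_score,
                "identity": round(h.identity, 4),
                "coverage": round(h.coverage, 4),
                "final_type": getattr(h, "final_type", ""),
                "orientation": getattr(h, "orientation", ""),
            }
        )
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[TypedHit]:
    df = pd.read_csv(path, sep="\t", dtype={"final_type": str, "orientation": str})
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            TypedHit(
                genome_id=row.genome_id,
                contig_id=row.contig,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                raw_score=int(row.score),
                identity=float(row.identity),
                coverage=float(row.coverage),
                candidate_type=row.type,
                final_type="" if pd.isna(row.final_type) else str(row.final_type),
                orientation="" if pd.isna(row.orientation) else str(row.orientation),
            )
        )
    return hits


def hits_to_bed(hits: list, path: str | Path) -> None:
    """BED6: 0-based half-open, name = type, score = raw alignment score."""
    with open(path, "w") as fh:
        for h in hits:
            name = getattr(h, "final_type", "") or h.candidate_type
            fh.write(f"{h.contig_id}\t{h.start - 1}\t{h.end}\t{name}\t{h.raw_score}\t{h.strand}\n")


def write_calls_tsv(calls: list, path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "genome_id": c.hit.genome_id,
                "contig": c.hit.contig_id,
                "start": c.hit.start,
                "end": c.hit.end,
                "strand": c.hit.strand,
                "final_type": c.hit.final_type,
                "orientation": c.hit.orientation,
                "left_gene": c.left_gene or "",
                "right_gene": c.right_gene or "",
                "left_distance": "" if c.left_distance is None else c.left_distance,
                "right_distance": "" if c.right_distance is None else c.right_distance,
                "locus_label": c.locus_label,
                "junction_pair": "/".join(sorted(c.junction_pair)) if c.junction_pair else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "contig",
            "start",
            "end",
            "strand",
            "final_type",
            "orientation",
            "left_gene",
            "right_gene",
            "left_distance",
            "right_distance",
            "locus_label",
            "junction_pair",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_events_tsv(events: list, path: str | Path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "genome_id": e.genome_id,
                "contig": e.contig_id,
                "junction_pair": "/".join(sorted(e.junction_pair)),
                "locus_pair": "/".join(sorted(e.locus_pair)),
                "repeat_type": e.repeat_type,
                "orientation": e.orientation,
                "repeat_start": e.repeat_start,
                "repeat_end": e.repeat_end,
                "paired": e.paired,
                "span": "" if e.span is None else e.span,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "contig",
            "junction_pair",
            "locus_pair",
            "repeat_type",
            "orientation",
            "repeat_start",
            "repeat_end",
            "paired",
            "span",
        ],
    ).to_csv(path, sep="\t", index=False)
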