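"""Readers/writers for the external formats the tool touches.

FASTA headers follow the grammar ``id[|gene]``: the first ``|`` separates
the record id from an optional gene symbol (used by the conservation
module).  BED12 records use the standard 0-based half-open convention;
blockStarts/blockSizes define the exon intervals.  Machine-readable
outputs print 0-based positions and 4-decimal floats; the human-readable
summary prints 1-based positions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .circseq import CircularSequence, GenomicLocus
from .conservation import ConservedPair
from .ires import IresCall
from .m6a import KnownSite, MotifHit
from .orf import OrfCall

__all__ = [
    "AnalysisReport",
    "CircRecordReport",
    "read_fasta",
    "write_fasta",
    "read_bed12",
    "write_bed12",
    "read_m6a_sites",
    "write_report",
    "write_conserved_pairs",
]

REPORT_DIALECTS = ("tsv", "csv", "fasta")
_FLOAT_FMT = "{:.4f}"


# ---------------------------------------------------------------------------
# FASTA


def _parse_header(header: str) -> tuple[str, Optional[str]]:
    if "|" in header:
        rec_id, gene = header.split("|", 1)
        return rec_id, gene or None
    return header, None


def read_fasta(path) -> list[CircularSequence]:
    """Read circRNA sequences; headers are ``id[|gene]``.

    Sequences are normalized (U->T, uppercased); illegal characters and
    duplicate ids are rejected.
    """
    records: list[CircularSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, gene = _parse_header(rec.id)
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {rec_id!r} has an empty sequence")
        records.append(CircularSequence(id=rec_id, seq=str(rec.seq), gene=gene))
    return records


def write_fasta(records: Sequence[CircularSequence], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.gene is None else f"{rec.id}|{rec.gene}"
            fh.write(f">{header}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# BED12


def read_bed12(path, assembly: str = "") -> list[GenomicLocus]:
    """Read BED12 loci (0-based half-open; blockStarts/blockSizes -> exons).

    Exon intervals are returned in transcript order (reversed for minus
    strand).  The BED name column is kept on ``GenomicLocus.name``.
    """
    loci: list[GenomicLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 BED columns, got {len(cols)}"
                )
            chrom, chrom_start, _chrom_end, name, _score, strand = cols[:6]
            chrom_start = int(chrom_start)
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand is required in BED12")
            block_count = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(
                    f"{path}:{lineno}: blockCount does not match "
                    "blockSizes/blockStarts"
                )
            intervals = [
                (chrom_start + s, chrom_start + s + sz)
                for s, sz in zip(starts, sizes)
            ]
            if strand == "-":
                intervals = intervals[::-1]
            loci.append(
                GenomicLocus(
                    chrom=chrom,
                    strand=strand,
                    exon_intervals=tuple(intervals),
                    assembly=assembly,
                    name=name,
                )
            )
    return loci


def write_bed12(loci: Sequence[GenomicLocus], path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            genomic = sorted(locus.exon_intervals)
            chrom_start = genomic[0][0]
            chrom_end = genomic[-1][1]
            sizes = ",".join(str(b - a) for a, b in genomic)
            starts = ",".join(str(a - chrom_start) for a, b in genomic)
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        locus.name or ".",
                        "0",
                        locus.strand,
                        str(chrom_start),
                        str(chrom_end),
                        "0",
                        str(len(genomic)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# known m6A site tables


def read_m6a_sites(path, assembly: str, default_strand: str = "+") -> list[KnownSite]:
    """Read a TSV/BED-like known-site table: chrom, position (0-based),
    strand, optional name."""
    sites: list[KnownSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least chrom and position"
                )
            chrom, pos = cols[0], int(cols[1])
            strand = cols[2] if len(cols) > 2 and cols[2] else default_strand
            source = cols[3] if len(cols) > 3 else ""
            sites.append(
                KnownSite(
                    chrom=chrom,
                    genomic_pos=pos,
                    strand=strand,
                    assembly=assembly,
                    source=source,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class CircRecordReport:
    """All results for a single circRNA."""

    circ: CircularSequence
    orfs: list[OrfCall] = field(default_factory=list)
    ires_calls: list[IresCall] = field(default_factory=list)
    ires_assignment: dict[str, Optional[IresCall]] = field(default_factory=dict)
    motifs: list[MotifHit] = field(default_factory=list)
    known_site_positions: Optional[frozenset[int]] = None


@dataclass
class AnalysisReport:
    records: list[CircRecordReport] = field(default_factory=list)

    def validate(self) -> None:
        for rec in self.records:
            orf_ids = {o.orf_id for o in rec.orfs}
            missing = set(rec.ires_assignment) - orf_ids
            if missing:
                raise ValueError(
                    f"record {rec.circ.id!r}: IRES assignment references "
                    f"unknown ORFs {sorted(missing)}"
                )


def _ires_field(call: Optional[IresCall]) -> str:
    if call is None:
        return "None"
    return f"{call.fragment.start}-{call.fragment.end}"


_ORF_COLUMNS = [
    "circ_id", "orf_id", "start", "stop", "length", "laps",
    "spans_junction", "inner_starts", "ires", "peptide",
]
_IRES_COLUMNS = ["circ_id", "frag_start", "frag_end", "score", "spans_junction"]
_M6A_COLUMNS = [
    "circ_id", "motif_start", "m6a_pos", "pentamer", "kind", "spans_junction",
]


def _orf_rows(report: AnalysisReport) -> list[list[str]]:
    rows = []
    for rec in report.records:
        for orf in rec.orfs:
            assigned = rec.ires_assignment.get(orf.orf_id)
            rows.append(
                [
                    rec.circ.id,
                    orf.orf_id,
                    str(orf.start_pos),
                    "" if orf.stop_pos is None else str(orf.stop_pos),
                    orf.length_label(),
                    str(orf.laps),
                    str(orf.spans_junction),
                    ",".join(str(p) for p in orf.inner_starts),
                    _ires_field(assigned),
                    orf.peptide,
                ]
            )
    return rows


def _ires_rows(report: AnalysisReport) -> list[list[str]]:
    rows = []
    for rec in report.records:
        for call in rec.ires_calls:
            rows.append(
                [
                    rec.circ.id,
                    str(call.fragment.start),
                    str(call.fragment.end),
                    _FLOAT_FMT.format(call.score),
                    str(call.spans_junction),
                ]
            )
    return rows


def _m6a_rows(report: AnalysisReport) -> tuple[list[str], list[list[str]]]:
    with_overlap = any(r.known_site_positions is not None for r in report.records)
    columns = _M6A_COLUMNS + (["known_site_overlap"] if with_overlap else [])
    rows = []
    for rec in report.records:
        for hit in rec.motifs:
            row = [
                rec.circ.id,
                str(hit.motif_start),
                str(hit.m6a_pos),
                hit.pentamer,
                hit.kind,
                str(hit.spans_junction),
            ]
            if with_overlap:
                known = rec.known_site_positions or frozenset()
                row.append(str(hit.m6a_pos in known))
            rows.append(row)
    return columns, rows


def _write_table(path: Path, columns: list[str], rows: list[list[str]],
                 delimiter: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(columns)
        writer.writerows(rows)


def write_report(report: AnalysisReport, out_dir, dialect: str = "tsv") -> list[Path]:
    """Write the report tables; returns the written paths.

    ``tsv``/``csv`` write orfs/ires/m6a tables plus a human-readable
    summary (1-based positions); ``fasta`` writes predicted peptides with
    headers ``circ_id|orf_id|len|infinite?`` (one repeat unit for
    infinite ORFs).
    """
    if dialect not in REPORT_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; valid dialects: "
            f"{', '.join(REPORT_DIALECTS)}"
        )
    report.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if dialect == "fasta":
        path = out_dir / "peptides.fasta"
        with open(path, "w") as fh:
            for rec in report.records:
                for orf in rec.orfs:
                    length = (
                        orf.repeat_nt_length if orf.is_infinite else orf.nt_length
                    )
                    fh.write(
                        f">{rec.circ.id}|{orf.orf_id}|{length}|"
                        f"{'infinite' if orf.is_infinite else 'finite'}\n"
                        f"{orf.peptide}\n"
                    )
        return [path]
    delim = "\t" if dialect == "tsv" else ","
    ext = dialect
    path = out_dir / f"orfs.{ext}"
    _write_table(path, _ORF_COLUMNS, _orf_rows(report), delim)
    written.append(path)
    path = out_dir / f"ires.{ext}"
    _write_table(path, _IRES_COLUMNS, _ires_rows(report), delim)
    written.append(path)
    m6a_cols, m6a_rows = _m6a_rows(report)
    path = out_dir / f"m6a.{ext}"
    _write_table(path, m6a_cols, m6a_rows, delim)
    written.append(path)
    path = out_dir / "summary.txt"
    with open(path, "w") as fh:
        for rec in report.records:
            fh.write(f"circRNA {rec.circ.id} (length {rec.circ.L} nt)\n")
            for orf in rec.orfs:
                assigned = rec.ires_assignment.get(orf.orf_id)
                fh.write(
                    f"  {orf.orf_id}: start {orf.start_pos + 1}, length "
                    f"{orf.length_label()}, IRES {_ires_field(assigned)}\n"
                )
            fh.write(
                f"  {len(rec.motifs)} DRACH/RRACH motifs, "
                f"{len(rec.ires_calls)} IRES-positive fragments\n"
            )
    written.append(path)
    return written


def write_conserved_pairs(pairs: Sequence[ConservedPair], path) -> None:
    """CSV: id_a, id_b, gene, length, identity_pct (4 decimals)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id_a", "id_b", "gene", "length", "identity_pct"])
        for p in pairs:
            writer.writerow(
                [p.id_a, p.id_b, p.gene, p.length, _FLOAT_FMT.format(p.identity_pct)]
            )
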