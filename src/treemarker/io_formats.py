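"""Readers and writers for every external format the toolkit touches.

This module is the single place where coordinate conventions are fixed:
internally everything is 0-based, half-open.  GFF3 and the marker table are
1-based inclusive on disk and are converted exactly once, at this boundary;
BED stays 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeqRecordRef:
    """One uppercase DNA sequence over {A,C,G,T,N} with a unique identifier."""

    seq_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeSet:
    """An ordered collection of scaffolds belonging to one species."""

    species_id: str
    records: list[SeqRecordRef]

    def __post_init__(self) -> None:
        ids = [r.seq_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate seq_id {dup!r} in genome {self.species_id!r}")

    def __iter__(self) -> Iterator[SeqRecordRef]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, seq_id: str) -> SeqRecordRef:
        for rec in self.records:
            if rec.seq_id == seq_id:
                return rec
        raise KeyError(seq_id)

    @property
    def total_size(self) -> int:
        return sum(r.length for r in self.records)


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to the exon chain of one representative transcript.

    Exons are 0-based half-open intervals, sorted by start and non-overlapping.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column BLAST tabular output."""

    query: str
    subject: str
    identity: float
    length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, species_id: str | None = None) -> GenomeSet:
    """Read a (multi-)FASTA file into a :class:`GenomeSet`.

    Sequences are uppercased; any character outside {A,C,G,T,N} is replaced
    by N with a logged warning.  Record order is preserved.
    """
    path = Path(path)
    records: list[SeqRecordRef] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = _NON_ACGTN.sub("N", seq)
        if cleaned != seq:
            n_bad = sum(1 for a, b in zip(seq, cleaned) if a != b)
            log.warning(
                "record %s: %d non-ACGTN characters replaced by N", rec.id, n_bad
            )
        records.append(SeqRecordRef(rec.id, cleaned))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA-formatted")
    return GenomeSet(species_id or path.stem, records)


def write_fasta(records: Iterable[SeqRecordRef], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, genome: GenomeSet | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive on disk).

    For multi-transcript genes, the transcript with the longest summed exon
    length is chosen as representative; ties break to the lexicographically
    smallest transcript id.  Genes without exon features are skipped with a
    warning.  Exons extending beyond their scaffold raise :class:`FormatError`
    when a genome is supplied.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    lengths = {r.seq_id: r.length for r in genome} if genome is not None else {}
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript"), level=1))
        best: tuple[int, str, list] | None = None
        if transcripts:
            for tr in transcripts:
                exons = list(db.children(tr, featuretype="exon"))
                if not exons:
                    continue
                total = sum(e.end - e.start + 1 for e in exons)
                key = (-total, tr.id)
                if best is None or key < (-best[0], best[1]):
                    best = (total, tr.id, exons)
        else:
            exons = list(db.children(gene, featuretype="exon", level=1))
            if exons:
                best = (sum(e.end - e.start + 1 for e in exons), gene.id, exons)
        if best is None:
            log.warning("gene %s has no exon features; skipped", gene.id)
            continue
        _, tr_id, exons = best
        intervals = sorted((e.start - 1, e.end) for e in exons)
        if genome is not None:
            limit = lengths.get(gene.seqid)
            if limit is None:
                raise FormatError(f"gene {gene.id}: unknown sequence {gene.seqid!r}")
            if intervals[-1][1] > limit or intervals[0][0] < 0:
                raise FormatError(
                    f"gene {gene.id}: exon outside sequence bounds of {gene.seqid!r}"
                )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=tuple(intervals),
                transcript_id=tr_id,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            tr = g.transcript_id or f"{g.gene_id}.t1"
            fh.write(
                f"{g.seq_id}\ttreemarker\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.seq_id}\ttreemarker\tmRNA\t{start + 1}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={tr};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.seq_id}\ttreemarker\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tr}.exon{i};Parent={tr}\n"
                )


# ---------------------------------------------------------------------------
# Marker table (TSV, 1-based inclusive)
# ---------------------------------------------------------------------------

MARKER_COLUMNS = [
    "marker_id",
    "type",
    "species",
    "seq_id",
    "locus_start_1based",
    "locus_end_1based",
    "motif",
    "repeat_count",
    "forward_primer",
    "reverse_primer",
    "expected_product_bp",
    "status",
]


def write_marker_table(markers: Iterable, path: str | Path) -> None:
    """Write markers as TSV with a fixed header and deterministic row order."""
    rows = []
    for m in markers:
        p = m.primers
        rows.append(
            {
                "marker_id": m.marker_id,
                "type": m.type,
                "species": m.species_id,
                "seq_id": m.seq_id,
                "locus_start_1based": m.start + 1,
                "locus_end_1based": m.end,
                "motif": m.motif,
                "repeat_count": m.repeat_count,
                "forward_primer": p.forward if p else "",
                "reverse_primer": p.reverse if p else "",
                "expected_product_bp": p.expected_product_bp if p else 0,
                "status": m.status,
            }
        )
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["species", "seq_id", "locus_start_1based", "type", "marker_id"]
        )
    df.to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> list:
    """Read a marker table back into :class:`~treemarker.insilico_pcr.Marker`s."""
    from .insilico_pcr import Marker
    from .primer_design import PrimerPair, gc_fraction, melting_temp

    df = pd.read_csv(path, sep="\t", dtype={"motif": str}, keep_default_na=False)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing marker-table columns {missing}")
    markers = []
    for row in df.itertuples(index=False):
        fwd, rev = str(row.forward_primer), str(row.reverse_primer)
        primers = None
        if fwd and rev:
            primers = PrimerPair(
                forward=fwd,
                reverse=rev,
                tm_forward=melting_temp(fwd),
                tm_reverse=melting_temp(rev),
                gc_forward=gc_fraction(fwd),
                gc_reverse=gc_fraction(rev),
                expected_product_bp=int(row.expected_product_bp),
            )
        markers.append(
            Marker(
                marker_id=str(row.marker_id),
                type=str(row.type),
                species_id=str(row.species),
                seq_id=str(row.seq_id),
                start=int(row.locus_start_1based) - 1,
                end=int(row.locus_end_1based),
                motif=str(row.motif),
                repeat_count=int(row.repeat_count),
                primers=primers,
                status=str(row.status),
            )
        )
    return markers


# ---------------------------------------------------------------------------
# BED6 (stays 0-based half-open)
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write (seq_id, start, end, name[, strand]) tuples as BED6, sorted."""
    rows = []
    for item in intervals:
        seq_id, start, end, name = item[0], item[1], item[2], item[3]
        strand = item[4] if len(item) > 4 else "+"
        rows.append((seq_id, int(start), int(end), str(name), 0, strand))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: BED row with fewer than 4 columns")
            strand = parts[5] if len(parts) > 5 else "+"
            out.append((parts[0], int(parts[1]), int(parts[2]), parts[3], strand))
    return out


# ---------------------------------------------------------------------------
# BLAST tabular (read only; produced externally)
# ---------------------------------------------------------------------------

def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output.

    Self-identical rows (query == subject with identical coordinates) are
    dropped; a row with the wrong column count raises :class:`FormatError`
    naming the line.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            hit = BlastHit(
                query=parts[0],
                subject=parts[1],
                identity=float(parts[2]),
                length=int(parts[3]),
                mismatches=int(parts[4]),
                gap_opens=int(parts[5]),
                qstart=int(parts[6]),
                qend=int(parts[7]),
                sstart=int(parts[8]),
                send=int(parts[9]),
                evalue=float(parts[10]),
                bitscore=float(parts[11]),
            )
            if (
                hit.query == hit.subject
                and (hit.qstart, hit.qend) == (hit.sstart, hit.send)
            ):
                continue
            hits.append(hit)
    return hits
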