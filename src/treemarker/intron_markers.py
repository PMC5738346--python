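"""Intron-based marker development.

ILP (intron length polymorphism) markers put both primers in the exons
flanking an intron, so the product length tracks the intron length.  PIP
(potential intron polymorphism) markers serve species with ESTs but no genome:
the EST is aligned to a model species' CDS, the model gene's intron positions
are projected through the alignment onto the EST, and primers are cut around
each projected junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from Bio import Align

from .io_formats import GeneModel, GenomeSet, SeqRecordRef
from .ssr_mining import FlankError, revcomp

log = logging.getLogger(__name__)


class GeneStructureError(ValueError):
    """Raised for structurally invalid gene models (e.g. overlapping exons)."""


@dataclass(frozen=True)
class IntronRecord:
    """One intron: the genomic gap between two consecutive exons of a gene."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    ordinal: int          # 1-based, 5'->3' in transcription order
    strand: str = "+"

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CDSAlignment:
    """Best local alignment of an EST against a model CDS."""

    est_id: str
    cds_id: str
    est_strand: str                      # strand of the EST that aligned
    est_interval: tuple[int, int]        # on the aligned-strand EST
    cds_interval: tuple[int, int]
    identity: float
    aligned_columns: int
    score: float
    cds_to_est: tuple[tuple[int, int], ...]  # aligned (cds_pos, est_pos) pairs


@dataclass(frozen=True)
class ESTProjection:
    """Model-gene intron positions carried through an EST/CDS alignment."""

    est_id: str
    model_gene_id: str
    cds_match_interval: tuple[int, int]
    projected_intron_cds_positions: tuple[int, ...]
    est_positions: tuple[int, ...]
    est_strand: str = "+"


# ---------------------------------------------------------------------------
# ILP: introns from annotation
# ---------------------------------------------------------------------------

def extract_introns(gene: GeneModel) -> list[IntronRecord]:
    """The gaps between consecutive exons, ordinals in transcription order.

    Single-exon genes yield an empty list; no length filter is applied.
    Overlapping or abutting exons raise :class:`GeneStructureError`.
    """
    exons = gene.exons
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise GeneStructureError(f"gene {gene.gene_id}: overlapping exons")
        if s2 == e1:
            raise GeneStructureError(f"gene {gene.gene_id}: zero-length intron")
    gaps = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]
    n = len(gaps)
    introns = []
    for i, (start, end) in enumerate(gaps):
        ordinal = i + 1 if gene.strand == "+" else n - i
        introns.append(
            IntronRecord(gene.gene_id, gene.seq_id, start, end, ordinal, gene.strand)
        )
    return introns


def ilp_precursors(
    intron: IntronRecord,
    gene: GeneModel,
    record: SeqRecordRef,
    flank_len: int = 60,
) -> tuple[str, str]:
    """Cut flank_len-bp precursors from the exons bordering an intron.

    Both flanks must lie entirely within the adjacent exons (a primer
    straddling another intron would break the length relationship) and be
    N-free.  Raises :class:`FlankError` otherwise.
    """
    left_exon = next((e for e in gene.exons if e[1] == intron.start), None)
    right_exon = next((e for e in gene.exons if e[0] == intron.end), None)
    if left_exon is None or right_exon is None:
        raise GeneStructureError(
            f"intron {intron.gene_id}:{intron.start} does not border exons of its gene"
        )
    if intron.start - flank_len < left_exon[0]:
        raise FlankError("flank not fully exonic")
    if intron.end + flank_len > right_exon[1]:
        raise FlankError("flank not fully exonic")
    left = record.sequence[intron.start - flank_len : intron.start]
    right = record.sequence[intron.end : intron.end + flank_len]
    if "N" in left or "N" in right:
        raise FlankError("ambiguous flank")
    return left, right


def design_ilp_markers(
    genome: GenomeSet,
    genes: Iterable[GeneModel],
    constraints=None,
    flank_len: int = 60,
):
    """One candidate ILP marker per usable intron (rejections only remove)."""
    from .insilico_pcr import Marker
    from .primer_design import DesignError, design_pair

    markers = []
    skipped = 0
    for gene in genes:
        rec = genome.get(gene.seq_id)
        for intron in extract_introns(gene):
            try:
                left, right = ilp_precursors(intron, gene, rec, flank_len)
                pair = design_pair(left, right, constraints, insert_len=intron.length)
            except (FlankError, DesignError):
                skipped += 1
                continue
            markers.append(
                Marker(
                    marker_id=f"{genome.species_id}_ILP_{gene.gene_id}_{intron.ordinal}",
                    type="ILP",
                    species_id=genome.species_id,
                    seq_id=gene.seq_id,
                    start=intron.start,
                    end=intron.end,
                    primers=pair,
                    model_gene_id=gene.gene_id,
                    amplicon_start=intron.start - (flank_len - pair.forward_start),
                    amplicon_end=intron.end + pair.reverse_end,
                )
            )
    if skipped:
        log.info("design_ilp_markers: %d introns skipped (flank/design rejection)", skipped)
    return markers


# ---------------------------------------------------------------------------
# PIP: projection through EST/CDS alignment
# ---------------------------------------------------------------------------

def map_model_introns(model_gene: GeneModel) -> list[int]:
    """Intron positions in spliced-CDS coordinates, 5'->3'.

    Position p means the intron interrupts the CDS between base p-1 and base
    p (1 <= p <= CDS length - 1): the cumulative exon lengths walked in
    transcription order.  Single-exon genes yield an empty list.
    """
    lengths = [e - s for s, e in model_gene.exons]
    if model_gene.strand == "-":
        lengths = lengths[::-1]
    positions = []
    acc = 0
    for ln in lengths[:-1]:
        acc += ln
        positions.append(acc)
    return positions


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def align_est_to_cds(
    est: SeqRecordRef,
    cds: SeqRecordRef,
    min_identity: float = 0.85,
    min_length: int = 100,
) -> CDSAlignment | None:
    """Single best local alignment of an EST against a model CDS.

    Smith-Waterman with affine gaps (match +1, mismatch -2, gap open -5,
    extend -1); both EST strands are tried and the higher-scoring kept.
    Returns None unless identity >= *min_identity* over >= *min_length*
    aligned columns.
    """
    if not est.sequence or not cds.sequence:
        return None
    aligner = _make_aligner()
    best = None
    for strand, est_seq in (("+", est.sequence), ("-", revcomp(est.sequence))):
        alignments = aligner.align(cds.sequence, est_seq)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        if best is None or aln.score > best[1].score:
            best = (strand, aln, est_seq)
    if best is None:
        return None
    strand, aln, est_seq = best
    cds_blocks, est_blocks = aln.aligned
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (cs, ce), (es, ee) in zip(cds_blocks, est_blocks):
        for k in range(ce - cs):
            cpos, epos = cs + k, es + k
            pairs.append((int(cpos), int(epos)))
            if cds.sequence[cpos] == est_seq[epos]:
                matches += 1
    # aligned columns include gap columns
    span_c = int(cds_blocks[-1][1] - cds_blocks[0][0])
    span_e = int(est_blocks[-1][1] - est_blocks[0][0])
    columns = len(pairs) + (span_c - len(pairs)) + (span_e - len(pairs))
    identity = matches / columns if columns else 0.0
    if columns < min_length or identity < min_identity:
        return None
    return CDSAlignment(
        est_id=est.seq_id,
        cds_id=cds.seq_id,
        est_strand=strand,
        est_interval=(int(est_blocks[0][0]), int(est_blocks[-1][1])),
        cds_interval=(int(cds_blocks[0][0]), int(cds_blocks[-1][1])),
        identity=identity,
        aligned_columns=columns,
        score=float(aln.score),
        cds_to_est=tuple(pairs),
    )


def project_introns(
    alignment: CDSAlignment, model_gene: GeneModel
) -> ESTProjection:
    """Carry the model gene's spliced-CDS intron positions onto the EST.

    A junction at CDS position p maps to the EST coordinate aligned with CDS
    base p (the first base 3' of the junction); junctions falling in an
    alignment gap snap to the nearest aligned CDS base to the right.
    Junctions outside the matched CDS interval are dropped.
    """
    cds_lo, cds_hi = alignment.cds_interval
    cmap = dict(alignment.cds_to_est)
    aligned_cds = sorted(cmap)
    cds_positions, est_positions = [], []
    for p in map_model_introns(model_gene):
        if not cds_lo < p < cds_hi:
            continue
        q = next((c for c in aligned_cds if c >= p), None)
        if q is None:
            continue
        cds_positions.append(p)
        est_positions.append(cmap[q])
    return ESTProjection(
        est_id=alignment.est_id,
        model_gene_id=model_gene.gene_id,
        cds_match_interval=alignment.cds_interval,
        projected_intron_cds_positions=tuple(cds_positions),
        est_positions=tuple(est_positions),
        est_strand=alignment.est_strand,
    )


def pip_markers(
    projection: ESTProjection,
    est: SeqRecordRef,
    constraints=None,
    flank_len: int = 60,
    species_id: str = "",
):
    """Design one candidate PIP marker per usable projected intron position.

    For each projected EST position with *flank_len* N-free bases on both
    sides, the two precursors are cut from the EST (on the strand that
    aligned) and handed to primer design.  Positions failing the flank rule
    or primer design are skipped.
    """
    from .insilico_pcr import Marker
    from .primer_design import DesignError, design_pair

    est_seq = est.sequence if projection.est_strand == "+" else revcomp(est.sequence)
    markers = []
    for pos in projection.est_positions:
        if pos - flank_len < 0 or pos + flank_len > len(est_seq):
            continue
        left = est_seq[pos - flank_len : pos]
        right = est_seq[pos : pos + flank_len]
        if "N" in left or "N" in right:
            continue
        try:
            pair = design_pair(left, right, constraints, insert_len=0)
        except DesignError:
            continue
        markers.append(
            Marker(
                marker_id=f"{species_id or est.seq_id}_PIP_{est.seq_id}_{pos}",
                type="PIP",
                species_id=species_id or est.seq_id,
                seq_id=est.seq_id,
                start=pos,
                end=pos,
                primers=pair,
                model_gene_id=projection.model_gene_id,
                amplicon_start=pos - (flank_len - pair.forward_start),
                amplicon_end=pos + pair.reverse_end,
            )
        )
    return markers
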