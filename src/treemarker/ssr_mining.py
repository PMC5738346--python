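"""Perfect microsatellite (SSR) mining under seven motif classes.

A locus is a maximal perfect tandem run of a primitive 1–7 bp motif whose
repeat count reaches its class threshold (monomers >=12 copies, dimers >=6,
trimers >=4, tetra-/pentamers >=3, hexa-/heptamers >=2).  Motifs are
normalised to a canonical form: the lexicographic minimum over all rotations
of the motif and of its reverse complement, so AC, CA, TG and GT all report
as AC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io_formats import GenomeSet, SeqRecordRef

log = logging.getLogger(__name__)

#: Minimum repeat count per motif class (class = motif length in bp).
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 2, 7: 2}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifError(ValueError):
    """Raised for motifs outside the canonicalisation domain."""


class FlankError(ValueError):
    """Raised when a primer-precursor flank cannot be cut."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True iff *motif* is not a whole-number repetition of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonicalize(raw_motif: str) -> str:
    """Canonical representative of a motif's rotation/reverse-complement class.

    Returns the lexicographically smallest string among all rotations of the
    motif and all rotations of its reverse complement.
    """
    if not 1 <= len(raw_motif) <= 7:
        raise MotifError(f"motif length must be 1-7, got {len(raw_motif)}")
    if any(c not in "ACGT" for c in raw_motif):
        raise MotifError(f"motif {raw_motif!r} contains characters outside ACGT")
    if not is_primitive(raw_motif):
        raise MotifError(f"motif {raw_motif!r} is not primitive")
    candidates = set()
    for s in (raw_motif, revcomp(raw_motif)):
        for i in range(len(s)):
            candidates.add(s[i:] + s[:i])
    return min(candidates)


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat: canonical motif, phase found, and interval."""

    seq_id: str
    start: int
    end: int
    motif: str            # canonical form
    motif_as_found: str   # phase actually present at interval start
    repeat_count: int
    species_id: str = ""

    @property
    def class_k(self) -> int:
        return len(self.motif)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan_ssr(
    record: SeqRecordRef,
    min_repeats: Mapping[int, int] | None = None,
    allow_nonprimitive: bool = False,
    species_id: str = "",
) -> list[SSRLocus]:
    """Report every maximal perfect tandem run at or above its class threshold.

    Each class k in 1..7 is scanned independently via the self-comparison
    s[i] == s[i+k]; a maximal run of matches of length L spans L+k bases and
    holds floor((L+k)/k) whole motif copies, anchored at the run start.  N
    matches nothing, so runs never cross an N.  Non-primitive motif units are
    suppressed unless *allow_nonprimitive* (their run is reported in the class
    of the primitive unit instead).  Output is sorted by (start, class).
    """
    thresholds = dict(DEFAULT_MIN_REPEATS)
    if min_repeats:
        thresholds.update(min_repeats)
    seq = record.sequence
    n = len(seq)
    loci: list[SSRLocus] = []
    if n == 0:
        return loci
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ok = (arr == 65) | (arr == 67) | (arr == 71) | (arr == 84)  # A C G T
    for k in range(1, 8):
        thr = thresholds[k]
        if n < k * thr:
            continue
        eq = (arr[:-k] == arr[k:]) & ok[:-k] & ok[k:]
        if not eq.any():
            continue
        flat = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for a, b in zip(flat[0::2], flat[1::2]):
            span = int(b - a) + k
            count = span // k
            if count < thr:
                continue
            unit = seq[a : a + k]
            if not allow_nonprimitive and not is_primitive(unit):
                continue
            loci.append(
                SSRLocus(
                    seq_id=record.seq_id,
                    start=int(a),
                    end=int(a) + count * k,
                    motif=canonicalize(unit) if is_primitive(unit) else min(unit, revcomp(unit)),
                    motif_as_found=unit,
                    repeat_count=count,
                    species_id=species_id,
                )
            )
    loci.sort(key=lambda l: (l.start, l.class_k))
    return loci


def scan_genome(
    genome: GenomeSet,
    min_repeats: Mapping[int, int] | None = None,
    allow_nonprimitive: bool = False,
) -> list[SSRLocus]:
    """Scan every scaffold of a genome; loci carry the species id."""
    loci: list[SSRLocus] = []
    for rec in genome:
        loci.extend(
            scan_ssr(rec, min_repeats, allow_nonprimitive, species_id=genome.species_id)
        )
    return loci


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

def classify_counts(loci: Iterable[SSRLocus]) -> dict[int, tuple[int, float]]:
    """Per-class locus counts and percentages (class -> (count, percent)).

    Percentages are NaN when the input is empty.
    """
    counts = {k: 0 for k in range(1, 8)}
    for locus in loci:
        counts[locus.class_k] += 1
    total = sum(counts.values())
    return {
        k: (c, 100.0 * c / total if total else float("nan"))
        for k, c in counts.items()
    }


def base_composition(loci: Iterable[SSRLocus]) -> tuple[int, int, float]:
    """A/T and G/C base counts over all locus spans, and the AT/GC ratio.

    The ratio is +inf when no G/C base occurs (flagging the undefined case).
    """
    at = gc = 0
    for locus in loci:
        for ch in locus.motif_as_found:
            if ch in "AT":
                at += locus.repeat_count
            elif ch in "GC":
                gc += locus.repeat_count
    ratio = at / gc if gc else float("inf")
    return at, gc, ratio


# ---------------------------------------------------------------------------
# Primer precursors
# ---------------------------------------------------------------------------

def extract_primer_precursors(
    locus: SSRLocus, record: SeqRecordRef, flank_len: int = 60
) -> tuple[str, str]:
    """Cut the *flank_len*-bp precursors immediately left and right of a locus.

    Raises :class:`FlankError` when a flank is truncated by a sequence end or
    contains N (primer matching treats N as matching nothing, so ambiguous
    flanks cannot yield usable primers).
    """
    if locus.start - flank_len < 0:
        raise FlankError("left flank truncated")
    if locus.end + flank_len > record.length:
        raise FlankError("right flank truncated")
    left = record.sequence[locus.start - flank_len : locus.start]
    right = record.sequence[locus.end : locus.end + flank_len]
    if "N" in left or "N" in right:
        raise FlankError("ambiguous flank")
    return left, right


def design_ssr_markers(
    genome: GenomeSet,
    loci: Iterable[SSRLocus],
    constraints=None,
    flank_len: int = 60,
):
    """Design one candidate marker per SSR locus (flank cut + primer pick).

    Loci whose flanks are rejected or where no primer window satisfies the
    constraints are skipped; the skip count is logged.
    """
    from .insilico_pcr import Marker
    from .primer_design import DesignError, design_pair

    markers: list = []
    skipped = 0
    for locus in loci:
        rec = genome.get(locus.seq_id)
        try:
            left, right = extract_primer_precursors(locus, rec, flank_len)
            pair = design_pair(left, right, constraints, insert_len=locus.length)
        except (FlankError, DesignError):
            skipped += 1
            continue
        markers.append(
            Marker(
                marker_id=f"{genome.species_id}_SSR_{locus.seq_id}_{locus.start + 1}",
                type="SSR",
                species_id=genome.species_id,
                seq_id=locus.seq_id,
                start=locus.start,
                end=locus.end,
                motif=locus.motif,
                repeat_count=locus.repeat_count,
                primers=pair,
                amplicon_start=locus.start - (flank_len - pair.forward_start),
                amplicon_end=locus.end + pair.reverse_end,
            )
        )
    if skipped:
        log.info("design_ssr_markers: %d loci skipped (flank/design rejection)", skipped)
    return markers
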