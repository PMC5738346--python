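"""Electronic PCR engine and the marker screens built on it.

A hit is reported wherever the forward primer matches one strand (at most
``max_mismatches`` mismatches, the 3'-terminal ``three_prime_exact`` bases
exact, N matching nothing) and the reverse primer matches the opposite strand
downstream with a product length inside [min_product, max_product].  Both
amplicon orientations are scanned.  On top of the engine sit marker
self-validation, forward/reverse-primer deduplication, monomorphic vs
polymorphic classification by genome-wide site count, and the cross-species
universal-marker screen.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeSet
from .primer_design import PrimerPair
from .ssr_mining import revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EPCRParams:
    """Matching and product-size parameters for electronic PCR."""

    max_mismatches: int = 0
    three_prime_exact: int = 3
    max_product: int = 5000
    min_product: int = 40
    max_hits_per_seq: int = 1000

    def __post_init__(self) -> None:
        if self.three_prime_exact < 0:
            raise ValueError("three_prime_exact must be >= 0")


@dataclass(frozen=True)
class AmpliconHit:
    """One in-silico PCR product; strand is that of the forward primer."""

    species_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    @property
    def product_bp(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass(frozen=True)
class Marker:
    """A typed primer pair tied to its source locus or intron."""

    marker_id: str
    type: str                    # SSR | ILP | PIP
    species_id: str
    seq_id: str
    start: int
    end: int
    motif: str = ""
    repeat_count: int = 0
    primers: PrimerPair | None = None
    status: str = "candidate"    # candidate | validated | rejected
    reject_reason: str = ""
    model_gene_id: str = ""
    amplicon_start: int = -1
    amplicon_end: int = -1

    @property
    def amplicon_interval(self) -> tuple[int, int]:
        """Expected amplicon span (forward 5' to reverse 5') on the source sequence."""
        if self.amplicon_start >= 0:
            return self.amplicon_start, self.amplicon_end
        return self.start, self.end


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

def _site_scan(
    arr: np.ndarray,
    primer: str,
    max_mm: int,
    exact_len: int,
    exact_at_end: bool,
    seq_bytes: bytes | None = None,
) -> np.ndarray:
    """Start positions where *primer* matches the plus-strand text of *arr*.

    ``exact_at_end`` selects which end of the window carries the exact zone:
    the window end for a primer lying 5'->3' on the plus strand, the window
    start for a primer whose 3' terminus faces leftward (a reverse-complement
    footprint).  N never matches (it differs from every primer byte).
    """
    n, m = len(arr), len(primer)
    if n < m:
        return np.empty(0, dtype=np.intp)
    if max_mm == 0:
        # strict matching reduces to exact substring search
        text = seq_bytes if seq_bytes is not None else arr.tobytes()
        needle = primer.encode("ascii")
        out = []
        i = text.find(needle)
        while i != -1:
            out.append(i)
            i = text.find(needle, i + 1)
        return np.asarray(out, dtype=np.intp)
    p = np.frombuffer(primer.encode("ascii"), dtype=np.uint8)
    width = n - m + 1
    mism = np.zeros(width, dtype=np.int32)
    for j in range(m):
        mism += arr[j : j + width] != p[j]
    ok = mism <= max_mm
    exact_len = min(exact_len, m)
    zone = range(m - exact_len, m) if exact_at_end else range(exact_len)
    for j in zone:
        ok &= arr[j : j + width] == p[j]
    return np.flatnonzero(ok)


def _pair_sites(
    left: np.ndarray, right: np.ndarray, right_len: int, params: EPCRParams
) -> list[tuple[int, int]]:
    """Pair upstream windows with downstream windows under product limits."""
    out: list[tuple[int, int]] = []
    ends = right + right_len
    for f in left:
        lo = np.searchsorted(ends, f + params.min_product, side="left")
        hi = np.searchsorted(ends, f + params.max_product, side="right")
        for r in right[lo:hi]:
            if r >= f:
                out.append((int(f), int(r + right_len)))
    return out


def epcr(
    marker: Marker | PrimerPair,
    genome: GenomeSet,
    params: EPCRParams | None = None,
) -> list[AmpliconHit]:
    """All amplicons a primer pair would produce anywhere in a genome.

    Hits are sorted by (seq_id, start, end); overlapping hits from the same
    pair are all reported.  Per scaffold, hits are capped at
    ``max_hits_per_seq`` with a warning (low-complexity primer guard).
    """
    params = params or EPCRParams()
    primers = marker.primers if isinstance(marker, Marker) else marker
    if primers is None:
        raise ValueError("marker has no designed primers")
    fwd, rev = primers.forward, primers.reverse
    hits: list[AmpliconHit] = []
    for rec in genome:
        seq_bytes = rec.sequence.encode("ascii")
        arr = np.frombuffer(seq_bytes, dtype=np.uint8)
        mm, t = params.max_mismatches, params.three_prime_exact
        # forward primer on plus strand, reverse primer footprint downstream
        f_plus = _site_scan(arr, fwd, mm, t, True, seq_bytes)
        r_minus = _site_scan(arr, revcomp(rev), mm, t, False, seq_bytes)
        spans = _pair_sites(f_plus, r_minus, len(rev), params)
        seq_hits = [
            AmpliconHit(genome.species_id, rec.seq_id, s, e, "+") for s, e in spans
        ]
        # flipped orientation: reverse primer on plus strand, forward on minus
        r_plus = _site_scan(arr, rev, mm, t, True, seq_bytes)
        f_minus = _site_scan(arr, revcomp(fwd), mm, t, False, seq_bytes)
        spans = _pair_sites(r_plus, f_minus, len(fwd), params)
        seq_hits += [
            AmpliconHit(genome.species_id, rec.seq_id, s, e, "-") for s, e in spans
        ]
        if len(seq_hits) > params.max_hits_per_seq:
            log.warning(
                "primer pair yields %d hits on %s; capped at %d",
                len(seq_hits), rec.seq_id, params.max_hits_per_seq,
            )
            seq_hits.sort(key=lambda h: (h.start, h.end, h.strand))
            seq_hits = seq_hits[: params.max_hits_per_seq]
        hits.extend(seq_hits)
    hits.sort(key=lambda h: (h.seq_id, h.start, h.end, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

def validate_marker(
    marker: Marker, own_genome: GenomeSet, params: EPCRParams | None = None
) -> Marker:
    """Self-validation: the pair must amplify its own source locus.

    A marker is validated iff at least one hit overlaps the source interval
    with a product within +/-20% of the expected product; otherwise it is
    rejected with a reason (any off-target hits remain observable via
    :func:`epcr`).
    """
    if marker.primers is None:
        return replace(marker, status="rejected", reject_reason="no primers designed")
    hits = epcr(marker, own_genome, params)
    expected = marker.primers.expected_product_bp
    for hit in hits:
        if hit.seq_id != marker.seq_id:
            continue
        if hit.start < marker.end and hit.end > marker.start:
            if abs(hit.product_bp - expected) <= 0.2 * expected:
                return replace(marker, status="validated", reject_reason="")
    reason = "no on-target product" if hits else "no amplification"
    return replace(marker, status="rejected", reject_reason=reason)


def deduplicate(markers: Sequence[Marker]) -> list[Marker]:
    """Collapse markers sharing a forward OR a reverse primer sequence.

    The relation is closed transitively (union-find); each group keeps the
    representative with the smallest (seq_id, start, marker_id).  Output is
    sorted by (species, seq_id, start, marker_id).
    """
    parent = list(range(len(markers)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    by_fwd: dict[str, int] = {}
    by_rev: dict[str, int] = {}
    for i, m in enumerate(markers):
        if m.primers is None:
            continue
        f, r = m.primers.forward, m.primers.reverse
        if f in by_fwd:
            union(i, by_fwd[f])
        else:
            by_fwd[f] = i
        if r in by_rev:
            union(i, by_rev[r])
        else:
            by_rev[r] = i

    groups: dict[int, list[Marker]] = {}
    for i, m in enumerate(markers):
        groups.setdefault(find(i), []).append(m)
    kept = [
        min(group, key=lambda m: (m.seq_id, m.start, m.marker_id))
        for group in groups.values()
    ]
    removed = len(markers) - len(kept)
    if removed:
        log.info("deduplicate: removed %d duplicate markers", removed)
    kept.sort(key=lambda m: (m.species_id, m.seq_id, m.start, m.marker_id))
    return kept


def classify_polymorphism(
    marker: Marker, own_genome: GenomeSet, params: EPCRParams | None = None
) -> tuple[int, str]:
    """Genome-wide amplification-site count and the monomorphic/polymorphic label.

    One site = one amplicon hit anywhere in the genome; a marker amplifying a
    single site is monomorphic, two or more sites polymorphic.  A validated
    marker with zero hits indicates an internal inconsistency.
    """
    hits = epcr(marker, own_genome, params)
    n = len(hits)
    if n == 0 and marker.status == "validated":
        raise RuntimeError(
            f"validated marker {marker.marker_id} produced no hits"
        )
    return n, ("monomorphic" if n <= 1 else "polymorphic")


def polymorphism_histogram(
    markers: Sequence[Marker],
    own_genome: GenomeSet,
    params: EPCRParams | None = None,
    sample_size: int | None = None,
    seed: int = 0,
) -> Counter:
    """Histogram of markers per number of amplification sites.

    When *sample_size* is given, that many markers are drawn without
    replacement using the explicit *seed*.
    """
    chosen: Sequence[Marker] = markers
    if sample_size is not None and sample_size < len(markers):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(markers), size=sample_size, replace=False)
        chosen = [markers[i] for i in sorted(idx)]
    hist: Counter = Counter()
    for m in chosen:
        n, _ = classify_polymorphism(m, own_genome, params)
        hist[n] += 1
    return hist


def universal_screen(
    markers: Sequence[Marker],
    genomes: Sequence[GenomeSet],
    params: EPCRParams | None = None,
) -> tuple[list[Marker], pd.DataFrame]:
    """Markers amplifying at least one product in EVERY genome of the panel.

    Also returns the marker x species site-count matrix.
    """
    if len(genomes) < 1:
        raise ValueError("at least one genome required")
    counts = pd.DataFrame(
        0,
        index=[m.marker_id for m in markers],
        columns=[g.species_id for g in genomes],
        dtype=int,
    )
    for m in markers:
        for g in genomes:
            counts.loc[m.marker_id, g.species_id] = len(epcr(m, g, params))
    kept = [m for m in markers if (counts.loc[m.marker_id] > 0).all()]
    return kept, counts
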