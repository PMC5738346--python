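"""Deterministic synthetic genomes with planted, bookkept ground truth.

The generator emulates the inputs of a genome-wide marker survey at desk
scale: scaffolds of background sequence with NO reportable repeats (rejection
sampling), planted SSR loci of known class/motif/count, gene models with
known introns, spliced-transcript ESTs with per-base substitutions, and
duplicated segments carrying marker cassettes.  Every byte derives from one
seed, and the emitted truth tables are verified against a fresh scan before
the fixture is returned, so specificity tests are exact.

Point mutations in duplicated segments are applied only outside each planted
locus +/- one flank length (the marker cassette), emulating conserved marker
sites so per-marker copy numbers stay exact under strict e-PCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, GenomeSet, SeqRecordRef, write_fasta, write_gff3
from .ssr_mining import (
    DEFAULT_MIN_REPEATS,
    SSRLocus,
    canonicalize,
    revcomp,
    scan_ssr,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_FLANK = 60

DEFAULT_MOTIF_POOL: dict[int, tuple[str, ...]] = {
    1: ("A", "C"),
    2: ("AT", "AG", "AC"),
    3: ("AAT", "AAG", "ACT"),
    4: ("AAAT", "AAAG", "ACAT"),
    5: ("AAAAT", "AAAAG", "AACAT"),
    6: ("AAAAAT", "AAACAT", "AACAGT"),
    7: ("AAAAAAT", "AAACAGT", "AACACGT"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the generator; every value participates in the truth."""

    seed: int = 42
    scaffold_lengths: tuple[int, ...] = (1_000_000, 1_000_000)
    ssr_per_class: Mapping[int, int] = field(
        default_factory=lambda: {1: 20, 2: 40, 3: 40, 4: 30, 5: 20, 6: 30, 7: 20}
    )
    motif_pool: Mapping[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_POOL)
    )
    extra_repeats_max: int = 3
    n_genes: int = 50
    exon_counts: tuple[int, ...] | None = None   # default: 4 exons per gene
    exon_len_range: tuple[int, int] = (150, 300)
    intron_len_range: tuple[int, int] = (80, 400)
    n_duplications: int = 3
    dup_ssrs_per_segment: int = 6
    dup_spacing: int = 260
    mutation_rate: float = 0.02
    est_substitution_rate: float = 0.0
    base_freqs: tuple[float, float, float, float] = (0.30, 0.20, 0.20, 0.30)
    species_id: str = "fixture"

    def total_planted(self) -> int:
        return sum(self.ssr_per_class.values())


@dataclass(frozen=True)
class ESTTruth:
    est_id: str
    gene_id: str
    junctions: tuple[int, ...]   # EST coordinates of intron positions, 5'->3'


@dataclass(frozen=True)
class DuplicationTruth:
    a_seq: str
    a_interval: tuple[int, int]
    b_seq: str
    b_interval: tuple[int, int]
    n_loci: int


@dataclass
class FixtureTruth:
    loci: list[SSRLocus]                      # originals + duplicated copies
    original_loci: list[SSRLocus]
    genes: list[GeneModel]
    duplications: list[DuplicationTruth]
    copy_numbers: dict[tuple, int]            # locus key -> genome-wide copies
    ests: list[ESTTruth]


@dataclass
class Fixture:
    genome: GenomeSet
    genes: list[GeneModel]
    ests: list[SeqRecordRef]     # possibly mutated spliced transcripts
    cds: list[SeqRecordRef]      # clean spliced transcripts (model CDS role)
    truth: FixtureTruth


def locus_key(locus: SSRLocus) -> tuple:
    return (locus.seq_id, locus.start, locus.end, locus.motif)


# ---------------------------------------------------------------------------
# Builder
# ---------------------------------------------------------------------------

class GenomeBuilder:
    """Mutable scaffolds plus placement, planting and suppression machinery."""

    def __init__(
        self,
        scaffold_lengths: Sequence[int],
        rng: np.random.Generator,
        base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        species_id: str = "fixture",
    ) -> None:
        self.rng = rng
        self.species_id = species_id
        self.seq_ids = [f"scaffold_{i + 1}" for i in range(len(scaffold_lengths))]
        p = np.asarray(base_freqs, dtype=float)
        p = p / p.sum()
        self.seqs = [rng.choice(_BASES, size=L, p=p) for L in scaffold_lengths]
        self.occupied = [np.zeros(L, dtype=bool) for L in scaffold_lengths]
        self.frozen = [np.zeros(L, dtype=bool) for L in scaffold_lengths]
        self.truth_loci: list[SSRLocus] = []
        for occ in self.occupied:   # keep clear of scaffold ends
            occ[:200] = True
            occ[-200:] = True
        self._freqs = p

    # -- placement ----------------------------------------------------------

    def place(
        self,
        length: int,
        margin: int = 80,
        avoid: Sequence[tuple[int, int, int]] = (),
        avoid_dist: int = 0,
    ) -> tuple[int, int]:
        """Find and claim a free spot; optionally keep a minimum distance
        from (scaffold, start, end) regions in *avoid* (same scaffold only)."""
        for _ in range(20_000):
            sc = int(self.rng.integers(len(self.seqs)))
            limit = len(self.seqs[sc]) - length - margin
            if limit <= margin:
                continue
            pos = int(self.rng.integers(margin, limit))
            if self.occupied[sc][pos - margin : pos + length + margin].any():
                continue
            if any(
                asc == sc
                and pos < aend + avoid_dist
                and astart < pos + length + avoid_dist
                for asc, astart, aend in avoid
            ):
                continue
            self.occupied[sc][pos - margin : pos + length + margin] = True
            return sc, pos
        raise RuntimeError("no free space left for placement (infeasible spec)")

    # -- SSR planting -------------------------------------------------------

    def plant_ssr(
        self, motif: str, count: int, at: tuple[int, int] | None = None
    ) -> SSRLocus:
        """Write a perfect tandem run and pin its maximality breaker bases."""
        k = len(motif)
        pattern = np.frombuffer((motif * count).encode("ascii"), dtype=np.uint8)
        if at is None:
            sc, pos = self.place(len(pattern), margin=_FLANK + 20)
        else:
            sc, pos = at
        seq = self.seqs[sc]
        seq[pos : pos + len(pattern)] = pattern
        locus = SSRLocus(
            seq_id=self.seq_ids[sc],
            start=pos,
            end=pos + count * k,
            motif=canonicalize(motif),
            motif_as_found=motif,
            repeat_count=count,
            species_id=self.species_id,
        )
        self.truth_loci.append(locus)
        self.frozen[sc][pos : pos + len(pattern)] = True
        self._fix_breakers(sc, locus)
        return locus

    def _fix_breakers(self, sc: int, locus: SSRLocus) -> None:
        """The bases adjacent to a planted run must not extend its period."""
        seq = self.seqs[sc]
        unit = locus.motif_as_found
        k = len(unit)
        left, right = locus.start - 1, locus.end
        if left >= 0 and seq[left] == ord(unit[-1]):
            seq[left] = self._other_base(ord(unit[-1]))
        if right < len(seq) and seq[right] == ord(unit[0]):
            seq[right] = self._other_base(ord(unit[0]))

    def _other_base(self, forbidden: int) -> int:
        choices = [b for b in _BASES if b != forbidden]
        return int(choices[int(self.rng.integers(len(choices)))])

    # -- segment copying ----------------------------------------------------

    def copy_segment(
        self,
        sc_src: int,
        interval: tuple[int, int],
        mutation_rate: float = 0.0,
        protect: Sequence[tuple[int, int]] = (),
        min_src_dist: int = 25_000,
    ) -> tuple[int, int]:
        """Copy a segment elsewhere, mutating only outside protected zones.

        *protect* holds segment-relative intervals (typically planted loci
        +/- one flank) to keep byte-identical.  Truth loci inside the segment
        are re-recorded at their copied coordinates.  The copy lands at least
        *min_src_dist* from the source, so the pair is segmental (never
        tandem) and primer pairs cannot bridge the two copies.
        """
        a, b = interval
        seg = self.seqs[sc_src][a:b].copy()
        if mutation_rate > 0:
            protected = np.zeros(len(seg), dtype=bool)
            for s, e in protect:
                protected[max(0, s) : min(len(seg), e)] = True
            mutate = (self.rng.random(len(seg)) < mutation_rate) & ~protected
            for idx in np.flatnonzero(mutate):
                seg[idx] = self._other_base(int(seg[idx]))
        sc_dst, pos = self.place(
            len(seg), margin=_FLANK + 20,
            avoid=[(sc_src, a, b)], avoid_dist=min_src_dist,
        )
        self.seqs[sc_dst][pos : pos + len(seg)] = seg
        src_id = self.seq_ids[sc_src]
        copied = []
        for locus in list(self.truth_loci):
            if locus.seq_id == src_id and a <= locus.start and locus.end <= b:
                shifted = replace(
                    locus,
                    seq_id=self.seq_ids[sc_dst],
                    start=pos + (locus.start - a),
                    end=pos + (locus.end - a),
                )
                copied.append(shifted)
                self.truth_loci.append(shifted)
                lo = max(0, shifted.start - _FLANK)
                hi = min(len(self.seqs[sc_dst]), shifted.end + _FLANK)
                self.frozen[sc_dst][lo:hi] = True
                self._fix_breakers(sc_dst, shifted)
        return sc_dst, pos

    def plant_cassette(
        self,
        cassette: np.ndarray,
        loci_relative: Sequence[SSRLocus],
        avoid: Sequence[tuple[int, int, int]] = (),
        avoid_dist: int = 6_000,
    ) -> tuple[int, int]:
        """Insert a foreign marker cassette; relative loci join the truth."""
        sc, pos = self.place(len(cassette), margin=_FLANK + 20,
                             avoid=avoid, avoid_dist=avoid_dist)
        self.seqs[sc][pos : pos + len(cassette)] = cassette
        self.frozen[sc][pos : pos + len(cassette)] = True
        for locus in loci_relative:
            shifted = replace(
                locus,
                seq_id=self.seq_ids[sc],
                start=pos + locus.start,
                end=pos + locus.end,
                species_id=self.species_id,
            )
            self.truth_loci.append(shifted)
            self._fix_breakers(sc, shifted)
        return sc, pos

    def freeze(self, sc: int, interval: tuple[int, int]) -> None:
        self.frozen[sc][interval[0] : interval[1]] = True

    # -- background suppression --------------------------------------------

    def suppress(self, max_iter: int = 80) -> None:
        """Redraw background until a scan finds exactly the planted loci.

        Accidental loci are patched base-by-base outside truth/frozen zones,
        breaker bases re-pinned, and the genome rescanned; raises if the
        planted truth is not exactly reproduced within *max_iter* rounds.
        """
        truth_mask = [np.zeros(len(s), dtype=bool) for s in self.seqs]
        truth_keys = set()
        by_seq = {sid: i for i, sid in enumerate(self.seq_ids)}
        for locus in self.truth_loci:
            sc = by_seq[locus.seq_id]
            truth_mask[sc][locus.start : locus.end] = True
            truth_keys.add(locus_key(locus))
        for _ in range(max_iter):
            extras = []
            found_keys = set()
            for sc, sid in enumerate(self.seq_ids):
                rec = SeqRecordRef(sid, self.seqs[sc].tobytes().decode("ascii"))
                for locus in scan_ssr(rec):
                    key = locus_key(locus)
                    found_keys.add(key)
                    if key not in truth_keys:
                        extras.append((sc, locus))
            if not extras and truth_keys <= found_keys:
                if found_keys != truth_keys:  # pragma: no cover
                    raise RuntimeError("planted locus lost during generation")
                return
            for sc, locus in extras:
                patchable = np.flatnonzero(
                    ~truth_mask[sc][locus.start : locus.end]
                    & ~self.frozen[sc][locus.start : locus.end]
                )
                if len(patchable) == 0:  # pragma: no cover
                    raise RuntimeError(
                        f"accidental locus at {locus.seq_id}:{locus.start} "
                        "cannot be patched (entirely frozen)"
                    )
                for off in patchable:
                    self.seqs[sc][locus.start + off] = self._other_base(
                        int(self.seqs[sc][locus.start + off])
                    )
            for locus in self.truth_loci:
                self._fix_breakers(by_seq[locus.seq_id], locus)
        raise RuntimeError("background suppression did not converge")

    # -- output -------------------------------------------------------------

    def record(self, sc: int) -> SeqRecordRef:
        return SeqRecordRef(self.seq_ids[sc], self.seqs[sc].tobytes().decode("ascii"))

    def genome(self) -> GenomeSet:
        return GenomeSet(self.species_id, [self.record(i) for i in range(len(self.seqs))])


# ---------------------------------------------------------------------------
# Full fixture generation
# ---------------------------------------------------------------------------

def _gene_plan(spec: FixtureSpec) -> tuple[int, ...]:
    if spec.exon_counts is not None:
        if len(spec.exon_counts) != spec.n_genes:
            raise ValueError("exon_counts length must equal n_genes")
        return tuple(spec.exon_counts)
    return tuple([4] * spec.n_genes)


def generate(spec: FixtureSpec) -> Fixture:
    """Generate the genome, annotation, ESTs and full truth for one spec."""
    total_feature = (
        spec.total_planted() * 40
        + spec.n_genes * (max(_gene_plan(spec) or (0,)) * spec.exon_len_range[1])
    )
    if total_feature > sum(spec.scaffold_lengths) / 2:
        raise ValueError("infeasible spec: planted features exceed half the genome")
    rng = np.random.default_rng(spec.seed)
    builder = GenomeBuilder(
        spec.scaffold_lengths, rng, spec.base_freqs, spec.species_id
    )
    thresholds = DEFAULT_MIN_REPEATS
    remaining = {k: int(v) for k, v in spec.ssr_per_class.items()}

    # 1. duplication donor segments (their loci count toward the class plan)
    donors: list[tuple[int, tuple[int, int], list[SSRLocus]]] = []
    donor_classes = [2, 3, 4, 6, 7, 5]
    for _ in range(spec.n_duplications):
        seg_len = spec.dup_ssrs_per_segment * spec.dup_spacing + 2 * (_FLANK + 40)
        sc, start = builder.place(seg_len, margin=_FLANK + 20)
        loci = []
        offset = _FLANK + 40
        ci = 0
        for _s in range(spec.dup_ssrs_per_segment):
            for _try in range(len(donor_classes)):
                k = donor_classes[ci % len(donor_classes)]
                ci += 1
                if remaining.get(k, 0) > 0:
                    break
            else:
                k = donor_classes[ci % len(donor_classes)]
            remaining[k] = remaining.get(k, 0) - 1
            pool = spec.motif_pool[k]
            motif = pool[int(rng.integers(len(pool)))]
            count = thresholds[k] + int(rng.integers(spec.extra_repeats_max + 1))
            jitter = int(rng.integers(0, 40))
            pos = start + offset + jitter
            builder.plant_ssr(motif, count, at=(sc, pos))
            loci.append(builder.truth_loci[-1])
            offset += spec.dup_spacing
        donors.append((sc, (start, start + seg_len), loci))

    # 2. remaining free-standing SSRs
    for k in sorted(remaining):
        pool = spec.motif_pool[k]
        for _ in range(max(0, remaining[k])):
            motif = pool[int(rng.integers(len(pool)))]
            count = thresholds[k] + int(rng.integers(spec.extra_repeats_max + 1))
            builder.plant_ssr(motif, count)
    original_loci = list(builder.truth_loci)

    # 3. gene models over background sequence
    genes: list[GeneModel] = []
    for gi, n_exons in enumerate(_gene_plan(spec)):
        exon_lens = rng.integers(*spec.exon_len_range, size=n_exons, endpoint=True)
        intron_lens = rng.integers(*spec.intron_len_range, size=max(0, n_exons - 1),
                                   endpoint=True)
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        sc, start = builder.place(gene_len, margin=40)
        exons = []
        cursor = start
        for i in range(n_exons):
            exons.append((cursor, cursor + int(exon_lens[i])))
            cursor += int(exon_lens[i])
            if i < n_exons - 1:
                cursor += int(intron_lens[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1:03d}",
                seq_id=builder.seq_ids[sc],
                strand=strand,
                exons=tuple(exons),
                transcript_id=f"gene{gi + 1:03d}.t1",
            )
        )

    # 4. clean the background BEFORE copying, so donor marker cassettes are
    # repeat-free when duplicated (their copies are frozen byte-identical)
    builder.suppress()

    # 5. copy donor segments (conserved marker cassettes, mutated elsewhere)
    duplications: list[DuplicationTruth] = []
    copy_numbers: dict[tuple, int] = {locus_key(l): 1 for l in original_loci}
    for sc, (a, b), loci in donors:
        protect = [
            (l.start - a - _FLANK, l.end - a + _FLANK) for l in loci
        ]
        for l in loci:  # pin the donor-side cassettes too
            builder.freeze(sc, (max(0, l.start - _FLANK), l.end + _FLANK))
        sc_dst, pos = builder.copy_segment(
            sc, (a, b), spec.mutation_rate, protect
        )
        for l in loci:
            copy_numbers[locus_key(l)] = 2
        duplications.append(
            DuplicationTruth(
                a_seq=builder.seq_ids[sc],
                a_interval=(a, b),
                b_seq=builder.seq_ids[sc_dst],
                b_interval=(pos, pos + (b - a)),
                n_loci=len(loci),
            )
        )

    # 6. re-suppress junction- or mutation-created repeats in the copies,
    # then verify the truth closure exactly
    builder.suppress()

    # 7. spliced transcripts (clean CDS role + substituted ESTs)
    genome = builder.genome()
    cds_records: list[SeqRecordRef] = []
    est_records: list[SeqRecordRef] = []
    est_truth: list[ESTTruth] = []
    for gene in genes:
        rec = genome.get(gene.seq_id)
        spliced = "".join(rec.sequence[s:e] for s, e in gene.exons)
        if gene.strand == "-":
            spliced = revcomp(spliced)
        lengths = [e - s for s, e in gene.exons]
        if gene.strand == "-":
            lengths = lengths[::-1]
        junctions = tuple(np.cumsum(lengths[:-1]).tolist())
        cds_records.append(SeqRecordRef(f"{gene.gene_id}.cds", spliced))
        est_seq = spliced
        if spec.est_substitution_rate > 0:
            arr = np.frombuffer(est_seq.encode("ascii"), dtype=np.uint8).copy()
            hit = rng.random(len(arr)) < spec.est_substitution_rate
            for idx in np.flatnonzero(hit):
                arr[idx] = builder._other_base(int(arr[idx]))
            est_seq = arr.tobytes().decode("ascii")
        est_id = f"{gene.gene_id}.est"
        est_records.append(SeqRecordRef(est_id, est_seq))
        est_truth.append(ESTTruth(est_id, gene.gene_id, junctions))

    truth = FixtureTruth(
        loci=sorted(builder.truth_loci, key=lambda l: (l.seq_id, l.start, l.class_k)),
        original_loci=original_loci,
        genes=genes,
        duplications=duplications,
        copy_numbers=copy_numbers,
        ests=est_truth,
    )
    return Fixture(genome=genome, genes=genes, ests=est_records,
                   cds=cds_records, truth=truth)


def benchmark_spec(seed: int = 42) -> FixtureSpec:
    """The canonical 2-Mb benchmark: 200 planted SSRs (18 of them inside three
    duplicated donor segments), 50 genes with 149 introns, 3 duplications."""
    return FixtureSpec(
        seed=seed,
        scaffold_lengths=(1_000_000, 1_000_000),
        ssr_per_class={1: 20, 2: 40, 3: 40, 4: 30, 5: 20, 6: 30, 7: 20},
        n_genes=50,
        exon_counts=tuple([4] * 49 + [3]),   # 49*3 + 2 = 149 introns
        n_duplications=3,
        dup_ssrs_per_segment=6,
    )


# ---------------------------------------------------------------------------
# Scenario builders for the screens
# ---------------------------------------------------------------------------

def copy_number_fixture(
    seed: int = 7,
    plan: Mapping[int, int] = None,
    genome_length: int = 400_000,
):
    """A genome plus 100 designed SSR markers with exact copy-number truth.

    *plan* maps copies -> number of markers (default {1: 70, 2: 20, 3: 10});
    extra copies are byte-exact cassette insertions of the marker's expected
    amplicon, so the e-PCR site count of every marker is known.  Returns
    (genome, markers, expected: dict marker_id -> copies).
    """
    from .ssr_mining import design_ssr_markers

    plan = dict(plan or {1: 70, 2: 20, 3: 10})
    n_markers = sum(plan.values())
    rng = np.random.default_rng(seed)
    builder = GenomeBuilder((genome_length,), rng, species_id="cnfix")
    pools = [(2, "AT"), (2, "AG"), (3, "AAG"), (3, "ACT"), (4, "AAAT")]
    for i in range(n_markers + 30):
        k, motif = pools[i % len(pools)]
        count = DEFAULT_MIN_REPEATS[k] + int(rng.integers(3))
        builder.plant_ssr(motif, count)
    builder.suppress()
    genome = builder.genome()
    loci = sorted(builder.truth_loci, key=lambda l: (l.seq_id, l.start))
    markers = design_ssr_markers(genome, loci)
    if len(markers) < n_markers:  # pragma: no cover - ample headroom planted
        raise RuntimeError("not enough designable markers for the copy plan")
    markers = markers[:n_markers]

    # freeze every marker's amplicon so later patching cannot touch a primer
    by_seq = {sid: i for i, sid in enumerate(builder.seq_ids)}
    locus_by_start = {(l.seq_id, l.start): l for l in loci}
    for m in markers:
        builder.freeze(by_seq[m.seq_id], m.amplicon_interval)

    expected: dict[str, int] = {}
    idx = 0
    for copies in sorted(plan):
        for _ in range(plan[copies]):
            m = markers[idx]
            idx += 1
            expected[m.marker_id] = copies
            src = locus_by_start[(m.seq_id, m.start)]
            a, b = m.amplicon_interval
            sc = by_seq[m.seq_id]
            sites = [(sc, a, b)]
            for _c in range(copies - 1):
                cassette = builder.seqs[sc][a:b].copy()
                rel = replace(src, start=src.start - a, end=src.end - a)
                sc2, pos2 = builder.plant_cassette(cassette, [rel], avoid=sites)
                sites.append((sc2, pos2, pos2 + (b - a)))
    builder.suppress()
    return builder.genome(), markers, expected


def universal_panel(seed: int = 11, n_markers: int = 10, n_universal: int = 4):
    """Three genomes and markers of which exactly *n_universal* amplify in all.

    Markers are designed on genome A; the expected amplicon cassettes of the
    first *n_universal* are planted byte-exact into genomes B and C.  Returns
    (genomes, markers, universal_ids).
    """
    from .ssr_mining import design_ssr_markers

    rng = np.random.default_rng(seed)
    builder_a = GenomeBuilder((250_000,), rng, species_id="species_A")
    pools = [(2, "AT"), (3, "AAG"), (2, "AC"), (4, "AAAT")]
    for i in range(n_markers + 8):
        k, motif = pools[i % len(pools)]
        builder_a.plant_ssr(motif, DEFAULT_MIN_REPEATS[k] + int(rng.integers(3)))
    builder_a.suppress()
    genome_a = builder_a.genome()
    loci = sorted(builder_a.truth_loci, key=lambda l: (l.seq_id, l.start))
    markers = design_ssr_markers(genome_a, loci)[:n_markers]
    if len(markers) < n_markers:  # pragma: no cover
        raise RuntimeError("not enough designable markers for the panel")

    locus_by_start = {(l.seq_id, l.start): l for l in loci}
    genomes = [genome_a]
    for species in ("species_B", "species_C"):
        b = GenomeBuilder((180_000,), rng, species_id=species)
        for m in markers[:n_universal]:
            a0, b0 = m.amplicon_interval
            sc = builder_a.seq_ids.index(m.seq_id)
            cassette = builder_a.seqs[sc][a0:b0].copy()
            src = locus_by_start[(m.seq_id, m.start)]
            rel = replace(src, start=src.start - a0, end=src.end - a0)
            b.plant_cassette(cassette, [rel])
        b.suppress()
        genomes.append(b.genome())
    universal_ids = [m.marker_id for m in markers[:n_universal]]
    return genomes, markers, universal_ids


# ---------------------------------------------------------------------------
# Disk emission
# ---------------------------------------------------------------------------

def write_fixture(fixture: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Emit FASTA / GFF3 / EST FASTA / truth TSVs for external use."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "genes": out / "genes.gff3",
        "ests": out / "ests.fa",
        "cds": out / "cds.fa",
        "loci": out / "truth_loci.tsv",
        "duplications": out / "truth_duplications.tsv",
        "ests_truth": out / "truth_ests.tsv",
    }
    write_fasta(fixture.genome.records, paths["genome"])
    write_gff3(fixture.genes, paths["genes"])
    write_fasta(fixture.ests, paths["ests"])
    write_fasta(fixture.cds, paths["cds"])
    with open(paths["loci"], "w") as fh:
        fh.write("seq_id\tstart\tend\tmotif\tmotif_as_found\trepeat_count\tcopies\n")
        for l in fixture.truth.loci:
            fh.write(
                f"{l.seq_id}\t{l.start}\t{l.end}\t{l.motif}\t{l.motif_as_found}\t"
                f"{l.repeat_count}\t{fixture.truth.copy_numbers.get(locus_key(l), 1)}\n"
            )
    with open(paths["duplications"], "w") as fh:
        fh.write("a_seq\ta_start\ta_end\tb_seq\tb_start\tb_end\tn_loci\n")
        for d in fixture.truth.duplications:
            fh.write(
                f"{d.a_seq}\t{d.a_interval[0]}\t{d.a_interval[1]}\t"
                f"{d.b_seq}\t{d.b_interval[0]}\t{d.b_interval[1]}\t{d.n_loci}\n"
            )
    with open(paths["ests_truth"], "w") as fh:
        fh.write("est_id\tgene_id\tjunctions\n")
        for e in fixture.truth.ests:
            fh.write(f"{e.est_id}\t{e.gene_id}\t{','.join(map(str, e.junctions))}\n")
    return paths
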