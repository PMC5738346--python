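# Methods

This note documents the models and procedures behind `treemarker`, the
parameter choices that matter, the conventions that make its output
deterministic, and what the synthetic fixtures do and do not demonstrate.

## Coordinates

All internal intervals are 0-based, half-open. Conversion to the 1-based
inclusive convention of GFF3 and the marker table happens exactly once, in
`io_formats`; BED output stays 0-based half-open. This single conversion
point is what the round-trip tests exercise.

## SSR mining

A locus is a **maximal perfect tandem run** of a primitive motif of length
k ∈ 1..7 whose whole-copy count reaches the class threshold
(k = 1: ≥12, 2: ≥6, 3: ≥4, 4: ≥3, 5: ≥3, 6: ≥2, 7: ≥2). Detection uses the
self-comparison s[i] = s[i+k]: a maximal run of matches of length L spans
L + k bases and holds ⌊(L+k)/k⌋ whole copies anchored at the run start;
trailing partial copies are trimmed, so the reported interval length always
equals repeat_count × k, and extending the interval by one whole motif copy
on either side breaks the repetition. N compares unequal to everything, so
runs never cross an N.

Conventions worth making explicit:

- **Canonical motifs.** Each motif class is represented by the
  lexicographic minimum over all rotations of the motif and of its reverse
  complement (so AC stands for {AC, CA, TG, GT}). The phase actually present
  at the locus start is kept separately (`motif_as_found`).
- **Primitivity.** A run of a non-primitive unit (ATAT as a "tetramer") is
  reported only in the class of its primitive unit. The most frequent
  hexamers and heptamers in published tree-genome surveys (AAAAAT, AAAAAAT,
  …) are primitive, so this rule does not conflict with those observations,
  but because it materially affects class frequencies it is exposed as
  `allow_nonprimitive` for the alternative counting.
- **Independent classes.** Each k is scanned independently; one region can
  host maximal runs of different primitive units, and each is reported under
  its own class rule. Compound/interrupted repeats are not merged.
- Density is reported as loci per Mb of scanned sequence; per-window counts
  bin loci by start position.

The scanner's contract is checked against a brute-force oracle that extends
every candidate position explicitly.

## Primer design

Each locus or intron contributes a pair of 60-bp precursor flanks. Flanks
truncated by a sequence end, containing N, or (for introns) not fully
contained in the adjacent exon are rejected — exonic placement is what makes
an intron marker's product length track the intron length.

The designer enumerates every 18–27-nt window per flank and applies hard
constraints: melting temperature 55–63 °C (optimum 60), GC fraction
0.35–0.65, homopolymer runs ≤4, pair Tm difference ≤3 °C. Tm is the
nearest-neighbor value under the SantaLucia (1998) unified parameters at
50 mM Na⁺ and 250 nM strand concentration, with the entropic salt
correction ΔS += 0.368·(N−1)·ln[Na⁺]; tests re-derive it by hand-summing
the published table. Windows are ranked by |Tm − 60| + 0.5·|len − 20|; the
best 12 per side are paired and the pair score adds 2 points per base of
self- or cross-complementarity beyond 8 bp anywhere or 4 bp at a 3' end.
Complementarity beyond those limits penalises and flags the pair rather
than rejecting it — a deliberate choice, since a flagged pair may still be
the only option for a locus and downstream screens will judge it by actual
amplification. Ties break to the leftmost forward, then leftmost reverse
window, making the output byte-deterministic; the whole selection is
re-implemented independently in the test suite as an enumeration oracle.

Product size is not constrained beyond flank geometry: an SSR product spans
the repeat, an intron product spans the intron with no upper bound (intron
marker screens deliberately impose no length limits).

## Electronic PCR and the screens

A hit is any placement where the forward primer matches one strand and the
reverse primer matches the opposite strand downstream with a product of
40–5000 bp. Matching allows `max_mismatches` (default 0 — strict, since the
appropriate tolerance depends on assembly quality and is a config knob)
but always requires the 3'-terminal 3 bases exact, emulating polymerase
extension sensitivity; N matches nothing. Both amplicon orientations are
scanned and hits per scaffold are capped at 1000 with a warning to bound
pathological low-complexity primers. The engine is property-tested against
an oracle that tries every position pair.

The screens implement the decision rules exactly:

- **Validation**: a marker is good iff some hit overlaps its source locus
  with a product within ±20% of the expected size.
- **Deduplication**: markers sharing a forward OR a reverse primer sequence
  are the same marker; the relation is closed transitively and the
  representative with the smallest (scaffold, position) survives.
- **Polymorphism**: a validated marker amplifying exactly one site
  genome-wide is monomorphic; two or more sites, polymorphic. The histogram
  aggregates markers per site count; subsampling for large panels uses an
  explicit seed.
- **Universality**: a marker is universal iff it amplifies ≥1 product in
  every genome of the panel; the marker × species site-count matrix is
  returned alongside.

## Intron markers

ILP extraction takes the gaps between consecutive exons of one
representative transcript per gene (the transcript with the longest summed
exon length; ties to the smallest id), ordinals counted 5'→3' in
transcription order, with no length filter. Intron positions of the model
species are read from its annotation as cumulative exon lengths on the
spliced transcript rather than re-derived by spliced alignment — the
annotation carries identical information with far less machinery.

For PIP projection, ESTs are aligned to the model CDS by local affine
alignment (match +1, mismatch −2, gap open −5, extend −1; both EST strands
tried) and accepted at ≥85% identity over ≥100 columns — conventional
cross-species EST mapping values, exposed as options since the right
stringency depends on the species pair. A junction at spliced position p
maps to the EST base aligned with CDS base p, snapping right across
alignment gaps. On fixture data the projection is exact at 0% substitution
and within ±2 bases at 5%.

## Diversity analysis

Band scoring emulates gel resolution: each (marker, product-size bin)
becomes a band column with bin edges at multiples of 5 bp (configurable),
and a sample scores 1 if any product falls in the bin. The default distance
is Dice (Nei–Li), the standard coefficient for dominant markers whose
shared absences are uninformative; simple matching and Jaccard are
selectable, and a sample with no bands is flagged (its dice/jaccard pairs
are undefined and set to the maximal distance 1).

UPGMA uses cluster-size-weighted arithmetic-mean linkage, merge height
d/2, and breaks ties to the pair whose merged leaf set sorts first, so
trees are reproducible; outputs are ultrametric to 10⁻⁹ by construction
and serialised as Newick with branch lengths. Bootstrap resamples band
*columns* with replacement (the standard for band data), rebuilds the tree
per replicate, and maps support onto the full-data tree by matching clade
leaf sets; everything is driven by one seed.

## Duplication detection

Anchors link two genomic positions: protein-level matches read from
12-column BLAST tabular (self-identical rows dropped), or — the novel use —
pairs of amplification sites of markers hitting ≥2 sites. Ordinals are
element ranks along each scaffold (gene rank, or hit rank over all
multi-site markers), the convention MCScanX uses for its gap constraint,
while genomic intervals define block spans. Same-scaffold site pairs within
10 kb are flagged tandem and excluded from segmental chaining.

Blocks are extracted greedily: the best remaining chain under strictly
increasing a-ordinals and strictly increasing (same) or decreasing
(inverted) b-ordinals with ordinal gaps ≤25 is removed until no chain
reaches `min_block` = 5 anchors (mirroring MCScanX's MATCH_SIZE). Among
equally long chains the lexicographically smallest anchor sequence wins,
same orientation before inverted — fully specified so an
exhaustive-enumeration oracle can (and does) check the dynamic programme
block for block. Two duplication events overlap iff both their span pairs
intersect under either axis pairing.

Note that when several duplicated segments lie on one scaffold pair with
few intervening anchors, their ordinal gaps are small and the chainer may
join them into one block; recovery is therefore assessed as coverage
(every planted segment pair intersected by some block), not as a
one-to-one block/segment match.

## Synthetic fixtures

The generator emulates the inputs of a genome-wide marker survey at desk
scale. Background sequence is drawn from configurable base frequencies
(default 30/20/20/30, plant-like AT richness) and then **rejection-cleaned**:
the genome is rescanned and every accidental reportable repeat is redrawn
until a scan finds exactly the planted loci, so specificity statements in
the tests are exact rather than probabilistic. Planted runs get their
flanking bases pinned so they cannot extend, making maximality exact too.

Genes are interval annotations over background sequence (default 4 exons of
150–300 bp, introns 80–400 bp — compact plant-gene scale); ESTs are spliced
transcripts with optional per-base substitutions. Duplications copy a donor
segment carrying several planted loci to a distant position (≥25 kb away,
so the pair is segmental and primers cannot bridge the copies), with 2%
point substitution everywhere **except** inside each planted locus ±60 bp.
Protecting the marker cassettes emulates conserved primer sites and keeps
per-marker copy numbers exact under strict e-PCR; it also means the
fixtures do not probe mismatch-tolerant recovery of diverged sites — that
path is exercised separately by the oracle tests with explicit mismatches.

The default benchmark (seed 42) plants 200 loci across all seven classes on
2 Mb in two scaffolds, 50 genes with 149 introns, and 3 duplicated segments
of 6 markers each. Scenario builders provide a 100-marker genome with
copy-number plan {1:70, 2:20, 3:10} and a three-genome panel in which
exactly 4 of 10 markers are universal.

What passing these tests shows: the algorithms implement their contracts
exactly on inputs whose truth is known. What they do not show: performance
on real assemblies — real genomes contain imperfect and compound repeats,
assembly gaps, paralogous primer sites with small divergence, and intron
annotations of uneven quality, none of which the generator models (no
indels, no motif mutation dynamics, no realistic repeat landscape).

## Problem sizes and defaults

The test suite and the acceptance script run on 10-kb oracle sequences
(100×), 100-kb e-PCR genomes (50 primer pairs), the 2-Mb benchmark fixture,
1000 bootstrap replicates on a 10-sample band matrix, and 200 random anchor
sets for the chaining oracle — sizes at which every oracle comparison is
exact and a full run takes on the order of a minute on one CPU. All
randomness flows from explicit seeds; reruns are byte-identical.
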