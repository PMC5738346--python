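"""Duplication-block detection from anchor pairs.

Anchors link two genomic positions through either a protein-level gene match
(read from BLAST tabular) or an SSR marker amplifying two or more sites.
Blocks are maximal collinear chains of anchors found by a longest-increasing
(or decreasing, for inverted blocks) subsequence dynamic programme with an
ordinal gap constraint — a self-contained, oracle-testable stand-in for
MCScanX-style chaining with ``min_block`` mirroring its MATCH_SIZE default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import BlastHit, GeneModel
from .insilico_pcr import AmpliconHit

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchorPair:
    """A matched element linking two genomic positions.

    Positions are ordinal ranks (gene rank or marker-hit rank along the
    sequence) used for gap constraints; the intervals are genomic and define
    block spans.
    """

    a_seq: str
    b_seq: str
    a_pos: int
    b_pos: int
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    source: str = "ssr"      # ssr | gene
    tandem: bool = False


@dataclass(frozen=True)
class CollinearBlock:
    """An ordered chain of anchors covering a duplicated segment pair."""

    block_id: str
    anchors: tuple[AnchorPair, ...]
    orientation: str         # same | inverted

    @property
    def a_seq(self) -> str:
        return self.anchors[0].a_seq

    @property
    def b_seq(self) -> str:
        return self.anchors[0].b_seq

    @property
    def a_span(self) -> tuple[int, int]:
        return (min(a.a_interval[0] for a in self.anchors),
                max(a.a_interval[1] for a in self.anchors))

    @property
    def b_span(self) -> tuple[int, int]:
        return (min(a.b_interval[0] for a in self.anchors),
                max(a.b_interval[1] for a in self.anchors))

    @property
    def score(self) -> int:
        return len(self.anchors)


# ---------------------------------------------------------------------------
# Anchor construction
# ---------------------------------------------------------------------------

def ssr_anchors(
    hits_by_marker: Mapping[str, Sequence[AmpliconHit]],
    min_sites: int = 2,
    tandem_dist: int = 10_000,
) -> list[AnchorPair]:
    """Anchor pairs from markers amplifying *min_sites* or more sites.

    Every unordered pair of hits of one marker becomes one anchor.  Hit
    ordinals are ranks along each sequence over all hits of all qualifying
    markers.  Pairs whose two hits overlap are dropped as self-pairs;
    same-sequence pairs closer than *tandem_dist* are flagged tandem (and
    excluded from segmental chaining by default).
    """
    multi = {m: list(h) for m, h in hits_by_marker.items() if len(h) >= min_sites}
    ranked: list[tuple[str, int, int, str]] = []  # (seq, start, end, marker)
    for marker, hits in multi.items():
        for h in hits:
            ranked.append((h.seq_id, h.start, h.end, marker))
    ranked.sort()
    # per-sequence ordinal rank
    ordinal: dict[tuple, int] = {}
    counter: dict[str, int] = {}
    for key in ranked:
        seq = key[0]
        ordinal[key] = counter.get(seq, 0)
        counter[seq] = ordinal[key] + 1

    anchors: list[AnchorPair] = []
    for marker in sorted(multi):
        hits = sorted(multi[marker], key=lambda h: (h.seq_id, h.start, h.end))
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                h1, h2 = hits[i], hits[j]
                if h1.seq_id == h2.seq_id and h1.start < h2.end and h2.start < h1.end:
                    continue  # overlapping hits: self pair
                tandem = (
                    h1.seq_id == h2.seq_id
                    and abs(h2.start - h1.start) <= tandem_dist
                )
                k1 = (h1.seq_id, h1.start, h1.end, marker)
                k2 = (h2.seq_id, h2.start, h2.end, marker)
                anchors.append(
                    AnchorPair(
                        a_seq=h1.seq_id, b_seq=h2.seq_id,
                        a_pos=ordinal[k1], b_pos=ordinal[k2],
                        a_interval=(h1.start, h1.end),
                        b_interval=(h2.start, h2.end),
                        source="ssr", tandem=tandem,
                    )
                )
    return anchors


def gene_anchors(
    blast_hits: Iterable[BlastHit], genes: Sequence[GeneModel]
) -> list[AnchorPair]:
    """Anchor pairs from protein self-comparison rows and gene positions.

    Gene ordinals are ranks along each sequence; rows naming unknown genes
    are skipped with a warning, and duplicate anchors (either orientation)
    are collapsed.
    """
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    info: dict[str, tuple[str, int, tuple[int, int]]] = {}
    for seq_id, gs in by_seq.items():
        gs.sort(key=lambda g: g.span)
        for rank, g in enumerate(gs):
            info[g.gene_id] = (seq_id, rank, g.span)
    anchors: dict[tuple, AnchorPair] = {}
    skipped = 0
    for hit in blast_hits:
        if hit.query not in info or hit.subject not in info:
            skipped += 1
            continue
        qa, sa = info[hit.query], info[hit.subject]
        if qa == sa:
            continue
        (a, b) = sorted((qa, sa))
        key = (a[0], a[1], b[0], b[1])
        if key not in anchors:
            anchors[key] = AnchorPair(
                a_seq=a[0], b_seq=b[0], a_pos=a[1], b_pos=b[1],
                a_interval=a[2], b_interval=b[2], source="gene",
            )
    if skipped:
        log.warning("gene_anchors: %d rows named unknown genes; skipped", skipped)
    return [anchors[k] for k in sorted(anchors)]


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def _best_chain(
    anchors: Sequence[AnchorPair], orientation: str, max_gap: int
) -> list[int]:
    """Longest valid chain over *anchors* (sorted by (a_pos, b_pos)).

    Valid transitions have strictly increasing a_pos with ordinal gap at most
    *max_gap*, and b_pos strictly increasing (same) or decreasing (inverted)
    with the same gap bound.  Among maximal chains the lexicographically
    smallest index sequence is returned, so the result is deterministic and
    matched by the exhaustive oracle.
    """
    n = len(anchors)

    def ok(i: int, j: int) -> bool:
        ai, aj = anchors[i], anchors[j]
        if aj.a_pos <= ai.a_pos or aj.a_pos - ai.a_pos > max_gap:
            return False
        if orientation == "same":
            return ai.b_pos < aj.b_pos <= ai.b_pos + max_gap
        return ai.b_pos > aj.b_pos >= ai.b_pos - max_gap

    best_from = [1] * n
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if ok(i, j) and best_from[j] + 1 > best_from[i]:
                best_from[i] = best_from[j] + 1
    if n == 0:
        return []
    target = max(best_from)
    chain: list[int] = []
    remaining = target
    prev: int | None = None
    start = 0
    while remaining:
        for i in range(start, n):
            if best_from[i] == remaining and (prev is None or ok(prev, i)):
                chain.append(i)
                prev = i
                start = i + 1
                remaining -= 1
                break
        else:  # pragma: no cover - DP guarantees a continuation exists
            raise AssertionError("chain reconstruction failed")
    return chain


def chain_anchors(
    anchors: Sequence[AnchorPair],
    min_block: int = 5,
    max_gap: int = 25,
    block_prefix: str = "block",
) -> list[CollinearBlock]:
    """Greedy extraction of maximal collinear chains for one sequence pair.

    Repeatedly finds the best remaining chain over both orientations
    (preferring longer chains, then same orientation, then the
    lexicographically smallest anchor sequence), removes its anchors, and
    stops when no chain reaches *min_block*.  Tandem-flagged anchors are
    excluded.  No anchor appears in two blocks.
    """
    pool = sorted(
        (a for a in anchors if not a.tandem),
        key=lambda a: (a.a_pos, a.b_pos),
    )
    pairs = {(a.a_seq, a.b_seq) for a in pool}
    if len(pairs) > 1:
        raise ValueError("chain_anchors expects anchors of a single sequence pair")
    blocks: list[CollinearBlock] = []
    counter = 0
    while pool:
        candidates = []
        for orientation in ("same", "inverted"):
            idx = _best_chain(pool, orientation, max_gap)
            key = (-len(idx), 0 if orientation == "same" else 1,
                   tuple((pool[i].a_pos, pool[i].b_pos) for i in idx))
            candidates.append((key, orientation, idx))
        key, orientation, idx = min(candidates)
        if len(idx) < min_block:
            break
        chain = tuple(pool[i] for i in idx)
        counter += 1
        blocks.append(
            CollinearBlock(f"{block_prefix}{counter}", chain, orientation)
        )
        used = set(idx)
        pool = [a for i, a in enumerate(pool) if i not in used]
    blocks.sort(key=lambda b: (b.a_seq, b.a_span[0], b.b_seq, b.b_span[0]))
    return blocks


def chain_all(
    anchors: Iterable[AnchorPair],
    min_block: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain every (a_seq, b_seq) pair independently; deterministic order."""
    groups: dict[tuple[str, str], list[AnchorPair]] = {}
    for a in anchors:
        groups.setdefault((a.a_seq, a.b_seq), []).append(a)
    blocks: list[CollinearBlock] = []
    for i, key in enumerate(sorted(groups)):
        blocks.extend(
            chain_anchors(groups[key], min_block, max_gap,
                          block_prefix=f"block_{key[0]}_{key[1]}_")
        )
    blocks.sort(key=lambda b: (b.a_seq, b.a_span[0], b.b_seq, b.b_span[0]))
    return blocks


# ---------------------------------------------------------------------------
# Overlap statistic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapStats:
    """Mutual overlap between gene-based and SSR-based duplication events."""

    n_gene: int
    n_ssr: int
    gene_overlapping: int
    ssr_overlapping: int

    @property
    def gene_pct(self) -> float:
        return 100.0 * self.gene_overlapping / self.n_gene if self.n_gene else 0.0

    @property
    def ssr_pct(self) -> float:
        return 100.0 * self.ssr_overlapping / self.n_ssr if self.n_ssr else 0.0


def _spans_intersect(seq1: str, span1: tuple[int, int],
                     seq2: str, span2: tuple[int, int]) -> bool:
    return seq1 == seq2 and span1[0] < span2[1] and span2[0] < span1[1]


def _blocks_overlap(x: CollinearBlock, y: CollinearBlock) -> bool:
    direct = (
        _spans_intersect(x.a_seq, x.a_span, y.a_seq, y.a_span)
        and _spans_intersect(x.b_seq, x.b_span, y.b_seq, y.b_span)
    )
    cross = (
        _spans_intersect(x.a_seq, x.a_span, y.b_seq, y.b_span)
        and _spans_intersect(x.b_seq, x.b_span, y.a_seq, y.a_span)
    )
    return direct or cross


def block_overlap(
    gene_blocks: Sequence[CollinearBlock], ssr_blocks: Sequence[CollinearBlock]
) -> OverlapStats:
    """Event pairs overlap iff both spans intersect under either pairing."""
    gene_hit = sum(
        1 for g in gene_blocks if any(_blocks_overlap(g, s) for s in ssr_blocks)
    )
    ssr_hit = sum(
        1 for s in ssr_blocks if any(_blocks_overlap(s, g) for g in gene_blocks)
    )
    return OverlapStats(len(gene_blocks), len(ssr_blocks), gene_hit, ssr_hit)


def write_blocks_tsv(blocks: Sequence[CollinearBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\ta_seq\ta_start\ta_end\tb_seq\tb_start\tb_end\t"
                 "orientation\tn_anchors\n")
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.a_seq}\t{b.a_span[0]}\t{b.a_span[1]}\t"
                f"{b.b_seq}\t{b.b_span[0]}\t{b.b_span[1]}\t{b.orientation}\t"
                f"{b.score}\n"
            )


def write_link_list(blocks: Sequence[CollinearBlock], path) -> None:
    """Plain two-interval rows (one line per block), browser/Circos friendly."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                f"{b.a_seq}\t{b.a_span[0]}\t{b.a_span[1]}\t"
                f"{b.b_seq}\t{b.b_span[0]}\t{b.b_span[1]}\n"
            )
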