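"""Deterministic primer-pair design from a pair of 60-bp precursor flanks.

The designer enumerates every window of 18-27 nt in each flank, filters on
hard constraints (melting temperature, GC fraction, homopolymer run, pair Tm
difference), scores the surviving pairs by distance from the optima plus
self/cross-complementarity penalties, and returns the single lowest-scoring
pair with fully specified tie-breaking — identical inputs yield
byte-identical primers on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.SeqUtils import MeltingTemp as _mt

from .ssr_mining import revcomp


class DesignError(ValueError):
    """Raised when no primer pair satisfies the constraints."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class DesignConstraints:
    """Hard and soft limits for primer selection.

    Lengths in nt, temperatures in deg C, GC as a fraction.  The
    complementarity limits are soft: exceeding them adds a score penalty and
    sets the pair's ``self_complementary`` flag rather than rejecting.
    """

    len_min: int = 18
    len_max: int = 27
    len_opt: int = 20
    tm_min: float = 55.0
    tm_max: float = 63.0
    tm_opt: float = 60.0
    gc_min: float = 0.35
    gc_max: float = 0.65
    max_tm_diff: float = 3.0
    max_homopolymer: int = 4
    max_3prime_selfcomp: int = 4
    max_anycomp: int = 8

    def __post_init__(self) -> None:
        if self.len_min > self.len_max or self.tm_min > self.tm_max:
            raise ValueError("empty constraint range")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair: both primers written 5'->3' on their own strands."""

    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    expected_product_bp: int
    forward_start: int = 0   # 5' offset of the forward primer within the left flank
    reverse_end: int = 0     # 5' offset of the reverse primer from the right flank start
    self_complementary: bool = False
    score: float = 0.0


def gc_fraction(seq: str) -> float:
    return sum(1 for c in seq if c in "GC") / len(seq) if seq else 0.0


def max_homopolymer(seq: str) -> int:
    best = run = 0
    prev = ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


@lru_cache(maxsize=200_000)
def melting_temp(primer: str) -> float:
    """Nearest-neighbor melting temperature in deg C, deterministic to 0.01.

    Uses the SantaLucia (1998) unified parameter set with 50 mM monovalent
    salt and 250 nM strand concentration; the salt correction adds
    0.368*(N-1)*ln[Na+] cal/(K*mol) to the duplex entropy.
    """
    if len(primer) < 8:
        raise DesignError("primer shorter than 8 nt")
    if any(c not in "ACGT" for c in primer):
        raise DesignError("primer contains non-ACGT characters")
    tm = _mt.Tm_NN(
        primer,
        nn_table=_mt.DNA_NN3,
        Na=50,
        dnac1=250.0,
        dnac2=0.0,
        saltcorr=5,
    )
    return round(float(tm), 2)


def complementarity_any(p: str, q: str) -> int:
    """Longest contiguous duplex two primers can form anywhere (in bp).

    A substring of *p* anneals to *q* exactly where it equals a substring of
    revcomp(q); the measure is the longest common substring of p and
    revcomp(q).
    """
    r = revcomp(q)
    best = 0
    prev = [0] * (len(r) + 1)
    for a in p:
        cur = [0]
        for j, b in enumerate(r, 1):
            v = prev[j - 1] + 1 if a == b else 0
            cur.append(v)
            if v > best:
                best = v
        prev = cur
    return best


def complementarity_3prime(p: str, q: str) -> int:
    """Longest 3'-terminal stretch of *p* that can anneal within *q*."""
    r = revcomp(q)
    for t in range(min(len(p), len(r)), 0, -1):
        if p[-t:] in r:
            return t
    return 0


def _windows(flank: str, c: DesignConstraints) -> list[tuple[float, int, int, str, float, float]]:
    """All windows passing the per-primer hard constraints.

    Returns (score, start, length, seq, tm, gc) tuples, score-sorted.
    """
    out = []
    n = len(flank)
    for ln in range(c.len_min, c.len_max + 1):
        for start in range(0, n - ln + 1):
            sub = flank[start : start + ln]
            if "N" in sub:
                continue
            gc = gc_fraction(sub)
            if not c.gc_min <= gc <= c.gc_max:
                continue
            if max_homopolymer(sub) > c.max_homopolymer:
                continue
            tm = melting_temp(sub)
            if not c.tm_min <= tm <= c.tm_max:
                continue
            score = abs(tm - c.tm_opt) + 0.5 * abs(ln - c.len_opt)
            out.append((score, start, ln, sub, tm, gc))
    out.sort(key=lambda w: (w[0], w[1], w[2]))
    return out


_MAX_CANDIDATES_PER_SIDE = 12


def design_pair(
    left_flank: str,
    right_flank: str,
    constraints: DesignConstraints | None = None,
    insert_len: int = 0,
) -> PrimerPair:
    """Pick the best primer pair from two precursor flanks.

    The forward primer is a substring of *left_flank*; the reverse primer is
    the reverse complement of a substring of *right_flank*.  *insert_len* is
    the number of template bases between the flanks (the SSR locus or intron),
    so the expected product runs from the forward 5' end through the insert to
    the reverse 5' end.  Raises :class:`DesignError` when no window passes.
    """
    c = constraints or DesignConstraints()
    if len(left_flank) < c.len_min or len(right_flank) < c.len_min:
        raise DesignError("flank shorter than minimum primer length")
    fwd_candidates = _windows(left_flank, c)
    rev_candidates = _windows(right_flank, c)
    if not fwd_candidates:
        raise DesignError("no acceptable window in left flank")
    if not rev_candidates:
        raise DesignError("no acceptable window in right flank")
    fwd_candidates = fwd_candidates[:_MAX_CANDIDATES_PER_SIDE]
    rev_candidates = rev_candidates[:_MAX_CANDIDATES_PER_SIDE]

    def self_pen(seq: str) -> tuple[int, int]:
        return complementarity_any(seq, seq), complementarity_3prime(seq, seq)

    fwd_self = [self_pen(w[3]) for w in fwd_candidates]
    rev_self = [self_pen(revcomp(w[3])) for w in rev_candidates]

    best = None
    best_key = None
    for fi, (fs, fstart, flen, fsub, ftm, fgc) in enumerate(fwd_candidates):
        for ri, (rs, rstart, rlen, rsub, rtm, rgc) in enumerate(rev_candidates):
            if abs(ftm - rtm) > c.max_tm_diff:
                continue
            fseq, rseq = fsub, revcomp(rsub)
            any_comp = max(
                complementarity_any(fseq, rseq), fwd_self[fi][0], rev_self[ri][0]
            )
            tp_comp = max(
                complementarity_3prime(fseq, rseq),
                complementarity_3prime(rseq, fseq),
                fwd_self[fi][1],
                rev_self[ri][1],
            )
            penalty = 2.0 * max(0, any_comp - c.max_anycomp) + 2.0 * max(
                0, tp_comp - c.max_3prime_selfcomp
            )
            score = fs + rs + penalty
            key = (score, fstart, rstart, flen, rlen)
            if best_key is None or key < best_key:
                best_key = key
                best = (
                    fstart, flen, fseq, ftm, fgc,
                    rstart, rlen, rseq, rtm, rgc,
                    penalty > 0, score,
                )
    if best is None:
        raise DesignError("no pair within the allowed Tm difference")
    (fstart, flen, fseq, ftm, fgc, rstart, rlen, rseq, rtm, rgc, flagged, score) = best
    product = (len(left_flank) - fstart) + insert_len + (rstart + rlen)
    return PrimerPair(
        forward=fseq,
        reverse=rseq,
        tm_forward=ftm,
        tm_reverse=rtm,
        gc_forward=fgc,
        gc_reverse=rgc,
        expected_product_bp=product,
        forward_start=fstart,
        reverse_end=rstart + rlen,
        self_complementary=flagged,
        score=score,
    )
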