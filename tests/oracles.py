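"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (character loops, exhaustive
enumeration, hand-copied parameter tables) and shares no code path with the
implementations it checks.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# SSR scanning by explicit extension
# ---------------------------------------------------------------------------

def brute_force_ssr(seq: str, thresholds: dict[int, int]):
    """Every maximal perfect tandem run, by per-position extension.

    Returns a set of (start, end, motif_as_found, repeat_count) with the run
    anchored at the leftmost position of its match run, whole copies only,
    primitive units only, N matching nothing.
    """

    def valid(i: int) -> bool:
        return seq[i] in "ACGT"

    def match(i: int, k: int) -> bool:
        return i + k < len(seq) and valid(i) and valid(i + k) and seq[i] == seq[i + k]

    def primitive(unit: str) -> bool:
        n = len(unit)
        return not any(n % d == 0 and unit == unit[:d] * (n // d) for d in range(1, n))

    found = set()
    n = len(seq)
    for k, thr in thresholds.items():
        for i in range(n - k):
            if i > 0 and match(i - 1, k):
                continue  # not the start of a match run
            if not match(i, k):
                continue
            unit = seq[i : i + k]
            if any(c not in "ACGT" for c in unit):
                continue
            count = 1
            while seq[i + count * k : i + (count + 1) * k] == unit:
                count += 1
            if count >= thr and primitive(unit):
                found.add((i, i + count * k, unit, count))
    return found


def canonical_by_enumeration(motif: str) -> str:
    """Minimum over explicitly listed rotations of motif and its revcomp."""
    forms = []
    for s in (motif, rc(motif)):
        for i in range(len(s)):
            forms.append(s[i:] + s[:i])
    return sorted(forms)[0]


# ---------------------------------------------------------------------------
# Electronic PCR by testing every position pair
# ---------------------------------------------------------------------------

def _matches_at(seq: str, pos: int, primer: str, max_mm: int,
                t: int, exact_at_end: bool) -> bool:
    m = len(primer)
    if pos < 0 or pos + m > len(seq):
        return False
    mm = 0
    for j in range(m):
        a = seq[pos + j]
        if a == primer[j] and a in "ACGT":
            continue
        in_exact_zone = (j >= m - t) if exact_at_end else (j < t)
        if in_exact_zone:
            return False
        mm += 1
        if mm > max_mm:
            return False
    return True


def naive_epcr(seq: str, fwd: str, rev: str, max_mm: int = 0,
               three_prime_exact: int = 3, min_product: int = 40,
               max_product: int = 5000):
    """Hit set {(start, end, strand)} by testing every site pair directly."""
    n = len(seq)
    lf, lr = len(fwd), len(rev)
    f_plus = [i for i in range(n - lf + 1)
              if _matches_at(seq, i, fwd, max_mm, three_prime_exact, True)]
    r_minus = [i for i in range(n - lr + 1)
               if _matches_at(seq, i, rc(rev), max_mm, three_prime_exact, False)]
    r_plus = [i for i in range(n - lr + 1)
              if _matches_at(seq, i, rev, max_mm, three_prime_exact, True)]
    f_minus = [i for i in range(n - lf + 1)
               if _matches_at(seq, i, rc(fwd), max_mm, three_prime_exact, False)]
    hits = set()
    for f in f_plus:
        for r in r_minus:
            product = r + lr - f
            if r >= f and min_product <= product <= max_product:
                hits.add((f, r + lr, "+"))
    for r in r_plus:
        for f in f_minus:
            product = f + lf - r
            if f >= r and min_product <= product <= max_product:
                hits.add((r, f + lf, "-"))
    return hits


# ---------------------------------------------------------------------------
# Nearest-neighbor Tm from the published unified parameter table
# ---------------------------------------------------------------------------

_NN_DH = {"AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2, "CA": -8.5,
          "TG": -8.5, "GT": -8.4, "AC": -8.4, "CT": -7.8, "AG": -7.8,
          "GA": -8.2, "TC": -8.2, "CG": -10.6, "GC": -9.8, "GG": -8.0,
          "CC": -8.0}
_NN_DS = {"AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3, "CA": -22.7,
          "TG": -22.7, "GT": -22.4, "AC": -22.4, "CT": -21.0, "AG": -21.0,
          "GA": -22.2, "TC": -22.2, "CG": -27.2, "GC": -24.4, "GG": -19.9,
          "CC": -19.9}


def hand_tm(seq: str, na: float = 0.05, conc: float = 250e-9) -> float:
    """Tm by hand-summed unified nearest-neighbor terms (kcal/mol, cal/mol/K)
    with terminal initiation penalties and entropic salt correction."""
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        if end in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    for i in range(len(seq) - 1):
        nn = seq[i : i + 2]
        dh += _NN_DH[nn]
        ds += _NN_DS[nn]
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    return 1000.0 * dh / (ds + 1.987 * math.log(conc)) - 273.15


# ---------------------------------------------------------------------------
# Collinear chaining by exhaustive enumeration
# ---------------------------------------------------------------------------

def _valid_step(a, b, orientation: str, max_gap: int) -> bool:
    if b.a_pos <= a.a_pos or b.a_pos - a.a_pos > max_gap:
        return False
    if orientation == "same":
        return a.b_pos < b.b_pos <= a.b_pos + max_gap
    return a.b_pos > b.b_pos >= a.b_pos - max_gap


def _enumerate_best(pool, orientation: str, max_gap: int):
    """Best chain (list of pool indices) by enumerating every valid chain."""
    n = len(pool)
    best: list[int] = []
    best_key = None

    def consider(chain):
        nonlocal best, best_key
        key = (-len(chain), tuple((pool[i].a_pos, pool[i].b_pos) for i in chain))
        if best_key is None or key < best_key:
            best_key = key
            best = list(chain)

    def dfs(chain):
        consider(chain)
        last = chain[-1] if chain else None
        for j in range((chain[-1] + 1) if chain else 0, n):
            if last is None or _valid_step(pool[last], pool[j], orientation, max_gap):
                chain.append(j)
                dfs(chain)
                chain.pop()

    dfs([])
    return best


def exhaustive_blocks(anchors, min_block: int = 5, max_gap: int = 25):
    """Greedy best-chain extraction with enumeration instead of DP.

    Returns a list of (orientation, tuple of (a_pos, b_pos)) in extraction
    order, mirroring the chaining contract exactly.
    """
    pool = sorted((a for a in anchors if not a.tandem),
                  key=lambda a: (a.a_pos, a.b_pos))
    blocks = []
    while pool:
        candidates = []
        for orientation in ("same", "inverted"):
            idx = _enumerate_best(pool, orientation, max_gap)
            key = (-len(idx), 0 if orientation == "same" else 1,
                   tuple((pool[i].a_pos, pool[i].b_pos) for i in idx))
            candidates.append((key, orientation, idx))
        key, orientation, idx = min(candidates)
        if len(idx) < min_block:
            break
        blocks.append(
            (orientation, tuple((pool[i].a_pos, pool[i].b_pos) for i in idx))
        )
        used = set(idx)
        pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


# ---------------------------------------------------------------------------
# Band distances by cell counting
# ---------------------------------------------------------------------------

def count_distance(row_i, row_j, coefficient: str) -> float:
    a = b = c = d = 0
    for x, y in zip(row_i, row_j):
        if x and y:
            a += 1
        elif x:
            b += 1
        elif y:
            c += 1
        else:
            d += 1
    n = a + b + c + d
    if coefficient == "dice":
        return 1.0 - 2 * a / (2 * a + b + c) if (2 * a + b + c) else 1.0
    if coefficient == "jaccard":
        return 1.0 - a / (a + b + c) if (a + b + c) else 1.0
    return 1.0 - (a + d) / n
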