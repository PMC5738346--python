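import itertools

import numpy as np
import pytest
from hypothesis import strategies as st

from conftest import make_genome, random_sequence
from oracles import naive_epcr, rc
from treemarker.insilico_pcr import (
    EPCRParams,
    Marker,
    classify_polymorphism,
    deduplicate,
    epcr,
    universal_screen,
    validate_marker,
)
from treemarker.primer_design import PrimerPair, gc_fraction


def _pair(fwd, rev, product=None):
    return PrimerPair(
        forward=fwd, reverse=rev,
        tm_forward=0.0, tm_reverse=0.0,
        gc_forward=gc_fraction(fwd), gc_reverse=gc_fraction(rev),
        expected_product_bp=product or 0,
    )


def _marker(fwd, rev, seq_id="s1", start=0, end=0, mid="m1", product=None,
            species="test", status="candidate"):
    return Marker(
        marker_id=mid, type="SSR", species_id=species, seq_id=seq_id,
        start=start, end=end, primers=_pair(fwd, rev, product), status=status,
    )


F = "ACGGTTACCAGTTACGGATC"
R = "TTACGGATCCAGGTTACAGG"   # written 5'->3' on the opposite strand


def _cassette(rng, insert=100):
    return F + random_sequence(rng, insert) + rc(R)


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

def test_single_planted_cassette_hit(rng):
    cassette = _cassette(rng)
    genome = make_genome(random_sequence(rng, 500) + cassette + random_sequence(rng, 500))
    hits = epcr(_marker(F, R), genome)
    assert len(hits) == 1
    h = hits[0]
    assert h.product_bp == len(F) + 100 + len(R)
    assert h.strand == "+"
    assert genome.records[0].sequence[h.start : h.start + len(F)] == F


def test_cassette_on_two_scaffolds_two_hits(rng):
    cassette = _cassette(rng)
    genome = make_genome(
        random_sequence(rng, 300) + cassette + random_sequence(rng, 300),
        random_sequence(rng, 200) + cassette + random_sequence(rng, 200),
    )
    hits = epcr(_marker(F, R), genome)
    assert len(hits) == 2
    assert {h.seq_id for h in hits} == {"s1", "s2"}


def test_reverse_complemented_cassette_reported_on_minus_strand(rng):
    cassette = _cassette(rng)
    genome = make_genome(random_sequence(rng, 300) + rc(cassette) + random_sequence(rng, 300))
    hits = epcr(_marker(F, R), genome)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].product_bp == len(cassette)


def test_three_prime_terminal_mismatch_kills_hit(rng):
    bad_f = F[:-1] + ("A" if F[-1] != "A" else "C")
    cassette = bad_f + random_sequence(rng, 100) + rc(R)
    genome = make_genome(random_sequence(rng, 300) + cassette + random_sequence(rng, 300))
    params = EPCRParams(max_mismatches=1)
    assert epcr(_marker(F, R), genome, params) == []
    # the same mismatch away from the 3' end is tolerated at max_mismatches=1
    bad_f5 = ("A" if F[0] != "A" else "C") + F[1:]
    cassette = bad_f5 + random_sequence(rng, 100) + rc(R)
    genome = make_genome(random_sequence(rng, 300) + cassette + random_sequence(rng, 300))
    assert len(epcr(_marker(F, R), genome, params)) == 1
    assert epcr(_marker(F, R), genome, EPCRParams(max_mismatches=0)) == []


def test_n_matches_nothing(rng):
    cassette = _cassette(rng)
    mid = 300 + len(F) // 2
    seq = random_sequence(rng, 300) + cassette + random_sequence(rng, 300)
    broken = seq[:mid] + "N" + seq[mid + 1 :]
    genome = make_genome(broken)
    assert epcr(_marker(F, R), genome, EPCRParams(max_mismatches=0)) == []


def test_product_size_limits(rng):
    cassette = F + random_sequence(rng, 100) + rc(R)
    genome = make_genome(random_sequence(rng, 200) + cassette + random_sequence(rng, 200))
    marker = _marker(F, R)
    assert len(epcr(marker, genome, EPCRParams(max_product=100))) == 0
    assert len(epcr(marker, genome, EPCRParams(min_product=500))) == 0


def _hit_tuples(hits):
    return {(h.start, h.end, h.strand) for h in hits}


def test_epcr_equals_naive_oracle_on_random_genomes(rng):
    """Planted + mutated cassettes on 10-kb genomes, exact hit-set equality
    against the all-positions oracle, with and without mismatch tolerance."""
    for trial in range(12):
        seq = random_sequence(rng, 10_000)
        inserts = []
        for _ in range(3):
            pos = int(rng.integers(0, 9_000))
            cassette = _cassette(rng, insert=int(rng.integers(20, 300)))
            if rng.random() < 0.5:
                cassette = rc(cassette)
            seq = seq[:pos] + cassette + seq[pos + len(cassette):]
        # sprinkle point mutations to exercise the mismatch path
        chars = list(seq)
        for pos in rng.integers(0, len(chars), size=30):
            chars[pos] = "ACGT"[int(rng.integers(4))]
        seq = "".join(chars)
        for mm in (0, 1, 2):
            params = EPCRParams(max_mismatches=mm)
            got = _hit_tuples(epcr(_marker(F, R), make_genome(seq), params))
            expected = naive_epcr(seq, F, R, max_mm=mm)
            assert got == expected, f"trial {trial}, mm={mm}"


def test_epcr_hit_cap(rng):
    seq = ("".join([F + "ACGT" * 10 + rc(R)]) * 30) + random_sequence(rng, 200)
    genome = make_genome(seq)
    params = EPCRParams(max_hits_per_seq=10)
    hits = epcr(_marker(F, R), genome, params)
    assert len(hits) == 10


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def test_marker_from_own_flanks_validates(small_fixture):
    from treemarker.ssr_mining import design_ssr_markers, scan_genome

    fx = small_fixture
    loci = scan_genome(fx.genome)
    markers = design_ssr_markers(fx.genome, loci)
    assert markers
    for m in markers[:20]:
        assert validate_marker(m, fx.genome).status == "validated"


def test_swapped_primers_rejected(small_fixture):
    from treemarker.ssr_mining import design_ssr_markers, scan_genome

    fx = small_fixture
    markers = design_ssr_markers(fx.genome, scan_genome(fx.genome))
    a, b = markers[0], markers[1]
    swapped = Marker(
        marker_id="swap", type="SSR", species_id=a.species_id,
        seq_id=a.seq_id, start=a.start, end=a.end,
        primers=_pair(a.primers.forward, b.primers.reverse,
                      a.primers.expected_product_bp),
    )
    out = validate_marker(swapped, fx.genome)
    assert out.status == "rejected"


def test_off_target_only_marker_rejected_but_hits_recorded(rng):
    cassette = _cassette(rng)
    seq = random_sequence(rng, 400) + cassette + random_sequence(rng, 400)
    genome = make_genome(seq)
    # marker claims a source locus far from where the cassette actually sits
    marker = _marker(F, R, start=10, end=30, product=len(cassette))
    out = validate_marker(marker, genome)
    assert out.status == "rejected"
    assert out.reject_reason == "no on-target product"
    assert len(epcr(marker, genome)) == 1  # the off-target hit is observable


def test_validation_requires_product_near_expected(rng):
    cassette = _cassette(rng, insert=100)
    pos = 400
    seq = random_sequence(rng, pos) + cassette + random_sequence(rng, 400)
    genome = make_genome(seq)
    start = pos + len(F)
    marker_ok = _marker(F, R, start=start, end=start + 100,
                        product=len(cassette))
    assert validate_marker(marker_ok, genome).status == "validated"
    marker_wrong = _marker(F, R, start=start, end=start + 100,
                           product=3 * len(cassette))
    assert validate_marker(marker_wrong, genome).status == "rejected"


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _mk(mid, fwd, rev, seq_id="s1", start=0):
    return _marker(fwd, rev, seq_id=seq_id, start=start, mid=mid)


def test_dedup_shared_forward_collapses():
    a = _mk("a", "ACGTACGTACGTACGTACGT", "TTTTGGGGCCCCAAAAACGT", start=10)
    b = _mk("b", "ACGTACGTACGTACGTACGT", "GGGGTTTTCCCCAAAAACGT", start=50)
    kept = deduplicate([a, b])
    assert [m.marker_id for m in kept] == ["a"]  # smallest (seq, start) wins


def test_dedup_transitive_closure_matches_brute_force(rng):
    # A shares forward with B; B shares reverse with C -> one survivor
    a = _mk("a", "AAAACCCCGGGGTTTTACGT", "ACGTACGTACGTACGTAAAA", start=1)
    b = _mk("b", "AAAACCCCGGGGTTTTACGT", "CCCCGGGGAAAATTTTACGT", start=2)
    c = _mk("c", "TTTTAAAACCCCGGGGACGT", "CCCCGGGGAAAATTTTACGT", start=3)
    d = _mk("d", "GGGGAAAATTTTCCCCACGT", "AAAATTTTGGGGCCCCACGT", start=4)
    kept = deduplicate([a, b, c, d])
    assert {m.marker_id for m in kept} == {"a", "d"}

    # brute-force closure on random small sets
    pool_f = [random_sequence(rng, 20) for _ in range(5)]
    pool_r = [random_sequence(rng, 20) for _ in range(5)]
    for trial in range(30):
        n = int(rng.integers(2, 9))
        markers = [
            _mk(f"m{i}", pool_f[int(rng.integers(5))],
                pool_r[int(rng.integers(5))], start=i)
            for i in range(n)
        ]
        kept = deduplicate(markers)
        # oracle: iterate pairwise merging until fixed point
        groups = [{i} for i in range(n)]
        changed = True
        while changed:
            changed = False
            for g1, g2 in itertools.combinations(list(groups), 2):
                if g1 not in groups or g2 not in groups:
                    continue
                if any(
                    markers[i].primers.forward == markers[j].primers.forward
                    or markers[i].primers.reverse == markers[j].primers.reverse
                    for i in g1 for j in g2
                ):
                    groups.remove(g1)
                    groups.remove(g2)
                    groups.append(g1 | g2)
                    changed = True
        assert len(kept) == len(groups)


def test_dedup_identity_when_all_distinct(rng):
    markers = [
        _mk(f"m{i}", random_sequence(rng, 20), random_sequence(rng, 20), start=i)
        for i in range(10)
    ]
    assert len(deduplicate(markers)) == 10


def test_dedup_idempotent_and_order_insensitive(rng):
    markers = [
        _mk("a", "AAAACCCCGGGGTTTTACGT", "ACGTACGTACGTACGTAAAA", start=1),
        _mk("b", "AAAACCCCGGGGTTTTACGT", "CCCCGGGGAAAATTTTACGT", start=2),
        _mk("c", random_sequence(rng, 20), random_sequence(rng, 20), start=3),
    ]
    once = deduplicate(markers)
    assert deduplicate(once) == once
    assert deduplicate(markers[::-1]) == once


# ---------------------------------------------------------------------------
# Polymorphism and universality screens
# ---------------------------------------------------------------------------

def test_classify_polymorphism_by_copy_number(rng):
    cassette = _cassette(rng)
    single = make_genome(random_sequence(rng, 300) + cassette + random_sequence(rng, 300))
    marker = _marker(F, R, status="validated")
    n, label = classify_polymorphism(marker, single)
    assert (n, label) == (1, "monomorphic")
    triple = make_genome(
        random_sequence(rng, 200) + cassette + random_sequence(rng, 6000)
        + cassette + random_sequence(rng, 6000) + cassette + random_sequence(rng, 200)
    )
    n, label = classify_polymorphism(marker, triple)
    assert (n, label) == (3, "polymorphic")


def test_zero_hits_on_validated_marker_is_inconsistency(rng):
    genome = make_genome(random_sequence(rng, 500))
    marker = _marker(F, R, status="validated")
    with pytest.raises(RuntimeError):
        classify_polymorphism(marker, genome)


def test_universal_screen_exact_recovery(rng):
    cassettes = [_cassette(rng) for _ in range(3)]
    pairs = [(F, R)]
    for i in range(2):
        f2, r2 = random_sequence(rng, 20), random_sequence(rng, 20)
        pairs.append((f2, r2))
        cassettes[i + 1] = f2 + random_sequence(rng, 80) + rc(r2)
    # genome A holds all cassettes; B and C miss the last one
    def build(*cs):
        seq = random_sequence(rng, 200)
        for c in cs:
            seq += c + random_sequence(rng, 200)
        return seq
    ga = make_genome(build(*cassettes), species_id="A")
    gb = make_genome(build(*cassettes[:2]), species_id="B")
    gc_ = make_genome(build(*cassettes[:2]), species_id="C")
    markers = [_marker(f, r, mid=f"m{i}") for i, (f, r) in enumerate(pairs)]
    kept, counts = universal_screen(markers, [ga, gb, gc_])
    assert [m.marker_id for m in kept] == ["m0", "m1"]
    assert counts.loc["m2", "A"] == 1 and counts.loc["m2", "B"] == 0


def test_universal_screen_single_genome_equals_amplifying_markers(rng):
    cassette = _cassette(rng)
    genome = make_genome(random_sequence(rng, 200) + cassette + random_sequence(rng, 200))
    hitter = _marker(F, R, mid="hit")
    misser = _marker(random_sequence(rng, 20), random_sequence(rng, 20), mid="miss")
    kept, _ = universal_screen([hitter, misser], [genome])
    assert [m.marker_id for m in kept] == ["hit"]
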