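import numpy as np
import pandas as pd
import pytest

import dendropy

from oracles import count_distance
from treemarker.insilico_pcr import AmpliconHit
from treemarker.phylo import (
    BandMatrix,
    band_distance,
    bands_from_hits,
    bootstrap_support,
    clades,
    to_newick,
    upgma,
)


# ---------------------------------------------------------------------------
# Band scoring
# ---------------------------------------------------------------------------

def test_bands_binning_merges_products_within_gel_resolution():
    hits = {
        "w1": {"m1": [150]},
        "w2": {"m1": [152]},
        "w3": {"m1": [160]},
    }
    bm = bands_from_hits(hits, bin_width=5)
    assert bm.values[:2, :].tolist()[0] == bm.values[:2, :].tolist()[1]
    assert len(bm.band_ids) == 2  # 150/152 share a bin; 160 differs


def test_bands_accept_amplicon_hits():
    h = AmpliconHit("sp", "s1", 100, 250, "+")
    bm = bands_from_hits({"w1": {"m1": [h]}, "w2": {"m1": []}})
    assert bm.values.tolist() == [[1], [0]]


def test_band_matrix_validation():
    with pytest.raises(ValueError, match="0 or 1"):
        BandMatrix(("a", "b"), ("x",), np.array([[2], [0]]))
    with pytest.raises(ValueError, match="duplicate"):
        BandMatrix(("a", "a"), ("x",), np.array([[1], [0]]))


def test_band_matrix_tsv_round_trip(tmp_path):
    bm = bands_from_hits({"w1": {"m1": [150, 200]}, "w2": {"m1": [150]}})
    p = tmp_path / "bands.tsv"
    bm.write_tsv(p)
    back = BandMatrix.read_tsv(p)
    assert back.sample_ids == bm.sample_ids
    assert back.band_ids == bm.band_ids
    assert (back.values == bm.values).all()


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def test_dice_hand_example():
    bm = BandMatrix(("s1", "s2"), ("a", "b", "c"), np.array([[1, 1, 0], [1, 0, 1]]))
    assert band_distance(bm, "dice").iloc[0, 1] == pytest.approx(0.5)


def test_identical_rows_distance_zero():
    bm = BandMatrix(("s1", "s2"), ("a", "b"), np.array([[1, 0], [1, 0]]))
    for coeff in ("dice", "simple_matching", "jaccard"):
        d = band_distance(bm, coeff)
        assert d.iloc[0, 1] == 0.0
        assert d.iloc[0, 0] == 0.0


@pytest.mark.parametrize("coefficient", ["dice", "simple_matching", "jaccard"])
def test_distances_match_cell_counting_oracle(coefficient, rng):
    for _ in range(20):
        vals = rng.integers(0, 2, size=(5, 8))
        if coefficient in ("dice", "jaccard") and (vals.sum(axis=1) == 0).any():
            vals[:, 0] = 1  # avoid the undefined all-zero case here
        bm = BandMatrix(tuple(f"s{i}" for i in range(5)),
                        tuple(f"b{j}" for j in range(8)), vals)
        d = band_distance(bm, coefficient)
        assert np.allclose(d, d.T)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else count_distance(
                    vals[i], vals[j], coefficient)
                assert d.iloc[i, j] == pytest.approx(expected)


def test_all_zero_sample_flagged_under_dice():
    bm = BandMatrix(("s1", "s2"), ("a", "b"), np.array([[0, 0], [1, 0]]))
    with pytest.warns(UserWarning, match="undefined"):
        d = band_distance(bm, "dice")
    assert d.iloc[0, 1] == 1.0


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def _dist(labels, rows):
    return pd.DataFrame(np.array(rows, dtype=float), index=labels, columns=labels)


def test_upgma_textbook_three_taxa():
    d = _dist(list("ABC"), [[0, 2, 4], [2, 0, 4], [4, 4, 0]])
    tree = upgma(d)
    assert tree.height == pytest.approx(2.0)
    assert clades(tree) == {frozenset({"A", "B"})}
    inner = next(n for n in tree.walk() if not n.is_leaf and n is not tree)
    assert inner.height == pytest.approx(1.0)


def test_upgma_equal_distances_resolved_by_tie_break():
    d = _dist(list("ABCD"), [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]])
    tree = upgma(d)
    heights = [n.height for n in tree.walk() if not n.is_leaf]
    assert all(h == pytest.approx(0.5) for h in heights)
    # deterministic: first merge joins the lexicographically smallest pair
    assert frozenset({"A", "B"}) in clades(tree)
    assert to_newick(upgma(d)) == to_newick(tree)


def test_upgma_recovers_random_ultrametric_tree(rng):
    """Distances generated from a random ultrametric tree invert exactly."""
    for _ in range(10):
        n = 8
        labels = [f"t{i}" for i in range(n)]
        heights = {}
        groups = [{l} for l in labels]
        height = 0.0
        merges = []
        while len(groups) > 1:
            height += float(rng.uniform(0.1, 1.0))
            i, j = sorted(rng.choice(len(groups), size=2, replace=False))
            merges.append((set(groups[i]), set(groups[j]), height))
            groups[i] = groups[i] | groups[j]
            del groups[j]
        d = np.zeros((n, n))
        for a, b, h in merges:
            for x in a:
                for y in b:
                    xi, yi = labels.index(x), labels.index(y)
                    d[xi, yi] = d[yi, xi] = 2 * h
        tree = upgma(_dist(labels, d))
        got = {frozenset(n_.leaves): n_.height for n_ in tree.walk()
               if not n_.is_leaf}
        expected = {frozenset(a | b): h for a, b, h in merges}
        assert got == pytest.approx(expected)


def test_upgma_ultrametricity_on_random_matrices(rng):
    for _ in range(25):
        n = int(rng.integers(3, 10))
        m = rng.uniform(0.1, 2.0, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma(d, labels=[f"x{i}" for i in range(n)])

        def depths(node, acc=0.0):
            if node.is_leaf:
                yield acc + node.height
            for c in node.children:
                yield from depths(c, acc + (node.height - c.height))

        # root-to-leaf path lengths are all equal
        root_depths = []
        def walk_depth(node, dist):
            if node.is_leaf:
                root_depths.append(dist)
            for c in node.children:
                walk_depth(c, dist + node.height - c.height)
        walk_depth(tree, 0.0)
        assert max(root_depths) - min(root_depths) < 1e-9
        # node heights never decrease toward the root
        for node in tree.walk():
            for c in node.children:
                assert node.height >= c.height - 1e-12


def test_upgma_label_permutation_invariance(rng):
    n = 7
    m = rng.uniform(0.1, 2.0, size=(n, n))
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"s{i}" for i in range(n)]
    t1 = upgma(_dist(labels, d))
    perm = list(rng.permutation(n))
    d2 = d[np.ix_(perm, perm)]
    t2 = upgma(_dist([labels[i] for i in perm], d2))
    assert clades(t1) == clades(t2)


def test_upgma_matches_scipy_average_linkage(rng):
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    for _ in range(10):
        n = 9
        m = rng.uniform(0.1, 2.0, size=(n, n))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = upgma(d, labels=[str(i) for i in range(n)])
        Z = average(squareform(d))
        got = sorted(n_.height for n_ in tree.walk() if not n_.is_leaf)
        expected = sorted(Z[:, 2] / 2)
        assert got == pytest.approx(expected)


def test_upgma_input_validation():
    with pytest.raises(ValueError, match="symmetric"):
        upgma(np.array([[0, 1.0], [2.0, 0]]), labels=["a", "b"])
    with pytest.raises(ValueError, match="negative"):
        upgma(np.array([[0, -1.0], [-1.0, 0]]), labels=["a", "b"])


def test_newick_round_trips_through_dendropy():
    d = _dist(list("ABCD"), [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]])
    newick = to_newick(upgma(d))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    assert taxa == set("ABCD")
    # branch lengths survive: both cherries sit at depth 1, root at 3
    depths = {l.taxon.label: l.distance_from_root() for l in tree.leaf_node_iter()}
    assert all(v == pytest.approx(3.0) for v in depths.values())


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _clade_matrix(rng, n_noise=12):
    samples = tuple(f"w{i:02d}" for i in range(8))
    vals = np.zeros((8, 10 + 6 + n_noise), dtype=int)
    vals[:4, :10] = 1                        # ten clade-private bands
    vals[:, 10:16] = 1                       # shared, uninformative
    vals[:, 16:] = rng.integers(0, 2, size=(8, n_noise))
    bands = tuple(f"b{j}" for j in range(vals.shape[1]))
    return BandMatrix(samples, bands, vals), frozenset(samples[:4])


def test_bootstrap_support_range_and_seeding(rng):
    bm, _ = _clade_matrix(rng)
    t1 = bootstrap_support(bm, replicates=50, seed=9)
    t2 = bootstrap_support(bm, replicates=50, seed=9)
    s1 = {n.leaves: n.support for n in t1.walk() if not n.is_leaf}
    s2 = {n.leaves: n.support for n in t2.walk() if not n.is_leaf}
    assert s1 == s2
    assert all(s is None or 0.0 <= s <= 100.0 for s in s1.values())
    t3 = bootstrap_support(bm, replicates=1, seed=1)
    assert t3 is not None  # single-replicate contract


def test_planted_clade_gets_high_support(rng):
    bm, clade = _clade_matrix(rng)
    tree = bootstrap_support(bm, replicates=300, seed=3)
    support = {n.leaves: n.support for n in tree.walk() if not n.is_leaf}
    assert support[clade] >= 95.0
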