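"""Dominant-marker diversity analysis.

Band presence/absence matrices (samples x bands, 0/1) are turned into a
pairwise distance matrix (Dice/Nei-Li by default, simple matching and Jaccard
selectable), clustered by UPGMA into an ultrametric rooted tree, and given
bootstrap support by resampling band columns.  Trees serialise to Newick with
branch lengths and support as internal-node labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BandMatrix:
    """Samples x bands 0/1 matrix with unique, ordered identifiers."""

    sample_ids: tuple[str, ...]
    band_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.band_ids)) != len(self.band_ids):
            raise ValueError("duplicate band ids")
        v = np.asarray(self.values)
        if v.shape != (len(self.sample_ids), len(self.band_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("band matrix cells must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.uint8))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.band_ids))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BandMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy())


def bands_from_hits(
    hits: Mapping[str, Mapping[str, Iterable]],
    bin_width: int = 5,
) -> BandMatrix:
    """Score amplicon products into gel-resolution band bins.

    *hits* maps sample -> marker -> iterable of products (either
    :class:`~treemarker.insilico_pcr.AmpliconHit` objects or plain product
    sizes in bp).  Each (marker, size bin) becomes a band column with bin
    edges at multiples of *bin_width*; a cell is 1 iff the sample has at
    least one product in that bin.
    """
    samples = sorted(hits)
    cells: dict[str, set[str]] = {s: set() for s in samples}
    band_ids: set[str] = set()
    for sample, by_marker in hits.items():
        for marker, products in by_marker.items():
            for p in products:
                size = p if isinstance(p, int) else p.product_bp
                b = (size // bin_width) * bin_width
                band = f"{marker}:{b}-{b + bin_width}"
                band_ids.add(band)
                cells[sample].add(band)
    bands = sorted(band_ids)
    values = np.zeros((len(samples), len(bands)), dtype=np.uint8)
    col = {b: j for j, b in enumerate(bands)}
    for i, s in enumerate(samples):
        for band in cells[s]:
            values[i, col[band]] = 1
    return BandMatrix(tuple(samples), tuple(bands), values)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

COEFFICIENTS = ("dice", "simple_matching", "jaccard")


def band_distance(matrix: BandMatrix, coefficient: str = "dice") -> pd.DataFrame:
    """Pairwise distances from shared/private band counts.

    With a = shared presences, b/c = private presences, d = shared absences,
    n = bands: dice = 1 - 2a/(2a+b+c); simple_matching = 1 - (a+d)/n;
    jaccard = 1 - a/(a+b+c).  Pairs undefined under dice/jaccard (no
    presences in either sample) are flagged with a warning and set to the
    maximal distance 1.
    """
    if coefficient not in COEFFICIENTS:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    v = matrix.values.astype(np.int64)
    s, n_bands = v.shape
    if s < 2:
        raise ValueError("at least 2 samples required")
    a = v @ v.T
    ones = v.sum(axis=1)
    si = ones[:, None] + ones[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        if coefficient == "dice":
            dist = 1.0 - 2.0 * a / si
        elif coefficient == "jaccard":
            denom = si - a
            dist = 1.0 - a / denom
        else:
            d = (1 - v) @ (1 - v).T
            dist = 1.0 - (a + d) / n_bands
    if coefficient in ("dice", "jaccard"):
        # a sample with no bands has no defined similarity to anything
        empty = ones == 0
        undef = empty[:, None] | empty[None, :]
        np.fill_diagonal(undef, False)
        if undef.any():
            warnings.warn(
                f"{int(undef.sum()) // 2} sample pair(s) undefined under "
                f"{coefficient} (sample without bands); distance set to 1.0",
                stacklevel=2,
            )
            dist[undef] = 1.0
        dist = np.nan_to_num(dist, nan=1.0)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=list(matrix.sample_ids),
                        columns=list(matrix.sample_ids))


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class CladeNode:
    """Rooted ultrametric tree node; leaves carry names, internals heights."""

    height: float
    children: tuple["CladeNode", ...] = ()
    name: str = ""
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset((self.name,))
        return frozenset().union(*(c.leaves for c in self.children))

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


def upgma(dist: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> CladeNode:
    """Agglomerate by arithmetic-mean linkage; merge height = distance / 2.

    The distance update is cluster-size weighted, so heights are exact mean
    pairwise leaf distances.  Ties break deterministically to the pair whose
    merged leaf set sorts lexicographically smallest.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(d))]
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if (d < 0).any():
        raise ValueError("negative distances")
    if n == 1:
        return CladeNode(0.0, name=labels[0])

    nodes = {i: CladeNode(0.0, name=labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    leafsets = {i: (labels[i],) for i in range(n)}
    D: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            ((D[(min(i, j), max(i, j))], tuple(sorted(leafsets[i] + leafsets[j])), (i, j))
             for i in active for j in active if i < j),
            key=lambda t: (t[0], t[1]),
        )
        dij, _, (i, j) = best
        h = dij / 2.0
        merged = CladeNode(h, children=(nodes[i], nodes[j]))
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = D[(min(i, k), max(i, k))]
            djk = D[(min(j, k), max(j, k))]
            D[(min(next_id, k), max(next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        active -= {i, j}
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        leafsets[next_id] = tuple(sorted(leafsets[i] + leafsets[j]))
        active.add(next_id)
        next_id += 1
    return nodes[next_id - 1]


def clades(tree: CladeNode) -> set[frozenset[str]]:
    """Non-trivial clade leaf sets (internal nodes below the root included)."""
    all_leaves = tree.leaves
    out = set()
    for node in tree.walk():
        if not node.is_leaf:
            ls = node.leaves
            if 1 < len(ls) < len(all_leaves):
                out.add(ls)
    return out


def to_newick(tree: CladeNode, include_support: bool = True, digits: int = 6) -> str:
    """Newick with branch lengths; support values label internal nodes."""

    def fmt(x: float) -> str:
        return f"{x:.{digits}g}"

    def render(node: CladeNode, parent_height: float) -> str:
        bl = fmt(parent_height - node.height)
        if node.is_leaf:
            return f"{node.name}:{bl}"
        inner = ",".join(render(c, node.height) for c in node.children)
        label = ""
        if include_support and node.support is not None:
            label = fmt(node.support)
        return f"({inner}){label}:{bl}"

    if tree.is_leaf:
        return f"{tree.name};"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    label = fmt(tree.support) if include_support and tree.support is not None else ""
    return f"({inner}){label};"


def bootstrap_support(
    matrix: BandMatrix,
    replicates: int = 1000,
    seed: int = 0,
    coefficient: str = "dice",
) -> CladeNode:
    """Column-resampling bootstrap; support mapped onto the full-data tree.

    Band columns are resampled with replacement per replicate, the tree is
    rebuilt, and each internal node of the full-data tree gets the percentage
    of replicate trees containing the same leaf clade.  Seeded and
    reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = upgma(band_distance(matrix, coefficient))
        rng = np.random.default_rng(seed)
        counts: dict[frozenset[str], int] = {c: 0 for c in clades(full)}
        b = len(matrix.band_ids)
        for _ in range(replicates):
            cols = rng.integers(0, b, size=b)
            rep = BandMatrix(
                matrix.sample_ids,
                tuple(f"b{i}" for i in range(b)),
                matrix.values[:, cols],
            )
            rep_clades = clades(upgma(band_distance(rep, coefficient)))
            for c in counts:
                if c in rep_clades:
                    counts[c] += 1
    for node in full.walk():
        if not node.is_leaf:
            ls = node.leaves
            if ls in counts:
                node.support = 100.0 * counts[ls] / replicates
    return full
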