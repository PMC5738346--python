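"""Marker distribution statistics: density per Mb, SSR/ILP concomitance,
and BED track export for genome browsers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import SeqRecordRef, write_bed

Interval = tuple[str, int, int]


@dataclass
class DensityProfile:
    """Windowed marker counts and the overall density (loci per Mb)."""

    seq_id: str
    length: int
    window: int
    counts: np.ndarray
    n: int

    @property
    def density_per_mb(self) -> float:
        return self.n * 1e6 / self.length

    @property
    def density_rounded(self) -> int:
        return round(self.density_per_mb)


def density(
    intervals: Iterable[tuple[int, int] | Interval],
    record: SeqRecordRef,
    window: int = 100_000,
) -> DensityProfile:
    """Per-window counts (by interval start) and overall density for one scaffold.

    Accepts (start, end) or (seq_id, start, end) items; in the latter form
    only items on *record* are counted.
    """
    if record.length == 0:
        raise ValueError(f"zero-length record {record.seq_id!r}")
    starts = []
    for item in intervals:
        if len(item) == 3:
            if item[0] != record.seq_id:
                continue
            starts.append(item[1])
        else:
            starts.append(item[0])
    n_windows = max(1, -(-record.length // window))
    counts = np.zeros(n_windows, dtype=int)
    for s in starts:
        if not 0 <= s < record.length:
            raise ValueError(f"interval start {s} outside record {record.seq_id!r}")
        counts[s // window] += 1
    return DensityProfile(record.seq_id, record.length, window, counts, len(starts))


@dataclass(frozen=True)
class ConcomitanceResult:
    """Counts of concomitant (>=1 shared base) and separated SSR/ILP markers."""

    n_ssr: int
    n_ilp: int
    n_concomitant: int       # SSR markers overlapping at least one ILP interval
    n_ilp_concomitant: int   # ILP markers overlapping at least one SSR interval

    @property
    def n_ssr_only(self) -> int:
        return self.n_ssr - self.n_concomitant

    @property
    def n_ilp_only(self) -> int:
        return self.n_ilp - self.n_ilp_concomitant

    @property
    def rate(self) -> float:
        return self.n_concomitant / self.n_ssr if self.n_ssr else 0.0


def _merge(intervals: Sequence[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for seq_id, start, end in intervals:
        per_seq.setdefault(seq_id, []).append((start, end))
    merged = {}
    for seq_id, ivals in per_seq.items():
        ivals.sort()
        out: list[list[int]] = []
        for s, e in ivals:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[seq_id] = (
            np.array([s for s, _ in out]),
            np.array([e for _, e in out]),
        )
    return merged


def _count_overlapping(queries: Sequence[Interval], targets: Sequence[Interval]) -> int:
    merged = _merge(targets)
    hit = 0
    for seq_id, start, end in queries:
        if seq_id not in merged:
            continue
        starts, ends = merged[seq_id]
        i = int(np.searchsorted(starts, end, side="left")) - 1
        # candidate is the rightmost merged interval starting before `end`
        if i >= 0 and ends[i] > start:
            hit += 1
    return hit


def concomitance(
    ssr_intervals: Sequence[Interval], ilp_intervals: Sequence[Interval]
) -> ConcomitanceResult:
    """Overlap bookkeeping between SSR and ILP marker intervals.

    Intervals are 0-based half-open (seq_id, start, end); markers touching
    only at a boundary share no base and count as separated.
    """
    return ConcomitanceResult(
        n_ssr=len(ssr_intervals),
        n_ilp=len(ilp_intervals),
        n_concomitant=_count_overlapping(ssr_intervals, ilp_intervals),
        n_ilp_concomitant=_count_overlapping(ilp_intervals, ssr_intervals),
    )


def export_tracks(
    markers_by_type: Mapping[str, Sequence], out_dir: str | Path
) -> dict[str, Path]:
    """One BED6 file per marker type; names carry the marker id."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for mtype, markers in markers_by_type.items():
        rows = [
            (m.seq_id, m.start, m.end, m.marker_id, "+") for m in markers
        ]
        path = out_dir / f"{mtype.lower()}_markers.bed"
        write_bed(rows, path)
        paths[mtype] = path
    return paths
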