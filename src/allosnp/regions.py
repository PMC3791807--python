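"""Coverage-qualified genomic intervals and their intersection.

The first step of the analysis restricts every downstream comparison to
positions that are adequately covered in *both* samples: a variant seen with
good depth in the polyploid but poorly covered in the diploid (or vice
versa) cannot be interpreted and is excluded.  Intervals are 1-based
inclusive; contig names are matched by exact string equality.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import DepthTrack


@dataclass
class RegionSet:
    """Per-contig sorted lists of disjoint, non-adjacent [start, end] intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: dict[str, list[tuple[int, int]]]) -> "RegionSet":
        """Normalize arbitrary interval lists: sort, merge overlaps and adjacency."""
        out: dict[str, list[tuple[int, int]]] = {}
        for contig, ivs in intervals.items():
            merged: list[tuple[int, int]] = []
            for start, end in sorted(ivs):
                if start > end:
                    raise ValueError(f"{contig}: interval start {start} > end {end}")
                if merged and start <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            if merged:
                out[contig] = merged
        return cls(out)

    def contigs(self) -> list[str]:
        return list(self.intervals)

    def __bool__(self) -> bool:
        return any(self.intervals.values())


def covered_intervals(track: DepthTrack, min_depth: int) -> RegionSet:
    """Maximal runs of positions with depth >= ``min_depth`` on one contig."""
    if min_depth < 1:
        raise ValueError(f"min_depth must be >= 1, got {min_depth}")
    mask = track.depths >= min_depth
    pos = track.positions[mask]
    if len(pos) == 0:
        return RegionSet({})
    breaks = np.flatnonzero(np.diff(pos) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(pos) - 1]])
    ivs = [(int(pos[s]), int(pos[e])) for s, e in zip(starts, ends)]
    return RegionSet({track.contig: ivs})


def coverage_regions(tracks: dict[str, DepthTrack], min_depth: int) -> RegionSet:
    """Union of per-contig covered intervals over a whole sample."""
    out: dict[str, list[tuple[int, int]]] = {}
    for contig, track in tracks.items():
        rs = covered_intervals(track, min_depth)
        if contig in rs.intervals:
            out[contig] = rs.intervals[contig]
    return RegionSet(out)


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    """Positions covered in both region sets; contigs missing from either side drop out."""
    out: dict[str, list[tuple[int, int]]] = {}
    for contig in a.intervals:
        if contig not in b.intervals:
            continue
        ia, ib = a.intervals[contig], b.intervals[contig]
        i = j = 0
        merged: list[tuple[int, int]] = []
        while i < len(ia) and j < len(ib):
            start = max(ia[i][0], ib[j][0])
            end = min(ia[i][1], ib[j][1])
            if start <= end:
                merged.append((start, end))
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
        if merged:
            out[contig] = merged
    return RegionSet(out)


def contains(r: RegionSet, contig: str, pos: int) -> bool:
    """True iff ``pos`` lies inside an interval of ``r`` on ``contig``."""
    ivs = r.intervals.get(contig)
    if not ivs:
        return False
    i = bisect_right(ivs, (pos, np.inf)) - 1
    return i >= 0 and ivs[i][0] <= pos <= ivs[i][1]


def total_positions(r: RegionSet) -> int:
    """Number of individual positions covered by the region set."""
    return sum(end - start + 1 for ivs in r.intervals.values() for start, end in ivs)


def restrict(r: RegionSet, contig: str, start: int, end: int) -> RegionSet:
    """Clip a region set to a single [start, end] window on one contig."""
    window = RegionSet({contig: [(start, end)]})
    return intersect(r, window)


def write_bed(r: RegionSet, path: str | Path) -> None:
    """Export as BED (0-based half-open) for inspection in genome browsers."""
    with open(path, "w") as fh:
        for contig in sorted(r.intervals):
            for start, end in r.intervals[contig]:
                fh.write(f"{contig}\t{start - 1}\t{end}\n")
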