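"""Per-genome repeat occupancy (by class or cluster) and windowed density.

Within a category, overlapping hits are merged so no base is counted twice;
the genome-level total is the union over *all* hits, so total occupancy can be
below the sum of per-category occupancies when categories overlap.  Strand is
ignored throughout.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import GenomeIndex, RepeatHit

__all__ = [
    "merge_intervals",
    "merge_hits_by_sequence",
    "GenomeIntervals",
    "OccupancyRow",
    "OccupancyTable",
    "category_occupancy",
    "relative_class_frequencies",
    "WindowTrack",
    "window_density",
]

IntervalLike = Union[tuple[int, int], Sequence[int]]


def merge_intervals(intervals: Iterable[IntervalLike]) -> tuple[np.ndarray, int]:
    """Merge possibly-overlapping half-open intervals on one sequence.

    Adjacent intervals (zero gap) are merged too.  Returns ``(merged, total)``
    where ``merged`` is a sorted ``(k, 2)`` int array of disjoint intervals and
    ``total`` their summed length.
    """
    arr = np.asarray(list(intervals), dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64), 0
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    merged = []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        if s <= cur_e:  # overlap or zero gap
            cur_e = max(cur_e, int(e))
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = int(s), int(e)
    merged.append((cur_s, cur_e))
    out = np.asarray(merged, dtype=np.int64)
    return out, int((out[:, 1] - out[:, 0]).sum())


def merge_hits_by_sequence(hits: Iterable[RepeatHit]) -> dict[str, np.ndarray]:
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        per_seq.setdefault(h.seq_id, []).append((h.start, h.end))
    return {seq: merge_intervals(iv)[0] for seq, iv in per_seq.items()}


def _category_key(group_by: str) -> Callable[[RepeatHit], str]:
    if group_by == "class":
        return lambda h: h.repeat_class
    if group_by == "cluster":
        def key(h: RepeatHit) -> str:
            if h.cluster_id is None:
                raise ValueError(
                    f"hit {h.repeat_name} on {h.seq_id} has no cluster_id; "
                    "run clustering first or group by class"
                )
            return str(h.cluster_id)
        return key
    raise ValueError(f"group_by must be 'class' or 'cluster', got {group_by!r}")


class GenomeIntervals:
    """Merged per-sequence intervals with vectorized coverage queries."""

    def __init__(self, per_seq: Mapping[str, np.ndarray]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._prefix: dict[str, np.ndarray] = {}
        for seq, arr in per_seq.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            self._starts[seq] = arr[:, 0]
            self._ends[seq] = arr[:, 1]
            lengths = arr[:, 1] - arr[:, 0]
            self._prefix[seq] = np.concatenate(([0], np.cumsum(lengths)))

    @classmethod
    def from_hits(
        cls,
        hits: Iterable[RepeatHit],
        category: Optional[str] = None,
        group_by: str = "class",
    ) -> "GenomeIntervals":
        if category is None or category == "total":
            selected = hits
        else:
            key = _category_key(group_by)
            selected = [h for h in hits if key(h) == category]
        return cls(merge_hits_by_sequence(selected))

    @property
    def total_bp(self) -> int:
        return int(sum(p[-1] for p in self._prefix.values()))

    def coverage(self, seq_id: str, starts, ends) -> np.ndarray:
        """Covered bp inside each query interval [starts[i], ends[i])."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if seq_id not in self._starts or len(self._starts[seq_id]) == 0:
            return np.zeros(starts.shape, dtype=np.int64)
        S, E, P = self._starts[seq_id], self._ends[seq_id], self._prefix[seq_id]
        i = np.searchsorted(E, starts, side="right")
        j = np.searchsorted(S, ends, side="left")
        cov = P[j] - P[i]
        any_overlap = j > i
        left_clip = np.where(any_overlap, np.maximum(starts - S[np.minimum(i, len(S) - 1)], 0), 0)
        right_clip = np.where(
            any_overlap, np.maximum(E[np.maximum(j - 1, 0)] - ends, 0), 0
        )
        return np.where(any_overlap, cov - left_clip - right_clip, 0)

    def intersect_bp(self, regions: Mapping[str, np.ndarray]) -> int:
        total = 0
        for seq, arr in regions.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            total += int(self.coverage(seq, arr[:, 0], arr[:, 1]).sum())
        return total


@dataclass
class OccupancyRow:
    """One genome's occupancy by category, as proportions of assembly size."""

    genome_id: str
    proportions: dict[str, float]
    total_repeat_proportion: float


@dataclass
class OccupancyTable:
    """Genomes x categories proportions plus the per-genome union totals."""

    proportions: pd.DataFrame
    totals: pd.Series

    @classmethod
    def from_rows(cls, rows: Sequence[OccupancyRow]) -> "OccupancyTable":
        frame = pd.DataFrame(
            {r.genome_id: r.proportions for r in rows}
        ).T.fillna(0.0)
        frame = frame.reindex(sorted(frame.columns), axis=1)
        frame.index.name = "genome_id"
        totals = pd.Series(
            {r.genome_id: r.total_repeat_proportion for r in rows}, name="total"
        )
        return cls(frame, totals)


def category_occupancy(
    hits: Sequence[RepeatHit],
    index: GenomeIndex,
    group_by: str = "class",
    exclude_classes: Sequence[str] = (),
    sequences: Optional[Sequence[str]] = None,
) -> OccupancyRow:
    """Merged-bp occupancy per category plus the all-hit union total.

    ``sequences`` restricts both the hits and the assembly-size denominator to
    the named sequences (e.g. chromosomes only); ``exclude_classes`` drops
    whole repeat classes (e.g. low-complexity) before any computation.
    """
    if index.assembly_size == 0:
        raise ValueError("assembly size is zero")
    if exclude_classes:
        excluded = set(exclude_classes)
        hits = [h for h in hits if h.repeat_class not in excluded]
    if sequences is not None:
        keep = set(sequences)
        hits = [h for h in hits if h.seq_id in keep]
        denom = sum(l for s, l in index.lengths.items() if s in keep)
        if denom == 0:
            raise ValueError("sequence filter leaves no assembly length")
    else:
        denom = index.assembly_size
    index.validate_intervals(hits)
    key = _category_key(group_by)
    by_cat: dict[str, list[RepeatHit]] = {}
    for h in hits:
        by_cat.setdefault(key(h), []).append(h)
    proportions = {}
    for cat, cat_hits in by_cat.items():
        bp = sum(merge_intervals(iv)[1] for iv in _group_intervals(cat_hits).values())
        proportions[cat] = bp / denom
    union_bp = sum(merge_intervals(iv)[1] for iv in _group_intervals(hits).values())
    return OccupancyRow(index.genome_id, proportions, union_bp / denom)


def _group_intervals(hits: Iterable[RepeatHit]) -> dict[str, list[tuple[int, int]]]:
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        per_seq.setdefault(h.seq_id, []).append((h.start, h.end))
    return per_seq


def relative_class_frequencies(proportions: pd.DataFrame) -> pd.DataFrame:
    """Normalize each genome's category vector to its within-repeatome sum.

    Rows sum to 1; a genome with zero repeat content raises.
    """
    sums = proportions.sum(axis=1)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"genomes with zero repeat occupancy: {bad}")
    return proportions.div(sums, axis=0)


@dataclass
class WindowTrack:
    """Tiled fixed-size windows with occupied proportion per window."""

    genome_id: str
    window_size: int
    windows: pd.DataFrame  # seq_id, start, end, occupied_bp, proportion
    category: Optional[str] = None

    def to_bed(self, path) -> None:
        cols = self.windows[["seq_id", "start", "end", "proportion"]]
        cols.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def window_density(
    hits: Sequence[RepeatHit],
    index: GenomeIndex,
    window_size: int = 100_000,
    category: Optional[str] = None,
    group_by: str = "class",
) -> WindowTrack:
    """Repeat bp occupation of tiling windows, as a proportion of window length.

    Windows tile each sequence without overlap; the final partial window uses
    its true length as denominator.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    index.validate_intervals(hits)
    gi = GenomeIntervals.from_hits(hits, category=category, group_by=group_by)
    rows = []
    for seq, length in index.lengths.items():
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        occ = gi.coverage(seq, starts, ends)
        for s, e, o in zip(starts, ends, occ):
            rows.append(
                {
                    "seq_id": seq,
                    "start": int(s),
                    "end": int(e),
                    "occupied_bp": int(o),
                    "proportion": float(o) / float(e - s),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["seq_id", "start", "end", "occupied_bp", "proportion"]
    )
    return WindowTrack(index.genome_id, window_size, frame, category)
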