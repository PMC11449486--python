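"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention.  A track is a named set of intervals grouped by chromosome;
interval arrays are kept sorted by start and a merged copy is cached for
point-containment and distance queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = ["AnnotationTrack", "GeneAnnotation", "merge_intervals"]


def merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent intervals of an ``(n, 2)`` array."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (promoter, enhancer, repeat, ...)."""

    name: str
    intervals: dict[str, np.ndarray]  # chrom -> (n, 2) int64, sorted by start
    _merged: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr):
                if np.any(arr[:, 0] < 0):
                    raise ValueError(f"track {self.name!r}: negative coordinate on {chrom}")
                if np.any(arr[:, 0] >= arr[:, 1]):
                    raise ValueError(f"track {self.name!r}: empty/inverted interval on {chrom}")
                arr = arr[np.argsort(arr[:, 0], kind="stable")]
            clean[chrom] = arr
        self.intervals = clean
        self._merged = {c: merge_intervals(a) for c, a in clean.items()}

    @classmethod
    def from_records(cls, name: str, records: Iterable[tuple[str, int, int]]) -> "AnnotationTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        return cls(name, {c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()})

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                yield chrom, int(s), int(e)

    def n_intervals(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def total_bp(self) -> int:
        """Total bases covered (union; overlapping intervals counted once)."""
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._merged.values()))

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: does each position fall inside some interval?"""
        positions = np.asarray(positions, dtype=np.int64)
        merged = self._merged.get(chrom)
        if merged is None or len(merged) == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(merged[:, 0], positions, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(positions.shape, dtype=bool)
        hit[ok] = positions[ok] < merged[idx[ok], 1]
        return hit

    def nearest_distance(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Distance in bp from each position to the nearest covered base.

        0 inside an interval; for a site ``s`` and interval ``[a, b)``
        entirely left or right of it, the gap is ``a - s`` or ``s - (b - 1)``
        (the nearest covered base is ``b - 1``).  ``nan`` when the chromosome
        carries no intervals.
        """
        positions = np.asarray(positions, dtype=np.int64)
        merged = self._merged.get(chrom)
        if merged is None or len(merged) == 0:
            return np.full(positions.shape, np.nan)
        starts, ends = merged[:, 0], merged[:, 1]
        idx = np.searchsorted(starts, positions, side="right") - 1
        dist = np.full(positions.shape, np.inf)
        prev_ok = idx >= 0
        inside = np.zeros(positions.shape, dtype=bool)
        inside[prev_ok] = positions[prev_ok] < ends[idx[prev_ok]]
        # gap to interval on the left
        left = prev_ok & ~inside
        dist[left] = positions[left] - (ends[idx[left]] - 1)
        # gap to interval on the right
        nxt = idx + 1
        right = nxt < len(starts)
        cand = np.where(right & ~inside, starts[np.clip(nxt, 0, len(starts) - 1)] - positions, np.inf)
        dist = np.minimum(dist, cand)
        dist[inside] = 0.0
        return dist

    def validate_bounds(self, chrom_lengths: Mapping[str, int]) -> None:
        for chrom, arr in self.intervals.items():
            if chrom not in chrom_lengths:
                raise ValueError(f"track {self.name!r}: unknown chromosome {chrom!r}")
            if len(arr) and arr[:, 1].max() > chrom_lengths[chrom]:
                raise ValueError(f"track {self.name!r}: interval beyond end of {chrom!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    """Minimal gene model: TSS, promoter and gene-body intervals."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    promoter: tuple[int, int]
    body: tuple[int, int]
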