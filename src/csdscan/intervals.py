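"""Genomic intervals and repeat-mask tracks.

All in-memory coordinates are 1-based inclusive, matching the convention in
which locus boundaries are reported (e.g. "chromosome 2: 16,237,070 to
16,281,509" spans 44,440 bp). BED serialization converts to 0-based
half-open; the round trip is the identity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Interval", "MaskTrack", "jaccard"]


@dataclass(frozen=True, order=True)
class Interval:
    """A contiguous genomic region, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end < start: [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersection_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    def to_bed_fields(self) -> tuple[str, int, int]:
        """(chrom, 0-based start, half-open end) for BED emission."""
        return (self.chrom, self.start - 1, self.end)

    @classmethod
    def from_bed_fields(cls, chrom: str, start0: int, end0: int) -> "Interval":
        return cls(chrom, start0 + 1, end0)


def jaccard(a: Interval, b: Interval) -> float:
    """Jaccard overlap |a ∩ b| / |a ∪ b| of two intervals, in bp."""
    inter = a.intersection_length(b)
    union = a.length + b.length - inter
    return inter / union if union else 0.0


def _merge(arr: np.ndarray) -> np.ndarray:
    """Sort and merge an (n, 2) array of 1-based inclusive intervals."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    arr = arr[np.argsort(arr[:, 0])]
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


@dataclass
class MaskTrack:
    """Non-overlapping masked intervals per chromosome (repeat soft-masking).

    Sites falling inside masked intervals are excluded from heterozygosity
    and diversity counting (hard-masking of soft-masked repeats).
    """

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, ivals: list[Interval]) -> "MaskTrack":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in ivals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return cls(
            {c: _merge(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}
        )

    def to_intervals(self) -> list[Interval]:
        out = []
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                out.append(Interval(chrom, int(s), int(e)))
        return out

    def is_masked(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: which 1-based positions fall in a masked interval."""
        positions = np.asarray(positions)
        arr = self.intervals.get(chrom)
        if arr is None or len(arr) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(positions), dtype=bool)
        res[ok] = positions[ok] <= arr[idx[ok], 1]
        return res

    def overlap_bp(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Masked bp inside each [start, end] window (1-based inclusive)."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        arr = self.intervals.get(chrom)
        if arr is None or len(arr) == 0:
            return np.zeros(len(starts), dtype=np.int64)
        lens = arr[:, 1] - arr[:, 0] + 1
        cum = np.concatenate([[0], np.cumsum(lens)])
        # first interval whose end >= window start; last whose start <= window end
        i0 = np.searchsorted(arr[:, 1], starts, side="left")
        i1 = np.searchsorted(arr[:, 0], ends, side="right") - 1
        out = np.zeros(len(starts), dtype=np.int64)
        has = i0 <= i1
        if not has.any():
            return out
        a, b = i0[has], i1[has]
        total = cum[b + 1] - cum[a]
        trim_left = np.maximum(0, starts[has] - arr[a, 0])
        trim_right = np.maximum(0, arr[b, 1] - ends[has])
        out[has] = total - trim_left - trim_right
        return out

    @property
    def total_masked_length(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0] + 1).sum() for a in self.intervals.values())
        )
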