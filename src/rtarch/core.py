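"""Core genomic data structures: intervals, interval sets, binned tracks.

Coordinates are 0-based, half-open throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["GenomicInterval", "IntervalSet", "BinnedTrack"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class IntervalSet:
    """An ordered collection of genomic intervals with overlap algebra.

    Intervals are kept sorted by (chrom, start, end). Most set-algebra
    methods operate on the merged (non-overlapping) representation.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.intervals: List[GenomicInterval] = sorted(intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, bp={self.total_bp})"

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    @property
    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def merge(self) -> "IntervalSet":
        """Union of intervals: overlapping or bookended intervals are fused."""
        merged: List[GenomicInterval] = []
        for iv in self.intervals:
            if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
                last = merged[-1]
                if iv.end > last.end:
                    merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
            else:
                merged.append(iv)
        return IntervalSet(merged)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-pair intersection of the merged representations."""
        a = self.merge().by_chrom()
        b = other.merge().by_chrom()
        out: List[GenomicInterval] = []
        for chrom in set(a) & set(b):
            ia, ib = a[chrom], b[chrom]
            i = j = 0
            while i < len(ia) and j < len(ib):
                s = max(ia[i].start, ib[j].start)
                e = min(ia[i].end, ib[j].end)
                if s < e:
                    out.append(GenomicInterval(chrom, s, e))
                if ia[i].end <= ib[j].end:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other)).merge()

    def coverage_bp_of(self, interval: GenomicInterval) -> int:
        """Base pairs of `interval` covered by this (merged) set."""
        covered = 0
        for iv in self.merge():
            if iv.chrom == interval.chrom:
                covered += iv.overlap_bp(interval)
        return covered

    def covers_point(self, chrom: str, pos: int) -> bool:
        return any(iv.contains_point(chrom, pos) for iv in self.intervals)

    def boundaries(self) -> Dict[str, np.ndarray]:
        """Per-chromosome sorted array of interval start/end coordinates.

        Junctions between bookended intervals are kept as boundaries.
        """
        out: Dict[str, List[int]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).extend((iv.start, iv.end))
        return {c: np.unique(np.asarray(v)) for c, v in out.items()}


@dataclass
class BinnedTrack:
    """Fixed-width binned values along one chromosome.

    ``mask`` is True where the bin carries no information (missing data);
    masked bins are excluded from every statistic computed on the track.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def length_bp(self) -> int:
        return self.n_bins * self.bin_size

    def bin_of(self, pos: int) -> int:
        i = pos // self.bin_size
        if not (0 <= i < self.n_bins):
            raise IndexError(f"position {pos} outside track {self.chrom}")
        return int(i)

    def value_at(self, pos: int) -> float:
        """Track value at a genomic position; NaN when masked."""
        i = self.bin_of(pos)
        return float("nan") if self.mask[i] else float(self.values[i])

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.bin_size

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and self.n_bins == other.n_bins
        )

    def _overlap_weights(self, start: int, end: int) -> Tuple[np.ndarray, np.ndarray]:
        """Bin indices overlapping [start, end) and their overlap in bp."""
        start = max(0, start)
        end = min(self.length_bp, end)
        if start >= end:
            return np.empty(0, dtype=int), np.empty(0)
        i0 = start // self.bin_size
        i1 = (end - 1) // self.bin_size + 1
        idx = np.arange(i0, i1)
        bs = idx * self.bin_size
        be = bs + self.bin_size
        w = np.minimum(be, end) - np.maximum(bs, start)
        return idx, w.astype(float)

    def mean_over(self, start: int, end: int) -> float:
        """Overlap-weighted mean of unmasked bins over [start, end)."""
        idx, w = self._overlap_weights(start, end)
        if len(idx) == 0:
            return float("nan")
        keep = ~self.mask[idx]
        if not keep.any() or w[keep].sum() == 0:
            return float("nan")
        return float(np.average(self.values[idx][keep], weights=w[keep]))

    def sample_columns(self, start: int, end: int, n: int) -> Tuple[np.ndarray, np.ndarray]:
        """Split [start, end) into ``n`` equal slots; overlap-weighted mean each.

        Returns (values, missing-mask); slots outside the chromosome or with
        no informative bins are masked.
        """
        if n <= 0:
            raise ValueError("n must be positive")
        edges = start + (end - start) * np.arange(n + 1) / n
        vals = np.full(n, np.nan)
        miss = np.ones(n, dtype=bool)
        for k in range(n):
            s, e = int(np.floor(edges[k])), int(np.ceil(edges[k + 1]))
            # use exact fractional overlap against bins
            s_f, e_f = edges[k], edges[k + 1]
            i0 = max(0, int(s_f // self.bin_size))
            i1 = min(self.n_bins, int(np.ceil(e_f / self.bin_size)))
            if i0 >= i1:
                continue
            idx = np.arange(i0, i1)
            bs = idx * self.bin_size
            be = bs + self.bin_size
            w = np.minimum(be, e_f) - np.maximum(bs, s_f)
            w = np.clip(w, 0.0, None)
            keep = (~self.mask[idx]) & (w > 0)
            if keep.any():
                vals[k] = np.average(self.values[idx][keep], weights=w[keep])
                miss[k] = False
        return vals, miss

    def resample(self, new_bin_size: int) -> "BinnedTrack":
        """Average onto a coarser grid; new bin size must be a multiple."""
        if new_bin_size % self.bin_size != 0:
            raise ValueError("new bin size must be a multiple of the old one")
        f = new_bin_size // self.bin_size
        n_new = int(np.ceil(self.n_bins / f))
        vals = np.full(n_new, np.nan)
        miss = np.ones(n_new, dtype=bool)
        for k in range(n_new):
            chunk_v = self.values[k * f : (k + 1) * f]
            chunk_m = self.mask[k * f : (k + 1) * f]
            keep = ~chunk_m
            if keep.any():
                vals[k] = chunk_v[keep].mean()
                miss[k] = False
        return BinnedTrack(self.chrom, new_bin_size, vals, miss)


def genome_mean(tracks: Dict[str, BinnedTrack]) -> float:
    """Mean over all unmasked bins of a per-chromosome track dictionary."""
    vals = np.concatenate([t.values[~t.mask] for t in tracks.values()])
    return float(vals.mean()) if len(vals) else float("nan")
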