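"""Interval arithmetic on 0-based half-open genomic intervals.

All interval sets in the pipeline are kept merged (overlapping or book-ended
intervals collapsed, i.e. distance-0 merge) and sorted, which makes
containment and point-membership queries O(log n) searchsorted lookups.
"""
from __future__ import annotations

from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np


def merge_pairs(pairs: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping or book-ended (start == previous end) intervals."""
    arr = sorted((int(s), int(e)) for s, e in pairs)
    out: List[List[int]] = []
    for s, e in arr:
        if s > e:
            raise ValueError(f"inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out if e > s]


class GenomicIntervals:
    """A merged, per-chromosome set of 0-based half-open intervals."""

    def __init__(self, by_chrom: Dict[str, Sequence[Tuple[int, int]]] | None = None):
        self._by: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        if by_chrom:
            for chrom, pairs in by_chrom.items():
                merged = merge_pairs(pairs)
                if merged:
                    arr = np.asarray(merged, dtype=np.int64)
                    self._by[chrom] = (np.ascontiguousarray(arr[:, 0]),
                                       np.ascontiguousarray(arr[:, 1]))

    @classmethod
    def from_tuples(cls, tuples: Iterable[Tuple[str, int, int]]) -> "GenomicIntervals":
        d: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e in tuples:
            d.setdefault(chrom, []).append((s, e))
        return cls(d)

    # -- introspection -----------------------------------------------------
    def chroms(self) -> List[str]:
        return sorted(self._by)

    def arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome (empty arrays if absent)."""
        if chrom in self._by:
            return self._by[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in self.chroms():
            starts, ends = self._by[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield chrom, s, e

    def __len__(self) -> int:
        return sum(len(v[0]) for v in self._by.values())

    @property
    def is_empty(self) -> bool:
        return not self._by

    @property
    def total_length(self) -> int:
        return int(sum((v[1] - v[0]).sum() for v in self._by.values()))

    # -- queries -----------------------------------------------------------
    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies fully inside one merged interval."""
        starts, ends = self.arrays(chrom)
        if len(starts) == 0 or start >= end:
            return False
        i = int(np.searchsorted(starts, start, side="right")) - 1
        return i >= 0 and end <= ends[i]

    def contains_points(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside the interval set."""
        pos = np.asarray(pos, dtype=np.int64)
        starts, ends = self.arrays(chrom)
        if len(starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] = pos[ok] < ends[idx[ok]]
        return ok

    # -- set ops -----------------------------------------------------------
    def union(self, other: "GenomicIntervals") -> "GenomicIntervals":
        return GenomicIntervals.from_tuples(list(self) + list(other))

    def subtract(self, other: "GenomicIntervals") -> "GenomicIntervals":
        """Bases in self but not in other."""
        out: Dict[str, List[Tuple[int, int]]] = {}
        for chrom in self.chroms():
            s_starts, s_ends = self.arrays(chrom)
            o_starts, o_ends = other.arrays(chrom)
            kept: List[Tuple[int, int]] = []
            j = 0
            for s, e in zip(s_starts.tolist(), s_ends.tolist()):
                cur = s
                while j < len(o_starts) and o_ends[j] <= cur:
                    j += 1
                k = j
                while k < len(o_starts) and o_starts[k] < e:
                    if o_starts[k] > cur:
                        kept.append((cur, int(o_starts[k])))
                    cur = max(cur, int(o_ends[k]))
                    k += 1
                if cur < e:
                    kept.append((cur, e))
            if kept:
                out[chrom] = kept
        return GenomicIntervals(out)

    def intersect_length(self, other: "GenomicIntervals") -> int:
        """Total number of bases shared with another interval set."""
        total = 0
        for chrom in self.chroms():
            o_starts, o_ends = other.arrays(chrom)
            if len(o_starts) == 0:
                continue
            for _, s, e in ((chrom, a, b) for (a, b) in zip(*self.arrays(chrom))):
                lo = np.maximum(o_starts, s)
                hi = np.minimum(o_ends, e)
                total += int(np.clip(hi - lo, 0, None).sum())
        return total
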