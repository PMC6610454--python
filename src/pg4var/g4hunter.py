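"""G4Hunter scoring and pG4 detection.

The G4Hunter score of a base reflects the G/C skew of its local context:
every G in a maximal run of n consecutive Gs scores +min(n, 4), every C in a
run of n Cs scores -min(n, 4), and all other bases score 0.  A window's
G4Hscore is the arithmetic mean of its base scores, bounded by +/-4; windows
with a high positive mean are G-rich and likely to fold into a G-quadruplex
on the scored strand, while strongly negative windows indicate a G4 on the
opposite strand.

Detection here follows a three-run protocol: sliding-window scans with
(ws=20, t=1.7), (ws=30, t=1.4) and (ws=25, t=1.6), whose qualifying window
spans are unioned, merged at distance 0, and rescored as whole intervals.
The original G4Hunter post-hoc trimming/extension of hits to G-run
boundaries is deliberately not applied; this dialect keeps plain
merge-then-rescore semantics (merged intervals are therefore always at
least ws long).

Masked bases (lowercase or N) score 0 by default, so detection on a
hard/soft-masked genome naturally avoids repeats.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .errors import ParameterError

#: The three (window size, threshold) detection runs.
DEFAULT_PARAMS: Tuple[Tuple[int, float], ...] = ((20, 1.7), (30, 1.4), (25, 1.6))

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_KNOWN = frozenset("ACGTUNacgtun")


def revcomp(sequence: str) -> str:
    """Reverse complement over the extended alphabet (case preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PG4Interval:
    """A predicted G-quadruplex: half-open genomic interval on its G-rich strand.

    ``g4hscore`` is the absolute mean base score of the merged interval
    (the strand field carries the sign).
    """

    chrom: str
    start: int
    end: int
    strand: str
    g4hscore: float
    pg4_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty pG4 interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


def _run_capped(mask: np.ndarray) -> np.ndarray:
    """Per-position min(run length, 4) for True runs of ``mask``."""
    out = np.zeros(len(mask), dtype=np.int8)
    if not mask.any():
        return out
    m = mask.astype(np.int8)
    diff = np.diff(m)
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        ends = np.concatenate((ends, [len(mask)]))
    lengths = ends - starts
    out[mask] = np.repeat(np.minimum(lengths, 4).astype(np.int8), lengths)
    return out


def base_scores(sequence: str, masked_as_zero: bool = True) -> np.ndarray:
    """Per-base G4Hunter scores in [-4, 4].

    Run lengths are computed on the full sequence before any windowing.
    With ``masked_as_zero`` (default) lowercase bases and N score 0; with the
    flag off, case is ignored.  Unknown characters score 0 with a warning.
    """
    if not sequence:
        return np.zeros(0, dtype=np.int8)
    if not masked_as_zero:
        sequence = sequence.upper()
    arr = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    unknown = set(sequence) - _KNOWN
    if unknown:
        warnings.warn(f"non-ACGTUN characters scored 0: {sorted(unknown)}")
    g = _run_capped(arr == ord("G"))
    c = _run_capped(arr == ord("C"))
    return (g - c).astype(np.int8)


def window_means(scores: np.ndarray, ws: int) -> np.ndarray:
    """Sliding arithmetic means: entry i averages scores[i : i+ws)."""
    if ws <= 0:
        raise ParameterError(f"window size must be positive, got {ws}")
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) < ws:
        return np.zeros(0, dtype=np.float64)
    csum = np.concatenate(([0.0], np.cumsum(scores)))
    return (csum[ws:] - csum[:-ws]) / ws


def detect_single_run(
    sequence: str,
    ws: int,
    t: float,
    sign: str = "+",
    *,
    scores: np.ndarray | None = None,
) -> List[Tuple[int, int]]:
    """One sliding-window detection pass.

    For sign '+', every window with mean >= t marks its full [i, i+ws) span;
    for sign '-', windows with mean <= -t (C-rich, i.e. a G4 on the opposite
    strand).  Overlapping or book-ended marked spans are merged into maximal
    intervals, returned in sequence-local half-open coordinates.
    """
    if t <= 0:
        raise ParameterError(f"threshold must be positive, got {t}")
    if sign not in "+-":
        raise ParameterError(f"sign must be '+' or '-', got {sign!r}")
    if scores is None:
        scores = base_scores(sequence)
    means = window_means(scores, ws)
    hits = np.flatnonzero(means >= t) if sign == "+" else np.flatnonzero(means <= -t)
    if len(hits) == 0:
        return []
    # consecutive qualifying windows closer than ws overlap or book-end
    breaks = np.flatnonzero(np.diff(hits) > ws)
    group_starts = np.concatenate(([0], breaks + 1))
    group_ends = np.concatenate((breaks, [len(hits) - 1]))
    return [(int(hits[a]), int(hits[b]) + ws) for a, b in zip(group_starts, group_ends)]


def rescore_interval(
    sequence: str, start: int, end: int, masked_as_zero: bool = True
) -> float:
    """Signed mean base score of [start, end), with full-sequence run context."""
    if not (0 <= start < end <= len(sequence)):
        raise IndexError(f"interval [{start}, {end}) out of bounds for length {len(sequence)}")
    return float(base_scores(sequence, masked_as_zero)[start:end].mean())


#: Runs of >4 identical bases score identically to runs of exactly 4, so a
#: 4-base context pad around an interval reproduces full-sequence scores.
_CONTEXT_PAD = 4


def rescore_with_context(sequence: str, start: int, end: int,
                         masked_as_zero: bool = True) -> float:
    """Fast exact equivalent of :func:`rescore_interval` using a local pad."""
    lo = max(0, start - _CONTEXT_PAD)
    hi = min(len(sequence), end + _CONTEXT_PAD)
    scores = base_scores(sequence[lo:hi], masked_as_zero)
    return float(scores[start - lo : end - lo].mean())


def multi_param_detect(
    sequence: str,
    params: Sequence[Tuple[int, float]] = DEFAULT_PARAMS,
    sign: str = "+",
    chrom: str = "",
) -> List[PG4Interval]:
    """Union of all detection runs, distance-0-merged and rescored.

    The reported g4hscore is the absolute interval mean; the sign of the
    underlying score is recorded as the strand ('+' for G-rich on the given
    sequence, '-' for C-rich, i.e. G-rich on the reverse complement).
    """
    for ws, t in params:
        if ws < 1:
            raise ParameterError(f"window size must be >= 1, got {ws}")
        if t <= 0:
            raise ParameterError(f"threshold must be positive, got {t}")
    scores = base_scores(sequence)
    spans: List[Tuple[int, int]] = []
    for ws, t in params:
        spans.extend(detect_single_run(sequence, ws, t, sign, scores=scores))
    from .intervals import merge_pairs

    out = []
    strand = "+" if sign == "+" else "-"
    for s, e in merge_pairs(spans):
        score = float(scores[s:e].mean())
        out.append(PG4Interval(chrom, s, e, strand, abs(score)))
    return out


def detect_genome(
    fasta: Dict[str, str],
    params: Sequence[Tuple[int, float]] = DEFAULT_PARAMS,
) -> List[PG4Interval]:
    """Detect pG4s on both strands of every sequence; assigns stable ids."""
    pg4s: List[PG4Interval] = []
    for chrom in sorted(fasta):
        seq = fasta[chrom]
        for sign in "+-":
            pg4s.extend(multi_param_detect(seq, params, sign, chrom=chrom))
    pg4s.sort(key=lambda p: (p.chrom, p.start, p.end, p.strand))
    return [replace(p, pg4_id=f"pG4_{i + 1}") for i, p in enumerate(pg4s)]


def write_bed(pg4s: Iterable[PG4Interval], path) -> None:
    """BED6; the score column holds the g4hscore rounded to 3 decimals
    (a documented non-standard dialect, not the 0-1000 BED convention)."""
    with open(path, "w") as fh:
        for p in pg4s:
            name = p.pg4_id or "pG4"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.g4hscore:.3f}\t{p.strand}\n")
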