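"""SNP-density variability of pG4s relative to their host regions.

Four analyses:

* region-level densities and a 2x2 Pearson chi-square contrast of variant
  sites inside pG4s vs the remainder of the region;
* a 90-position SNP-density landscape per label (30 bp 5' flank, pG4 body
  linearly resampled to 30 points, 30 bp 3' flank), optionally min-max
  scaled to [0, 1] for plotting;
* a per-pG4 two-sided Fisher's exact classification into significantly
  variable / conserved / non-significant pG4s;
* an ordinary least-squares regression of the pG4-vs-control density ratio
  on region fold-enrichment, with explicit outlier exclusion.

Densities are variant sites per bp of merged interval length; masked bases
are not removed from denominators.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import interpolate, stats

from .errors import InsufficientDataError, UndefinedDensityError
from .g4hunter import PG4Interval
from .intervals import GenomicIntervals
from .variants import Variant, count_sites_in, position_counts, site_positions


def _as_intervals(obj) -> GenomicIntervals:
    if isinstance(obj, GenomicIntervals):
        return obj
    if obj and isinstance(next(iter(obj)), PG4Interval):
        return GenomicIntervals.from_tuples((p.chrom, p.start, p.end) for p in obj)
    return GenomicIntervals.from_tuples(obj)


def snp_density(
    intervals,
    variants: Iterable[Variant],
    include_indels: bool = False,
) -> float:
    """Variant sites per bp of merged interval length.

    Indels count at their leftmost reference position when included
    (mirroring the indel-inclusive analysis mode); otherwise SNP sites only.
    """
    ivals = _as_intervals(intervals)
    if ivals.total_length <= 0:
        raise UndefinedDensityError("cannot compute density over zero-length intervals")
    sites = site_positions(variants, include_indels)
    return count_sites_in(ivals, sites) / ivals.total_length


class Chi2Result(NamedTuple):
    statistic: float
    p_value: float
    low_count: bool


def region_variability_test(
    pg4_intervals,
    region_intervals,
    variants: Iterable[Variant],
    include_indels: bool = False,
) -> Chi2Result:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    [variant sites, non-variant sites] x [inside pG4s, region outside pG4s]."""
    pg4 = _as_intervals(pg4_intervals)
    region = _as_intervals(region_intervals)
    if pg4.total_length <= 0:
        raise UndefinedDensityError("empty pG4 interval set")
    inside_len = pg4.total_length
    outside = region.subtract(pg4)
    outside_len = outside.total_length
    if outside_len <= 0:
        raise UndefinedDensityError("region does not extend beyond the pG4 footprint")
    variants = list(variants)
    sites = site_positions(variants, include_indels)
    a = count_sites_in(pg4, sites)
    c = count_sites_in(outside, sites)
    table = np.array([[a, inside_len - a], [c, outside_len - c]], dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    expected = np.asarray(res.expected_freq)
    low = bool((expected < 1).any())
    if low:
        warnings.warn("chi-square expected cell < 1; result flagged low-count")
    return Chi2Result(float(res.statistic), float(res.pvalue), low)


@dataclass
class LandscapeProfile:
    """Averaged 90-position SNP-count profile around pG4s.

    Positions 0-29 are the 5' flank, 30-59 the length-normalized pG4 body,
    60-89 the 3' flank (profiles of minus-strand pG4s are reversed before
    averaging so position 0 is always the 5'-most flank base).
    """

    values: np.ndarray  # length flank + body + flank
    n_pg4s: int
    flank: int = 30
    body: int = 30

    @property
    def flank5(self) -> np.ndarray:
        return self.values[: self.flank]

    @property
    def body_values(self) -> np.ndarray:
        return self.values[self.flank : self.flank + self.body]

    @property
    def flank3(self) -> np.ndarray:
        return self.values[self.flank + self.body :]

    def scaled(self) -> np.ndarray:
        """Min-max scaling to [0, 1]; a constant profile scales to all zeros."""
        lo, hi = float(self.values.min()), float(self.values.max())
        if hi == lo:
            return np.zeros_like(self.values)
        return (self.values - lo) / (hi - lo)


def landscape(
    pg4s: Sequence[PG4Interval],
    variants: Iterable[Variant],
    sequence_bounds: Dict[str, int],
    flank: int = 30,
    body: int = 30,
    include_indels: bool = False,
) -> LandscapeProfile:
    """Average per-position variant counts over pG4s and their flanks.

    Each pG4 contributes a (flank + L + flank) count array; the body part is
    resampled to ``body`` points by linear interpolation over [0, L-1]
    (endpoints preserved, so the first/last body positions survive
    unchanged).  Flank positions beyond chromosome bounds are masked out of
    the average rather than counted as zero.  pG4s shorter than 2 bp are
    skipped with a warning.
    """
    counts_by_chrom = position_counts(variants, include_indels)
    n = flank + body + flank
    total = np.zeros(n, dtype=float)
    contrib = np.zeros(n, dtype=float)
    used = 0

    def counts_at(chrom: str, lo: int, hi: int) -> Tuple[np.ndarray, np.ndarray]:
        """(counts, validity mask) for genomic positions lo..hi."""
        size = hi - lo
        vals = np.zeros(size, dtype=float)
        bound = sequence_bounds.get(chrom)
        pos_idx = np.arange(lo, hi)
        valid = (pos_idx >= 0)
        if bound is not None:
            valid &= pos_idx < bound
        if chrom in counts_by_chrom:
            pos, cnt = counts_by_chrom[chrom]
            j = np.searchsorted(pos, pos_idx)
            hit = (j < len(pos))
            hit[hit] &= pos[j[hit]] == pos_idx[hit]
            vals[hit] = cnt[j[hit]]
        return vals, valid

    for p in pg4s:
        L = p.length
        if L < 2:
            warnings.warn(f"pG4 {p.pg4_id or p.key()} shorter than 2 bp skipped")
            continue
        f5, m5 = counts_at(p.chrom, p.start - flank, p.start)
        bd, mb = counts_at(p.chrom, p.start, p.end)
        f3, m3 = counts_at(p.chrom, p.end, p.end + flank)
        if L == body:
            body_vals = bd
        else:
            f = interpolate.interp1d(np.arange(L), bd, kind="linear")
            body_vals = f(np.linspace(0, L - 1, body))
        arr = np.concatenate([f5, body_vals, f3])
        mask = np.concatenate([m5, np.ones(body, dtype=bool), m3])
        if p.strand == "-":
            arr = arr[::-1]
            mask = mask[::-1]
        total += np.where(mask, arr, 0.0)
        contrib += mask
        used += 1
    values = np.divide(total, contrib, out=np.zeros(n), where=contrib > 0)
    return LandscapeProfile(values, used, flank, body)


CLASS_VARIABLE = "variable"
CLASS_CONSERVED = "conserved"
CLASS_NS = "ns"


@dataclass
class PG4Class:
    pg4_id: str
    observed_variants: int
    pg4_length: int
    region_variants: int
    region_length: int
    fisher_p: float
    pg4_class: str


def classify_extreme(
    pg4: PG4Interval,
    region_intervals,
    variants: Iterable[Variant],
    alpha: float = 0.05,
    background: Optional[GenomicIntervals] = None,
    include_indels: bool = False,
) -> PG4Class:
    """Two-sided Fisher's exact test of this pG4's variant sites against its
    host region's background.

    The background defaults to the region minus this pG4; callers comparing
    many pG4s should pass the region minus *all* pG4 footprints (see
    :func:`classify_all`).  A pG4 is ``variable`` when p < alpha and its
    site density exceeds the background's, ``conserved`` when p < alpha and
    it falls below, otherwise ``ns`` (equal densities are always ns).
    """
    pg4_ivals = _as_intervals([pg4])
    region = _as_intervals(region_intervals)
    if background is None:
        background = region.subtract(pg4_ivals)
    bg_len = background.total_length
    if bg_len <= 0:
        raise UndefinedDensityError("background region is empty")
    variants = list(variants)
    sites = site_positions(variants, include_indels)
    a = count_sites_in(pg4_ivals, sites)
    c = count_sites_in(background, sites)
    L = pg4_ivals.total_length
    _, p = stats.fisher_exact([[a, L - a], [c, bg_len - c]], alternative="two-sided")
    d_in, d_bg = a / L, c / bg_len
    if p < alpha and d_in > d_bg:
        cls = CLASS_VARIABLE
    elif p < alpha and d_in < d_bg:
        cls = CLASS_CONSERVED
    else:
        cls = CLASS_NS
    return PG4Class(pg4.pg4_id, a, L, c, bg_len, float(p), cls)


def classify_all(
    pg4s: Sequence[PG4Interval],
    region_intervals,
    variants: Iterable[Variant],
    alpha: float = 0.05,
    include_indels: bool = False,
) -> List[PG4Class]:
    """Classify every pG4 against the region minus all pG4 footprints.

    Equivalent to calling :func:`classify_extreme` per pG4 with the shared
    background, but indexes the variant sites once.
    """
    region = _as_intervals(region_intervals)
    footprint = _as_intervals(pg4s)
    background = region.subtract(footprint)
    bg_len = background.total_length
    if bg_len <= 0:
        raise UndefinedDensityError("background region is empty")
    sites = site_positions(variants, include_indels)
    c = count_sites_in(background, sites)
    out: List[PG4Class] = []
    for p in pg4s:
        L = p.length
        pos = sites.get(p.chrom)
        if pos is None:
            a = 0
        else:
            a = int(np.searchsorted(pos, p.end) - np.searchsorted(pos, p.start))
        _, pval = stats.fisher_exact([[a, L - a], [c, bg_len - c]],
                                     alternative="two-sided")
        d_in, d_bg = a / L, c / bg_len
        if pval < alpha and d_in > d_bg:
            cls = CLASS_VARIABLE
        elif pval < alpha and d_in < d_bg:
            cls = CLASS_CONSERVED
        else:
            cls = CLASS_NS
        out.append(PG4Class(p.pg4_id, a, L, c, bg_len, float(pval), cls))
    return out


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    n_used: int
    excluded: List[str] = field(default_factory=list)


def enrichment_variability_regression(
    points: Sequence[Tuple[str, float, float]],
    exclude: Set[str] = frozenset(),
) -> RegressionResult:
    """OLS of the pG4/control SNP-density ratio on pG4 fold-enrichment.

    ``points`` are (point_id, fold_enrichment, density_ratio) triples;
    ids in ``exclude`` are dropped before fitting (reported separately).
    """
    kept = [(pid, fe, ratio) for pid, fe, ratio in points if pid not in exclude]
    if len(kept) < 3:
        raise InsufficientDataError(
            f"regression needs >= 3 points after exclusion, got {len(kept)}"
        )
    x = np.array([fe for _, fe, _ in kept], dtype=float)
    y = np.array([r for _, _, r in kept], dtype=float)
    fit = stats.linregress(x, y)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue),
        len(kept), sorted(set(pid for pid, _, _ in points) & set(exclude)),
    )
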