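"""Impact of single-nucleotide substitutions on G4-forming potential.

For a pG4 and a substitution, the delta-G4Hscore is the change in the
interval's G4Hscore (mean base score over the merged interval, evaluated on
the G-rich strand) caused by that substitution; negative values destabilize
the predicted structure.  Three distributions are compared per structural
region:

* ``all_positions`` — the theoretical multiset of deltas across every pG4
  position and each of its three alternative bases, weighted by the
  region's background substitution probabilities;
* ``fixed_positions`` — the same construction restricted to positions that
  actually carry variants in the callset (isolating the substitution-type
  effect from the positional effect);
* ``observed`` — the deltas of the substitutions actually present in the
  callset, uniformly weighted.

Background probabilities are the 12 conditional P(alt | ref) frequencies
estimated from the region's own SNPs.  Because a rank test has no native
weighting, theoretical samples are expanded by seeded categorical sampling
(``mc_draws`` draws per position) before a two-sided Wilcoxon rank-sum
(Mann-Whitney) comparison with the observed deltas.  Signed deltas are the
default (needed to detect a preference for score-lowering variants); an
absolute-value mode is available.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DataInconsistencyError, InsufficientDataError
from .g4hunter import PG4Interval, rescore_with_context
from .intervals import GenomicIntervals
from .variants import SNP, Variant

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

ALL_POSITIONS = "all_positions"
FIXED_POSITIONS = "fixed_positions"
OBSERVED = "observed"


@dataclass
class SubstitutionSpectrum:
    """Conditional probabilities of the 12 ref->alt substitutions.

    ``probs[i, j]`` is P(alt=BASES[j] | ref=BASES[i]); each row sums to 1
    over the three off-diagonal entries.
    """

    probs: np.ndarray  # (4, 4), zero diagonal
    counts: np.ndarray  # (4, 4) raw counts the probabilities came from

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0) or (self.probs < 0).any():
            raise ValueError("each ref row must be a probability distribution")
        if not np.allclose(np.diag(self.probs), 0.0):
            raise ValueError("ref == alt entries must be zero")

    def prob(self, ref: str, alt: str) -> float:
        return float(self.probs[_BASE_INDEX[ref], _BASE_INDEX[alt]])

    @classmethod
    def uniform(cls) -> "SubstitutionSpectrum":
        p = np.full((4, 4), 1 / 3.0)
        np.fill_diagonal(p, 0.0)
        return cls(p, np.zeros((4, 4)))


def background_spectrum(
    variants: Iterable[Variant],
    region_intervals: GenomicIntervals,
) -> SubstitutionSpectrum:
    """Estimate the 12 substitution probabilities from a region's SNPs.

    A reference base with no observed substitutions in the region falls
    back to the uniform 1/3 row, with a warning.
    """
    counts = np.zeros((4, 4), dtype=float)
    for v in variants:
        if v.vtype != SNP or v.ref not in _BASE_INDEX or v.alt not in _BASE_INDEX:
            continue
        if region_intervals.contains_points(v.chrom, np.array([v.pos]))[0]:
            counts[_BASE_INDEX[v.ref], _BASE_INDEX[v.alt]] += 1
    probs = counts.copy()
    for i, base in enumerate(BASES):
        row_sum = counts[i].sum()
        if row_sum == 0:
            warnings.warn(f"no {base}-ref substitutions observed; uniform 1/3 fallback")
            probs[i] = 1 / 3.0
            probs[i, i] = 0.0
        else:
            probs[i] /= row_sum
    return SubstitutionSpectrum(probs, counts)


def delta_g4hscore(
    sequence: str,
    pg4: PG4Interval,
    pos: int,
    alt: str,
    ref: Optional[str] = None,
    absolute: bool = False,
) -> float:
    """Signed G4Hscore change of the pG4 under the substitution pos->alt.

    ``pos`` and ``alt`` are in plus-strand genomic coordinates; for a
    minus-strand pG4 the score is evaluated on the reverse complement,
    which equals the negated plus-strand interval mean, so the sign flip is
    applied directly.  If ``ref`` is given it is checked against the FASTA.
    """
    if not (pg4.start <= pos < pg4.end):
        raise ValueError(f"position {pos} outside pG4 [{pg4.start}, {pg4.end})")
    seq_ref = sequence[pos].upper()
    if ref is not None and seq_ref != ref.upper():
        raise DataInconsistencyError(
            f"REF mismatch at {pg4.chrom}:{pos}: VCF says {ref}, FASTA has {seq_ref}"
        )
    alt = alt.upper()
    if alt == seq_ref:
        raise ValueError(f"alt equals reference base {alt} at {pos}")
    before = rescore_with_context(sequence, pg4.start, pg4.end)
    mutated = sequence[:pos] + alt + sequence[pos + 1 :]
    after = rescore_with_context(mutated, pg4.start, pg4.end)
    sign = 1.0 if pg4.strand == "+" else -1.0
    delta = sign * (after - before)
    return abs(delta) if absolute else delta


@dataclass
class DeltaSample:
    """Weighted sample of delta-G4Hscore values.

    Theoretical samples are laid out in consecutive triples (the three
    alternative bases of one position), whose weights sum to 1 within each
    triple; observed samples carry uniform weights.
    """

    model: str
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.values) != len(self.weights):
            raise ValueError("values and weights must have equal length")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def concat(cls, samples: Sequence["DeltaSample"]) -> "DeltaSample":
        if not samples:
            return cls(OBSERVED, np.zeros(0), np.zeros(0))
        model = samples[0].model
        return cls(
            model,
            np.concatenate([s.values for s in samples]),
            np.concatenate([s.weights for s in samples]),
        )


def theoretical_sample(
    pg4: PG4Interval,
    sequence: str,
    spectrum: SubstitutionSpectrum,
    model: str = ALL_POSITIONS,
    variant_positions: Optional[Sequence[int]] = None,
    absolute: bool = False,
) -> DeltaSample:
    """Multiset of deltas over candidate positions, weighted by the spectrum.

    ``all_positions`` uses every pG4 position (sample size 3L);
    ``fixed_positions`` restricts to the given variant-carrying positions
    (size 3m).  Positions whose reference base is not A/C/G/T are skipped.
    """
    if model == ALL_POSITIONS:
        positions = range(pg4.start, pg4.end)
    elif model == FIXED_POSITIONS:
        if not variant_positions:
            raise InsufficientDataError("fixed_positions model needs variant positions")
        positions = sorted(variant_positions)
    else:
        raise ValueError(f"unknown model {model!r}")
    values: List[float] = []
    weights: List[float] = []
    for pos in positions:
        ref = sequence[pos].upper()
        if ref not in _BASE_INDEX:
            continue
        for alt in BASES:
            if alt == ref:
                continue
            values.append(delta_g4hscore(sequence, pg4, pos, alt, absolute=absolute))
            weights.append(spectrum.prob(ref, alt))
    return DeltaSample(model, np.array(values), np.array(weights))


def observed_sample(
    pg4s: Sequence[PG4Interval],
    sequences: Dict[str, str],
    variants: Iterable[Variant],
    absolute: bool = False,
) -> DeltaSample:
    """One signed delta per (pG4, SNP-within-pG4) pair, uniform weights.

    pG4s are expected to be deduplicated and non-overlapping (the output of
    the merge step), so each variant hits at most one pG4 per strand.
    """
    by_chrom: Dict[str, List[PG4Interval]] = {}
    for p in pg4s:
        by_chrom.setdefault(p.chrom, []).append(p)
    values: List[float] = []
    for v in variants:
        if v.vtype != SNP:
            continue
        for p in by_chrom.get(v.chrom, ()):
            if p.start <= v.pos < p.end:
                values.append(
                    delta_g4hscore(sequences[p.chrom], p, v.pos, v.alt,
                                   ref=v.ref, absolute=absolute)
                )
    return DeltaSample(OBSERVED, np.array(values), np.ones(len(values)))


@dataclass
class DeltaComparison:
    label: str
    model: str
    wilcoxon_stat: float
    p_value: float
    median_observed: float
    median_theoretical: float
    n_observed: int
    n_theoretical: int


def expand_theoretical(
    sample: DeltaSample, mc_draws: int = 10, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Expand a weighted triple-structured sample into an unweighted one.

    For each position's triple of (value, weight) pairs, draw ``mc_draws``
    values with the weights as categorical probabilities.
    """
    if len(sample) % 3 != 0:
        raise ValueError("theoretical sample length must be a multiple of 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = sample.values.reshape(-1, 3)
    w = sample.weights.reshape(-1, 3)
    w = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    u = rng.random((vals.shape[0], mc_draws))
    idx = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
    return vals[np.arange(vals.shape[0])[:, None], idx].ravel()


def compare_distributions(
    observed: DeltaSample,
    theoretical: DeltaSample,
    mc_draws: int = 10,
    seed: int = 0,
    label: str = "",
) -> DeltaComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney, normal approximation with
    tie correction) of observed deltas against the expanded theoretical
    sample; deterministic for a given seed."""
    if len(observed) == 0 or len(theoretical) == 0:
        raise InsufficientDataError("both delta samples must be non-empty")
    expanded = expand_theoretical(theoretical, mc_draws, seed)
    res = stats.mannwhitneyu(
        observed.values, expanded, alternative="two-sided", method="asymptotic"
    )
    return DeltaComparison(
        label,
        theoretical.model,
        float(res.statistic),
        float(res.pvalue),
        float(np.median(observed.values)),
        float(np.median(expanded)),
        len(observed),
        len(expanded),
    )


def per_position_expectation(sample: DeltaSample) -> np.ndarray:
    """Alternative reading of the theoretical distribution: one weighted
    mean delta per position instead of the full 3-per-position multiset."""
    if len(sample) % 3 != 0:
        raise ValueError("theoretical sample length must be a multiple of 3")
    vals = sample.values.reshape(-1, 3)
    w = sample.weights.reshape(-1, 3)
    w = w / w.sum(axis=1, keepdims=True)
    return (vals * w).sum(axis=1)
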