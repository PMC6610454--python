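"""SNP densities, chi-square contrasts, landscapes, Fisher classification."""
from __future__ import annotations

import math

import numpy as np
import pytest

from pg4var.errors import InsufficientDataError, UndefinedDensityError
from pg4var.g4hunter import PG4Interval
from pg4var.intervals import GenomicIntervals
from pg4var.variability import (CLASS_CONSERVED, CLASS_NS, CLASS_VARIABLE,
                                classify_all, classify_extreme,
                                enrichment_variability_regression, landscape,
                                region_variability_test, snp_density)
from pg4var.variants import INDEL, SNP, Variant


def _snps(positions, chrom="chr1"):
    return [Variant(chrom, p, "G", "A", SNP) for p in positions]


class TestSnpDensity:
    def test_sites_per_bp(self):
        assert snp_density([("chr1", 0, 100)], _snps(range(5))) == pytest.approx(0.05)

    def test_overlapping_intervals_use_merged_length(self):
        ivals = [("chr1", 0, 50), ("chr1", 25, 75)]
        assert snp_density(ivals, _snps([30])) == pytest.approx(1 / 75)

    def test_indels_only_counted_when_enabled(self):
        indel = [Variant("chr1", 10, "GT", "G", INDEL)]
        assert snp_density([("chr1", 0, 100)], indel) == 0.0
        assert snp_density([("chr1", 0, 100)], indel, include_indels=True) == 0.01

    def test_zero_length_raises(self):
        with pytest.raises(UndefinedDensityError):
            snp_density([], _snps([1]))


def _pearson_chi2(table):
    """Independent direct-formula oracle for the 2x2 Pearson statistic."""
    (a, b), (c, d) = table
    n = a + b + c + d
    stat = 0.0
    for i, row in enumerate((a + b, c + d)):
        for j, col in enumerate((a + c, b + d)):
            obs = table[i][j]
            exp = row * col / n
            stat += (obs - exp) ** 2 / exp
    return stat


class TestRegionVariabilityTest:
    def test_proportional_counts_give_null_result(self):
        # 1 site per 100 bp both inside and outside
        pg4 = [("chr1", 0, 100)]
        region = [("chr1", 0, 1000)]
        variants = _snps([50]) + _snps(range(150, 1000, 100))
        stat, p, low = region_variability_test(pg4, region, variants)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)
        assert not low

    def test_matches_direct_formula_oracle(self):
        # construct [[30, 970], [970, 98030]]
        pg4 = [("chr1", 0, 1000)]
        region = [("chr1", 0, 100000)]
        variants = _snps(range(30)) + _snps(range(1000, 1970))
        stat, p, low = region_variability_test(pg4, region, variants)
        expected = _pearson_chi2([[30, 970], [970, 98030]])
        assert stat == pytest.approx(expected)
        assert 0 < p < 1 and not low

    def test_empty_pg4_set_raises(self):
        with pytest.raises(UndefinedDensityError):
            region_variability_test([], [("chr1", 0, 100)], _snps([5]))


BOUNDS = {"chr1": 10_000}


class TestLandscape:
    def test_length_30_bodies_equal_raw_means(self):
        pg4s = [PG4Interval("chr1", 100, 130, "+", 2.0, "a"),
                PG4Interval("chr1", 500, 530, "+", 2.0, "b")]
        variants = _snps([105, 505, 510])  # body offsets 5 (x2) and 10 (x1)
        prof = landscape(pg4s, variants, BOUNDS)
        expected = np.zeros(30)
        expected[5] = 1.0   # both pG4s have a variant at body offset 5
        expected[10] = 0.5  # one of two
        assert prof.body_values == pytest.approx(expected)
        assert prof.n_pg4s == 2

    def test_length_59_single_variant_keeps_endpoint(self):
        pg4 = PG4Interval("chr1", 100, 159, "+", 2.0, "a")
        prof = landscape([pg4], _snps([100]), BOUNDS)
        # interpolant through (0,1),(1,0),...,(58,0) sampled at x_j = 2j
        assert prof.body_values[0] == pytest.approx(1.0)
        assert prof.body_values[1:] == pytest.approx(np.zeros(29))

    def test_no_variants_gives_zero_profile_and_zero_scaled(self):
        pg4 = PG4Interval("chr1", 100, 130, "+", 2.0, "a")
        prof = landscape([pg4], [], BOUNDS)
        assert prof.values == pytest.approx(np.zeros(90))
        assert prof.scaled() == pytest.approx(np.zeros(90))

    def test_minus_strand_profile_is_reversed(self):
        pg4 = PG4Interval("chr1", 100, 130, "-", 2.0, "a")
        # variant at genomic body offset 29 = 5'-most body base on minus strand
        prof = landscape([pg4], _snps([129]), BOUNDS)
        assert prof.body_values[0] == pytest.approx(1.0)

    def test_flank_positions_beyond_chromosome_are_masked_not_zero(self):
        pg4 = PG4Interval("chr1", 10, 40, "+", 2.0, "a")  # 5' flank clipped at 0
        prof = landscape([pg4], _snps([5]), BOUNDS)
        # positions -20..-1 are missing; flank indices 0..19 had no coverage
        assert prof.flank5[:20] == pytest.approx(np.zeros(20))
        assert prof.flank5[25] == pytest.approx(1.0)  # genomic position 5

    def test_scaling_maps_to_unit_range(self):
        pg4 = PG4Interval("chr1", 100, 130, "+", 2.0, "a")
        prof = landscape([pg4], _snps([90, 105, 106]), BOUNDS)
        scaled = prof.scaled()
        assert scaled.min() == 0.0 and scaled.max() == 1.0


def _fisher_two_sided_oracle(a, b, c, d):
    """Brute-force hypergeometric two-sided p: sum P(k) over all tables at
    least as extreme (pmf <= pmf(a)) with the margins fixed."""
    N = a + b + c + d
    K = a + c          # total variant sites
    n = a + b          # pG4 positions
    def pmf(k):
        return (math.comb(K, k) * math.comb(N - K, n - k)) / math.comb(N, n)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(max(0, n + K - N), min(K, n) + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


class TestClassifyExtreme:
    def _run(self, a, pg4_len, c, region_extra_len, alpha=0.05):
        pg4 = PG4Interval("chr1", 0, pg4_len, "+", 2.0, "p1")
        region = GenomicIntervals({"chr1": [(0, pg4_len + region_extra_len)]})
        variants = _snps(range(a)) + _snps(range(pg4_len, pg4_len + c))
        return classify_extreme(pg4, region, variants, alpha)

    def test_no_variants_is_ns_with_p_one(self):
        res = self._run(0, 20, 0, 10_000)
        assert res.pg4_class == CLASS_NS and res.fisher_p == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        res = self._run(5, 20, 100, 10_000)
        oracle = _fisher_two_sided_oracle(5, 15, 100, 9_900)
        assert res.fisher_p == pytest.approx(oracle, rel=1e-6)
        assert res.pg4_class == (CLASS_VARIABLE if oracle < 0.05 else CLASS_NS)

    def test_depleted_pg4_classified_conserved(self):
        res = self._run(0, 100, 3000, 10_000)
        assert res.pg4_class == CLASS_CONSERVED

    def test_equal_densities_are_ns_regardless_of_p(self):
        res = self._run(2, 20, 1000, 10_000)
        if res.observed_variants / res.pg4_length == \
                res.region_variants / res.region_length:
            assert res.pg4_class == CLASS_NS

    def test_classify_all_excludes_all_footprints_from_background(self):
        pg4s = [PG4Interval("chr1", 0, 20, "+", 2.0, "a"),
                PG4Interval("chr1", 50, 70, "+", 2.0, "b")]
        region = GenomicIntervals({"chr1": [(0, 1000)]})
        out = classify_all(pg4s, region, _snps([5, 55, 200]))
        assert all(r.region_length == 1000 - 40 for r in out)
        assert all(r.region_variants == 1 for r in out)  # only pos 200


class TestRegression:
    def test_collinear_decreasing_points(self):
        pts = [("a", 1.0, 3.0), ("b", 2.0, 2.0), ("c", 3.0, 1.0)]
        res = enrichment_variability_regression(pts)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-1.0)

    def test_excluding_planted_outlier_restores_fit(self):
        base = [("a", 1.0, 2.0), ("b", 2.0, 1.5), ("c", 3.0, 1.0), ("d", 4.0, 0.5)]
        clean = enrichment_variability_regression(base)
        with_outlier = base + [("x", 10.0, 9.0)]
        restored = enrichment_variability_regression(with_outlier, exclude={"x"})
        assert restored.slope == pytest.approx(clean.slope)
        assert restored.intercept == pytest.approx(clean.intercept)
        assert restored.excluded == ["x"]

    def test_two_points_raise(self):
        with pytest.raises(InsufficientDataError):
            enrichment_variability_regression([("a", 1, 1), ("b", 2, 2)])
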