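"""Substitution spectra and delta-G4Hscore distributions."""
from __future__ import annotations

import numpy as np
import pytest

from pg4var.delta_score import (ALL_POSITIONS, FIXED_POSITIONS, DeltaSample,
                                SubstitutionSpectrum, background_spectrum,
                                compare_distributions, delta_g4hscore,
                                expand_theoretical, observed_sample,
                                per_position_expectation, theoretical_sample)
from pg4var.errors import DataInconsistencyError, InsufficientDataError
from pg4var.g4hunter import PG4Interval, revcomp
from pg4var.intervals import GenomicIntervals
from pg4var.variants import SNP, Variant

SEQ = "GGGGAGGGGAGGGGAGGGG"  # 19 nt, rescore 64/19
PG4 = PG4Interval("chr1", 0, 19, "+", 64 / 19, "p1")
REGION = GenomicIntervals({"chr1": [(0, 10_000)]})


class TestBackgroundSpectrum:
    def test_single_substitution_type(self):
        variants = [Variant("chr1", i, "G", "A", SNP) for i in range(10)]
        spec = background_spectrum(variants, REGION)
        assert spec.prob("G", "A") == 1.0
        assert spec.prob("G", "C") == 0.0 and spec.prob("G", "T") == 0.0

    def test_counts_normalized_per_ref(self):
        variants = ([Variant("chr1", i, "G", "A", SNP) for i in (0, 1)]
                    + [Variant("chr1", 2, "G", "T", SNP)]
                    + [Variant("chr1", 3, "G", "C", SNP)])
        spec = background_spectrum(variants, REGION)
        assert spec.prob("G", "A") == pytest.approx(0.5)
        assert spec.prob("G", "T") == pytest.approx(0.25)

    def test_equal_counts_give_uniform_rows(self):
        variants = [Variant("chr1", i, r, a, SNP)
                    for i, (r, a) in enumerate((r, a) for r in "ACGT"
                                               for a in "ACGT" if r != a)]
        spec = background_spectrum(variants, REGION)
        assert np.allclose(spec.probs[spec.probs > 0], 1 / 3)

    def test_missing_ref_falls_back_to_uniform_with_warning(self):
        variants = [Variant("chr1", 0, "G", "A", SNP)]
        with pytest.warns(UserWarning):
            spec = background_spectrum(variants, REGION)
        assert spec.prob("A", "C") == pytest.approx(1 / 3)

    def test_variants_outside_region_ignored(self):
        variants = [Variant("chr1", 50_000, "G", "A", SNP)]
        with pytest.warns(UserWarning):
            spec = background_spectrum(variants, REGION)
        assert spec.counts.sum() == 0


class TestDeltaG4Hscore:
    def test_g_run_truncation_worked_example(self):
        assert delta_g4hscore(SEQ, PG4, 0, "A") == pytest.approx(57 / 19 - 64 / 19)

    def test_loop_substitution_is_neutral(self):
        assert delta_g4hscore(SEQ, PG4, 4, "T") == 0.0

    def test_reversion_negates(self):
        mutated = "A" + SEQ[1:]
        fwd = delta_g4hscore(SEQ, PG4, 0, "A")
        back = delta_g4hscore(mutated, PG4, 0, "G")
        assert back == pytest.approx(-fwd)

    def test_minus_strand_evaluated_on_g_rich_strand(self):
        rc = revcomp(SEQ)  # C-rich on plus strand
        pg4 = PG4Interval("chr1", 0, 19, "-", 64 / 19, "p1")
        # plus-strand C->T at position 18 is G->A at G-rich position 0
        assert delta_g4hscore(rc, pg4, 18, "T") == pytest.approx(57 / 19 - 64 / 19)

    def test_ref_mismatch_raises(self):
        with pytest.raises(DataInconsistencyError, match="chr1:0"):
            delta_g4hscore(SEQ, PG4, 0, "A", ref="T")

    def test_position_outside_pg4_rejected(self):
        with pytest.raises(ValueError):
            delta_g4hscore(SEQ, PG4, 30, "A")


class TestTheoreticalSample:
    def test_all_positions_sample_size_3l(self):
        spec = SubstitutionSpectrum.uniform()
        sample = theoretical_sample(PG4, SEQ, spec, ALL_POSITIONS)
        assert len(sample) == 3 * 19

    def test_fixed_positions_sample_size_3m(self):
        spec = SubstitutionSpectrum.uniform()
        sample = theoretical_sample(PG4, SEQ, spec, FIXED_POSITIONS,
                                    variant_positions=[0, 5])
        assert len(sample) == 6

    def test_weights_sum_to_one_per_position(self):
        spec = SubstitutionSpectrum.uniform()
        sample = theoretical_sample(PG4, SEQ, spec, ALL_POSITIONS)
        assert sample.weights.reshape(-1, 3).sum(axis=1) == pytest.approx(
            np.ones(19))

    def test_fixed_positions_requires_positions(self):
        with pytest.raises(InsufficientDataError):
            theoretical_sample(PG4, SEQ, SubstitutionSpectrum.uniform(),
                               FIXED_POSITIONS)

    def test_per_position_expectation_mode(self):
        spec = SubstitutionSpectrum.uniform()
        sample = theoretical_sample(PG4, SEQ, spec, ALL_POSITIONS)
        exp = per_position_expectation(sample)
        assert len(exp) == 19
        assert exp[4] == pytest.approx(sample.values.reshape(-1, 3)[4].mean())


class TestObservedSample:
    def test_no_variants_empty(self):
        assert len(observed_sample([PG4], {"chr1": SEQ}, [])) == 0

    def test_single_variant_worked_value(self):
        variants = [Variant("chr1", 0, "G", "A", SNP)]
        sample = observed_sample([PG4], {"chr1": SEQ}, variants)
        assert sample.values == pytest.approx([57 / 19 - 64 / 19])
        assert sample.weights.tolist() == [1.0]

    def test_variants_outside_pg4_ignored_and_indels_skipped(self):
        variants = [Variant("chr1", 500, "G", "A", SNP),
                    Variant("chr1", 2, "GA", "G", "INDEL")]
        assert len(observed_sample([PG4], {"chr1": SEQ}, variants)) == 0


class TestCompareDistributions:
    def _theo(self, values):
        # degenerate weights: expansion deterministically returns `values`
        vals = np.repeat(np.asarray(values, dtype=float), 3)
        weights = np.tile([1.0, 0.0, 0.0], len(values))
        vals = vals.reshape(-1, 3)
        vals[:, 1:] = 99.0  # would be chosen only with nonzero weight
        return DeltaSample(ALL_POSITIONS, vals.ravel(), weights)

    def test_identical_samples_give_p_near_one(self):
        values = np.linspace(-1, 1, 200)
        theo = self._theo(values)
        obs = DeltaSample("observed", np.repeat(values, 10), np.ones(2000))
        res = compare_distributions(obs, theo, mc_draws=10, seed=0)
        assert res.p_value > 0.9

    def test_shifted_sample_detected(self):
        values = np.linspace(-1, 1, 200)
        theo = self._theo(values)
        obs = DeltaSample("observed", values - 1.0, np.ones(200))
        res = compare_distributions(obs, theo, mc_draws=10, seed=0)
        assert res.p_value < 0.01
        assert res.median_observed < res.median_theoretical

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(0)
        theo = DeltaSample(ALL_POSITIONS, rng.normal(size=30),
                           np.tile([0.2, 0.3, 0.5], 10))
        obs = DeltaSample("observed", rng.normal(size=40), np.ones(40))
        a = compare_distributions(obs, theo, seed=5)
        b = compare_distributions(obs, theo, seed=5)
        assert a == b

    def test_empty_sample_rejected(self):
        empty = DeltaSample("observed", np.zeros(0), np.zeros(0))
        theo = self._theo([0.0, 1.0])
        with pytest.raises(InsufficientDataError):
            compare_distributions(empty, theo)

    def test_expansion_respects_weights(self):
        theo = DeltaSample(ALL_POSITIONS, np.array([1.0, 2.0, 3.0]),
                           np.array([0.0, 1.0, 0.0]))
        expanded = expand_theoretical(theo, mc_draws=50, seed=1)
        assert set(expanded.tolist()) == {2.0}
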