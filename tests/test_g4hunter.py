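"""G4Hunter scoring and detection against independent oracles."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pg4var.errors import ParameterError
from pg4var.g4hunter import (DEFAULT_PARAMS, base_scores, detect_single_run,
                             multi_param_detect, rescore_interval,
                             rescore_with_context, revcomp, window_means)

from conftest import naive_base_scores, random_sequence

FOUR_TRACT = "GGGGTTAGGGGTTAGGGGTTAGGGG"  # 25 nt, 16 G at +4


@pytest.mark.parametrize("seq,expected", [
    ("GGGTTAGGG", [3, 3, 3, 0, 0, 0, 3, 3, 3]),
    ("CCCCC", [-4] * 5),
    ("ATATN", [0] * 5),
    ("GGGGGGG", [4] * 7),          # run cap at 4
    ("gggTTA", [0, 0, 0, 0, 0, 0]),  # soft-masked bases score 0
])
def test_base_scores_examples(seq, expected):
    assert base_scores(seq).tolist() == expected


def test_base_scores_mask_flag_off_restores_case_insensitivity():
    assert base_scores("gggTTA", masked_as_zero=False).tolist() == [3, 3, 3, 0, 0, 0]


def test_base_scores_warns_on_unknown_characters():
    with pytest.warns(UserWarning):
        scores = base_scores("GGXGG")
    assert scores.tolist() == [2, 2, 0, 2, 2]


def test_revcomp_negates_and_reverses_scores():
    seq = "GGGTTACCAGGGG"
    fwd = base_scores(seq.upper())
    rev = base_scores(revcomp(seq.upper()))
    assert rev.tolist() == (-fwd[::-1]).tolist()


@pytest.mark.parametrize("scores,ws,expected", [
    (base_scores("GGGTTAGGG"), 9, [2.0]),
    ([4] * 20, 20, [4.0]),
    ([1] * 10, 20, []),
])
def test_window_means_examples(scores, ws, expected):
    assert window_means(np.asarray(scores), ws).tolist() == pytest.approx(expected)


def test_window_means_rejects_nonpositive_window():
    with pytest.raises(ParameterError):
        window_means(np.zeros(5), 0)


class TestDetectSingleRun:
    def test_four_tract_example_marks_full_span(self):
        # every ws=20 window scores 48/20 = 2.4 >= 1.7 -> one merged [0, 25)
        assert detect_single_run(FOUR_TRACT, 20, 1.7, "+") == [(0, 25)]

    def test_all_a_yields_nothing(self):
        assert detect_single_run("A" * 50, 20, 1.7, "+") == []

    def test_reverse_complement_detected_on_minus_sign(self):
        assert detect_single_run(revcomp(FOUR_TRACT), 20, 1.7, "-") == [(0, 25)]

    def test_sequence_shorter_than_window_is_empty(self):
        assert detect_single_run("GGGG", 20, 1.7, "+") == []

    def test_two_separated_blocks_give_two_intervals(self):
        # windows reaching into the A-spacer may still qualify, so each
        # interval can extend beyond its G block but the blocks never merge
        seq = FOUR_TRACT + "A" * 40 + FOUR_TRACT
        hits = detect_single_run(seq, 20, 1.7, "+")
        assert len(hits) == 2
        (s1, e1), (s2, e2) = hits
        assert s1 <= 0 < 25 <= e1 <= 45 and s2 <= 65 < 90 <= e2
        assert e1 < s2


class TestMultiParamDetect:
    def test_default_params_on_four_tract(self):
        (pg4,) = multi_param_detect(FOUR_TRACT)
        assert (pg4.start, pg4.end) == (0, 25)
        assert pg4.g4hscore == pytest.approx(64 / 25)  # 2.56
        assert pg4.strand == "+"

    def test_all_a_sequence_empty(self):
        assert multi_param_detect("A" * 100) == []

    def test_two_blocks_with_wide_gap_stay_separate(self):
        seq = FOUR_TRACT + "A" * 40 + FOUR_TRACT
        pg4s = multi_param_detect(seq)
        assert len(pg4s) == 2
        assert pg4s[0].start <= 0 and pg4s[0].end >= 25
        assert pg4s[1].start <= 65 and pg4s[1].end >= 90
        assert pg4s[0].end < pg4s[1].start

    def test_minus_sign_reports_positive_score_with_minus_strand(self):
        (pg4,) = multi_param_detect(revcomp(FOUR_TRACT), sign="-")
        assert pg4.strand == "-"
        assert pg4.g4hscore == pytest.approx(64 / 25)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            multi_param_detect("GGGG", params=((0, 1.7),))
        with pytest.raises(ParameterError):
            multi_param_detect("GGGG", params=((20, -1.0),))


@pytest.mark.parametrize("seq,start,end,expected", [
    ("G" * 10, 0, 10, 4.0),
    ("GGGTTAGGGTTAGGGTTAGGG", 0, 21, 36 / 21),
    ("GGGGAGGGGAGGGGAGGGG", 0, 19, 64 / 19),
])
def test_rescore_worked_examples(seq, start, end, expected):
    assert rescore_interval(seq, start, end) == pytest.approx(expected)


def test_rescore_out_of_bounds_raises():
    with pytest.raises(IndexError):
        rescore_interval("GGGG", 0, 10)


def test_rescore_uses_full_sequence_run_context():
    # the Gs at [2, 4) belong to a run of 4, so they score 4 even though
    # the interval itself only holds 2 of them
    assert rescore_interval("GGGGTT", 2, 4) == pytest.approx(4.0)


@given(st.data())
@settings(max_examples=200, deadline=None)
def test_base_scores_match_naive_oracle(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    seq = random_sequence(rng, int(rng.integers(30, 301)),
                          float(rng.uniform(0.2, 0.8)), masked=True)
    assert base_scores(seq).tolist() == naive_base_scores(seq)


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=60, deadline=None)
def test_strand_antisymmetry_of_detection(seed):
    """G-rich hits on the plus strand mirror C-rich hits on the revcomp."""
    rng = np.random.default_rng(seed)
    seq = random_sequence(rng, 150, 0.7).upper()
    fwd = detect_single_run(seq, 20, 1.2, "+")
    rev = detect_single_run(revcomp(seq), 20, 1.2, "-")
    n = len(seq)
    mirrored = sorted((n - e, n - s) for s, e in rev)
    assert fwd == mirrored


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=60, deadline=None)
def test_lowering_threshold_never_shrinks_intervals(seed):
    rng = np.random.default_rng(seed)
    seq = random_sequence(rng, 200, 0.65).upper()
    strict = detect_single_run(seq, 20, 1.5, "+")
    loose = detect_single_run(seq, 20, 1.0, "+")
    for s, e in strict:
        assert any(ls <= s and e <= le for ls, le in loose)


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None)
def test_detected_intervals_rescore_in_unit_range(seed):
    rng = np.random.default_rng(seed)
    seq = random_sequence(rng, 400, 0.7).upper()
    for sign in "+-":
        for p in multi_param_detect(seq, DEFAULT_PARAMS, sign):
            assert 0 < p.g4hscore <= 4


@given(seed=st.integers(0, 2**31 - 1))
@settings(max_examples=100, deadline=None)
def test_context_rescore_matches_full_sequence_rescore(seed):
    rng = np.random.default_rng(seed)
    seq = random_sequence(rng, 120, 0.6).upper()
    s = int(rng.integers(0, 100))
    e = int(rng.integers(s + 1, 121))
    assert rescore_with_context(seq, s, e) == pytest.approx(
        rescore_interval(seq, s, e))
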