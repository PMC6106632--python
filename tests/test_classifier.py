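"""The five-split avoidance classifier: examples, boundaries, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kidscore.cohort import AnnotationTimes
from kidscore.model import (
    DegenerateTimesError,
    KidThresholds,
    SplitRule,
    UnclassifiableError,
    classify,
    irregularity_index,
)


def brute_force_classify(times: AnnotationTimes, th: KidThresholds):
    """Independent oracle: evaluate all five predicates, apply first match.

    Written as a flat predicate list rather than short-circuiting code so
    it shares no structure with the implementation under test.
    """
    tpnf, t2, t3, t5, t8 = times.tPNf, times.t2, times.t3, times.t5, times.t8
    idx = None
    if t5 is not None and t5 > t2:
        idx = (t5 - t3) / (t5 - t2)
    predicates = [
        (1, SplitRule.FAST_START, t3 - tpnf < th.fast_start_cut),
        (2, SplitRule.SLOW_START, t3 >= th.slow_start_cut),
        (3, SplitRule.IRREGULAR_LOW, idx is not None and idx < th.index_low_cut),
        (4, SplitRule.IRREGULAR_HIGH, idx is not None and idx >= th.index_high_cut),
        (4, SplitRule.SLOW_T8, t5 is None or t8 is None or t8 >= th.t8_deadline),
        (5, SplitRule.PASS, True),
    ]
    for cls, rule, fired in predicates:
        if fired:
            return cls, rule
    raise AssertionError("unreachable")


@pytest.mark.parametrize(
    "t2,t3,t5,expected",
    [
        (26.0, 38.0, 50.0, 0.5),
        (26.0, 26.0, 50.0, 1.0),
        (26.0, 50.0, 50.0, 0.0),
    ],
)
def test_irregularity_index_values(t2, t3, t5, expected):
    assert irregularity_index(t2, t3, t5) == pytest.approx(expected)


def test_irregularity_index_degenerate_inputs():
    with pytest.raises(DegenerateTimesError):
        irregularity_index(26.0, 26.0, 26.0)  # t5 <= t2
    with pytest.raises(DegenerateTimesError):
        irregularity_index(26.0, 55.0, 50.0)  # t3 outside [t2, t5]


@pytest.mark.parametrize(
    "times,expected_class,expected_rule",
    [
        # too fast start: t3 - tPNf = 11.0 < 11.48
        (dict(tPNf=24.0, t2=26.0, t3=35.0), 1, SplitRule.FAST_START),
        # too slow start: t3 = 43.0 >= 42.91 (and split 1 passed: 17.0)
        (dict(tPNf=26.0, t2=30.0, t3=43.0), 2, SplitRule.SLOW_START),
        # increasing pace: index 5/17 ~ 0.294 < 0.3408
        (dict(tPNf=24.0, t2=26.0, t3=38.0, t5=43.0), 3, SplitRule.IRREGULAR_LOW),
        # decreasing pace: index 23/34 ~ 0.676 >= 0.5781 (splits 1-3 passed)
        (dict(tPNf=24.0, t2=26.0, t3=37.0, t5=60.0), 4, SplitRule.IRREGULAR_HIGH),
        # index inside window but eight cells only at 67 h
        (dict(tPNf=24.0, t2=26.0, t3=36.0, t5=44.0, t8=67.0), 4, SplitRule.SLOW_T8),
        # passes every avoidance criterion
        (dict(tPNf=24.0, t2=26.0, t3=36.0, t5=44.0, t8=52.0), 5, SplitRule.PASS),
    ],
)
def test_classify_examples(times, expected_class, expected_rule):
    res = classify(AnnotationTimes(**times))
    assert (res.kid_class, res.rule) == (expected_class, expected_rule)


@pytest.mark.parametrize(
    "times,expected_class",
    [
        # t3 - tPNf == 11.48 exactly (float-exact with tPNf=20): NOT too fast
        (dict(tPNf=20.0, t2=24.0, t3=31.48, t5=36.0, t8=52.0), 5),
        (dict(tPNf=20.0, t2=24.0, t3=31.47, t5=36.0, t8=52.0), 1),
        # t3 exactly 42.91 IS too slow; a frame earlier is not
        (dict(tPNf=20.0, t2=30.0, t3=42.91), 2),
        (dict(tPNf=20.0, t2=30.0, t3=42.90, t5=52.0, t8=60.0), 5),
        # index one ulp below 0.3408 IS irregular-low
        # ((51-42.480000000000004)/25 -> 0.3407999999999998)
        (dict(tPNf=24.0, t2=26.0, t3=42.480000000000004, t5=51.0, t8=60.0), 3),
        # index one ulp above 0.3408 is NOT ((36-32.592)/10 -> 0.3408000000000001)
        (dict(tPNf=20.0, t2=26.0, t3=32.592, t5=36.0, t8=55.0), 5),
        # index one ulp above 0.5781 IS irregular-high
        # ((51-36.5475)/25 -> 0.5781000000000001)
        (dict(tPNf=24.0, t2=26.0, t3=36.5475, t5=51.0, t8=60.0), 4),
        # index one ulp below 0.5781 is NOT ((36-30.219)/10 -> 0.5780999999999998)
        (dict(tPNf=18.0, t2=26.0, t3=30.219, t5=36.0, t8=55.0), 5),
        # t8 exactly at the 66 h deadline is NOT "before 66"
        (dict(tPNf=24.0, t2=26.0, t3=36.0, t5=44.0, t8=66.0), 4),
        (dict(tPNf=24.0, t2=26.0, t3=36.0, t5=44.0, t8=65.99), 5),
    ],
)
def test_boundary_semantics(times, expected_class):
    assert classify(AnnotationTimes(**times)).kid_class == expected_class


@pytest.mark.parametrize(
    "low,high,t3,t5,expected_class",
    [
        # exactly-representable cuts: index == low_cut is NOT irregular-low,
        # index == high_cut IS irregular-high (comparison directions)
        (0.25, 0.5781, 38.0, 42.0, 5),  # idx = 4/16 = 0.25 exactly
        (0.25, 0.5, 34.0, 42.0, 4),     # idx = 8/16 = 0.5 exactly
    ],
)
def test_index_cut_inclusivity_exact(low, high, t3, t5, expected_class):
    th = KidThresholds(index_low_cut=low, index_high_cut=high)
    times = AnnotationTimes(tPNf=20.0, t2=26.0, t3=t3, t5=t5, t8=55.0)
    assert classify(times, th).kid_class == expected_class


def test_split_order_fast_beats_slow():
    """An embryo failing both start splits is class 1: order is part of the model."""
    # t3 - tPNf = 10 < 11.48 AND t3 = 45 >= 42.91
    res = classify(AnnotationTimes(tPNf=35.0, t2=40.0, t3=45.0))
    assert res.kid_class == 1 and res.rule == SplitRule.FAST_START


def test_absent_t5_routes_to_class4():
    """No five-cell stage means no eight cells before the deadline either."""
    res = classify(AnnotationTimes(tPNf=24.0, t2=28.0, t3=38.0))
    assert res.kid_class == 4 and res.rule == SplitRule.SLOW_T8
    assert res.index is None


def test_absent_t8_routes_to_class4():
    res = classify(AnnotationTimes(tPNf=24.0, t2=26.0, t3=36.0, t5=44.0))
    assert res.kid_class == 4 and res.rule == SplitRule.SLOW_T8
    assert res.index == pytest.approx(8 / 18)


@pytest.mark.parametrize("missing", ["tPNf", "t2", "t3"])
def test_missing_mandatory_annotation(missing):
    kwargs = dict(tPNf=24.0, t2=26.0, t3=36.0)
    kwargs.pop(missing)
    with pytest.raises(UnclassifiableError, match=missing):
        classify(AnnotationTimes(**kwargs))


def _random_times(rng: np.random.Generator) -> AnnotationTimes:
    """A random valid annotation vector spanning all decision regions."""
    tpnf = rng.uniform(18.0, 36.0)
    t2 = tpnf + rng.uniform(0.1, 10.0)
    t3 = t2 + rng.uniform(0.0, 18.0)
    t5 = t8 = None
    if rng.random() < 0.9:
        t5 = t3 + rng.uniform(0.01, 25.0)
        if rng.random() < 0.9:
            t8 = t5 + rng.uniform(0.0, 25.0)
    return AnnotationTimes(tPNf=tpnf, t2=t2, t3=t3, t5=t5, t8=t8)


def test_oracle_agreement_10k(rng, thresholds):
    """classify matches the flat predicate-enumeration oracle on 10,000 vectors."""
    for _ in range(10_000):
        times = _random_times(rng)
        res = classify(times, thresholds)
        assert (res.kid_class, res.rule) == brute_force_classify(times, thresholds)


@given(
    tpnf=st.floats(15.0, 40.0),
    d2=st.floats(0.1, 12.0),
    d3=st.floats(0.0, 20.0),
    d5=st.floats(0.01, 30.0),
    d8=st.floats(0.0, 30.0),
    have5=st.booleans(),
    have8=st.booleans(),
)
def test_classify_total_and_consistent(tpnf, d2, d3, d5, d8, have5, have8):
    """Exactly one result on every classifiable vector; index in [0, 1]."""
    t2 = tpnf + d2
    t3 = t2 + d3
    t5 = t3 + d5 if have5 else None
    t8 = t5 + d8 if have5 and have8 else None
    res = classify(AnnotationTimes(tPNf=tpnf, t2=t2, t3=t3, t5=t5, t8=t8))
    assert res.kid_class in (1, 2, 3, 4, 5)
    if res.index is not None:
        assert 0.0 <= res.index <= 1.0
    if res.kid_class == 5:
        assert res.index is not None  # splits 3-4 were necessarily evaluated


def test_threshold_config_validation():
    with pytest.raises(ValueError):
        KidThresholds(index_low_cut=0.7, index_high_cut=0.6)
    with pytest.raises(ValueError):
        KidThresholds(fast_start_cut=-1.0)


def test_thresholds_from_yaml(tmp_path):
    cfg = tmp_path / "th.yaml"
    cfg.write_text("fast_start_cut: 10.0\nt8_deadline: 70\n")
    th = KidThresholds.from_yaml(cfg)
    assert th.fast_start_cut == 10.0 and th.t8_deadline == 70.0
    assert th.slow_start_cut == 42.91  # untouched defaults remain
    # the override changes the verdict of a borderline embryo
    times = AnnotationTimes(tPNf=24.0, t2=26.0, t3=35.0)
    assert classify(times).kid_class == 1
    assert classify(times, th).kid_class != 1
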