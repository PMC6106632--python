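"""KIDScore D3 Basic: a five-split hierarchical avoidance classifier.

The model ranks a day-3 embryo into an ordinal class 1 (avoid) to 5
(best) from a handful of annotated division times, by applying five
exclusion rules strictly in order and stopping at the first that fires:

1. too fast initial development, t3 - tPNf < 11.48 h          -> class 1
2. too slow initial development, t3 >= 42.91 h                -> class 2
3. irregularity index (t5-t3)/(t5-t2) < 0.3408                -> class 3
4. irregularity index >= 0.5781                               -> class 4
5. eight-cell stage not reached before 66 h post insemination -> class 4
else                                                          -> class 5

The irregularity index is the fraction of the 2-cell -> 5-cell interval
spent after the 3-cell stage; values near 0 or 1 mean the two division
rounds were strongly uneven.  Class 4 therefore contains two embryo
types, tagged by the rule that fired.  Being an avoidance model, it
keeps many embryos in the top class rather than selecting a narrow
ideal window.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .cohort import AnnotationTimes

__all__ = [
    "KidThresholds",
    "KidResult",
    "SplitRule",
    "UnclassifiableError",
    "DegenerateTimesError",
    "irregularity_index",
    "classify",
]


class UnclassifiableError(ValueError):
    """A mandatory annotation (tPNf, t2 or t3) is absent."""

    def __init__(self, missing: str):
        self.missing = missing
        super().__init__(f"cannot classify: annotation {missing!r} is absent")


class DegenerateTimesError(ValueError):
    """Times violate the ordering the index formula needs (t2 <= t3 <= t5, t5 > t2)."""


class SplitRule(str, enum.Enum):
    """Which split fired (PASS = none did)."""

    FAST_START = "FAST_START"
    SLOW_START = "SLOW_START"
    IRREGULAR_LOW = "IRREGULAR_LOW"
    IRREGULAR_HIGH = "IRREGULAR_HIGH"
    SLOW_T8 = "SLOW_T8"
    PASS = "PASS"


#: class implied by each rule
_RULE_CLASS = {
    SplitRule.FAST_START: 1,
    SplitRule.SLOW_START: 2,
    SplitRule.IRREGULAR_LOW: 3,
    SplitRule.IRREGULAR_HIGH: 4,
    SplitRule.SLOW_T8: 4,
    SplitRule.PASS: 5,
}


@dataclass(frozen=True)
class KidThresholds:
    """Numeric cut-offs of the five splits (hours / index ratio).

    Defaults are the published model constants; override for sensitivity
    analysis (e.g. :meth:`from_yaml`).
    """

    fast_start_cut: float = 11.48  # on t3 - tPNf, strict <
    slow_start_cut: float = 42.91  # on t3, inclusive >=
    index_low_cut: float = 0.3408  # strict <
    index_high_cut: float = 0.5781  # inclusive >=
    t8_deadline: float = 66.0  # "before 66 HPI": t8 >= 66 fails

    def __post_init__(self) -> None:
        if not (0.0 < self.index_low_cut < self.index_high_cut < 1.0):
            raise ValueError("need 0 < index_low_cut < index_high_cut < 1")
        for name in ("fast_start_cut", "slow_start_cut", "t8_deadline"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "KidThresholds":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class KidResult:
    """Ordinal class 1-5 with the rule that fired and the irregularity index.

    ``index`` is present whenever splits 3-4 were evaluated (t5 known and
    splits 1-2 passed), and then lies in [0, 1].
    """

    kid_class: int
    rule: SplitRule
    index: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kid_class != _RULE_CLASS[self.rule]:
            raise ValueError(f"class {self.kid_class} inconsistent with rule {self.rule}")


def irregularity_index(t2: float, t3: float, t5: float) -> float:
    """(t5 - t3) / (t5 - t2): fraction of the 2->5-cell interval after 3 cells.

    Requires t2 <= t3 <= t5 and t5 > t2; the value then lies in [0, 1].
    """
    if t5 <= t2:
        raise DegenerateTimesError(f"t5 must exceed t2 (t2={t2}, t5={t5})")
    if not (t2 <= t3 <= t5):
        raise DegenerateTimesError(f"t3 must lie in [t2, t5] (t2={t2}, t3={t3}, t5={t5})")
    return (t5 - t3) / (t5 - t2)


def classify(times: AnnotationTimes, thresholds: KidThresholds | None = None) -> KidResult:
    """Apply the five splits in order; return the first that fires.

    tPNf, t2 and t3 must be present (splits 1-2).  If splits 3-4 are
    reached with t5 absent the embryo never reached five cells, so it
    cannot have reached eight cells before the deadline either: it is
    routed to class 4 via the slow-t8 rule with no index.  An absent t8
    at split 5 likewise means the eight-cell stage was not observed
    before the deadline.
    """
    th = thresholds or KidThresholds()
    for name in ("tPNf", "t2", "t3"):
        if times.get(name) is None:
            raise UnclassifiableError(name)
    tpnf, t2, t3 = times.tPNf, times.t2, times.t3

    if t3 - tpnf < th.fast_start_cut:
        return KidResult(1, SplitRule.FAST_START)
    if t3 >= th.slow_start_cut:
        return KidResult(2, SplitRule.SLOW_START)

    t5 = times.t5
    if t5 is None:
        return KidResult(4, SplitRule.SLOW_T8)
    idx = irregularity_index(t2, t3, t5)
    if idx < th.index_low_cut:
        return KidResult(3, SplitRule.IRREGULAR_LOW, idx)
    if idx >= th.index_high_cut:
        return KidResult(4, SplitRule.IRREGULAR_HIGH, idx)

    t8 = times.t8
    if t8 is None or t8 >= th.t8_deadline:
        return KidResult(4, SplitRule.SLOW_T8, idx)
    return KidResult(5, SplitRule.PASS, idx)
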