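"""Cohort outcome statistics: nested endpoint rates, contributions, tests.

Three nested binary endpoints are tracked per transfer: a positive
beta-hCG test (pregnancy rate, PR), a clinical pregnancy confirmed by
fetal heartbeat on ultrasound (CPR), and a live birth (LBR).  Nesting
means live birth implies clinical pregnancy implies positive hCG, so
LBR <= CPR <= PR for any group.

Rates are percentages of transfers; the "contribution" of a class to an
endpoint is its share of all events of that endpoint (e.g. the fraction
of all live births that came from class-5 transfers).  Rates and
contributions are reported to one decimal, rounding half away from
zero, matching clinical table conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ENDPOINTS",
    "OutcomeFlags",
    "ClassSummary",
    "UndefinedRateError",
    "round_half_away",
    "rate",
    "summarize_by",
    "fold_change",
    "fisher_exact",
    "ordinal_trend",
    "cross_table",
]

ENDPOINTS = ("PR", "CPR", "LBR")

#: endpoint -> OutcomeFlags attribute
_ENDPOINT_ATTR = {"PR": "hcg_positive", "CPR": "clinical_pregnancy", "LBR": "live_birth"}


class UndefinedRateError(ZeroDivisionError):
    """A rate or ratio over an empty denominator."""


@dataclass(frozen=True)
class OutcomeFlags:
    """Nested transfer outcome: hCG rise, clinical pregnancy, live birth."""

    hcg_positive: bool
    clinical_pregnancy: bool
    live_birth: bool

    def violations(self) -> list[str]:
        """Breaches of the nesting live birth => clinical => hCG."""
        out = []
        if self.live_birth and not self.clinical_pregnancy:
            out.append("live_birth without clinical_pregnancy")
        if self.clinical_pregnancy and not self.hcg_positive:
            out.append("clinical_pregnancy without hcg_positive")
        return out

    def is_nested(self) -> bool:
        return not self.violations()

    def event(self, endpoint: str) -> bool:
        return getattr(self, _ENDPOINT_ATTR[endpoint])


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (25.05 -> 25.1, not banker's 25.0)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def rate(events: int, n: int, ndigits: int = 1) -> float:
    """Percentage of transfers with the event, to one decimal by default."""
    if n <= 0:
        raise UndefinedRateError("rate undefined for n = 0")
    if not 0 <= events <= n:
        raise ValueError(f"events {events} outside [0, {n}]")
    return round_half_away(100.0 * events / n, ndigits)


@dataclass
class ClassSummary:
    """Per-class transfer count, endpoint rates and cohort contributions.

    Rates and contributions are 1-decimal percentages; ``None`` marks a
    class with no transfers (rate undefined) or an endpoint with zero
    events cohort-wide (contribution undefined).
    """

    label: str
    n: int
    events: dict[str, int] = field(default_factory=dict)  # endpoint -> count
    pr: Optional[float] = None
    cpr: Optional[float] = None
    lbr: Optional[float] = None
    contribution_transfers: Optional[float] = None
    contribution_pr: Optional[float] = None
    contribution_cpr: Optional[float] = None
    contribution_lbr: Optional[float] = None

    def rate_of(self, endpoint: str) -> Optional[float]:
        return {"PR": self.pr, "CPR": self.cpr, "LBR": self.lbr}[endpoint]

    def unrounded_rate(self, endpoint: str) -> float:
        if self.n == 0:
            raise UndefinedRateError(f"class {self.label} has no transfers")
        return 100.0 * self.events[endpoint] / self.n


def summarize_by(
    records: Iterable,
    classifier: Callable[[object], Hashable],
    order: Sequence[Hashable] | None = None,
) -> list[ClassSummary]:
    """Group records by ``classifier`` and tabulate n, rates, contributions.

    Every record must carry outcome flags (transferred embryos); a record
    without them raises, naming its embryo id.  ``order`` fixes the class
    order (and forces empty classes to appear, with rates marked
    undefined); by default classes appear in first-encounter order.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort: nothing to summarize")
    counts: dict[Hashable, int] = {}
    events: dict[Hashable, dict[str, int]] = {}
    if order is not None:
        for label in order:
            counts[label] = 0
            events[label] = {e: 0 for e in ENDPOINTS}
    for rec in records:
        outcome: OutcomeFlags | None = getattr(rec, "outcome", None)
        if outcome is None:
            eid = getattr(rec, "embryo_id", "?")
            raise ValueError(f"record {eid!r} lacks outcome flags")
        label = classifier(rec)
        counts.setdefault(label, 0)
        events.setdefault(label, {e: 0 for e in ENDPOINTS})
        counts[label] += 1
        for e in ENDPOINTS:
            events[label][e] += int(outcome.event(e))
    total_n = sum(counts.values())
    total_events = {e: sum(ev[e] for ev in events.values()) for e in ENDPOINTS}
    out: list[ClassSummary] = []
    for label in counts:
        n = counts[label]
        ev = events[label]
        summary = ClassSummary(label=str(label), n=n, events=dict(ev))
        if n > 0:
            summary.pr = rate(ev["PR"], n)
            summary.cpr = rate(ev["CPR"], n)
            summary.lbr = rate(ev["LBR"], n)
        summary.contribution_transfers = rate(n, total_n)
        for e, attr in (("PR", "contribution_pr"), ("CPR", "contribution_cpr"),
                        ("LBR", "contribution_lbr")):
            if total_events[e] > 0:
                setattr(summary, attr, rate(ev[e], total_events[e]))
        out.append(summary)
    return out


def fold_change(
    summaries: Sequence[ClassSummary], num: str, den: str, endpoint: str = "LBR"
) -> float:
    """Rate ratio between two classes on one endpoint, to one decimal.

    Computed on the unrounded rates (the printed 1-decimal rates give the
    same answer for the published comparisons).
    """
    by_label = {s.label: s for s in summaries}
    try:
        s_num, s_den = by_label[str(num)], by_label[str(den)]
    except KeyError as exc:
        raise KeyError(f"class {exc.args[0]!r} not present in summaries") from None
    den_rate = s_den.unrounded_rate(endpoint)
    if den_rate == 0:
        raise UndefinedRateError(f"denominator class {den!r} has zero {endpoint}")
    return round_half_away(s_num.unrounded_rate(endpoint) / den_rate, 1)


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Probability-mass rule: with margins fixed, sum the hypergeometric
    probabilities of every table at most as probable as the observed one
    (with 1e-7 relative slack against ties lost to floating point).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table: p undefined")
    row1, col1 = a + b, a + c
    k_min = max(0, col1 - (c + d))
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def ordinal_trend(
    summaries: Sequence[ClassSummary], endpoint: str = "LBR"
) -> tuple[float, float, float]:
    """OLS of the endpoint rate on the class rank 1..k.

    Classes are coded by their position in ``summaries`` (rank order);
    classes with undefined rates are skipped.  Returns (slope in
    percentage points per class, intercept, r-squared).
    """
    xs, ys = [], []
    for i, s in enumerate(summaries, start=1):
        r = s.rate_of(endpoint)
        if r is not None:
            xs.append(float(i))
            ys.append(r)
    if len(xs) < 2:
        raise ValueError("need at least two classes with defined rates")
    if all(y == ys[0] for y in ys):  # linregress r is undefined for constant y
        return 0.0, ys[0], 0.0
    fit = stats.linregress(xs, ys)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2


def cross_table(
    records: Iterable,
    classifier_a: Callable[[object], Hashable],
    classifier_b: Callable[[object], Hashable],
    endpoint: str = "LBR",
) -> dict[tuple[Hashable, Hashable], tuple[int, Optional[float]]]:
    """Joint table over two classings: cell -> (n, endpoint rate or None).

    Only populated cells appear; a cell with n > 0 carries its 1-decimal
    rate.  Used for the morphokinetics-by-morphology interaction (e.g.
    live birth rate of class-5 embryos within each morphology group).
    """
    cells: dict[tuple[Hashable, Hashable], list[int]] = {}
    for rec in records:
        outcome: OutcomeFlags | None = getattr(rec, "outcome", None)
        if outcome is None:
            eid = getattr(rec, "embryo_id", "?")
            raise ValueError(f"record {eid!r} lacks outcome flags")
        key = (classifier_a(rec), classifier_b(rec))
        n_ev = cells.setdefault(key, [0, 0])
        n_ev[0] += 1
        n_ev[1] += int(outcome.event(endpoint))
    return {key: (n, rate(ev, n) if n else None) for key, (n, ev) in cells.items()}
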