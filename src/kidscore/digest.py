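"""The published validation-study summary tables, encoded as fixture data.

The underlying patient-level cohort (768 single-embryo transfers,
2013-2015) was never deposited; what survives are the per-group and
per-class summary tables: transfer counts with pregnancy (PR), clinical
pregnancy (CPR) and live-birth (LBR) percentages, class contributions,
morphokinetic-class-conditional blastulation rates, and the live-birth
rates of top-class embryos within each morphology group.

This module packages those printed numbers, reconstructs integer event
counts from (n, rate) pairs by nearest-integer inversion, and exposes
arithmetic self-consistency checks (reconstructed counts must sum to the
printed totals).  One known misprint is preserved rather than hidden:
the per-group PR counts in the transfer-group table sum to 379 while
the printed total is 380 (the per-class table is consistent at 380);
``consistency_report`` flags it as informational.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .outcomes import round_half_away

__all__ = [
    "GroupRow",
    "ClassRow",
    "TABLE1",
    "TABLE1_TOTAL",
    "TABLE2_DAY3",
    "TABLE2_BLAST",
    "TABLE3_DAY3",
    "BLASTULATION_BY_KID",
    "KID5_LBR_BY_MORPH",
    "KID_ORDER",
    "reconstruct_events",
    "pooled_kid_counts",
    "consistency_report",
]

KID_ORDER = ("KID1", "KID2", "KID3", "KID4", "KID5")


def reconstruct_events(n: int, rate_pct: float) -> int:
    """Nearest-integer event count implied by a printed (n, rate%) pair."""
    return int(round_half_away(n * rate_pct / 100.0, 0))


@dataclass(frozen=True)
class GroupRow:
    """One transfer group: printed n, rates (%) and absolute event counts."""

    transfer_day: str
    state: str
    n: int
    pr: float
    pr_n: int
    cpr: float
    cpr_n: int
    lbr: float
    lbr_n: int


@dataclass(frozen=True)
class ClassRow:
    """One class within a stage: printed n, rates (%) and contributions (%)."""

    label: str
    n: int
    c_transfers: float
    pr: float
    c_pr: float
    cpr: float
    c_cpr: float
    lbr: float
    c_lbr: float

    def events(self, endpoint: str) -> int:
        pct = {"PR": self.pr, "CPR": self.cpr, "LBR": self.lbr}[endpoint]
        return reconstruct_events(self.n, pct)


#: outcome by transfer group (day of transfer x fresh/frozen)
TABLE1 = (
    GroupRow("D3", "fresh", 116, 31.0, 36, 28.4, 33, 25.0, 29),
    GroupRow("D5", "fresh", 287, 55.7, 160, 44.9, 129, 43.2, 124),
    GroupRow("D5", "frozen", 285, 54.4, 155, 38.9, 111, 36.5, 104),
    GroupRow("D6", "frozen", 80, 35.0, 28, 32.5, 26, 32.5, 26),
)

#: printed cohort totals (n, PR%, PR n, CPR%, CPR n, LBR%, LBR n)
TABLE1_TOTAL = GroupRow("all", "all", 768, 49.5, 380, 38.9, 299, 36.8, 283)

#: morphokinetic class x outcome for day-3 (cleavage stage) transfers
TABLE2_DAY3 = (
    ClassRow("KID1", 4, 3.4, 25.0, 2.8, 25.0, 3.0, 0.0, 0.0),
    ClassRow("KID2", 11, 9.5, 9.1, 2.8, 9.1, 3.0, 0.0, 0.0),
    ClassRow("KID3", 7, 6.0, 28.6, 5.6, 28.6, 6.1, 14.3, 3.4),
    ClassRow("KID4", 22, 19.0, 22.7, 13.9, 22.7, 15.2, 18.2, 13.8),
    ClassRow("KID5", 72, 62.1, 37.5, 75.0, 33.3, 72.7, 33.3, 82.8),
)

#: morphokinetic class x outcome for blastocyst (day-5 + day-6) transfers
TABLE2_BLAST = (
    ClassRow("KID1", 33, 5.1, 30.3, 2.9, 21.2, 2.6, 21.2, 2.8),
    ClassRow("KID2", 45, 6.9, 33.3, 4.4, 22.2, 3.8, 22.2, 3.9),
    ClassRow("KID3", 24, 3.7, 45.8, 3.2, 37.5, 3.4, 33.3, 3.1),
    ClassRow("KID4", 146, 22.4, 54.1, 23.0, 37.7, 20.7, 35.6, 20.5),
    ClassRow("KID5", 404, 62.0, 56.7, 66.6, 45.8, 69.5, 43.8, 69.7),
)

#: morphology class x outcome for day-3 transfers, worst class first.
#: The blastocyst half of this table is internally inconsistent as
#: printed (rate columns duplicating contribution columns, shares that
#: cannot arise from the printed n) and is deliberately not packaged.
TABLE3_DAY3 = (
    ClassRow("PQE", 11, 9.5, 18.2, 5.6, 18.2, 6.1, 18.2, 6.9),
    ClassRow("GQE", 71, 61.2, 32.4, 63.9, 31.0, 66.7, 26.8, 65.5),
    ClassRow("TQE", 34, 29.3, 32.4, 30.6, 26.5, 27.3, 23.5, 27.6),
)

#: probability of forming a clinically usable blastocyst by class
#: (separate cohort of 656 normally fertilized oocytes)
BLASTULATION_BY_KID = {
    "KID1": 0.23, "KID2": 0.21, "KID3": 0.21, "KID4": 0.36, "KID5": 0.66,
}

#: live-birth rate (%) of class-5 embryos within each morphology group
KID5_LBR_BY_MORPH = {"TQE": 45.0, "GQE": 41.0, "PQE": 40.0, "Slow": 34.0}


def pooled_kid_counts(endpoint: str = "LBR") -> dict[str, tuple[int, int]]:
    """Per-class (events, n) pooled over day-3 and blastocyst transfers."""
    out: dict[str, tuple[int, int]] = {}
    for d3, bl in zip(TABLE2_DAY3, TABLE2_BLAST):
        assert d3.label == bl.label
        out[d3.label] = (d3.events(endpoint) + bl.events(endpoint), d3.n + bl.n)
    return out


@dataclass(frozen=True)
class Check:
    """One arithmetic self-consistency check on the packaged tables."""

    name: str
    expected: float
    computed: float
    informational: bool = False

    @property
    def ok(self) -> bool:
        return self.expected == self.computed


def consistency_report() -> list[Check]:
    """Arithmetic checks: reconstructed counts vs printed totals.

    Failures of informational checks reflect misprints in the source
    tables, not packaging errors.
    """
    checks: list[Check] = []
    checks.append(Check("transfer-group n sum", TABLE1_TOTAL.n,
                        sum(r.n for r in TABLE1)))
    for endpoint, total in (("PR", TABLE1_TOTAL.pr_n), ("CPR", TABLE1_TOTAL.cpr_n),
                            ("LBR", TABLE1_TOTAL.lbr_n)):
        attr = {"PR": "pr_n", "CPR": "cpr_n", "LBR": "lbr_n"}[endpoint]
        checks.append(Check(
            f"transfer-group {endpoint} count sum", total,
            sum(getattr(r, attr) for r in TABLE1),
            informational=(endpoint == "PR"),  # known misprint: 379 vs 380
        ))
    for endpoint, total in (("PR", TABLE1_TOTAL.pr_n), ("CPR", TABLE1_TOTAL.cpr_n),
                            ("LBR", TABLE1_TOTAL.lbr_n)):
        pooled = pooled_kid_counts(endpoint)
        checks.append(Check(
            f"per-class reconstructed {endpoint} count sum", total,
            sum(ev for ev, _ in pooled.values()),
        ))
    checks.append(Check("per-class n sum", TABLE1_TOTAL.n,
                        sum(n for _, n in pooled_kid_counts("LBR").values())))
    checks.append(Check("day-3 morphology n sum", 116,
                        sum(r.n for r in TABLE3_DAY3)))
    checks.append(Check(
        "day-3 morphology reconstructed LBR count sum",
        TABLE1[0].lbr_n, sum(r.events("LBR") for r in TABLE3_DAY3),
    ))
    for rows, stage in ((TABLE2_DAY3, "day-3"), (TABLE2_BLAST, "blastocyst"),
                        (TABLE3_DAY3, "day-3 morphology")):
        for r in rows:
            if not (r.lbr <= r.cpr <= r.pr):
                checks.append(Check(f"{stage} {r.label} nesting LBR<=CPR<=PR", 1, 0))
    return checks
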