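"""Seeded synthetic time-lapse cohorts with the study's statistical structure.

The generator emulates a single-embryo-transfer validation cohort: four
transfer groups (day-3 fresh, day-5 fresh, day-5 frozen, day-6 frozen),
a fixed morphokinetic class distribution, class- and stage-conditional
nested outcome probabilities, stage-conditional morphology grades, and
class-conditional blastulation.  Defaults reproduce the published
cohort's marginal structure (group sizes 116/287/285/80, class shares
5/7/4/22/62%, the per-class outcome triples, blastulation rates
23/21/21/36/66%).

Annotation times are drawn by *constructive inversion* of the
classifier: for a target class, times are sampled uniformly inside the
threshold-defined region that fails exactly that split while passing
all earlier ones, so ``classify(sample_times_for_class(k)) == k`` holds
by construction and rare classes cost no rejection sampling.  The time
distributions themselves (pronuclear fading ~ U(20, 28) h, uniform
inter-division gaps) are non-biological conveniences: no within-class
kinetic distributions were ever published, so the kinetics are a
labelled stand-in, not a model of real embryos.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort import AnnotationTimes, EmbryoRecord
from .model import KidThresholds, classify
from .outcomes import OutcomeFlags
from . import digest

__all__ = [
    "GeneratorConfig",
    "sample_times_for_class",
    "sample_outcomes",
    "generate_cohort",
]

#: safety margin (hours) kept between sampled times and threshold cuts,
#: wide enough that rounding times to 0.01 h cannot flip a split
_T_EPS = 0.15
#: margin kept on the irregularity-index cuts (times are constructed with
#: t3 - t2 >= 2 h so 0.01 h rounding moves the index by < 0.01)
_I_EPS = 0.015

_GROUPS = (("D3", "fresh"), ("D5", "fresh"), ("D5", "frozen"), ("D6", "frozen"))

#: representative grade strings per morphology class (blastocyst stage)
_BLAST_GRADES = {
    "TQE": ("4AA", "4AB", "4BA", "5AA", "3AB"),
    "GQE": ("4BB", "3BB", "5BB"),
    "PQE": ("4BC", "3CB", "4CC", "3AC"),
    "Slow": ("2", "1"),
}
#: representative grade strings per morphology class (day 3)
_DAY3_GRADES = {
    "TQE": ("8/5/even", "8/10/even", "8/15/even"),
    "GQE": ("7/10/even", "8/30/even", "9/15/uneven", "6/25/even"),
    "PQE": ("4/10/even", "12/20/even", "5/60/uneven"),
}


def _triple(row: digest.ClassRow) -> tuple[float, float, float]:
    return (row.pr / 100.0, row.cpr / 100.0, row.lbr / 100.0)


@dataclass
class GeneratorConfig:
    """All knobs of the cohort generator; defaults are the study's values."""

    #: transfer counts for (D3 fresh, D5 fresh, D5 frozen, D6 frozen)
    n_per_group: tuple[int, int, int, int] = (116, 287, 285, 80)
    #: probability of classes 1..5
    kid_distribution: tuple[float, ...] = (0.05, 0.07, 0.04, 0.22, 0.62)
    #: class -> (PR, CPR, LBR) as fractions, per stage
    class_conditional_day3: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {r.label: _triple(r) for r in digest.TABLE2_DAY3})
    class_conditional_blast: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {r.label: _triple(r) for r in digest.TABLE2_BLAST})
    #: probability of forming a clinically usable blastocyst, classes 1..5
    blastulation_by_kid: tuple[float, ...] = (0.23, 0.21, 0.21, 0.36, 0.66)
    #: morphology class shares per stage
    morph_distribution_day3: dict[str, float] = field(
        default_factory=lambda: {"TQE": 0.29, "GQE": 0.61, "PQE": 0.10})
    morph_distribution_blast: dict[str, float] = field(
        default_factory=lambda: {"TQE": 0.37, "GQE": 0.50, "PQE": 0.05, "Slow": 0.08})
    #: optional (kid_class, morph_class) -> LBR coupling for the
    #: morphokinetics x morphology interaction; None keeps morphology
    #: independent of kinetics (the default study assumption)
    cell_conditional_lbr: Optional[dict[tuple[int, str], float]] = None
    icsi_fraction: float = 426 / 768
    thresholds: KidThresholds = field(default_factory=KidThresholds)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, dist in (
            ("kid_distribution", self.kid_distribution),
            ("morph_distribution_day3", tuple(self.morph_distribution_day3.values())),
            ("morph_distribution_blast", tuple(self.morph_distribution_blast.values())),
        ):
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(dist)})")
            if any(p < 0 for p in dist):
                raise ValueError(f"{name} has negative mass")
        if len(self.kid_distribution) != 5 or len(self.blastulation_by_kid) != 5:
            raise ValueError("need one probability per class 1..5")
        for table in (self.class_conditional_day3, self.class_conditional_blast):
            for label, (pr, cpr, lbr) in table.items():
                if not 0.0 <= lbr <= cpr <= pr <= 1.0:
                    raise ValueError(
                        f"{label}: outcome triple must satisfy LBR <= CPR <= PR"
                    )
        if any(n < 0 for n in self.n_per_group) or len(self.n_per_group) != 4:
            raise ValueError("n_per_group must be four non-negative counts")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "thresholds" in data:
            data["thresholds"] = KidThresholds(**data["thresholds"])
        for key in ("n_per_group", "kid_distribution", "blastulation_by_kid"):
            if key in data:
                data[key] = tuple(data[key])
        for key in ("class_conditional_day3", "class_conditional_blast"):
            if key in data:
                data[key] = {k: tuple(v) for k, v in data[key].items()}
        if data.get("cell_conditional_lbr"):
            data["cell_conditional_lbr"] = {
                (int(k.split("/")[0]), k.split("/")[1]): float(v)
                for k, v in data["cell_conditional_lbr"].items()
            }
        return cls(**data)


def _u(rng: np.random.Generator, lo: float, hi: float) -> float:
    if hi <= lo:
        raise ValueError(f"empty sampling interval [{lo}, {hi}]")
    return float(rng.uniform(lo, hi))


def _t5_for_index(t2: float, t3: float, u: float) -> float:
    """t5 such that (t5 - t3)/(t5 - t2) == u, for 0 < u < 1 and t3 > t2."""
    return t3 + u * (t3 - t2) / (1.0 - u)


def sample_times_for_class(
    target: int,
    thresholds: KidThresholds | None = None,
    rng: np.random.Generator | None = None,
) -> AnnotationTimes:
    """Draw annotation times whose classification is exactly ``target``.

    Times are uniform within the threshold-carved region for the target
    class (failing its split, passing all earlier ones) and extended
    monotonically through tEB; all values are rounded to 0.01 h with
    margins wide enough that rounding never crosses a cut.  For class 4
    the sub-rule is mixed: mostly the high-irregularity branch and the
    late/missing eight-cell branch in roughly equal parts, including a
    small share of embryos that never reach five cells.
    """
    if target not in (1, 2, 3, 4, 5):
        raise ValueError(f"target class {target} outside 1..5")
    th = thresholds or KidThresholds()
    rng = rng if rng is not None else np.random.default_rng()

    tpna = _u(rng, 6.0, 10.0)
    tpnf = _u(rng, 20.0, 28.0)
    t5: Optional[float] = None
    t8: Optional[float] = None

    if target == 1:
        d3 = _u(rng, 1.2, th.fast_start_cut - _T_EPS)
        t3 = tpnf + d3
        t2 = tpnf + _u(rng, 0.3, d3 - 0.2)
        t5 = t3 + _u(rng, 2.0, 12.0)
        t8 = t5 + _u(rng, 2.0, 12.0)
    elif target == 2:
        t3 = th.slow_start_cut + _u(rng, _T_EPS, 7.0)
        tpnf = min(tpnf, t3 - th.fast_start_cut - _T_EPS)  # pass split 1
        t2 = _u(rng, tpnf + 2.0, t3 - 2.0)
        t5 = t3 + _u(rng, 2.0, 10.0)
        t8 = t5 + _u(rng, 2.0, 12.0)
    else:
        # pass splits 1-2: t3 in [tPNf + fast_cut, slow_cut), t3 - t2 >= 2
        t2 = tpnf + _u(rng, 3.0, 7.0)
        t3_lo = max(t2 + 2.0, tpnf + th.fast_start_cut + _T_EPS)
        t3 = _u(rng, t3_lo, th.slow_start_cut - _T_EPS)
        if target == 3:
            u = _u(rng, 0.02, th.index_low_cut - _I_EPS)
            t5 = _t5_for_index(t2, t3, u)
            t8 = t5 + _u(rng, 2.0, 12.0)
        elif target == 4:
            branch = rng.random()
            if branch < 0.45:  # decreasing pace: index above the high cut
                cap = (110.0 - t3) / ((110.0 - t3) + (t3 - t2))  # keep t5 <= 110
                u = _u(rng, th.index_high_cut + _I_EPS, min(0.90, cap))
                t5 = _t5_for_index(t2, t3, u)
                t8 = t5 + _u(rng, 2.0, 12.0)
            elif branch < 0.90:  # regular pace but eight cells at/after the deadline
                u = _u(rng, th.index_low_cut + _I_EPS, th.index_high_cut - _I_EPS)
                t5 = _t5_for_index(t2, t3, u)
                late = max(th.t8_deadline + _T_EPS, t5 + 0.3)
                t8 = None if rng.random() < 0.35 else _u(rng, late, late + 8.0)
            else:  # never reached five cells at all
                t5 = None
                t8 = None
        else:  # target == 5: inside the index window, eight cells in time
            # cap u so t5 (hence t8) stays clear of the deadline
            room = th.t8_deadline - 2.2 - t3
            cap = room / (room + (t3 - t2))
            u = _u(rng, th.index_low_cut + _I_EPS,
                   min(th.index_high_cut - _I_EPS, cap))
            t5 = _t5_for_index(t2, t3, u)
            t8 = _u(rng, t5 + 0.3, th.t8_deadline - _T_EPS)

    t4 = None if t5 is None else _u(rng, t3, t5)
    if t5 is not None and t8 is not None:
        t6 = _u(rng, t5, t8)
        t7 = _u(rng, t6, t8)
        tail_base = t8
    elif t5 is not None:
        t6 = t7 = None
        tail_base = t5
    else:
        t6 = t7 = None
        tail_base = t3
    t9 = None if t8 is None else t8 + _u(rng, 2.0, 8.0)
    tm = (t9 if t9 is not None else tail_base) + _u(rng, 4.0, 12.0)
    tsb = tm + _u(rng, 3.0, 10.0)
    tb = tsb + _u(rng, 2.0, 6.0)
    teb = tb + _u(rng, 2.0, 8.0)

    def r(v: Optional[float]) -> Optional[float]:
        return None if v is None else round(v, 2)

    return AnnotationTimes(
        tPNa=r(tpna), tPNf=r(tpnf), t2=r(t2), t3=r(t3), t4=r(t4), t5=r(t5),
        t6=r(t6), t7=r(t7), t8=r(t8), t9plus=r(t9), tM=r(tm), tSB=r(tsb),
        tB=r(tb), tEB=r(teb),
    )


def sample_outcomes(
    p: tuple[float, float, float], rng: np.random.Generator
) -> OutcomeFlags:
    """Draw nested outcome flags with marginals (PR, CPR, LBR).

    Live birth ~ Bernoulli(LBR); non-live embryos get a clinical
    pregnancy with the conditional probability (CPR-LBR)/(1-LBR), and
    non-clinical ones an hCG rise with (PR-CPR)/(1-CPR), so the
    marginals match and nesting holds by construction.
    """
    pr, cpr, lbr = p
    if not 0.0 <= lbr <= cpr <= pr <= 1.0:
        raise ValueError(f"outcome triple must satisfy LBR <= CPR <= PR, got {p}")
    live = rng.random() < lbr
    if live:
        return OutcomeFlags(True, True, True)
    clinical = lbr < 1.0 and rng.random() < (cpr - lbr) / (1.0 - lbr)
    if clinical:
        return OutcomeFlags(True, True, False)
    hcg = cpr < 1.0 and rng.random() < (pr - cpr) / (1.0 - cpr)
    return OutcomeFlags(hcg, False, False)


def generate_cohort(config: GeneratorConfig | None = None) -> list[EmbryoRecord]:
    """Generate a full synthetic cohort; deterministic for a given seed.

    Each record carries class-consistent annotation times, a stage-
    appropriate morphology grade (independent of the morphokinetic class
    unless ``cell_conditional_lbr`` couples them), nested outcome flags
    with the configured stage- and class-conditional marginals, and a
    blastulation flag drawn from the class-conditional blastulation
    probabilities.  Day-3 transfer records have no post-cleavage
    annotations (tM through tEB).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    records: list[EmbryoRecord] = []
    counter = 0
    kid_probs = np.asarray(cfg.kid_distribution)
    for (day, state), n in zip(_GROUPS, cfg.n_per_group):
        is_day3 = day == "D3"
        morph_dist = (cfg.morph_distribution_day3 if is_day3
                      else cfg.morph_distribution_blast)
        morph_labels = list(morph_dist)
        morph_probs = np.asarray([morph_dist[m] for m in morph_labels])
        grades = _DAY3_GRADES if is_day3 else _BLAST_GRADES
        cond = (cfg.class_conditional_day3 if is_day3
                else cfg.class_conditional_blast)
        for _ in range(n):
            counter += 1
            kid = int(rng.choice(5, p=kid_probs)) + 1
            times = sample_times_for_class(kid, cfg.thresholds, rng)
            if is_day3:
                times = replace(times, tM=None, tSB=None, tB=None, tEB=None)
            morph = morph_labels[int(rng.choice(len(morph_labels), p=morph_probs))]
            grade_pool = grades[morph]
            grade = grade_pool[int(rng.integers(len(grade_pool)))]
            triple = cond[f"KID{kid}"]
            if cfg.cell_conditional_lbr is not None:
                override = cfg.cell_conditional_lbr.get((kid, morph))
                if override is not None:
                    pr, cpr, _ = triple
                    triple = (max(pr, override), max(cpr, override), override)
            outcome = sample_outcomes(triple, rng)
            blastulated = bool(rng.random() < cfg.blastulation_by_kid[kid - 1])
            records.append(EmbryoRecord(
                embryo_id=f"E{counter:04d}",
                treatment="ICSI" if rng.random() < cfg.icsi_fraction else "IVF",
                transfer_day=day,
                state=state,
                times=times,
                morph_raw=grade,
                outcome=outcome,
                blastulated=blastulated,
            ))
    return records
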