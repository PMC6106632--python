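"""Morphology grades and their grouping into quality classes.

Blastocysts carry a Gardner-Schoolcraft grade: an expansion stage 0-6
plus, from stage 3 on, letter grades A-C for the inner cell mass (ICM)
and the trophectoderm (TE), e.g. ``"4AB"``.  Day-3 (cleavage-stage)
embryos are graded locally by blastomere count, fragmentation percentage
and evenness, written here as ``"cells/frag%/even|uneven"``, e.g.
``"8/10/even"``.

For statistics both are grouped into ordered quality classes:

* blastocysts -> TQE (any A, no C), GQE (B for both), PQE (any C),
  Slow (expansion 0-2, i.e. pre-blastocyst at scoring time);
* day-3       -> TQE (exactly 8 even cells, <20% fragmentation),
  PQE (<6 or >10 cells, or >=50% fragmentation), GQE (the rest).

Because the letter definitions overlap (a grade like 4AC has both an A
and a C), classing uses a worst-component-dominates precedence:
Slow -> PQE -> TQE -> GQE for blastocysts and TQE -> PQE -> GQE for
day-3 embryos.  A blastocyst is "clinically usable" (transfer /
vitrification threshold) at grade 3BB or better: expansion >= 3 with
both letters A or B.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "MorphClass",
    "BlastocystGrade",
    "CleavageGrade",
    "GradeParseError",
    "parse_gardner",
    "parse_cleavage",
    "parse_morph_grade",
    "class_blastocyst",
    "class_cleavage",
    "classify_morphology",
    "is_clinically_usable",
]


class GradeParseError(ValueError):
    """A grade string does not match the expected grammar."""


class MorphClass(str, enum.Enum):
    """Quality grouping used for the outcome statistics."""

    TQE = "TQE"  # top quality
    GQE = "GQE"  # good quality
    PQE = "PQE"  # poor quality
    SLOW = "Slow"  # blastocyst scoring only: expansion 0-2

    def __str__(self) -> str:
        return self.value


#: ranking order, best first (used for trend fits and table ordering)
MORPH_ORDER = (MorphClass.TQE, MorphClass.GQE, MorphClass.PQE, MorphClass.SLOW)

_GARDNER_RE = re.compile(r"^\s*([0-6])\s*(?:([A-Ca-c])\s*([A-Ca-c]))?\s*$")
_CLEAVAGE_RE = re.compile(
    r"^\s*(\d+)\s*/\s*(\d+(?:\.\d+)?)\s*%?\s*/\s*(even|uneven)\s*$", re.IGNORECASE
)


@dataclass(frozen=True)
class BlastocystGrade:
    """Gardner grade: expansion 0-6, ICM and TE letters (absent below stage 3)."""

    expansion: int
    icm: Optional[str] = None
    te: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.expansion <= 6:
            raise GradeParseError(f"expansion {self.expansion} outside 0-6")
        for name in ("icm", "te"):
            v = getattr(self, name)
            if v is not None and v not in ("A", "B", "C"):
                raise GradeParseError(f"{name} letter {v!r} not in A/B/C")
        if self.expansion >= 3 and (self.icm is None or self.te is None):
            raise GradeParseError(
                f"expansion {self.expansion} requires ICM and TE letters"
            )

    def __str__(self) -> str:
        return f"{self.expansion}{self.icm or ''}{self.te or ''}"


@dataclass(frozen=True)
class CleavageGrade:
    """Day-3 grade: blastomere count, fragmentation %, evenness."""

    cell_count: int
    fragmentation_pct: float
    even_blastomeres: bool

    def __post_init__(self) -> None:
        if self.cell_count < 1:
            raise GradeParseError(f"cell count {self.cell_count} must be >= 1")
        if not 0 <= self.fragmentation_pct <= 100:
            raise GradeParseError(
                f"fragmentation {self.fragmentation_pct} outside 0-100"
            )

    def __str__(self) -> str:
        frag = self.fragmentation_pct
        frag_s = str(int(frag)) if frag == int(frag) else str(frag)
        return f"{self.cell_count}/{frag_s}/{'even' if self.even_blastomeres else 'uneven'}"


def parse_gardner(text: str) -> BlastocystGrade:
    """Parse a Gardner string like ``"4AB"`` or ``"2"`` (case-insensitive)."""
    m = _GARDNER_RE.match(text or "")
    if not m:
        raise GradeParseError(f"malformed Gardner grade {text!r}")
    expansion = int(m.group(1))
    icm = m.group(2).upper() if m.group(2) else None
    te = m.group(3).upper() if m.group(3) else None
    return BlastocystGrade(expansion, icm, te)


def parse_cleavage(text: str) -> CleavageGrade:
    """Parse a day-3 grade like ``"8/10/even"`` (fragmentation may carry %)."""
    m = _CLEAVAGE_RE.match(text or "")
    if not m:
        raise GradeParseError(f"malformed cleavage grade {text!r}")
    return CleavageGrade(int(m.group(1)), float(m.group(2)),
                         m.group(3).lower() == "even")


def parse_morph_grade(text: str, transfer_day: str) -> BlastocystGrade | CleavageGrade:
    """Dispatch on transfer day: D3 -> cleavage grammar, D5/D6 -> Gardner."""
    if transfer_day == "D3":
        return parse_cleavage(text)
    return parse_gardner(text)


def class_blastocyst(grade: BlastocystGrade) -> MorphClass:
    """Group a blastocyst grade; precedence Slow -> PQE -> TQE -> GQE."""
    if grade.expansion <= 2:
        return MorphClass.SLOW
    # expansion >= 3 guarantees both letters (type invariant)
    letters = (grade.icm, grade.te)
    if "C" in letters:
        return MorphClass.PQE
    if "A" in letters:
        return MorphClass.TQE
    return MorphClass.GQE  # (B, B)


def class_cleavage(grade: CleavageGrade) -> MorphClass:
    """Group a day-3 grade; precedence TQE -> PQE -> GQE."""
    if (grade.cell_count == 8 and grade.fragmentation_pct < 20
            and grade.even_blastomeres):
        return MorphClass.TQE
    if (grade.cell_count < 6 or grade.cell_count > 10
            or grade.fragmentation_pct >= 50):
        return MorphClass.PQE
    return MorphClass.GQE


def classify_morphology(text: str, transfer_day: str) -> MorphClass:
    """Parse and class a raw grade string for the given transfer day."""
    grade = parse_morph_grade(text, transfer_day)
    if isinstance(grade, CleavageGrade):
        return class_cleavage(grade)
    return class_blastocyst(grade)


def is_clinically_usable(grade: BlastocystGrade) -> bool:
    """Grade 3BB or better: expansion >= 3 with ICM and TE both A or B."""
    return (grade.expansion >= 3
            and grade.icm in ("A", "B")
            and grade.te in ("A", "B"))
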