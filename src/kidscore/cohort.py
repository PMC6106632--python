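"""Per-embryo data model and cohort CSV input/output.

A cohort is a flat CSV with one row per embryo: identity and treatment
metadata, the annotated morphokinetic time points in hours post
insemination (HPI), a morphology grade string, and (for transferred
embryos) the nested outcome flags.  Empty cells mean "absent": an event
that was never observed or annotated, or an embryo that was never
transferred.

Times are decimal hours post insemination.  For IVF the insemination
time is the start of gamete co-incubation, for ICSI the microinjection;
values are taken at face value and no origin correction is applied.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .outcomes import OutcomeFlags

__all__ = [
    "TIME_FIELDS",
    "AnnotationTimes",
    "EmbryoRecord",
    "ValidationMessage",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "messages_to_json",
]

#: Annotation fields in biological order; present values must be
#: non-decreasing along this sequence.
TIME_FIELDS = (
    "tPNa", "tPNf", "t2", "t3", "t4", "t5", "t6", "t7", "t8",
    "t9plus", "tM", "tSB", "tB", "tEB",
)

#: Column names as they appear in cohort files (t9plus is written "t9",
#: read as "time of reaching 9 or more cells").
TIME_COLUMNS = tuple(f if f != "t9plus" else "t9" for f in TIME_FIELDS)

META_COLUMNS = ("embryo_id", "treatment", "transfer_day", "state")
OUTCOME_COLUMNS = ("hcg_positive", "clinical_pregnancy", "live_birth")
ALL_COLUMNS = (
    META_COLUMNS + TIME_COLUMNS + ("morph_grade",) + OUTCOME_COLUMNS + ("blastulated",)
)

TREATMENTS = ("IVF", "ICSI")
TRANSFER_DAYS = ("D3", "D5", "D6")
STATES = ("fresh", "frozen")


class CohortFormatError(Exception):
    """A cohort file is structurally unreadable (bad header, bad cell)."""


@dataclass(frozen=True)
class ValidationMessage:
    """One validation finding for one embryo."""

    embryo_id: str
    field: str
    message: str
    severity: str = "error"  # "error" | "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.embryo_id}/{self.field}: {self.message}"


@dataclass(frozen=True)
class AnnotationTimes:
    """Morphokinetic time points of one embryo, hours post insemination.

    Each field is optional; ``None`` means the event was not observed or
    not annotated.  tPNa/tPNf are appearance and fading of the pronuclei,
    t2..t9plus the first frames with 2..9-or-more cells, tM the morula,
    tSB the first frame with a blastocoel, tB a fully formed blastocyst
    and tEB an expanding blastocyst.
    """

    tPNa: Optional[float] = None
    tPNf: Optional[float] = None
    t2: Optional[float] = None
    t3: Optional[float] = None
    t4: Optional[float] = None
    t5: Optional[float] = None
    t6: Optional[float] = None
    t7: Optional[float] = None
    t8: Optional[float] = None
    t9plus: Optional[float] = None
    tM: Optional[float] = None
    tSB: Optional[float] = None
    tB: Optional[float] = None
    tEB: Optional[float] = None

    def get(self, name: str) -> Optional[float]:
        return getattr(self, name)

    def present(self) -> dict[str, float]:
        """Present annotations, in biological order."""
        return {f: v for f in TIME_FIELDS if (v := getattr(self, f)) is not None}

    def validate(self, embryo_id: str = "?") -> list[ValidationMessage]:
        """Check non-negativity, finiteness and biological ordering.

        Ordering violations are reported as warnings (real annotation
        data contains them); non-finite or negative values as errors.
        """
        out: list[ValidationMessage] = []
        import math

        for name in TIME_FIELDS:
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v):
                out.append(ValidationMessage(embryo_id, name, "non-finite time"))
            elif v < 0:
                out.append(ValidationMessage(embryo_id, name, "negative time"))
        prev_name, prev = None, None
        for name in TIME_FIELDS:
            v = getattr(self, name)
            if v is None or not (v >= 0):
                continue
            if prev is not None and v < prev:
                out.append(
                    ValidationMessage(
                        embryo_id, name,
                        f"{prev_name} > {name} ({prev} > {v})", severity="warning",
                    )
                )
            prev_name, prev = name, v
        tpnf, t2 = self.tPNf, self.t2
        if tpnf is not None and t2 is not None and not (tpnf < t2):
            out.append(
                ValidationMessage(
                    embryo_id, "t2",
                    f"tPNf must precede t2 strictly ({tpnf} >= {t2})",
                    severity="warning",
                )
            )
        return out


@dataclass
class EmbryoRecord:
    """One transferred (or simulated) embryo with annotations and outcome."""

    embryo_id: str
    treatment: str  # IVF | ICSI
    transfer_day: str  # D3 | D5 | D6
    state: str  # fresh | frozen
    times: AnnotationTimes = field(default_factory=AnnotationTimes)
    morph_raw: str = ""
    outcome: Optional[OutcomeFlags] = None
    blastulated: Optional[bool] = None
    #: validation messages attached by lenient reading
    flags: list[ValidationMessage] = field(default_factory=list)

    def validate(self) -> list[ValidationMessage]:
        out: list[ValidationMessage] = []
        if self.treatment not in TREATMENTS:
            out.append(ValidationMessage(self.embryo_id, "treatment",
                                         f"unknown treatment {self.treatment!r}"))
        if self.transfer_day not in TRANSFER_DAYS:
            out.append(ValidationMessage(self.embryo_id, "transfer_day",
                                         f"unknown transfer day {self.transfer_day!r}"))
        if self.state not in STATES:
            out.append(ValidationMessage(self.embryo_id, "state",
                                         f"unknown state {self.state!r}"))
        # no fresh D6 transfers in the study design; tolerate but warn
        if self.transfer_day == "D6" and self.state == "fresh":
            out.append(ValidationMessage(self.embryo_id, "state",
                                         "D6 transfer marked fresh (expected frozen)",
                                         severity="warning"))
        out.extend(self.times.validate(self.embryo_id))
        if self.outcome is not None:
            out.extend(
                ValidationMessage(self.embryo_id, "outcome", m)
                for m in self.outcome.violations()
            )
        return out


def _parse_bool(cell: str) -> bool:
    if cell in ("1", "true", "True", "yes"):
        return True
    if cell in ("0", "false", "False", "no"):
        return False
    raise ValueError(f"not a boolean flag: {cell!r}")


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return repr(v) if isinstance(v, float) else str(v)


def read_cohort(
    path: str | Path, strict: bool = False
) -> tuple[list[EmbryoRecord], list[ValidationMessage]]:
    """Read a cohort CSV.

    Returns ``(records, messages)``.  In strict mode any invariant
    violation (including warnings such as ordering glitches) raises
    :class:`CohortFormatError` naming the embryo and field; in lenient
    mode violating records are returned with their messages attached to
    ``record.flags``.  A missing mandatory column or a non-numeric time
    cell is always a format error.
    """
    path = Path(path)
    records: list[EmbryoRecord] = []
    messages: list[ValidationMessage] = []
    seen_ids: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in META_COLUMNS + TIME_COLUMNS + ("morph_grade",)
                   if c not in header]
        if missing:
            raise CohortFormatError(f"{path}: missing mandatory column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            eid = (row.get("embryo_id") or "").strip()
            times_kwargs: dict[str, Optional[float]] = {}
            row_msgs: list[ValidationMessage] = []
            for col, fieldname in zip(TIME_COLUMNS, TIME_FIELDS):
                cell = (row.get(col) or "").strip()
                if cell == "":
                    times_kwargs[fieldname] = None
                    continue
                try:
                    times_kwargs[fieldname] = float(cell)
                except ValueError:
                    raise CohortFormatError(
                        f"{path}:{lineno}: non-numeric time cell "
                        f"{col}={cell!r} (embryo {eid or '?'})"
                    ) from None
            outcome = None
            cells = [(row.get(c) or "").strip() for c in OUTCOME_COLUMNS]
            if any(cells):
                if not all(cells):
                    row_msgs.append(ValidationMessage(
                        eid, "outcome", "partially filled outcome flags"))
                try:
                    outcome = OutcomeFlags(*(_parse_bool(c or "0") for c in cells))
                except ValueError as exc:
                    raise CohortFormatError(f"{path}:{lineno}: {exc}") from None
            blast_cell = (row.get("blastulated") or "").strip()
            blastulated = _parse_bool(blast_cell) if blast_cell else None
            rec = EmbryoRecord(
                embryo_id=eid,
                treatment=(row.get("treatment") or "").strip(),
                transfer_day=(row.get("transfer_day") or "").strip(),
                state=(row.get("state") or "").strip(),
                times=AnnotationTimes(**times_kwargs),
                morph_raw=(row.get("morph_grade") or "").strip(),
                outcome=outcome,
                blastulated=blastulated,
            )
            if not eid:
                row_msgs.append(ValidationMessage("?", "embryo_id", "empty embryo id"))
            elif eid in seen_ids:
                row_msgs.append(ValidationMessage(eid, "embryo_id",
                                                  "duplicate embryo id"))
            seen_ids.add(eid)
            row_msgs.extend(rec.validate())
            if row_msgs and strict:
                first = row_msgs[0]
                raise CohortFormatError(
                    f"{path}:{lineno}: embryo {first.embryo_id!r} "
                    f"field {first.field}: {first.message}"
                )
            rec.flags = row_msgs
            messages.extend(row_msgs)
            records.append(rec)
    return records, messages


def write_cohort(records: Iterable[EmbryoRecord], path: str | Path) -> Path:
    """Write records to a cohort CSV (round-trips with :func:`read_cohort`)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ALL_COLUMNS)
        for rec in records:
            row = [rec.embryo_id, rec.treatment, rec.transfer_day, rec.state]
            row += [_fmt(getattr(rec.times, f)) for f in TIME_FIELDS]
            row.append(rec.morph_raw)
            if rec.outcome is None:
                row += ["", "", ""]
            else:
                row += [_fmt(rec.outcome.hcg_positive),
                        _fmt(rec.outcome.clinical_pregnancy),
                        _fmt(rec.outcome.live_birth)]
            row.append(_fmt(rec.blastulated))
            writer.writerow(row)
    return path


def messages_to_json(messages: Iterable[ValidationMessage], path: str | Path) -> Path:
    """Export validation messages as a JSON array."""
    path = Path(path)
    payload = [
        {"embryo_id": m.embryo_id, "field": m.field,
         "message": m.message, "severity": m.severity}
        for m in messages
    ]
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path
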