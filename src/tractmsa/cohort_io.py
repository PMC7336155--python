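"""Patient-table ingestion and cohort descriptive statistics.

The patient table mirrors the layout used in clinical reports of
visuospatial-neglect cohorts: one row per patient with demographics,
stroke characteristics, and raw scores on the three attention tests
(line bisection as signed percent deviation of a 20 cm line; bells and
letter cancellation as ``left/right`` found-target counts).  Missing
entries are written as a dash and kept explicitly missing in memory —
never coerced to 0, which would be a valid (and pathological) score.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PatientRecord",
    "CohortSummary",
    "read_patient_table",
    "write_patient_table",
    "summarize_cohort",
    "load_reference_cohort",
]

BELLS_MAX = 15
LETTER_MAX = 30

#: strings accepted as an explicitly missing cell (ASCII hyphen,
#: en-dash, em-dash, empty)
_MISSING = {"", "-", "–", "—", "na", "nan"}


class TableFormatError(ValueError):
    """Raised when a patient table violates the documented layout."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient row: demographics plus raw test scores.

    ``None`` encodes a missing score; counts are found targets per
    hemifield (bells out of 15, letters out of 30); the bisection score
    is the signed mean percent deviation across the five bisected lines.
    """

    id: str
    sex: str
    age: float
    onset: float
    etiology: str = ""
    visual_field: str = ""
    line_bisection_pct: float | None = None
    bells_left: int | None = None
    bells_right: int | None = None
    letter_left: int | None = None
    letter_right: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise TableFormatError(f"patient {self.id}: sex must be M or F, got {self.sex!r}")
        if not self.age > 0:
            raise TableFormatError(f"patient {self.id}: age must be positive")
        if not self.onset > 0:
            raise TableFormatError(f"patient {self.id}: onset must be positive")
        for side in ("left", "right"):
            b = getattr(self, f"bells_{side}")
            if b is not None and not (0 <= b <= BELLS_MAX):
                raise TableFormatError(
                    f"patient {self.id}: bells_{side}={b} outside [0, {BELLS_MAX}]"
                )
            letter = getattr(self, f"letter_{side}")
            if letter is not None and not (0 <= letter <= LETTER_MAX):
                raise TableFormatError(
                    f"patient {self.id}: letter_{side}={letter} outside [0, {LETTER_MAX}]"
                )

    @property
    def has_bisection(self) -> bool:
        return self.line_bisection_pct is not None

    @property
    def has_bells(self) -> bool:
        return self.bells_left is not None and self.bells_right is not None

    @property
    def has_letter(self) -> bool:
        return self.letter_left is not None and self.letter_right is not None


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_male: int
    age_mean: float
    age_sd: float | None
    age_min: float
    age_max: float
    onset_mean: float
    onset_sd: float | None
    onset_min: float
    onset_max: float
    n_complete_bisection: int
    n_complete_bells: int
    n_complete_letter: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def __str__(self) -> str:  # formatted text table
        sd = lambda v: "n/a" if v is None else f"{v:.2f}"
        return (
            f"n = {self.n} ({self.n_male} men)\n"
            f"age   [y]: {self.age_mean:.2f} ± {sd(self.age_sd)}"
            f" (range {self.age_min:g}–{self.age_max:g})\n"
            f"onset [d]: {self.onset_mean:.2f} ± {sd(self.onset_sd)}"
            f" (range {self.onset_min:g}–{self.onset_max:g})\n"
            f"complete: bisection {self.n_complete_bisection}, "
            f"bells {self.n_complete_bells}, letter {self.n_complete_letter}"
        )


def _parse_missing(cell: str) -> str | None:
    cell = cell.strip()
    return None if cell.lower() in _MISSING else cell


def _parse_number(cell: str, row: str, field: str) -> float:
    # tolerate thousands separators and typographic minus signs
    cell = cell.replace(",", "").replace("−", "-").replace("+", "")
    try:
        return float(cell)
    except ValueError as exc:
        raise TableFormatError(f"row {row!r}: cannot parse {field}={cell!r}") from exc


def _parse_pair(cell: str, row: str, field: str) -> tuple[int, int]:
    parts = cell.split("/")
    if len(parts) != 2:
        raise TableFormatError(f"row {row!r}: {field}={cell!r} is not 'left/right'")
    try:
        left, right = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise TableFormatError(f"row {row!r}: non-integer counts in {field}={cell!r}") from exc
    return left, right


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read a patient table CSV into records.

    Dashes (ASCII or typographic) and empty cells parse as missing;
    ``left/right`` cells are split into two counts; duplicate patient
    ids and out-of-range counts are rejected with the offending row
    named.
    """
    records: list[PatientRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"patient", "sex", "age", "onset_days"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TableFormatError(f"{path}: header must include {sorted(required)}")
        for raw in reader:
            pid = raw["patient"].strip()
            if pid in seen:
                raise TableFormatError(f"duplicate patient id {pid!r}")
            seen.add(pid)
            bis = _parse_missing(raw.get("line_bisection_pct", "") or "")
            bells = _parse_missing(raw.get("bells_left_right", "") or "")
            letter = _parse_missing(raw.get("letter_left_right", "") or "")
            bl = br = ll = lr = None
            if bells is not None:
                bl, br = _parse_pair(bells, pid, "bells")
            if letter is not None:
                ll, lr = _parse_pair(letter, pid, "letter")
            try:
                rec = PatientRecord(
                    id=pid,
                    sex=raw["sex"].strip(),
                    age=_parse_number(raw["age"], pid, "age"),
                    onset=_parse_number(raw["onset_days"], pid, "onset_days"),
                    etiology=raw.get("etiology", "").strip(),
                    visual_field=raw.get("visual_field", "").strip(),
                    line_bisection_pct=(
                        None if bis is None else _parse_number(bis, pid, "line_bisection_pct")
                    ),
                    bells_left=bl,
                    bells_right=br,
                    letter_left=ll,
                    letter_right=lr,
                )
            except TableFormatError:
                raise
            records.append(rec)
    if not records:
        raise TableFormatError(f"{path}: no patient rows")
    return records


def write_patient_table(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records back to CSV, preserving missingness as ``-``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "patient", "sex", "age", "onset_days", "etiology", "visual_field",
                "line_bisection_pct", "bells_left_right", "letter_left_right",
            ]
        )
        for r in records:
            bis = "-" if r.line_bisection_pct is None else f"{r.line_bisection_pct:+g}"
            bells = "-" if not r.has_bells else f"{r.bells_left}/{r.bells_right}"
            letter = "-" if not r.has_letter else f"{r.letter_left}/{r.letter_right}"
            writer.writerow(
                [r.id, r.sex, f"{r.age:g}", f"{r.onset:g}", r.etiology, r.visual_field,
                 bis, bells, letter]
            )


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Descriptive statistics of a cohort.

    Means are arithmetic; standard deviations use the n-1 denominator.
    With a single record the SD is reported missing rather than 0.
    Per-test completion counts the patients with a non-missing score set
    for that test.
    """
    if not records:
        raise ValueError("summarize_cohort: empty record list")
    ages = np.array([r.age for r in records], dtype=float)
    onsets = np.array([r.onset for r in records], dtype=float)
    n = len(records)
    sd = (lambda x: float(np.std(x, ddof=1))) if n > 1 else (lambda x: None)
    return CohortSummary(
        n=n,
        n_male=sum(r.sex == "M" for r in records),
        age_mean=float(ages.mean()),
        age_sd=sd(ages),
        age_min=float(ages.min()),
        age_max=float(ages.max()),
        onset_mean=float(onsets.mean()),
        onset_sd=sd(onsets),
        onset_min=float(onsets.min()),
        onset_max=float(onsets.max()),
        n_complete_bisection=sum(r.has_bisection for r in records),
        n_complete_bells=sum(r.has_bells for r in records),
        n_complete_letter=sum(r.has_letter for r in records),
    )


def load_reference_cohort() -> list[PatientRecord]:
    """The bundled 25-patient right-hemisphere stroke cohort table.

    Published demographic and raw-score data for the chronic neglect
    cohort the package's defaults are modelled on (23/24/19 of 25
    patients completed bisection/bells/letter respectively).
    """
    ref = resources.files("tractmsa.data").joinpath("neglect_cohort.csv")
    with resources.as_file(ref) as path:
        return read_patient_table(path)
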