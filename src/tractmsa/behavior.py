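"""Test scoring: laterality scores, clinical cut-offs, performance labels.

Each of the three neuropsychological tests yields a signed laterality
score that is binarized against its published clinical cut-off into a
*deficit* label (1 = pathological).  Because the coalition analysis
needs a score that grows with ability rather than with impairment, the
deficit label is inverted into a *performance* label (1 = normal,
``performance = 1 - deficit``).

Conventions
-----------
line bisection
    Raw scores are mean percent deviations of 20 cm (200 mm) lines, so
    ``mm = pct / 100 * 200``.  Deviations beyond +6.5 mm (rightward) or
    below -7.3 mm (leftward) are pathological; both bounds are strict,
    so a score exactly at a cut-off is classified normal.
cancellation (bells out of 15 per side, letters out of 30 per side)
    The laterality score is the signed right-minus-left difference
    (found targets for bells, omissions for letters); an absolute
    difference strictly greater than 2 is pathological.  With a
    right-hemisphere (left-neglect) cohort the convention reads
    positively for the typical deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import BELLS_MAX, LETTER_MAX, PatientRecord

__all__ = [
    "TestScore",
    "TESTS",
    "binarize_line_bisection",
    "binarize_bells",
    "binarize_letter",
    "invert_score",
    "score_cohort",
    "performance_labels",
    "LINE_LENGTH_MM",
    "BISECTION_CUTOFF_RIGHT_MM",
    "BISECTION_CUTOFF_LEFT_MM",
    "CANCELLATION_CUTOFF",
]

TESTS = ("line_bisection", "bells", "letter")

LINE_LENGTH_MM = 200.0
BISECTION_CUTOFF_RIGHT_MM = 6.5
BISECTION_CUTOFF_LEFT_MM = -7.3
CANCELLATION_CUTOFF = 2


@dataclass(frozen=True)
class TestScore:
    """A scored test: raw laterality value plus its binary labels."""

    test: str
    raw: float
    deficit: int

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}")
        if not math.isfinite(self.raw):
            raise ValueError("raw score must be finite")
        if self.deficit not in (0, 1):
            raise ValueError("deficit must be 0 or 1")

    @property
    def performance(self) -> int:
        return 1 - self.deficit


def binarize_line_bisection(mean_deviation_pct: float) -> TestScore:
    """Binarize a mean bisection deviation given in percent of the line.

    The raw score stored is the deviation in mm.  Strictly beyond
    +6.5 mm or strictly below -7.3 mm is a deficit.
    """
    if mean_deviation_pct is None or not math.isfinite(mean_deviation_pct):
        raise ValueError("mean_deviation_pct must be finite (missing scores are excluded upstream)")
    mm = mean_deviation_pct / 100.0 * LINE_LENGTH_MM
    deficit = int(mm > BISECTION_CUTOFF_RIGHT_MM or mm < BISECTION_CUTOFF_LEFT_MM)
    return TestScore(test="line_bisection", raw=mm, deficit=deficit)


def binarize_bells(left_found: int, right_found: int) -> TestScore:
    """Bells cancellation: signed right-left difference of found bells."""
    for name, v in (("left_found", left_found), ("right_found", right_found)):
        if not 0 <= v <= BELLS_MAX:
            raise ValueError(f"{name}={v} outside [0, {BELLS_MAX}]")
    raw = float(right_found - left_found)
    return TestScore(test="bells", raw=raw, deficit=int(abs(raw) > CANCELLATION_CUTOFF))


def binarize_letter(left_found: int, right_found: int) -> TestScore:
    """Letter cancellation: signed right-left difference of omissions."""
    for name, v in (("left_found", left_found), ("right_found", right_found)):
        if not 0 <= v <= LETTER_MAX:
            raise ValueError(f"{name}={v} outside [0, {LETTER_MAX}]")
    omissions_left = LETTER_MAX - left_found
    omissions_right = LETTER_MAX - right_found
    raw = float(omissions_right - omissions_left)
    return TestScore(test="letter", raw=raw, deficit=int(abs(raw) > CANCELLATION_CUTOFF))


def invert_score(deficit: int) -> int:
    """Map a deficit label to a performance label (``1 - deficit``)."""
    if deficit not in (0, 1):
        raise ValueError(f"deficit label must be 0 or 1, got {deficit!r}")
    return 1 - deficit


def _score_record(record: PatientRecord, test: str) -> TestScore | None:
    if test == "line_bisection":
        if not record.has_bisection:
            return None
        return binarize_line_bisection(record.line_bisection_pct)
    if test == "bells":
        if not record.has_bells:
            return None
        return binarize_bells(record.bells_left, record.bells_right)
    if test == "letter":
        if not record.has_letter:
            return None
        return binarize_letter(record.letter_left, record.letter_right)
    raise ValueError(f"unknown test {test!r}")


def score_cohort(records: list[PatientRecord]) -> pd.DataFrame:
    """Score every patient on every test.

    Returns a tidy frame with one row per patient per test and columns
    ``patient, test, raw, deficit, performance``; missing scores yield
    NaN rows so the per-test subcohorts remain visible.
    """
    rows = []
    for rec in records:
        for test in TESTS:
            ts = _score_record(rec, test)
            rows.append(
                {
                    "patient": rec.id,
                    "test": test,
                    "raw": np.nan if ts is None else ts.raw,
                    "deficit": np.nan if ts is None else ts.deficit,
                    "performance": np.nan if ts is None else ts.performance,
                }
            )
    return pd.DataFrame(rows)


def performance_labels(
    records: list[PatientRecord], test: str
) -> tuple[list[str], np.ndarray]:
    """Per-test subcohort: ids and binary performance labels (1 = normal).

    Patients with a missing score for this test are excluded — the
    subcohorts are formed here, never by pre-filtering files.
    """
    ids: list[str] = []
    labels: list[int] = []
    for rec in records:
        ts = _score_record(rec, test)
        if ts is None:
            continue
        ids.append(rec.id)
        labels.append(ts.performance)
    return ids, np.asarray(labels, dtype=int)
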