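"""Spontaneous-report records and their tabular serialization.

A report mirrors the fields retained from a cleaned FAERS-style extraction:
patient age and gender, the drug list, the comorbidity (pathology) flags, the
observed ADR set, and the two severity outcomes — hospitalization and
death/life-threat.  The comorbidity predictors are a fixed set of six.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = ["CANONICAL_PATHOLOGIES", "ReportRecord", "read_corpus", "write_corpus"]

#: The six comorbidity predictors, in vocabulary (lexicographic) order.
CANONICAL_PATHOLOGIES: tuple[str, ...] = (
    "Cardiac failure",
    "Diabetes mellitus",
    "Hepatic insufficiency",
    "Hypertension",
    "Renal insufficiency",
    "Thrombosis risk factors",
)

GENDERS = ("female", "male")

_CORPUS_COLUMNS = (
    "age",
    "gender",
    "drugs",
    "pathologies",
    "adrs",
    "hospitalized",
    "fatal_or_life_threat",
)


@dataclass(frozen=True)
class ReportRecord:
    """One spontaneous report: demographics, exposures, ADRs, outcomes."""

    age: int
    gender: str
    drugs: frozenset[str]
    pathologies: frozenset[str]
    adrs: frozenset[str]
    hospitalized: bool
    fatal_or_life_threat: bool

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.gender not in GENDERS:
            raise ValidationError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if not self.adrs:
            raise ValidationError("a report must carry at least one ADR")
        extra = self.pathologies - set(CANONICAL_PATHOLOGIES)
        if extra:
            raise ValidationError(
                f"unknown pathology flag(s): {sorted(extra)}; "
                f"allowed: {CANONICAL_PATHOLOGIES}"
            )


def write_corpus(records: Iterable[ReportRecord], path: str | Path) -> None:
    """Write reports as UTF-8 TSV; multi-valued fields ';'-joined, booleans 0/1."""
    rows = [
        (
            r.age,
            r.gender,
            ";".join(sorted(r.drugs)),
            ";".join(sorted(r.pathologies)),
            ";".join(sorted(r.adrs)),
            int(r.hospitalized),
            int(r.fatal_or_life_threat),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=_CORPUS_COLUMNS).to_csv(path, sep="\t", index=False)


def _split(field: str) -> frozenset[str]:
    return frozenset(part for part in str(field).split(";") if part)


def read_corpus(path: str | Path) -> list[ReportRecord]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _CORPUS_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column {column!r}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                ReportRecord(
                    age=int(row.age),
                    gender=row.gender,
                    drugs=_split(row.drugs),
                    pathologies=_split(row.pathologies),
                    adrs=_split(row.adrs),
                    hospitalized=bool(int(row.hospitalized)),
                    fatal_or_life_threat=bool(int(row.fatal_or_life_threat)),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}, row {i}: {exc}") from None
    return records
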