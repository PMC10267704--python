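"""Descriptive clinical summaries for a familial Crohn's disease cohort.

Patients are coded with the Montreal classification: disease location L1
(terminal ileum), L2 (colon), L3 (ileocolon) with L4 (upper GI) as a
modifier that only occurs in combination; disease behavior B1
(non-stricturing, non-penetrating), B2 (stricturing) or B3 (penetrating).
Location is a *set* of codes, so location percentages may sum to more than
100% (a patient with L3+L4 counts toward both), while behavior is a single
code and its percentages sum to 100%.

Disease duration printed as "<1" year is kept as a left-open interval
rather than coerced to a number; no duration aggregate is computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from statistics import median
from typing import Sequence

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "LOCATION_CODES",
    "BEHAVIOR_CODES",
    "ClinicalRecord",
    "CohortSummary",
    "read_clinical_table",
    "packaged_clinical_table",
    "summarize",
]

LOCATION_CODES = ("L1", "L2", "L3", "L4")
BEHAVIOR_CODES = ("B1", "B2", "B3")


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    family_id: str
    age: float
    sex: str                       # "male" / "female"
    location: frozenset[str]       # subset of LOCATION_CODES, non-empty
    behavior: str                  # one of BEHAVIOR_CODES
    pelvic_disease: bool
    abdominal_surgery: bool
    kinship: str = ""
    duration_years: float | None = None   # None when only "<1" is recorded
    duration_under_one: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"{self.patient_id}: sex must be male/female")
        if not self.location:
            raise ValidationError(f"{self.patient_id}: location set is empty")
        bad = self.location - set(LOCATION_CODES)
        if bad:
            raise ValidationError(f"{self.patient_id}: unknown location {sorted(bad)}")
        if self.location == {"L4"}:
            raise ValidationError(
                f"{self.patient_id}: L4 is a modifier and only occurs in "
                f"combination with L1-L3")
        if self.behavior not in BEHAVIOR_CODES:
            raise ValidationError(f"{self.patient_id}: unknown behavior "
                                  f"{self.behavior!r}")


@dataclass(frozen=True)
class CohortSummary:
    """Counts and percentages over a cohort of clinical records."""

    n: int
    sex_counts: dict[str, int]
    median_age: float
    age_min: float
    age_max: float
    location_counts: dict[str, int]   # membership counts: may overlap
    behavior_counts: dict[str, int]
    pelvic_count: int
    surgery_count: int

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n

    def location_pct(self, code: str) -> float:
        return self.pct(self.location_counts.get(code, 0))

    def behavior_pct(self, code: str) -> float:
        return self.pct(self.behavior_counts.get(code, 0))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "sex": {s: {"count": c, "percent": round(self.pct(c), 2)}
                    for s, c in self.sex_counts.items()},
            "age": {"median": self.median_age, "min": self.age_min,
                    "max": self.age_max},
            "location": {code: {"count": self.location_counts.get(code, 0),
                                "percent": round(self.location_pct(code), 2)}
                         for code in LOCATION_CODES},
            "behavior": {code: {"count": self.behavior_counts.get(code, 0),
                                "percent": round(self.behavior_pct(code), 2)}
                         for code in BEHAVIOR_CODES},
            "pelvic_disease": {"count": self.pelvic_count,
                               "percent": round(self.pct(self.pelvic_count), 2)},
            "abdominal_surgery": {"count": self.surgery_count,
                                  "percent": round(self.pct(self.surgery_count), 2)},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        d = self.to_dict()
        lines = ["category\tlevel\tcount\tpercent"]
        lines.append(f"cohort\tn\t{self.n}\t100.00")
        lines.append(f"age\tmedian\t{self.median_age:g}\t.")
        lines.append(f"age\trange\t{self.age_min:g}-{self.age_max:g}\t.")
        for cat in ("sex", "location", "behavior"):
            for level, v in d[cat].items():
                lines.append(f"{cat}\t{level}\t{v['count']}\t{v['percent']:.2f}")
        for cat in ("pelvic_disease", "abdominal_surgery"):
            v = d[cat]
            lines.append(f"{cat}\tyes\t{v['count']}\t{v['percent']:.2f}")
        Path(path).write_text("\n".join(lines) + "\n")


_CLINICAL_COLUMNS = ("patient_id", "family_id", "kinship", "age", "sex",
                     "duration", "location", "behavior", "pelvic_disease",
                     "abdominal_surgery")


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical characteristics TSV (Montreal-coded; see packaged
    fixture for the column layout)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"{path}: empty clinical table")
    header = tuple(lines[0].split("\t"))
    if header != _CLINICAL_COLUMNS:
        raise FormatError(f"{path}: unexpected clinical header {header}")
    records = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(_CLINICAL_COLUMNS):
            raise ParseError(f"{path} line {lineno}: expected "
                             f"{len(_CLINICAL_COLUMNS)} columns")
        row = dict(zip(_CLINICAL_COLUMNS, (p.strip() for p in parts)))
        duration_raw = row["duration"]
        under_one = duration_raw.startswith("<")
        records.append(ClinicalRecord(
            patient_id=row["patient_id"],
            family_id=row["family_id"],
            kinship=row["kinship"],
            age=float(row["age"]),
            sex=row["sex"].lower(),
            duration_years=None if under_one else float(duration_raw),
            duration_under_one=under_one,
            location=frozenset(row["location"].upper().split("+")),
            behavior=row["behavior"].upper(),
            pelvic_disease=row["pelvic_disease"].lower() in ("1", "yes", "true"),
            abdominal_surgery=row["abdominal_surgery"].lower() in ("1", "yes", "true"),
        ))
    return records


def packaged_clinical_table() -> list[ClinicalRecord]:
    """The 24-patient / 12-family clinical table shipped with the package."""
    with resources.as_file(
        resources.files("famvar").joinpath("data/table1_clinical.tsv")
    ) as p:
        return read_clinical_table(p)


def summarize(records: Sequence[ClinicalRecord]) -> CohortSummary:
    """Tally the cohort: sex, age median/range, Montreal location membership
    counts, behavior counts, pelvic disease and surgical history."""
    if not records:
        raise ValidationError("cannot summarize an empty cohort")
    ages = [r.age for r in records]
    sex_counts = {s: sum(1 for r in records if r.sex == s)
                  for s in ("male", "female")}
    location_counts = {code: sum(1 for r in records if code in r.location)
                       for code in LOCATION_CODES}
    behavior_counts = {code: sum(1 for r in records if r.behavior == code)
                       for code in BEHAVIOR_CODES}
    return CohortSummary(
        n=len(records),
        sex_counts=sex_counts,
        median_age=float(median(ages)),
        age_min=min(ages),
        age_max=max(ages),
        location_counts=location_counts,
        behavior_counts=behavior_counts,
        pelvic_count=sum(1 for r in records if r.pelvic_disease),
        surgery_count=sum(1 for r in records if r.abdominal_surgery),
    )
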