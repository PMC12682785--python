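"""Subject-level cohort records and CSV input/output.

A cohort is a list of :class:`SubjectRecord`, one per participant, carrying
demographics, CSF biomarkers (Aβ42, t-tau, p-tau in pg/mL), vascular markers
(Fazekas score, microbleed count, stroke history), clinical status (global
CDR), quality-control flags, total intracranial volume (TIV) and the raw
volumes of the analyzed brain regions.  Region volumes and TIV share the same
units; only their ratio enters the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: Fixed, ordered set of non-region columns in the cohort CSV dialect.
BASE_COLUMNS = [
    "subject_id",
    "age",
    "gender",
    "abeta42",
    "ttau",
    "ptau",
    "fazekas",
    "microbleeds",
    "stroke_history",
    "cdr_global",
    "qc_pass",
    "radiological_exclusion",
    "tiv",
]


@dataclass
class SubjectRecord:
    """One participant of the cohort.

    ``qc_pass`` is the conjunction of the four volumetric QC grades of the
    source pipeline; ``radiological_exclusion`` flags clinically relevant
    radiological findings (siderosis, ARIA-E, ...).  ``volumes`` maps region
    codes (e.g. ``LLENTAV``) to raw volumes in the same units as ``tiv``.
    """

    subject_id: str
    age: float
    gender: str  # "female" | "male"
    abeta42: float
    ttau: float
    ptau: float
    fazekas: int
    microbleeds: int
    stroke_history: bool
    cdr_global: float
    qc_pass: bool
    radiological_exclusion: bool
    tiv: float
    volumes: dict[str, float] = field(default_factory=dict)

    def has_complete_biomarkers(self) -> bool:
        """True when all CSF and vascular biomarker fields are usable.

        Aβ42 must be strictly positive for the p-tau/Aβ42 ratio to be
        defined; NaN in any biomarker field counts as missing.
        """
        values = (self.abeta42, self.ttau, self.ptau)
        if any(v is None or math.isnan(v) for v in values):
            return False
        if self.abeta42 <= 0:
            return False
        if self.fazekas is None or self.microbleeds is None:
            return False
        return True


def region_codes(cohort: Iterable[SubjectRecord]) -> list[str]:
    """Region codes of the cohort (taken from the first subject, verified
    identical across subjects)."""
    cohort = list(cohort)
    if not cohort:
        return []
    regions = list(cohort[0].volumes)
    for s in cohort[1:]:
        if list(s.volumes) != regions:
            raise ValueError(
                f"subject {s.subject_id!r} has region set differing from "
                f"subject {cohort[0].subject_id!r}"
            )
    return regions


def cohort_to_frame(cohort: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Serialize a cohort to the flat CSV dialect (booleans as 0/1)."""
    cohort = list(cohort)
    regions = region_codes(cohort)
    rows = []
    for s in cohort:
        row = {
            "subject_id": s.subject_id,
            "age": s.age,
            "gender": s.gender,
            "abeta42": s.abeta42,
            "ttau": s.ttau,
            "ptau": s.ptau,
            "fazekas": s.fazekas,
            "microbleeds": s.microbleeds,
            "stroke_history": int(s.stroke_history),
            "cdr_global": s.cdr_global,
            "qc_pass": int(s.qc_pass),
            "radiological_exclusion": int(s.radiological_exclusion),
            "tiv": s.tiv,
        }
        for r in regions:
            row[r] = s.volumes[r]
        rows.append(row)
    return pd.DataFrame(rows, columns=BASE_COLUMNS + regions)


def frame_to_cohort(df: pd.DataFrame) -> list[SubjectRecord]:
    """Parse the flat cohort table back into records."""
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks required columns: {missing}")
    regions = [c for c in df.columns if c not in BASE_COLUMNS]
    cohort = []
    for row in df.itertuples(index=False):
        d: Mapping = row._asdict()
        cohort.append(
            SubjectRecord(
                subject_id=str(d["subject_id"]),
                age=float(d["age"]),
                gender=str(d["gender"]),
                abeta42=float(d["abeta42"]),
                ttau=float(d["ttau"]),
                ptau=float(d["ptau"]),
                fazekas=int(d["fazekas"]),
                microbleeds=int(d["microbleeds"]),
                stroke_history=bool(int(d["stroke_history"])),
                cdr_global=float(d["cdr_global"]),
                qc_pass=bool(int(d["qc_pass"])),
                radiological_exclusion=bool(int(d["radiological_exclusion"])),
                tiv=float(d["tiv"]),
                volumes={r: float(d[r]) for r in regions},
            )
        )
    return cohort


def write_cohort_csv(cohort: Iterable[SubjectRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[SubjectRecord]:
    return frame_to_cohort(pd.read_csv(path))
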