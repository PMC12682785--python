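"""Inclusion filtering and A/T/N/V biomarker stratification.

Cognitively normal participants are classified on four binary axes derived
from CSF and vascular markers:

* **A** (amyloid):      Aβ42 < 1030 pg/mL  or  p-tau/Aβ42 > 0.023
* **T** (tau):          p-tau > 27 pg/mL
* **N** (neurodegeneration): t-tau > 300 pg/mL
* **V** (vascular):     Fazekas > 1  or  microbleeds > 3  or  stroke history

All comparisons are strict: a value exactly at a threshold is negative.
The sixteen A/T/N/V combinations partition into five study groups plus an
excluded profile:

========  =========================================
label     definition
========  =========================================
AD        A+ and V-            (any T, N)
AV        A+ and V+            (any T, N)
V         A- and V+ and T-     (any N)
EXCLUDED  A- and V+ and T+     (ambiguous profile)
OP        A- and V- and (T+ or N+)
N         all four axes negative
========  =========================================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .cohort import SubjectRecord

ABETA42_CUTOFF = 1030.0  # pg/mL, positive strictly below
PTAU_CUTOFF = 27.0  # pg/mL, positive strictly above
TTAU_CUTOFF = 300.0  # pg/mL, positive strictly above
RATIO_CUTOFF = 0.023  # p-tau/Aβ42, positive strictly above
FAZEKAS_CUTOFF = 1  # positive strictly above (i.e. score >= 2)
MICROBLEED_CUTOFF = 3  # positive strictly above (i.e. >= 4 microbleeds)


class GroupLabel(str, enum.Enum):
    """Study group of a subject; EXCLUDED profiles are dropped from analysis."""

    N = "N"
    AD = "AD"
    V = "V"
    AV = "AV"
    OP = "OP"
    EXCLUDED = "EXCLUDED"

    def __str__(self) -> str:  # keeps CSV output plain
        return self.value


#: Analysis groups, i.e. every label except EXCLUDED.
ANALYSIS_GROUPS = (GroupLabel.N, GroupLabel.AD, GroupLabel.V, GroupLabel.AV, GroupLabel.OP)


@dataclass(frozen=True)
class BiomarkerStatus:
    """Binary positivity on the four A/T/N/V axes."""

    A: bool
    T: bool
    N: bool
    V: bool


class MissingBiomarkerError(ValueError):
    """Raised when a record lacks the biomarkers needed for classification."""


def classify_biomarkers(s: SubjectRecord) -> BiomarkerStatus:
    """Derive the A/T/N/V status of one subject from raw marker values.

    Raises :class:`MissingBiomarkerError` when Aβ42 is missing or
    non-positive (the p-tau/Aβ42 ratio would be undefined) or any other
    biomarker field is missing.
    """
    if not s.has_complete_biomarkers():
        raise MissingBiomarkerError(
            f"subject {s.subject_id!r}: incomplete or non-positive biomarkers"
        )
    a = s.abeta42 < ABETA42_CUTOFF or (s.ptau / s.abeta42) > RATIO_CUTOFF
    t = s.ptau > PTAU_CUTOFF
    n = s.ttau > TTAU_CUTOFF
    v = (
        s.fazekas > FAZEKAS_CUTOFF
        or s.microbleeds > MICROBLEED_CUTOFF
        or s.stroke_history
    )
    return BiomarkerStatus(A=a, T=t, N=n, V=v)


def assign_group(b: BiomarkerStatus) -> GroupLabel:
    """Map an A/T/N/V status to its study group.

    Total on all 16 combinations; the A-/T+/V+ profile (any N) is the
    ambiguous combination excluded from analysis.
    """
    if b.A:
        return GroupLabel.AV if b.V else GroupLabel.AD
    if b.V:
        return GroupLabel.EXCLUDED if b.T else GroupLabel.V
    if b.T or b.N:
        return GroupLabel.OP
    return GroupLabel.N


# --- inclusion filtering -------------------------------------------------

#: Machine-readable rejection reason codes, in the order filters are checked.
REASONS = (
    "missing_biomarker",
    "cdr_nonzero",
    "qc_fail",
    "radiological_exclusion",
    "age_below_50",
)


def apply_inclusion_filters(
    cohort: list[SubjectRecord],
) -> tuple[list[SubjectRecord], list[tuple[str, str]]]:
    """Split a cohort into included subjects and rejections with reasons.

    Inclusion requires complete biomarkers, a global CDR of exactly 0,
    passing volumetric QC, no radiological exclusion finding, and age >= 50.
    Each rejected subject carries the first failing reason code.

    Returns ``(kept, rejected)`` where ``rejected`` is a list of
    ``(subject_id, reason_code)`` pairs.  Raises ``ValueError`` if nothing
    survives (the pipeline cannot proceed on an empty cohort).
    """
    kept: list[SubjectRecord] = []
    rejected: list[tuple[str, str]] = []
    for s in cohort:
        if not s.has_complete_biomarkers():
            rejected.append((s.subject_id, "missing_biomarker"))
        elif s.cdr_global != 0:
            rejected.append((s.subject_id, "cdr_nonzero"))
        elif not s.qc_pass:
            rejected.append((s.subject_id, "qc_fail"))
        elif s.radiological_exclusion:
            rejected.append((s.subject_id, "radiological_exclusion"))
        elif s.age < 50:
            rejected.append((s.subject_id, "age_below_50"))
        else:
            kept.append(s)
    if cohort and not kept:
        raise ValueError("inclusion filters rejected every subject")
    return kept, rejected


def stratify_cohort(
    cohort: list[SubjectRecord],
) -> dict[GroupLabel, list[SubjectRecord]]:
    """Partition an included cohort into the study groups.

    Every subject lands under exactly one label.  EXCLUDED subjects are
    returned under their own key so callers can report them, but they take
    no part in any analysis group.
    """
    groups: dict[GroupLabel, list[SubjectRecord]] = {g: [] for g in GroupLabel}
    for s in cohort:
        groups[assign_group(classify_biomarkers(s))].append(s)
    return groups
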