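"""Volume normalization, outlier removal and age-range computation.

Raw region volumes are corrected for head size by dividing by the subject's
total intracranial volume (TIV) and then z-scored.  The z-score mean and SD
are computed once over the full included cohort and stored, so that group or
gender subsets can be expressed on the same scale — a prerequisite for the
between-group area comparisons downstream.

Because kernel estimates are unreliable where subjects are sparse, each
group is assigned a valid age range: the longest contiguous run of two-year
windows that each contain at least five subjects.  Two curves are only
compared over the overlap of their groups' ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SubjectRecord, region_codes


@dataclass(frozen=True)
class AgeRange:
    """Closed integer-year interval ``[lo, hi]`` with a validity flag."""

    lo: int
    hi: int
    valid: bool = True

    def grid(self) -> np.ndarray:
        """Integer-year evaluation grid lo..hi inclusive."""
        if not self.valid:
            raise ValueError("invalid age range has no grid")
        return np.arange(self.lo, self.hi + 1)


@dataclass
class NormalizedCohort:
    """Cohort together with its z-scored TIV-ratio volumes.

    ``zvolumes`` is indexed by subject_id with one column per region;
    ``stats`` maps region code to the ``(mean, sd)`` of the TIV-ratio in the
    normalization population, so the same scale can be reapplied to subsets.
    """

    subjects: list[SubjectRecord]
    zvolumes: pd.DataFrame
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def regions(self) -> list[str]:
        return list(self.zvolumes.columns)

    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)

    def subset(self, subject_ids) -> "NormalizedCohort":
        """Restrict to the given subjects, keeping the normalization stats."""
        wanted = set(subject_ids)
        subs = [s for s in self.subjects if s.subject_id in wanted]
        z = self.zvolumes.loc[[s.subject_id for s in subs]]
        return NormalizedCohort(subjects=subs, zvolumes=z, stats=dict(self.stats))

    def group_arrays(self, subjects: list[SubjectRecord], region: str):
        """(ages, z-volumes) arrays for a set of subjects in one region."""
        ids = [s.subject_id for s in subjects]
        x = np.array([s.age for s in subjects], dtype=float)
        y = self.zvolumes.loc[ids, region].to_numpy(dtype=float)
        return x, y


def normalize_volumes(
    cohort: list[SubjectRecord], regions: list[str] | None = None
) -> NormalizedCohort:
    """TIV-normalize and z-score the region volumes of a cohort.

    For each region the ratio volume/TIV is computed per subject; the mean
    and sample SD (n-1 denominator) of the ratio over the *whole* cohort
    define the z-transform.  A region with zero ratio variance cannot be
    analyzed and raises ``ValueError`` naming the region.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if regions is None:
        regions = region_codes(cohort)
    if not regions:
        raise ValueError("no regions to normalize")
    for s in cohort:
        if s.tiv <= 0:
            raise ValueError(f"subject {s.subject_id!r} has non-positive TIV")

    ids = [s.subject_id for s in cohort]
    ratios = pd.DataFrame(
        {r: [s.volumes[r] / s.tiv for s in cohort] for r in regions}, index=ids
    )
    stats: dict[str, tuple[float, float]] = {}
    z = pd.DataFrame(index=ids, columns=regions, dtype=float)
    for r in regions:
        mean = float(ratios[r].mean())
        sd = float(ratios[r].std(ddof=1))
        if sd == 0 or not math.isfinite(sd):
            raise ValueError(f"zero variance in region {r!r}: cannot z-score")
        stats[r] = (mean, sd)
        z[r] = (ratios[r] - mean) / sd
    return NormalizedCohort(subjects=list(cohort), zvolumes=z, stats=stats)


def remove_outliers(nc: NormalizedCohort, z_limit: float = 4.0) -> NormalizedCohort:
    """Drop subjects with any |z| above ``z_limit`` in any analyzed region.

    Single pass: z-scores are *not* recomputed after removal, so the
    retained subjects stay on the original cohort scale.
    """
    if z_limit <= 0:
        raise ValueError("z_limit must be positive")
    ok = (nc.zvolumes.abs() <= z_limit).all(axis=1)
    keep_ids = set(nc.zvolumes.index[ok])
    subs = [s for s in nc.subjects if s.subject_id in keep_ids]
    return NormalizedCohort(
        subjects=subs,
        zvolumes=nc.zvolumes.loc[[s.subject_id for s in subs]],
        stats=dict(nc.stats),
    )


def compute_age_range(
    ages, min_count: int = 5, window: int = 2
) -> AgeRange:
    """Valid age range of a group: longest run of dense sliding windows.

    Windows ``[a, a+window)`` are evaluated for integer ``a`` from
    ``floor(min age)`` to ``ceil(max age) - window``; a window is dense when
    it holds at least ``min_count`` ages.  The result spans the longest
    contiguous run of dense windows, ``[first a, last a + window]``; ties
    break toward the younger end.  Invalid when no window is dense.
    """
    if min_count < 1 or window < 1:
        raise ValueError("min_count and window must be >= 1")
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        return AgeRange(0, 0, valid=False)
    lo = math.floor(ages.min())
    hi = math.ceil(ages.max())
    starts = range(lo, hi - window + 1)
    dense = [
        int(np.count_nonzero((ages >= a) & (ages < a + window))) >= min_count
        for a in starts
    ]
    best_len, best_start = 0, None
    run_len, run_start = 0, None
    for a, d in zip(starts, dense):
        if d:
            if run_len == 0:
                run_start = a
            run_len += 1
            if run_len > best_len:
                best_len, best_start = run_len, run_start
        else:
            run_len = 0
    if best_start is None:
        return AgeRange(0, 0, valid=False)
    return AgeRange(best_start, best_start + best_len - 1 + window, valid=True)


def overlap_range(a: AgeRange, b: AgeRange) -> AgeRange:
    """Intersection of two valid age ranges; invalid when disjoint."""
    if not (a.valid and b.valid):
        return AgeRange(0, 0, valid=False)
    lo, hi = max(a.lo, b.lo), min(a.hi, b.hi)
    if lo >= hi:
        return AgeRange(0, 0, valid=False)
    return AgeRange(lo, hi, valid=True)
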