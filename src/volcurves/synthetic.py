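"""Synthetic biomarker-stratified cohorts with known ground truth.

The source cohort (cognitively unimpaired adults 50+ with CSF and
volumetric MRI data) is access-restricted, so this module generates
cohorts that emulate its structure: five biomarker groups with the
published sizes, gender mixes and truncated-normal age distributions;
CSF and vascular marker values drawn from intervals that realize each
group's A/T/N/V definition with a safety margin; and region volumes
following group-specific, piecewise-linear declining age trajectories
on a latent z-scale, mapped affinely to volume/TIV ratios.

Every generated subject passes QC with CDR 0, so the generator's output
exercises stratification, normalization, curve estimation and comparison
end to end against analytically known mean curves (:func:`true_mean_curve`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps

from .cohort import SubjectRecord
from .stratification import (
    ABETA42_CUTOFF,
    PTAU_CUTOFF,
    RATIO_CUTOFF,
    TTAU_CUTOFF,
    GroupLabel,
)

#: Published group sizes (cohort of 1,380 after exclusions).
DEFAULT_GROUP_SIZES = {"N": 782, "AD": 178, "V": 212, "AV": 118, "OP": 90}

#: Female counts per group, as published.
DEFAULT_FEMALE_COUNTS = {"N": 439, "AD": 93, "V": 115, "AV": 62, "OP": 49}

#: Per group and gender: mean age and SD of the (truncated-at-50) normal.
DEFAULT_AGE_MODEL = {
    "N": {"female": (62.8, 6.7), "male": (64.2, 6.8)},
    "AD": {"female": (68.4, 5.8), "male": (68.2, 6.7)},
    "V": {"female": (69.0, 6.5), "male": (69.5, 6.9)},
    "AV": {"female": (72.1, 5.1), "male": (73.2, 5.1)},
    "OP": {"female": (66.5, 5.4), "male": (71.0, 5.7)},
}

#: Default region set (medial-temporal, basal forebrain and assorted
#: cortical/subcortical codes in the source parcellation's naming style).
DEFAULT_REGIONS = [
    "LLENTAV", "LRENTAV", "LLAMYG", "LRAMYG", "LRBFBV",
    "LRMTGV", "LLILVV", "LRINFOGV", "LRPOSTGV", "LLPLANPV",
]


@dataclass(frozen=True)
class RegionModel:
    """Latent age trajectory and volume mapping of one region.

    The latent trajectory is ``z(age) = baseline + slope * (age - 50)`` in
    z-units; the volume/TIV ratio is the affine map
    ``ratio = ratio_base + ratio_scale * z``.
    """

    baseline: float = 0.7  # z at age 50
    slope: float = -0.02  # z per year: gradual normative decline
    ratio_base: float = 0.005
    ratio_scale: float = 0.00025


@dataclass(frozen=True)
class Effect:
    """Group-specific atrophy acceleration in one region.

    Adds ``extra_slope * max(0, age - onset_age)`` z-units to the latent
    trajectory of ``region`` for subjects of ``group``; restricted to one
    gender when ``gender`` is set (a constant gender offset would be
    absorbed by per-subset z-scoring, an age-dependent one is not).
    """

    group: str
    region: str
    onset_age: float = 60.0
    extra_slope: float = -0.03
    gender: str | None = None


#: Default pathology pattern: medial-temporal acceleration in the amyloid
#: groups (stronger with added vascular burden), fronto-parietal and basal
#: forebrain involvement without amygdalae in the pure vascular group.
DEFAULT_EFFECTS = (
    Effect("AD", "LLENTAV", 60.0, -0.030),
    Effect("AD", "LRENTAV", 60.0, -0.028),
    Effect("AD", "LLAMYG", 60.0, -0.028),
    Effect("AD", "LRAMYG", 60.0, -0.030),
    Effect("AD", "LRBFBV", 62.0, -0.020),
    Effect("AV", "LLENTAV", 58.0, -0.034),
    Effect("AV", "LRENTAV", 58.0, -0.032),
    Effect("AV", "LLAMYG", 58.0, -0.034),
    Effect("AV", "LRAMYG", 58.0, -0.032),
    Effect("AV", "LRBFBV", 60.0, -0.024),
    Effect("V", "LLENTAV", 60.0, -0.030),
    Effect("V", "LRBFBV", 60.0, -0.024),
    Effect("V", "LRPOSTGV", 60.0, -0.026),
    Effect("V", "LRINFOGV", 60.0, -0.024),
)


def _default_region_models() -> dict[str, RegionModel]:
    models = {}
    for i, r in enumerate(DEFAULT_REGIONS):
        base = 0.0015 * (i + 2)  # spread ratio magnitudes across regions
        models[r] = RegionModel(
            baseline=0.7, slope=-0.02, ratio_base=base, ratio_scale=0.05 * base
        )
    return models


@dataclass
class SyntheticConfig:
    """Full specification of a synthetic cohort."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    female_fraction: dict[str, float] = field(
        default_factory=lambda: {
            g: DEFAULT_FEMALE_COUNTS[g] / DEFAULT_GROUP_SIZES[g]
            for g in DEFAULT_GROUP_SIZES
        }
    )
    age_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            g: dict(v) for g, v in DEFAULT_AGE_MODEL.items()
        }
    )
    regions: dict[str, RegionModel] = field(default_factory=_default_region_models)
    effects: list[Effect] = field(default_factory=lambda: list(DEFAULT_EFFECTS))
    noise_sd: float = 0.5  # z-units of subject-level scatter
    gender_offset: dict[str, float] = field(default_factory=dict)  # z, added to males
    threshold_margin: float = 0.05  # keep biomarker draws 5% away from cutoffs
    age_bounds: tuple[float, float] = (50.0, 95.0)
    tiv_mean: float = 1450.0
    tiv_sd: float = 130.0
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 < self.threshold_margin < 0.3:
            raise ValueError("threshold_margin must be in (0, 0.3)")
        for e in self.effects:
            if e.onset_age < 50:
                raise ValueError("effect onset_age must be >= 50")
            if e.group not in DEFAULT_GROUP_SIZES:
                raise ValueError(f"effect for unknown group {e.group!r}")
            if e.region not in self.regions:
                raise ValueError(f"effect for unknown region {e.region!r}")


def default_config(seed: int = 0) -> SyntheticConfig:
    return SyntheticConfig(seed=seed)


# --- status and biomarker sampling ---------------------------------------


def _draw_status(group: str, rng: np.random.Generator) -> tuple[bool, bool, bool, bool]:
    """Draw an (A, T, N, V) combination consistent with the group."""
    if group == "N":
        return False, False, False, False
    if group == "AD":
        return True, bool(rng.integers(2)), bool(rng.integers(2)), False
    if group == "V":
        return False, False, bool(rng.integers(2)), True
    if group == "AV":
        return True, bool(rng.integers(2)), bool(rng.integers(2)), True
    if group == "OP":
        t, n = [(True, False), (False, True), (True, True)][rng.integers(3)]
        return False, t, n, False
    raise ValueError(f"unknown group {group!r}")


def _draw_biomarkers(a: bool, t: bool, n: bool, margin: float, rng):
    """CSF values realizing the given A/T/N status with a threshold margin."""
    ptau = (
        rng.uniform(PTAU_CUTOFF * (1 + margin), 40.0)
        if t
        else rng.uniform(12.0, PTAU_CUTOFF * (1 - margin))
    )
    ttau = (
        rng.uniform(TTAU_CUTOFF * (1 + margin), 450.0)
        if n
        else rng.uniform(120.0, TTAU_CUTOFF * (1 - margin))
    )
    if a:
        abeta = rng.uniform(500.0, ABETA42_CUTOFF * (1 - margin))
    else:
        lo = max(ABETA42_CUTOFF * (1 + margin), ptau / (RATIO_CUTOFF * (1 - margin)))
        abeta = rng.uniform(lo, lo + 1200.0)
    return abeta, ttau, ptau


def _draw_vascular(v: bool, rng) -> tuple[int, int, bool]:
    """(fazekas, microbleeds, stroke) realizing the vascular status."""
    if not v:
        return int(rng.choice([0, 0, 1, 1])), int(rng.choice([0, 0, 0, 1, 2, 3])), False
    mech = rng.choice(3, p=[0.7, 0.2, 0.1])
    fazekas = int(rng.choice([2, 3])) if mech == 0 else int(rng.choice([0, 1]))
    mb = int(rng.integers(4, 9)) if mech == 1 else int(rng.integers(0, 4))
    return fazekas, mb, mech == 2


def _truncnorm(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _effect_map(config: SyntheticConfig) -> dict[tuple[str, str], list[Effect]]:
    out: dict[tuple[str, str], list[Effect]] = {}
    for e in config.effects:
        out.setdefault((e.group, e.region), []).append(e)
    return out


def latent_z(
    config: SyntheticConfig, group: str, region: str, ages, gender: str
) -> np.ndarray:
    """Noiseless latent z-trajectory of a group×region for one gender
    (before the constant gender offset)."""
    ages = np.asarray(ages, dtype=float)
    rm = config.regions[region]
    z = rm.baseline + rm.slope * (ages - 50.0)
    for e in _effect_map(config).get((group, region), []):
        if e.gender in (None, gender):
            z = z + e.extra_slope * np.clip(ages - e.onset_age, 0.0, None)
    return z


def generate_cohort(config: SyntheticConfig | None = None) -> list[SubjectRecord]:
    """Generate one synthetic cohort according to ``config``.

    Group sizes are exact; ages come from per-group/gender truncated
    normals; biomarkers satisfy each group's A/T/N/V definition by
    construction; volumes follow the configured latent trajectories plus
    Gaussian noise.  Deterministic given ``config.seed``.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo_age, hi_age = config.age_bounds
    cohort: list[SubjectRecord] = []
    counter = 0
    # canonical iteration order: results must not depend on dict insertion
    # order (configs round-trip through sorted YAML)
    region_order = sorted(config.regions)
    for group in sorted(config.group_sizes):
        n = config.group_sizes[group]
        if n == 0:
            continue
        n_female = int(round(config.female_fraction.get(group, 0.5) * n))
        genders = np.array(["female"] * n_female + ["male"] * (n - n_female))
        ages = np.empty(n)
        for gender in ("female", "male"):
            mask = genders == gender
            mean, sd = config.age_model[group][gender]
            ages[mask] = _truncnorm(mean, sd, lo_age, hi_age, mask.sum(), rng)
        tiv = _truncnorm(config.tiv_mean, config.tiv_sd, 1.0, np.inf, n, rng)

        region_z = {}
        for region in region_order:
            rm = config.regions[region]
            z = np.empty(n)
            for gender in ("female", "male"):
                mask = genders == gender
                z[mask] = latent_z(config, group, region, ages[mask], gender)
            offset = config.gender_offset.get(region, 0.0)
            z = z + np.where(genders == "male", offset, 0.0)
            z = z + rng.normal(0.0, config.noise_sd, size=n)
            region_z[region] = rm.ratio_base + rm.ratio_scale * z

        for i in range(n):
            a, t, nn, v = _draw_status(group, rng)
            abeta, ttau, ptau = _draw_biomarkers(a, t, nn, config.threshold_margin, rng)
            fazekas, mb, stroke = _draw_vascular(v, rng)
            counter += 1
            cohort.append(
                SubjectRecord(
                    subject_id=f"SYN{counter:05d}",
                    age=float(ages[i]),
                    gender=str(genders[i]),
                    abeta42=float(abeta),
                    ttau=float(ttau),
                    ptau=float(ptau),
                    fazekas=fazekas,
                    microbleeds=mb,
                    stroke_history=stroke,
                    cdr_global=0.0,
                    qc_pass=True,
                    radiological_exclusion=False,
                    tiv=float(tiv[i]),
                    volumes={
                        r: float(tiv[i] * region_z[r][i]) for r in region_order
                    },
                )
            )
    return cohort


def true_mean_curve(
    config: SyntheticConfig, group: str, region: str, grid
) -> np.ndarray:
    """Noiseless latent z-trajectory marginalized over the group's gender mix."""
    f = config.female_fraction.get(group, 0.5)
    zf = latent_z(config, group, region, grid, "female")
    zm = latent_z(config, group, region, grid, "male")
    return f * zf + (1.0 - f) * (zm + config.gender_offset.get(region, 0.0))


def true_curve_on_cohort_scale(
    config: SyntheticConfig,
    group: str,
    region: str,
    grid,
    stats: dict[str, tuple[float, float]],
) -> np.ndarray:
    """Ground-truth mean curve expressed in the analysis z-units.

    The pipeline z-scores volume/TIV ratios with cohort-wide (mean, sd)
    ``stats``; this maps the latent truth through the same affine chain
    (latent z → ratio → cohort z) so estimated and true curves are
    directly comparable.
    """
    rm = config.regions[region]
    ratio = rm.ratio_base + rm.ratio_scale * true_mean_curve(config, group, region, grid)
    mean, sd = stats[region]
    return (ratio - mean) / sd


def cohort_curve_to_latent(
    config: SyntheticConfig,
    region: str,
    stats: dict[str, tuple[float, float]],
    values,
) -> np.ndarray:
    """Map an estimated curve from analysis z-units back to latent z-units.

    Inverts the affine chain latent z → ratio → cohort z (the latter
    defined by the normalization ``stats`` of the analyzed cohort), so an
    estimated curve can be compared to :func:`true_mean_curve` on the scale
    where ``noise_sd`` and the configured trajectories live.
    """
    rm = config.regions[region]
    mean, sd = stats[region]
    ratio = mean + sd * np.asarray(values, dtype=float)
    return (ratio - rm.ratio_base) / rm.ratio_scale


def intended_group_sizes(config: SyntheticConfig) -> dict[GroupLabel, int]:
    return {GroupLabel(g): n for g, n in config.group_sizes.items()}


# --- YAML round-trip ------------------------------------------------------


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["regions"] = {r: asdict(m) for r, m in config.regions.items()}
    d["effects"] = [asdict(e) for e in config.effects]
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    if "regions" in d:
        d["regions"] = {r: RegionModel(**m) for r, m in d["regions"].items()}
    if "effects" in d:
        d["effects"] = [Effect(**e) for e in d["effects"]]
    if "age_model" in d:
        d["age_model"] = {
            g: {sex: tuple(ms) for sex, ms in v.items()}
            for g, v in d["age_model"].items()
        }
    if "age_bounds" in d:
        d["age_bounds"] = tuple(d["age_bounds"])
    return SyntheticConfig(**d)
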