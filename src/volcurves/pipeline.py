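"""End-to-end analysis pipeline and run artifacts.

Orchestrates: inclusion filtering → A/T/N/V stratification → TIV + z-score
normalization → outlier removal → per-group age ranges → bootstrap volume
curves per region×group → configured group comparisons (area between
curves, calibrated chi-squared test, Bonferroni) → ranking and significance
tables.  With ``gender="each"`` the full analysis is rerun independently on
the female and male subsets, recomputing normalization statistics within
each subset.

All artifacts are written under the output directory together with a
``manifest.yaml`` that records every setting and seed; a run can be
reproduced exactly from its manifest alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import SubjectRecord, read_cohort_csv
from .comparison import (
    ALL,
    ComparisonSettings,
    CurveComparison,
    compare_groups,
    fit_group_curves,
    rank_regions,
)
from .preprocessing import normalize_volumes, remove_outliers
from .stratification import (
    ANALYSIS_GROUPS,
    GroupLabel,
    apply_inclusion_filters,
    stratify_cohort,
)
from .synthetic import (
    SyntheticConfig,
    config_from_dict,
    config_to_dict,
    generate_cohort,
)

DEFAULT_COMPARISONS = (("N", ALL), ("N", "AD"), ("N", "V"), ("N", "AV"), ("N", "OP"))


class PipelineError(RuntimeError):
    """Stage failure with the stage name and offending entity."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Complete, serializable configuration of a pipeline run."""

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    regions: list[str] | None = None  # None = all regions in the cohort
    comparisons: tuple = DEFAULT_COMPARISONS
    n_boot: int = 100
    bandwidths: tuple = (5.0, 10.0, 15.0)
    cv_folds: int = 5
    alpha: float = 0.01
    min_count: int = 5
    window: int = 2
    z_limit: float = 4.0
    gender: str = "all"  # all | female | male | each
    top_k: int = 10
    seed: int = 0
    out_dir: str = "volcurves_out"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise PipelineError("config", "provide exactly one of input_csv or synthetic")
        if not 0 < self.alpha < 1:
            raise PipelineError("config", f"alpha {self.alpha} outside (0, 1)")
        if self.n_boot < 2:
            raise PipelineError("config", "n_boot must be >= 2")
        if self.gender not in ("all", "female", "male", "each"):
            raise PipelineError("config", f"unknown gender mode {self.gender!r}")

    def settings(self) -> ComparisonSettings:
        return ComparisonSettings(
            bandwidths=tuple(self.bandwidths),
            cv_folds=self.cv_folds,
            n_boot=self.n_boot,
            min_count=self.min_count,
            window=self.window,
            alpha=self.alpha,
            seed=self.seed,
        )


@dataclass
class RunReport:
    """In-memory summary of a run; files on disk hold the full tables."""

    flow: dict = field(default_factory=dict)  # stage → subject counts
    comparisons: dict = field(default_factory=dict)  # subset → list[CurveComparison]
    warnings: list = field(default_factory=list)
    out_dir: str = ""


def _load_cohort(config: RunConfig) -> list[SubjectRecord]:
    if config.input_csv is not None:
        try:
            return read_cohort_csv(config.input_csv)
        except Exception as exc:
            raise PipelineError("load", f"cannot read {config.input_csv}: {exc}")
    syn = config_from_dict(config_to_dict(config.synthetic))
    syn.seed = config.seed
    return generate_cohort(syn)


def _curves_frame(curve_sets: dict) -> pd.DataFrame:
    rows = []
    for label, curves in sorted(curve_sets.items()):
        for region in sorted(curves):
            c = curves[region]
            for age, m, sd in zip(c.grid, c.mean, c.sd):
                rows.append(
                    {
                        "region_code": region, "group": label, "age": int(age),
                        "mean": m, "sd": sd, "bandwidth": c.bandwidth,
                        "n_subjects": c.n_subjects,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["region_code", "group", "age", "mean", "sd", "bandwidth", "n_subjects"],
    )


def _comparisons_frame(comps: list[CurveComparison]) -> pd.DataFrame:
    rows = [
        {
            "region_code": c.region_code, "group_a": c.group_a, "group_b": c.group_b,
            "overlap_lo": c.overlap.lo if c.overlap.valid else "",
            "overlap_hi": c.overlap.hi if c.overlap.valid else "",
            "area": c.area, "chi2": c.chi2, "df": c.df,
            "df_effective": c.df_effective, "p_raw": c.p_raw, "p_adj": c.p_adj,
            "significant": int(c.significant), "descriptive": int(c.descriptive),
            "valid": int(c.valid), "reason": c.reason,
            "bandwidth_a": c.bandwidth_a, "bandwidth_b": c.bandwidth_b,
            "n_a": c.n_a, "n_b": c.n_b,
        }
        for c in comps
    ]
    return pd.DataFrame(rows)


def _run_subset(
    cohort: list[SubjectRecord],
    config: RunConfig,
    subset: str,
    report: RunReport,
    out: Path,
) -> None:
    """Run the full analysis on one gender subset and write its tables."""
    if subset != "all":
        cohort = [s for s in cohort if s.gender == subset]
    if not cohort:
        raise PipelineError("subset", f"no subjects in gender subset {subset!r}")
    flow = {"included": len(cohort)}

    try:
        nc = normalize_volumes(cohort, config.regions)
    except ValueError as exc:
        raise PipelineError("normalization", str(exc))
    nc = remove_outliers(nc, config.z_limit)
    flow["after_outlier_removal"] = len(nc.subjects)

    groups = stratify_cohort(nc.subjects)
    flow.update({f"group_{g}": len(groups[g]) for g in GroupLabel})
    settings = config.settings()
    regions = nc.regions

    labels_needed = sorted({str(l) for pair in config.comparisons for l in pair})
    curve_cache, range_cache = {}, {}
    for label in labels_needed:
        if label == ALL:
            subjects = [s for g in ANALYSIS_GROUPS for s in groups[g]]
        else:
            subjects = groups[GroupLabel(label)]
        if not subjects:
            report.warnings.append(f"{subset}: group {label} empty, comparisons skipped")
            continue
        curves, age_range = fit_group_curves(nc, subjects, label, regions, settings)
        if not age_range.valid:
            report.warnings.append(
                f"{subset}: group {label} has no dense age range, comparisons skipped"
            )
            continue
        curve_cache[label], range_cache[label] = curves, age_range

    all_comps: list[CurveComparison] = []
    for ga, gb in config.comparisons:
        ga, gb = str(ga), str(gb)
        if ga not in curve_cache or gb not in curve_cache:
            continue
        all_comps.extend(
            compare_groups(
                nc, ga, gb, regions, settings,
                curves_a=curve_cache[ga], curves_b=curve_cache[gb],
                range_a=range_cache[ga], range_b=range_cache[gb],
            )
        )

    out.mkdir(parents=True, exist_ok=True)
    _curves_frame(curve_cache).to_csv(out / "curves.csv", index=False)
    comp_df = _comparisons_frame(all_comps)
    comp_df.to_csv(out / "comparisons.csv", index=False)

    rank_rows = []
    for ga, gb in config.comparisons:
        pair = [c for c in all_comps if c.group_a == str(ga) and c.group_b == str(gb)]
        if not pair:
            continue
        for rank, c in enumerate(rank_regions(pair, config.top_k), start=1):
            rank_rows.append(
                {"group_a": c.group_a, "group_b": c.group_b, "rank": rank,
                 "region_code": c.region_code, "area": c.area}
            )
    pd.DataFrame(
        rank_rows, columns=["group_a", "group_b", "rank", "region_code", "area"]
    ).to_csv(out / "ranking_top10.csv", index=False)

    if len(comp_df):
        sig = comp_df[comp_df["significant"] == 1]
    else:
        sig = comp_df
    sig.to_csv(out / "significant_regions.csv", index=False)

    report.flow[subset] = flow
    report.comparisons[subset] = all_comps


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute a full run; returns the report and writes all artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=str(out))
    manifest_path = out / "manifest.yaml"
    try:
        raw = _load_cohort(config)
        report.flow["loaded"] = {"total": len(raw)}
        try:
            kept, rejected = apply_inclusion_filters(raw)
        except ValueError as exc:
            raise PipelineError("inclusion", str(exc))
        report.flow["inclusion"] = {
            "kept": len(kept),
            "rejected": len(rejected),
        }
        pd.DataFrame(rejected, columns=["subject_id", "reason_code"]).to_csv(
            out / "rejections.csv", index=False
        )
        # the ambiguous A-/T+/V+ profile is dropped once, after inclusion
        groups0 = stratify_cohort(kept)
        excluded = groups0[GroupLabel.EXCLUDED]
        analysis = [s for g in ANALYSIS_GROUPS for s in groups0[g]]
        report.flow["stratification"] = {
            "analysis": len(analysis),
            "excluded_ambiguous": len(excluded),
        }
        subsets = (
            ["all", "female", "male"] if config.gender == "each" else [config.gender]
        )
        for subset in subsets:
            sub_out = out / subset
            _run_subset(analysis, config, subset, report, sub_out)
    except Exception as exc:
        _write_manifest(manifest_path, config, report, status="FAILED", error=str(exc))
        raise
    _write_manifest(manifest_path, config, report, status="OK")
    return report


def _write_manifest(path, config: RunConfig, report: RunReport, status, error=None):
    d = dataclasses.asdict(config)
    if config.synthetic is not None:
        d["synthetic"] = config_to_dict(config.synthetic)
    d["comparisons"] = [list(map(str, pair)) for pair in config.comparisons]
    d["bandwidths"] = list(config.bandwidths)
    manifest = {
        "volcurves_version": __version__,
        "status": status,
        "config": d,
        "flow": report.flow,
        "warnings": report.warnings,
    }
    if error is not None:
        manifest["error"] = error
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def config_from_manifest(path) -> RunConfig:
    """Rebuild the RunConfig of a previous run from its manifest."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    d = dict(manifest["config"])
    if d.get("synthetic") is not None:
        d["synthetic"] = config_from_dict(d["synthetic"])
    d["comparisons"] = tuple(tuple(pair) for pair in d["comparisons"])
    d["bandwidths"] = tuple(d["bandwidths"])
    if d.get("regions") is not None:
        d["regions"] = list(d["regions"])
    return RunConfig(**d)


def rerun_from_manifest(manifest_path, out_dir) -> RunReport:
    """Reproduce a run exactly from its manifest into a new directory."""
    config = config_from_manifest(manifest_path)
    config.out_dir = str(out_dir)
    return run_pipeline(config)
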