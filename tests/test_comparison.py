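"""Area between curves, chi-squared curve test, Bonferroni and ranking."""

import numpy as np
import pytest
from scipy import stats as sps

from volcurves.comparison import (
    ComparisonSettings,
    area_between,
    bonferroni_adjust,
    chi2_curve_test,
    compare_groups,
    rank_regions,
)
from volcurves.curves import VolumeCurve
from volcurves.preprocessing import AgeRange
from volcurves.synthetic import Effect
import volcurves as vc


def toy_curve(grid, mean, sd=None, n_boot=100, jitter_seed=None):
    """A VolumeCurve with prescribed mean/sd and synthetic replicates.

    Replicates are mean + sd * standard-normal draws (or exactly the mean
    when sd is None), so pointwise statistics approximate the prescription
    while the exact `mean`/`sd` fields carry it.
    """
    grid = np.asarray(grid)
    mean = np.asarray(mean, dtype=float)
    if sd is None:
        sd = np.zeros_like(mean)
        boot = np.tile(mean, (n_boot, 1))
    else:
        sd = np.asarray(sd, dtype=float)
        rng = np.random.default_rng(jitter_seed or 0)
        boot = mean + sd * rng.standard_normal((n_boot, grid.size))
    return VolumeCurve(
        region_code="toy", group="G", grid=grid, mean=mean, sd=sd,
        bootstrap=boot, bandwidth=10.0, n_subjects=50,
    )


class TestAreaBetween:
    def test_identical_curves_have_zero_area(self):
        grid = np.arange(60, 81)
        c = toy_curve(grid, np.sin(grid / 7.0))
        assert area_between(c, c, AgeRange(60, 80)) == 0.0

    def test_constant_offset_is_a_rectangle(self):
        grid = np.arange(60, 81)
        a = toy_curve(grid, np.zeros(grid.size))
        b = toy_curve(grid, np.full(grid.size, 0.5))
        assert area_between(a, b, AgeRange(60, 80)) == pytest.approx(10.0, abs=1e-12)

    def test_crossing_piecewise_linear_curves_sum_triangles(self):
        # difference falls linearly from 0.4 at 60 to -0.4 at 68 (crossing
        # at 64): two triangles of area 0.5*4*0.4 = 0.8 each
        grid = np.arange(60, 69)
        diff = 0.4 - 0.1 * (grid - 60)
        a = toy_curve(grid, diff)
        b = toy_curve(grid, np.zeros(grid.size))
        assert area_between(a, b, AgeRange(60, 68)) == pytest.approx(1.6, abs=1e-12)

    def test_symmetry_and_triangle_inequality(self, rng):
        grid = np.arange(60, 81)
        a = toy_curve(grid, rng.normal(0, 1, grid.size))
        b = toy_curve(grid, rng.normal(0, 1, grid.size))
        c = toy_curve(grid, rng.normal(0, 1, grid.size))
        ov = AgeRange(60, 80)
        assert area_between(a, b, ov) == area_between(b, a, ov)
        assert area_between(a, c, ov) <= (
            area_between(a, b, ov) + area_between(b, c, ov) + 1e-12
        )

    def test_subgrid_overlap_and_invalid_overlap(self):
        grid = np.arange(55, 86)
        a = toy_curve(grid, np.zeros(grid.size))
        b = toy_curve(grid, np.ones(grid.size))
        assert area_between(a, b, AgeRange(60, 70)) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            area_between(a, b, AgeRange(0, 0, valid=False))


class TestChi2CurveTest:
    def test_equal_curves_give_zero_statistic_p_one(self):
        grid = np.arange(60, 71)
        m = np.sin(grid / 5.0)
        a = toy_curve(grid, m, sd=np.full(grid.size, 0.1), jitter_seed=1)
        b = toy_curve(grid, m, sd=np.full(grid.size, 0.1), jitter_seed=2)
        res = chi2_curve_test(a, b, AgeRange(60, 70))
        assert res.chi2 == 0.0
        assert res.p_raw == 1.0

    def test_single_point_matches_chi2_survival_oracle(self):
        grid = np.array([65])
        a = toy_curve(grid, [1.0], sd=np.array([1.0]), jitter_seed=1)
        b = toy_curve(grid, [0.0])  # sd exactly zero
        res = chi2_curve_test(a, b, AgeRange(65, 65))
        assert res.chi2 == pytest.approx(1.0)
        assert res.df == 1
        assert res.p_raw == pytest.approx(sps.chi2.sf(1.0, 1), abs=1e-4)

    def test_statistic_invariant_under_swap(self, rng):
        grid = np.arange(60, 76)
        a = toy_curve(grid, rng.normal(0, 1, grid.size),
                      sd=np.full(grid.size, 0.2), jitter_seed=3)
        b = toy_curve(grid, rng.normal(0, 1, grid.size),
                      sd=np.full(grid.size, 0.3), jitter_seed=4)
        ov = AgeRange(60, 75)
        r1, r2 = chi2_curve_test(a, b, ov), chi2_curve_test(b, a, ov)
        assert r1.chi2 == pytest.approx(r2.chi2)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_zero_pooled_variance_is_an_error(self):
        grid = np.arange(60, 63)
        a = toy_curve(grid, [0.0, 0.0, 0.0])
        b = toy_curve(grid, [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="pooled variance"):
            chi2_curve_test(a, b, AgeRange(60, 62))

    def test_effective_df_shrinks_under_correlated_replicates(self, rng):
        """Smooth (correlated) replicate noise must reduce the effective df
        well below the grid size, while keeping it at least one."""
        grid = np.arange(60, 81)
        shared = rng.standard_normal((100, 1)) * np.ones(grid.size)
        boot = 0.02 * rng.standard_normal((100, grid.size)) + shared
        a = toy_curve(grid, boot.mean(0), sd=boot.std(0, ddof=1))
        a.bootstrap = boot
        b = toy_curve(grid, np.zeros(grid.size), sd=np.full(grid.size, 1.0),
                      jitter_seed=8)
        res = chi2_curve_test(a, b, AgeRange(60, 80))
        assert 1.0 <= res.df_effective < res.df / 2


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni_adjust([0.002] * 10)[0] == pytest.approx(0.02)
        assert bonferroni_adjust([0.2] * 10)[0] == 1.0
        assert bonferroni_adjust([0.37]) == [0.37]

    def test_explicit_family_size(self):
        assert bonferroni_adjust([0.004], m=5) == [pytest.approx(0.02)]

    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])


def small_cohort(seed, effects=(), n_per_group=150):
    cfg = vc.default_config(seed)
    cfg.group_sizes = {"N": n_per_group, "AD": n_per_group}
    cfg.female_fraction = {"N": 0.5, "AD": 0.5}
    cfg.age_model = {
        "N": {"female": (65.0, 7.0), "male": (65.0, 7.0)},
        "AD": {"female": (65.0, 7.0), "male": (65.0, 7.0)},
    }
    cfg.effects = list(effects)
    cohort = vc.generate_cohort(cfg)
    kept, _ = vc.apply_inclusion_filters(cohort)
    return vc.remove_outliers(vc.normalize_volumes(kept), 4.0)


class TestCompareGroups:
    def test_self_comparison_is_null(self):
        nc = small_cohort(5)
        comps = compare_groups(
            nc, "N", "N", regions=["LLENTAV", "LLAMYG"],
            settings=ComparisonSettings(seed=5, n_boot=30),
        )
        for c in comps:
            assert c.area == 0.0
            assert c.p_raw == 1.0

    def test_known_effect_region_ranks_first_in_most_runs(self):
        wins = 0
        for seed in range(5):
            nc = small_cohort(seed, effects=[Effect("AD", "LRAMYG", 55.0, -0.05)])
            comps = compare_groups(
                nc, "N", "AD", settings=ComparisonSettings(seed=seed, n_boot=50)
            )
            wins += rank_regions(comps, 1)[0].region_code == "LRAMYG"
        assert wins >= 4

    def test_results_sorted_by_descending_area(self):
        nc = small_cohort(2)
        comps = compare_groups(
            nc, "N", "AD", settings=ComparisonSettings(seed=2, n_boot=30)
        )
        areas = [c.area for c in comps if c.valid]
        assert areas == sorted(areas, reverse=True)

    def test_bonferroni_family_is_region_count(self):
        nc = small_cohort(3)
        comps = compare_groups(
            nc, "N", "AD", regions=["LLENTAV", "LLAMYG", "LRAMYG"],
            settings=ComparisonSettings(seed=3, n_boot=30),
        )
        tested = [c for c in comps if c.valid]
        for c in tested:
            assert c.p_adj == pytest.approx(min(1.0, c.p_raw * len(tested)))


class TestRankRegions:
    def _comp(self, region, area):
        return type(
            "C", (), {"region_code": region, "area": area, "valid": True}
        )()

    def test_orders_by_area_then_code(self):
        comps = [self._comp("A", 3.0), self._comp("B", 5.0), self._comp("C", 1.0)]
        assert [c.region_code for c in rank_regions(comps, 2)] == ["B", "A"]

    def test_equal_areas_break_lexicographically(self):
        comps = [self._comp("Z", 2.0), self._comp("A", 2.0)]
        assert [c.region_code for c in rank_regions(comps, 2)] == ["A", "Z"]

    def test_top_k_larger_than_list_returns_all(self):
        comps = [self._comp("A", 1.0)]
        assert len(rank_regions(comps, 10)) == 1

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            rank_regions([], 3)
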