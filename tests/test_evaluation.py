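"""Top-percent summaries, rolling-null chance, improvement, and bootstraps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import funcsearchlight as fs
from funcsearchlight.engine import MetricMap


def make_map(values, kind="anatomical"):
    vals = np.asarray(values, dtype=np.float64)
    return MetricMap(
        centers=np.arange(vals.size), values=vals, kernel_label="test", kind=kind
    )


class TestTopPercent:
    def test_top_one_of_hundred(self):
        assert fs.top_percent_summary(make_map(np.arange(1, 101)), 1.0) == 100.0

    def test_percent_hundred_is_mean(self, rng):
        vals = rng.standard_normal(73)
        assert fs.top_percent_summary(make_map(vals), 100.0) == pytest.approx(vals.mean())

    def test_ceil_rule_250_values(self, rng):
        vals = rng.standard_normal(250)
        expected = np.sort(vals)[-3:].mean()  # ceil(2.5) = 3
        assert fs.top_percent_summary(make_map(vals), 1.0) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(n=st.integers(1, 400), percent=st.floats(0.1, 100.0))
    def test_matches_sort_and_slice_oracle(self, n, percent):
        rng = np.random.default_rng(n)
        vals = rng.standard_normal(n)
        expected = np.mean(sorted(vals)[-math.ceil(percent / 100 * n):])
        assert fs.top_percent_summary(make_map(vals), percent) == pytest.approx(expected)

    def test_missing_values_excluded(self):
        vals = np.array([1.0, np.nan, 3.0, np.nan])
        assert fs.top_percent_summary(make_map(vals), 100.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            fs.top_percent_summary(make_map([np.nan, np.nan]), 1.0)


class TestPercentImprovement:
    def test_equal_corrected_stats_zero(self):
        assert fs.percent_improvement(0.3, 0.2, 0.1, 0.0) == pytest.approx(0.0)

    def test_doubling_is_hundred_percent(self):
        assert fs.percent_improvement(0.2, 0.1) == pytest.approx(100.0)

    def test_worked_arithmetic_example(self):
        assert fs.percent_improvement(0.15, 0.12, 0.02, 0.04) == pytest.approx(62.5)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            fs.percent_improvement(0.2, 0.1, 0.0, 0.1)


class TestBootstrap:
    def test_single_subject_ci_collapses(self):
        res = fs.bootstrap_improvement([5.0], n_boot=100, seed=0)
        assert res.ci_low == res.ci_high == res.mean == 5.0

    def test_identical_subjects_floor_p(self):
        res = fs.bootstrap_improvement([3.0] * 6, n_boot=1000, seed=0)
        assert res.mean == res.ci_low == res.ci_high == 3.0
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.significant

    def test_ci_brackets_mean_and_seed_reproducible(self, rng):
        vals = rng.standard_normal(12) + 1.0
        r1 = fs.bootstrap_improvement(vals, n_boot=2000, seed=42)
        r2 = fs.bootstrap_improvement(vals, n_boot=2000, seed=42)
        assert r1.ci_low <= r1.mean <= r1.ci_high
        assert (r1.ci_low, r1.ci_high, r1.p_value) == (r2.ci_low, r2.ci_high, r2.p_value)

    def test_ci_narrows_with_more_subjects(self, rng):
        widths = []
        for n in (4, 16, 64):
            w = []
            for seed in range(10):
                vals = rng.standard_normal(n)
                r = fs.bootstrap_improvement(vals, n_boot=500, seed=seed)
                w.append(r.ci_high - r.ci_low)
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]


class TestRollingNull:
    def test_independent_noise_chance_near_zero(self, small_mask, rng):
        data = rng.standard_normal((small_mask.n_voxels, 60))
        feats = fs.FeatureSeries(rng.standard_normal((6, 60)), label="noise")
        nmap = fs.anatomical_neighborhoods(small_mask, radius=1)
        null = fs.rolling_null_chance(
            data, feats, nmap, kernel="rsa", shift_unit=7, n_shifts=6,
            percent=100.0, buffer_trs=5,
        )
        assert null.chance == pytest.approx(np.mean(null.null_values))
        # average over all searchlights and shifts: correlation null, ~0
        n_pairs = fs.buffered_rsm(rng.standard_normal((3, 60)), 5).n_retained
        se = 1.0 / np.sqrt(n_pairs)
        assert abs(null.chance) < 3 * se

    def test_multiples_of_t_skipped(self, small_mask, rng):
        data = rng.standard_normal((small_mask.n_voxels, 20))
        feats = rng.standard_normal((4, 20))
        nmap = fs.anatomical_neighborhoods(small_mask, radius=1)
        null = fs.rolling_null_chance(
            data, feats, nmap, shift_unit=10, n_shifts=4, percent=50.0, buffer_trs=3
        )
        assert list(null.shifts) == [10, 30]
        with pytest.raises(ValueError):
            fs.rolling_null_chance(
                data, feats, nmap, shift_unit=20, n_shifts=2, percent=50.0, buffer_trs=3
            )


class TestContributionMap:
    def test_single_subject_single_top_searchlight(self):
        mmap = make_map([0.1, 0.9, 0.2])
        nmap = fs.NeighborhoodMap(
            centers=np.arange(3),
            members=(np.array([0, 1]), np.array([1, 2, 0]), np.array([2])),
            kind="anatomical",
        )
        counts = fs.contribution_map([mmap], [nmap], n_voxels=3, percent=1.0)
        np.testing.assert_array_equal(counts, [1, 1, 1])  # members of center 1

    def test_centers_mode_counts_centers_only(self):
        mmap = make_map([0.1, 0.9, 0.2])
        nmap = fs.NeighborhoodMap(
            centers=np.arange(3),
            members=(np.array([0, 1]), np.array([1, 2, 0]), np.array([2])),
            kind="anatomical",
        )
        counts = fs.contribution_map([mmap], [nmap], n_voxels=3, percent=1.0, mode="centers")
        np.testing.assert_array_equal(counts, [0, 1, 0])

    def test_disjoint_top_sets_max_one(self):
        m1, m2 = make_map([1.0, 0.0]), make_map([0.0, 1.0])
        nmap = fs.NeighborhoodMap(
            centers=np.arange(2), members=(np.array([0]), np.array([1])), kind="anatomical"
        )
        counts = fs.contribution_map([m1, m2], [nmap, nmap], n_voxels=2, percent=1.0)
        np.testing.assert_array_equal(counts, [1, 1])


class TestAnatomicalDistance:
    def test_two_voxels_three_apart(self):
        coords = np.array([[0, 0, 0], [3, 0, 0]])
        assert fs.median_anatomical_distance([0, 1], coords) == pytest.approx(3.0)

    def test_full_cube_matches_brute_force(self, cube_mask):
        nmap = fs.anatomical_neighborhoods(cube_mask, radius=3)
        grid = cube_mask.id_grid()
        center = grid[4, 4, 4]
        members = nmap.members[center]
        got = fs.median_anatomical_distance(members, cube_mask.voxels)
        pts = cube_mask.voxels[members]
        dists = [
            float(np.linalg.norm(pts[i] - pts[j]))
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        ]
        assert got == pytest.approx(np.median(dists))

    def test_random_subsets_approach_mask_ceiling(self, rng):
        mask = fs.solid_mask(12, 12, 12)
        all_ids = np.arange(mask.n_voxels)
        ceiling = fs.median_anatomical_distance(
            rng.choice(all_ids, 400, replace=False), mask.voxels
        )
        tight = fs.anatomical_neighborhoods(mask, radius=2)
        grid = mask.id_grid()
        local = fs.median_anatomical_distance(tight.members[grid[6, 6, 6]], mask.voxels)
        assert local < 0.5 * ceiling


class TestCompareSpaces:
    @staticmethod
    def make_coords(pts):
        return fs.FunctionalCoordinates(
            voxel_ids=np.arange(pts.shape[0]), coords=pts,
            dropped_ids=np.array([], dtype=np.intp),
        )

    def test_identical_spaces_correlate_perfectly(self, rng):
        pts = rng.standard_normal((80, 5))
        r, p = fs.compare_functional_spaces(
            self.make_coords(pts), self.make_coords(pts),
            n_pairs=300, n_samples=10, n_perm=99, seed=0,
        )
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_independent_spaces_near_zero(self, rng):
        a = self.make_coords(rng.standard_normal((150, 5)))
        b = self.make_coords(rng.standard_normal((150, 5)))
        r, p = fs.compare_functional_spaces(a, b, n_pairs=500, n_samples=20, n_perm=99, seed=1)
        assert abs(r) < 0.1
        assert p > 0.01
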