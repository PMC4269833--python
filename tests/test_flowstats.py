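"""Flow-field statistics: binning, v_c, intensity splits, rank-sum tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from chiralflow import (
    AxialProfile,
    BinScheme,
    VectorField2D,
    average_profiles,
    bin_velocity_profile,
    compare_conditions,
    counter_rotation_velocity,
    counter_rotation_velocity_4cell,
    half_intensity_difference,
)

SCHEME = BinScheme(ap_extent=(0.0, 50.0), y_center=15.0)


def grid_field(vy_fn, vx_fn=lambda x, y: 0.0 * x, frame=0):
    xs = np.arange(0.5, 50.0, 1.0)
    ys = np.arange(9.0, 21.5, 0.5)  # inside the stripe
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    vec = np.column_stack([vx_fn(X, Y).ravel(), vy_fn(X, Y).ravel()])
    return VectorField2D(frame, pts, vec, np.ones(len(pts), dtype=bool))


class TestBinVelocityProfile:
    def test_uniform_field_fills_every_bin(self):
        prof = bin_velocity_profile(grid_field(lambda x, y: np.ones_like(x)), SCHEME, "y")
        np.testing.assert_allclose(prof.values, 1.0)

    def test_piecewise_constant_halves(self):
        f = grid_field(lambda x, y: np.where(x < 25.0, 3.0, -1.0))
        prof = bin_velocity_profile(f, SCHEME, "y")
        np.testing.assert_allclose(prof.values[:9], 3.0)
        np.testing.assert_allclose(prof.values[9:], -1.0)

    def test_random_field_against_bruteforce_reaggregation(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform([0, 0], [50, 30], size=(4000, 2))
        vec = rng.normal(size=(4000, 2))
        mask = rng.uniform(size=4000) < 0.9
        field = VectorField2D(0, pts, vec, mask)
        prof = bin_velocity_profile(field, SCHEME, "x")
        edges = SCHEME.edges
        for b in range(18):
            sel = (
                mask
                & (np.abs(pts[:, 1] - 15.0) <= 6.5)
                & (pts[:, 0] >= edges[b])
                & (pts[:, 0] < edges[b + 1] if b < 17 else pts[:, 0] <= edges[b + 1])
            )
            if np.any(sel):
                assert prof.values[b] == pytest.approx(vec[sel, 0].mean(), rel=1e-12)
            else:
                assert math.isnan(prof.values[b])

    def test_points_outside_stripe_are_excluded(self):
        pts = np.array([[10.0, 15.0], [10.0, 28.0], [30.0, 15.0]])
        vec = np.array([[0.0, 1.0], [0.0, 99.0], [0.0, 2.0]])
        f = VectorField2D(0, pts, vec, np.ones(3, dtype=bool))
        prof = bin_velocity_profile(f, SCHEME, "y")
        assert prof.values[3] == 1.0  # the y=28 outlier did not contaminate
        assert prof.values[10] == 2.0


class TestAverageProfiles:
    def test_identical_frames_reproduce_frame_with_zero_sem(self, bins18):
        p = AxialProfile(bins18, np.linspace(0, 1, 18))
        stats_ = average_profiles([p, p, p, p], [0, 0, 1, 1])
        np.testing.assert_allclose(stats_.mean, p.values)
        np.testing.assert_allclose(stats_.sem, 0.0)

    def test_two_embryo_sem(self, bins18):
        p0 = AxialProfile(bins18, np.zeros(18))
        p2 = AxialProfile(bins18, np.full(18, 2.0))
        stats_ = average_profiles([p0, p2], [0, 1])
        np.testing.assert_allclose(stats_.mean, 1.0)
        np.testing.assert_allclose(stats_.sem, 1.0)

    def test_embryo_first_ordering_differs_from_pooled_on_unbalanced_counts(
        self, bins18
    ):
        """Embryo A contributes 3 frames of value 0, embryo B one frame of 3:
        embryo-first gives 1.5, pooled frame average would give 0.75."""
        pa = AxialProfile(bins18, np.zeros(18))
        pb = AxialProfile(bins18, np.full(18, 3.0))
        stats_ = average_profiles([pa, pa, pa, pb], [0, 0, 0, 1])
        np.testing.assert_allclose(stats_.mean, 1.5)

    def test_single_embryo_sem_missing(self, bins18):
        p = AxialProfile(bins18, np.ones(18))
        stats_ = average_profiles([p, p], [0, 0])
        assert np.all(np.isnan(stats_.sem))


class TestCounterRotation:
    def test_constructed_regional_offsets(self):
        """+1 um/min anterior, -2.5 posterior gives v_c = -3.5 exactly."""
        edges = SCHEME.edges

        def vy(x, y):
            out = np.zeros_like(x)
            out[(x >= edges[2]) & (x <= edges[6])] = 1.0
            out[(x >= edges[12]) & (x <= edges[16])] = -2.5
            return out

        assert counter_rotation_velocity(grid_field(vy), SCHEME) == pytest.approx(
            -3.5, abs=1e-12
        )

    def test_uniform_field_and_offset_invariance(self):
        f = grid_field(lambda x, y: np.full_like(x, 0.7))
        assert counter_rotation_velocity(f, SCHEME) == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(0)
        g = grid_field(lambda x, y: rng.normal(size=x.shape))
        vc = counter_rotation_velocity(g, SCHEME)
        shifted = VectorField2D(
            g.frame, g.points, g.vectors + np.array([0.0, 123.4]), g.mask
        )
        assert counter_rotation_velocity(shifted, SCHEME) == pytest.approx(
            vc, abs=1e-9
        )

    def test_mirror_reflection_flips_sign(self):
        rng = np.random.default_rng(1)
        g = grid_field(lambda x, y: rng.normal(size=x.shape))
        vc = counter_rotation_velocity(g, SCHEME)
        mirrored = VectorField2D(
            g.frame,
            np.column_stack([g.points[:, 0], 30.0 - g.points[:, 1]]),
            np.column_stack([g.vectors[:, 0], -g.vectors[:, 1]]),
            g.mask,
        )
        assert counter_rotation_velocity(mirrored, SCHEME) == pytest.approx(
            -vc, abs=1e-12
        )

    def test_scaling_commutes_with_binning(self):
        rng = np.random.default_rng(2)
        g = grid_field(lambda x, y: rng.normal(size=x.shape))
        vc = counter_rotation_velocity(g, SCHEME)
        doubled = VectorField2D(g.frame, g.points, 2.0 * g.vectors, g.mask)
        assert counter_rotation_velocity(doubled, SCHEME) == pytest.approx(2 * vc)


class TestCounterRotation4Cell:
    def plane(self):
        return (25.0, 15.0), (0.0, 1.0)  # vertical cleavage plane at x=25

    def test_antisymmetric_shear(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform([15, 0], [35, 30], size=(600, 2))
        s = 1.3
        v_par = np.where(pts[:, 0] < 25.0, s, -s)  # left of plane: +s
        vec = np.column_stack([np.zeros(600), v_par])
        f = VectorField2D(0, pts, vec, np.ones(600, dtype=bool))
        p0, d = self.plane()
        assert counter_rotation_velocity_4cell(f, p0, d) == pytest.approx(2 * s)

    def test_normal_only_field_gives_zero(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform([15, 0], [35, 30], size=(400, 2))
        vec = np.column_stack([rng.normal(size=400), np.zeros(400)])
        f = VectorField2D(0, pts, vec, np.ones(400, dtype=bool))
        p0, d = self.plane()
        assert counter_rotation_velocity_4cell(f, p0, d) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_rotational_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform([15, 0], [35, 30], size=(500, 2))
        vec = rng.normal(size=(500, 2))
        f = VectorField2D(0, pts, vec, np.ones(500, dtype=bool))
        p0, d = self.plane()
        vc = counter_rotation_velocity_4cell(f, p0, d)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        f_rot = VectorField2D(0, pts @ R.T, vec @ R.T, f.mask)
        vc_rot = counter_rotation_velocity_4cell(f_rot, R @ np.asarray(p0), R @ d)
        assert vc_rot == pytest.approx(vc, abs=1e-10)


class TestHalfIntensityDifference:
    def test_uniform_image_zero(self):
        img = np.full((20, 30), 4.2)
        mask = np.ones_like(img, dtype=bool)
        assert half_intensity_difference(img, mask) == pytest.approx(0.0)

    def test_posterior_minus_anterior_convention(self):
        img = np.ones((20, 30))
        img[:, 15:] = 2.0  # posterior (high column index) brighter
        mask = np.ones_like(img, dtype=bool)
        assert half_intensity_difference(img, mask, "AP-halves") == pytest.approx(1.0)

    def test_random_image_against_pixel_sums(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(size=(24, 40))
        mask = rng.uniform(size=img.shape) < 0.8
        delta = half_intensity_difference(img, mask, "top-bottom-posterior")
        rows, cols = np.nonzero(mask)
        x_mid = 0.5 * (cols.min() + cols.max())
        post = mask & (np.arange(img.shape[1])[None, :] > x_mid)
        prow, _ = np.nonzero(post)
        y_mid = 0.5 * (prow.min() + prow.max())
        top = post & (np.arange(img.shape[0])[:, None] < y_mid)
        bottom = post & (np.arange(img.shape[0])[:, None] >= y_mid)
        expected = img[top].mean() - img[bottom].mean()
        assert delta == pytest.approx(expected, rel=1e-12)


def exact_ranksum_pvalue(a, b):
    """Two-sided exact rank-sum p by full enumeration (no ties)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    observed = ranks[:n1].sum()
    sums = [
        sum(comb) for comb in itertools.combinations(ranks, n1)
    ]
    sums = np.asarray(sums)
    mean = sums.mean()
    p = np.mean(np.abs(sums - mean) >= abs(observed - mean) - 1e-12)
    return p


class TestCompareConditions:
    def test_identical_samples_not_significant(self):
        r = compare_conditions([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], 0.01)
        assert r.p_value == 1.0 and not r.significant

    def test_extreme_separation_significant(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 0.1, 50)
        b = rng.normal(10.0, 0.1, 50)
        r = compare_conditions(a, b, 0.01)
        assert r.significant and r.p_value < 1e-6

    def test_moderate_case_matches_exact_enumeration(self):
        a = np.array([-2.1, -3.0, -2.6, -1.4, -2.9, -3.3])
        b = np.array([-1.1, -2.2, -0.4, -1.9, -2.4, -0.8, -1.6])
        r = compare_conditions(a, b, 0.05)
        assert r.p_value == pytest.approx(exact_ranksum_pvalue(a, b), abs=1e-6)

    def test_confidence_halfwidths_use_matching_z(self):
        a = np.array([0.0, 1.0, 2.0, 3.0])
        r99 = compare_conditions(a, a + 0.1, 0.01)
        r95 = compare_conditions(a, a + 0.1, 0.05)
        sem = np.std(a, ddof=1) / 2.0
        assert r99.ci_halfwidth_a == pytest.approx(2.5758 * sem, rel=1e-3)
        assert r95.ci_halfwidth_a == pytest.approx(1.9600 * sem, rel=1e-3)
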