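import math

import numpy as np
import pytest

from sarscan import metrics as met
from sarscan.simulator import FWHM_FACTOR, applicator_preset

from conftest import gaussian_plane_grid


def scattered_gaussian(spacing, sigma_x=8.0, sigma_y=5.0, centre=(0.0, 0.0),
                       half=(16.0, 12.0)):
    u = np.arange(-half[0], half[0] + 1e-9, spacing)
    v = np.arange(-half[1], half[1] + 1e-9, spacing)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pts = np.column_stack([uu.ravel(), vv.ravel()])
    vals = 100.0 * np.exp(
        -((pts[:, 0] - centre[0]) ** 2) / (2 * sigma_x**2)
        - ((pts[:, 1] - centre[1]) ** 2) / (2 * sigma_y**2)
    )
    return pts, vals


class TestInterpolatePlane:
    def test_constant_square_gives_constant_grid(self):
        pts = np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]])
        grid = met.interpolate_plane(pts, np.full(4, 100.0))
        assert np.allclose(grid.values[grid.unmasked], 100.0)

    def test_linear_function_reproduced(self):
        pts, _ = scattered_gaussian(1.0, half=(4.0, 4.0))
        vals = pts[:, 0] + pts[:, 1]
        grid = met.interpolate_plane(pts, vals)
        uu, vv = np.meshgrid(grid.u, grid.v, indexing="ij")
        assert np.allclose(grid.values[grid.unmasked], (uu + vv)[grid.unmasked],
                           atol=1e-9)

    def test_measurement_points_reproduced_exactly(self):
        pts, vals = scattered_gaussian(1.0)
        got = met.linear_interpolate(pts, vals, pts)
        assert np.allclose(got, vals, atol=1e-9)

    def test_outside_hull_masked(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        grid = met.interpolate_plane(pts, np.array([1.0, 1.0, 1.0]))
        assert grid.mask.any() and grid.unmasked.any()

    def test_collinear_cloud_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError):
            met.interpolate_plane(pts, np.ones(4))

    def test_refinement_changes_little_for_smooth_field(self):
        coarse_pts, coarse_vals = scattered_gaussian(1.0)
        fine_pts, fine_vals = scattered_gaussian(0.25)
        g1 = met.interpolate_plane(coarse_pts, coarse_vals)
        g2 = met.interpolate_plane(fine_pts, fine_vals)
        both = g1.unmasked & g2.unmasked
        rms = np.sqrt(np.mean((g1.values[both] - g2.values[both]) ** 2))
        assert rms < 1.5


class TestResamplePlane:
    def test_identity_at_equal_spacing(self):
        pts, vals = scattered_gaussian(1.0)
        sub_pts, sub_vals = met.resample_plane(pts, vals, 1.0, 1.0)
        assert np.array_equal(sub_pts, pts)

    def test_quarter_to_one_cm_point_count(self):
        pts, vals = scattered_gaussian(0.25)
        assert len(pts) == 129 * 97
        sub_pts, _ = met.resample_plane(pts, vals, 0.25, 1.0)
        assert len(sub_pts) == 33 * 25 == 825

    def test_subset_composition(self):
        pts, vals = scattered_gaussian(0.25)
        one_p, one_v = met.resample_plane(pts, vals, 0.25, 1.0)
        via = met.resample_plane(one_p, one_v, 1.0, 2.0)[0]
        direct = met.resample_plane(pts, vals, 0.25, 2.0)[0]
        assert np.array_equal(
            via[np.lexsort(via.T)], direct[np.lexsort(direct.T)]
        )

    def test_non_commensurate_rejected(self):
        pts, vals = scattered_gaussian(1.0)
        with pytest.raises(ValueError):
            met.resample_plane(pts, vals, 1.0, 1.5)


class TestIsolines:
    def test_cone_half_height_contour_is_circle(self):
        grid = gaussian_plane_grid(1.0, 1.0)  # replaced below by a cone
        uu, vv = np.meshgrid(grid.u, grid.v, indexing="ij")
        r = np.hypot(uu, vv)
        grid.values = np.clip(100.0 * (1.0 - r / 10.0), 0.0, None)
        iso = met.extract_isolines(grid, levels=(50.0,))
        for poly in iso.contours[50.0]:
            radii = np.hypot(poly[:, 0], poly[:, 1])
            assert np.all(np.abs(radii - 5.0) < 0.1)

    def test_nesting_of_levels(self):
        grid = gaussian_plane_grid(8.0, 5.0)
        iso = met.extract_isolines(grid)
        region = {
            lv: (grid.values >= lv) & grid.unmasked for lv in iso.levels
        }
        for lo, hi in zip(iso.levels, iso.levels[1:]):
            assert not (region[hi] & ~region[lo]).any()
        assert len(iso.contours[98.0]) > 0

    def test_level_above_maximum_yields_empty_set(self):
        grid = gaussian_plane_grid(8.0, 5.0)
        grid.values *= 0.9
        iso = met.extract_isolines(grid, levels=(98.0,))
        assert iso.contours[98.0] == []
        assert iso.component_counts[98.0] == 0

    def test_contour_and_region_extents_agree(self):
        grid = gaussian_plane_grid(8.88, 5.31)
        iso = met.extract_isolines(grid, levels=(50.0,))
        poly = np.vstack(iso.contours[50.0])
        efs = met.compute_efs(grid)
        assert poly[:, 0].max() - poly[:, 0].min() == pytest.approx(
            efs.efs_x, abs=0.1
        )
        assert poly[:, 1].max() - poly[:, 1].min() == pytest.approx(
            efs.efs_y, abs=0.1
        )


class TestEFS:
    def test_gaussian_closed_form(self):
        grid = gaussian_plane_grid(8.88, 5.31)
        efs = met.compute_efs(grid)
        assert efs.efs_x == pytest.approx(2 * 8.88 * math.sqrt(2 * math.log(2)),
                                          abs=0.1)
        assert efs.efs_y == pytest.approx(2 * 5.31 * math.sqrt(2 * math.log(2)),
                                          abs=0.1)
        assert abs(efs.dx) < 0.1 and abs(efs.dy) < 0.1

    @pytest.mark.parametrize("sigma", [2.0, 5.0, 9.0, 12.0])
    def test_fwhm_relation_across_widths(self, sigma):
        grid = gaussian_plane_grid(sigma, sigma, half=(40.0, 40.0))
        efs = met.compute_efs(grid)
        assert efs.efs_x == pytest.approx(FWHM_FACTOR * sigma, abs=0.1)

    def test_translation_moves_centre_not_size(self):
        base = met.compute_efs(gaussian_plane_grid(8.88, 5.31))
        shifted = met.compute_efs(
            gaussian_plane_grid(8.88, 5.31, centre=(0.8, -0.9))
        )
        assert shifted.dx == pytest.approx(0.8, abs=0.05)
        assert shifted.dy == pytest.approx(-0.9, abs=0.05)
        assert shifted.efs_x == pytest.approx(base.efs_x, abs=0.1)
        assert shifted.efs_y == pytest.approx(base.efs_y, abs=0.1)

    def test_scaling_invariance(self):
        grid = gaussian_plane_grid(8.88, 5.31)
        a = met.compute_efs(grid)
        grid.values = grid.values * 2.0  # e.g. renormalised to a different anchor
        b = met.compute_efs(grid, level=100.0)
        assert b.efs_x == pytest.approx(a.efs_x, abs=1e-9)

    def test_uniform_disk(self):
        grid = gaussian_plane_grid(1.0, 1.0)
        uu, vv = np.meshgrid(grid.u, grid.v, indexing="ij")
        grid.values = np.where(np.hypot(uu, vv) <= 5.0, 100.0, 0.0)
        efs = met.compute_efs(grid)
        assert efs.efs_x == pytest.approx(10.0, abs=0.1)
        assert efs.efs_y == pytest.approx(10.0, abs=0.1)
        assert efs.area_cm2 == pytest.approx(math.pi * 25.0, rel=0.01)

    def test_truncated_region_warns(self):
        grid = gaussian_plane_grid(8.88, 5.31, half=(6.0, 6.0))
        with pytest.warns(met.TruncationWarning):
            met.compute_efs(grid)


def depth_plane_grid(profile, half_u=12.0, sigma=8.0, d_max=6.0):
    """0.1 cm (u, depth) grid with values 100*gauss(u)*profile(depth)."""
    u = np.round(np.arange(-half_u, half_u + 1e-9, met.GRID_SPACING), 10)
    d = np.round(np.arange(1.0, d_max + 1e-9, met.GRID_SPACING), 10)
    uu, dd = np.meshgrid(u, d, indexing="ij")
    vals = 100.0 * np.exp(-(uu**2) / (2 * sigma**2)) * profile(dd)
    return met.RelativeSARGrid(
        u=u, v=d, values=vals, mask=np.zeros_like(vals, dtype=bool),
        axis_names=("u", "depth"),
    )


class TestEPD:
    def test_exponential_closed_form(self):
        grid = depth_plane_grid(lambda d: 2.0 ** (-(d - 1.0) / 1.5))
        epd = met.compute_epd_from_plane(grid)
        assert not epd.censored
        assert epd.value == pytest.approx(1.5, abs=0.01)
        assert epd.from_interface == pytest.approx(2.5, abs=0.01)

    @pytest.mark.parametrize("delta", [3.0, 6.0, 9.0, 12.0])
    def test_power_decay_closed_form_across_scales(self, delta):
        grid = depth_plane_grid(
            lambda d: np.exp(-2.0 * (d - 1.0) / delta), d_max=7.0
        )
        epd = met.compute_epd_from_plane(grid)
        if delta * math.log(2) / 2 <= 6.0:
            assert epd.value == pytest.approx(delta * math.log(2) / 2, abs=0.05)
        else:
            assert epd.censored

    def test_increasing_column_censored(self):
        grid = depth_plane_grid(lambda d: 1.0 + 0.1 * (d - 1.0))
        epd = met.compute_epd_from_plane(grid)
        assert epd.censored

    def test_max_position_tie_breaks_toward_origin(self):
        grid = depth_plane_grid(lambda d: 2.0 ** (-(d - 1.0) / 1.5))
        grid.values[:, 0] = 100.0  # flat reference row: every column ties
        epd = met.compute_epd_from_plane(grid)
        assert epd.column == (0.0,)

    def test_shallow_plane_rejected(self):
        grid = depth_plane_grid(lambda d: np.exp(-(d - 1.0)), d_max=3.0)
        with pytest.raises(ValueError):
            met.compute_epd_from_plane(grid)


def column_epd_oracle(depths, vals):
    """Brute-force first-halving scan, independent of the implementation."""
    target = 0.5 * vals[0]
    for k in range(1, len(vals)):
        if vals[k] < target <= vals[k - 1]:
            f = (vals[k - 1] - target) / (vals[k - 1] - vals[k])
            return depths[k - 1] + f * (depths[k] - depths[k - 1]) - depths[0]
    return None


class TestDeltaEPD:
    def build_volume(self, model):
        u = np.arange(-16.0, 16.0 + 1e-9, 1.0)
        v = np.arange(-12.0, 12.0 + 1e-9, 1.0)
        d = np.arange(1.0, 6.0 + 1e-9, 1.0)
        uu, vv, dd = np.meshgrid(u, v, d, indexing="ij")
        vals = model.relative_sar(uu, vv, dd)
        vals = 100.0 * vals / vals[:, :, 0].max()
        return met.SARVolume(u=u, v=v, depth=d, values=vals)

    def test_separable_field_has_zero_delta_everywhere(self):
        vol = self.build_volume(applicator_preset("5H", kappa=0.0))
        dm = met.compute_delta_epd(vol)
        finite = ~np.isnan(dm.delta_pct)
        assert np.allclose(dm.delta_pct[finite], 0.0, atol=1e-9)
        assert dm.region[finite].all()
        assert dm.crosses_u0 and dm.crosses_v0

    def test_matches_brute_force_per_column(self):
        vol = self.build_volume(applicator_preset("5H"))
        dm = met.compute_delta_epd(vol)
        for i in range(vol.u.size):
            for j in range(vol.v.size):
                want = column_epd_oracle(vol.depth, vol.values[i, j, :])
                if want is None:
                    assert np.isnan(dm.epd[i, j])
                else:
                    assert dm.epd[i, j] == want

    def test_delta_is_zero_at_max_sar_cell(self):
        vol = self.build_volume(applicator_preset("5H"))
        dm = met.compute_delta_epd(vol)
        i = np.argmin(np.abs(vol.u - dm.max_sar_uv[0]))
        j = np.argmin(np.abs(vol.v - dm.max_sar_uv[1]))
        assert dm.delta_pct[i, j] == 0.0

    def test_too_shallow_volume_rejected(self):
        m = applicator_preset("5H", delta=30.0)  # halves only beyond 6 cm
        with pytest.raises(met.VolumeTooShallowError):
            met.compute_delta_epd(self.build_volume(m))


class TestThresholdArithmetic:
    def test_five_percent_of_epd(self):
        assert met.epd_difference_at_threshold(2.6, 5.0) == pytest.approx(0.13)

    def test_requires_positive_epd(self):
        with pytest.raises(ValueError):
            met.epd_difference_at_threshold(0.0)
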