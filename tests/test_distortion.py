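"""Grid-target calibration: corners -> homography -> spline -> LUT."""

import numpy as np
import pytest
from scipy import ndimage

from braintile.distortion import (CalibrationError, CornerLattice,
                                  DeformationModel, Homography,
                                  apply_correction, build_correction_lut,
                                  build_template_lattice, calibrate_from_grid,
                                  detect_grid_corners, fit_homography,
                                  fit_residual_spline)
from braintile.fixtures import (PhantomSpec, SyntheticWarp,
                                generate_grid_image,
                                generate_phantom_section, warp_image)


def _match_error(detected: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Distance of each detected point to its nearest true point."""
    t = truth.reshape(-1, 2)
    return np.array([np.hypot(t[:, 0] - p[0], t[:, 1] - p[1]).min()
                     for p in detected.reshape(-1, 2)])


class TestDetectGridCorners:
    def test_unwarped_grid_interior_lattice(self):
        grid, _ = generate_grid_image(20, 4, (200, 200))
        lat = detect_grid_corners(grid, 20)
        # interior nodes of complete cells: (1..9)x(1..9) times the pitch
        assert lat.points.shape == (9, 9, 2)
        ii, jj = np.mgrid[1:10, 1:10]
        truth = np.stack([ii * 20.0, jj * 20.0], axis=-1)
        assert np.abs(lat.points - truth).max() <= 0.5

    def test_partial_border_cells_excluded(self):
        # shift the pattern so the top row of cells is cut in half
        grid, _ = generate_grid_image(40, 8, (420, 440))
        full = detect_grid_corners(grid, 40)
        cropped = detect_grid_corners(grid[20:, :], 40)
        assert cropped.n_rows == full.n_rows - 1
        assert cropped.n_cols == full.n_cols

    def test_warped_grid_corners_within_1px_rms_of_truth(self):
        w = SyntheticWarp(amplitude_px=3, smoothness_scale_px=60, seed=3)
        grid, truth = generate_grid_image(40, 8, (400, 400), warp=w)
        lat = detect_grid_corners(grid, 40)
        err = _match_error(lat.points, truth)
        assert np.sqrt((err ** 2).mean()) <= 1.0

    def test_too_few_cells_is_calibration_error(self):
        grid, _ = generate_grid_image(60, 10, (100, 100))  # ~1 complete cell
        with pytest.raises(CalibrationError):
            detect_grid_corners(grid, 60)


class TestTemplateLattice:
    def test_arithmetic_lattice(self):
        lat = build_template_lattice(3, 3, 10.0, origin=(0.0, 0.0))
        assert lat.source == "template"
        np.testing.assert_array_equal(lat.points[..., 0],
                                      [[0, 0, 0], [10, 10, 10], [20, 20, 20]])
        np.testing.assert_array_equal(lat.points[..., 1],
                                      [[0, 10, 20]] * 3)

    def test_spacing_exactly_pitch(self):
        lat = build_template_lattice(5, 7, 13.5, origin=(2.0, -1.0))
        np.testing.assert_array_equal(np.diff(lat.points[:, 0, 0]), 13.5)
        np.testing.assert_array_equal(np.diff(lat.points[0, :, 1]), 13.5)

    def test_template_matches_detected_shape(self):
        grid, _ = generate_grid_image(20, 4, (200, 200))
        det = detect_grid_corners(grid, 20)
        tmpl = build_template_lattice(det.n_rows, det.n_cols, 20)
        assert (tmpl.n_rows, tmpl.n_cols) == (det.n_rows, det.n_cols)


class TestHomography:
    def _lattice(self, pts):
        return CornerLattice(points=pts, source="template")

    def test_identity(self):
        lat = build_template_lattice(4, 4, 10)
        h = fit_homography(lat, lat)
        np.testing.assert_allclose(h.matrix, np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        src = build_template_lattice(4, 4, 10)
        dst = self._lattice(src.points + np.array([5.0, -3.0]))
        h = fit_homography(src, dst)
        expected = np.array([[1, 0, 5], [0, 1, -3], [0, 0, 1]], float)
        np.testing.assert_allclose(h.matrix, expected, atol=1e-9)

    def test_recovers_random_projective_map(self):
        rng = np.random.default_rng(12)
        true = np.eye(3) + rng.uniform(-0.05, 0.05, (3, 3))
        true[2, 2] = 1.0
        true_h = Homography(true)
        src = build_template_lattice(5, 5, 25, origin=(10, 10))
        dst = self._lattice(true_h.apply(src.points))
        fit = fit_homography(src, dst)
        np.testing.assert_allclose(fit.matrix, true_h.matrix, rtol=0, atol=1e-6)
        resid = np.abs(fit.apply(src.points) - dst.points).max()
        assert resid <= 1e-6

    def test_collinear_points_rejected(self):
        pts = np.zeros((2, 3, 2))
        pts[..., 1] = [[0, 1, 2], [3, 4, 5]]  # all on the line y=0
        with pytest.raises(ValueError):
            fit_homography(self._lattice(pts), self._lattice(pts + 1))


class TestResidualSpline:
    def test_zero_displacement_gives_zero_field(self):
        tmpl = build_template_lattice(5, 5, 20)
        field = fit_residual_spline(tmpl, tmpl)
        yy, xx = np.mgrid[0:80:7j, 0:80:7j]
        dy, dx = field.evaluate(yy.ravel(), xx.ravel())
        assert np.abs(dy).max() <= 1e-12 and np.abs(dx).max() <= 1e-12

    def test_exact_interpolation_at_nodes(self):
        rng = np.random.default_rng(3)
        tmpl = build_template_lattice(6, 5, 30)
        proj = CornerLattice(points=tmpl.points
                             + rng.uniform(-2, 2, tmpl.points.shape),
                             source="detected")
        field = fit_residual_spline(proj, tmpl)
        nodes = tmpl.flat()
        dy, dx = field.evaluate(nodes[:, 0], nodes[:, 1])
        d_true = (tmpl.points - proj.points).reshape(-1, 2)
        np.testing.assert_allclose(dy, d_true[:, 0], atol=1e-9)
        np.testing.assert_allclose(dx, d_true[:, 1], atol=1e-9)

    def test_midcell_accuracy_for_smooth_warp(self):
        # nodes every 40 px, warp amplitude 3 px: spline mid-cell error small
        w = SyntheticWarp(amplitude_px=3, smoothness_scale_px=80, seed=9)
        shape = (360, 360)
        dy_f, dx_f = w.displacement(shape)
        tmpl = build_template_lattice(9, 9, 40)
        nodes = tmpl.points.astype(int)
        proj_pts = tmpl.points - np.stack(
            [dy_f[nodes[..., 0], nodes[..., 1]],
             dx_f[nodes[..., 0], nodes[..., 1]]], axis=-1)
        field = fit_residual_spline(
            CornerLattice(points=proj_pts, source="detected"), tmpl)
        # mid-cell sample points
        yy, xx = np.mgrid[20:320:40, 20:320:40]
        dy, dx = field.evaluate(yy.ravel().astype(float),
                                xx.ravel().astype(float))
        true_dy = dy_f[yy.ravel(), xx.ravel()]
        true_dx = dx_f[yy.ravel(), xx.ravel()]
        assert np.abs(dy - true_dy).max() <= 0.25
        assert np.abs(dx - true_dx).max() <= 0.25


class TestCorrectionLut:
    def test_identity_lut_is_exact(self):
        model = build_correction_lut(Homography(np.eye(3)), None, (32, 40))
        yy, xx = np.mgrid[0:32, 0:40]
        np.testing.assert_array_equal(model.dense_lut[0], yy)
        np.testing.assert_array_equal(model.dense_lut[1], xx)

    def test_save_load_bit_exact(self, tmp_path):
        w = SyntheticWarp(amplitude_px=2, smoothness_scale_px=50, seed=5)
        grid, _ = generate_grid_image(40, 8, (320, 320), warp=w)
        model = calibrate_from_grid(grid, 40)
        model.save(tmp_path / "model.npz")
        back = DeformationModel.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.dense_lut, model.dense_lut)
        assert back.metadata["grid_pitch_px"] == 40
        # reuse: identical output on an arbitrary tile
        tile = generate_phantom_section(
            PhantomSpec(height_px=320, width_px=320, seed=6))
        np.testing.assert_array_equal(apply_correction(tile, back),
                                      apply_correction(tile, model))

    def test_calibration_corner_rms_within_half_pixel(self):
        w = SyntheticWarp(amplitude_px=5, smoothness_scale_px=70, seed=13)
        grid, _ = generate_grid_image(40, 8, (400, 400), warp=w)
        model = calibrate_from_grid(grid, 40)
        assert model.metadata["corner_rms_px"] <= 0.5


class TestApplyCorrection:
    def test_identity_model_is_noop(self):
        tile = np.random.default_rng(0).integers(0, 65535, (64, 64)).astype(
            np.uint16)
        model = DeformationModel.identity((64, 64))
        np.testing.assert_array_equal(apply_correction(tile, model), tile)

    def test_constant_tile_stays_constant(self):
        w = SyntheticWarp(amplitude_px=2, smoothness_scale_px=40, seed=1)
        grid, _ = generate_grid_image(40, 8, (320, 320), warp=w)
        model = calibrate_from_grid(grid, 40)
        out = apply_correction(np.full((320, 320), 42.0), model)
        np.testing.assert_allclose(out, 42.0)

    def test_shape_mismatch_rejected(self):
        model = DeformationModel.identity((32, 32))
        with pytest.raises(ValueError):
            apply_correction(np.zeros((16, 16)), model)

    def test_inverse_recovery_of_warped_phantom(self):
        """Calibrating on the warp's grid image undoes the warp on a phantom
        to within 1% mean error over the interior."""
        w = SyntheticWarp(amplitude_px=3, smoothness_scale_px=60, seed=3)
        grid, _ = generate_grid_image(40, 8, (400, 400), warp=w)
        model = calibrate_from_grid(grid, 40)
        phantom = ndimage.gaussian_filter(generate_phantom_section(
            PhantomSpec(height_px=400, width_px=400, cell_density=60,
                        cell_radius_px=10, noise_sd=0, seed=5)).astype(float), 2)
        corrected = apply_correction(warp_image(phantom, w), model)
        interior = (slice(5, -5), slice(5, -5))
        mean_err = np.abs(corrected[interior] - phantom[interior]).mean()
        dyn = phantom.max() - phantom.min()
        assert mean_err <= 0.01 * dyn
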