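"""Box extraction, 2D collapse, constrained alignment and measurements."""

import numpy as np
import pandas as pd
import pytest

from mcsquant import collapse
from mcsquant.collapse import (
    BoxStack,
    DensityVolume,
    align_and_classify,
    collapse_stack,
    collapse_to_2d,
    extract_boxes_along_path,
    extract_particle_boxes,
    fit_path_spline,
    layer_thickness,
    rod_length,
)
from mcsquant.synthetic import RodSpec, VolumeTruth, gen_contact_volume, gen_particle_picks


def make_stack(images, pixel_nm=1.0, priors=None):
    images = np.asarray(images, dtype=float)
    priors = np.zeros(len(images)) if priors is None else np.asarray(priors, float)
    return BoxStack(
        data=images,
        pixel_nm=pixel_nm,
        priors_deg=priors,
        source=pd.DataFrame({"item": np.arange(len(images))}),
    )


class TestPathSpline:
    def test_collinear_points_straight_line(self):
        pts = np.column_stack([np.arange(0.0, 80.0, 8.0), np.zeros(10), np.zeros(10)])
        sp = fit_path_spline(pts)
        s = np.linspace(0, sp.length_nm, 25)
        tangents = sp.tangent(s)
        np.testing.assert_allclose(tangents, np.tile([1.0, 0, 0], (25, 1)), atol=1e-6)
        assert sp.length_nm == pytest.approx(72.0, rel=1e-3)

    def test_circle_tangents_match_analytic(self):
        ang = np.linspace(0, np.pi, 30)
        pts = np.column_stack([50 * np.cos(ang), 50 * np.sin(ang), np.zeros_like(ang)])
        sp = fit_path_spline(pts)
        s_mid = np.linspace(0.1 * sp.length_nm, 0.9 * sp.length_nm, 15)
        tangents = sp.tangent(s_mid)
        pos = sp.point(s_mid)
        analytic = np.column_stack([-pos[:, 1], pos[:, 0], np.zeros(len(pos))])
        analytic /= np.linalg.norm(analytic, axis=1, keepdims=True)
        dots = np.abs(np.sum(tangents * analytic, axis=1))
        assert np.degrees(np.arccos(np.clip(dots, -1, 1))).max() < 2.0

    def test_residuals_below_1nm(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack(
            [np.arange(0.0, 120.0, 8.0), rng.normal(0, 0.5, 15), np.zeros(15)]
        )
        sp = fit_path_spline(pts)
        assert sp.residual_nm <= 1.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_path_spline(np.zeros((2, 3)))


class TestExtractBoxes:
    def test_box_count_straight_path(self):
        """Straight path of length 10*box with step box/2 yields 19 boxes."""
        box, step = 10, 5
        n = 120
        vol = DensityVolume(np.ones((20, 20, n)), voxel_nm=1.0)
        pts = np.column_stack(
            [np.linspace(0, 100, 14), np.full(14, 10.0), np.full(14, 10.0)]
        )
        sp = fit_path_spline(pts)
        stack = extract_boxes_along_path(vol, sp, box_px=box, step_px=step)
        assert len(stack) == 19

    def test_priors_equal_along_straight_path(self):
        vol = DensityVolume(np.ones((20, 20, 60)), voxel_nm=1.0)
        pts = np.column_stack([np.linspace(2, 58, 8), np.full(8, 10.0), np.full(8, 10.0)])
        stack = extract_boxes_along_path(vol, fit_path_spline(pts), box_px=10, step_px=5)
        assert np.all(stack.priors_deg == stack.priors_deg[0])
        assert np.allclose(stack.source["tangent_deg"], stack.source["tangent_deg"][0])

    def test_constant_volume_identical_boxes(self):
        vol = DensityVolume(np.full((20, 20, 60), 3.25), voxel_nm=1.0)
        pts = np.column_stack([np.linspace(2, 58, 8), np.full(8, 10.0), np.full(8, 10.0)])
        stack = extract_boxes_along_path(vol, fit_path_spline(pts), box_px=10, step_px=5)
        np.testing.assert_allclose(stack.data, 3.25, atol=1e-9)

    def test_short_spline_rejected(self):
        vol = DensityVolume(np.ones((20, 20, 20)), voxel_nm=1.0)
        pts = np.column_stack([np.linspace(0, 5, 4), np.full(4, 10.0), np.full(4, 10.0)])
        with pytest.raises(ValueError, match="shorter"):
            extract_boxes_along_path(vol, fit_path_spline(pts), box_px=10, step_px=5)

    def test_overlap_required(self):
        vol = DensityVolume(np.ones((20, 20, 60)), voxel_nm=1.0)
        pts = np.column_stack([np.linspace(2, 58, 8), np.full(8, 10.0), np.full(8, 10.0)])
        with pytest.raises(ValueError, match="overlap"):
            extract_boxes_along_path(vol, fit_path_spline(pts), box_px=10, step_px=10)


class TestExtractParticleBoxes:
    def test_box_px_from_angstrom(self):
        vol = DensityVolume(np.zeros((130, 130, 130)), voxel_nm=0.37)
        picks = gen_particle_picks(
            {
                "rods": pd.DataFrame(
                    [
                        {"rod_id": 0, "x_nm": 24.0, "y_nm": 24.0, "tilt_deg": 0.0,
                         "azimuth_deg": 0.0, "length_nm": 10.0,
                         "ax_nm": 24.0, "ay_nm": 24.0, "az_nm": 29.0,
                         "bx_nm": 24.0, "by_nm": 24.0, "bz_nm": 19.0}
                    ]
                )
            }
        )
        stack = extract_particle_boxes(vol, picks)
        assert stack.data.shape[1:] == (120, 120, 120)  # 444 A / 3.7 A

    def test_corner_pick_dropped(self):
        vol = DensityVolume(np.zeros((40, 40, 40)), voxel_nm=1.0)
        rows = []
        for i, x in enumerate((20.0, 2.0)):  # second pick is at the volume corner
            rows.append(
                {"rod_id": i, "x_nm": x, "y_nm": 20.0, "tilt_deg": 0.0,
                 "azimuth_deg": 0.0, "length_nm": 10.0,
                 "ax_nm": x, "ay_nm": 20.0, "az_nm": 25.0,
                 "bx_nm": x, "by_nm": 20.0, "bz_nm": 15.0}
            )
        picks = gen_particle_picks({"rods": pd.DataFrame(rows)})
        stack = extract_particle_boxes(vol, picks, box_A=200.0)
        assert len(stack) == 1

    def test_perpendicular_rod_vertical_in_collapsed_image(self):
        rods = [RodSpec(x_nm=22.0, y_nm=22.0, tilt_deg=0.0)]
        truth = VolumeTruth(voxel_nm=0.74, pm_z_nm=15.0, er_z_nm=37.0, rods=rods)
        vol, tables = gen_contact_volume(truth, (70, 60, 60), seed=0)
        picks = gen_particle_picks(tables)
        stack = collapse_stack(extract_particle_boxes(vol, picks, box_A=300.0))
        img = stack.data[0]
        # between the membranes the rod contributes one bright column band;
        # its column center of mass must sit at the box center, every row
        rows = img.shape[0]
        inner = img[rows // 2 - 5 : rows // 2 + 5]
        cols = np.arange(img.shape[1])
        com = (inner * cols).sum(axis=1) / inner.sum(axis=1)
        np.testing.assert_allclose(com, (img.shape[1] - 1) / 2.0, atol=0.5)


class TestCollapse:
    def test_constant_volume_projection(self):
        sub = np.full((7, 5, 5), 2.0)
        img = collapse_to_2d(sub)
        np.testing.assert_allclose(img, 14.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 6, 5, 5))
        np.testing.assert_allclose(
            collapse_to_2d(a + b), collapse_to_2d(a) + collapse_to_2d(b), atol=1e-12
        )

    def test_intensity_conserved(self):
        rng = np.random.default_rng(1)
        sub = rng.normal(size=(8, 9, 10))
        assert collapse_to_2d(sub).sum() == pytest.approx(sub.sum())

    def test_membrane_volume_projection_matches_analytic(self, small_membrane_volume):
        truth, volume, tables = small_membrane_volume
        depth = volume.shape[1]
        sub = volume.voxels.transpose(1, 0, 2)  # project along y
        img = collapse_to_2d(sub)
        zc = np.arange(volume.shape[0]) * truth.voxel_nm
        centers = [11.0, 15.0, 37.0, 41.0]
        analytic = depth * sum(
            np.exp(-((zc - c) ** 2) / 2.0) for c in centers
        )
        np.testing.assert_allclose(img[:, 0], analytic, atol=1e-6)


class TestAlignAndClassify:
    def test_identical_images_k1_self_alignment(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(24, 24))
        stack = make_stack([base] * 8)
        res = align_and_classify(stack, k=1, max_shift_px=3, lowpass_nm=None, seed=0)
        assert np.all(res.assignments["dy_px"] == 0)
        assert np.all(res.assignments["dx_px"] == 0)
        assert np.all(res.assignments["rotation_deg"] == 0.0)
        np.testing.assert_allclose(res.class_averages[0], base, atol=1e-9)

    def test_two_separable_populations_pure_classes(self):
        rng = np.random.default_rng(1)
        a = np.zeros((20, 20))
        a[8:12, :] = 1.0  # horizontal bar
        b = np.zeros((20, 20))
        b[:, 8:12] = 1.0  # vertical bar
        images = [a] * 6 + [b] * 6
        stack = make_stack(images)
        res = align_and_classify(stack, k=2, max_shift_px=1, lowpass_nm=None, seed=3)
        labels = res.assignments["class_id"].to_numpy()
        first, second = labels[:6], labels[6:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]
        np.testing.assert_allclose(sorted(res.fractions), [0.5, 0.5])

    def test_noise_averaging_law(self):
        """Averaging n noisy copies reduces background SD ~ sigma/sqrt(n)."""
        rng = np.random.default_rng(2)
        base = np.zeros((32, 32))
        base[12:20, 14:18] = 5.0
        sigma, n = 1.0, 64
        images = base + rng.normal(0, sigma, (n, 32, 32))
        stack = make_stack(list(images))
        res = align_and_classify(
            stack, k=1, rot_window_deg=0.0, max_shift_px=0, lowpass_nm=None, seed=0
        )
        bg = res.class_averages[0][:8, :8]
        assert np.std(bg) == pytest.approx(sigma / np.sqrt(n), rel=0.2)

    def test_rotation_never_leaves_prior_window(self):
        rng = np.random.default_rng(3)
        images = rng.normal(size=(10, 16, 16))
        priors = rng.uniform(-30, 30, 10)
        stack = make_stack(list(images), priors=priors)
        res = align_and_classify(stack, k=2, rot_window_deg=10.0, max_shift_px=1, seed=1)
        devs = np.abs(res.assignments["rotation_deg"].to_numpy() - priors)
        assert devs.max() <= 10.0 + 1e-9

    def test_shuffle_equivariance_of_averages(self):
        rng = np.random.default_rng(4)
        a = np.zeros((16, 16)); a[6:10, :] = 1.0
        b = np.zeros((16, 16)); b[:, 6:10] = 1.0
        images = np.array([a, b] * 5) + rng.normal(0, 0.01, (10, 16, 16))
        stack = make_stack(list(images))
        res1 = align_and_classify(stack, k=2, max_shift_px=0, lowpass_nm=None, seed=7)
        perm = rng.permutation(10)
        stack2 = make_stack(list(images[perm]))
        res2 = align_and_classify(stack2, k=2, max_shift_px=0, lowpass_nm=None, seed=7)
        # class averages match up to relabeling
        def keyed(res):
            return sorted(res.class_averages, key=lambda im: im.std())
        for x, y in zip(keyed(res1), keyed(res2)):
            np.testing.assert_allclose(x, y, atol=0.05)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            align_and_classify(make_stack(np.zeros((0, 4, 4))), k=1)


class TestMeasurements:
    def _coat_average(self, thickness, voxel=0.74, noise=0.0, seed=0):
        nz = 96
        pm_z = 26.0
        truth = VolumeTruth(
            voxel_nm=voxel,
            pm_z_nm=pm_z,
            er_z_nm=pm_z + 22.0,
            coat_thickness_nm=thickness,
            noise_sd=noise,
        )
        vol, _ = gen_contact_volume(truth, (nz, 16, 16), seed=seed)
        profile = vol.voxels.mean(axis=(1, 2))
        return np.tile(profile, (32, 1))  # membrane along rows, normal along cols

    def test_slab_fwhm_recovers_truth(self):
        avg = self._coat_average(5.2)
        meas = layer_thickness(avg, pixel_nm=0.74, membrane_axis=0)
        assert meas.kind == "layer_thickness"
        assert abs(meas.length_nm - 5.2) <= 0.74

    def test_no_coat_reports_no_layer(self):
        avg = self._coat_average(None, noise=0.01, seed=4)
        meas = layer_thickness(avg, pixel_nm=0.74, membrane_axis=0)
        assert meas.kind == "no_layer"

    def test_fwhm_contrast_invariant(self):
        avg = self._coat_average(5.2)
        m1 = layer_thickness(avg, pixel_nm=0.74, membrane_axis=0)
        m2 = layer_thickness(2.0 * avg, pixel_nm=0.74, membrane_axis=0)
        assert m1.length_nm == pytest.approx(m2.length_nm, abs=1e-9)

    def _rod_average(self, separation, voxel=0.74):
        nz = 96
        pm_z = (nz * voxel - separation) / 2.0
        rods = [RodSpec(x_nm=24.0, y_nm=24.0, tilt_deg=0.0)]
        truth = VolumeTruth(
            voxel_nm=voxel, pm_z_nm=pm_z, er_z_nm=pm_z + separation, rods=rods
        )
        vol, _ = gen_contact_volume(truth, (nz, 64, 64), seed=0)
        return collapse_to_2d(vol.voxels.transpose(1, 0, 2)[:, ::-1, :])

    @pytest.mark.parametrize("sep", [16.7, 22.0])
    def test_rod_length_recovers_truth(self, sep):
        img = self._rod_average(sep)
        meas = rod_length(img, pixel_nm=0.74, axis=0, profile_width_px=15)
        assert abs(meas.length_nm - sep) <= 0.74

    def test_rod_length_intensity_scale_invariant(self):
        img = self._rod_average(20.0)
        m1 = rod_length(img, pixel_nm=0.74)
        m2 = rod_length(0.3 * img, pixel_nm=0.74)
        assert m1.length_nm == pytest.approx(m2.length_nm, abs=1e-9)

    def test_rod_length_needs_two_peaks(self):
        flat = np.ones((40, 40))
        with pytest.raises(ValueError):
            rod_length(flat, pixel_nm=0.74)


class TestEndToEndRecovery:
    def test_extraction_collapse_average_recovers_rod_length(self):
        from mcsquant.pipelines import rod_length_pipeline

        r = rod_length_pipeline(22.0, n_rods=12, seed=1, noise_sd=0.1)
        assert abs(r.measured - 22.0) <= 0.74
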