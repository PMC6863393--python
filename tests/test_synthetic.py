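"""Ground-truth fidelity and determinism of the synthetic-data generators."""

import numpy as np
import pytest

from mcsquant.particles import particle_axis_angle
from mcsquant.synthetic import (
    PlateTruth,
    RodSpec,
    SiteTruth,
    VolumeTruth,
    gen_colony_experiment,
    gen_contact_volume,
    gen_cortex_image,
    gen_membrane_site,
    gen_particle_picks,
)
from mcsquant.synthetic.rings import RingSpec


class TestMembraneSite:
    def test_zero_noise_flat_is_exact(self):
        truth = SiteTruth(separation_nm=22.0, jitter_sd_nm=0.0, seed=0)
        pm, er = gen_membrane_site(truth, 100.0)
        assert np.all(pm.points[:, 2] == 0.0)
        assert np.all(er.points[:, 2] == 22.0)

    def test_jitter_sd_matches_normal_statistics(self):
        truth = SiteTruth(separation_nm=22.0, jitter_sd_nm=1.0, seed=12)
        pm, er = gen_membrane_site(truth, 200.0)
        assert len(er) >= 100
        sd = np.std(er.points[:, 2], ddof=1)
        assert 0.8 <= sd <= 1.2  # +-20% at >= 100 points

    def test_buckle_construction(self):
        truth = SiteTruth(
            separation_nm=22.0, geometry="buckled", buckle_depth_nm=8.0, seed=0
        )
        pm, er = gen_membrane_site(truth, 200.0)
        apex = er.points[np.argmin(er.points[:, 2])]
        assert er.points[:, 2].min() == pytest.approx(14.0, abs=0.1)
        assert np.hypot(apex[0], apex[1]) < 8.0  # apex near the buckle centre
        far = er.points[np.hypot(er.points[:, 0], er.points[:, 1]) > 80.0]
        np.testing.assert_allclose(far[:, 2], 22.0, atol=0.1)

    def test_click_spacing(self):
        truth = SiteTruth(separation_nm=20.0, seed=0)
        pm, _ = gen_membrane_site(truth, 100.0)
        xs = np.unique(pm.points[:, 0])
        ys = np.unique(pm.points[:, 1])
        assert np.allclose(np.diff(xs), 10.0)
        assert np.allclose(np.diff(ys), 5.5)

    def test_extent_too_small_rejected(self):
        with pytest.raises(ValueError):
            gen_membrane_site(SiteTruth(separation_nm=20.0), 30.0)

    def test_fixed_seed_bit_identical(self):
        truth = SiteTruth(separation_nm=20.0, jitter_sd_nm=1.0, seed=42)
        pm1, er1 = gen_membrane_site(truth, 100.0)
        pm2, er2 = gen_membrane_site(truth, 100.0)
        assert np.array_equal(pm1.points, pm2.points)
        assert np.array_equal(er1.points, er2.points)


class TestContactVolume:
    def test_no_rods_translation_invariant_in_xy(self, small_membrane_volume):
        _, volume, _ = small_membrane_volume
        ref = volume.voxels[:, 0, 0]
        assert np.all(volume.voxels == ref[:, None, None])

    def test_perpendicular_rod_density_on_axis(self):
        rod = RodSpec(x_nm=9.0, y_nm=9.0, tilt_deg=0.0)
        truth = VolumeTruth(voxel_nm=0.74, pm_z_nm=15.0, er_z_nm=37.0, rods=[rod])
        volume, tables = gen_contact_volume(truth, (70, 24, 24), seed=0)
        mid_z = int(round(26.0 / 0.74))  # between the membranes
        plane = volume.voxels[mid_z]
        iy, ix = np.meshgrid(np.arange(24), np.arange(24), indexing="ij")
        cy = (plane * iy).sum() / plane.sum() * 0.74
        cx = (plane * ix).sum() / plane.sum() * 0.74
        assert cx == pytest.approx(9.0, abs=0.2) and cy == pytest.approx(9.0, abs=0.2)
        assert plane.max() == pytest.approx(truth.rod_amp, abs=1e-6)
        assert len(tables["rods"]) == 1
        assert tables["rods"].iloc[0].length_nm == pytest.approx(22.0)

    def test_slab_thickness_by_half_amplitude_scan(self):
        """Brute-force profile scan: rendered slab spans its truth +- 1 voxel."""
        truth = VolumeTruth(
            voxel_nm=0.37, pm_z_nm=15.0, er_z_nm=37.0, coat_thickness_nm=5.2
        )
        volume, tables = gen_contact_volume(truth, (140, 8, 8), seed=0)
        profile = volume.voxels[:, 0, 0]
        membranes_only, _ = gen_contact_volume(
            VolumeTruth(voxel_nm=0.37, pm_z_nm=15.0, er_z_nm=37.0), (140, 8, 8), seed=0
        )
        slab = profile - membranes_only.voxels[:, 0, 0]
        above = np.flatnonzero(slab >= 0.5 * truth.coat_amp)
        measured = (above[-1] - above[0] + 1) * 0.37
        assert abs(measured - 5.2) <= 0.37

    def test_rod_longer_than_gap_rejected(self):
        rods = [RodSpec(x_nm=9.0, y_nm=9.0, tilt_deg=0.0, length_nm=30.0)]
        truth = VolumeTruth(voxel_nm=0.74, pm_z_nm=15.0, er_z_nm=37.0, rods=rods)
        _, tables = gen_contact_volume(truth, (70, 24, 24), seed=0)
        assert len(tables["rods"]) == 0

    def test_truth_tilt_matches_rendered_endpoints(self):
        rods = [RodSpec(x_nm=20.0, y_nm=20.0, tilt_deg=25.0, azimuth_deg=40.0)]
        truth = VolumeTruth(voxel_nm=0.74, pm_z_nm=15.0, er_z_nm=37.0, rods=rods)
        _, tables = gen_contact_volume(truth, (70, 56, 56), seed=0)
        row = tables["rods"].iloc[0]
        axis = np.array([row.bx_nm - row.ax_nm, row.by_nm - row.ay_nm, row.bz_nm - row.az_nm])
        tilt = np.degrees(np.arccos(abs(axis[2]) / np.linalg.norm(axis)))
        assert tilt == pytest.approx(25.0, abs=1e-9)

    def test_volume_too_small_rejected(self):
        truth = VolumeTruth(voxel_nm=0.74, pm_z_nm=15.0, er_z_nm=37.0)
        with pytest.raises(ValueError, match="margin"):
            gen_contact_volume(truth, (40, 8, 8), seed=0)

    def test_fixed_seed_bit_identical(self):
        truth = VolumeTruth(voxel_nm=0.74, pm_z_nm=15.0, er_z_nm=37.0, noise_sd=0.3)
        v1, _ = gen_contact_volume(truth, (70, 16, 16), seed=9)
        v2, _ = gen_contact_volume(truth, (70, 16, 16), seed=9)
        assert np.array_equal(v1.voxels, v2.voxels)


class TestParticlePicks:
    def _tables(self, tilt_deg, n=1, azimuth_deg=0.0):
        rods = [
            RodSpec(x_nm=30.0 + 25.0 * i, y_nm=30.0, tilt_deg=tilt_deg, azimuth_deg=azimuth_deg)
            for i in range(n)
        ]
        truth = VolumeTruth(voxel_nm=0.74, pm_z_nm=15.0, er_z_nm=37.0, rods=rods)
        nx = int((60.0 + 25.0 * n) / 0.74)
        _, tables = gen_contact_volume(truth, (70, 84, nx), seed=0)
        return tables

    def test_perpendicular_pick_angle_is_90(self):
        picks = gen_particle_picks(self._tables(0.0), click_jitter_nm=0.0)
        p = picks[0]
        u = p.B - p.A
        t = p.D - p.B
        ang = np.degrees(np.arccos(u @ t / np.linalg.norm(u) / np.linalg.norm(t)))
        assert ang == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("tilt", [5.0, 15.2, 33.0])
    def test_noiseless_deviation_machine_precision(self, tilt):
        picks = gen_particle_picks(self._tables(tilt, azimuth_deg=25.0), click_jitter_nm=0.0)
        o = particle_axis_angle(picks[0])
        assert o.tilt_deviation_deg == pytest.approx(tilt, abs=1e-9)

    def test_jittered_mean_recovery(self):
        """1000 rods at 20 deg with 1 nm click jitter: mean within 1 deg."""
        rng = np.random.default_rng(0)
        rows = []
        for i in range(1000):
            theta = np.radians(20.0)
            phi = rng.uniform(0, 2 * np.pi)
            a = np.array([0.0, 0.0, 37.0])
            d = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), -np.cos(theta)])
            b = a + (22.0 / np.cos(theta)) * d
            rows.append(
                {"rod_id": i, "x_nm": 0.0, "y_nm": 0.0, "tilt_deg": 20.0,
                 "azimuth_deg": np.degrees(phi), "length_nm": 22.0 / np.cos(theta),
                 "ax_nm": a[0], "ay_nm": a[1], "az_nm": a[2],
                 "bx_nm": b[0], "by_nm": b[1], "bz_nm": b[2]}
            )
        import pandas as pd

        picks = gen_particle_picks({"rods": pd.DataFrame(rows)}, click_jitter_nm=1.0, seed=7)
        alphas = [particle_axis_angle(p).tilt_deviation_deg for p in picks]
        assert np.mean(alphas) == pytest.approx(20.0, abs=1.0)


class TestColonyExperiment:
    def test_no_effects_no_noise_identical_plates(self):
        truth = PlateTruth(noise_sd=0.0)
        query, control = gen_colony_experiment(truth, n_plates=2)
        assert np.array_equal(query["size"].to_numpy(), control["size"].to_numpy())

    def test_interaction_factor_scales_query_only(self):
        truth = PlateTruth(noise_sd=0.0, interaction_factors={"g00_00": 0.5})
        query, control = gen_colony_experiment(truth)
        q = query.set_index(["row", "col"])["size"]
        c = control.set_index(["row", "col"])["size"]
        assert q[(1, 1)] == pytest.approx(0.5 * c[(1, 1)])
        assert q[(2, 2)] == pytest.approx(c[(2, 2)])

    def test_row_effect_applied_multiplicatively(self):
        row_eff = np.ones(16)
        row_eff[0] = 2.0
        truth = PlateTruth(noise_sd=0.0, row_effects=row_eff)
        _, control = gen_colony_experiment(truth)
        c = control.set_index(["row", "col"])["size"]
        assert c[(1, 5)] == pytest.approx(2.0 * c[(2, 5)])

    def test_fixed_seed_bit_identical(self):
        truth = PlateTruth(noise_sd=0.2, seed=5)
        q1, c1 = gen_colony_experiment(truth, n_plates=3)
        q2, c2 = gen_colony_experiment(truth, n_plates=3)
        assert q1.equals(q2) and c1.equals(c2)


class TestCortexImage:
    def test_identical_domains_identical_channels(self):
        domains = ([(0.0, 90.0)], [(0.0, 90.0)])
        image, _ = gen_cortex_image(domains, seed=0)
        assert np.array_equal(image[0], image[1])

    def test_empty_domain_flat_background(self):
        image, _ = gen_cortex_image(([], [(0.0, 90.0)]), seed=0)
        assert np.all(image[0] == RingSpec().background)

    def test_contour_is_generating_circle(self):
        _, contour = gen_cortex_image(([], []), seed=0)
        spec = RingSpec()
        r = np.hypot(
            contour[:, 0] - spec.center[0], contour[:, 1] - spec.center[1]
        )
        np.testing.assert_allclose(r, spec.radius_px, atol=1e-9)
        np.testing.assert_allclose(contour[0], contour[-1])

    def test_fixed_seed_bit_identical(self):
        domains = ([(0.0, 45.0)], [(180.0, 225.0)])
        spec = RingSpec(noise_sd=2.0)
        i1, _ = gen_cortex_image(domains, seed=3, spec=spec)
        i2, _ = gen_cortex_image(domains, seed=3, spec=spec)
        assert np.array_equal(i1, i2)
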