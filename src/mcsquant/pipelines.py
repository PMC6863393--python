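"""End-to-end analysis pipelines over synthetic contact-site data.

Each driver generates inputs with the synthetic module at stated study
conditions, runs the corresponding measurement chain, and returns both the
measured quantity and the ground truth, so recovery can be assessed.  The
analysis scripts and the acceptance checks are thin wrappers over these
functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import collapse, sga, surface
from .synthetic import (
    PlateTruth,
    RodSpec,
    SiteTruth,
    VolumeTruth,
    gen_colony_experiment,
    gen_contact_volume,
    gen_membrane_site,
    gen_particle_picks,
)
from .particles import orientation_summary, particle_axis_angle

#: 2x-binned voxel size (nm) used for the averaging pipelines; the unbinned
#: tomogram pixel is 0.37 nm.
BINNED_VOXEL_NM = 0.74


@dataclass
class RecoveryResult:
    """A measured quantity next to its ground truth."""

    measured: float
    truth: float
    n: int
    detail: object = None

    @property
    def error(self) -> float:
        return self.measured - self.truth


def distance_survey(
    n_sites: int,
    separation_nm: float,
    jitter_sd_nm: float = 1.0,
    seed: int = 1,
    extent_nm: float = 200.0,
    geometry: str = "flat",
) -> RecoveryResult:
    """Intermembrane-distance recovery over a cohort of synthetic sites.

    Generates ``n_sites`` contact sites at the given true separation, runs
    the full surface-distance chain per site and returns the grand mean of
    the per-site mean distances (one measurement N per site, as in the
    survey this emulates).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sites):
        truth = SiteTruth(
            separation_nm=separation_nm,
            geometry=geometry,
            jitter_sd_nm=jitter_sd_nm,
            seed=int(rng.integers(0, 2**31 - 1)),
            site_id=f"site{i:03d}",
        )
        pm, er = gen_membrane_site(truth, extent_nm)
        stats = surface.site_distance_stats(pm, er)
        rows.append(
            {
                "site_id": stats.site_id,
                "n_er_points": stats.n_er_points,
                "mean_nm": stats.mean_nm,
                "sd_nm": stats.sd_nm,
                "min_nm": stats.min_nm,
                "max_nm": stats.max_nm,
            }
        )
    detail = pd.DataFrame(rows)
    return RecoveryResult(
        measured=float(detail["mean_nm"].mean()),
        truth=separation_nm,
        n=n_sites,
        detail=detail,
    )


def tilt_recovery(
    n_particles: int,
    tilt_deg: float,
    click_jitter_nm: float = 0.0,
    seed: int = 0,
    separation_nm: float = 22.0,
) -> RecoveryResult:
    """Tilt-deviation recovery from 4-point picks of rods at a known tilt.

    Rods are generated at the stated tilt with azimuths spread around the
    circle; picks carry isotropic click jitter.  Returns the mean recovered
    deviation from perpendicular.
    """
    azimuths = np.linspace(0.0, 360.0, n_particles, endpoint=False)
    spacing = 25.0
    rods = [
        RodSpec(x_nm=50.0 + i * spacing, y_nm=50.0, tilt_deg=tilt_deg, azimuth_deg=az)
        for i, az in enumerate(azimuths)
    ]
    truth = VolumeTruth(voxel_nm=BINNED_VOXEL_NM, pm_z_nm=15.0, er_z_nm=15.0 + separation_nm)
    # picks need only the truth tables; build them without rendering a volume
    rows = []
    gap = truth.gap_nm
    for i, rod in enumerate(rods):
        theta = np.radians(rod.tilt_deg)
        phi = np.radians(rod.azimuth_deg)
        length = gap / np.cos(theta)
        a = np.array([rod.x_nm, rod.y_nm, truth.er_z_nm])
        d = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), -np.cos(theta)]
        )
        b = a + length * d
        rows.append(
            {
                "rod_id": i,
                "x_nm": rod.x_nm,
                "y_nm": rod.y_nm,
                "tilt_deg": rod.tilt_deg,
                "azimuth_deg": rod.azimuth_deg,
                "length_nm": length,
                "ax_nm": a[0], "ay_nm": a[1], "az_nm": a[2],
                "bx_nm": b[0], "by_nm": b[1], "bz_nm": b[2],
            }
        )
    tables = {"rods": pd.DataFrame(rows)}
    picks = gen_particle_picks(tables, click_jitter_nm=click_jitter_nm, seed=seed)
    orients = [particle_axis_angle(p) for p in picks]
    summary = orientation_summary(orients)
    return RecoveryResult(
        measured=summary.mean_deg, truth=tilt_deg, n=summary.n, detail=summary
    )


def coat_thickness_pipeline(
    thickness_nm: float,
    seed: int = 3,
    voxel_nm: float = BINNED_VOXEL_NM,
    noise_rel: float = 0.2,
    n_boxes_min: int = 100,
    box_px: int = 64,
    step_px: int = 2,
) -> RecoveryResult:
    """Coat thickness through the full extraction/averaging chain.

    Renders a flat contact volume whose PM carries a coat slab of the given
    thickness and additive noise of ``noise_rel`` times the slab amplitude;
    clicks a path along the PM leaflet, extracts overlapping boxes along the
    fitted spline, collapses them to 2D, aligns with k = 1 (constrained
    global averaging) and measures the layer thickness on the average by
    FWHM.
    """
    nz = box_px + 32  # boxes are centred on the PM leaflet and must fit in z
    pm_z = round(0.37 * nz * voxel_nm)  # leaflet a little below the volume centre
    truth = VolumeTruth(
        voxel_nm=voxel_nm,
        pm_z_nm=pm_z,
        er_z_nm=pm_z + 22.0,
        coat_thickness_nm=thickness_nm,
        noise_sd=noise_rel * 0.8,  # slab amplitude is 0.8
    )
    nx = (n_boxes_min + 8) * step_px + box_px + 8
    shape = (nz, box_px + 4, nx)
    volume, tables = gen_contact_volume(truth, shape, seed=seed)

    # click points along the PM cytosolic leaflet every 8 nm
    y_mid = (shape[1] / 2) * voxel_nm
    xs = np.arange(2.0, nx * voxel_nm - 2.0, 8.0)
    path_pts = np.column_stack(
        [xs, np.full_like(xs, y_mid), np.full_like(xs, truth.pm_z_nm)]
    )
    spline = collapse.fit_path_spline(path_pts)
    stack = collapse.extract_boxes_along_path(volume, spline, box_px=box_px, step_px=step_px)
    images = collapse.collapse_stack(stack)
    result = collapse.align_and_classify(
        images, k=1, rot_window_deg=15.0, max_shift_px=2, lowpass_nm=2.0, seed=seed
    )
    meas = collapse.layer_thickness(
        result.class_averages[0], pixel_nm=voxel_nm, membrane_axis=0
    )
    if meas.kind == "no_layer":
        raise RuntimeError("coat layer not detected in the class average")
    return RecoveryResult(
        measured=float(meas.length_nm), truth=thickness_nm, n=len(images), detail=meas
    )


def rod_length_pipeline(
    separation_nm: float,
    n_rods: int = 50,
    seed: int = 5,
    voxel_nm: float = BINNED_VOXEL_NM,
    noise_sd: float = 0.2,
    tilt_deg: float = 0.0,
) -> RecoveryResult:
    """Rod length through particle extraction, collapse, k=1 averaging.

    Renders two membranes whose cytosolic leaflets sit ``separation_nm``
    apart bridged by ``n_rods`` rods at the stated tilt, extracts particle
    boxes at the truth picks (444 Angstrom box), collapses, aligns with
    k = 1 and measures the leaflet-to-leaflet distance on a 15-pixel-wide
    line profile of the average.
    """
    box_px = int(round(444.0 / (10.0 * voxel_nm)))
    spacing_px = 16
    nx = n_rods * spacing_px + box_px + 16
    # z must fit the box around the gap midpoint and 10 nm margins beyond
    # the outer leaflets
    nz = max(box_px + 4, int(np.ceil((separation_nm + 29.0) / voxel_nm)))
    shape = (nz, box_px + 4, nx)
    pm_z = (nz * voxel_nm - separation_nm) / 2.0
    rods = [
        RodSpec(
            x_nm=(box_px / 2 + 8 + i * spacing_px) * voxel_nm,
            y_nm=shape[1] / 2 * voxel_nm,
            tilt_deg=tilt_deg,
            azimuth_deg=0.0,
        )
        for i in range(n_rods)
    ]
    truth = VolumeTruth(
        voxel_nm=voxel_nm,
        pm_z_nm=pm_z,
        er_z_nm=pm_z + separation_nm,
        rods=rods,
        noise_sd=noise_sd,
    )
    volume, tables = gen_contact_volume(truth, shape, seed=seed)
    picks = gen_particle_picks(tables, click_jitter_nm=0.0, seed=seed)
    stack = collapse.extract_particle_boxes(volume, picks)
    images = collapse.collapse_stack(stack)
    result = collapse.align_and_classify(
        images, k=1, rot_window_deg=15.0, max_shift_px=2, lowpass_nm=2.0, seed=seed
    )
    meas = collapse.rod_length(
        result.class_averages[0], pixel_nm=voxel_nm, axis=0, profile_width_px=15
    )
    return RecoveryResult(
        measured=float(meas.length_nm), truth=separation_nm, n=len(images), detail=meas
    )


def sga_null_fpr(
    n_seeds: int = 100,
    noise_sd: float = 0.1,
    n_replicates: int = 4,
    cutoff: float = -1.0,
    seed: int = 0,
) -> RecoveryResult:
    """False-positive rate of hit calling under the null (no interactions)."""
    rng = np.random.default_rng(seed)
    n_hits = 0
    n_genes = 0
    for _ in range(n_seeds):
        truth = PlateTruth(noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)))
        query, control = gen_colony_experiment(truth, n_plates=n_replicates)
        scores = sga.interaction_scores(query, control, cutoff=cutoff)
        n_hits += len(sga.call_hits(scores, cutoff))
        n_genes += len(scores)
    return RecoveryResult(measured=n_hits / n_genes, truth=0.0, n=n_genes)
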