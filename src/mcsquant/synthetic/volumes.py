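"""Synthetic tomographic volumes of ER-PM contact sites with known truth.

A contact volume holds two double-leaflet membranes roughly parallel to the
x-y plane (the PM below, the ER above; the cytosol in between), optional
rod-shaped densities bridging the cytosolic leaflets at specified tilt
angles, an optional coat slab of density on the cytosolic PM leaflet, and
additive Gaussian noise.  Density is positive-up (more mass = higher value).

Rendering model (chosen here; tomographic density models are not part of the
annotation protocol being emulated):

* each leaflet is a Gaussian sheet of sigma 1 nm; the two leaflets of one
  membrane are 4 nm apart (centre to centre), matching bilayer appearance in
  cryo-ET at ~2 nm resolution;
* rods are antialiased cylinders of 2.5 nm radius spanning the cytosolic
  leaflets at their stated tilt;
* the coat is a uniform slab starting 3 nm on the cytosolic side of the
  cytosolic PM leaflet centre (i.e. adjacent to the membrane surface),
  rendered with partial-voxel coverage so its half-maximum width equals the
  requested thickness to within one voxel.

The default voxel size of 0.37 nm mirrors the average tomogram pixel size of
3.7 Angstrom; binned variants are accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..collapse import DensityVolume
from ..particles import ParticlePick

log = logging.getLogger(__name__)

LEAFLET_SIGMA_NM = 1.0
LEAFLET_SPACING_NM = 4.0
ROD_RADIUS_NM = 2.5
COAT_OFFSET_NM = 3.0
AUX_OFFSET_NM = 10.0  # auxiliary pick points ~10 nm away along the membranes


@dataclass
class RodSpec:
    """One bridging rod: in-plane centre, tilt from the membrane normal."""

    x_nm: float
    y_nm: float
    tilt_deg: float
    azimuth_deg: float = 0.0
    length_nm: float | None = None  # None -> span the gap exactly

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_deg <= 90.0:
            raise ValueError("tilt_deg must be in [0, 90]")


@dataclass
class VolumeTruth:
    """Ground truth for one synthetic contact volume."""

    voxel_nm: float = 0.37
    pm_z_nm: float = 15.0  # cytosolic PM leaflet centre
    er_z_nm: float = 37.0  # cytosolic ER leaflet centre (gap = er - pm)
    rods: list = field(default_factory=list)
    coat_thickness_nm: float | None = None
    coat_footprint_x_nm: tuple | None = None  # (x0, x1) or None = everywhere
    noise_sd: float = 0.0
    membrane_amp: float = 1.0
    rod_amp: float = 0.5
    coat_amp: float = 0.8

    def __post_init__(self) -> None:
        if self.voxel_nm <= 0:
            raise ValueError("voxel_nm must be positive")
        if self.er_z_nm <= self.pm_z_nm:
            raise ValueError("ER leaflet must lie above the PM leaflet")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def gap_nm(self) -> float:
        return self.er_z_nm - self.pm_z_nm


def _leaflet_profile(z: np.ndarray, centers: list[float], amp: float) -> np.ndarray:
    prof = np.zeros_like(z)
    for c in centers:
        prof += amp * np.exp(-((z - c) ** 2) / (2.0 * LEAFLET_SIGMA_NM**2))
    return prof


def gen_contact_volume(
    truth: VolumeTruth, shape_voxels: tuple[int, int, int], seed: int = 0
) -> tuple[DensityVolume, dict]:
    """Render a contact volume and return it with its truth tables.

    ``shape_voxels`` is (nz, ny, nx).  The volume must contain both
    membranes plus a 10 nm margin beyond the outer leaflets.  Rod records
    whose length exceeds the gap at their tilt, or whose centre falls outside
    the volume, are rejected with a log entry.  The truth tables list the
    rendered rod endpoints/angles/lengths, the coat footprint, and the
    membrane geometry.
    """
    nz, ny, nx = shape_voxels
    v = truth.voxel_nm
    extent = np.array([nx, ny, nz]) * v  # (x, y, z) nm
    pm_outer = truth.pm_z_nm - LEAFLET_SPACING_NM
    er_outer = truth.er_z_nm + LEAFLET_SPACING_NM
    if pm_outer - 10.0 < 0 or er_outer + 10.0 > extent[2]:
        raise ValueError(
            "volume too small: need both membranes plus a 10 nm z-margin "
            f"(outer leaflets at {pm_outer:.1f}/{er_outer:.1f} nm, extent {extent[2]:.1f} nm)"
        )

    zc = np.arange(nz) * v
    profile = _leaflet_profile(
        zc,
        [pm_outer, truth.pm_z_nm, truth.er_z_nm, er_outer],
        truth.membrane_amp,
    )
    vol = np.broadcast_to(profile[:, None, None], (nz, ny, nx)).astype(float).copy()

    coat_table = None
    if truth.coat_thickness_nm:
        z0 = truth.pm_z_nm + COAT_OFFSET_NM
        z1 = z0 + truth.coat_thickness_nm
        if z1 > truth.er_z_nm - 2.0:
            raise ValueError("coat slab would reach the ER membrane")
        # per-voxel z coverage of the slab (voxel spans [z - v/2, z + v/2])
        cover = np.clip(
            (np.minimum(zc + v / 2, z1) - np.maximum(zc - v / 2, z0)) / v, 0.0, 1.0
        )
        slab = truth.coat_amp * cover
        if truth.coat_footprint_x_nm is None:
            vol += slab[:, None, None]
            x0, x1 = 0.0, extent[0]
        else:
            x0, x1 = truth.coat_footprint_x_nm
            xc = np.arange(nx) * v
            xmask = np.clip((np.minimum(xc + v / 2, x1) - np.maximum(xc - v / 2, x0)) / v, 0, 1)
            vol += slab[:, None, None] * xmask[None, None, :]
        coat_table = {
            "thickness_nm": truth.coat_thickness_nm,
            "z0_nm": z0,
            "z1_nm": z1,
            "x0_nm": x0,
            "x1_nm": x1,
            "amp": truth.coat_amp,
        }

    rod_rows = []
    for i, rod in enumerate(truth.rods):
        theta = np.radians(rod.tilt_deg)
        phi = np.radians(rod.azimuth_deg)
        span = truth.gap_nm / np.cos(theta) if rod.tilt_deg < 90 else np.inf
        length = span if rod.length_nm is None else rod.length_nm
        if length * np.cos(theta) > truth.gap_nm + 1e-6 or not np.isfinite(length):
            log.warning("rod %d longer than the gap at tilt %.1f deg; rejected", i, rod.tilt_deg)
            continue
        a = np.array([rod.x_nm, rod.y_nm, truth.er_z_nm])  # ER base
        d = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), -np.cos(theta)]
        )
        b = a + length * d  # PM end
        if not ((0 <= a[:2]) & (a[:2] <= extent[:2])).all() or not (
            (0 <= b[:2]) & (b[:2] <= extent[:2])
        ).all():
            log.warning("rod %d endpoints outside the volume; rejected", i)
            continue
        _render_rod(vol, v, a, b, truth.rod_amp)
        rod_rows.append(
            {
                "rod_id": i,
                "x_nm": rod.x_nm,
                "y_nm": rod.y_nm,
                "tilt_deg": rod.tilt_deg,
                "azimuth_deg": rod.azimuth_deg,
                "length_nm": length,
                "ax_nm": a[0],
                "ay_nm": a[1],
                "az_nm": a[2],
                "bx_nm": b[0],
                "by_nm": b[1],
                "bz_nm": b[2],
            }
        )

    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol += rng.normal(0.0, truth.noise_sd, vol.shape)

    tables = {
        "rods": pd.DataFrame(
            rod_rows,
            columns=[
                "rod_id", "x_nm", "y_nm", "tilt_deg", "azimuth_deg", "length_nm",
                "ax_nm", "ay_nm", "az_nm", "bx_nm", "by_nm", "bz_nm",
            ],
        ),
        "coat": coat_table,
        "membranes": {
            "pm_z_nm": truth.pm_z_nm,
            "er_z_nm": truth.er_z_nm,
            "leaflet_spacing_nm": LEAFLET_SPACING_NM,
            "leaflet_sigma_nm": LEAFLET_SIGMA_NM,
        },
    }
    return DensityVolume(voxels=vol, voxel_nm=v), tables


def _render_rod(
    vol: np.ndarray, voxel_nm: float, a: np.ndarray, b: np.ndarray, amp: float
) -> None:
    """Add an antialiased cylinder of ROD_RADIUS_NM between endpoints a, b."""
    pad = ROD_RADIUS_NM + 2.0 * voxel_nm
    lo_nm = np.minimum(a, b) - pad
    hi_nm = np.maximum(a, b) + pad
    nz, ny, nx = vol.shape
    lo = np.maximum(np.floor(lo_nm / voxel_nm).astype(int), 0)
    hi = np.minimum(np.ceil(hi_nm / voxel_nm).astype(int) + 1, [nx, ny, nz])
    xs = np.arange(lo[0], hi[0]) * voxel_nm
    ys = np.arange(lo[1], hi[1]) * voxel_nm
    zs = np.arange(lo[2], hi[2]) * voxel_nm
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    p = np.stack([gx, gy, gz], axis=-1)
    ab = b - a
    L2 = float(ab @ ab)
    t = np.clip(((p - a) @ ab) / L2, 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist = np.linalg.norm(p - closest, axis=-1)
    dens = amp * np.clip((ROD_RADIUS_NM - dist) / voxel_nm + 0.5, 0.0, 1.0)
    vol[lo[2] : hi[2], lo[1] : hi[1], lo[0] : hi[0]] += dens


def gen_particle_picks(
    truth_tables: dict, click_jitter_nm: float = 0.0, seed: int = 0, tomogram_id: str = ""
) -> list[ParticlePick]:
    """4-point picks for every rendered rod, with isotropic click jitter.

    Per rod: A at the ER cytosolic leaflet at the rod base, B at the PM
    cytosolic leaflet at the rod end, and auxiliary points C (ER) and D (PM)
    10 nm away from the rod along the membranes in the rod's azimuthal
    direction.  Each point is perturbed by isotropic Gaussian jitter of
    ``click_jitter_nm``.
    """
    rods = truth_tables["rods"]
    rng = np.random.default_rng(seed)
    picks = []
    for _, row in rods.iterrows():
        a = np.array([row.ax_nm, row.ay_nm, row.az_nm])
        b = np.array([row.bx_nm, row.by_nm, row.bz_nm])
        phi = np.radians(row.azimuth_deg)
        e = np.array([np.cos(phi), np.sin(phi), 0.0])
        c = a + AUX_OFFSET_NM * e
        d = b + AUX_OFFSET_NM * e
        pts = np.vstack([a, b, c, d])
        if click_jitter_nm > 0:
            pts = pts + rng.normal(0.0, click_jitter_nm, pts.shape)
        picks.append(
            ParticlePick(
                particle_id=f"rod{int(row.rod_id):04d}",
                A=pts[0],
                B=pts[1],
                C=pts[2],
                D=pts[3],
                tomogram_id=tomogram_id,
            )
        )
    return picks
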