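"""Synthetic clicked membrane point clouds for one ER-PM contact site.

Emulates the annotation protocol used on tomograms of contact sites: points
clicked along the cytosolic leaflets of the PM and the ER roughly every 10 nm
within the membrane plane and every 5.5 nm across slices, with Gaussian click
jitter applied along the local membrane normal.  The PM surface is the z = 0
plane (optionally with a cylindrical ER partner or a local buckle of the ER
toward the PM); the ER surface is offset from the PM by the true separation
along the local normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..surface import MembranePointCloud

#: In-plane click spacing (nm) and slice tracing spacing (nm).
XY_SPACING_NM = 10.0
Z_TRACING_NM = 5.5


@dataclass
class SiteTruth:
    """Ground truth for one synthetic contact site."""

    separation_nm: float  # true PM-ER gap between cytosolic leaflets
    geometry: str = "flat"  # flat | tubular | buckled
    tubule_radius_nm: float = 25.0
    buckle_depth_nm: float = 0.0
    buckle_radius_nm: float = 20.0
    jitter_sd_nm: float = 0.0
    seed: int = 0
    site_id: str = "site"

    def __post_init__(self) -> None:
        if self.separation_nm <= 0:
            raise ValueError("separation_nm must be positive")
        if self.jitter_sd_nm < 0:
            raise ValueError("jitter_sd_nm must be non-negative")
        if self.geometry not in ("flat", "tubular", "buckled"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "buckled" and not self.buckle_depth_nm < self.separation_nm:
            raise ValueError("buckle_depth_nm must be smaller than separation_nm")


def _er_height_and_normal(
    truth: SiteTruth, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ER surface height above the PM plane and its unit normal, per point.

    flat:    z = separation everywhere.
    buckled: Gaussian dimple toward the PM, depth ``buckle_depth_nm`` at the
             apex (x = y = 0), lateral scale ``buckle_radius_nm``.
    tubular: lower surface of a cylinder of radius R running along y, closest
             approach = separation at x = 0; defined for |x| < R only.
    """
    sep = truth.separation_nm
    if truth.geometry == "flat":
        z = np.full_like(x, sep)
        normal = np.tile([0.0, 0.0, 1.0], (len(x), 1))
        return z, normal, np.ones_like(x, dtype=bool)
    if truth.geometry == "buckled":
        r2 = x**2 + y**2
        g = np.exp(-r2 / (2.0 * truth.buckle_radius_nm**2))
        z = sep - truth.buckle_depth_nm * g
        # normal of z(x, y): (-dz/dx, -dz/dy, 1) normalized
        fac = truth.buckle_depth_nm * g / truth.buckle_radius_nm**2
        nx, ny = -fac * x, -fac * y
        normal = np.column_stack([nx, ny, np.ones_like(x)])
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        return z, normal, np.ones_like(x, dtype=bool)
    # tubular: cylinder axis along y at height sep + R, lower surface
    R = truth.tubule_radius_nm
    keep = np.abs(x) < 0.98 * R
    z = np.full_like(x, np.nan)
    z[keep] = sep + R - np.sqrt(R**2 - x[keep] ** 2)
    normal = np.zeros((len(x), 3))
    # outward (downward-facing) cylinder normal, pointing away from the axis
    normal[keep, 0] = x[keep] / R
    normal[keep, 2] = -np.sqrt(R**2 - x[keep] ** 2) / R
    normal[keep] *= -1.0  # orient +z-ish (toward the cytosol side of the ER)
    return z, normal, keep


def gen_membrane_site(
    truth: SiteTruth, extent_nm: float
) -> tuple[MembranePointCloud, MembranePointCloud]:
    """Generate the clicked PM and ER point clouds for one contact site.

    Points are laid out on a regular grid over ``extent_nm`` x ``extent_nm``
    (10 nm spacing along x, 5.5 nm along y mirroring the slice tracing), on
    the PM plane and on the ER surface offset by the true separation.
    Independent Gaussian jitter of ``jitter_sd_nm`` is added along the local
    surface normal of each membrane.
    """
    if extent_nm < 50:
        raise ValueError("extent_nm must be >= 50 to yield enough clicks")
    rng = np.random.default_rng(truth.seed)
    half = extent_nm / 2.0
    xs = np.arange(-half, half + 1e-9, XY_SPACING_NM)
    ys = np.arange(-half, half + 1e-9, Z_TRACING_NM)
    gx, gy = np.meshgrid(xs, ys)
    x, y = gx.ravel(), gy.ravel()

    pm_pts = np.column_stack([x, y, np.zeros_like(x)])
    if truth.jitter_sd_nm > 0:
        pm_pts[:, 2] += rng.normal(0.0, truth.jitter_sd_nm, len(pm_pts))

    ez, enormal, keep = _er_height_and_normal(truth, x, y)
    er_pts = np.column_stack([x, y, ez])[keep]
    enormal = enormal[keep]
    if truth.jitter_sd_nm > 0:
        er_pts += enormal * rng.normal(0.0, truth.jitter_sd_nm, len(er_pts))[:, None]

    if len(pm_pts) < 4 or len(er_pts) < 4:
        raise ValueError("extent too small to yield >= 4 points per membrane")
    pm = MembranePointCloud(truth.site_id, "PM", pm_pts)
    er = MembranePointCloud(truth.site_id, "ER", er_pts)
    return pm, er
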