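"""Tilt geometry of membrane-bridging particles from 4-point picks.

Each rod-shaped density bridging the ER and PM is annotated with four clicked
points: A at the ER membrane base of the rod, B at the PM end, and two
auxiliary points roughly 10 nm away from the rod along each membrane (C on
the ER, D on the PM).  From these the particle axis B-A, its deviation from
perpendicular to the PM (alpha), and the in-plane rotation prior used to
restrain 2D alignment are computed.  The analysis is strictly in-plane: the
four points are projected onto their common best-fit plane first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surface import fit_plane


@dataclass
class ParticlePick:
    """4-point click set for one bridging particle (coordinates in nm)."""

    particle_id: str
    A: np.ndarray  # ER base of the rod
    B: np.ndarray  # PM end of the rod
    C: np.ndarray  # auxiliary point on the ER membrane
    D: np.ndarray  # auxiliary point on the PM
    tomogram_id: str = ""

    def __post_init__(self) -> None:
        for name in "ABCD":
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if np.linalg.norm(self.B - self.A) <= 2.0:
            raise ValueError(
                f"particle {self.particle_id!r}: |B-A| must exceed 2 nm "
                f"(got {np.linalg.norm(self.B - self.A):.3f})"
            )
        if np.allclose(self.C, self.A) or np.allclose(self.D, self.B):
            raise ValueError(f"particle {self.particle_id!r}: degenerate auxiliary point")


@dataclass
class ParticleOrientation:
    """In-plane orientation of one particle relative to the PM."""

    particle_id: str
    tilt_deviation_deg: float  # alpha in [0, 90], deviation from perpendicular
    inplane_rotation_deg: float  # signed rotation making B-A vertical in-frame
    axis_length_nm: float


@dataclass
class OrientationSummary:
    n: int
    mean_deg: float
    sd_deg: float
    bin_edges_deg: np.ndarray
    counts: np.ndarray


def _project_to_plane(points: np.ndarray) -> np.ndarray:
    """Project points onto their total-least-squares plane.

    When the points are already coplanar this is the identity.
    """
    plane = fit_plane(points)
    centered = points - plane.centroid
    return points - np.outer(centered @ plane.normal, plane.normal)


def particle_axis_angle(pick: ParticlePick) -> ParticleOrientation:
    """Axis angle of one pick: deviation from perpendicular to the PM.

    The four points are projected onto their best-fit plane; with axis
    u = B - A and PM tangent t = D - B, alpha = |90 deg - angle(u, t)|
    clipped to [0, 90].  The ER auxiliary point C enters the plane fit only;
    the deviation is measured against the PM tangent (the histogramed
    quantity is "relative to the PM").  The in-plane rotation is the signed
    angle of u away from the PM normal direction within the plane, i.e. the
    rotation that makes the axis vertical in the extraction frame.
    """
    pts = np.vstack([pick.A, pick.B, pick.C, pick.D])
    proj = _project_to_plane(pts)
    a, b, _, d = proj
    u = b - a
    t = d - b
    lu = np.linalg.norm(u)
    lt = np.linalg.norm(t)
    if lu < 1e-12:
        raise ValueError(f"particle {pick.particle_id!r}: zero-length axis after projection")
    if lt < 1e-12:
        raise ValueError(f"particle {pick.particle_id!r}: zero-length PM tangent")
    cosang = np.clip(np.dot(u, t) / (lu * lt), -1.0, 1.0)
    angle_ut = np.degrees(np.arccos(cosang))
    alpha = float(np.clip(abs(90.0 - angle_ut), 0.0, 90.0))

    # In-plane frame: x along the PM tangent, y along the in-plane PM normal
    # pointing from B toward A (ER side).  The signed rotation of the ER-ward
    # axis direction v = A - B away from +y.
    that = t / lt
    v = a - b
    nvec = v - np.dot(v, that) * that
    ln = np.linalg.norm(nvec)
    nhat = nvec / ln if ln > 1e-12 else np.zeros(3)
    inplane = float(np.degrees(np.arctan2(np.dot(v, that), np.dot(v, nhat))))
    return ParticleOrientation(
        particle_id=pick.particle_id,
        tilt_deviation_deg=alpha,
        inplane_rotation_deg=inplane,
        axis_length_nm=float(lu),
    )


def orientation_summary(
    orients: list[ParticleOrientation] | np.ndarray, bin_width_deg: float = 5.0
) -> OrientationSummary:
    """Mean, SD (n-1) and histogram of tilt deviations over [0, 90] deg.

    Bins are half-open [k*w, (k+1)*w); a deviation of exactly 90 deg falls in
    the last bin.
    """
    if len(orients) == 0:
        raise ValueError("need at least one orientation")
    alphas = np.asarray(
        [o.tilt_deviation_deg if isinstance(o, ParticleOrientation) else o for o in orients],
        dtype=float,
    )
    n_bins = int(np.ceil(90.0 / bin_width_deg))
    edges = np.arange(n_bins + 1) * bin_width_deg
    idx = np.minimum((alphas // bin_width_deg).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sd = float(np.std(alphas, ddof=1)) if len(alphas) > 1 else 0.0
    return OrientationSummary(
        n=len(alphas),
        mean_deg=float(np.mean(alphas)),
        sd_deg=sd,
        bin_edges_deg=edges,
        counts=counts,
    )
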