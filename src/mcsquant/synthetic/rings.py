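"""Synthetic two-channel cortical fluorescence images.

The cell cortex is emulated as a ring of Gaussian cross-section; each
channel's intensity along the ring follows a specification of bright angular
domains (colocalized domains overlap between channels, segregated domains do
not), over a uniform background, plus Gaussian noise.  The generating circle
polygon is returned as the cortex contour so the line-profile extraction can
be checked against the known domain geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RingSpec:
    """Geometry and noise of a synthetic two-channel cortical ring image."""

    shape: tuple = (128, 128)
    center: tuple = (64.0, 64.0)  # (row, col) px
    radius_px: float = 40.0
    ring_sigma_px: float = 2.0
    background: float = 10.0
    amplitude: float = 100.0
    noise_sd: float = 0.0
    n_contour_vertices: int = 360


def _angular_intensity(theta_deg: np.ndarray, domains, amplitude: float) -> np.ndarray:
    """Sum of bright-domain indicators at angles (deg, measured CCW from +x)."""
    out = np.zeros_like(theta_deg)
    for dom in domains:
        start, end = dom[0] % 360.0, dom[1] % 360.0
        amp = dom[2] if len(dom) > 2 else amplitude
        t = theta_deg % 360.0
        if start <= end:
            out += amp * ((t >= start) & (t < end))
        else:  # wraps through 0
            out += amp * ((t >= start) | (t < end))
    return out


def gen_cortex_image(
    domains: tuple[list, list], seed: int = 0, spec: RingSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Render a 2-channel ring image plus its cortex contour.

    ``domains`` holds one list of angular intervals per channel, each
    interval ``(start_deg, end_deg)`` or ``(start_deg, end_deg, amplitude)``.
    Returns (image, contour): image is (2, H, W) float, contour the closed
    generating circle polygon as (n + 1, 2) (row, col) vertices starting at
    angle 0 and proceeding clockwise in image coordinates (row axis points
    down, so clockwise on screen is mathematically CCW in (x, -y)).
    """
    spec = spec or RingSpec()
    if len(domains) != 2:
        raise ValueError("domains must hold one interval list per channel")
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    dy = rr - spec.center[0]
    dx = cc - spec.center[1]
    r = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(-dy, dx)) % 360.0  # CCW from +x, y up
    radial = np.exp(-((r - spec.radius_px) ** 2) / (2.0 * spec.ring_sigma_px**2))

    image = np.empty((2, h, w))
    for ch in range(2):
        ang = _angular_intensity(theta, domains[ch], spec.amplitude)
        image[ch] = spec.background + ang * radial
        if spec.noise_sd > 0:
            image[ch] += rng.normal(0.0, spec.noise_sd, (h, w))

    # clockwise-on-screen contour: angle decreases in the y-up frame
    ang = -np.linspace(0.0, 2.0 * np.pi, spec.n_contour_vertices, endpoint=False)
    rows = spec.center[0] - spec.radius_px * np.sin(ang)
    cols = spec.center[1] + spec.radius_px * np.cos(ang)
    contour = np.column_stack([rows, cols])
    contour = np.vstack([contour, contour[:1]])  # closed: first = last
    return image, contour
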