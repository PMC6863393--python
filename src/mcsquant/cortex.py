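"""Linearized fluorescence line profiles along the cell cortex.

Given a two-channel image and a closed contour traced along the cortex of a
cell, the cortical signal is straightened into one intensity vector per
channel: the contour is resampled at fixed arc-length steps starting from a
marked start point and traversed clockwise (on screen), and at every step
the maximum intensity within a short band along the local inward normal is
recorded.  Channel co-occurrence is summarized by the Pearson correlation of
the two profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class CortexContour:
    """Ordered closed polygon along the cortex ((row, col) px, sub-pixel).

    ``start_index`` marks the traversal start (the arrow position in a
    linearized-signal display).
    """

    vertices: np.ndarray  # (n, 2) rows, cols; closed: first == last
    start_index: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 8:
            raise ValueError("contour needs at least 8 vertices")
        if not np.allclose(self.vertices[0], self.vertices[-1]):
            raise ValueError("contour must be closed (first vertex == last)")

    @property
    def open_vertices(self) -> np.ndarray:
        return self.vertices[:-1]


@dataclass
class LinearProfile:
    """Arc-length positions plus one intensity vector per channel."""

    positions_px: np.ndarray
    intensities: np.ndarray  # (n_channels, n_steps)

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 1], poly[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def linearize_profile(
    image_2ch: np.ndarray,
    contour: CortexContour,
    band_halfwidth_px: float = 2.0,
    step_px: float = 1.0,
) -> LinearProfile:
    """Straighten the cortical signal along the contour.

    At each arc-length step the profile records, per channel, the maximum
    bilinearly interpolated intensity over offsets within
    ``+/- band_halfwidth_px`` along the local inward normal (cortical
    signals sit slightly inside the traced contour).  Traversal is clockwise
    on screen starting from the contour's start point.  A contour running
    closer than the band to the image border is rejected.
    """
    img = np.asarray(image_2ch, dtype=float)
    if img.ndim == 2:
        img = img[None]
    n_ch, h, w = img.shape

    verts = np.roll(contour.open_vertices, -contour.start_index, axis=0)
    # clockwise on screen = negative signed area in (x=col, y=row) with y down
    if _signed_area(np.vstack([verts, verts[:1]])) > 0:
        verts = np.vstack([verts[:1], verts[1:][::-1]])
    closed = np.vstack([verts, verts[:1]])

    margin = band_halfwidth_px + 1.0
    if (
        closed[:, 0].min() < margin
        or closed[:, 1].min() < margin
        or closed[:, 0].max() > h - 1 - margin
        or closed[:, 1].max() > w - 1 - margin
    ):
        raise ValueError("contour touches the image border (within the sampling band)")

    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = arc[-1]
    positions = np.arange(0.0, perimeter, step_px)
    rows = np.interp(positions, arc, closed[:, 0])
    cols = np.interp(positions, arc, closed[:, 1])

    # local tangent by central differences along the resampled closed curve
    drow = np.gradient(np.unwrap(rows, discont=np.inf))
    dcol = np.gradient(np.unwrap(cols, discont=np.inf))
    norm = np.hypot(drow, dcol)
    norm[norm == 0] = 1.0
    trow, tcol = drow / norm, dcol / norm
    # two normal candidates; pick the inward one (toward the centroid)
    nrow, ncol = -tcol, trow
    crow, ccol = closed[:-1, 0].mean(), closed[:-1, 1].mean()
    flip = (nrow * (crow - rows) + ncol * (ccol - cols)) < 0
    nrow = np.where(flip, -nrow, nrow)
    ncol = np.where(flip, -ncol, ncol)

    offsets = np.linspace(-band_halfwidth_px, band_halfwidth_px, int(4 * band_halfwidth_px) + 1)
    sample_rows = rows[None, :] + offsets[:, None] * nrow[None, :]
    sample_cols = cols[None, :] + offsets[:, None] * ncol[None, :]
    coords = np.stack([sample_rows.ravel(), sample_cols.ravel()])
    intensities = np.empty((n_ch, len(positions)))
    for ch in range(n_ch):
        vals = ndimage.map_coordinates(img[ch], coords, order=1, mode="nearest")
        intensities[ch] = vals.reshape(len(offsets), len(positions)).max(axis=0)
    return LinearProfile(positions_px=positions, intensities=intensities)


def profile_correlation(profile: LinearProfile) -> float:
    """Pearson correlation between the two channel profiles.

    Returns NaN (undefined) when either channel has zero variance.
    """
    if profile.n_channels < 2:
        raise ValueError("profile correlation needs two channels")
    a, b = profile.intensities[0], profile.intensities[1]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
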