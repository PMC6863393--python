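"""Subvolume extraction, 2D collapse, constrained alignment and measurement.

Implements the collapsed-2D subtomogram averaging route used to resolve
membrane-associated densities in noisy cellular tomograms:

1. a path is clicked along a membrane and fitted with a smoothing spline;
2. overlapping subvolumes are extracted along the path (or centred on picked
   particles), oriented so the membrane normal is the image x-axis;
3. each subvolume is collapsed (sum-projected) along the in-plane
   perpendicular axis into a 2D image;
4. the image stack is aligned and classified by constrained multi-reference
   cross-correlation, searching rotations only within a window around each
   image's orientation prior;
5. coat thickness (FWHM of the density layer on the cytosolic PM leaflet)
   and rod length (cytosolic-leaflet-to-cytosolic-leaflet peak distance) are
   measured on the class averages.

Axis convention for extracted boxes: arrays are (depth, rows, cols); the
projection in :func:`collapse_to_2d` sums over ``depth``.  For boxes
extracted along a membrane path, image columns run along the membrane normal
(cytosol toward increasing column) and rows along the path.  For particle
boxes, image rows run along the volume z-axis (the nominal rod axis) and
columns along x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage, signal

log = logging.getLogger(__name__)


@dataclass
class DensityVolume:
    """3D density map, indexed (z, y, x), higher value = more mass.

    ``voxel_nm`` is the isotropic voxel size; the world position of voxel
    (iz, iy, ix) is ``origin_nm + voxel_nm * (ix, iy, iz)`` (world
    coordinates are (x, y, z)).  Cryo-EM maps in the inverse contrast
    convention (protein dark) should be loaded with ``invert_contrast``.
    """

    voxels: np.ndarray
    voxel_nm: float
    origin_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if self.voxel_nm <= 0:
            raise ValueError("voxel_nm must be positive")
        if not np.isfinite(self.voxels).all():
            raise ValueError("volume contains non-finite values")
        self.origin_nm = np.asarray(self.origin_nm, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_to_index(self, xyz_nm: np.ndarray) -> np.ndarray:
        """Map world (x, y, z) nm coordinates to fractional (z, y, x) indices."""
        xyz = (np.atleast_2d(xyz_nm) - self.origin_nm) / self.voxel_nm
        return xyz[:, ::-1]


@dataclass
class PathSpline:
    """Chord-length parameterized cubic smoothing spline through clicked points."""

    tck: tuple
    length_nm: float
    residual_nm: float
    _arc_u: np.ndarray = field(repr=False, default=None)
    _arc_s: np.ndarray = field(repr=False, default=None)

    def point(self, s: np.ndarray) -> np.ndarray:
        """Evaluate (n, 3) positions at arc lengths ``s`` (nm)."""
        u = np.interp(np.atleast_1d(s), self._arc_s, self._arc_u)
        return np.column_stack(interpolate.splev(u, self.tck))

    def tangent(self, s: np.ndarray) -> np.ndarray:
        """Unit tangents at arc lengths ``s`` (nm)."""
        u = np.interp(np.atleast_1d(s), self._arc_s, self._arc_u)
        d = np.column_stack(interpolate.splev(u, self.tck, der=1))
        return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class BoxStack:
    """Stack of subvolumes (n, D, H, W) or collapsed images (n, H, W).

    ``priors_deg`` is the per-item in-plane rotation prior used to centre the
    constrained rotation search during alignment.  ``source`` records where
    each item came from (tomogram id, position, local tangent angle).
    """

    data: np.ndarray
    pixel_nm: float
    priors_deg: np.ndarray
    source: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.priors_deg = np.asarray(self.priors_deg, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (n, H, W) images or (n, D, H, W) subvolumes")
        if len(self.priors_deg) != len(self.data):
            raise ValueError("one prior per stack item required")
        if not np.isfinite(self.priors_deg).all():
            raise ValueError("priors must be finite")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_collapsed(self) -> bool:
        return self.data.ndim == 3


@dataclass
class ClassResult:
    """Outcome of constrained alignment and classification."""

    assignments: pd.DataFrame  # item, class_id, rotation_deg, dy_px, dx_px, score
    class_averages: np.ndarray  # (k, H, W)
    class_n: np.ndarray  # (k,)
    pixel_nm: float

    @property
    def fractions(self) -> np.ndarray:
        return self.class_n / self.class_n.sum()


@dataclass
class ProfileMeasurement:
    """1D profile with detected peaks and a derived length or thickness."""

    positions_nm: np.ndarray
    values: np.ndarray
    peak_positions_nm: np.ndarray
    length_nm: float | None
    kind: str  # "layer_thickness" | "rod_length" | "no_layer"


# ---------------------------------------------------------------------------
# Path spline fitting and box extraction
# ---------------------------------------------------------------------------


def fit_path_spline(points: np.ndarray, z_spacing_nm: float = 8.0) -> PathSpline:
    """Fit a chord-length parameterized cubic smoothing spline to clicked points.

    The smoothing factor is reduced until the maximum residual at the control
    points is at most 1 nm (falling back to interpolation).  Points are used
    in click order.  ``z_spacing_nm`` documents the click protocol; it does
    not enter the fit.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n < 3:
        raise ValueError("need >= 3 points per path")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    if chord[-1] <= 0:
        raise ValueError("path has zero length")
    u = chord / chord[-1]
    k = min(3, n - 1)
    tck = None
    residual = np.inf
    for s in [n * 1.0, n * 0.1, n * 0.01, 0.0]:
        tck_try, _ = interpolate.splprep(pts.T, u=u, s=s, k=k)
        fitted = np.column_stack(interpolate.splev(u, tck_try))
        residual = float(np.max(np.linalg.norm(fitted - pts, axis=1)))
        tck = tck_try
        if residual <= 1.0:
            break
    # arc-length table on a dense grid
    ud = np.linspace(0.0, 1.0, max(20 * n, 200))
    pd_ = np.column_stack(interpolate.splev(ud, tck))
    seg = np.linalg.norm(np.diff(pd_, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return PathSpline(
        tck=tck,
        length_nm=float(arc[-1]),
        residual_nm=residual,
        _arc_u=ud,
        _arc_s=arc,
    )


def _extract_rotated_box(
    volume: DensityVolume, center_nm: np.ndarray, axes: np.ndarray, box_px: int
) -> np.ndarray | None:
    """Trilinear resample of a cube around ``center_nm`` onto rotated axes.

    ``axes`` rows are the world-frame unit vectors of (depth, rows, cols).
    Returns None when any sample would fall outside the volume.
    """
    half = (box_px - 1) / 2.0
    offs = (np.arange(box_px) - half) * volume.voxel_nm
    dd, rr, cc = np.meshgrid(offs, offs, offs, indexing="ij")
    world = (
        center_nm
        + dd[..., None] * axes[0]
        + rr[..., None] * axes[1]
        + cc[..., None] * axes[2]
    )
    idx = volume.world_to_index(world.reshape(-1, 3)).T  # (3, m) in (z, y, x)
    shape = np.array(volume.shape)
    if (idx.min(axis=1) < 0).any() or (idx.max(axis=1) > shape - 1 + 1e-9).any():
        return None
    out = ndimage.map_coordinates(volume.voxels, idx, order=1, mode="nearest")
    return out.reshape(box_px, box_px, box_px)


def extract_boxes_along_path(
    volume: DensityVolume,
    spline: PathSpline,
    box_px: int,
    step_px: int,
    tomogram_id: str = "",
) -> BoxStack:
    """Extract overlapping boxes centred at arc-length steps along a spline.

    Boxes are resampled on a rotated grid so that the membrane normal is the
    image column axis (columns increase toward the cytosol) and rows run
    along the local path tangent; the projection depth axis is perpendicular
    to both.  The membrane normal is taken as the volume z-axis component
    orthogonal to the local tangent (paths are clicked along a membrane that
    is roughly perpendicular to z).  Because the grid itself is rotated by
    the spline-tangent angle, the residual in-plane prior of each box is 0;
    the tangent angle is kept in ``source['tangent_deg']``.

    Out-of-bounds boxes are dropped with a log entry.  ``step_px`` must be
    smaller than ``box_px`` (overlapping boxes).
    """
    if step_px >= box_px:
        raise ValueError("step_px must be smaller than box_px (overlapping boxes)")
    box_nm = box_px * volume.voxel_nm
    if spline.length_nm < box_nm:
        raise ValueError(
            f"spline length {spline.length_nm:.1f} nm shorter than one box ({box_nm:.1f} nm)"
        )
    step_nm = step_px * volume.voxel_nm
    centers_s = np.arange(box_nm / 2.0, spline.length_nm - box_nm / 2.0 + 1e-9, step_nm)
    zhat = np.array([0.0, 0.0, 1.0])
    boxes, rows = [], []
    for s in centers_s:
        c = spline.point(s)[0]
        t = spline.tangent(s)[0]
        n = zhat - np.dot(zhat, t) * t
        nn = np.linalg.norm(n)
        if nn < 1e-6:
            log.warning("path tangent parallel to z at s=%.1f nm; box skipped", s)
            continue
        n /= nn
        b = np.cross(t, n)
        box = _extract_rotated_box(volume, c, np.vstack([b, t, n]), box_px)
        if box is None:
            log.info("box at s=%.1f nm out of bounds; dropped", s)
            continue
        boxes.append(box)
        rows.append(
            {
                "tomogram_id": tomogram_id,
                "s_nm": s,
                "x_nm": c[0],
                "y_nm": c[1],
                "z_nm": c[2],
                "tangent_deg": float(np.degrees(np.arctan2(t[1], t[0]))),
            }
        )
    if not boxes:
        raise ValueError("no box could be extracted along the path")
    return BoxStack(
        data=np.stack(boxes),
        pixel_nm=volume.voxel_nm,
        priors_deg=np.zeros(len(boxes)),
        source=pd.DataFrame(rows),
    )


def extract_particle_boxes(
    volume: DensityVolume,
    picks,
    box_A: float = 444.0,
    priors_deg: np.ndarray | None = None,
) -> BoxStack:
    """Extract axis-aligned boxes centred at the A-B midpoint of each pick.

    The box edge is ``box_A`` Angstrom (444 A default), converted to pixels
    with the volume's voxel size.  Subvolumes are arranged so that collapse
    projects along the volume y-axis, rows run along z (flipped so the ER
    side is up in the image) and columns along x.  The per-item prior is the
    in-plane rotation from the 4-point geometry (computed here unless
    supplied).  Out-of-bounds picks are dropped with a log entry.
    """
    from .particles import particle_axis_angle

    box_px = int(round(box_A / (10.0 * volume.voxel_nm)))
    if box_px < 2:
        raise ValueError("box size below 2 px")
    half_lo = box_px // 2
    half_hi = box_px - half_lo
    boxes, priors, rows = [], [], []
    for i, pick in enumerate(picks):
        center = 0.5 * (pick.A + pick.B)
        czyx = np.round(volume.world_to_index(center)[0]).astype(int)
        lo = czyx - half_lo
        hi = czyx + half_hi
        if (lo < 0).any() or (hi > np.array(volume.shape)).any():
            log.info("pick %s out of bounds; dropped", pick.particle_id)
            continue
        sub = volume.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        # (z, y, x) -> (depth=y, rows=z flipped so ER/cytosol up, cols=x)
        boxes.append(sub.transpose(1, 0, 2)[:, ::-1, :])
        if priors_deg is not None:
            priors.append(priors_deg[i])
        else:
            priors.append(particle_axis_angle(pick).inplane_rotation_deg)
        rows.append(
            {
                "tomogram_id": pick.tomogram_id,
                "particle_id": pick.particle_id,
                "x_nm": center[0],
                "y_nm": center[1],
                "z_nm": center[2],
            }
        )
    if not boxes:
        raise ValueError("no pick yielded an in-bounds box")
    return BoxStack(
        data=np.stack(boxes),
        pixel_nm=volume.voxel_nm,
        priors_deg=np.asarray(priors, dtype=float),
        source=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Collapse and constrained alignment
# ---------------------------------------------------------------------------


def collapse_to_2d(subvolume: np.ndarray, prior_deg: float = 0.0) -> np.ndarray:
    """Sum-project a (D, H, W) subvolume along its depth axis.

    Total intensity is conserved: ``image.sum() == subvolume.sum()``.  The
    prior is untouched by the projection (the depth axis is the in-plane
    perpendicular); it is threaded through for bookkeeping.
    """
    sub = np.asarray(subvolume)
    if sub.ndim != 3:
        raise ValueError("subvolume must be 3D (depth, rows, cols)")
    return sub.sum(axis=0)


def collapse_stack(stack: BoxStack) -> BoxStack:
    """Collapse every subvolume in a stack to a 2D image."""
    if stack.is_collapsed:
        return stack
    return BoxStack(
        data=stack.data.sum(axis=1),
        pixel_nm=stack.pixel_nm,
        priors_deg=stack.priors_deg.copy(),
        source=stack.source.copy(),
    )


def _lowpass(img: np.ndarray, pixel_nm: float, lowpass_nm: float | None) -> np.ndarray:
    if not lowpass_nm or lowpass_nm <= 0:
        return img
    # Gaussian band limit with FWHM equal to the cutoff wavelength
    sigma_px = lowpass_nm / (2.3548 * pixel_nm)
    return ndimage.gaussian_filter(img, sigma_px)


def _normalize(img: np.ndarray) -> np.ndarray:
    out = img - img.mean()
    norm = np.linalg.norm(out)
    return out / norm if norm > 0 else out


def _best_shift_score(
    ref_ft_conj: np.ndarray, img: np.ndarray, max_shift: int
) -> tuple[float, int, int]:
    """Peak normalized cross-correlation over integer shifts within a window."""
    corr = np.fft.ifft2(np.fft.fft2(img) * ref_ft_conj).real
    if max_shift == 0:
        return float(corr[0, 0]), 0, 0
    window = np.arange(-max_shift, max_shift + 1)
    sub = corr[np.ix_(window, window)]  # negative indices wrap
    k = int(np.argmax(sub))
    dy = window[k // sub.shape[1]]
    dx = window[k % sub.shape[1]]
    return float(sub.ravel()[k]), int(dy), int(dx)


def align_and_classify(
    stack: BoxStack,
    k: int,
    rot_window_deg: float = 15.0,
    max_shift_px: int = 4,
    lowpass_nm: float | None = 2.0,
    n_iter: int = 10,
    seed: int = 0,
    rot_step_deg: float = 1.0,
) -> ClassResult:
    """Constrained multi-reference alignment and hard classification.

    References are initialized from a seeded random partition.  In each
    iteration every image is compared against every reference over rotations
    within ``prior +/- rot_window_deg`` (1 degree steps) and integer shifts
    within ``max_shift_px``, scored by normalized cross-correlation after
    band-limiting to ``lowpass_nm``; the image joins its best class and the
    references are rebuilt as aligned within-class means.  Iteration stops
    after ``n_iter`` rounds or when fewer than 1% of assignments change.
    With ``k=1`` this is constrained global averaging.  An emptied class is
    reseeded from the worst-scoring images.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    work = collapse_stack(stack)
    imgs = work.data
    n = len(imgs)
    if n == 0:
        raise ValueError("empty stack")
    filt = np.stack([_normalize(_lowpass(im, work.pixel_nm, lowpass_nm)) for im in imgs])

    rng = np.random.default_rng(seed)
    labels = rng.permutation(np.arange(n) % k)
    rot = np.zeros(n)
    dy = np.zeros(n, dtype=int)
    dx = np.zeros(n, dtype=int)
    scores = np.zeros(n)
    rotations = np.arange(-rot_window_deg, rot_window_deg + 1e-9, rot_step_deg)

    def aligned_raw(i: int) -> np.ndarray:
        out = imgs[i]
        if abs(rot[i]) > 1e-12:
            out = ndimage.rotate(out, -rot[i], reshape=False, order=1)
        if dy[i] or dx[i]:
            out = np.roll(out, (-dy[i], -dx[i]), axis=(0, 1))
        return out

    def build_refs() -> np.ndarray:
        refs = np.zeros((k,) + imgs.shape[1:])
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members):
                refs[c] = np.mean([aligned_raw(i) for i in members], axis=0)
        return refs

    refs = build_refs()
    for _ in range(n_iter):
        ref_ft = [
            np.conj(np.fft.fft2(_normalize(_lowpass(r, work.pixel_nm, lowpass_nm))))
            for r in refs
        ]
        new_labels = labels.copy()
        for i in range(n):
            best = (-np.inf, 0, 0.0, 0, 0)
            for r_off in rotations:
                r_tot = work.priors_deg[i] + r_off
                im = filt[i]
                if abs(r_tot) > 1e-12:
                    im = _normalize(ndimage.rotate(filt[i], -r_tot, reshape=False, order=1))
                for c in range(k):
                    sc, sy, sx = _best_shift_score(ref_ft[c], im, max_shift_px)
                    if sc > best[0]:
                        best = (sc, c, r_tot, sy, sx)
            scores[i], new_labels[i], rot[i], dy[i], dx[i] = best
        # reseed emptied classes from the worst-scoring images
        for c in range(k):
            if not (new_labels == c).any():
                worst = int(np.argmin(scores))
                log.info("class %d emptied; reseeded from item %d", c, worst)
                new_labels[worst] = c
                scores[worst] = np.inf
        changed = np.count_nonzero(new_labels != labels)
        labels = new_labels
        refs = build_refs()
        if changed < max(1, int(0.01 * n)):
            break

    window_ok = np.abs(rot - stack.priors_deg) <= rot_window_deg + 1e-9
    if not window_ok.all():  # pragma: no cover - guarded by construction
        raise AssertionError("refined rotation escaped the prior window")
    assignments = pd.DataFrame(
        {
            "item": np.arange(n),
            "class_id": labels,
            "rotation_deg": rot,
            "dy_px": dy,
            "dx_px": dx,
            "score": scores,
        }
    )
    class_n = np.array([np.count_nonzero(labels == c) for c in range(k)])
    return ClassResult(
        assignments=assignments,
        class_averages=refs,
        class_n=class_n,
        pixel_nm=work.pixel_nm,
    )


# ---------------------------------------------------------------------------
# Measurements on class averages
# ---------------------------------------------------------------------------


def _fwhm_span(x: np.ndarray, y: np.ndarray, peak_idx: int, half: float) -> tuple[float, float]:
    """Interpolated crossings of ``half`` on both sides of a peak."""
    left = x[0]
    for j in range(peak_idx, 0, -1):
        if y[j - 1] < half <= y[j]:
            frac = (half - y[j - 1]) / (y[j] - y[j - 1])
            left = x[j - 1] + frac * (x[j] - x[j - 1])
            break
    right = x[-1]
    for j in range(peak_idx, len(y) - 1):
        if y[j + 1] < half <= y[j]:
            frac = (y[j] - half) / (y[j] - y[j + 1])
            right = x[j] + frac * (x[j + 1] - x[j])
            break
    return left, right


def layer_thickness(
    class_average: np.ndarray,
    pixel_nm: float,
    membrane_axis: int = 0,
    cytosol_high: bool = True,
    noise_sd: float | None = None,
) -> ProfileMeasurement:
    """Thickness of the extra density layer on the cytosolic PM leaflet.

    The class average is averaged along the membrane direction to a 1D
    profile across the membrane.  The bilayer is located as the most
    prominent peak plus its partner peak 2.5-6 nm away; the cytosolic leaflet
    is the one on the cytosol side (increasing coordinate when
    ``cytosol_high``).  The layer is the density region on the cytosolic side
    of that leaflet: thickness is its full width at half maximum above the
    local background.  Returns kind ``"no_layer"`` when no peak rises above
    background + 3 * noise SD (noise estimated from the profile tail when not
    given).
    """
    img = np.asarray(class_average, dtype=float)
    profile = img.mean(axis=membrane_axis)
    if not cytosol_high:
        profile = profile[::-1]
    x = np.arange(len(profile)) * pixel_nm

    pk, props = signal.find_peaks(profile, prominence=0.05 * np.ptp(profile))
    if len(pk) == 0:
        raise ValueError("no peaks found in membrane-normal profile")
    main = pk[int(np.argmax(props["prominences"]))]
    partners = [
        q for q in pk if q != main and 2.5 <= abs(x[q] - x[main]) <= 6.0
    ]
    if partners:
        partner = max(partners, key=lambda q: profile[q])
        cyt = max(main, partner)
    else:
        cyt = main

    start = cyt + 1
    while start < len(profile) - 1 and profile[start + 1] < profile[start]:
        start += 1  # walk down to the first minimum past the cytosolic leaflet
    search_end = min(len(profile), start + int(round(15.0 / pixel_nm)))
    region = profile[start:search_end]
    if len(region) < 3:
        raise ValueError("profile too short on the cytosolic side")
    background = float(np.median(np.sort(region)[: max(3, len(region) // 2)]))
    if noise_sd is None:
        resid = region - ndimage.uniform_filter1d(region, 5)
        noise_sd = float(1.4826 * np.median(np.abs(resid - np.median(resid)))) or 1e-12
    # the layer must be an internal maximum of the search region -- a profile
    # that merely rises toward the far end (e.g. the partner membrane's tail)
    # is not a layer
    cand, _ = signal.find_peaks(region, height=background + 3.0 * noise_sd)
    cand = cand[cand < len(region) - 2]
    if len(cand) == 0:
        return ProfileMeasurement(
            positions_nm=x,
            values=profile,
            peak_positions_nm=x[pk],
            length_nm=None,
            kind="no_layer",
        )
    peak_rel = int(cand[np.argmax(region[cand])])
    peak_val = float(region[peak_rel])
    half = background + 0.5 * (peak_val - background)
    left, right = _fwhm_span(x[start:search_end], region, peak_rel, half)
    return ProfileMeasurement(
        positions_nm=x,
        values=profile,
        peak_positions_nm=np.array([x[cyt], x[start + peak_rel]]),
        length_nm=float(right - left),
        kind="layer_thickness",
    )


def rod_length(
    class_average: np.ndarray,
    pixel_nm: float,
    axis: int = 0,
    profile_width_px: int = 15,
    center_col: int | None = None,
) -> ProfileMeasurement:
    """Rod length from a line profile along the particle's major axis.

    The profile runs along ``axis`` and is averaged over ``profile_width_px``
    perpendicular pixels centred on the rod (the particle sits at the box
    centre unless ``center_col`` is given).  The length is the distance
    between the cytosolic-leaflet peaks of PM and ER: among the detected
    peaks, those below/above the span midpoint are split into the two
    membranes and the innermost peak of each side is taken.
    """
    img = np.asarray(class_average, dtype=float)
    if axis == 1:
        img = img.T
    ncols = img.shape[1]
    c = ncols // 2 if center_col is None else int(center_col)
    half = profile_width_px // 2
    lo, hi = max(0, c - half), min(ncols, c + half + 1)
    profile = img[:, lo:hi].mean(axis=1)
    x = np.arange(len(profile)) * pixel_nm

    smoothed = ndimage.gaussian_filter1d(profile, 1.0)
    pk, _ = signal.find_peaks(smoothed, prominence=0.1 * np.ptp(smoothed))
    if len(pk) < 2:
        raise ValueError("fewer than 2 leaflet peaks detected in rod profile")
    mid = 0.5 * (x[pk[0]] + x[pk[-1]])
    lower = [q for q in pk if x[q] < mid]
    upper = [q for q in pk if x[q] >= mid]
    if not lower or not upper:
        raise ValueError("could not split leaflet peaks across the intermembrane span")
    p_lo = max(lower)  # innermost (cytosolic) leaflet of the lower membrane
    p_hi = min(upper)  # innermost leaflet of the upper membrane
    length = float(x[p_hi] - x[p_lo])
    if length <= 0:
        raise ValueError("non-positive rod length")
    return ProfileMeasurement(
        positions_nm=x,
        values=profile,
        peak_positions_nm=x[pk],
        length_nm=length,
        kind="rod_length",
    )
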