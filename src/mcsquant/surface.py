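"""PM surface reconstruction and ER-PM intermembrane distance statistics.

One contact site is described by two clicked point clouds, one along the
cytosolic leaflet of the plasma membrane (PM) and one along the cytosolic
leaflet of the cortical ER. The PM cloud is reduced to a smooth surface model
(total-least-squares plane fit, rotation of the cloud into the plane frame,
biharmonic spline interpolation onto a regular 20 x 20 grid) and the distance
of every ER point to the triangulated surface yields per-site statistics:
mean, SD, minimum and maximum intermembrane distance in nm.

All coordinates are in nanometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from trimesh.proximity import closest_point_naive


class DegenerateCloudError(ValueError):
    """Raised when a point cloud cannot support a plane or surface fit."""


@dataclass
class MembranePointCloud:
    """Clicked 3D points (nm) for one membrane at one contact site."""

    site_id: str
    membrane: str  # "PM" or "ER"
    points: np.ndarray  # (n, 3) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError(f"non-finite coordinates in site {self.site_id!r}")
        if self.membrane not in ("PM", "ER"):
            raise ValueError("membrane must be 'PM' or 'ER'")

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, rotation: np.ndarray, origin: np.ndarray) -> "MembranePointCloud":
        """Return a copy with points mapped by p -> R @ (p - origin)."""
        pts = (self.points - origin) @ np.asarray(rotation).T
        return MembranePointCloud(self.site_id, self.membrane, pts)


@dataclass
class PlaneFit:
    """Total-least-squares plane through a point cloud."""

    centroid: np.ndarray  # (3,)
    normal: np.ndarray  # (3,) unit vector, z-component >= 0
    rms_residual_nm: float


@dataclass
class SurfaceModel:
    """Biharmonic spline surface on a regular grid, in the rotated plane frame.

    ``rotation`` maps world coordinates into the plane frame (the fitted
    plane normal becomes +z) about ``origin``.  ``grid_x``/``grid_y`` span the
    bounding box of the rotated PM cloud; ``grid_z`` holds the interpolated
    heights on the ``n_grid x n_grid`` lattice.
    """

    rotation: np.ndarray  # (3, 3) world -> plane frame
    origin: np.ndarray  # (3,) rotation centre (plane-fit centroid)
    grid_x: np.ndarray  # (n_grid,)
    grid_y: np.ndarray  # (n_grid,)
    grid_z: np.ndarray  # (n_grid, n_grid), grid_z[i, j] at (grid_x[j], grid_y[i])
    centers_xy: np.ndarray = field(repr=False, default=None)  # RBF centres
    weights: np.ndarray = field(repr=False, default=None)  # RBF weights
    affine: np.ndarray = field(repr=False, default=None)  # (3,) constant, x, y

    def evaluate(self, xy: np.ndarray) -> np.ndarray:
        """Evaluate the spline height at (n, 2) plane-frame locations."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        r = np.linalg.norm(xy[:, None, :] - self.centers_xy[None, :, :], axis=-1)
        return _greens(r) @ self.weights + self.affine[0] + xy @ self.affine[1:]

    def mesh(self) -> trimesh.Trimesh:
        """Triangulate the grid (two triangles per cell, (i,j)->(i+1,j+1) diagonal)."""
        n = len(self.grid_x)
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        vertices = np.column_stack([gx.ravel(), gy.ravel(), self.grid_z.ravel()])
        idx = np.arange(n * n).reshape(n, n)
        a = idx[:-1, :-1].ravel()  # (i, j)
        b = idx[:-1, 1:].ravel()  # (i, j+1)
        c = idx[1:, :-1].ravel()  # (i+1, j)
        d = idx[1:, 1:].ravel()  # (i+1, j+1)
        faces = np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])
        return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


@dataclass
class DistanceStats:
    """Per-site ER-to-PM-surface distance statistics (nm)."""

    site_id: str
    n_er_points: int
    mean_nm: float
    sd_nm: float
    min_nm: float
    max_nm: float
    n_boundary_flagged: int = 0


def fit_plane(cloud: MembranePointCloud | np.ndarray) -> PlaneFit:
    """Fit a total-least-squares plane: normal = direction of least variance.

    The normal is oriented so its z-component is >= 0 (ties broken by y, then
    x component).  Collinear or degenerate clouds raise
    :class:`DegenerateCloudError` naming the site.
    """
    if isinstance(cloud, MembranePointCloud):
        pts, label = cloud.points, cloud.site_id
    else:
        pts, label = np.asarray(cloud, dtype=float), "<array>"
    if len(pts) < 3:
        raise DegenerateCloudError(f"site {label!r}: need >= 3 points for a plane fit")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centered cloud: the right singular vector with the smallest
    # singular value spans the direction of least variance.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(s[0], 1.0)
    if s[1] / scale < 1e-10:
        raise DegenerateCloudError(f"site {label!r}: points are collinear or coincident")
    normal = vt[2]
    for comp in (2, 1, 0):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(centroid=centroid, normal=normal, rms_residual_nm=rms)


def rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Proper rotation matrix mapping ``normal`` onto +z (Rodrigues)."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(n, z))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        # 180 degrees about x
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(n, z)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def rotate_to_plane(
    cloud: MembranePointCloud, plane: PlaneFit
) -> tuple[MembranePointCloud, np.ndarray]:
    """Rotate a cloud about the plane centroid so the plane normal is +z.

    Returns the rotated cloud and the (3, 3) rotation matrix (world -> plane
    frame); applying the transpose and re-adding the centroid recovers the
    input to machine precision.
    """
    rot = rotation_to_z(plane.normal)
    return cloud.transformed(rot, plane.centroid), rot


def _greens(r: np.ndarray) -> np.ndarray:
    """Biharmonic Green's function g(r) = r^2 (ln r - 1), with g(0) = 0."""
    out = np.zeros_like(r)
    mask = r > 0
    rm = r[mask]
    out[mask] = rm * rm * (np.log(rm) - 1.0)
    return out


def _dedupe_xy(xy: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average heights at duplicate (x, y) locations (exact match at 1e-9)."""
    key = np.round(xy / 1e-9).astype(np.int64)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if (counts == 1).all():
        return xy, h
    n = counts.size
    xs = np.zeros(n)
    ys = np.zeros(n)
    hs = np.zeros(n)
    np.add.at(xs, inverse, xy[:, 0])
    np.add.at(ys, inverse, xy[:, 1])
    np.add.at(hs, inverse, h)
    return np.column_stack([xs / counts, ys / counts]), hs / counts


def biharmonic_surface(
    points_xy: np.ndarray,
    heights: np.ndarray,
    n_grid: int = 20,
    ridge: float = 1e-8,
    rotation: np.ndarray | None = None,
    origin: np.ndarray | None = None,
) -> SurfaceModel:
    """Biharmonic (thin-plate-like) radial-basis interpolation on a regular grid.

    Solves the dense augmented system

        [ G + ridge*I   P ] [w]   [h]
        [ P^T           0 ] [a] = [0]

    with G_ij = g(|x_i - x_j|), g(r) = r^2 (ln r - 1), and P = [1, x, y].
    The affine block makes the interpolant reproduce constants and planes
    exactly while the radial part absorbs the curvature; the ridge term keeps
    the system well conditioned for near-duplicate clicks.  The surface is
    evaluated on a regular ``n_grid x n_grid`` lattice over the data bounding
    box.
    """
    xy = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    h = np.asarray(heights, dtype=float).ravel()
    if len(xy) != len(h):
        raise ValueError("points_xy and heights length mismatch")
    xy, h = _dedupe_xy(xy, h)
    m = len(xy)
    if m < 4:
        raise DegenerateCloudError(f"need >= 4 unique (x, y) locations, got {m}")
    r = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    G = _greens(r) + ridge * np.eye(m)
    P = np.column_stack([np.ones(m), xy])
    A = np.zeros((m + 3, m + 3))
    A[:m, :m] = G
    A[:m, m:] = P
    A[m:, :m] = P.T
    rhs = np.concatenate([h, np.zeros(3)])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological input
        raise DegenerateCloudError(f"singular biharmonic system: {exc}") from exc
    weights, affine = sol[:m], sol[m:]

    grid_x = np.linspace(xy[:, 0].min(), xy[:, 0].max(), n_grid)
    grid_y = np.linspace(xy[:, 1].min(), xy[:, 1].max(), n_grid)
    model = SurfaceModel(
        rotation=np.eye(3) if rotation is None else np.asarray(rotation, dtype=float),
        origin=np.zeros(3) if origin is None else np.asarray(origin, dtype=float),
        grid_x=grid_x,
        grid_y=grid_y,
        grid_z=np.empty((n_grid, n_grid)),
        centers_xy=xy,
        weights=weights,
        affine=affine,
    )
    gx, gy = np.meshgrid(grid_x, grid_y)
    model.grid_z = model.evaluate(np.column_stack([gx.ravel(), gy.ravel()])).reshape(
        n_grid, n_grid
    )
    return model


def principal_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Covariant plane frame: rows (e1, e2, n) from the cloud's SVD basis.

    e1 is the in-plane principal axis and n the least-variance direction, so
    the frame (and hence any axis-aligned grid built in it) rotates rigidly
    with the data; unsigned distances to a grid surface built in this frame
    are rigid-motion invariant.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] / max(s[0], 1.0) < 1e-10:
        raise DegenerateCloudError("points are collinear or coincident")
    e1, n = vt[0], vt[2]
    e2 = np.cross(n, e1)
    return np.vstack([e1, e2, n]), centroid


def fit_surface(pm: MembranePointCloud, n_grid: int = 20) -> SurfaceModel:
    """Full PM surface model: plane fit, rotation, biharmonic grid.

    The rotation into the plane frame uses the cloud's principal axes (the
    plane normal becomes +z, the in-plane principal axis +x), which makes
    the grid bounding box -- and therefore the distance statistics --
    invariant under rigid motions of the input.
    """
    if len(pm) < 4:
        raise DegenerateCloudError(f"site {pm.site_id!r}: need >= 4 PM points")
    try:
        rot, centroid = principal_frame(pm.points)
    except DegenerateCloudError as exc:
        raise DegenerateCloudError(f"site {pm.site_id!r}: {exc}") from exc
    rotated = pm.transformed(rot, centroid)
    return biharmonic_surface(
        rotated.points[:, :2],
        rotated.points[:, 2],
        n_grid=n_grid,
        rotation=rot,
        origin=centroid,
    )


def point_mesh_distances(
    surface: SurfaceModel, points_world: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance of world-frame points to the triangulated surface grid.

    Returns (distances, boundary_flags); a point is flagged when its nearest
    mesh point lies on the outer boundary of the grid, i.e. the distance is an
    extrapolation beyond the clicked PM footprint.
    """
    pts = np.atleast_2d(np.asarray(points_world, dtype=float))
    local = (pts - surface.origin) @ surface.rotation.T
    mesh = surface.mesh()
    closest, dist, _ = closest_point_naive(mesh, local)
    eps = 1e-9
    on_edge = (
        (closest[:, 0] <= surface.grid_x[0] + eps)
        | (closest[:, 0] >= surface.grid_x[-1] - eps)
        | (closest[:, 1] <= surface.grid_y[0] + eps)
        | (closest[:, 1] >= surface.grid_y[-1] - eps)
    )
    return dist, on_edge


def site_distance_stats(
    pm: MembranePointCloud, er: MembranePointCloud, n_grid: int = 20
) -> DistanceStats:
    """ER-to-PM-surface distance statistics for one contact site.

    Fits the PM surface model, takes for every ER point the minimum Euclidean
    point-to-triangle distance over the triangulated grid, and returns mean,
    SD (n-1 denominator; 0 for a single point), min and max.  ER points whose
    nearest mesh point lies on the grid boundary are counted but flagged.
    """
    if pm.site_id != er.site_id:
        raise ValueError(f"site mismatch: {pm.site_id!r} vs {er.site_id!r}")
    if len(er) < 1:
        raise ValueError(f"site {er.site_id!r}: ER cloud is empty")
    surf = fit_surface(pm, n_grid=n_grid)
    dist, flagged = point_mesh_distances(surf, er.points)
    sd = float(np.std(dist, ddof=1)) if len(dist) > 1 else 0.0
    return DistanceStats(
        site_id=pm.site_id,
        n_er_points=len(dist),
        mean_nm=float(np.mean(dist)),
        sd_nm=sd,
        min_nm=float(np.min(dist)),
        max_nm=float(np.max(dist)),
        n_boundary_flagged=int(np.count_nonzero(flagged)),
    )


def buckle_distance(pm: MembranePointCloud | SurfaceModel, er_points: np.ndarray) -> float:
    """Shortest ER-to-PM distance at a site (automated buckle measurement).

    Minimum over ER points of the point-to-mesh distance; equals the ``min``
    field of :func:`site_distance_stats` on the same inputs.
    """
    surf = pm if isinstance(pm, SurfaceModel) else fit_surface(pm)
    dist, _ = point_mesh_distances(surf, np.atleast_2d(er_points))
    return float(np.min(dist))
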