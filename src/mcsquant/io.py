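"""File I/O: MRC volumes and masks, point models, picks, plates, images.

Formats
-------
* Density volumes and segmentation masks: MRC/CCP4 maps (via gemmi); the
  voxel size in nm is carried in the map header (stored in Angstrom).
* Clicked point models: whitespace-separated text records
  ``object contour x y z`` with coordinates in nm, as exported from tomogram
  annotation tools (object = membrane, contour = site).
* Particle picks: text records ``particle_id label x y z`` with one A/B/C/D
  row quartet per particle.
* Colony plates: CSV with columns ``plate,row,col,gene,size``.
* Fluorescence images: TIFF (channel-first for multichannel stacks).
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import tifffile

from .collapse import DensityVolume
from .cortex import CortexContour
from .coverage import VoxelMask
from .particles import ParticlePick
from .surface import MembranePointCloud

# ---------------------------------------------------------------------------
# MRC volumes
# ---------------------------------------------------------------------------


def write_mrc(path: str | Path, volume: DensityVolume | VoxelMask) -> None:
    """Write a volume or mask as an MRC/CCP4 map (voxel size in the header)."""
    data = volume.voxels if isinstance(volume, DensityVolume) else volume.values
    nz, ny, nx = data.shape
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(nx, ny, nz)
    arr = np.array(m.grid, copy=False)
    arr[...] = np.ascontiguousarray(data.transpose(2, 1, 0)).astype(np.float32)
    a = 10.0 * volume.voxel_nm  # nm -> Angstrom
    m.grid.set_unit_cell(gemmi.UnitCell(nx * a, ny * a, nz * a, 90.0, 90.0, 90.0))
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path, invert_contrast: bool = False) -> DensityVolume:
    """Read an MRC/CCP4 map as a (z, y, x) density volume.

    ``invert_contrast`` negates the data for maps in the cryo-EM convention
    (protein dark) so that higher value = more mass throughout the package.
    """
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=False).transpose(2, 1, 0).astype(float)
    spacing = m.grid.spacing  # Angstrom per voxel, per axis
    if abs(spacing[0] - spacing[1]) > 1e-6 or abs(spacing[0] - spacing[2]) > 1e-6:
        raise ValueError(f"anisotropic voxels not supported: {spacing}")
    if invert_contrast:
        arr = -arr
    return DensityVolume(voxels=arr, voxel_nm=spacing[0] / 10.0)


def read_mrc_mask(path: str | Path, threshold: float = 0.5) -> VoxelMask:
    """Read a segmentation mask map, binarizing at ``threshold``."""
    vol = read_mrc(path)
    return VoxelMask(values=(vol.voxels >= threshold).astype(np.uint8), voxel_nm=vol.voxel_nm)


# ---------------------------------------------------------------------------
# Point models and picks
# ---------------------------------------------------------------------------


def write_point_model(path: str | Path, clouds: list[MembranePointCloud]) -> None:
    """Write clouds as ``object contour x y z`` text (coordinates in nm).

    Objects are membrane labels (1 = PM, 2 = ER), contours number the sites
    in order of first appearance.
    """
    site_ids: dict[str, int] = {}
    lines = []
    for cloud in clouds:
        contour = site_ids.setdefault(cloud.site_id, len(site_ids) + 1)
        obj = 1 if cloud.membrane == "PM" else 2
        for x, y, z in cloud.points:
            lines.append(f"{obj} {contour} {x:.4f} {y:.4f} {z:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_point_model(path: str | Path) -> list[MembranePointCloud]:
    """Read an ``object contour x y z`` text model into per-site clouds."""
    raw = np.loadtxt(str(path), ndmin=2)
    if raw.shape[1] != 5:
        raise ValueError("point model must have 5 columns: object contour x y z")
    clouds = []
    for obj in np.unique(raw[:, 0]).astype(int):
        membrane = "PM" if obj == 1 else "ER"
        sub = raw[raw[:, 0] == obj]
        for contour in np.unique(sub[:, 1]).astype(int):
            pts = sub[sub[:, 1] == contour, 2:5]
            clouds.append(MembranePointCloud(f"site{contour:03d}", membrane, pts))
    return clouds


def write_picks(path: str | Path, picks: list[ParticlePick]) -> None:
    """Write picks as ``particle_id label x y z`` rows (A/B/C/D per particle)."""
    lines = []
    for p in picks:
        for label in "ABCD":
            x, y, z = getattr(p, label)
            lines.append(f"{p.particle_id} {label} {x:.4f} {y:.4f} {z:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_picks(path: str | Path) -> list[ParticlePick]:
    """Read a pick text file (4 labelled rows per particle)."""
    table: dict[str, dict[str, np.ndarray]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        pid, label = parts[0], parts[1].upper()
        if label not in "ABCD":
            raise ValueError(f"unknown point label {label!r} for particle {pid!r}")
        if pid not in table:
            table[pid] = {}
            order.append(pid)
        table[pid][label] = np.array(parts[2:5], dtype=float)
    picks = []
    for pid in order:
        pts = table[pid]
        missing = set("ABCD") - set(pts)
        if missing:
            raise ValueError(f"particle {pid!r} missing points: {sorted(missing)}")
        picks.append(ParticlePick(pid, pts["A"], pts["B"], pts["C"], pts["D"]))
    return picks


# ---------------------------------------------------------------------------
# Plates, images, contours
# ---------------------------------------------------------------------------


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    from .sga import _check_plate_frame

    _check_plate_frame(df)
    return df


def write_plate_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_contour_csv(path: str | Path, contour: CortexContour) -> None:
    pd.DataFrame(
        {"row": contour.vertices[:, 0], "col": contour.vertices[:, 1]}
    ).to_csv(path, index=False)


def read_contour_csv(path: str | Path, start_index: int = 0) -> CortexContour:
    df = pd.read_csv(path)
    return CortexContour(df[["row", "col"]].to_numpy(dtype=float), start_index=start_index)


def write_mesh_obj(path: str | Path, mesh) -> None:
    """Export a surface mesh for inspection (OBJ)."""
    mesh.export(str(path))
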