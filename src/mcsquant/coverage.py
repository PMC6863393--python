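"""Coat-layer extent as a volume ratio from voxel segmentation masks.

The extent of the density layer coating the PM at a contact site is
quantified as the ratio of the layer's segmented volume to the volume of the
cortical ER in the same tomogram.  Masks are produced upstream (interactive
segmentation on real data; thresholding on synthetic volumes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .collapse import DensityVolume


@dataclass
class VoxelMask:
    """Binary 3D mask aligned to a density volume."""

    values: np.ndarray  # (z, y, x) of {0, 1}
    voxel_nm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        if self.voxel_nm <= 0:
            raise ValueError("voxel_nm must be positive")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def volume_nm3(self) -> float:
        return float(np.count_nonzero(self.values)) * self.voxel_nm**3


@dataclass
class CoverageResult:
    layer_volume_nm3: float
    cer_volume_nm3: float
    ratio: float


def volume_ratio(layer: VoxelMask, cer: VoxelMask) -> CoverageResult:
    """Ratio of coat-layer volume to cER volume.

    Both masks must share shape and voxel size; an empty cER mask makes the
    ratio undefined and raises.
    """
    if layer.values.shape != cer.values.shape:
        raise ValueError("layer and cER masks must share a shape")
    if abs(layer.voxel_nm - cer.voxel_nm) > 1e-12:
        raise ValueError("layer and cER masks must share a voxel size")
    cer_vol = cer.volume_nm3
    if cer_vol == 0:
        raise ValueError("empty cER mask: coverage ratio undefined")
    layer_vol = layer.volume_nm3
    return CoverageResult(
        layer_volume_nm3=layer_vol,
        cer_volume_nm3=cer_vol,
        ratio=layer_vol / cer_vol,
    )


def threshold_mask(
    volume: DensityVolume, level: float, z_range_nm: tuple | None = None
) -> VoxelMask:
    """Threshold helper for building masks from synthetic volumes.

    Voxels with density >= ``level`` are set; ``z_range_nm`` optionally
    restricts the mask to a z slab (e.g. the region between the membranes
    when masking a rendered coat at half its amplitude).
    """
    values = (volume.voxels >= level).astype(np.uint8)
    if z_range_nm is not None:
        z = volume.origin_nm[2] + np.arange(volume.shape[0]) * volume.voxel_nm
        keep = (z >= z_range_nm[0]) & (z <= z_range_nm[1])
        values[~keep] = 0
    return VoxelMask(values=values, voxel_nm=volume.voxel_nm)
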