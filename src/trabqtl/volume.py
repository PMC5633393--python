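"""Binary voxel volumes, ROI selection and volume I/O.

The measurement substrate is a 3D binary image of segmented trabecular
bone with an isotropic voxel edge length in micrometres.  Axis 0 is the
bone (axial) axis along which the region of interest is selected as a
slab below a user-supplied reference slice (the growth-plate slice).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelVolume", "RoiSpec", "select_roi", "read_volume", "write_volume"]


@dataclass
class VoxelVolume:
    """A 3D binary image (foreground = bone) with isotropic voxel size.

    Parameters
    ----------
    data : ndarray of bool, shape (nz, ny, nx)
        Foreground mask.  Integer arrays containing only {0, 1} or
        {0, 255} are accepted and cast.
    voxel_um : float
        Isotropic voxel edge length in micrometres.  Anisotropic voxels
        are not supported.
    meta : dict
        Free-form metadata (e.g. analytic ground truth for phantoms).
    """

    data: np.ndarray
    voxel_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={data.ndim}")
        if data.dtype != bool:
            vals = np.unique(data)
            if not np.all(np.isin(vals, (0, 1, 255))):
                raise ValueError("volume is not binary")
            data = data > 0
        self.data = data
        if not (np.isfinite(self.voxel_um) and self.voxel_um > 0):
            raise ValueError(f"voxel_um must be positive, got {self.voxel_um}")
        if max(data.shape) < 8:
            raise ValueError("at least one dimension must be >= 8 voxels")

    # -- convenience ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_mm(self) -> float:
        return self.voxel_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_mm**3

    @property
    def tv_mm3(self) -> float:
        """Total volume of the image domain in mm^3."""
        return self.data.size * self.voxel_volume_mm3

    @property
    def bone_voxels(self) -> int:
        return int(self.data.sum())

    def complement(self) -> "VoxelVolume":
        return VoxelVolume(~self.data, self.voxel_um, dict(self.meta))


@dataclass(frozen=True)
class RoiSpec:
    """Axial slab ROI: ``[reference + offset, reference + offset + width)``.

    ``reference_slice_index`` stands for the growth-plate slice and is
    supplied by the user; the offset and width are in millimetres along
    axis 0.
    """

    reference_slice_index: int = 0
    offset_mm: float = 0.0
    width_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.offset_mm < 0:
            raise ValueError("offset_mm must be >= 0")
        if self.width_mm <= 0:
            raise ValueError("width_mm must be > 0")


def select_roi(volume: VoxelVolume, roi: RoiSpec) -> VoxelVolume:
    """Extract the ROI slab along axis 0, preserving voxel metadata.

    Slice indices are 0-based and the slab is half-open.
    """
    vpm = 1000.0 / volume.voxel_um  # voxels per mm
    start = roi.reference_slice_index + int(round(roi.offset_mm * vpm))
    n = int(round(roi.width_mm * vpm))
    stop = start + n
    nz = volume.shape[0]
    if start < 0 or stop > nz:
        missing = max(0, -start) + max(0, stop - nz)
        raise ValueError(
            f"ROI slab [{start}, {stop}) exceeds volume extent [0, {nz}); "
            f"missing {missing * volume.voxel_mm:.3f} mm"
        )
    return VoxelVolume(volume.data[start:stop], volume.voxel_um, dict(volume.meta))


# -- I/O ---------------------------------------------------------------


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a multi-page 8-bit TIFF stack plus a JSON sidecar.

    The sidecar records the voxel size, shape and any metadata (e.g.
    phantom ground truth).  Returns the sidecar path.
    """
    path = Path(path)
    tifffile.imwrite(path, (volume.data.astype(np.uint8) * 255))
    sidecar = _sidecar_path(path)
    payload = {"voxel_um": volume.voxel_um, "shape": list(volume.shape)}
    payload.update(volume.meta)
    sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return sidecar


def read_volume(path: str | Path, voxel_um: float | None = None) -> VoxelVolume:
    """Read a TIFF stack; voxel size from the JSON sidecar unless given."""
    path = Path(path)
    data = tifffile.imread(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        meta.pop("shape", None)
        if voxel_um is None:
            voxel_um = meta.pop("voxel_um", None)
        else:
            meta.pop("voxel_um", None)
    if voxel_um is None:
        raise ValueError(f"voxel size not given and no sidecar found for {path}")
    return VoxelVolume(data, float(voxel_um), meta)
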