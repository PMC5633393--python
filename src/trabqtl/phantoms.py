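"""Geometric phantoms with analytic ground-truth morphometry.

Idealized trabecular geometries — parallel plates, square lattices of
cylindrical rods, solid balls and a plate/rod mix — generated as binary
voxel volumes.  Each phantom carries its closed-form morphometry
(BV/TV, Tb.Th, Tb.Sp where defined) in ``meta["ground_truth"]`` so the
voxel-based estimators can be validated against known values.

Generation is implicit: the defining inequality is evaluated at voxel
centres in coordinates relative to the volume centre, so an optional
rigid rotation of the geometry is exact (no resampling).  All phantoms
are deterministic functions of their spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import VoxelVolume

__all__ = ["PhantomSpec", "PhantomGeometryError", "make_phantom", "make_torus"]

KINDS = ("parallel_plates", "square_lattice_rods", "solid_ball", "mixed")


class PhantomGeometryError(ValueError):
    """Geometry not representable at the requested voxel size."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of an idealized trabecular geometry.

    Lengths are micrometres.  ``rotate_deg`` applies an extrinsic
    z-y-x Euler rotation to the geometry about the volume centre;
    (0, 0, 0) leaves the phantom axis-aligned.
    """

    kind: str
    voxel_um: float
    shape_voxels: tuple[int, int, int]
    plate_thickness_um: float = 0.0
    plate_spacing_um: float = 0.0
    rod_radius_um: float = 0.0
    rod_pitch_um: float = 0.0
    ball_radius_um: float = 0.0
    rotate_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; one of {KINDS}")
        if self.voxel_um <= 0:
            raise ValueError("voxel_um must be positive")
        if len(self.shape_voxels) != 3 or any(s < 8 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be a triple with each entry >= 8")
        v = self.voxel_um
        if self.kind in ("parallel_plates", "mixed"):
            if self.plate_thickness_um < 2 * v:
                raise PhantomGeometryError(
                    f"plate thickness {self.plate_thickness_um} um is below 2 voxels "
                    f"({2 * v} um)"
                )
            if self.plate_spacing_um < v:
                raise PhantomGeometryError("plate spacing below one voxel")
            period = self.plate_thickness_um + self.plate_spacing_um
            if period > self.shape_voxels[0] * v:
                raise PhantomGeometryError("plate period exceeds axial extent")
        if self.kind in ("square_lattice_rods", "mixed"):
            if self.rod_radius_um < v:
                raise PhantomGeometryError(
                    f"rod diameter {2 * self.rod_radius_um} um is below 2 voxels"
                )
            if self.rod_pitch_um < 2 * self.rod_radius_um:
                raise PhantomGeometryError("rod pitch smaller than rod diameter")
        if self.kind == "solid_ball":
            if self.ball_radius_um < v:
                raise PhantomGeometryError("ball diameter below 2 voxels")


def _rotation_matrix(rotate_deg: tuple[float, float, float]) -> np.ndarray:
    az, ay, ax = np.deg2rad(rotate_deg)
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])  # about axis 0
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _centered_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates (um) relative to the volume centre,
    rotated into the phantom's frame."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * spec.voxel_um for n in spec.shape_voxels
    ]
    z, y, x = np.meshgrid(*axes, indexing="ij", sparse=False)
    if spec.rotate_deg != (0.0, 0.0, 0.0):
        r = _rotation_matrix(spec.rotate_deg)
        # rotate the geometry by R == evaluate implicit fn at R^T p
        pts = np.stack([z, y, x])
        z, y, x = np.einsum("ij,jabc->iabc", r.T, pts)
    return z, y, x


def _plates(z: np.ndarray, t: float, s: float) -> np.ndarray:
    # plates normal to axis 0, one plate centred on the volume centre
    p = t + s
    return np.abs(((z + p / 2.0) % p) - p / 2.0) <= t / 2.0 + 1e-9


def _rods(y: np.ndarray, x: np.ndarray, radius: float, pitch: float) -> np.ndarray:
    # rods parallel to axis 0 on a square lattice, one rod through the centre
    dy = ((y + pitch / 2.0) % pitch) - pitch / 2.0
    dx = ((x + pitch / 2.0) % pitch) - pitch / 2.0
    return dy**2 + dx**2 <= radius**2 + 1e-9


def make_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Generate the binary phantom with ground truth attached.

    ``meta["ground_truth"]`` holds the analytic values (units: BVTV is a
    fraction, thicknesses are mm); entries without a closed form for the
    given kind are omitted.
    """
    z, y, x = _centered_coords(spec)
    t, s = spec.plate_thickness_um, spec.plate_spacing_um
    truth: dict[str, float] = {}
    if spec.kind == "parallel_plates":
        mask = _plates(z, t, s)
        truth = {
            "BVTV": t / (t + s),
            "TbTh_mm": t / 1000.0,
            "TbSp_mm": s / 1000.0,
            "TbN_per_mm": 1000.0 / (t + s),
        }
    elif spec.kind == "square_lattice_rods":
        rho, q = spec.rod_radius_um, spec.rod_pitch_um
        mask = _rods(y, x, rho, q)
        truth = {
            "BVTV": np.pi * rho**2 / q**2,
            "TbTh_mm": 2 * rho / 1000.0,
        }
    elif spec.kind == "solid_ball":
        r = spec.ball_radius_um
        mask = z**2 + y**2 + x**2 <= r**2 + 1e-9
        box = np.prod(spec.shape_voxels) * spec.voxel_um**3
        truth = {
            "BVTV": (4.0 / 3.0) * np.pi * r**3 / box,
            "TbTh_mm": 2 * r / 1000.0,
        }
    elif spec.kind == "mixed":
        rho, q = spec.rod_radius_um, spec.rod_pitch_um
        lower = z < 0
        mask = np.where(lower, _plates(z, t, s), _rods(y, x, rho, q))
        truth = {"BVTV": 0.5 * (t / (t + s)) + 0.5 * (np.pi * rho**2 / q**2)}
    else:  # pragma: no cover - guarded by the spec validator
        raise ValueError(spec.kind)
    if not np.all(np.isfinite(list(truth.values()))):
        raise PhantomGeometryError("analytic ground truth is not finite")
    meta = {"phantom_kind": spec.kind, "ground_truth": truth}
    return VoxelVolume(mask, spec.voxel_um, meta)


def make_torus(
    major_um: float,
    minor_um: float,
    voxel_um: float,
    shape_voxels: tuple[int, int, int],
) -> VoxelVolume:
    """Voxelized solid torus (axis along axis 0); Euler characteristic 0,
    one handle.  Used to probe connectivity estimators."""
    if minor_um < voxel_um:
        raise PhantomGeometryError("torus tube diameter below 2 voxels")
    axes = [(np.arange(n) - (n - 1) / 2.0) * voxel_um for n in shape_voxels]
    z, y, x = np.meshgrid(*axes, indexing="ij")
    mask = (np.sqrt(y**2 + x**2) - major_um) ** 2 + z**2 <= minor_um**2
    return VoxelVolume(mask, voxel_um, {"phantom_kind": "torus"})
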