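"""NIfTI label-volume I/O, RAS canonicalization and voxel/world geometry.

Conventions
-----------
* Voxel indices are 0-based; the affine maps voxel *centers* to world
  coordinates (NIfTI convention).
* World space is RAS millimetres: +x = right, +y = anterior, +z = superior.
* ``world_to_voxel`` rounds half *up* per axis so endpoint reporting is
  deterministic.
* Oblique grids (off-axis direction cosine > 0.2) are rejected rather than
  resampled: the pipeline's contract is axis-aligned input (phantoms and
  upstream-registered scans).
"""

from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .errors import GeometryError, InputError

__all__ = [
    "LabelVolume",
    "LandmarkSet",
    "read_mask_volume",
    "write_mask_volume",
    "reorient_to_ras",
    "voxel_to_world",
    "world_to_voxel",
    "read_landmarks",
    "write_landmarks",
]

_OBLIQUE_TOL = 0.2


@dataclass(frozen=True)
class LabelVolume:
    """A 3D integer voxel grid with a 4x4 voxel-to-world (RAS mm) affine.

    Attributes
    ----------
    grid : ndarray of int, shape (nx, ny, nz)
        Label values; 0 is background.
    affine : ndarray of float, shape (4, 4)
        Maps homogeneous voxel indices to world millimetres.
    """

    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        affine = np.asarray(self.affine, dtype=float)
        if grid.ndim != 3:
            raise InputError(f"expected 3D volume, got {grid.ndim}D")
        if min(grid.shape) < 1:
            raise InputError(f"degenerate grid shape {grid.shape}")
        if affine.shape != (4, 4):
            raise InputError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise GeometryError("affine upper-left 3x3 block is singular")
        if not np.issubdtype(grid.dtype, np.integer):
            raise InputError(f"grid dtype must be integer, got {grid.dtype}")
        if grid.size and grid.min() < 0:
            raise InputError("label values must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm along each grid axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass(frozen=True)
class LandmarkSet:
    """AC, PC and IVF positions as world-mm 3-vectors (RAS).

    The anterior commissure must lie anterior to the posterior commissure
    (``ac_y > pc_y``); reversed or coincident landmarks are rejected.
    """

    ac: np.ndarray
    pc: np.ndarray
    ivf: np.ndarray
    space_tag: str = "world_ras"

    def __post_init__(self) -> None:
        for name in ("ac", "pc", "ivf"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(v)):
                raise InputError(f"landmark {name.upper()} has non-finite coordinates")
            object.__setattr__(self, name, v)
        if np.linalg.norm(self.ac - self.pc) < 1e-12:
            raise GeometryError("AC and PC coincide")
        if self.ac[1] - self.pc[1] <= 0:
            raise GeometryError("AC must be anterior to PC (ac_y - pc_y > 0); landmarks reversed or implausible")

    @property
    def acpc_midpoint(self) -> np.ndarray:
        return (self.ac + self.pc) / 2.0


def read_mask_volume(path: str | pathlib.Path) -> LabelVolume:
    """Load a 3D NIfTI label volume (optionally gzip-compressed).

    Float-stored volumes whose values are within 1e-6 of integers are cast
    with a warning; anything further from an integer is an error.
    """
    p = pathlib.Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    try:
        img = nib.load(str(p))
    except Exception as exc:  # nibabel raises several types for bad files
        raise InputError(f"could not read NIfTI file {p}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise InputError(f"expected 3D volume, got {data.ndim}D in {p}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        err = float(np.max(np.abs(data - rounded))) if data.size else 0.0
        if err > 1e-6:
            raise InputError(
                f"voxel values in {p} are not integers (max deviation {err:.3g})"
            )
        warnings.warn(
            f"{p}: float-stored labels within 1e-6 of integers; casting to int",
            stacklevel=2,
        )
        data = rounded.astype(np.int32)
    return LabelVolume(np.asarray(data), np.asarray(img.affine, dtype=float))


def write_mask_volume(vol: LabelVolume, path: str | pathlib.Path) -> None:
    """Write a label volume as NIfTI-1 (.nii or .nii.gz by suffix)."""
    dtype = np.int16 if vol.grid.max(initial=0) < 2**15 else np.int32
    img = nib.Nifti1Image(vol.grid.astype(dtype), vol.affine)
    nib.save(img, str(path))


def _normalized_columns(affine: np.ndarray) -> np.ndarray:
    cols = affine[:3, :3].astype(float)
    return cols / np.linalg.norm(cols, axis=0, keepdims=True)


def _check_not_oblique(affine: np.ndarray) -> None:
    cols = _normalized_columns(affine)
    for j in range(3):
        dominant = float(np.max(np.abs(cols[:, j])))
        off = float(np.sqrt(max(0.0, 1.0 - dominant**2)))
        if off > _OBLIQUE_TOL:
            raise GeometryError(
                f"oblique affine: grid axis {j} has off-axis direction cosine "
                f"{off:.3f} > {_OBLIQUE_TOL}; only axis-aligned grids are supported"
            )


def is_canonical_ras(vol: LabelVolume) -> bool:
    """True when grid axis i points along world axis i with positive sign."""
    cols = _normalized_columns(vol.affine)
    for j in range(3):
        if np.argmax(np.abs(cols[:, j])) != j or cols[j, j] <= 0:
            return False
    return True


def reorient_to_ras(vol: LabelVolume) -> LabelVolume:
    """Permute/flip grid axes so they align with +Right, +Anterior, +Superior.

    World coordinates of every voxel are preserved exactly (the affine is
    adjusted to compensate for the axis permutation). Idempotent. Oblique
    affines are rejected.
    """
    _check_not_oblique(vol.affine)
    if is_canonical_ras(vol):
        return vol
    ornt = nib.orientations.io_orientation(vol.affine)
    grid = nib.orientations.apply_orientation(vol.grid, ornt)
    affine = vol.affine @ nib.orientations.inv_ornt_aff(ornt, vol.grid.shape)
    out = LabelVolume(np.ascontiguousarray(grid), affine)
    if not is_canonical_ras(out):
        raise GeometryError("reorientation failed to produce a canonical RAS grid")
    return out


def voxel_to_world(vol: LabelVolume, index) -> np.ndarray:
    """World-mm coordinate of a voxel center: ``affine @ [i, 1]``."""
    idx = np.asarray(index, dtype=float).reshape(3)
    for ax in range(3):
        if not (0 <= idx[ax] < vol.shape[ax]):
            raise InputError(
                f"voxel index {idx[ax]:g} out of bounds on axis {ax} (size {vol.shape[ax]})"
            )
    return vol.affine[:3, :3] @ idx + vol.affine[:3, 3]


def world_to_voxel(vol: LabelVolume, point) -> np.ndarray:
    """Nearest voxel index for a world point (round half up per axis)."""
    p = np.asarray(point, dtype=float).reshape(3)
    inv = np.linalg.inv(vol.affine)
    cont = inv[:3, :3] @ p + inv[:3, 3]
    idx = np.floor(cont + 0.5).astype(int)
    for ax in range(3):
        if not (0 <= idx[ax] < vol.shape[ax]):
            raise InputError(
                f"world point maps outside the grid on axis {ax} "
                f"(index {idx[ax]}, size {vol.shape[ax]})"
            )
    return idx


_LANDMARK_KEYS = ("AC", "PC", "IVF")


def read_landmarks(path: str | pathlib.Path) -> LandmarkSet:
    """Read a landmark JSON file: {"AC": [x,y,z], "PC": ..., "IVF": ..., "space": "world_ras"}."""
    p = pathlib.Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    with open(p) as fh:
        obj = json.load(fh)
    for key in _LANDMARK_KEYS:
        if key not in obj:
            raise InputError(f"landmark file {p} missing key {key!r}")
    space = obj.get("space", "world_ras")
    if space != "world_ras":
        raise InputError(f"unsupported landmark space {space!r} (expected 'world_ras')")
    return LandmarkSet(ac=obj["AC"], pc=obj["PC"], ivf=obj["IVF"])


def write_landmarks(landmarks: LandmarkSet, path: str | pathlib.Path) -> None:
    obj = {
        "AC": [float(v) for v in landmarks.ac],
        "PC": [float(v) for v in landmarks.pc],
        "IVF": [float(v) for v in landmarks.ivf],
        "space": landmarks.space_tag,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")
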