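"""AC-PC rigid realignment and controlled rotational perturbations.

The realignment takes the unit AC-PC direction v = (AC - PC)/|AC - PC| to the
world anterior axis (0, 1, 0) by the minimal-angle rotation, pivoted at the
AC-PC midpoint. This zeroes pitch and yaw of the AC-PC line; roll (rotation
about the A-P axis) cannot be constrained by two collinear landmarks and is
left unchanged — the pipeline documents roll as uncorrectable, which is what
the rotational-robustness protocol probes.

Axis convention (RAS): pitch = world x (left-right), yaw = world z
(inferior-superior), roll = world y (posterior-anterior).

Label volumes are resampled with nearest-neighbour lookup (label identity is
preserved exactly); the output grid equals the input grid, so content rotated
out of the field of view is lost — phantoms carry >= 20 mm padding to make
that impossible for rotations up to about 25 degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InputError
from .volume_io import LabelVolume, LandmarkSet

__all__ = [
    "RigidTransform",
    "RotationSpec",
    "rotation_about",
    "acpc_rotation",
    "apply_rigid",
    "rotate_landmarks",
    "perturb",
    "AXIS_UNIT",
]

AXIS_UNIT = {
    "pitch": np.array([1.0, 0.0, 0.0]),
    "roll": np.array([0.0, 1.0, 0.0]),
    "yaw": np.array([0.0, 0.0, 1.0]),
}

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about a pivot plus translation, acting on world points.

    Action: ``p -> R @ (p - pivot) + pivot + translation``.
    """

    rotation: np.ndarray
    pivot: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.max(np.abs(R.T @ R - np.eye(3))) > _ORTHO_TOL:
            raise GeometryError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise GeometryError("rotation matrix determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "pivot", np.asarray(self.pivot, dtype=float).reshape(3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))

    def apply_point(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float).reshape(3)
        return self.rotation @ (p - self.pivot) + self.pivot + self.translation

    def inverse(self) -> "RigidTransform":
        RT = self.rotation.T
        return RigidTransform(RT, self.pivot, -(RT @ self.translation))

    @property
    def angle_deg(self) -> float:
        """Rotation angle in degrees (0 for the identity)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    @property
    def is_identity(self) -> bool:
        return (
            np.max(np.abs(self.rotation - np.eye(3))) < 1e-12
            and np.max(np.abs(self.translation)) < 1e-12
        )

    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "pivot": [float(v) for v in self.pivot],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "RigidTransform":
        return cls(
            np.asarray(obj["rotation"], dtype=float).reshape(3, 3),
            np.asarray(obj["pivot"], dtype=float),
            np.asarray(obj.get("translation", np.zeros(3)), dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class RotationSpec:
    """A named-axis rotation: pitch (x), yaw (z) or roll (y), in degrees."""

    axis: str
    angle_deg: float

    def __post_init__(self) -> None:
        if self.axis not in AXIS_UNIT:
            raise InputError(f"unknown rotation axis {self.axis!r}; expected one of {sorted(AXIS_UNIT)}")
        if not math.isfinite(self.angle_deg):
            raise InputError("rotation angle must be finite")


def rotation_about(axis, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    u = np.asarray(axis, dtype=float).reshape(3)
    n = np.linalg.norm(u)
    if n < 1e-15:
        raise GeometryError("rotation axis has zero length")
    u = u / n
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)


def acpc_rotation(landmarks: LandmarkSet) -> RigidTransform:
    """Minimal rotation taking the AC-PC direction onto the anterior axis.

    Returns the rotation (pivot = AC-PC midpoint, zero translation) whose
    axis is ``v x y_hat`` and whose angle is ``arccos(v . y_hat)``; identity
    when the line is already anterior-aligned. Roll about the A-P axis is
    left unchanged (two collinear points cannot constrain it).
    """
    v = landmarks.ac - landmarks.pc
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise GeometryError("AC and PC coincide")
    v = v / norm
    y_hat = np.array([0.0, 1.0, 0.0])
    vy = float(v @ y_hat)
    if vy <= 0:
        raise GeometryError("landmarks reversed or implausible (AC-PC direction not anterior)")
    angle = math.acos(min(1.0, vy))
    pivot = landmarks.acpc_midpoint
    if angle < 1e-9:
        return RigidTransform(np.eye(3), pivot)
    axis = np.cross(v, y_hat)
    return RigidTransform(rotation_about(axis, angle), pivot)


def _content_bbox(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Inclusive (lo, hi) voxel bounds of foreground, or None if empty."""
    lo = np.empty(3, dtype=int)
    hi = np.empty(3, dtype=int)
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        proj = np.flatnonzero(np.any(grid > 0, axis=other))
        if proj.size == 0:
            return None
        lo[ax], hi[ax] = proj[0], proj[-1]
    return lo, hi


def apply_rigid(vol: LabelVolume, t: RigidTransform) -> LabelVolume:
    """Resample a label volume under a rigid transform (nearest neighbour).

    Output grid and affine equal the input's. Each output voxel takes the
    label of the input voxel nearest to the inverse-mapped world point
    (round half up per axis); points mapping outside the grid become
    background.
    """
    if t.is_identity:
        return LabelVolume(vol.grid.copy(), vol.affine.copy())
    bbox = _content_bbox(vol.grid)
    out = np.zeros_like(vol.grid)
    if bbox is None:
        return LabelVolume(out, vol.affine.copy())
    lo, hi = bbox
    A = vol.affine
    Ainv = np.linalg.inv(A)
    # Forward-map the content bbox corners to bound the output region.
    corners = np.array(
        [
            [x, y, z]
            for x in (lo[0], hi[0])
            for y in (lo[1], hi[1])
            for z in (lo[2], hi[2])
        ],
        dtype=float,
    )
    world = corners @ A[:3, :3].T + A[:3, 3]
    mapped = (world - t.pivot) @ t.rotation.T + t.pivot + t.translation
    cont = mapped @ Ainv[:3, :3].T + Ainv[:3, 3]
    out_lo = np.maximum(np.floor(cont.min(axis=0)).astype(int) - 1, 0)
    out_hi = np.minimum(np.ceil(cont.max(axis=0)).astype(int) + 1, np.array(vol.shape) - 1)
    if np.any(out_lo > out_hi):
        return LabelVolume(out, vol.affine.copy())

    axes = [np.arange(out_lo[d], out_hi[d] + 1, dtype=float) for d in range(3)]
    I, J, K = np.meshgrid(*axes, indexing="ij", sparse=True)
    # world coords of output voxel centers
    M = A[:3, :3]
    px = M[0, 0] * I + M[0, 1] * J + M[0, 2] * K + A[0, 3]
    py = M[1, 0] * I + M[1, 1] * J + M[1, 2] * K + A[1, 3]
    pz = M[2, 0] * I + M[2, 1] * J + M[2, 2] * K + A[2, 3]
    # inverse transform: q = R^T (p - pivot - translation) + pivot
    RT = t.rotation.T
    off = t.pivot + t.translation
    qx = RT[0, 0] * (px - off[0]) + RT[0, 1] * (py - off[1]) + RT[0, 2] * (pz - off[2]) + t.pivot[0]
    qy = RT[1, 0] * (px - off[0]) + RT[1, 1] * (py - off[1]) + RT[1, 2] * (pz - off[2]) + t.pivot[1]
    qz = RT[2, 0] * (px - off[0]) + RT[2, 1] * (py - off[1]) + RT[2, 2] * (pz - off[2]) + t.pivot[2]
    N = Ainv[:3, :3]
    ci = N[0, 0] * qx + N[0, 1] * qy + N[0, 2] * qz + Ainv[0, 3]
    cj = N[1, 0] * qx + N[1, 1] * qy + N[1, 2] * qz + Ainv[1, 3]
    ck = N[2, 0] * qx + N[2, 1] * qy + N[2, 2] * qz + Ainv[2, 3]
    ii = np.floor(ci + 0.5).astype(np.int64)
    jj = np.floor(cj + 0.5).astype(np.int64)
    kk = np.floor(ck + 0.5).astype(np.int64)
    inb = (
        (ii >= 0) & (ii < vol.shape[0])
        & (jj >= 0) & (jj < vol.shape[1])
        & (kk >= 0) & (kk < vol.shape[2])
    )
    region = np.zeros(inb.shape, dtype=vol.grid.dtype)
    region[inb] = vol.grid[ii[inb], jj[inb], kk[inb]]
    out[out_lo[0]:out_hi[0] + 1, out_lo[1]:out_hi[1] + 1, out_lo[2]:out_hi[2] + 1] = region
    return LabelVolume(out, vol.affine.copy())


def rotate_landmarks(landmarks: LandmarkSet, t: RigidTransform) -> LandmarkSet:
    """Map AC, PC and IVF by the forward transform (invariants re-checked)."""
    return LandmarkSet(
        ac=t.apply_point(landmarks.ac),
        pc=t.apply_point(landmarks.pc),
        ivf=t.apply_point(landmarks.ivf),
    )


def perturb(
    vol: LabelVolume, landmarks: LandmarkSet, spec: RotationSpec
) -> tuple[LabelVolume, LandmarkSet]:
    """Rotate a volume and its landmarks together about the AC-PC midpoint."""
    if spec.angle_deg == 0:
        return vol, landmarks
    R = rotation_about(AXIS_UNIT[spec.axis], math.radians(spec.angle_deg))
    t = RigidTransform(R, landmarks.acpc_midpoint)
    return apply_rigid(vol, t), rotate_landmarks(landmarks, t)
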