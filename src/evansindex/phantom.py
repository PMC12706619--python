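"""Synthetic head phantoms with analytic ground-truth Evans Index.

A phantom stands in for a segmented head: the intracranial volume is a
voxelized ellipsoid (semi-axes a, b, c along right, anterior, superior); the
lateral ventricles are two mirrored frontal-horn spheres at (+/-x_h, y_h, 0)
joined to posterior body bars (rectangular blocks reaching back from the
horns, posterior of the IVF and thinner than the horn span so they never set
the frontal width). Horn spheres sit at the skull's equatorial plane z = 0,
so the inner-skull diameter at the matched slice is exactly 2a and the truth
is closed form:

    true width W = 2 (x_h + r),   true diameter D = 2a,   true EI = W / D.

Shapes are voxelized by a voxel-center inside-or-on test. Rotated phantoms
are voxelized directly in the rotated frame (analytic shapes rotated before
voxelization), so they carry no resampling error of their own — deviations
measured by the pipeline on them are attributable to the pipeline.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .alignment import AXIS_UNIT, RotationSpec, rotation_about
from .errors import GeometryError, InputError
from .volume_io import LabelVolume, LandmarkSet, write_landmarks, write_mask_volume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortCase",
    "make_phantom",
    "make_rotated_phantom",
    "jitter_mask",
    "simulate_paired_measurements",
    "generate_cohort",
    "write_phantom_case",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic head; defaults give a true EI of 0.30."""

    skull_semiaxes: tuple = (50.0, 65.0, 55.0)  # (a, b, c) mm
    horn_radius: float = 5.0  # r, mm
    horn_center_x: float = 10.0  # x_h, mm; true width = 2 (x_h + r)
    horn_center_y: float = 14.0  # mm, anterior of the IVF
    body_y_posterior: float = -30.0  # posterior end of the ventricle bodies
    body_half_z: float = 4.0
    ac: tuple = (0.0, 2.0, 0.0)
    pc: tuple = (0.0, -24.0, 0.0)
    ivf: tuple = (0.0, -1.0, 4.0)
    spacing: float = 1.0  # isotropic mm/voxel
    padding: float = 25.0  # mm of background beyond the skull

    def __post_init__(self) -> None:
        a, b, c = self.skull_semiaxes
        if min(a, b, c) <= 0 or self.horn_radius <= 0:
            raise InputError("semi-axes and horn radius must be positive")
        if self.spacing <= 0 or self.padding <= 0:
            raise InputError("spacing and padding must be positive")
        if self.true_width_mm >= 2 * a:
            raise GeometryError("horn width must be smaller than the skull diameter (W < 2a)")
        # conservative containment check: horn spheres inside the ellipsoid
        r = self.horn_radius
        margin = (
            ((abs(self.horn_center_x) + r) / a) ** 2
            + ((abs(self.horn_center_y) + r) / b) ** 2
            + (r / c) ** 2
        )
        if margin > 1.0:
            raise GeometryError("horn spheres are not contained in the skull ellipsoid")
        if self.horn_center_y <= self.ivf[1]:
            raise GeometryError("horn centers must lie anterior to the IVF")
        if self.ac[1] - self.pc[1] <= 0:
            raise GeometryError("AC must be anterior to PC")
        if self.body_y_posterior >= self.ivf[1]:
            raise GeometryError("ventricle bodies must extend posterior of the IVF")

    @property
    def true_width_mm(self) -> float:
        return 2.0 * (self.horn_center_x + self.horn_radius)

    @property
    def true_diameter_mm(self) -> float:
        return 2.0 * self.skull_semiaxes[0]

    @property
    def true_ei(self) -> float:
        return self.true_width_mm / self.true_diameter_mm

    @classmethod
    def from_target_ei(cls, ei: float, **overrides) -> "PhantomSpec":
        """Place the horns so the analytic EI equals ``ei`` exactly."""
        probe = cls(**{**overrides, "horn_center_x": 1.0}) if overrides else cls(horn_center_x=1.0)
        a = probe.skull_semiaxes[0]
        x_h = a * ei - probe.horn_radius
        if x_h <= 0:
            raise GeometryError(f"target EI {ei} too small for horn radius {probe.horn_radius}")
        return replace(probe, horn_center_x=x_h)

    @property
    def landmarks(self) -> LandmarkSet:
        return LandmarkSet(ac=self.ac, pc=self.pc, ivf=self.ivf)


@dataclass(frozen=True)
class PhantomTruth:
    true_width_mm: float
    true_diameter_mm: float
    true_ei: float
    true_z_mm: float
    applied_rotation: RotationSpec | None = None

    def to_dict(self) -> dict:
        d = {
            "true_width_mm": self.true_width_mm,
            "true_diameter_mm": self.true_diameter_mm,
            "true_ei": self.true_ei,
            "true_z_mm": self.true_z_mm,
        }
        if self.applied_rotation is not None:
            d["applied_rotation"] = {
                "axis": self.applied_rotation.axis,
                "angle_deg": self.applied_rotation.angle_deg,
            }
        return d


def _grid_geometry(spec: PhantomSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    """Cell-centered grid covering the skull plus padding; affine diag(spacing).

    Voxel centers sit at half-integer multiples of the spacing, symmetric
    about the world origin. A vertex-centered lattice would place the
    phantom's analytic surfaces (integer-valued radii and semi-axes) exactly
    on voxel centers, making the measured extents degenerate under the
    inside-or-on inclusion test; cell centering keeps surfaces between
    sample points.
    """
    s = spec.spacing
    half = [math.ceil((ax + spec.padding) / s) for ax in spec.skull_semiaxes]
    shape = tuple(2 * h for h in half)
    affine = np.diag([s, s, s, 1.0])
    affine[:3, 3] = [-s * (2 * h - 1) / 2.0 for h in half]
    return shape, affine


def _shapes(spec: PhantomSpec):
    """(predicate, world-aabb) pairs for ICV and LV in the canonical frame.

    Predicates take canonical-frame coordinate arrays and return boolean
    inclusion (inside-or-on).
    """
    a, b, c = spec.skull_semiaxes
    r = spec.horn_radius
    x_h, y_h = spec.horn_center_x, spec.horn_center_y
    y_post = spec.body_y_posterior
    y_ant = spec.ivf[1]  # bodies stay posterior of the IVF plane
    hz = spec.body_half_z
    # Ventricle bodies: mirrored slabs that are narrow at the foramen level
    # and widen posteriorly (the ventricle necks down to the IVF and opens
    # into body/atrium behind it). They never reach the frontal-horn span,
    # so the frontal width is always set by the horn spheres.
    bar_inner = 0.15 * x_h
    bar_out_ant = 0.30 * x_h  # lateral extent at the foramen level
    bar_out_post = 0.85 * x_h  # lateral extent at the posterior end

    def ellipsoid(X, Y, Z):
        return (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0

    def horns(X, Y, Z):
        r2 = r * r
        return ((X - x_h) ** 2 + (Y - y_h) ** 2 + Z**2 <= r2) | (
            (X + x_h) ** 2 + (Y - y_h) ** 2 + Z**2 <= r2
        )

    def bars(X, Y, Z):
        ax = np.abs(X)
        frac = np.clip((y_ant - Y) / (y_ant - y_post), 0.0, 1.0)
        outer = bar_out_ant + (bar_out_post - bar_out_ant) * frac
        return (ax >= bar_inner) & (ax <= outer) & (Y >= y_post) & (Y <= y_ant) & (np.abs(Z) <= hz)

    icv_shapes = [(ellipsoid, np.array([[-a, -b, -c], [a, b, c]]))]
    lv_shapes = [
        (horns, np.array([[-x_h - r, y_h - r, -r], [x_h + r, y_h + r, r]])),
        (bars, np.array([[-bar_out_post, y_post, -hz], [bar_out_post, y_ant, hz]])),
    ]
    return icv_shapes, lv_shapes


def _voxelize(shapes, shape, affine, rotation=None, pivot=None) -> np.ndarray:
    """OR the shape predicates into a grid, evaluating only inside each
    shape's (rotated) bounding box. ``rotation`` maps canonical -> rotated
    frame; voxel centers are pulled back with its transpose."""
    grid = np.zeros(shape, dtype=np.uint8)
    s = np.diag(affine)[:3]
    origin = affine[:3, 3]
    for pred, aabb in shapes:
        if rotation is not None:
            corners = np.array(
                [[aabb[i][0], aabb[j][1], aabb[k][2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
            )
            rot_corners = (corners - pivot) @ rotation.T + pivot
            lo_w = rot_corners.min(axis=0)
            hi_w = rot_corners.max(axis=0)
        else:
            lo_w, hi_w = aabb[0], aabb[1]
        lo = np.maximum(np.floor((lo_w - origin) / s).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((hi_w - origin) / s).astype(int) + 1, np.array(shape) - 1)
        if np.any(lo > hi):
            continue
        X = (origin[0] + s[0] * np.arange(lo[0], hi[0] + 1)).reshape(-1, 1, 1)
        Y = (origin[1] + s[1] * np.arange(lo[1], hi[1] + 1)).reshape(1, -1, 1)
        Z = (origin[2] + s[2] * np.arange(lo[2], hi[2] + 1)).reshape(1, 1, -1)
        if rotation is not None:
            RT = rotation.T
            px, py, pz = pivot
            Xc = RT[0, 0] * (X - px) + RT[0, 1] * (Y - py) + RT[0, 2] * (Z - pz) + px
            Yc = RT[1, 0] * (X - px) + RT[1, 1] * (Y - py) + RT[1, 2] * (Z - pz) + py
            Zc = RT[2, 0] * (X - px) + RT[2, 1] * (Y - py) + RT[2, 2] * (Z - pz) + pz
            inside = pred(Xc, Yc, Zc)
        else:
            inside = pred(X, Y, Z)
        sl = tuple(slice(lo[d], hi[d] + 1) for d in range(3))
        grid[sl] |= inside.astype(np.uint8)
    return grid


def make_rotated_phantom(
    spec: PhantomSpec, rotation: RotationSpec | None = None
) -> tuple[LabelVolume, LabelVolume, LandmarkSet, PhantomTruth]:
    """Voxelize a phantom, optionally in a rigidly rotated frame.

    The analytic shapes are rotated about the AC-PC midpoint before
    voxelization and the landmarks are rotated exactly, so the output has no
    resampling error. A zero-angle rotation is voxel-identical to the
    unrotated phantom.
    """
    if rotation is not None and abs(rotation.angle_deg) > 25:
        raise InputError("rotation angles beyond +/-25 degrees exceed the phantom padding")
    shape, affine = _grid_geometry(spec)
    landmarks = spec.landmarks
    icv_shapes, lv_shapes = _shapes(spec)
    if rotation is None or rotation.angle_deg == 0:
        R, pivot = None, None
        out_landmarks = landmarks
    else:
        R = rotation_about(AXIS_UNIT[rotation.axis], math.radians(rotation.angle_deg))
        pivot = landmarks.acpc_midpoint
        out_landmarks = LandmarkSet(
            ac=R @ (landmarks.ac - pivot) + pivot,
            pc=R @ (landmarks.pc - pivot) + pivot,
            ivf=R @ (landmarks.ivf - pivot) + pivot,
        )
    icv = LabelVolume(_voxelize(icv_shapes, shape, affine, R, pivot), affine)
    lv = LabelVolume(_voxelize(lv_shapes, shape, affine, R, pivot), affine)
    truth = PhantomTruth(
        true_width_mm=spec.true_width_mm,
        true_diameter_mm=spec.true_diameter_mm,
        true_ei=spec.true_ei,
        true_z_mm=0.0,
        applied_rotation=rotation,
    )
    return lv, icv, out_landmarks, truth


def make_phantom(spec: PhantomSpec | None = None):
    """Voxelize a phantom in the canonical (aligned) frame."""
    return make_rotated_phantom(spec or PhantomSpec(), None)


def jitter_mask(mask: LabelVolume, flip_prob: float, seed: int) -> LabelVolume:
    """Flip boundary voxels with probability ``flip_prob`` (segmentation noise).

    A boundary voxel is foreground with a 6-connected background neighbour
    or background with a 6-connected foreground neighbour; interior voxels
    are untouched. Reproducible for a given seed.
    """
    if not (0 <= flip_prob <= 1):
        raise InputError(f"flip probability must be in [0, 1], got {flip_prob}")
    fg = mask.grid > 0
    if flip_prob == 0:
        return LabelVolume(mask.grid.copy(), mask.affine)
    struct = ndi.generate_binary_structure(3, 1)
    inner = fg & ~ndi.binary_erosion(fg, structure=struct, border_value=0)
    outer = ~fg & ndi.binary_dilation(fg, structure=struct, border_value=0)
    boundary = inner | outer
    rng = np.random.default_rng(seed)
    coords = np.argwhere(boundary)
    flips = rng.random(coords.shape[0]) < flip_prob
    out = fg.copy()
    sel = coords[flips]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = ~out[sel[:, 0], sel[:, 1], sel[:, 2]]
    return LabelVolume(out.astype(mask.grid.dtype), mask.affine)


def simulate_paired_measurements(
    n: int, true_bias: float, sd: float, ei_range: tuple = (0.22, 0.42), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated (auto, manual) EI pairs for agreement-recovery checks.

    manual ~ Uniform(ei_range); auto = manual + true_bias + Normal(0, sd).
    """
    lo, hi = ei_range
    if not (0 < lo < hi < 1):
        raise InputError(f"invalid EI range {ei_range}")
    if n < 2:
        raise InputError("need n >= 2 pairs")
    if sd < 0:
        raise InputError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    manual = rng.uniform(lo, hi, size=n)
    auto = manual + true_bias + rng.normal(0.0, sd, size=n) if sd > 0 else manual + true_bias
    return auto, manual


@dataclass(frozen=True)
class CohortCase:
    case_id: str
    spec: PhantomSpec


_DEFAULT_RANGES = {
    "ei": (0.22, 0.42),
    "skull_a": (46.0, 54.0),
    "skull_b": (60.0, 70.0),
    "skull_c": (50.0, 60.0),
    "horn_radius": (4.0, 6.0),
    "horn_center_y": (12.0, 16.0),
}


def generate_cohort(
    n: int, seed: int, spec_ranges: dict | None = None
) -> tuple[list[CohortCase], pd.DataFrame]:
    """Sample a deterministic cohort of phantoms spanning normal to NPH-like EI.

    True EI is uniform over ``spec_ranges["ei"]`` (default 0.22-0.42,
    straddling the 0.30 threshold); skull semi-axes, horn radius and horn
    height vary mildly so voxelization noise decorrelates across cases.
    Returns the cases and a manifest table.
    """
    if n < 1:
        raise InputError("cohort size must be >= 1")
    ranges = {**_DEFAULT_RANGES, **(spec_ranges or {})}
    for key, (lo, hi) in ranges.items():
        if not lo <= hi:
            raise InputError(f"invalid range for {key}: {(lo, hi)}")
    rng = np.random.default_rng(seed)
    cases = []
    rows = []
    for i in range(n):
        ei = rng.uniform(*ranges["ei"])
        a = rng.uniform(*ranges["skull_a"])
        b = rng.uniform(*ranges["skull_b"])
        c = rng.uniform(*ranges["skull_c"])
        r = rng.uniform(*ranges["horn_radius"])
        y_h = rng.uniform(*ranges["horn_center_y"])
        spec = PhantomSpec(
            skull_semiaxes=(a, b, c),
            horn_radius=r,
            horn_center_x=a * ei - r,
            horn_center_y=y_h,
        )
        case_id = f"phantom_{i:03d}"
        cases.append(CohortCase(case_id, spec))
        rows.append(
            {
                "case_id": case_id,
                "true_ei": spec.true_ei,
                "skull_a": a,
                "skull_b": b,
                "skull_c": c,
                "horn_radius": r,
                "horn_center_x": spec.horn_center_x,
                "horn_center_y": y_h,
            }
        )
    return cases, pd.DataFrame(rows)


def write_phantom_case(
    out_dir: str | pathlib.Path,
    spec: PhantomSpec,
    rotation: RotationSpec | None = None,
    case_id: str = "phantom",
) -> dict:
    """Write one phantom (masks, landmark JSON, truth JSON) into a directory.

    Returns the file paths, suitable as a batch-manifest row.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lv, icv, landmarks, truth = make_rotated_phantom(spec, rotation)
    paths = {
        "case_id": case_id,
        "lv": str(out / f"{case_id}_lv.nii.gz"),
        "icv": str(out / f"{case_id}_icv.nii.gz"),
        "landmarks": str(out / f"{case_id}_landmarks.json"),
        "truth": str(out / f"{case_id}_truth.json"),
    }
    write_mask_volume(lv, paths["lv"])
    write_mask_volume(icv, paths["icv"])
    write_landmarks(landmarks, paths["landmarks"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
        fh.write("\n")
    return paths
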