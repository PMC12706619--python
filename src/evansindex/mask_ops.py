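"""Binary-mask postprocessing: cluster removal, void filling, frontal-horn
extraction, volumes and Dice.

Foreground connectivity defaults to 26-neighbourhood; hole filling uses
6-connected background (the standard dual choice that avoids topological
paradoxes). "Anterior to the IVF" is a strict inequality on voxel-center
world y.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .errors import EmptyMaskError, GeometryError, InputError
from .volume_io import LabelVolume

__all__ = [
    "ensure_binary",
    "largest_component",
    "remove_small_components",
    "fill_holes",
    "frontal_horn_mask",
    "mask_volume_mm3",
    "dice",
    "crop_to_bbox",
    "world_y_coordinates",
]

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


def ensure_binary(mask: LabelVolume) -> None:
    if mask.grid.max(initial=0) > 1:
        raise InputError("mask is not binary (labels other than 0/1 present)")


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[connectivity]
    except KeyError:
        raise InputError(f"connectivity must be one of 6, 18, 26; got {connectivity}") from None


def largest_component(mask: LabelVolume, connectivity: int = 26) -> LabelVolume:
    """Keep only the largest connected foreground component.

    Ties are broken by the component containing the lexicographically
    smallest voxel index (first foreground voxel in C order).
    """
    ensure_binary(mask)
    labels, n = ndi.label(mask.grid > 0, structure=_structure(connectivity))
    if n == 0:
        raise EmptyMaskError("mask has no foreground voxels")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.flatnonzero(counts == best)
    if len(candidates) == 1:
        winner = candidates[0]
    else:
        flat = labels.ravel()
        # first occurrence in C order == lexicographic minimum index
        firsts = {lab: np.flatnonzero(flat == lab)[0] for lab in candidates}
        winner = min(firsts, key=firsts.get)
    return LabelVolume((labels == winner).astype(mask.grid.dtype), mask.affine)


def remove_small_components(
    mask: LabelVolume, min_frac: float = 0.01, connectivity: int = 26
) -> LabelVolume:
    """Drop foreground components smaller than ``min_frac`` of total foreground.

    Used for lateral-ventricle cleanup: the two ventricles may be
    disconnected, so a single-largest-component rule would delete one of
    them; a relative size floor removes only spurious specks.
    """
    ensure_binary(mask)
    labels, n = ndi.label(mask.grid > 0, structure=_structure(connectivity))
    if n == 0:
        raise EmptyMaskError("mask has no foreground voxels")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    total = counts.sum()
    keep = np.flatnonzero(counts >= min_frac * total)
    out = np.isin(labels, keep) & (labels > 0)
    return LabelVolume(out.astype(mask.grid.dtype), mask.affine)


def fill_holes(mask: LabelVolume) -> LabelVolume:
    """Fill internal voids: 6-connected background unreachable from the border."""
    ensure_binary(mask)
    if not np.any(mask.grid):
        raise EmptyMaskError("mask has no foreground voxels")
    filled = ndi.binary_fill_holes(mask.grid > 0, structure=_STRUCTURES[6])
    return LabelVolume(filled.astype(mask.grid.dtype), mask.affine)


def world_y_coordinates(vol: LabelVolume) -> np.ndarray:
    """World y (anterior) coordinate of every voxel center, full-grid array."""
    A = vol.affine
    i = np.arange(vol.shape[0]).reshape(-1, 1, 1)
    j = np.arange(vol.shape[1]).reshape(1, -1, 1)
    k = np.arange(vol.shape[2]).reshape(1, 1, -1)
    return A[1, 0] * i + A[1, 1] * j + A[1, 2] * k + A[1, 3]


def frontal_horn_mask(lv: LabelVolume, ivf) -> LabelVolume:
    """Retain LV voxels strictly anterior to the IVF (world y > ivf_y)."""
    ensure_binary(lv)
    ivf = np.asarray(ivf, dtype=float).reshape(3)
    if not np.all(np.isfinite(ivf)):
        raise InputError("IVF coordinates must be finite")
    y = world_y_coordinates(lv)
    out = (lv.grid > 0) & (y > ivf[1])
    if not np.any(out):
        raise EmptyMaskError("no frontal-horn voxels anterior to IVF")
    return LabelVolume(out.astype(lv.grid.dtype), lv.affine)


def mask_volume_mm3(mask: LabelVolume) -> float:
    """Foreground voxel count times voxel volume (0.0 for an empty mask)."""
    ensure_binary(mask)
    return float(np.count_nonzero(mask.grid)) * mask.voxel_volume_mm3


def dice(a: LabelVolume, b: LabelVolume) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    ensure_binary(a)
    ensure_binary(b)
    if a.shape != b.shape:
        raise InputError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-9):
        raise InputError("affine mismatch between masks")
    na = int(np.count_nonzero(a.grid))
    nb = int(np.count_nonzero(b.grid))
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero((a.grid > 0) & (b.grid > 0)))
    return 2.0 * inter / (na + nb)


def crop_to_bbox(vols: list[LabelVolume], margin: int = 1) -> tuple[list[LabelVolume], np.ndarray]:
    """Crop volumes to the union foreground bounding box (+margin).

    All volumes must share shape and affine. Returns the cropped volumes
    (affine shifted so world coordinates are unchanged) and the voxel offset
    of the crop origin in the original grid.
    """
    base = vols[0]
    for v in vols[1:]:
        if v.shape != base.shape or not np.allclose(v.affine, base.affine, atol=1e-9):
            raise InputError("crop_to_bbox requires identical grids")
    union = np.zeros(base.shape, dtype=bool)
    for v in vols:
        union |= v.grid > 0
    if not union.any():
        raise EmptyMaskError("all masks empty; nothing to crop to")
    lo = np.empty(3, dtype=int)
    hi = np.empty(3, dtype=int)
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        proj = np.flatnonzero(np.any(union, axis=other))
        lo[ax] = max(0, proj[0] - margin)
        hi[ax] = min(base.shape[ax] - 1, proj[-1] + margin)
    sl = tuple(slice(lo[ax], hi[ax] + 1) for ax in range(3))
    affine = base.affine.copy()
    affine[:3, 3] = affine[:3, :3] @ lo + affine[:3, 3]
    return [LabelVolume(np.ascontiguousarray(v.grid[sl]), affine) for v in vols], lo
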