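"""Voxel-volume preprocessing: orientation, sagittal split/mirror, silhouette
projection and size-normalized rasterization onto a 128x128 canvas.

Conventions (fixed package-wide):

* Volumes are boolean arrays indexed ``[z, y, x]``.  Points and landmarks are
  given in ``(x, y, z)`` voxel coordinates.
* Canonical pose: the base plane through the three anatomical points is
  parallel to xy with the object body on the +z side (teeth side at low z),
  and the condyle-midpoint -> tip direction is +y.
* Projections: ``x_proj`` collapses x (rows = z, cols = y), ``y_proj``
  collapses y (rows = z, cols = x), ``z_proj`` collapses z (rows = y,
  cols = x).
* Crop/slab windows are 0-based and half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CanvasOverflowError, EmptyHalfError, InvalidLandmarkError

CANVAS = 128

__all__ = [
    "VoxelVolume",
    "HalfSpecimen",
    "ProjectionTriplet",
    "RasterTransform",
    "canonicalize_orientation",
    "split_and_mirror",
    "project_volume",
    "normalize_and_rasterize",
    "apply_transform",
    "preprocess_specimen",
    "CANVAS",
]


@dataclass
class VoxelVolume:
    """Binary occupancy grid in the anatomical frame (index order z, y, x)."""

    occupancy: np.ndarray
    voxel_size: float = 1.0
    specimen_id: str = ""
    orientation_checked: bool = False

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be 3-D")
        if not self.occupancy.any():
            raise ValueError("occupancy must contain at least one true voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class HalfSpecimen:
    occupancy: np.ndarray
    side: str
    mirrored: bool
    parent_id: str

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass
class ProjectionTriplet:
    x_proj: np.ndarray
    y_proj: np.ndarray
    z_proj: np.ndarray
    reference_length_px: int = 0
    parent_id: str = ""
    side: str = ""

    def __post_init__(self):
        for name in ("x_proj", "y_proj", "z_proj"):
            img = np.asarray(getattr(self, name), dtype=np.uint8)
            if img.shape != (CANVAS, CANVAS):
                raise ValueError(f"{name} must be {CANVAS}x{CANVAS}, got {img.shape}")
            if img.max(initial=0) > 1:
                raise ValueError(f"{name} must be binary")
            setattr(self, name, img)

    def stack(self) -> np.ndarray:
        """(3, 128, 128) float32 channel stack in x, y, z order."""
        return np.stack([self.x_proj, self.y_proj, self.z_proj]).astype(np.float32)


@dataclass
class RasterTransform:
    """Scale and per-image placement used by :func:`normalize_and_rasterize`.

    Re-applying the identical transform to a modified (e.g. cropped) half
    keeps the remaining anatomy at the original scale and position.
    """

    scale: float
    offsets: dict[str, tuple[int, int]] = field(default_factory=dict)
    reference_length_px: int = 0


def _rotation_from_landmarks(condyle_points, tip_point, centroid_xyz):
    c1, c2 = (np.asarray(p, dtype=float) for p in condyle_points)
    tip = np.asarray(tip_point, dtype=float)
    mid = 0.5 * (c1 + c2)
    v = tip - mid
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise InvalidLandmarkError("condyle midpoint coincides with the tip")
    e_y = v / nv

    normal = np.cross(c2 - c1, tip - c1)
    if np.linalg.norm(normal) < 1e-9:
        normal = np.array([0.0, 0.0, 1.0])  # colinear landmarks: fall back to z
    e_z = normal - (normal @ e_y) * e_y
    if np.linalg.norm(e_z) < 1e-9:
        e_z = np.array([0.0, 0.0, 1.0]) - e_y[2] * e_y
    e_z = e_z / np.linalg.norm(e_z)
    # object body must sit on the +z side of the landmark plane (teeth at -z)
    if (np.asarray(centroid_xyz) - mid) @ e_z < 0:
        e_z = -e_z
    e_x = np.cross(e_y, e_z)
    return np.stack([e_x, e_y, e_z]), mid  # rows: canonical axes in world coords


def canonicalize_orientation(
    volume: VoxelVolume,
    condyle_points,
    tip_point,
    return_transform: bool = False,
):
    """Rigidly rotate a volume into the canonical anatomical pose.

    ``condyle_points`` are the two (x, y, z) medial condyle tips, ``tip_point``
    the anterior tip.  If the pose is already canonical the volume is returned
    voxelwise unchanged.  With ``return_transform=True`` a mapping function
    world-(x, y, z) -> canonical-(x, y, z) is returned alongside.
    """
    occ = volume.occupancy
    zz, yy, xx = np.nonzero(occ)
    centroid = np.array([xx.mean(), yy.mean(), zz.mean()])
    R, pivot = _rotation_from_landmarks(condyle_points, tip_point, centroid)

    if np.abs(R - np.eye(3)).max() < 1e-6:
        out = VoxelVolume(
            occ.copy(), volume.voxel_size, volume.specimen_id, orientation_checked=True
        )
        if return_transform:
            return out, lambda p: np.asarray(p, dtype=float)
        return out

    d = int(np.ceil(np.linalg.norm(occ.shape))) + 2
    out_center = np.full(3, (d - 1) / 2.0)  # (x, y, z)
    # affine_transform maps output index -> input index: in = A @ out + off,
    # with indices in (z, y, x) order; our rotation acts on (x, y, z).
    a_xyz = R.T
    a_zyx = a_xyz[::-1, ::-1]
    off = np.asarray(pivot)[::-1] - a_zyx @ out_center[::-1]
    resampled = ndimage.affine_transform(
        occ.astype(np.float32), a_zyx, offset=off, output_shape=(d, d, d), order=1
    )
    new_occ = resampled > 0.5
    if not new_occ.any():
        raise InvalidLandmarkError("canonicalization produced an empty volume")
    change = abs(int(new_occ.sum()) - volume.n_voxels) / volume.n_voxels
    if change > 0.02:
        warnings.warn(
            f"occupancy changed by {change:.1%} during resampling", RuntimeWarning
        )
    out = VoxelVolume(
        new_occ, volume.voxel_size, volume.specimen_id, orientation_checked=True
    )
    if return_transform:
        piv = np.asarray(pivot)

        def to_canonical(p, R=R, piv=piv, out_center=out_center):
            return R @ (np.asarray(p, dtype=float) - piv) + out_center

        return out, to_canonical
    return out


def split_and_mirror(volume: VoxelVolume, tip_point) -> tuple[HalfSpecimen, HalfSpecimen]:
    """Split at the sagittal plane through the tip and mirror the right half.

    The plane sits between x-columns ``c-1`` and ``c`` with
    ``c = floor(tip_x + 0.5)``; the two halves partition the occupancy exactly
    and the mirrored half is flipped along x so both share one chirality.
    """
    occ = volume.occupancy
    c = int(np.floor(float(np.asarray(tip_point, dtype=float)[0]) + 0.5))
    if c <= 0 or c >= occ.shape[2]:
        raise EmptyHalfError(f"splitting plane at x={c} lies outside the volume grid")
    left_occ = occ[:, :, :c]
    right_occ = occ[:, :, c:]
    if not left_occ.any() or not right_occ.any():
        raise EmptyHalfError("sagittal split produced an empty half")
    left = HalfSpecimen(left_occ.copy(), "left", False, volume.specimen_id)
    right = HalfSpecimen(right_occ[:, :, ::-1].copy(), "right", True, volume.specimen_id)
    return left, right


def project_volume(half: HalfSpecimen) -> dict[str, np.ndarray]:
    """Silhouette projections: pixel on iff any occupied voxel along the ray."""
    occ = half.occupancy
    if not occ.any():
        raise EmptyHalfError("cannot project an empty half")
    return {
        "x": occ.any(axis=2),  # (z, y)
        "y": occ.any(axis=1),  # (z, x)
        "z": occ.any(axis=0),  # (y, x)
    }


def _scale_image(img: np.ndarray, scale: float) -> np.ndarray:
    """Bilinear rescale of a binary image, re-binarized at 0.5."""
    if abs(scale - 1.0) < 1e-12:
        return img.astype(bool)
    out = ndimage.zoom(img.astype(np.float32), scale, order=1, grid_mode=True, mode="grid-constant")
    return out > 0.5


def _place(img: np.ndarray, top_left: tuple[int, int], canvas: int) -> np.ndarray:
    r0, c0 = top_left
    h, w = img.shape
    rows, cols = np.nonzero(img)
    if len(rows) == 0:
        return np.zeros((canvas, canvas), dtype=np.uint8)
    if r0 + rows.min() < 0 or c0 + cols.min() < 0 or r0 + rows.max() >= canvas or c0 + cols.max() >= canvas:
        need_r = rows.max() - rows.min() + 1
        need_c = cols.max() - cols.min() + 1
        raise CanvasOverflowError(int(max(need_r, need_c)), canvas)
    out = np.zeros((canvas, canvas), dtype=np.uint8)
    rr, cc = rows + r0, cols + c0
    out[rr, cc] = 1
    return out


def normalize_and_rasterize(
    raw: dict[str, np.ndarray],
    landmark_a,
    landmark_b,
    target_length_px: int,
    parent_id: str = "",
    side: str = "",
    canvas: int = CANVAS,
) -> tuple[ProjectionTriplet, RasterTransform]:
    """Scale all three projections by one factor and center them on the canvas.

    ``landmark_a``/``landmark_b`` are (row, col) points in the ``x`` projection
    (the reference-length segment, e.g. angular process to tip).  All images are
    scaled by ``target_length_px / |a - b|``; the x projection is placed with
    the scaled landmark midpoint at the canvas center, the other two are
    centered on their occupied bounding boxes.
    """
    a = np.asarray(landmark_a, dtype=float)
    b = np.asarray(landmark_b, dtype=float)
    dist = float(np.linalg.norm(a - b))
    if dist < 1e-9:
        raise InvalidLandmarkError("normalization landmarks coincide")
    if not 0 < target_length_px < canvas:
        raise ValueError(f"target_length_px must be in (0, {canvas})")
    scale = target_length_px / dist

    images: dict[str, np.ndarray] = {}
    offsets: dict[str, tuple[int, int]] = {}
    center = (canvas - 1) / 2.0
    for key in ("x", "y", "z"):
        scaled = _scale_image(np.asarray(raw[key], dtype=bool), scale)
        if key == "x":
            mid = 0.5 * (a + b) * scale
            off = (int(round(center - mid[0])), int(round(center - mid[1])))
        else:
            rows, cols = np.nonzero(scaled)
            if len(rows) == 0:
                off = (0, 0)
            else:
                off = (
                    int(round(center - 0.5 * (rows.min() + rows.max()))),
                    int(round(center - 0.5 * (cols.min() + cols.max()))),
                )
        images[key] = _place(scaled, off, canvas)
        offsets[key] = off

    triplet = ProjectionTriplet(
        x_proj=images["x"],
        y_proj=images["y"],
        z_proj=images["z"],
        reference_length_px=int(target_length_px),
        parent_id=parent_id,
        side=side,
    )
    return triplet, RasterTransform(scale=scale, offsets=offsets, reference_length_px=int(target_length_px))


def apply_transform(
    raw: dict[str, np.ndarray],
    transform: RasterTransform,
    parent_id: str = "",
    side: str = "",
    canvas: int = CANVAS,
) -> ProjectionTriplet:
    """Rasterize projections with a previously computed scale and placement."""
    images = {
        key: _place(_scale_image(np.asarray(raw[key], dtype=bool), transform.scale),
                    transform.offsets[key], canvas)
        for key in ("x", "y", "z")
    }
    return ProjectionTriplet(
        x_proj=images["x"],
        y_proj=images["y"],
        z_proj=images["z"],
        reference_length_px=transform.reference_length_px,
        parent_id=parent_id,
        side=side,
    )


def preprocess_specimen(
    volume: VoxelVolume,
    condyle_points,
    tip_point,
    landmark_a,
    landmark_b,
    target_length_px: int = 96,
):
    """Full per-specimen path: canonicalize, split/mirror, project, rasterize.

    ``landmark_a``/``landmark_b`` are 3-D (x, y, z) points in the input frame
    (the reference-length segment, e.g. angular-process tip and mandible tip);
    they are mapped to the canonical x-projection plane (row = z, col = y)
    internally, so one pair serves both halves (the x projection is invariant
    to the sagittal split and mirror).  Returns a list of two
    ``(half, triplet, transform)`` tuples.
    """
    canonical, to_canonical = canonicalize_orientation(
        volume, condyle_points, tip_point, return_transform=True
    )
    tip_c = to_canonical(tip_point)
    a_c = to_canonical(landmark_a)
    b_c = to_canonical(landmark_b)
    landmark_a = (a_c[2], a_c[1])
    landmark_b = (b_c[2], b_c[1])
    halves = split_and_mirror(canonical, tip_c)
    out = []
    for half in halves:
        raw = project_volume(half)
        triplet, transform = normalize_and_rasterize(
            raw,
            landmark_a,
            landmark_b,
            target_length_px,
            parent_id=volume.specimen_id,
            side=half.side,
        )
        out.append((half, triplet, transform))
    return out
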