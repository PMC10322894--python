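"""Class-labeled synthetic 3-D shapes with mandible-like protrusions.

Each specimen is an ellipsoidal body plus three pairs of rod-like processes
("coronoid", "condylar", "angular") whose angles and lengths are drawn from
class-specific distributions.  Classes differ mainly in process angles, so
their silhouette projections are separable the way family silhouettes are.
Every generated volume comes with the landmark points the preprocessing
pipeline needs: two "condyle" markers, the anterior "tip", and the
angular-process tip / mandible tip pair that defines the normalization length.

Shapes are generated directly in the canonical pose (landmark plane parallel
to xy, condyle-midpoint -> tip along +y), so orientation canonicalization is
an identity for them; tests rotate them to exercise the non-trivial path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import VoxelVolume

__all__ = [
    "ProcessParams",
    "ShapeClassParams",
    "generate_shape_volume",
    "generate_dataset",
    "separable_class_params",
    "hard_class_params",
    "quadrant_informative_triplets",
]


@dataclass
class ProcessParams:
    length_mean: float
    length_sd: float
    thickness: float
    angle_mean_deg: float
    angle_sd_deg: float

    def validate(self):
        if self.length_mean <= 0 or self.thickness <= 0:
            raise ValueError("process lengths and thickness must be positive")


@dataclass
class ShapeClassParams:
    class_id: int
    body_axes: tuple[float, float, float] = (9.0, 20.0, 7.0)
    coronoid: ProcessParams = field(
        default_factory=lambda: ProcessParams(14.0, 1.0, 2.0, 20.0, 2.0)
    )
    condylar: ProcessParams = field(
        default_factory=lambda: ProcessParams(12.0, 1.0, 2.2, 45.0, 2.0)
    )
    angular: ProcessParams = field(
        default_factory=lambda: ProcessParams(8.0, 0.8, 2.0, 35.0, 2.0)
    )
    size_jitter: tuple[float, float] = (0.5, 2.5)
    # class-independent nuisance variation of the body shape (fraction of the
    # semi-axes); keeps pixel-space variance from being dominated by the
    # class-informative process geometry
    body_jitter: float = 0.15

    def validate(self):
        for p in (self.coronoid, self.condylar, self.angular):
            p.validate()
        if any(a <= 0 for a in self.body_axes):
            raise ValueError("body semi-axes must be positive")
        lo, hi = self.size_jitter
        if not 0 < lo <= hi:
            raise ValueError("size_jitter must satisfy 0 < lo <= hi")
        return self


def _capsule_mask(grid_shape, p0, p1, radius):
    """Boolean mask of a capsule (segment with radius), evaluated on a bbox."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo = np.floor(np.minimum(p0, p1) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 1).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(grid_shape)[::-1])  # grid is (z, y, x)
    out = np.zeros(grid_shape, dtype=bool)
    if np.any(hi <= lo):
        return out
    xs = np.arange(lo[0], hi[0])
    ys = np.arange(lo[1], hi[1])
    zs = np.arange(lo[2], hi[2])
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1).astype(float)
    d = p1 - p0
    denom = float(d @ d)
    if denom < 1e-12:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
        proj = p0[None, None, None, :] + t[..., None] * d[None, None, None, :]
        dist = np.linalg.norm(pts - proj, axis=-1)
    out[lo[2] : hi[2], lo[1] : hi[1], lo[0] : hi[0]] = dist <= radius
    return out


def _ellipsoid_mask(grid_shape, center, axes):
    zs, ys, xs = (np.arange(n) for n in grid_shape)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij", sparse=True)
    cx, cy, cz = center
    ax, ay, az = axes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _draw_geometry(params: ShapeClassParams, rng: np.random.Generator):
    s = rng.uniform(*params.size_jitter)

    def draw(p: ProcessParams):
        length = max(0.2 * p.length_mean, rng.normal(p.length_mean, p.length_sd))
        angle = np.deg2rad(rng.normal(p.angle_mean_deg, p.angle_sd_deg))
        return length * s, angle, p.thickness * s

    bj = params.body_jitter
    ax, ay, az = (
        a * s * rng.uniform(1.0 - bj, 1.0 + bj) for a in params.body_axes
    )
    x_off = 0.55 * ax
    geom = {
        "scale": s,
        "body_axes": (ax, ay, az),
        "tip": np.array([0.0, ay, 0.0]),
        "condyle_markers": [
            np.array([-x_off, -0.6 * ay, 0.0]),
            np.array([x_off, -0.6 * ay, 0.0]),
        ],
        "rods": [],
    }
    # upward processes tilt backwards (-y) by their angle from vertical
    l, th, r = draw(params.coronoid)
    for sx in (-1, 1):
        base = np.array([sx * x_off, -0.7 * ay, 0.5 * az])
        geom["rods"].append((base, base + l * np.array([0, -np.sin(th), np.cos(th)]), r))
    l, th, r = draw(params.condylar)
    cond_tips = []
    for sx in (-1, 1):
        base = np.array([sx * x_off, -0.9 * ay, 0.25 * az])
        tip = base + l * np.array([0, -np.sin(th), np.cos(th)])
        geom["rods"].append((base, tip, r))
        cond_tips.append(tip)
    # angular process points backwards and down
    l, th, r = draw(params.angular)
    ang_tips = []
    for sx in (-1, 1):
        base = np.array([sx * x_off, -0.8 * ay, -0.4 * az])
        tip = base + l * np.array([0, -np.sin(th), -np.cos(th)])
        geom["rods"].append((base, tip, r))
        ang_tips.append(tip)
    geom["angular_tip"] = ang_tips[1]
    geom["condylar_tips"] = cond_tips
    return geom


def generate_shape_volume(
    params: ShapeClassParams, sample_seed: int, max_attempts: int = 10
) -> tuple[VoxelVolume, dict]:
    """Rasterize one specimen; deterministic per (params, sample_seed).

    Returns the volume and a landmark dict with (x, y, z) voxel coordinates:
    ``condyles`` (two points), ``tip``, and the normalization pair
    ``norm_a`` (angular-process tip) / ``norm_b`` (mandible tip).
    """
    params.validate()
    for attempt in range(max_attempts):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(sample_seed), int(params.class_id), attempt])
        )
        geom = _draw_geometry(params, rng)
        pts = (
            [geom["tip"]]
            + geom["condyle_markers"]
            + [p for rod in geom["rods"] for p in rod[:2]]
        )
        pts = np.array(pts)
        radius = max(rod[2] for rod in geom["rods"])
        ax, ay, az = geom["body_axes"]
        lo = np.minimum(pts.min(axis=0), [-ax, -ay, -az]) - radius - 3
        hi = np.maximum(pts.max(axis=0), [ax, ay, az]) + radius + 3
        origin = lo  # world -> grid: g = p - origin  (x, y, z)
        shape = tuple(int(np.ceil(h - l)) + 1 for l, h in zip(lo[::-1], hi[::-1]))

        occ = _ellipsoid_mask(shape, -origin, geom["body_axes"])
        for base, tip, r in geom["rods"]:
            occ |= _capsule_mask(shape, base - origin, tip - origin, r)

        labeled, n_comp = ndimage.label(occ, structure=ndimage.generate_binary_structure(3, 1))
        if n_comp == 1:
            break
        params = replace(params)  # retry with a fresh stream (attempt in seed)
    else:
        raise RuntimeError(f"disconnected shape after {max_attempts} attempts")

    landmarks = {
        "condyles": [tuple(p - origin) for p in geom["condyle_markers"]],
        "tip": tuple(geom["tip"] - origin),
        "norm_a": tuple(geom["angular_tip"] - origin),
        "norm_b": tuple(geom["tip"] - origin),
        "scale": geom["scale"],
    }
    vol = VoxelVolume(occ, voxel_size=1.0, specimen_id="", orientation_checked=True)
    return vol, landmarks


def separable_class_params(
    n_classes: int = 3, size_jitter: tuple[float, float] = (0.8, 1.6)
) -> list[ShapeClassParams]:
    """Classes whose process-angle means differ by > 3 within-class SDs."""
    out = []
    for k in range(n_classes):
        out.append(
            ShapeClassParams(
                class_id=k,
                coronoid=ProcessParams(14.0, 1.0, 2.0, 8.0 + 18.0 * k, 2.0),
                condylar=ProcessParams(12.0 + 1.5 * k, 1.0, 2.2, 52.0 - 13.0 * k, 2.0),
                angular=ProcessParams(8.0 + 1.0 * k, 0.8, 2.0, 25.0 + 12.0 * k, 2.0),
                size_jitter=size_jitter,
            ).validate()
        )
    return out


def hard_class_params(
    n_classes: int = 3, size_jitter: tuple[float, float] = (0.8, 1.6)
) -> list[ShapeClassParams]:
    """Overlapping angle distributions (means ~1 SD apart)."""
    out = []
    for k in range(n_classes):
        out.append(
            ShapeClassParams(
                class_id=k,
                coronoid=ProcessParams(14.0, 1.0, 2.0, 20.0 + 4.0 * k, 5.0),
                condylar=ProcessParams(12.0, 1.0, 2.2, 45.0 - 3.0 * k, 5.0),
                angular=ProcessParams(8.0, 0.8, 2.0, 30.0 + 3.0 * k, 5.0),
                size_jitter=size_jitter,
            ).validate()
        )
    return out


def generate_dataset(
    class_params: list[ShapeClassParams],
    n_per_class,
    seed: int = 0,
    out_dir=None,
) -> tuple[pd.DataFrame, dict[str, VoxelVolume]]:
    """Generate labeled volumes plus a manifest of ids, labels and landmarks.

    ``n_per_class`` is an int (balanced) or a per-class list (imbalance is
    supported).  With ``out_dir`` set, volumes are written as NPZ files and
    the manifest as ``manifest.csv`` in the preprocessing input format.
    """
    if len(class_params) < 2:
        raise ValueError("need at least two classes")
    counts = (
        [int(n_per_class)] * len(class_params)
        if np.isscalar(n_per_class)
        else [int(n) for n in n_per_class]
    )
    if len(counts) != len(class_params) or any(n < 1 for n in counts):
        raise ValueError("n_per_class must be >= 1 for every class")

    rows = []
    volumes: dict[str, VoxelVolume] = {}
    for ci, (params, n) in enumerate(zip(class_params, counts)):
        for i in range(n):
            sample_seed = int(seed) * 1_000_000 + ci * 10_000 + i
            vol, lms = generate_shape_volume(params, sample_seed)
            sid = f"class{params.class_id}_s{i:03d}"
            vol.specimen_id = sid
            volumes[sid] = vol
            row = {"specimen_id": sid, "label": f"class{params.class_id}"}
            for name, pt in (
                ("condyle1", lms["condyles"][0]),
                ("condyle2", lms["condyles"][1]),
                ("tip", lms["tip"]),
                ("norm_a", lms["norm_a"]),
                ("norm_b", lms["norm_b"]),
            ):
                for axis, v in zip("xyz", pt):
                    row[f"{name}_{axis}"] = float(v)
            rows.append(row)
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        from . import io as mio

        mio.save_dataset(out_dir, manifest, volumes)
    return manifest, volumes


def quadrant_informative_triplets(
    n_per_class: int = 40,
    n_classes: int = 3,
    seed: int = 0,
    canvas: int = 128,
):
    """Triplet images whose class signal sits in one quadrant of one channel.

    The x channel carries a class-specific glyph confined to the upper-left
    quadrant plus a class-independent bar in the lower half; the y and z
    channels are blank.  Built for the saliency-localization and
    projection-ablation fixtures.  Returns (X, labels, quadrant_slice).
    """
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    X = np.zeros((n, 3, canvas, canvas), dtype=np.float32)
    y = np.repeat(np.arange(n_classes), n_per_class)
    half = canvas // 2
    for idx, label in enumerate(y):
        img = np.zeros((canvas, canvas), dtype=np.float32)
        # shared, uninformative bar in the lower half
        r0 = int(3 * canvas / 4)
        img[r0 : r0 + 6, canvas // 8 : canvas - canvas // 8] = 1.0
        # class glyph inside the upper-left quadrant
        cy = half // 2 + rng.integers(-4, 5)
        cx = half // 2 + rng.integers(-4, 5)
        size = 14 + rng.integers(-2, 3)
        rr, cc = np.meshgrid(np.arange(canvas), np.arange(canvas), indexing="ij")
        if label % 3 == 0:
            glyph = (rr - cy) ** 2 + (cc - cx) ** 2 <= size**2
        elif label % 3 == 1:
            d2 = (rr - cy) ** 2 + (cc - cx) ** 2
            glyph = (d2 <= size**2) & (d2 >= (size - 5) ** 2)
        else:
            glyph = (np.abs(rr - cy) <= 3) | (np.abs(cc - cx) <= 3)
            glyph &= (np.abs(rr - cy) <= size) & (np.abs(cc - cx) <= size)
        quad = np.zeros_like(glyph)
        quad[:half, :half] = True
        img[glyph & quad] = 1.0
        X[idx, 0] = img
    order = rng.permutation(n)
    return X[order], y[order], (slice(0, half), slice(0, half))
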