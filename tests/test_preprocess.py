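"""Preprocessing: orientation, split/mirror, projection and rasterization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from morphovae import (
    HalfSpecimen,
    VoxelVolume,
    canonicalize_orientation,
    normalize_and_rasterize,
    project_volume,
    split_and_mirror,
    synthetic,
)
from morphovae.errors import CanvasOverflowError, EmptyHalfError, InvalidLandmarkError


def make_specimen(scale=1.2, seed=0):
    params = synthetic.separable_class_params(1, size_jitter=(scale, scale))[0]
    return synthetic.generate_shape_volume(params, seed)


def brute_force_projections(occ):
    nz, ny, nx = occ.shape
    x_proj = np.zeros((nz, ny), dtype=bool)
    y_proj = np.zeros((nz, nx), dtype=bool)
    z_proj = np.zeros((ny, nx), dtype=bool)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if occ[z, y, x]:
                    x_proj[z, y] = True
                    y_proj[z, x] = True
                    z_proj[y, x] = True
    return {"x": x_proj, "y": y_proj, "z": z_proj}


# ---------------------------------------------------------------- orientation
def test_canonical_volume_returned_unchanged():
    vol, lms = make_specimen()
    out = canonicalize_orientation(vol, lms["condyles"], lms["tip"])
    assert out.orientation_checked
    np.testing.assert_array_equal(out.occupancy, vol.occupancy)


def test_rotation_recovered_with_high_dice():
    vol, lms = make_specimen(scale=2.0)
    occ = vol.occupancy
    theta = np.deg2rad(30)
    rz = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    d = int(np.ceil(np.linalg.norm(occ.shape))) + 2
    center_in = (np.array(occ.shape[::-1], dtype=float) - 1) / 2
    center_out = np.full(3, (d - 1) / 2.0)
    a_zyx = rz.T[::-1, ::-1]
    off = center_in[::-1] - a_zyx @ center_out[::-1]
    rotated = (
        ndimage.affine_transform(
            occ.astype(np.float32), a_zyx, offset=off, output_shape=(d, d, d), order=1
        )
        > 0.5
    )
    rot_pt = lambda p: rz @ (np.asarray(p, dtype=float) - center_in) + center_out
    rvol = VoxelVolume(rotated, specimen_id="rot")
    out, to_canonical = canonicalize_orientation(
        rvol,
        [rot_pt(p) for p in lms["condyles"]],
        rot_pt(lms["tip"]),
        return_transform=True,
    )
    # overlap with the original translated (subvoxel, same interpolation) so
    # its condyle midpoint lands on the output cube center, then Dice
    mid_orig = 0.5 * (np.asarray(lms["condyles"][0]) + np.asarray(lms["condyles"][1]))
    big = out.occupancy.shape[0]
    shift = np.full(3, (big - 1) / 2.0) - mid_orig  # (x, y, z)
    reference = (
        ndimage.affine_transform(
            occ.astype(np.float32),
            np.eye(3),
            offset=-shift[::-1],
            output_shape=(big, big, big),
            order=1,
        )
        > 0.5
    )
    inter = (reference & out.occupancy).sum()
    dice = 2 * inter / (reference.sum() + out.occupancy.sum())
    assert dice >= 0.98, f"dice {dice:.3f}"
    # occupancy preserved within resampling tolerance
    assert abs(out.n_voxels - vol.n_voxels) / vol.n_voxels <= 0.02


def test_degenerate_landmarks_raise():
    vol, lms = make_specimen()
    tip = lms["tip"]
    mid_as_condyles = [tip, tip]
    with pytest.raises(InvalidLandmarkError):
        canonicalize_orientation(vol, mid_as_condyles, tip)


# ---------------------------------------------------------------- split/mirror
def test_symmetric_volume_halves_identical():
    occ = np.zeros((8, 8, 10), dtype=bool)
    occ[2:6, 1:7, 2:8] = True  # symmetric about x plane between cols 4 and 5
    occ[3, 2, 3] = occ[3, 2, 6] = True
    vol = VoxelVolume(occ, specimen_id="sym")
    left, right = split_and_mirror(vol, tip_point=(4.5, 3.0, 3.0))
    assert left.mirrored is False and right.mirrored is True
    assert left.parent_id == right.parent_id == "sym"
    np.testing.assert_array_equal(left.occupancy, right.occupancy)


def test_asymmetric_volume_reassembles_exactly():
    vol, lms = make_specimen(seed=3)
    occ = vol.occupancy.copy()
    occ[5:9, 5:9, 2:5] |= True  # break symmetry
    vol = VoxelVolume(occ, specimen_id="asym")
    left, right = split_and_mirror(vol, lms["tip"])
    c = left.occupancy.shape[2]
    rebuilt = np.concatenate([left.occupancy, right.occupancy[:, :, ::-1]], axis=2)
    assert c + right.occupancy.shape[2] == occ.shape[2]
    np.testing.assert_array_equal(rebuilt, occ)


def test_split_plane_outside_raises():
    occ = np.zeros((4, 4, 6), dtype=bool)
    occ[1:3, 1:3, 1:5] = True
    vol = VoxelVolume(occ)
    with pytest.raises(EmptyHalfError):
        split_and_mirror(vol, tip_point=(20.0, 2.0, 2.0))


# ---------------------------------------------------------------- projections
def test_single_voxel_projection():
    occ = np.zeros((5, 6, 7), dtype=bool)
    occ[2, 3, 4] = True
    half = HalfSpecimen(occ, "left", False, "p")
    proj = project_volume(half)
    assert proj["x"].sum() == proj["y"].sum() == proj["z"].sum() == 1
    assert proj["x"][2, 3] and proj["y"][2, 4] and proj["z"][3, 4]


def test_random_volume_matches_brute_force():
    rng = np.random.default_rng(12)
    occ = rng.random((20, 20, 20)) < 0.05
    occ[10, 10, 10] = True
    half = HalfSpecimen(occ, "left", False, "p")
    proj = project_volume(half)
    expected = brute_force_projections(occ)
    for key in "xyz":
        np.testing.assert_array_equal(proj[key], expected[key])


def test_full_cuboid_projects_to_full_rectangles():
    occ = np.zeros((6, 7, 8), dtype=bool)
    occ[1:5, 2:6, 3:7] = True
    proj = project_volume(HalfSpecimen(occ, "left", False, "p"))
    assert proj["x"].sum() == 4 * 4 and proj["y"].sum() == 4 * 4 and proj["z"].sum() == 4 * 4
    assert proj["x"][1:5, 2:6].all() and proj["y"][1:5, 3:7].all() and proj["z"][2:6, 3:7].all()


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_projection_oracle_property(seed):
    rng = np.random.default_rng(seed)
    occ = rng.random((8, 9, 10)) < 0.2
    occ[4, 4, 5] = True
    proj = project_volume(HalfSpecimen(occ, "left", False, "p"))
    np.testing.assert_array_equal(proj["x"], occ.any(axis=2))
    np.testing.assert_array_equal(proj["y"], occ.any(axis=1))
    np.testing.assert_array_equal(proj["z"], occ.any(axis=0))


def test_mirrored_projections_equal_flipped():
    vol, lms = make_specimen(seed=5)
    left, right = split_and_mirror(vol, lms["tip"])
    unmirrored_right = HalfSpecimen(
        right.occupancy[:, :, ::-1], "right", False, right.parent_id
    )
    proj_m = project_volume(right)
    proj_u = project_volume(unmirrored_right)
    np.testing.assert_array_equal(proj_m["x"], proj_u["x"])  # x-proj invariant
    np.testing.assert_array_equal(proj_m["y"], proj_u["y"][:, ::-1])
    np.testing.assert_array_equal(proj_m["z"], proj_u["z"][:, ::-1])


# ------------------------------------------------------------- rasterization
def _blob_projections(radius, size):
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    disk = (rr - size / 2) ** 2 + (cc - size / 2) ** 2 <= radius**2
    return {"x": disk, "y": disk, "z": disk}


def test_unit_scale_keeps_geometry():
    raw = _blob_projections(15, 64)
    a = (32.0 - 20.0, 32.0)
    b = (32.0 + 20.0, 32.0)
    triplet, transform = normalize_and_rasterize(raw, a, b, target_length_px=40)
    assert transform.scale == pytest.approx(1.0)
    assert triplet.x_proj.sum() == raw["x"].sum()
    rows, cols = np.nonzero(triplet.x_proj)
    # landmark midpoint at the canvas center
    assert abs(rows.mean() - 63.5) < 1.5 and abs(cols.mean() - 63.5) < 1.5


def test_double_distance_quarters_area():
    raw = _blob_projections(20, 100)
    a, b = (10.0, 50.0), (90.0, 50.0)  # distance 80 = 2x target
    triplet, transform = normalize_and_rasterize(raw, a, b, target_length_px=40)
    assert transform.scale == pytest.approx(0.5)
    in_area = raw["x"].sum()
    out_area = triplet.x_proj.sum()
    assert abs(out_area - in_area / 4) <= 0.10 * in_area / 4
    # landmark distance in the output within +-1 px of the target
    assert abs(80 * transform.scale - 40) <= 1


def test_five_fold_size_invariance():
    """Same geometry at 5x size maps to nearly identical triplets."""
    vol_small, lm_s = make_specimen(scale=0.45, seed=9)
    vol_large, lm_l = make_specimen(scale=2.25, seed=9)
    from morphovae import preprocess_specimen

    tri_s = preprocess_specimen(
        vol_small, lm_s["condyles"], lm_s["tip"], lm_s["norm_a"], lm_s["norm_b"], 80
    )[0][1]
    tri_l = preprocess_specimen(
        vol_large, lm_l["condyles"], lm_l["tip"], lm_l["norm_a"], lm_l["norm_b"], 80
    )[0][1]
    for key in ("x_proj", "y_proj", "z_proj"):
        a, c = getattr(tri_s, key).astype(bool), getattr(tri_l, key).astype(bool)
        agree = (a == c).sum() / a.size
        assert agree >= 0.95, f"{key}: only {agree:.3f} pixel agreement"


def test_coincident_landmarks_raise():
    raw = _blob_projections(5, 32)
    with pytest.raises(InvalidLandmarkError):
        normalize_and_rasterize(raw, (10.0, 10.0), (10.0, 10.0), 40)


def test_canvas_overflow_reports_required_size():
    raw = _blob_projections(30, 64)
    a, b = (32.0, 12.0), (32.0, 52.0)  # distance 40
    with pytest.raises(CanvasOverflowError):
        # scale 3x -> blob diameter ~180 px > 128
        normalize_and_rasterize(raw, a, b, target_length_px=120)
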