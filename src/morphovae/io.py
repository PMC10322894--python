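"""On-disk formats: NPZ/HDF5 voxel containers, manifests and triplet archives."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ProjectionTriplet, VoxelVolume

__all__ = [
    "save_volume",
    "load_volume",
    "save_dataset",
    "load_dataset",
    "save_triplet",
    "load_triplet",
]


def save_volume(path, volume: VoxelVolume) -> None:
    """Write a volume as NPZ (default) or HDF5 depending on the suffix.

    Both containers carry an ``occupancy`` uint8 dataset and a ``voxel_size``
    attribute/array.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("occupancy", data=volume.occupancy.astype(np.uint8))
            ds.attrs["voxel_size"] = volume.voxel_size
            ds.attrs["specimen_id"] = volume.specimen_id
    else:
        np.savez_compressed(
            path,
            occupancy=volume.occupancy.astype(np.uint8),
            voxel_size=np.float64(volume.voxel_size),
            specimen_id=np.bytes_(volume.specimen_id.encode()),
        )


def load_volume(path) -> VoxelVolume:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["occupancy"]
            return VoxelVolume(
                ds[...].astype(bool),
                voxel_size=float(ds.attrs.get("voxel_size", 1.0)),
                specimen_id=str(ds.attrs.get("specimen_id", "")),
            )
    with np.load(path) as data:
        return VoxelVolume(
            data["occupancy"].astype(bool),
            voxel_size=float(data["voxel_size"]),
            specimen_id=bytes(data["specimen_id"]).decode(),
        )


def save_dataset(out_dir, manifest: pd.DataFrame, volumes: dict[str, VoxelVolume]) -> None:
    out_dir = Path(out_dir)
    (out_dir / "volumes").mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    paths = []
    for sid in manifest["specimen_id"]:
        rel = f"volumes/{sid}.npz"
        save_volume(out_dir / rel, volumes[sid])
        paths.append(rel)
    manifest["path"] = paths
    manifest.to_csv(out_dir / "manifest.csv", index=False)


def load_dataset(in_dir) -> tuple[pd.DataFrame, dict[str, VoxelVolume]]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    volumes = {
        row.specimen_id: load_volume(in_dir / row.path)
        for row in manifest.itertuples(index=False)
    }
    return manifest, volumes


def save_triplet(path, triplet: ProjectionTriplet) -> None:
    """NPZ with the three projections plus a JSON provenance sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        x_proj=triplet.x_proj,
        y_proj=triplet.y_proj,
        z_proj=triplet.z_proj,
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "parent_id": triplet.parent_id,
                "side": triplet.side,
                "reference_length_px": triplet.reference_length_px,
            }
        )
    )


def load_triplet(path) -> ProjectionTriplet:
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    with np.load(path) as data:
        return ProjectionTriplet(
            x_proj=data["x_proj"],
            y_proj=data["y_proj"],
            z_proj=data["z_proj"],
            reference_length_px=int(meta.get("reference_length_px", 0)),
            parent_id=meta.get("parent_id", ""),
            side=meta.get("side", ""),
        )
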