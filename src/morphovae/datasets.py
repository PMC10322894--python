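"""In-memory dataset of projection triplets plus construction from volumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    HalfSpecimen,
    ProjectionTriplet,
    RasterTransform,
    VoxelVolume,
    preprocess_specimen,
)

__all__ = ["TripletDataset", "build_triplet_dataset"]


@dataclass
class TripletDataset:
    """Arrays ready for the network plus per-item provenance.

    ``X`` is (N, 3, S, S) float32 with channels in x/y/z-projection order;
    ``y`` holds integer label codes indexing ``label_names``.  ``halves`` and
    ``transforms`` are kept when the dataset was built from volumes so the
    occlusion experiments can re-project modified geometry with the original
    scale and placement.
    """

    X: np.ndarray
    y: np.ndarray
    label_names: list[str]
    parent_ids: np.ndarray
    sides: list[str] = field(default_factory=list)
    halves: list[HalfSpecimen] | None = None
    transforms: list[RasterTransform] | None = None

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_classes(self) -> int:
        return len(self.label_names)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": self.parent_ids,
                "label": [self.label_names[c] for c in self.y],
                "side": self.sides if self.sides else [""] * len(self),
            }
        )

    def parent_manifest(self) -> pd.DataFrame:
        """One row per parent specimen (for split planning)."""
        return (
            self.manifest()[["specimen_id", "label"]]
            .drop_duplicates("specimen_id")
            .reset_index(drop=True)
        )

    def subset(self, idx) -> "TripletDataset":
        idx = np.asarray(idx)
        return TripletDataset(
            X=self.X[idx],
            y=self.y[idx],
            label_names=self.label_names,
            parent_ids=self.parent_ids[idx],
            sides=[self.sides[i] for i in idx] if self.sides else [],
            halves=[self.halves[i] for i in idx] if self.halves is not None else None,
            transforms=[self.transforms[i] for i in idx] if self.transforms is not None else None,
        )

    def indices_for_parents(self, parent_ids) -> np.ndarray:
        wanted = set(parent_ids)
        return np.array([i for i, p in enumerate(self.parent_ids) if p in wanted], dtype=int)


def build_triplet_dataset(
    manifest: pd.DataFrame,
    volumes: dict[str, VoxelVolume],
    target_length_px: int = 80,
) -> TripletDataset:
    """Run the full preprocessing path over a manifest of volumes.

    The manifest needs columns ``specimen_id``, ``label`` and landmark columns
    ``{condyle1,condyle2,tip,norm_a,norm_b}_{x,y,z}``.
    """
    label_names = sorted(manifest["label"].unique())
    code = {name: i for i, name in enumerate(label_names)}

    xs, ys, parents, sides, halves, transforms = [], [], [], [], [], []
    for row in manifest.itertuples(index=False):
        vol = volumes[row.specimen_id]
        pt = lambda name: (
            getattr(row, f"{name}_x"),
            getattr(row, f"{name}_y"),
            getattr(row, f"{name}_z"),
        )
        for half, triplet, transform in preprocess_specimen(
            vol,
            condyle_points=(pt("condyle1"), pt("condyle2")),
            tip_point=pt("tip"),
            landmark_a=pt("norm_a"),
            landmark_b=pt("norm_b"),
            target_length_px=target_length_px,
        ):
            xs.append(triplet.stack())
            ys.append(code[row.label])
            parents.append(row.specimen_id)
            sides.append(half.side)
            halves.append(half)
            transforms.append(transform)

    return TripletDataset(
        X=np.stack(xs),
        y=np.array(ys, dtype=int),
        label_names=label_names,
        parent_ids=np.array(parents, dtype=object),
        sides=sides,
        halves=halves,
        transforms=transforms,
    )
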