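"""Missing-segment experiment: crop half-volumes along an axis, re-project
with the original raster transform, reconstruct through a trained model and
trace loss / accuracy versus crop rate."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import TripletDataset
from .errors import EmptyCropError
from .model import MorphoVAE, binary_cross_entropy
from .preprocess import HalfSpecimen, apply_transform, project_volume

__all__ = ["CropSpec", "crop_volume", "crop_response_curve"]

# removal side convention: vertical crops eat the teeth-side (low-z) slab,
# horizontal crops eat the anterior-tip (high-y) slab
_AXES = {"vertical": 0, "horizontal": 1}  # occupancy index (z, y, x)


@dataclass
class CropSpec:
    axis: str  # 'vertical' | 'horizontal'
    crop_rate: float  # fraction of the *occupied* extent removed

    def __post_init__(self):
        if self.axis not in _AXES:
            raise ValueError("axis must be 'vertical' or 'horizontal'")
        if not 0.0 <= self.crop_rate < 1.0:
            raise ValueError("crop_rate must be in [0, 1)")


def crop_volume(half: HalfSpecimen, spec: CropSpec) -> HalfSpecimen:
    """Empty a slab covering ``crop_rate`` of the occupied extent on one axis.

    The slab thickness is round(rate * occupied extent); windows are half-open
    voxel index ranges.  Raises :class:`EmptyCropError` if nothing remains.
    """
    occ = half.occupancy
    if not occ.any():
        raise EmptyCropError("cannot crop an empty half")
    out = occ.copy()
    if spec.crop_rate == 0.0:
        return HalfSpecimen(out, half.side, half.mirrored, half.parent_id)

    ax = _AXES[spec.axis]
    filled = np.nonzero(occ.any(axis=tuple(i for i in range(3) if i != ax)))[0]
    lo, hi = int(filled.min()), int(filled.max())
    extent = hi - lo + 1
    thickness = int(round(spec.crop_rate * extent))
    if thickness >= extent:
        raise EmptyCropError(f"crop rate {spec.crop_rate} removes the whole extent")
    if thickness == 0:
        return HalfSpecimen(out, half.side, half.mirrored, half.parent_id)

    if spec.axis == "vertical":
        window = slice(lo, lo + thickness)  # teeth side upward
    else:
        window = slice(hi - thickness + 1, hi + 1)  # anterior tip backward
    index = [slice(None)] * 3
    index[ax] = window
    out[tuple(index)] = False
    if not out.any():
        raise EmptyCropError("crop removed all voxels")
    return HalfSpecimen(out, half.side, half.mirrored, half.parent_id)


def crop_response_curve(
    model: MorphoVAE,
    dataset: TripletDataset,
    axis: str,
    rates,
    indices=None,
) -> pd.DataFrame:
    """Per-rate mean/SD reconstruction loss against the *uncropped* originals
    and classification accuracy of the cropped inputs.

    The cropped halves are re-projected with each sample's stored raster
    transform (same scale and placement; no re-normalization, so the defect
    stays visible).  Failed samples are skipped and counted in ``n_failed``.
    Requires a dataset built from volumes (``halves``/``transforms`` present).
    """
    if dataset.halves is None or dataset.transforms is None:
        raise ValueError("dataset lacks half-volumes/transforms; rebuild from volumes")
    rates = sorted(float(r) for r in rates)
    if rates[0] != 0.0:
        raise ValueError("rates must include 0 (the uncropped baseline)")
    idx = np.arange(len(dataset)) if indices is None else np.asarray(indices)

    rows = []
    for rate in rates:
        spec_v = CropSpec(axis, rate)
        x_crops, kept, failed = [], [], 0
        for i in idx:
            try:
                cropped = crop_volume(dataset.halves[i], spec_v)
                raw = project_volume(cropped)
                triplet = apply_transform(raw, dataset.transforms[i])
            except Exception:
                failed += 1
                continue
            x_crops.append(triplet.stack())
            kept.append(i)
        if x_crops:
            xc = np.stack(x_crops)
            recon = model.reconstruct(xc)
            originals = dataset.X[kept].astype(np.float64)
            losses = np.array(
                [binary_cross_entropy(originals[j], recon[j]) for j in range(len(kept))]
            )
            preds = model.predict_probs(xc).argmax(axis=1)
            accuracy = float(np.mean(preds == dataset.y[kept]))
        else:
            losses, accuracy = np.array([]), np.nan
        rows.append(
            {
                "rate": rate,
                "mean_loss": float(losses.mean()) if losses.size else np.nan,
                "sd_loss": float(losses.std()) if losses.size else np.nan,
                "accuracy": accuracy,
                "n": len(kept),
                "n_failed": failed,
            }
        )
    return pd.DataFrame(rows)
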