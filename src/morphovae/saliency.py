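"""Score-CAM saliency maps and the projection-direction ablation experiment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skimage.transform import resize

from .model import MorphoVAE

CHANNEL_NAMES = ("x", "y", "z")

__all__ = [
    "SaliencyMap",
    "score_cam",
    "class_mean_saliency",
    "direction_ablation",
    "direction_ablation_table",
    "CHANNEL_NAMES",
]


@dataclass
class SaliencyMap:
    """Non-negative saliency, overall and per input channel.

    ``combined`` is the plain Score-CAM output: the sum over activation
    filters of the min-max-normalized upsampled activation map weighted by
    the target-class probability of the correspondingly masked input.
    ``per_channel`` restricts the combined map to each projection's silhouette
    (the display convention: saliency lives on the shape, so a blank channel
    has a blank map).
    """

    combined: np.ndarray
    per_channel: np.ndarray
    target_class: int
    n_filters: int


def score_cam(
    model: MorphoVAE,
    triplet: np.ndarray,
    target_class: int,
    batch_size: int = 64,
) -> SaliencyMap:
    """Score-CAM for one input.

    For every filter of the designated encoder conv layer: upsample its
    activation map to the input resolution (bilinear), min-max normalize to
    [0, 1], mask the input by elementwise multiplication, re-run the model and
    read the softmax probability of ``target_class``; the saliency map is the
    probability-weighted sum of the normalized maps.  Constant activation maps
    contribute zero (with a warning).
    """
    x = np.asarray(triplet, dtype=np.float32)
    if x.ndim != 3:
        raise ValueError("score_cam expects a single (C, S, S) input")
    size = x.shape[-1]

    acts = model.conv_activations(x)[0]  # (F, s, s)
    n_filters = acts.shape[0]
    maps = np.zeros((n_filters, size, size), dtype=np.float64)
    alive = np.zeros(n_filters, dtype=bool)
    for k in range(n_filters):
        a = acts[k]
        lo, hi = a.min(), a.max()
        if hi - lo < 1e-12:
            continue
        up = resize(a, (size, size), order=1, anti_aliasing=False, preserve_range=True)
        maps[k] = (up - up.min()) / (up.max() - up.min())
        alive[k] = True
    if not alive.any():
        warnings.warn("all activation maps are constant: zero saliency", RuntimeWarning)
        zero = np.zeros((size, size))
        return SaliencyMap(zero, np.zeros_like(x, dtype=np.float64), target_class, n_filters)
    if not alive.all():
        warnings.warn(
            f"{int((~alive).sum())} constant activation map(s) contribute zero saliency",
            RuntimeWarning,
        )

    idx = np.nonzero(alive)[0]
    weights = np.zeros(n_filters)
    for start in range(0, len(idx), batch_size):
        sel = idx[start : start + batch_size]
        masked = x[None] * maps[sel, None, :, :].astype(np.float32)
        probs = model.predict_probs(masked)
        weights[sel] = probs[:, target_class]

    combined = np.tensordot(weights, maps, axes=1)
    per_channel = combined[None, :, :] * (x > 0)
    return SaliencyMap(combined, per_channel, int(target_class), n_filters)


def class_mean_saliency(
    model: MorphoVAE, X: np.ndarray, labels: np.ndarray, target_class: int
) -> SaliencyMap:
    """Mean of per-sample Score-CAM maps over the samples of one class."""
    labels = np.asarray(labels)
    members = np.nonzero(labels == target_class)[0]
    if len(members) == 0:
        raise ValueError(f"no samples with label {target_class}")
    acc_combined = None
    acc_channel = None
    n_filters = 0
    for i in members:
        sm = score_cam(model, X[i], target_class)
        n_filters = sm.n_filters
        acc_combined = sm.combined if acc_combined is None else acc_combined + sm.combined
        acc_channel = sm.per_channel if acc_channel is None else acc_channel + sm.per_channel
    return SaliencyMap(
        acc_combined / len(members), acc_channel / len(members), int(target_class), n_filters
    )


def direction_ablation(
    model: MorphoVAE, X: np.ndarray, labels: np.ndarray, kept_directions
) -> float:
    """Classification accuracy with the non-kept projection channels blanked."""
    kept = set(kept_directions)
    if not kept:
        raise ValueError("kept_directions must not be empty")
    unknown = kept - set(CHANNEL_NAMES)
    if unknown:
        raise ValueError(f"unknown directions {sorted(unknown)}")
    Xa = np.array(X, dtype=np.float32, copy=True)
    for ci, name in enumerate(CHANNEL_NAMES):
        if name not in kept:
            Xa[:, ci] = 0.0
    probs = model.predict_probs(Xa)
    return float(np.mean(probs.argmax(axis=1) == np.asarray(labels)))


def direction_ablation_table(model: MorphoVAE, X: np.ndarray, labels: np.ndarray) -> dict:
    """Accuracy for all 7 non-empty subsets of {x, y, z}."""
    out = {}
    for r in (1, 2, 3):
        for combo in combinations(CHANNEL_NAMES, r):
            out["".join(combo)] = direction_ablation(model, X, labels, combo)
    return out
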