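"""Latent-space evaluation: cluster separation (CSI / Davies-Bouldin), SVM
accuracy, baselines, reconstruction re-classification and latent-grid panels.

CSI for clusters i, j is (delta_i + delta_j) / Delta_ij where delta is the
root-mean-square distance of a cluster's points to its centroid and Delta the
Euclidean centroid distance; values below 1 indicate separated clusters.
Averaging the per-cluster max over partners yields the Davies-Bouldin index
(p = q = 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .model import MorphoVAE, one_hot  # noqa: F401  (re-exported for harness use)

__all__ = [
    "ClusterStats",
    "GridPanel",
    "compute_csi",
    "davies_bouldin",
    "svm_latent_accuracy",
    "reclassification_accuracy",
    "latent_pca_grid",
    "pca_baseline",
    "latent_points",
]


@dataclass
class ClusterStats:
    points: np.ndarray
    labels: np.ndarray
    cluster_ids: np.ndarray
    centroids: np.ndarray
    dispersions: np.ndarray
    centroid_distances: np.ndarray
    csi: np.ndarray


@dataclass
class GridPanel:
    basis: np.ndarray  # (2, latent_dim) orthonormal rows (top-2 PCs)
    mean: np.ndarray
    grid_u: np.ndarray
    grid_v: np.ndarray
    images: np.ndarray  # (gu, gv, C, S, S)
    predicted_labels: np.ndarray  # (gu, gv)
    point_coords: np.ndarray  # (n, 2) projections of the data points
    point_plane_distance: np.ndarray  # (n,) |distance| to the PC1-PC2 plane
    explained_ratio: np.ndarray


def compute_csi(points: np.ndarray, labels) -> ClusterStats:
    """Centroids, RMS dispersions, pairwise distances and the CSI matrix."""
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    if points.ndim != 2 or len(points) != len(labels):
        raise ValueError("points must be (n, d) with one label per point")
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("need at least two clusters")

    k = len(ids)
    centroids = np.stack([points[labels == c].mean(axis=0) for c in ids])
    dispersions = np.array(
        [
            np.sqrt(np.mean(np.sum((points[labels == c] - centroids[i]) ** 2, axis=1)))
            for i, c in enumerate(ids)
        ]
    )
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    csi = np.full((k, k), np.nan)
    off = ~np.eye(k, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = dispersions[:, None] + dispersions[None, :]
        csi[off] = (num / np.where(dist > 0, dist, np.nan))[off]
    coincident = off & (dist == 0)
    if coincident.any():
        warnings.warn("coincident centroids: CSI reported as inf", RuntimeWarning)
        csi[coincident] = np.inf
    return ClusterStats(points, labels, ids, centroids, dispersions, dist, csi)


def davies_bouldin(stats: ClusterStats) -> float:
    """(1/k) * sum_i max_{j != i} CSI_ij; < 1 means well-separated clusters."""
    csi = stats.csi
    k = csi.shape[0]
    if k < 2:
        raise ValueError("need at least two clusters")
    worst = np.array([np.nanmax(np.delete(csi[i], i)) for i in range(k)])
    if np.isinf(worst).any():
        warnings.warn("infinite CSI propagated into the Davies-Bouldin index", RuntimeWarning)
    return float(worst.mean())


def svm_latent_accuracy(
    train_points, train_labels, test_points, test_labels, latent_dim: int | None = None
) -> float:
    """RBF-kernel SVM accuracy in the latent space.

    Fixed settings: C = 1.0, tol = 0.001, gamma = 1 / latent_dim.
    """
    train_points = np.asarray(train_points, dtype=np.float64)
    test_points = np.asarray(test_points, dtype=np.float64)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("SVM needs at least two classes in the training set")
    if latent_dim is None:
        latent_dim = train_points.shape[1]
    clf = SVC(kernel="rbf", C=1.0, tol=1e-3, gamma=1.0 / latent_dim)
    clf.fit(train_points, train_labels)
    return float(np.mean(clf.predict(test_points) == np.asarray(test_labels)))


def latent_points(model: MorphoVAE, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Deterministic latent coordinates (zeta = mu) for a batch of images."""
    out = [
        model.encode(X[i : i + batch_size]).mu for i in range(0, len(X), batch_size)
    ]
    return np.concatenate(out, axis=0)


def reclassification_accuracy(
    model: MorphoVAE, X: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Classifier accuracy on the inputs and on their reconstructions.

    The reconstruction path is decode(encode(x)) with deterministic encoding;
    the reconstructed image is re-encoded and classified like a fresh input.
    """
    labels = np.asarray(labels)
    probs = model.predict_probs(X)
    original = float(np.mean(probs.argmax(axis=1) == labels))
    recon = model.reconstruct(X).astype(np.float32)
    probs_r = model.predict_probs(recon)
    reconstructed = float(np.mean(probs_r.argmax(axis=1) == labels))
    return original, reconstructed


def pca_baseline(X: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Mean-centered pixel PCA of flattened triplets (no scaling), top
    ``n_components`` scores — the linear baseline for the comparison harness."""
    flat = np.asarray(X, dtype=np.float64).reshape(len(X), -1)
    return PCA(n_components=n_components, svd_solver="randomized", random_state=0).fit_transform(
        flat
    )


def latent_pca_grid(
    model: MorphoVAE,
    points: np.ndarray,
    grid_size: int = 7,
    expand: float = 0.10,
) -> GridPanel:
    """Decode a grid of latent positions on the top-2 PC plane (PC3 = 0).

    The plane basis comes from a PCA of the latent points; grid nodes span the
    projected data's bounding box expanded by ``expand`` on each side.  Each
    node is decoded and classified; data points carry their |distance| to the
    plane for size-coded plotting.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        raise ValueError("need at least three latent points")
    mean = points.mean(axis=0)
    centered = points - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-12 * max(1.0, s[0]):
        raise ValueError("degenerate latent covariance: no 2-D plane")
    basis = vt[:2]
    var = s**2 / max(len(points) - 1, 1)
    explained = var / var.sum()

    coords = centered @ basis.T
    resid = centered - coords @ basis
    plane_dist = np.linalg.norm(resid, axis=1)

    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = hi - lo
    lo = lo - expand * span
    hi = hi + expand * span
    grid_u = np.linspace(lo[0], hi[0], grid_size)
    grid_v = np.linspace(lo[1], hi[1], grid_size)

    uu, vv = np.meshgrid(grid_u, grid_v, indexing="ij")
    zetas = mean[None, :] + uu.reshape(-1, 1) * basis[0] + vv.reshape(-1, 1) * basis[1]
    images = model.decode(zetas)
    preds = model.classify(zetas).argmax(axis=1)
    img_shape = images.shape[1:]
    return GridPanel(
        basis=basis,
        mean=mean,
        grid_u=grid_u,
        grid_v=grid_v,
        images=images.reshape(grid_size, grid_size, *img_shape),
        predicted_labels=preds.reshape(grid_size, grid_size),
        point_coords=coords,
        point_plane_distance=plane_dist,
        explained_ratio=explained[:2],
    )
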