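"""Imaging-modality clustering from HSV colour statistics.

Nuclei benchmarks ship no modality metadata, so domains for style transfer
must be discovered from the images themselves.  Appearance is summarised as
three 16-bin normalized histograms over the hue, saturation and value
channels (a 48-dim feature that is invariant to flips and right-angle
rotations), clustered with K-means.  CLAHE contrast enhancement for dark
fluorescent images and a PCA embedding for visual inspection round out the
stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage import color, exposure
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "hsv_features",
    "fit_modalities",
    "assign_modality",
    "clahe_enhance",
    "pca_embed",
    "ModalityModel",
    "merge_to_domains",
    "purity",
]

N_BINS = 16


def hsv_features(image: np.ndarray) -> np.ndarray:
    """48-dim HSV histogram feature: 16 normalized bins per channel."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    hsv = color.rgb2hsv(image)
    blocks = []
    for c in range(3):
        hist, _ = np.histogram(hsv[:, :, c], bins=N_BINS, range=(0.0, 1.0))
        blocks.append(hist / hsv[:, :, c].size)
    return np.concatenate(blocks)


@dataclass
class ModalityModel:
    """Fitted K-means over HSV features."""

    k: int
    centroids: np.ndarray  # k x 48
    seed: int
    labels_: Optional[np.ndarray] = None
    inertia_: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"k": self.k, "seed": self.seed,
                 "centroids": self.centroids.tolist()},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "ModalityModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(k=d["k"], centroids=np.asarray(d["centroids"]), seed=d["seed"])


def fit_modalities(
    features: Sequence[np.ndarray], k: int = 6, seed: int = 0
) -> ModalityModel:
    """Cluster HSV features into `k` modalities (k-means++, 10 restarts)."""
    X = np.asarray(features, dtype=float)
    if len(X) < k:
        raise ValueError(f"need at least k={k} samples, got {len(X)}")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=10, max_iter=300,
        random_state=seed,
    ).fit(X)
    return ModalityModel(
        k=k, centroids=km.cluster_centers_, seed=seed,
        labels_=km.labels_.astype(int), inertia_=float(km.inertia_),
    )


def assign_modality(image: np.ndarray, model: ModalityModel) -> int:
    """Nearest-centroid cluster for one image; ties break to the lowest id."""
    f = hsv_features(image)
    d = np.linalg.norm(model.centroids - f, axis=1)
    return int(np.argmin(d))  # argmin returns the first (lowest) on ties


def assign_features(features: np.ndarray, model: ModalityModel) -> np.ndarray:
    """Vectorized nearest-centroid assignment for precomputed features."""
    X = np.asarray(features, dtype=float)
    d = np.linalg.norm(X[:, None, :] - model.centroids[None], axis=2)
    return np.argmin(d, axis=1)


def merge_to_domains(model: ModalityModel, n_domains: int) -> np.ndarray:
    """Map k clusters onto `n_domains` style domains.

    Repeatedly merges the pair of (possibly already merged) centroids at
    smallest Euclidean distance until `n_domains` groups remain; returns an
    array mapping cluster id -> domain id (domains numbered by the lowest
    member cluster id).  Used to reconcile a 6-cluster modality model with a
    5-domain style model.
    """
    if n_domains > model.k:
        raise ValueError("cannot split clusters into more domains")
    groups = [[i] for i in range(model.k)]
    cents = [model.centroids[i].copy() for i in range(model.k)]
    sizes = [1] * model.k
    while len(groups) > n_domains:
        best, pair = np.inf, None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = np.linalg.norm(cents[i] - cents[j])
                if d < best:
                    best, pair = d, (i, j)
        i, j = pair
        w = sizes[i] + sizes[j]
        cents[i] = (cents[i] * sizes[i] + cents[j] * sizes[j]) / w
        sizes[i] = w
        groups[i] = sorted(groups[i] + groups[j])
        del groups[j], cents[j], sizes[j]
    mapping = np.empty(model.k, dtype=int)
    for dom, members in enumerate(sorted(groups, key=lambda g: g[0])):
        for m in members:
            mapping[m] = dom
    return mapping


def clahe_enhance(
    image: np.ndarray, clip_limit: float = 0.01, tile: int = 8
) -> np.ndarray:
    """CLAHE on the value channel only; hue and saturation are preserved."""
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    image = np.asarray(image, dtype=float)
    hsv = color.rgb2hsv(image)
    v = hsv[:, :, 2]
    kernel = max(1, min(image.shape[0], image.shape[1]) // tile)
    hsv[:, :, 2] = exposure.equalize_adapthist(
        np.clip(v, 0, 1), kernel_size=kernel, clip_limit=clip_limit
    )
    out = color.hsv2rgb(hsv)
    return np.clip(out, 0.0, 1.0)


def enhance_images(
    images: Sequence[np.ndarray],
    mode: str = "auto",
    dark_threshold: float = 0.25,
    clip_limit: float = 0.01,
    tile: int = 8,
):
    """Apply CLAHE selectively as a preprocessing pass.

    ``auto`` enhances only dark images (mean value channel below
    `dark_threshold`, the regime of low-contrast fluorescence); ``all``
    enhances everything; ``off`` is the identity.  Masks are never touched —
    enhancement operates on pixels only, so instance membership is
    unchanged by construction.
    """
    if mode not in ("auto", "all", "off"):
        raise ValueError("mode must be one of auto|all|off")
    out = []
    for img in images:
        img = np.asarray(img, dtype=float)
        if mode == "all" or (
            mode == "auto" and color.rgb2hsv(img)[:, :, 2].mean() < dark_threshold
        ):
            img = clahe_enhance(img, clip_limit=clip_limit, tile=tile)
        out.append(img)
    return out


def pca_embed(features: Sequence[np.ndarray], n_components: int = 2):
    """Mean-centred PCA projection; returns (coords, explained_variance_ratio)."""
    X = np.asarray(features, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds feature dimension")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_


def plot_embedding(coords: np.ndarray, labels=None, ax=None):
    """Scatter a 2-D PCA embedding, coloured by cluster label."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    coords = np.asarray(coords)
    labels = np.zeros(len(coords), dtype=int) if labels is None else np.asarray(labels)
    for c in np.unique(labels):
        pts = coords[labels == c]
        ax.scatter(pts[:, 0], pts[:, 1], s=12, label=f"cluster {c}")
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.legend(fontsize=8)
    return ax


def purity(labels: np.ndarray, truth: np.ndarray) -> float:
    """Cluster purity: fraction of samples in their cluster's majority class."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    total = 0
    for c in np.unique(labels):
        members = truth[labels == c]
        total += np.bincount(members).max()
    return total / len(truth)
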