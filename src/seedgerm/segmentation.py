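"""Color-based seed/background segmentation.

Rice seed coats photographed on a dark dish background are yellowish: high
red and green, low blue. Each pixel is therefore reduced to the two channel
differences ``f1 = R - B`` and ``f2 = G - B``, which are large and positive
on seed coat and near zero on both the dark background and the near-white
radicle (whose channels are balanced). A two-cluster k-means in this feature
plane, seeded at (0, 0) and (30, 30), separates seed-coat pixels from
everything else; the cluster whose final center has the larger ``f1 + f2``
is the seed coat.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

#: label values in a :class:`ClusterLabelMap`
SEED_COAT = 1
BACKGROUND_OR_RADICLE = 0

_INITIAL_CENTERS = np.array([[0.0, 0.0], [30.0, 30.0]])


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if image.dtype == np.uint8:
        return image
    if np.issubdtype(image.dtype, np.integer):
        if image.min() < 0 or image.max() > 255:
            raise ValueError("integer image values must lie in [0, 255]")
        return image.astype(np.uint8)
    raise ValueError(f"unsupported image dtype {image.dtype}")


def load_rgb(path) -> np.ndarray:
    """Read a JPEG/PNG as an 8-bit RGB array.

    16-bit rasters are rescaled to 8-bit with a warning; alpha channels and
    grayscale are converted through Pillow's RGB mode.
    """
    from PIL import Image

    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B"):
            warnings.warn(f"{path}: 16-bit input rescaled to 8-bit", stacklevel=2)
            arr = np.asarray(im, dtype=np.float64)
            arr = (arr / max(arr.max(), 1) * 255.0).round()
            return np.repeat(arr[..., None], 3, axis=2).astype(np.uint8)
        return np.asarray(im.convert("RGB"))


def gaussian_smooth(image: np.ndarray, sigma: float = 0.8) -> np.ndarray:
    """Smooth each channel with a 3x3 Gaussian kernel.

    The kernel is the sampled Gaussian (normalized to unit sum) with the
    given sigma, truncated to a single-pixel radius; borders are handled by
    edge replication. Output is rounded half-away-from-zero and clamped to
    [0, 255].
    """
    image = _validate_rgb(image)
    out = np.empty_like(image)
    radius = 1
    for c in range(3):
        smoothed = ndimage.gaussian_filter(
            image[..., c].astype(np.float64),
            sigma=sigma,
            mode="nearest",
            radius=radius,
        )
        out[..., c] = np.clip(np.floor(smoothed + 0.5), 0, 255).astype(np.uint8)
    return out


def color_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel (f1, f2) = (R - B, G - B), signed, unclamped.

    Returns an HxWx2 int16 array; values span [-255, 255].
    """
    image = _validate_rgb(image).astype(np.int16)
    return np.stack(
        [image[..., 0] - image[..., 2], image[..., 1] - image[..., 2]], axis=-1
    )


@dataclasses.dataclass
class ClusterLabelMap:
    """Result of the two-cluster segmentation.

    ``labels`` holds ``SEED_COAT`` (1) or ``BACKGROUND_OR_RADICLE`` (0) per
    pixel. ``centers`` are the converged (f1, f2) cluster centers indexed by
    label value. ``degenerate`` flags inputs without two separable feature
    populations (all pixels identical, or a cluster emptied during Lloyd
    iteration).
    """

    labels: np.ndarray
    centers: np.ndarray
    n_iter: int
    degenerate: bool = False

    @property
    def seed_coat_mask(self) -> np.ndarray:
        return self.labels == SEED_COAT


def kmeans_two_clusters(
    features: np.ndarray,
    *,
    tol: float = 1e-3,
    max_iter: int = 100,
    subsample_stride: int = 1,
) -> ClusterLabelMap:
    """Two-cluster Lloyd k-means on the (f1, f2) feature plane.

    Centers start at (0, 0) and (30, 30) and iterate until both move less
    than ``tol`` (Euclidean) or ``max_iter`` is hit. The cluster whose final
    center has the larger coordinate sum is labeled seed coat; a tie goes to
    the cluster initialized at (30, 30). With ``subsample_stride > 1`` the
    centers are fit on a strided pixel subsample (for very large images) and
    the final assignment still covers every pixel.

    If a cluster empties, its previous center is kept and the result is
    flagged degenerate; an all-identical input likewise yields a degenerate
    single-cluster result (with a warning) labeled by the nearest initial
    center.
    """
    features = np.asarray(features)
    if features.ndim != 3 or features.shape[2] != 2:
        raise ValueError("expected an HxWx2 feature map")
    shape = features.shape[:2]
    pts = features.reshape(-1, 2).astype(np.float64)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 pixels")
    if subsample_stride > 1:
        fit_pts = features[::subsample_stride, ::subsample_stride].reshape(-1, 2)
        fit_pts = fit_pts.astype(np.float64)
    else:
        fit_pts = pts

    centers = _INITIAL_CENTERS.copy()
    degenerate = False
    if np.all(fit_pts == fit_pts[0]):
        warnings.warn(
            "all feature values identical: degenerate single-cluster result",
            stacklevel=2,
        )
        labels_flat = _assign(pts, centers)
        return ClusterLabelMap(
            labels=_orient(labels_flat, centers).reshape(shape),
            centers=_oriented_centers(centers),
            n_iter=0,
            degenerate=True,
        )

    # features are small integers, so Lloyd iteration on the unique feature
    # values with multiplicity weights is exactly equivalent to iterating
    # over all pixels, at a fraction of the cost
    codes = (fit_pts[:, 0].astype(np.int32) + 255) * 511 + (
        fit_pts[:, 1].astype(np.int32) + 255
    )
    uniq_codes, counts = np.unique(codes, return_counts=True)
    uniq = np.stack(
        [uniq_codes // 511 - 255, uniq_codes % 511 - 255], axis=1
    ).astype(np.float64)
    weights = counts.astype(np.float64)

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        assign = _assign(uniq, centers)
        new_centers = centers.copy()
        for k in range(2):
            sel = assign == k
            w = weights[sel]
            if w.sum() == 0:
                degenerate = True  # keep previous center (Lloyd fallback)
            else:
                new_centers[k] = (uniq[sel] * w[:, None]).sum(axis=0) / w.sum()
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        if shift < tol:
            break

    labels_flat = _assign(pts, centers)
    return ClusterLabelMap(
        labels=_orient(labels_flat, centers).reshape(shape),
        centers=_oriented_centers(centers),
        n_iter=n_iter,
        degenerate=degenerate,
    )


def _assign(pts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # squared Euclidean distance to each of the two centers; ties go to the
    # second (higher-initialized) center so the seed-coat tie-break below is
    # deterministic
    d0 = np.square(pts - centers[0]).sum(axis=1)
    d1 = np.square(pts - centers[1]).sum(axis=1)
    return (d1 <= d0).astype(np.uint8)


def _coat_index(centers: np.ndarray) -> int:
    s0, s1 = centers.sum(axis=1)
    return 1 if s1 >= s0 else 0


def _orient(labels_flat: np.ndarray, centers: np.ndarray) -> np.ndarray:
    coat = _coat_index(centers)
    return np.where(labels_flat == coat, SEED_COAT, BACKGROUND_OR_RADICLE).astype(
        np.uint8
    )


def _oriented_centers(centers: np.ndarray) -> np.ndarray:
    coat = _coat_index(centers)
    # index 0 = background/radicle center, index 1 = seed-coat center
    return np.stack([centers[1 - coat], centers[coat]])


def segment_image(
    image: np.ndarray,
    *,
    sigma: float = 0.8,
    subsample_stride: int = 1,
) -> tuple[np.ndarray, ClusterLabelMap]:
    """Smooth, featurize and cluster an RGB image in one call.

    Returns the smoothed image together with the label map (clustering runs
    on features of the smoothed image).
    """
    smoothed = gaussian_smooth(image, sigma=sigma)
    labels = kmeans_two_clusters(
        color_features(smoothed), subsample_stride=subsample_stride
    )
    return smoothed, labels
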