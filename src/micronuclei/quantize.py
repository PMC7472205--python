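"""Sharpening and color-layer quantization of a stain channel.

Each channel is quantized into ``k`` grayscale layers by 1-D k-means over
the intensity histogram.  Layers are numbered 1 (brightest) .. k (darkest);
the darkest layer is the background.  The *cumulative* layer region at
level q — all pixels at least as bright as layer q — is the thresholded
region whose contour the signature analysis traces: the lower the layer's
grayscale value, the larger its region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import unsharp_mask
from sklearn.cluster import KMeans

from .io_images import ChannelImage

__all__ = [
    "QuantizedImage",
    "LayerRegion",
    "sharpen",
    "quantize_channel",
    "background_mask",
    "foreground_mask",
    "layer_region",
]

K_SOFT_RANGE = (10, 20)


@dataclass(frozen=True)
class QuantizedImage:
    """Per-pixel layer assignment plus the grayscale centroid of each layer.

    ``level_index`` holds integers in ``[1, k]`` with 1 the brightest layer
    and ``k`` the darkest (background).  ``level_values`` are the k-means
    centroids sorted strictly descending.
    """

    level_index: np.ndarray
    level_values: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if self.level_values.shape != (self.k,):
            raise ValueError("level_values length must equal k")
        if self.k > 1 and not np.all(np.diff(self.level_values) < 0):
            raise ValueError("level_values must be strictly decreasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.level_index.shape


@dataclass(frozen=True)
class LayerRegion:
    """Cumulative thresholded region of one color layer."""

    layer: int
    mask: np.ndarray
    threshold_value: float


def sharpen(ch: ChannelImage, amount: float = 1.0) -> ChannelImage:
    """Unsharp-mask a channel (3x3-scale Gaussian blur), clipped to [0, 255].

    ``amount = 0`` returns the input unchanged; a constant image is a fixed
    point for any amount.
    """
    if amount < 0:
        raise ValueError(f"sharpen amount must be >= 0, got {amount}")
    if amount == 0:
        return ch
    out = unsharp_mask(ch.intensity.astype(float), radius=1.0, amount=amount,
                       preserve_range=True)
    return ChannelImage(np.clip(np.rint(out), 0, 255).astype(np.uint8), ch.role)


def _quantile_init(values: np.ndarray, counts: np.ndarray, k: int) -> np.ndarray:
    """k evenly spaced count-weighted intensity quantiles, deduplicated."""
    cum = np.cumsum(counts)
    targets = (np.arange(k) + 0.5) / k * cum[-1]
    init = values[np.searchsorted(cum, targets)]
    init = np.unique(init)
    if len(init) < k:
        # fall back to rank-evenly-spaced distinct values for the remainder
        ranks = np.round(np.linspace(0, len(values) - 1, k)).astype(int)
        init = np.unique(np.concatenate([init, values[ranks]]))[:k]
    return np.sort(init.astype(float))


def quantize_channel(ch: ChannelImage, k: int = 15, seed: int = 0) -> QuantizedImage:
    """Quantize a channel into ``k`` grayscale layers by histogram k-means.

    The clustering runs on the 1-D intensity histogram (unique values
    weighted by pixel counts) with a deterministic quantile initialization,
    so identical ``(image, k, seed)`` always yields identical output.  If
    the image has fewer than ``k`` distinct intensities, ``k`` is reduced
    with a warning (a constant image collapses to a single layer).
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not (K_SOFT_RANGE[0] <= k <= K_SOFT_RANGE[1]):
        warnings.warn(
            f"k={k} outside the recommended range {K_SOFT_RANGE}", stacklevel=2
        )
    values, counts = np.unique(ch.intensity, return_counts=True)
    if len(values) < k:
        warnings.warn(
            f"only {len(values)} distinct intensities; reducing k from {k}",
            stacklevel=2,
        )
        k = len(values)
    if k == 1:
        level_index = np.ones(ch.shape, dtype=np.int16)
        return QuantizedImage(level_index, np.array([float(values[0])]), 1)

    init = _quantile_init(values, counts, k).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300, tol=1e-6,
                random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatter about explicit init
        km.fit(values.reshape(-1, 1).astype(float), sample_weight=counts.astype(float))
    centroids = np.unique(km.cluster_centers_.ravel())
    if len(centroids) < k:
        warnings.warn("k-means produced duplicate centroids; reducing k", stacklevel=2)
        k = len(centroids)
    level_values = np.sort(centroids)[::-1]  # level 1 = brightest

    # nearest-centroid lookup for every possible 8-bit intensity
    grid = np.arange(256, dtype=float)
    lut = np.argmin(np.abs(grid[:, None] - level_values[None, :]), axis=1) + 1
    level_index = lut[ch.intensity].astype(np.int16)
    return QuantizedImage(level_index, level_values.astype(float), k)


def background_mask(q: QuantizedImage) -> np.ndarray:
    """Pixels of the darkest layer (level k): the background region."""
    return q.level_index == q.k


def foreground_mask(q: QuantizedImage) -> np.ndarray:
    """Complement of the background: the stained (nucleus/cytoskeleton) region."""
    return q.level_index < q.k


def layer_region(q: QuantizedImage, level: int) -> LayerRegion:
    """Cumulative region of all pixels at least as bright as ``level``.

    Valid levels are ``1 .. k-1`` (level k is background).  Regions are
    nested: ``layer_region(a).mask`` is a subset of ``layer_region(b).mask``
    whenever ``a < b``.
    """
    if not (1 <= level <= q.k - 1):
        raise ValueError(f"level must be in [1, {q.k - 1}], got {level}")
    return LayerRegion(level, q.level_index <= level, float(q.level_values[level - 1]))
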