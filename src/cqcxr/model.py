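"""Image preprocessing and the pluggable feature extractor.

The preprocessing pipeline matches the transfer-learning convention for
ImageNet-pretrained backbones: resize to 256x256, center-crop to 224x224,
replicate the grayscale values across three channels and normalize each
channel by a mean and standard deviation.

The default extractor is a deterministic *toy convolution bank*: a
seed-initialized set of unit-norm filters applied to a downsampled copy
of the input, followed by ReLU and average pooling onto a small spatial
grid that is flattened into the feature vector. It is a stand-in for a
pretrained CNN with the same interface (images in, fixed-length feature
vector out, last-layer maps exposed for saliency) at desk scale; an
external pretrained CNN can be plugged in through the same adapter
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from skimage.transform import resize

__all__ = [
    "PreprocessSpec",
    "preprocess_image",
    "FeatureExtractor",
    "ToyConvExtractor",
]


@dataclass(frozen=True)
class PreprocessSpec:
    resize_to: int = 256
    crop_to: int = 224
    mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    sd: tuple[float, float, float] = (0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.crop_to > self.resize_to:
            raise ValueError("crop_to must not exceed resize_to")


def resize_square(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a 2-D grayscale image to size x size."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.shape == (size, size):
        return image
    return resize(image, (size, size), order=1, anti_aliasing=True)


def center_crop(image: np.ndarray, size: int) -> np.ndarray:
    h, w = image.shape
    top, left = (h - size) // 2, (w - size) // 2
    return image[top : top + size, left : left + size]


def preprocess_image(image: np.ndarray, spec: PreprocessSpec = PreprocessSpec()) -> np.ndarray:
    """Resize, center-crop, replicate to 3 channels and normalize.

    Returns a (3, crop_to, crop_to) array; the three channels are
    identical before normalization.
    """
    cropped = center_crop(resize_square(image, spec.resize_to), spec.crop_to)
    out = np.empty((3, spec.crop_to, spec.crop_to))
    for c in range(3):
        out[c] = (cropped - spec.mean[c]) / spec.sd[c]
    return out


class FeatureExtractor(Protocol):
    """Adapter protocol: preprocessed (B, 3, H, W) batch -> (B, f) features."""

    feature_dim: int

    def forward(self, batch: np.ndarray) -> np.ndarray: ...

    def feature_maps(self, batch: np.ndarray) -> np.ndarray: ...


class ToyConvExtractor:
    """Seed-initialized random convolution bank + ReLU + spatial average pool.

    The (3, 224, 224) input is collapsed to its channel mean (channels are
    replicas), average-pooled by ``pool`` to a small image, convolved with
    ``n_filters`` unit-norm ``kernel x kernel`` filters (sign-aligned to a
    positive DC component, see ``__init__``) and passed through ReLU. The
    post-ReLU maps are average-pooled onto a ``grid x grid`` spatial grid
    and flattened to ``feature_dim = n_filters * grid**2`` features — the
    same pool-to-a-grid-then-flatten layout pretrained CNN backbones use,
    which keeps coarse location information (essential when the
    discriminative structure, the cardiac silhouette, is localized).
    Deterministic given the seed. The pooled maps are the "last
    convolutional layer" exposed to Grad-CAM++. Filters are trainable
    unless frozen by the training protocol.
    """

    def __init__(
        self,
        feature_dim: int = 64,
        seed: int = 0,
        kernel: int = 5,
        pool: int = 4,
        grid: int | None = None,
    ) -> None:
        if grid is None:
            grid = 4 if feature_dim % 16 == 0 else 1
        if feature_dim % (grid * grid) != 0:
            raise ValueError("feature_dim must be divisible by grid**2")
        self.feature_dim = feature_dim
        self.n_filters = feature_dim // (grid * grid)
        self.grid = grid
        self.seed = seed
        self.kernel = kernel
        self.pool = pool
        rng = np.random.default_rng(seed)
        filt = rng.standard_normal((self.n_filters, kernel, kernel))
        filt /= np.linalg.norm(filt.reshape(self.n_filters, -1), axis=1)[:, None, None]
        # sign-align every filter to a positive DC component: with the ReLU
        # downstream, zero-mean filters would form a pure edge-detector bank
        # in which extended bright structure (the cardiac silhouette) never
        # activates map interiors and the dark background lights up through
        # negative-DC filters; real backbone channels respond to extended
        # structure, and the saliency layer inherits that behaviour from
        # this choice
        filt *= np.sign(filt.sum(axis=(1, 2)))[:, None, None]
        # scale so pooled features are O(1) for normalized inputs
        self.filters = 2.0 * filt
        self._cache: dict | None = None

    # -- parameter plumbing used by the trainer ------------------------------
    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"filters": self.filters}

    def set_params_array(self, filters: np.ndarray) -> None:
        self.filters = filters

    # -- forward / backward ---------------------------------------------------
    def _downsample(self, batch: np.ndarray) -> np.ndarray:
        x = batch.mean(axis=1)  # collapse replicated channels
        b, h, w = x.shape
        p = self.pool
        return x[:, : h - h % p, : w - w % p].reshape(
            b, h // p, p, w // p, p
        ).mean(axis=(2, 4))

    def _patches(self, small: np.ndarray) -> np.ndarray:
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(small, (k, k), axis=(1, 2))
        b, oh, ow = win.shape[:3]
        return win.reshape(b, oh * ow, k * k), (oh, ow)

    def _conv_maps(self, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
        small = self._downsample(np.asarray(batch, dtype=float))
        flat, (oh, ow) = self._patches(small)
        pre = flat @ self.filters.reshape(self.n_filters, -1).T  # (B, oh*ow, K)
        return flat, pre, (oh, ow)

    def map_shape(self, input_size: int = 224) -> tuple[int, int]:
        side = input_size // self.pool - self.kernel + 1
        return side, side

    def feature_maps(self, batch: np.ndarray) -> np.ndarray:
        """Post-ReLU conv maps, shape (B, n_filters, oh, ow)."""
        _, pre, (oh, ow) = self._conv_maps(batch)
        maps = np.maximum(pre, 0.0)
        return np.moveaxis(maps.reshape(-1, oh, ow, self.n_filters), 3, 1)

    def _pool_cells(self, oh: int, ow: int) -> tuple[int, int]:
        # pooled region: leading (grid * cell) rows/cols; trailing remainder
        # pixels (if any) do not contribute to the features
        return oh // self.grid, ow // self.grid

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Features (B, feature_dim); caches intermediates for backward.

        Feature layout: index = k * grid**2 + (cell_row * grid + cell_col).
        """
        flat, pre, (oh, ow) = self._conv_maps(batch)
        post = np.maximum(pre, 0.0)
        b = post.shape[0]
        g = self.grid
        ch, cw = self._pool_cells(oh, ow)
        maps = post.reshape(b, oh, ow, self.n_filters)
        pooled = maps[:, : g * ch, : g * cw].reshape(b, g, ch, g, cw, self.n_filters)
        pooled = pooled.mean(axis=(2, 4))  # (B, g, g, K)
        features = np.moveaxis(pooled, 3, 1).reshape(b, self.feature_dim)
        self._cache = {"flat": flat, "pre": pre, "shape": (oh, ow)}
        return features

    def pooled_maps(self, batch: np.ndarray) -> np.ndarray:
        """The layer output as spatial maps: (B, n_filters, grid, grid).

        This is exactly the tensor the head flattens into features, at its
        native coarse resolution — the analogue of a pretrained backbone's
        last convolutional maps, and the input Grad-CAM-style methods
        weight and upsample.
        """
        features = self.forward(batch)
        b = features.shape[0]
        return features.reshape(b, self.n_filters, self.grid, self.grid)

    def grad_to_map(self, grad_features: np.ndarray, oh: int, ow: int) -> np.ndarray:
        """Spread per-feature derivatives onto map pixels, shape (K, oh, ow).

        Each pooled cell's derivative is divided by its pixel count; the
        unpooled remainder strip (when the map side is not divisible by
        ``grid``) gets zero.
        """
        g = self.grid
        ch, cw = self._pool_cells(oh, ow)
        per_cell = grad_features.reshape(self.n_filters, g, g) / (ch * cw)
        out = np.zeros((self.n_filters, oh, ow))
        out[:, : g * ch, : g * cw] = np.repeat(np.repeat(per_cell, ch, axis=1), cw, axis=2)
        return out

    def backward(self, grad_features: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of the loss w.r.t. the filters given d(loss)/d(features)."""
        if self._cache is None:
            raise RuntimeError("forward must run before backward")
        flat = self._cache["flat"]
        mask = self._cache["pre"] > 0.0
        oh, ow = self._cache["shape"]
        b = grad_features.shape[0]
        up = np.stack([self.grad_to_map(grad_features[i], oh, ow) for i in range(b)])
        up = np.moveaxis(up, 1, 3).reshape(b, oh * ow, self.n_filters) * mask
        dflt = np.einsum("bpk,bpq->kq", up, flat)
        return {"filters": dflt.reshape(self.filters.shape)}
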