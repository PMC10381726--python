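"""Grad-CAM++ saliency and automated heatmap trustworthiness rules.

Grad-CAM++ weights the last convolutional feature maps ``A^k`` by

    alpha_ij^kc = (d2 Y^c / d A_ij^2) /
                  (2 * d2 Y^c / d A_ij^2 + sum_ab A_ab^k * d3 Y^c / d A_ij^3)
    w_k = sum_ij alpha_ij^kc * relu(d Y^c / d A_ij^k)
    L   = relu(sum_k w_k * A^k),

with derivatives taken on the pre-softmax class score. The maps used are
the extractor's pooled output at native (grid x grid) resolution — every
map pixel is one feature the head consumes, the direct analogue of a
backbone's coarse last-conv maps, upsampled bilinearly to the input
frame. As in the method's reference formulation the curvature terms are
those of the exponential of the score (the common exp factor cancels in
the alpha ratio), which keeps alpha well-behaved through the smooth
quantum layer while leaving piecewise-linear heads unchanged. The 0/0
case of the alpha ratio is resolved as in common implementations: where
the curvature terms vanish but the first derivative does not, alpha
falls back to the uniform 1/Z weighting, which reduces the method to
Grad-CAM; where the gradient vanishes too, alpha = 0.

First derivatives are analytic (reverse mode + parameter shift through a
quantum layer); the diagonal second and third derivatives are central
finite differences of the head score along each feature coordinate,
which is exact for piecewise-linear heads away from kinks.

Trustworthiness operationalizes a radiologist's review rule for a single
target organ: the hot zone (pixels >= tau * max) must essentially be the
cardiac silhouette. A heatmap is rejected as ``not_visible`` (no hot
pixels), ``extensive`` (hot area above a fraction kappa of the image),
``multiple_zones`` (second hot component comparable to the largest) or
``outside_cardiac`` (largest component covering less than ``coverage_min``
of the heart mask); otherwise it is ``trustworthy``. The four thresholds
are explicit, reviewable parameters, not fitted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .heads import HybridNetwork
from .model import PreprocessSpec, center_crop, preprocess_image

__all__ = [
    "Heatmap",
    "TrustRules",
    "TrustAssessment",
    "gradcam_pp",
    "gradcam_pp_from_maps",
    "classify_trustworthy",
    "project_mask",
]


@dataclass(frozen=True)
class Heatmap:
    """2-D saliency values in model-input coordinates, max-normalized to
    [0, 1] (all-zero when the model offers no positive evidence)."""

    values: np.ndarray
    source_layer: str
    target_class: int


@dataclass(frozen=True)
class TrustRules:
    hot_threshold: float = 0.5  # tau, fraction of the heatmap maximum
    coverage_min: float = 0.5  # required |hot ∩ heart| / |heart|
    max_extent: float = 0.5  # kappa, max hot fraction of the image
    multiplicity_ratio: float = 0.5  # rho, 2nd / largest component area

    def __post_init__(self) -> None:
        for name in ("hot_threshold", "coverage_min", "max_extent", "multiplicity_ratio"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class TrustAssessment:
    verdict: str  # "trustworthy" | "non_trustworthy"
    reason: str  # "ok" | "outside_cardiac" | "extensive" | "not_visible" | "multiple_zones"


_EPS = 1e-10


def gradcam_pp_from_maps(
    maps: np.ndarray,
    grad1: np.ndarray,
    grad2: np.ndarray,
    grad3: np.ndarray,
    out_size: int | None = None,
) -> np.ndarray:
    """Grad-CAM++ combination from maps and per-pixel derivative arrays.

    ``maps`` and the derivative arrays are all (K, h, w): first, second
    (diagonal) and third (diagonal) derivatives of the class score w.r.t.
    each map pixel. Spatially uniform derivatives may be passed as
    per-map scalars of shape (K,).
    """
    k, h, w = maps.shape
    z = h * w
    expand = lambda g: (np.broadcast_to(np.reshape(g, (k, 1, 1)), maps.shape)
                        if np.ndim(g) == 1 else np.asarray(g))
    g1, g2, g3 = expand(grad1), expand(grad2), expand(grad3)
    denom = 2.0 * g2 + maps.sum(axis=(1, 2), keepdims=True) * g3
    alpha = np.where(np.abs(denom) > _EPS, g2 / np.where(np.abs(denom) > _EPS, denom, 1.0), 0.0)
    # Grad-CAM fallback where the curvature terms vanish but the gradient
    # does not (piecewise-linear heads): uniform alpha = 1/Z
    fallback = (np.abs(denom) <= _EPS) & (np.abs(g1) > _EPS)
    alpha = np.where(fallback, 1.0 / z, alpha)
    weights = np.sum(alpha * np.maximum(g1, 0.0), axis=(1, 2))  # (K,)
    cam = np.maximum(np.einsum("k,khw->hw", weights, maps), 0.0)
    if out_size is not None and cam.shape != (out_size, out_size):
        cam = resize(cam, (out_size, out_size), order=1, anti_aliasing=False)
        cam = np.maximum(cam, 0.0)
    peak = cam.max()
    return cam / peak if peak > 0 else cam


def gradcam_pp(
    network: HybridNetwork,
    image: np.ndarray,
    target_class: int,
    preprocess: PreprocessSpec = PreprocessSpec(),
    fd_step: float = 1e-2,
) -> Heatmap:
    """Grad-CAM++ heatmap of the extractor's last conv layer for one image.

    Returned values live on the preprocessed ``crop_to`` x ``crop_to``
    input frame (use :func:`project_mask` to carry masks into the same
    frame). Gradients through a shot-sampled quantum layer use the exact
    expectation path.
    """
    batch = preprocess_image(image, preprocess)[None]
    extractor = network.extractor
    # the last layer's maps at native resolution: every pixel of map k is
    # one feature the head consumes, so per-pixel derivatives are exactly
    # per-feature derivatives
    maps = extractor.pooled_maps(batch)[0]  # (K, g, g)
    features = maps.reshape(-1)
    nf = features.size

    def score(f_batch: np.ndarray) -> np.ndarray:
        return network.head_logits(f_batch)[:, target_class]

    # analytic first derivative w.r.t. features via reverse mode
    logits = network.head_logits(features[None])
    onehot = np.zeros_like(logits)
    onehot[0, target_class] = 1.0
    dfeat, _ = network.head.backward(onehot)

    # diagonal 2nd/3rd derivatives by vectorized central differences
    hstep = fd_step
    offsets = np.array([-2.0, -1.0, 1.0, 2.0]) * hstep
    probes = features[None, None, :] + offsets[None, :, None] * np.eye(nf)[:, None, :]
    vals = score(probes.reshape(-1, nf)).reshape(nf, 4)
    f0 = score(features[None])[0]
    d2 = (vals[:, 2] - 2.0 * f0 + vals[:, 1]) / hstep**2
    d3 = (vals[:, 3] - 2.0 * vals[:, 2] + 2.0 * vals[:, 1] - vals[:, 0]) / (2.0 * hstep**3)

    # the closed-form alpha weights are derived for the exponential of the
    # class score; with S the raw score, Y = exp(S) gives (up to the common
    # exp(S) factor, which cancels in the alpha ratio)
    #   Y'  ~ S',  Y'' ~ S'^2 + S'',  Y''' ~ S'^3 + 3 S' S'' + S'''
    s1 = dfeat[0]
    y2 = s1**2 + d2
    y3 = s1**3 + 3.0 * s1 * d2 + d3
    shape = maps.shape
    cam = gradcam_pp_from_maps(
        maps,
        s1.reshape(shape),
        y2.reshape(shape),
        y3.reshape(shape),
        preprocess.crop_to,
    )
    return Heatmap(cam, source_layer="toy_conv_pooled", target_class=target_class)


def project_mask(mask: np.ndarray, preprocess: PreprocessSpec = PreprocessSpec()) -> np.ndarray:
    """Carry a binary mask through resize + center-crop into the model-input
    frame (nearest-neighbour, so the mask stays binary)."""
    resized = resize(
        mask.astype(float), (preprocess.resize_to, preprocess.resize_to), order=0
    )
    return center_crop(resized, preprocess.crop_to) > 0.5


def classify_trustworthy(
    heatmap: Heatmap | np.ndarray,
    heart_mask: np.ndarray,
    rules: TrustRules = TrustRules(),
) -> TrustAssessment:
    """Automated trustworthiness verdict for one heatmap.

    The decision is invariant to positive rescaling of the raw heatmap
    because the hot zone is defined relative to the maximum.
    """
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    heart_mask = np.asarray(heart_mask, dtype=bool)
    if heart_mask.shape != values.shape:
        raise ValueError("heart mask must match the heatmap shape")
    if not heart_mask.any():
        raise ValueError("empty heart mask")
    peak = values.max()
    if peak <= 0.0:
        return TrustAssessment("non_trustworthy", "not_visible")
    hot = values >= rules.hot_threshold * peak
    if not hot.any():
        return TrustAssessment("non_trustworthy", "not_visible")
    if hot.mean() > rules.max_extent:
        return TrustAssessment("non_trustworthy", "extensive")
    labeled, n_comp = ndimage.label(hot)
    areas = np.sort(ndimage.sum_labels(hot, labeled, np.arange(1, n_comp + 1)))[::-1]
    if n_comp > 1 and areas[1] >= rules.multiplicity_ratio * areas[0]:
        return TrustAssessment("non_trustworthy", "multiple_zones")
    largest = labeled == (1 + int(np.argmax(
        ndimage.sum_labels(hot, labeled, np.arange(1, n_comp + 1))
    )))
    coverage = np.sum(largest & heart_mask) / heart_mask.sum()
    if coverage < rules.coverage_min:
        return TrustAssessment("non_trustworthy", "outside_cardiac")
    return TrustAssessment("trustworthy", "ok")
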