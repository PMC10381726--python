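"""Training protocol: augmentation, freezer schedule, optimizer, splits.

The protocol deliberately keeps every hyperparameter shared between the
classical and quantum heads so the comparison is on equal footing: Adam
with learning rate 1e-4, weight decay 1e-4 (standard L2, folded into the
gradient), cross-entropy loss, batch size 8, 20 epochs, and an optional
"freezer" phase during which the pretrained/extractor parameters receive
no updates (classifier heads always train). With identical seeds two runs
— including runs with different heads — see identical batch orders and
augmentations, because the data-order/augmentation random stream is
separate from everything head-specific.

Augmentation is a reduced RandAugment: per training image and epoch,
``rand_n`` ops drawn from {rotate +/-15 deg, translate <=10%, brightness
+/-20%, contrast +/-20%, autocontrast}, followed by a 50%-probability
autocontrast. It is applied to the training split only and re-drawn each
epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .heads import HybridNetwork, cross_entropy
from .model import PreprocessSpec, center_crop, resize_square

__all__ = [
    "TrainConfig",
    "AugmentationSpec",
    "SplitSpec",
    "augment_image",
    "make_splits",
    "train",
    "predict_proba",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 20
    freezer_epochs: int = 2
    batch_size: int = 8
    seed: int = 0
    augment: bool = True

    def __post_init__(self) -> None:
        if self.freezer_epochs > self.epochs:
            raise ValueError("freezer_epochs must not exceed epochs")


AUGMENT_OPS = ("rotate", "translate", "brightness", "contrast", "autocontrast")


@dataclass(frozen=True)
class AugmentationSpec:
    ops: tuple[str, ...] = AUGMENT_OPS
    rand_n: int = 2
    autocontrast_prob: float = 0.5
    max_rotate_deg: float = 15.0
    max_translate: float = 0.10
    brightness: float = 0.20
    contrast: float = 0.20


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "holdout_70_30"  # or "kfold"
    k: int = 10
    seed: int = 0
    stratified: bool = True
    test_fraction: float = 0.30


def _autocontrast(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return img
    return (img - lo) / (hi - lo)


def augment_image(
    image: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator
) -> np.ndarray:
    """One randomized augmentation draw; the input array is not modified."""
    out = np.asarray(image, dtype=float)
    chosen = rng.choice(len(spec.ops), size=min(spec.rand_n, len(spec.ops)), replace=False)
    for idx in chosen:
        op = spec.ops[idx]
        if op == "rotate":
            angle = rng.uniform(-spec.max_rotate_deg, spec.max_rotate_deg)
            out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
        elif op == "translate":
            dy = rng.uniform(-spec.max_translate, spec.max_translate) * out.shape[0]
            dx = rng.uniform(-spec.max_translate, spec.max_translate) * out.shape[1]
            out = ndimage.shift(out, (dy, dx), order=1, mode="nearest")
        elif op == "brightness":
            out = np.clip(out * rng.uniform(1 - spec.brightness, 1 + spec.brightness), 0, 1)
        elif op == "contrast":
            m = out.mean()
            out = np.clip((out - m) * rng.uniform(1 - spec.contrast, 1 + spec.contrast) + m, 0, 1)
        elif op == "autocontrast":
            out = _autocontrast(out)
        else:
            raise ValueError(f"unknown augmentation op {op!r}")
    if rng.uniform() < spec.autocontrast_prob:
        out = _autocontrast(out)
    return out


def make_splits(
    labels: Sequence[int], spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index pairs: one 70/30 pair or k cross-validation folds."""
    y = np.asarray(labels)
    idx = np.arange(y.size)
    if spec.mode == "holdout_70_30":
        tr, te = train_test_split(
            idx,
            test_size=spec.test_fraction,
            random_state=spec.seed,
            stratify=y if spec.stratified else None,
            shuffle=True,
        )
        return [(np.sort(tr), np.sort(te))]
    if spec.mode == "kfold":
        if spec.stratified:
            counts = np.bincount(y)
            if counts.min() < spec.k:
                raise ValueError("need at least k records per class for stratified folds")
            splitter = StratifiedKFold(spec.k, shuffle=True, random_state=spec.seed)
        else:
            splitter = KFold(spec.k, shuffle=True, random_state=spec.seed)
        return [(tr, te) for tr, te in splitter.split(idx, y)]
    raise ValueError(f"unknown split mode {spec.mode!r}")


def _finalize(img: np.ndarray, spec: PreprocessSpec) -> np.ndarray:
    cropped = center_crop(img, spec.crop_to)
    out = np.empty((3, spec.crop_to, spec.crop_to))
    for c in range(3):
        out[c] = (cropped - spec.mean[c]) / spec.sd[c]
    return out


class _Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, lr: float, weight_decay: float) -> None:
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t: dict[str, int] = {}

    def step(self, key: str, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        g = grad + self.wd * param
        if key not in self.m:
            self.m[key] = np.zeros_like(param)
            self.v[key] = np.zeros_like(param)
            self.t[key] = 0
        self.t[key] += 1
        t = self.t[key]
        self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
        self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
        mhat = self.m[key] / (1 - self.beta1**t)
        vhat = self.v[key] / (1 - self.beta2**t)
        return param - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    network: HybridNetwork,
    images: Sequence[np.ndarray],
    labels: Sequence[int],
    config: TrainConfig,
    augmentation: AugmentationSpec = AugmentationSpec(),
    preprocess: PreprocessSpec = PreprocessSpec(),
) -> list[float]:
    """Train the network in place on (image, label) pairs.

    ``images`` are raw 2-D grayscale arrays — the *training split only*;
    evaluation data never passes through here. Returns the per-epoch loss
    history (mean over batches of batch-mean cross-entropy). During the
    first ``freezer_epochs`` epochs the extractor parameters are frozen.
    Raises on a single-class dataset and aborts on a non-finite loss.
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    # geometric augmentation happens on a cached resized copy; the final
    # crop + normalization is re-applied per draw
    resized = [resize_square(img, preprocess.resize_to) for img in images]
    rng_data = np.random.default_rng(config.seed)
    optimizer = _Adam(config.learning_rate, config.weight_decay)
    history: list[float] = []
    n = len(resized)
    for epoch in range(config.epochs):
        frozen = epoch < config.freezer_epochs
        order = rng_data.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            take = order[start : start + config.batch_size]
            batch = np.stack(
                [
                    _finalize(
                        augment_image(resized[i], augmentation, rng_data)
                        if config.augment
                        else resized[i],
                        preprocess,
                    )
                    for i in take
                ]
            )
            features = network.extractor.forward(batch)
            logits = network.head_logits(features)
            loss, dlogits = cross_entropy(logits, y[take])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            dfeat, grads = network.head.backward(dlogits)
            if not frozen:
                ext = network.extractor.backward(dfeat)
                grads.update({f"extractor.{k}": v for k, v in ext.items()})
            for key, grad in grads.items():
                if key.startswith("extractor."):
                    short = key.split(".", 1)[1]
                    new = optimizer.step(key, network.extractor.params[short], grad)
                    network.extractor.set_params_array(new)
                else:
                    new = optimizer.step(key, network.head.params[key], grad)
                    network.head.set_param(key, new)
            epoch_losses.append(loss)
        history.append(float(np.mean(epoch_losses)))
    return history


def predict_proba(
    network: HybridNetwork,
    images: Sequence[np.ndarray],
    preprocess: PreprocessSpec = PreprocessSpec(),
    rng: np.random.Generator | None = None,
    batch_size: int = 32,
) -> np.ndarray:
    """Class probabilities for raw grayscale images (no augmentation).

    Pass a seeded ``rng`` to exercise shot sampling in a sampling head;
    omit it for the deterministic exact-measurement path.
    """
    out = []
    for start in range(0, len(images), batch_size):
        batch = np.stack(
            [
                _finalize(resize_square(img, preprocess.resize_to), preprocess)
                for img in images[start : start + batch_size]
            ]
        )
        out.append(network.forward(batch, rng))
    return np.concatenate(out, axis=0)
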