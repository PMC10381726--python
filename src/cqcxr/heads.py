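"""Classifier heads and the assembled hybrid network.

Three head variants sit on top of the feature extractor:

* ``classical``           — linear(f, 512) · ReLU · linear(512, 2)
* ``quantum_expectation`` — linear(f, n) · tanh · PQC · Z-expectations · linear(n, 2)
* ``quantum_sampling``    — linear(f, n) · tanh · PQC · class-probs(D) · linear(D, 2)

The tanh output in (-1, 1) is scaled by pi/2 before entering the PQC as
RY encoding angles, giving a bijective angle range. The two logits go
through a softmax to produce class probabilities (equivalent decision
surface to a sigmoid output under the cross-entropy loss used for
training).

Gradients are exact: classical layers by reverse-mode differentiation,
the quantum layer by parameter-shift Jacobians composed via the chain
rule. In shots mode the stochastic measurement affects the forward
(prediction) pass only; training gradients always flow through the exact
expectations.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .model import FeatureExtractor
from .quantum import (
    CircuitSpec,
    build_pqc,
    class_probability_jacobians,
    run_circuit,
    sample_class_probabilities,
    z_expectation_jacobians,
)

__all__ = [
    "Linear",
    "ReLU",
    "Tanh",
    "QuantumExpectationLayer",
    "QuantumSamplingLayer",
    "HybridHead",
    "HybridNetwork",
    "build_head",
    "softmax",
    "cross_entropy",
]

HeadVariant = Literal["classical", "quantum_expectation", "quantum_sampling"]

ENCODING_SCALE = np.pi / 2.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    b = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(b), labels] + eps)))
    grad = p.copy()
    grad[np.arange(b), labels] -= 1.0
    return loss, grad / b


class Linear:
    def __init__(self, w: np.ndarray, b: np.ndarray, name: str) -> None:
        self.w = w
        self.b = b
        self.name = name
        self.grads: dict[str, np.ndarray] = {}
        self._x: np.ndarray | None = None

    @classmethod
    def init(cls, n_in: int, n_out: int, rng: np.random.Generator, name: str) -> "Linear":
        bound = 1.0 / np.sqrt(n_in)
        return cls(
            rng.uniform(-bound, bound, (n_in, n_out)),
            rng.uniform(-bound, bound, n_out),
            name,
        )

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.w": self.w, f"{self.name}.b": self.b}

    def set_param(self, key: str, value: np.ndarray) -> None:
        if key.endswith(".w"):
            self.w = value
        else:
            self.b = value

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.grads = {f"{self.name}.w": self._x.T @ g, f"{self.name}.b": g.sum(axis=0)}
        return g @ self.w.T


class ReLU:
    params: dict[str, np.ndarray] = {}
    grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0.0
        return np.maximum(x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Tanh:
    params: dict[str, np.ndarray] = {}
    grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * (1.0 - self._y**2)


class QuantumExpectationLayer:
    """tanh output -> RY encoding angles -> PQC -> Z expectation per qubit."""

    def __init__(self, spec: CircuitSpec, theta: np.ndarray, name: str = "pqc") -> None:
        self.spec = spec
        self.theta = theta
        self.name = name
        self.grads: dict[str, np.ndarray] = {}
        self._phi: np.ndarray | None = None

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.theta": self.theta}

    def set_param(self, key: str, value: np.ndarray) -> None:
        self.theta = value

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._phi = ENCODING_SCALE * x
        state = run_circuit(self.spec, self._phi, self.theta)
        from .quantum import measure_z_expectations

        return measure_z_expectations(state)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._phi is not None
        _, d_theta, d_phi = z_expectation_jacobians(self.spec, self._phi, self.theta)
        self.grads = {f"{self.name}.theta": np.einsum("bo,bop->p", g, d_theta)}
        return ENCODING_SCALE * np.einsum("bo,boi->bi", g, d_phi)


class QuantumSamplingLayer:
    """tanh output -> PQC -> basis sampling aggregated to D class probabilities.

    ``shots=None`` returns exact probabilities; finite shots return seeded
    empirical frequencies. Gradients always use the exact probabilities.
    """

    def __init__(
        self,
        spec: CircuitSpec,
        theta: np.ndarray,
        n_classes: int,
        shots: int | None = None,
        name: str = "pqc",
    ) -> None:
        if n_classes > spec.dim:
            raise ValueError("n_classes exceeds the basis dimension")
        self.spec = spec
        self.theta = theta
        self.n_classes = n_classes
        self.shots = shots
        self.name = name
        self.grads: dict[str, np.ndarray] = {}
        self._phi: np.ndarray | None = None

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.theta": self.theta}

    def set_param(self, key: str, value: np.ndarray) -> None:
        self.theta = value

    def forward(
        self, x: np.ndarray, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        self._phi = ENCODING_SCALE * x
        state = run_circuit(self.spec, self._phi, self.theta)
        if self.shots is not None and rng is not None:
            return sample_class_probabilities(state, self.n_classes, self.shots, rng)
        return sample_class_probabilities(state, self.n_classes)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._phi is not None
        _, d_theta, d_phi = class_probability_jacobians(
            self.spec, self._phi, self.theta, self.n_classes
        )
        self.grads = {f"{self.name}.theta": np.einsum("bo,bop->p", g, d_theta)}
        return ENCODING_SCALE * np.einsum("bo,boi->bi", g, d_phi)


class HybridHead:
    """An ordered stack of layers mapping features to 2 logits."""

    def __init__(self, variant: HeadVariant, layers: list) -> None:
        self.variant = variant
        self.layers = layers

    @property
    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self.layers:
            out.update(layer.params)
        return out

    def set_param(self, key: str, value: np.ndarray) -> None:
        for layer in self.layers:
            if key in layer.params:
                layer.set_param(key, value)
                return
        raise KeyError(key)

    def forward(self, features: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        x = features
        for layer in self.layers:
            if isinstance(layer, QuantumSamplingLayer):
                x = layer.forward(x, rng)
            else:
                x = layer.forward(x)
        return x

    def backward(self, grad_logits: np.ndarray) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """Backprop from d(loss)/d(logits); returns (d features, grads)."""
        g = grad_logits
        grads: dict[str, np.ndarray] = {}
        for layer in reversed(self.layers):
            g = layer.backward(g)
            grads.update(layer.grads)
        return g, grads


def build_head(
    variant: HeadVariant,
    feature_dim: int,
    rng: np.random.Generator,
    n_qubits: int = 4,
    depth: int = 4,
    n_classes: int = 2,
    shots: int | None = None,
) -> HybridHead:
    """Seeded construction of one of the three head variants.

    Hidden linear weights are uniform in [-1/sqrt(fan_in), +1/sqrt(fan_in)]
    and trainable PQC angles uniform in [0, 2*pi). The final output layer
    is zero-initialized so every model starts exactly at chance with no
    class offset — with the short shared training budget, a random output
    layer leaves the narrow quantum bottleneck a residual logit bias it
    cannot unlearn in time.
    """
    if variant == "classical":
        layers = [
            Linear.init(feature_dim, 512, rng, "fc1"),
            ReLU(),
            Linear(np.zeros((512, 2)), np.zeros(2), "fc2"),
        ]
    elif variant in ("quantum_expectation", "quantum_sampling"):
        spec = build_pqc(n_qubits, depth)
        theta = rng.uniform(0.0, 2.0 * np.pi, spec.n_params)
        pre = Linear.init(feature_dim, n_qubits, rng, "fc1")
        if variant == "quantum_expectation":
            q = QuantumExpectationLayer(spec, theta)
            post = Linear(np.zeros((n_qubits, 2)), np.zeros(2), "fc2")
        else:
            q = QuantumSamplingLayer(spec, theta, n_classes, shots)
            post = Linear(np.zeros((n_classes, 2)), np.zeros(2), "fc2")
        layers = [pre, Tanh(), q, post]
    else:
        raise ValueError(f"unknown head variant {variant!r}")
    return HybridHead(variant, layers)


class HybridNetwork:
    """Feature extractor + classifier head + softmax output."""

    def __init__(self, extractor: FeatureExtractor, head: HybridHead) -> None:
        self.extractor = extractor
        self.head = head

    @property
    def params(self) -> dict[str, np.ndarray]:
        out = {f"extractor.{k}": v for k, v in self.extractor.params.items()}
        out.update(self.head.params)
        return out

    def head_logits(self, features: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        return self.head.forward(features, rng)

    def forward(
        self, batch: np.ndarray, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Preprocessed (B, 3, H, W) batch -> per-class probabilities (B, 2)."""
        features = self.extractor.forward(batch)
        return softmax(self.head_logits(features, rng))
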