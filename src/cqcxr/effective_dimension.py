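"""Empirical Fisher information and the normalized global effective dimension.

The effective dimension is a Fisher-information-based capacity measure for
a statistical model ``p(y | x; theta)``. For the quantum layer it is
computed *globally*: Fisher matrices are sampled over a uniform prior on
the trainable angles (and over random encoding inputs), normalized so the
mean trace equals the parameter count P, and combined as

    d_eff(n) = 2 * log( E_theta sqrt(det(I + c_n * Fhat(theta))) ) / log(c_n),
    c_n = gamma * n / (2 * pi * log n),

where n is the dataset size and gamma = 1. The *normalized* global
effective dimension (NGED) is ``d_eff / P``, so models of different
parameter counts are comparable. Determinants are evaluated through
eigenvalue log-sums and the average over theta-samples through a
log-sum-exp, which keeps the computation finite at large n.

Here the model is the sampling-head quantum layer: encoding angles in,
D-class basis-aggregated probabilities out, with score vectors obtained
from exact parameter-shift gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .quantum import CircuitSpec, class_probability_jacobians

__all__ = [
    "FisherEstimate",
    "NGEDCurve",
    "empirical_fisher",
    "normalize_fisher",
    "nged",
    "nged_curve",
]


@dataclass(frozen=True)
class FisherEstimate:
    """Per-theta-sample P x P empirical Fisher matrices."""

    matrices: np.ndarray  # (S, P, P)
    n_theta_samples: int
    n_input_samples: int
    clamped: bool = False  # True if any probability hit the 1e-12 floor

    @property
    def n_params(self) -> int:
        return self.matrices.shape[-1]


@dataclass(frozen=True)
class NGEDCurve:
    sizes: np.ndarray
    values: np.ndarray
    n_params: int
    gamma: float = 1.0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.sizes, "nged": self.values})


_PROB_FLOOR = 1e-12


def empirical_fisher(
    spec: CircuitSpec,
    theta_samples: np.ndarray,
    input_samples: np.ndarray,
    n_classes: int,
) -> FisherEstimate:
    """Empirical Fisher matrices of the quantum sampling layer.

    For each theta sample, ``F(theta)`` is the average over inputs and
    classes (weighted by ``p(y | x; theta)``) of the outer product of
    ``grad_theta log p``. Gradients come from the parameter-shift rule;
    probabilities below 1e-12 are clamped and flagged.
    """
    theta_samples = np.atleast_2d(np.asarray(theta_samples, dtype=float))
    input_samples = np.atleast_2d(np.asarray(input_samples, dtype=float))
    s, p_count = theta_samples.shape
    if p_count != spec.n_params:
        raise ValueError("theta sample width must equal the parameter count")
    mats = np.empty((s, p_count, p_count))
    clamped = False
    for i, theta in enumerate(theta_samples):
        probs, d_theta, _ = class_probability_jacobians(
            spec, input_samples, theta, n_classes
        )
        if np.any(probs < _PROB_FLOOR):
            clamped = True
        probs = np.clip(probs, _PROB_FLOOR, None)
        scores = d_theta / probs[:, :, None]  # (M, D, P)
        mats[i] = np.einsum("md,mdp,mdq->pq", probs, scores, scores) / input_samples.shape[0]
        mats[i] = (mats[i] + mats[i].T) / 2.0
    return FisherEstimate(mats, s, input_samples.shape[0], clamped)


def normalize_fisher(estimate: FisherEstimate) -> np.ndarray:
    """Trace-normalize: Fhat = P * F / mean_trace, so the mean trace of
    Fhat over theta samples equals P. Scale-invariant in F."""
    mats = estimate.matrices
    mean_trace = float(np.trace(mats, axis1=1, axis2=2).mean())
    if mean_trace <= 0.0:
        raise ValueError("all-zero Fisher: normalization undefined")
    return estimate.n_params * mats / mean_trace


def _c_n(n: float, gamma: float) -> float:
    if n < 2:
        raise ValueError("dataset size must be >= 2")
    c = gamma * n / (2.0 * np.pi * np.log(n))
    if c <= 0.0:
        raise ValueError("c_n must be positive")
    if abs(np.log(c)) < 1e-12:
        raise ValueError("c_n = 1 makes the effective dimension undefined")
    return c


def nged(fhat: np.ndarray, n: float, gamma: float = 1.0) -> float:
    """Normalized global effective dimension at dataset size n.

    ``fhat`` holds the trace-normalized Fisher samples, shape (S, P, P).
    """
    fhat = np.asarray(fhat, dtype=float)
    if fhat.ndim == 2:
        fhat = fhat[None]
    s, p_count = fhat.shape[0], fhat.shape[-1]
    c = _c_n(n, gamma)
    half_logdets = np.empty(s)
    for i in range(s):
        eig = np.linalg.eigvalsh(fhat[i])
        eig = np.clip(eig, 0.0, None)  # PSD up to roundoff
        half_logdets[i] = 0.5 * np.sum(np.log1p(c * eig))
    log_mean = logsumexp(half_logdets) - np.log(s)
    d_eff = 2.0 * log_mean / np.log(c)
    return float(d_eff / p_count)


def nged_curve(
    spec: CircuitSpec,
    n_classes: int,
    n_grid: np.ndarray,
    n_theta_samples: int = 30,
    n_input_samples: int = 30,
    seed: int = 0,
    gamma: float = 1.0,
) -> NGEDCurve:
    """NGED over a dataset-size grid with shared seeded Fisher samples.

    Trainable angles are drawn uniformly from [0, 2*pi)^P and encoding
    inputs uniformly from [-pi/2, pi/2]^n (the image of the tanh encoding
    scale), both from ``seed``.
    """
    n_grid = np.asarray(n_grid, dtype=float)
    if n_grid.size == 0 or np.any(n_grid < 2):
        raise ValueError("n_grid must contain sizes >= 2")
    rng = np.random.default_rng(seed)
    thetas = rng.uniform(0.0, 2.0 * np.pi, (n_theta_samples, spec.n_params))
    inputs = rng.uniform(-np.pi / 2.0, np.pi / 2.0, (n_input_samples, spec.n_encoding))
    fhat = normalize_fisher(empirical_fisher(spec, thetas, inputs, n_classes))
    values = np.array([nged(fhat, n, gamma) for n in n_grid])
    return NGEDCurve(n_grid, values, spec.n_params, gamma)
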