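"""Scikit-learn estimator interface for the hybrid classifier.

``HybridClassifier`` composes the preprocessing pipeline, the toy
convolutional feature extractor and one of the three classifier heads
into a ``fit``/``predict_proba`` estimator that plugs into sklearn model
selection. All randomness (weight initialization, batch order,
augmentation, shot sampling) flows from ``random_state``; in exact
measurement mode two fits with equal parameters are identical.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .heads import HybridNetwork, build_head
from .model import PreprocessSpec, ToyConvExtractor
from .training import AugmentationSpec, TrainConfig, predict_proba, train

__all__ = ["HybridClassifier"]


class HybridClassifier(BaseEstimator, ClassifierMixin):
    """Cardiomegaly classifier with a classical or quantum head.

    Parameters
    ----------
    head : {"classical", "quantum_expectation", "quantum_sampling"}
        Classifier head variant. The quantum heads insert an
        ``n_qubits``-qubit parameterized quantum circuit between two
        linear layers.
    n_qubits, circuit_depth : int
        PQC size; the default 4-qubit, depth-4 circuit has 24 trainable
        rotation angles.
    output_dim : int
        Class-probability dimension D of the sampling head (basis
        outcomes are aggregated modulo D).
    shots : int or None
        Measurement shots for the sampling head at prediction time;
        ``None`` uses exact probabilities. Training gradients always use
        the exact path.
    feature_dim : int
        Toy extractor feature-vector length f.
    epochs, freezer_epochs, learning_rate, weight_decay, batch_size :
        Training protocol; the defaults are the shared equal-footing
        protocol (Adam, lr = weight decay = 1e-4, batch 8, 20 epochs, 2
        freezer epochs during which the extractor is frozen).
    augment : bool
        Re-drawn per-epoch reduced RandAugment + 50% autocontrast on the
        training split.
    random_state : int
        Root seed for every random choice.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    network_ : HybridNetwork with the trained weights
    loss_history_ : list of per-epoch mean training losses
    """

    def __init__(
        self,
        head: str = "classical",
        n_qubits: int = 4,
        circuit_depth: int = 4,
        output_dim: int = 2,
        shots: int | None = None,
        feature_dim: int = 64,
        epochs: int = 20,
        freezer_epochs: int = 2,
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-4,
        batch_size: int = 8,
        augment: bool = True,
        random_state: int = 0,
    ) -> None:
        self.head = head
        self.n_qubits = n_qubits
        self.circuit_depth = circuit_depth
        self.output_dim = output_dim
        self.shots = shots
        self.feature_dim = feature_dim
        self.epochs = epochs
        self.freezer_epochs = freezer_epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.augment = augment
        self.random_state = random_state

    @staticmethod
    def _as_images(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return [X[i] for i in range(X.shape[0])]
        images = [np.asarray(x, dtype=float) for x in X]
        if any(img.ndim != 2 for img in images):
            raise ValueError("X must be a stack or list of 2-D grayscale images")
        return images

    def _build_network(self) -> HybridNetwork:
        rng = np.random.default_rng(self.random_state)
        extractor = ToyConvExtractor(self.feature_dim, seed=self.random_state)
        head = build_head(
            self.head,
            self.feature_dim,
            rng,
            n_qubits=self.n_qubits,
            depth=self.circuit_depth,
            n_classes=self.output_dim,
            shots=self.shots,
        )
        return HybridNetwork(extractor, head)

    def fit(self, X, y) -> "HybridClassifier":
        images = self._as_images(X)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != len(images):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("HybridClassifier is a binary classifier")
        self.preprocess_ = PreprocessSpec()
        self.network_ = self._build_network()
        config = TrainConfig(
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            freezer_epochs=self.freezer_epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
            augment=self.augment,
        )
        labels01 = np.searchsorted(self.classes_, y)
        self.loss_history_ = train(
            self.network_, images, labels01, config,
            AugmentationSpec(), self.preprocess_,
        )
        self.n_features_in_ = images[0].size
        return self

    def predict_proba(self, X, rng: np.random.Generator | None = None) -> np.ndarray:
        check_is_fitted(self, "network_")
        images = self._as_images(X)
        if self.shots is not None and rng is None and self.head == "quantum_sampling":
            rng = np.random.default_rng(self.random_state)
        return predict_proba(self.network_, images, self.preprocess_, rng)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def decision_function(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return p[:, 1] - p[:, 0]
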