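"""Preprocessing, toy extractor, heads, and end-to-end gradient checks."""

import numpy as np
import pytest

from cqcxr.heads import (
    HybridNetwork,
    Linear,
    build_head,
    cross_entropy,
    softmax,
)
from cqcxr.model import PreprocessSpec, ToyConvExtractor, preprocess_image
from cqcxr.quantum import build_pqc, measure_z_expectations, run_circuit
from cqcxr.synthetic import SyntheticConfig, generate_cxr


class TestPreprocess:
    def test_output_shape_from_rectangular_input(self):
        rng = np.random.default_rng(0)
        out = preprocess_image(rng.uniform(size=(300, 400)))
        assert out.shape == (3, 224, 224)

    def test_constant_image_at_mean_maps_to_zero(self):
        spec = PreprocessSpec(mean=(0.3, 0.3, 0.3), sd=(1.0, 1.0, 1.0))
        out = preprocess_image(np.full((320, 320), 0.3), spec)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_channels_identical_before_normalization(self):
        rng = np.random.default_rng(1)
        spec = PreprocessSpec(mean=(0.1, 0.2, 0.3), sd=(1.0, 2.0, 4.0))
        out = preprocess_image(rng.uniform(size=(320, 320)), spec)
        c0 = out[0] * spec.sd[0] + spec.mean[0]
        for c in (1, 2):
            assert np.allclose(out[c] * spec.sd[c] + spec.mean[c], c0, atol=1e-9)

    def test_rejects_bad_images(self):
        with pytest.raises(ValueError):
            preprocess_image(np.zeros((0, 0)))
        with pytest.raises(ValueError):
            preprocess_image(np.full((300, 300), np.nan))
        with pytest.raises(ValueError):
            PreprocessSpec(resize_to=100, crop_to=224)


class TestToyExtractor:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        batch = rng.uniform(size=(2, 3, 224, 224))
        a = ToyConvExtractor(64, seed=7).forward(batch)
        b = ToyConvExtractor(64, seed=7).forward(batch)
        assert np.array_equal(a, b)
        c = ToyConvExtractor(64, seed=8).forward(batch)
        assert not np.allclose(a, c)

    def test_batch_shape(self):
        rng = np.random.default_rng(3)
        batch = rng.uniform(size=(5, 3, 224, 224))
        feats = ToyConvExtractor(64, seed=0).forward(batch)
        assert feats.shape == (5, 64)

    def test_heart_region_changes_move_features(self):
        cfg = SyntheticConfig(seed=5, noise_sd=0.0, confounder_prob=0.0, jitter=0.0)
        small = generate_cxr(0.38, cfg)
        large = generate_cxr(0.68, cfg)
        ext = ToyConvExtractor(64, seed=0)
        fa = ext.forward(preprocess_image(small.image)[None])
        fb = ext.forward(preprocess_image(large.image)[None])
        assert np.linalg.norm(fa - fb) > 0.0

    def test_pooled_maps_flatten_to_features(self):
        rng = np.random.default_rng(4)
        batch = rng.uniform(size=(2, 3, 224, 224))
        ext = ToyConvExtractor(64, seed=0)
        feats = ext.forward(batch)
        maps = ext.pooled_maps(batch)
        assert maps.shape == (2, ext.n_filters, ext.grid, ext.grid)
        assert np.allclose(maps.reshape(2, -1), feats)

    def test_filter_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(6)
        batch = rng.uniform(size=(2, 3, 224, 224))
        ext = ToyConvExtractor(16, seed=0)
        v = rng.normal(size=(2, 16))  # arbitrary downstream gradient

        def loss(filters):
            ext.filters = filters
            return float(np.sum(ext.forward(batch) * v))

        base = ext.filters.copy()
        _ = loss(base)
        grad = ext.backward(v)["filters"]
        h = 1e-6
        for idx in [(0, 0, 0), (0, 2, 3), (0, 4, 4)]:
            fp, fm = base.copy(), base.copy()
            fp[idx] += h
            fm[idx] -= h
            fd = (loss(fp) - loss(fm)) / (2 * h)
            assert grad[idx] == pytest.approx(fd, abs=1e-5)
        ext.filters = base


class TestHeads:
    def test_softmax_probs_sum_to_one(self):
        rng = np.random.default_rng(0)
        head = build_head("quantum_expectation", 8, rng, n_qubits=2, depth=1)
        x = rng.normal(size=(4, 8))
        p = softmax(head.forward(x))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((p >= 0) & (p <= 1))

    def test_zero_weights_give_chance_probabilities(self):
        rng = np.random.default_rng(0)
        head = build_head("classical", 8, rng)
        for key, val in head.params.items():
            head.set_param(key, np.zeros_like(val))
        p = softmax(head.forward(rng.normal(size=(3, 8))))
        assert np.allclose(p, 0.5, atol=1e-12)

    def test_quantum_forward_equals_hand_composed_pipeline(self):
        """The expectation head must equal extract->linear->tanh->circuit->
        measure->linear composed by hand."""
        rng = np.random.default_rng(1)
        ext = ToyConvExtractor(16, seed=0)
        head = build_head("quantum_expectation", 16, rng, n_qubits=3, depth=2)
        net = HybridNetwork(ext, head)
        batch = rng.uniform(size=(1, 3, 224, 224))

        feats = ext.forward(batch)
        fc1, _, q, fc2 = head.layers
        pre = feats @ fc1.w + fc1.b
        phi = (np.pi / 2.0) * np.tanh(pre)
        spec = build_pqc(3, 2)
        z = measure_z_expectations(run_circuit(spec, phi[0], q.theta))
        logits_oracle = z @ fc2.w + fc2.b
        probs_oracle = softmax(logits_oracle[None])

        assert np.allclose(net.forward(batch), probs_oracle, atol=1e-10)

    def test_sampling_head_shots_reproducible(self):
        rng = np.random.default_rng(2)
        head = build_head("quantum_sampling", 8, rng, n_qubits=2, depth=1, shots=10)
        x = rng.normal(size=(3, 8))
        a = head.forward(x, np.random.default_rng(11))
        b = head.forward(x, np.random.default_rng(11))
        assert np.array_equal(a, b)

    def test_batch_permutation_equivariance(self):
        """Permuting the batch permutes outputs identically (no leakage)."""
        rng = np.random.default_rng(3)
        ext = ToyConvExtractor(64, seed=0)
        head = build_head("quantum_expectation", 64, rng, n_qubits=2, depth=1)
        # make outputs nontrivial
        head.set_param("fc2.w", rng.normal(size=(2, 2)))
        net = HybridNetwork(ext, head)
        batch = rng.uniform(size=(5, 3, 224, 224))
        perm = np.array([3, 1, 4, 0, 2])
        assert np.allclose(net.forward(batch)[perm], net.forward(batch[perm]), atol=1e-12)


class TestEndToEndGradients:
    @pytest.mark.parametrize("variant", ["classical", "quantum_expectation", "quantum_sampling"])
    def test_analytic_gradients_match_finite_difference(self, variant):
        """Reverse mode composed with parameter-shift Jacobians must match
        central finite differences for every trainable weight class."""
        rng = np.random.default_rng(42)
        ext = ToyConvExtractor(16, seed=1)
        head = build_head(variant, 16, rng, n_qubits=3, depth=1, n_classes=2)
        # nonzero output layer so gradients reach every layer
        fc2 = head.layers[-1]
        head.set_param("fc2.w", rng.normal(size=fc2.w.shape) * 0.3)
        head.set_param("fc2.b", rng.normal(size=fc2.b.shape) * 0.1)
        net = HybridNetwork(ext, head)
        batch = rng.uniform(size=(2, 3, 224, 224))
        labels = np.array([0, 1])

        def loss_fn() -> float:
            feats = net.extractor.forward(batch)
            logits = net.head_logits(feats)
            return cross_entropy(logits, labels)[0]

        base_loss = loss_fn()
        feats = net.extractor.forward(batch)
        logits = net.head_logits(feats)
        _, dlogits = cross_entropy(logits, labels)
        dfeat, grads = net.head.backward(dlogits)
        grads.update(
            {f"extractor.{k}": v for k, v in net.extractor.backward(dfeat).items()}
        )

        h = 1e-5
        params = net.params
        for key, grad in grads.items():
            flat_param = params[key]
            coords = [np.unravel_index(i, flat_param.shape)
                      for i in np.linspace(0, flat_param.size - 1, 3).astype(int)]
            for idx in coords:
                orig = flat_param[idx]
                flat_param[idx] = orig + h
                lp = loss_fn()
                flat_param[idx] = orig - h
                lm = loss_fn()
                flat_param[idx] = orig
                fd = (lp - lm) / (2 * h)
                # conv filters feed thousands of ReLU pre-activations, so a
                # finite-difference probe occasionally straddles a kink
                tol = 5e-3 if key == "extractor.filters" else 1e-4
                assert grad[idx] == pytest.approx(fd, abs=tol), (key, idx)
        assert loss_fn() == pytest.approx(base_loss)
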