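"""Statevector simulator checked against explicit dense-matrix oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cqcxr.quantum import (
    CircuitSpec,
    GateOp,
    apply_gate,
    build_pqc,
    class_probability_jacobians,
    measure_z_expectations,
    parameter_shift_gradient,
    run_circuit,
    sample_class_probabilities,
    z_expectation_jacobians,
)

H2 = np.array([[1, 1], [1, -1]]) / np.sqrt(2)


def ry(a):
    return np.array(
        [[np.cos(a / 2), -np.sin(a / 2)], [np.sin(a / 2), np.cos(a / 2)]]
    )


def embed_1q(mat, q, n):
    """Single-qubit gate as a full 2^n x 2^n matrix, qubit 0 = MSB."""
    out = np.eye(1)
    for i in range(n):
        out = np.kron(out, mat if i == q else np.eye(2))
    return out


def cnot_matrix(control, target, n):
    dim = 1 << n
    out = np.zeros((dim, dim))
    for b in range(dim):
        if (b >> (n - 1 - control)) & 1:
            out[b ^ (1 << (n - 1 - target)), b] = 1.0
        else:
            out[b, b] = 1.0
    return out


def circuit_unitary(spec, phi, theta):
    """Brute-force oracle: product of explicitly embedded gate matrices."""
    u = np.eye(spec.dim, dtype=complex)
    for g in spec.gates:
        if g.kind == "H":
            m = embed_1q(H2, g.target, spec.n_qubits)
        elif g.kind == "CNOT":
            m = cnot_matrix(g.control, g.target, spec.n_qubits)
        else:
            kind, ref = g.angle_source
            a = {"enc": lambda: phi[int(ref)], "param": lambda: theta[int(ref)]}.get(
                kind, lambda: float(ref)
            )()
            m = embed_1q(ry(a), g.target, spec.n_qubits)
        u = m @ u
    return u


class TestBuildPqc:
    @pytest.mark.parametrize(
        "n,depth,n_params,n_cnots",
        [(4, 4, 24, 12), (2, 1, 6, 1), (3, 2, 12, 4), (4, 1, 12, 3)],
    )
    def test_parameter_and_cnot_counts(self, n, depth, n_params, n_cnots):
        spec = build_pqc(n, depth)
        assert spec.n_params == n_params == n * (depth + 2)
        assert sum(g.kind == "CNOT" for g in spec.gates) == n_cnots
        assert spec.n_encoding == n

    def test_layout_prefix_is_h_then_encoding(self):
        spec = build_pqc(3, 1)
        kinds = [g.kind for g in spec.gates[:6]]
        assert kinds == ["H"] * 3 + ["RY"] * 3
        assert [g.angle_source for g in spec.gates[3:6]] == [
            ("enc", 0), ("enc", 1), ("enc", 2)
        ]

    @pytest.mark.parametrize("n,depth", [(1, 4), (0, 1), (2, 0)])
    def test_rejects_degenerate_shapes(self, n, depth):
        with pytest.raises(ValueError):
            build_pqc(n, depth)


class TestApplyGate:
    def test_hadamard_on_ground_state(self):
        out = apply_gate(np.array([1.0, 0.0], dtype=complex), GateOp("H", 0), 1)
        assert np.allclose(out, [1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_cnot_truth_table_pins_bit_order(self):
        # |10> = index 2 with qubit 0 as MSB; CNOT(0 -> 1) maps it to |11>.
        state = np.zeros(4, dtype=complex)
        state[2] = 1.0
        out = apply_gate(state, GateOp("CNOT", target=1, control=0), 2)
        expect = np.zeros(4)
        expect[3] = 1.0
        assert np.allclose(out, expect)

    def test_ry_pi_flips_ground_state(self):
        out = apply_gate(
            np.array([1.0, 0.0], dtype=complex),
            GateOp("RY", 0, angle_source=("const", np.pi)),
            1,
        )
        assert np.allclose(np.abs(out), [0.0, 1.0])

    def test_rejects_out_of_range_index(self):
        with pytest.raises(ValueError):
            apply_gate(np.array([1.0, 0.0], dtype=complex), GateOp("H", 1), 1)

    def test_gateop_validation(self):
        with pytest.raises(ValueError):
            GateOp("CNOT", target=0, control=0)
        with pytest.raises(ValueError):
            GateOp("RY", target=0)
        with pytest.raises(ValueError):
            GateOp("H", target=0, angle_source=("const", 1.0))


class TestRunCircuit:
    def test_zero_angles_give_uniform_superposition(self):
        spec = build_pqc(3, 2)
        state = run_circuit(spec, np.zeros(3), np.zeros(spec.n_params))
        assert np.allclose(state, np.full(8, 1 / np.sqrt(8)))
        assert np.allclose(measure_z_expectations(state), 0.0)

    def test_h_ry_z_expectation_matches_closed_form(self):
        # minimal circuit [H, RY(theta)]: <Z> = -sin(theta); oracle = 2x2 products
        spec = CircuitSpec(
            n_qubits=2,
            depth=0,
            gates=(GateOp("H", 0), GateOp("RY", 0, angle_source=("param", 0))),
            n_encoding=2,
            n_params=1,
        )
        for theta in [0.0, 0.3, -1.2, np.pi / 2]:
            state = run_circuit(spec, np.zeros(2), np.array([theta]))
            z = measure_z_expectations(state)[0]
            # dense oracle on the single active qubit
            vec = ry(theta) @ H2 @ np.array([1.0, 0.0])
            z_oracle = vec[0] ** 2 - vec[1] ** 2
            assert z == pytest.approx(-np.sin(theta), abs=1e-12)
            assert z == pytest.approx(z_oracle, abs=1e-12)

    @pytest.mark.parametrize("n,depth", [(2, 1), (3, 2), (4, 4)])
    def test_matches_dense_matrix_oracle(self, n, depth):
        rng = np.random.default_rng(7 + n + depth)
        spec = build_pqc(n, depth)
        phi = rng.uniform(-np.pi, np.pi, n)
        theta = rng.uniform(0, 2 * np.pi, spec.n_params)
        state = run_circuit(spec, phi, theta)
        ground = np.zeros(spec.dim)
        ground[0] = 1.0
        oracle = circuit_unitary(spec, phi, theta) @ ground
        assert np.max(np.abs(state - oracle)) < 1e-10

    def test_batched_equals_loop(self):
        spec = build_pqc(3, 1)
        rng = np.random.default_rng(0)
        phi = rng.uniform(-1, 1, (5, 3))
        theta = rng.uniform(0, 2 * np.pi, spec.n_params)
        batch = run_circuit(spec, phi, theta)
        for i in range(5):
            assert np.allclose(batch[i], run_circuit(spec, phi[i], theta), atol=1e-12)

    def test_rejects_length_mismatch(self):
        spec = build_pqc(2, 1)
        with pytest.raises(ValueError):
            run_circuit(spec, np.zeros(3), np.zeros(spec.n_params))
        with pytest.raises(ValueError):
            run_circuit(spec, np.zeros(2), np.zeros(spec.n_params + 1))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 6),
    seed=st.integers(0, 10_000),
    n_gates=st.integers(1, 30),
)
def test_norm_preserved_through_random_gate_sequences(n, seed, n_gates):
    """Unitarity: arbitrary H/RY/CNOT sequences keep the norm at 1."""
    rng = np.random.default_rng(seed)
    state = np.zeros(1 << n, dtype=complex)
    state[0] = 1.0
    for _ in range(n_gates):
        kind = rng.choice(["H", "RY", "CNOT"])
        q = int(rng.integers(n))
        if kind == "CNOT":
            c = int(rng.integers(n - 1))
            c = c if c != q else n - 1
            gate = GateOp("CNOT", target=q, control=c)
        elif kind == "RY":
            gate = GateOp("RY", q, angle_source=("const", float(rng.uniform(-4, 4))))
        else:
            gate = GateOp("H", q)
        state = apply_gate(state, gate, n)
    assert abs(np.linalg.norm(state) - 1.0) < 1e-9


class TestMeasurement:
    def test_ground_and_plus_states(self):
        ground = np.zeros(8, dtype=complex)
        ground[0] = 1.0
        assert np.allclose(measure_z_expectations(ground), 1.0)
        plus = np.full(8, 1 / np.sqrt(8), dtype=complex)
        assert np.allclose(measure_z_expectations(plus), 0.0)

    def test_random_state_matches_observable_matrix_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=8) + 1j * rng.normal(size=8)
        v /= np.linalg.norm(v)
        z = measure_z_expectations(v)
        zmat = np.diag([1.0, -1.0])
        for q in range(3):
            obs = embed_1q(zmat, q, 3)
            assert z[q] == pytest.approx(np.real(v.conj() @ obs @ v), abs=1e-10)

    def test_rejects_unnormalized_state(self):
        with pytest.raises(ValueError):
            measure_z_expectations(np.array([1.0, 1.0], dtype=complex))


class TestClassProbabilities:
    def test_ground_state_exact(self):
        ground = np.zeros(16, dtype=complex)
        ground[0] = 1.0
        assert np.allclose(sample_class_probabilities(ground, 2), [1.0, 0.0])

    def test_uniform_superposition_exact(self):
        plus = np.full(4, 0.5, dtype=complex)
        assert np.allclose(sample_class_probabilities(plus, 4), 0.25)

    def test_modulo_aggregation(self):
        # n=2, D=2: classes of basis indices (0,1,2,3) are (0,1,0,1)
        v = np.sqrt(np.array([0.1, 0.2, 0.3, 0.4], dtype=complex))
        p = sample_class_probabilities(v, 2)
        assert np.allclose(p, [0.4, 0.6])

    def test_shots_reproducible_and_valid(self):
        v = np.full(4, 0.5, dtype=complex)
        a = sample_class_probabilities(v, 2, shots=10, rng=np.random.default_rng(5))
        b = sample_class_probabilities(v, 2, shots=10, rng=np.random.default_rng(5))
        assert np.array_equal(a, b)
        assert a.sum() == pytest.approx(1.0)
        assert np.all(a >= 0)

    def test_shots_converge_to_exact(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=16) + 1j * rng.normal(size=16)
        v /= np.linalg.norm(v)
        exact = sample_class_probabilities(v, 4)
        emp = sample_class_probabilities(v, 4, shots=100_000, rng=np.random.default_rng(0))
        assert np.max(np.abs(emp - exact)) < 0.01

    def test_rejects_bad_arguments(self):
        v = np.array([1.0, 0.0], dtype=complex)
        with pytest.raises(ValueError):
            sample_class_probabilities(v, 4)
        with pytest.raises(ValueError):
            sample_class_probabilities(v, 2, shots=0, rng=np.random.default_rng(0))


def finite_difference(fn, x, h=1e-6):
    g = np.zeros_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2 * h)
    return g


class TestParameterShift:
    def test_h_ry_gradient_at_zero(self):
        spec = CircuitSpec(
            n_qubits=2,
            depth=0,
            gates=(GateOp("H", 0), GateOp("RY", 0, angle_source=("param", 0))),
            n_encoding=2,
            n_params=1,
        )
        d_par, d_enc = parameter_shift_gradient(
            spec, np.zeros(2), np.zeros(1), lambda s: measure_z_expectations(s)[0]
        )
        # <Z> = -sin(theta); derivative at 0 is -1
        assert d_par[0] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(d_enc, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n,depth,seed", [(2, 1, 0), (3, 2, 1), (3, 1, 2)])
    def test_matches_finite_difference(self, n, depth, seed):
        rng = np.random.default_rng(seed)
        spec = build_pqc(n, depth)
        phi = rng.uniform(-np.pi, np.pi, n)
        theta = rng.uniform(0, 2 * np.pi, spec.n_params)
        obs = lambda s: measure_z_expectations(s)[0]
        d_par, d_enc = parameter_shift_gradient(spec, phi, theta, obs)
        fd_par = finite_difference(
            lambda t: obs(run_circuit(spec, phi, t)), theta
        )
        fd_enc = finite_difference(
            lambda p: obs(run_circuit(spec, p, theta)), phi
        )
        assert np.max(np.abs(d_par - fd_par)) < 1e-6
        assert np.max(np.abs(d_enc - fd_enc)) < 1e-6

    def test_zero_gradient_at_critical_point(self):
        # theta = pi/2 puts <Z> = -sin(theta) at its minimum
        spec = CircuitSpec(
            n_qubits=2,
            depth=0,
            gates=(GateOp("H", 0), GateOp("RY", 0, angle_source=("param", 0))),
            n_encoding=2,
            n_params=1,
        )
        d_par, _ = parameter_shift_gradient(
            spec,
            np.zeros(2),
            np.array([np.pi / 2]),
            lambda s: measure_z_expectations(s)[0],
        )
        assert abs(d_par[0]) < 1e-9

    def test_rejects_complex_observable(self):
        spec = build_pqc(2, 1)
        with pytest.raises(ValueError):
            parameter_shift_gradient(
                spec, np.zeros(2), np.zeros(spec.n_params), lambda s: s[0]
            )


class TestJacobians:
    def test_z_jacobians_match_scalar_shifts(self):
        rng = np.random.default_rng(4)
        spec = build_pqc(3, 1)
        phi = rng.uniform(-1, 1, (2, 3))
        theta = rng.uniform(0, 2 * np.pi, spec.n_params)
        z, d_theta, d_phi = z_expectation_jacobians(spec, phi, theta)
        for b in range(2):
            for q in range(3):
                d_par, d_enc = parameter_shift_gradient(
                    spec, phi[b], theta, lambda s: measure_z_expectations(s)[q]
                )
                assert np.allclose(d_theta[b, q], d_par, atol=1e-10)
                assert np.allclose(d_phi[b, q], d_enc, atol=1e-10)

    def test_class_prob_jacobians_match_finite_difference(self):
        rng = np.random.default_rng(9)
        spec = build_pqc(2, 1)
        phi = rng.uniform(-1, 1, (1, 2))
        theta = rng.uniform(0, 2 * np.pi, spec.n_params)
        p, d_theta, _ = class_probability_jacobians(spec, phi, theta, 2)
        assert p.shape == (1, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        for k in range(spec.n_params):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += 1e-6
            tm[k] -= 1e-6
            fd = (
                sample_class_probabilities(run_circuit(spec, phi[0], tp), 2)
                - sample_class_probabilities(run_circuit(spec, phi[0], tm), 2)
            ) / 2e-6
            assert np.allclose(d_theta[0, :, k], fd, atol=1e-6)
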