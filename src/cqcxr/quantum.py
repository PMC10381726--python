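"""Dense statevector simulation of the parameterized quantum circuit (PQC).

The circuit family used by the hybrid classifier heads is built from three
gates only: Hadamard (H), y-axis rotations (RY) and CNOT. Data enter through
one RY *encoding* angle per qubit (the feature map); the trainable ansatz is
``depth`` blocks of a linear CNOT entangling chain, each followed by an RY
rotation layer, bracketed by an initial and a final rotation layer. For
``n`` qubits and depth ``d`` this gives ``P = n * (d + 2)`` trainable angles
(24 for the default 4-qubit, depth-4 circuit).

Bit convention: qubit 0 is the **most significant bit** of the computational
basis index, i.e. basis state ``|b_0 b_1 ... b_{n-1}>`` has index
``sum(b_q << (n - 1 - q))``. All tests pin this ordering.

States are plain complex numpy vectors of length ``2**n``; every function
also accepts a batch ``(B, 2**n)`` and then returns batched results.

Gradients of rotation-angle expectations use the exact parameter-shift rule

    dE/da = [E(a + pi/2) - E(a - pi/2)] / 2,

valid because every angle parameterizes a single RY gate (eigenvalue gap 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

__all__ = [
    "GateOp",
    "CircuitSpec",
    "build_pqc",
    "apply_gate",
    "run_circuit",
    "measure_z_expectations",
    "sample_class_probabilities",
    "parameter_shift_gradient",
    "z_expectation_jacobians",
    "class_probability_jacobians",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_H = np.array([[_INV_SQRT2, _INV_SQRT2], [_INV_SQRT2, -_INV_SQRT2]], dtype=complex)

AngleSource = tuple[Literal["enc", "param", "const"], int | float]


@dataclass(frozen=True)
class GateOp:
    """One gate: H, RY or CNOT acting on addressed qubits.

    ``angle_source`` (RY only) says where the rotation angle comes from:
    ``("enc", i)`` = i-th encoding angle, ``("param", k)`` = k-th trainable
    angle, ``("const", value)`` = fixed angle in radians.
    """

    kind: Literal["H", "RY", "CNOT"]
    target: int
    control: int | None = None
    angle_source: AngleSource | None = None

    def __post_init__(self) -> None:
        if self.kind == "CNOT":
            if self.control is None:
                raise ValueError("CNOT requires a control qubit")
            if self.control == self.target:
                raise ValueError("CNOT control must differ from target")
        elif self.control is not None:
            raise ValueError(f"{self.kind} takes no control qubit")
        if self.kind == "RY" and self.angle_source is None:
            raise ValueError("RY requires an angle source")
        if self.kind != "RY" and self.angle_source is not None:
            raise ValueError(f"{self.kind} takes no angle")


@dataclass(frozen=True)
class CircuitSpec:
    """An n-qubit circuit layout with ``n_params`` trainable angles."""

    n_qubits: int
    depth: int
    gates: tuple[GateOp, ...]
    n_encoding: int
    n_params: int

    @property
    def dim(self) -> int:
        return 1 << self.n_qubits


def build_pqc(n: int, depth: int) -> CircuitSpec:
    """Build the default hybrid-head PQC.

    Layout: H on every qubit; RY(phi_i) encoding layer; RY(theta) layer;
    ``depth`` blocks of [CNOT chain control i -> target i+1, RY(theta)
    layer]; final RY(theta) layer. Trainable count P = n * (depth + 2).

    Parameters
    ----------
    n : int
        Qubit count, >= 2 (the linear entangling chain needs two qubits).
    depth : int
        Number of entangling blocks, >= 1.
    """
    if n < 2:
        raise ValueError("n must be >= 2 (no entanglement possible otherwise)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    gates: list[GateOp] = []
    for q in range(n):
        gates.append(GateOp("H", q))
    for q in range(n):
        gates.append(GateOp("RY", q, angle_source=("enc", q)))
    k = 0

    def rotation_layer() -> None:
        nonlocal k
        for q in range(n):
            gates.append(GateOp("RY", q, angle_source=("param", k)))
            k += 1

    rotation_layer()
    for _ in range(depth):
        for q in range(n - 1):
            gates.append(GateOp("CNOT", target=q + 1, control=q))
        rotation_layer()
    rotation_layer()
    return CircuitSpec(
        n_qubits=n,
        depth=depth,
        gates=tuple(gates),
        n_encoding=n,
        n_params=k,
    )


def _as_batch(state: np.ndarray, n: int) -> tuple[np.ndarray, bool]:
    state = np.asarray(state, dtype=complex)
    if state.ndim == 1:
        return state[None, :], True
    if state.ndim != 2:
        raise ValueError("state must be a vector or a (B, 2**n) batch")
    if state.shape[-1] != (1 << n):
        raise ValueError("state length does not match qubit count")
    return state, False


def _ry_matrix(angle: float) -> np.ndarray:
    c, s = np.cos(angle / 2.0), np.sin(angle / 2.0)
    return np.array([[c, -s], [s, c]], dtype=complex)


def _apply_1q(batch: np.ndarray, mat: np.ndarray, q: int, n: int) -> np.ndarray:
    b = batch.shape[0]
    x = batch.reshape((b,) + (2,) * n)
    x = np.moveaxis(x, q + 1, -1)
    x = x @ mat.T
    x = np.moveaxis(x, -1, q + 1)
    return x.reshape(b, 1 << n)


def _apply_cnot(batch: np.ndarray, control: int, target: int, n: int) -> np.ndarray:
    b = batch.shape[0]
    x = batch.reshape((b,) + (2,) * n).copy()
    view = np.moveaxis(x, (control + 1, target + 1), (-2, -1))
    tmp = view[..., 1, 0].copy()
    view[..., 1, 0] = view[..., 1, 1]
    view[..., 1, 1] = tmp
    return x.reshape(b, 1 << n)


def _resolve_angle(
    source: AngleSource, encoding: np.ndarray, params: np.ndarray
) -> np.ndarray | float:
    kind, ref = source
    if kind == "enc":
        return encoding[..., int(ref)]
    if kind == "param":
        return params[int(ref)]
    return float(ref)


def apply_gate(
    state: np.ndarray,
    gate: GateOp,
    n_qubits: int,
    encoding: np.ndarray | None = None,
    params: np.ndarray | None = None,
) -> np.ndarray:
    """Apply one gate to a state (or batch), returning the new state."""
    if gate.target >= n_qubits or (gate.control is not None and gate.control >= n_qubits):
        raise ValueError("gate qubit index out of range")
    batch, squeeze = _as_batch(state, n_qubits)
    if gate.kind == "H":
        out = _apply_1q(batch, _H, gate.target, n_qubits)
    elif gate.kind == "CNOT":
        out = _apply_cnot(batch, gate.control, gate.target, n_qubits)
    else:
        assert gate.angle_source is not None
        enc = np.zeros(0) if encoding is None else np.asarray(encoding, dtype=float)
        par = np.zeros(0) if params is None else np.asarray(params, dtype=float)
        angle = _resolve_angle(gate.angle_source, enc, par)
        if np.ndim(angle) == 0:
            out = _apply_1q(batch, _ry_matrix(float(angle)), gate.target, n_qubits)
        else:
            # per-sample encoding angles: apply the 2x2 rotation sample-wise
            a = np.asarray(angle, dtype=float)
            c, s = np.cos(a / 2.0), np.sin(a / 2.0)
            b = batch.shape[0]
            x = batch.reshape((b,) + (2,) * n_qubits)
            x = np.moveaxis(x, gate.target + 1, -1)
            shape = (b,) + (1,) * (n_qubits - 1)
            c = c.reshape(shape)
            s = s.reshape(shape)
            x0, x1 = x[..., 0], x[..., 1]
            y0 = c * x0 - s * x1
            y1 = s * x0 + c * x1
            x = np.stack([y0, y1], axis=-1)
            x = np.moveaxis(x, -1, gate.target + 1)
            out = x.reshape(b, 1 << n_qubits)
    return out[0] if squeeze else out


def run_circuit(
    spec: CircuitSpec, encoding: np.ndarray, params: np.ndarray
) -> np.ndarray:
    """Run the full circuit from |0...0>.

    ``encoding`` may be a length-n vector or a (B, n) batch; the returned
    state is a ``2**n`` vector or a (B, 2**n) batch accordingly.
    """
    encoding = np.asarray(encoding, dtype=float)
    params = np.asarray(params, dtype=float)
    if encoding.shape[-1] != spec.n_encoding:
        raise ValueError(
            f"expected {spec.n_encoding} encoding angles, got {encoding.shape[-1]}"
        )
    if params.shape != (spec.n_params,):
        raise ValueError(f"expected {spec.n_params} trainable angles")
    squeeze = encoding.ndim == 1
    enc = encoding[None, :] if squeeze else encoding
    state = np.zeros((enc.shape[0], spec.dim), dtype=complex)
    state[:, 0] = 1.0
    for gate in spec.gates:
        state = apply_gate(state, gate, spec.n_qubits, enc, params)
    return state[0] if squeeze else state


def _check_normalized(batch: np.ndarray) -> None:
    norms = np.linalg.norm(batch, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("state is not normalized")


def measure_z_expectations(state: np.ndarray) -> np.ndarray:
    """Exact Pauli-Z expectation per qubit, each in [-1, 1].

    Component i is ``sum_b (+1 if bit i of b is 0 else -1) * |amp_b|**2``
    with qubit 0 as the most significant bit.
    """
    arr = np.asarray(state, dtype=complex)
    n = int(round(np.log2(arr.shape[-1])))
    batch, squeeze = _as_batch(arr, n)
    _check_normalized(batch)
    probs = np.abs(batch) ** 2
    p = probs.reshape((batch.shape[0],) + (2,) * n)
    out = np.empty((batch.shape[0], n))
    for q in range(n):
        m = np.moveaxis(p, q + 1, 1).reshape(batch.shape[0], 2, -1).sum(axis=2)
        out[:, q] = m[:, 0] - m[:, 1]
    return out[0] if squeeze else out


def sample_class_probabilities(
    state: np.ndarray,
    n_classes: int,
    shots: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class probabilities from the basis-outcome distribution.

    Basis outcome ``b`` maps to class ``b % n_classes``. With ``shots=None``
    the exact aggregated probabilities are returned; with finite shots,
    empirical frequencies of ``shots`` seeded draws (reproducible given the
    generator state).
    """
    arr = np.asarray(state, dtype=complex)
    n = int(round(np.log2(arr.shape[-1])))
    batch, squeeze = _as_batch(arr, n)
    _check_normalized(batch)
    dim = batch.shape[-1]
    if n_classes < 2 or n_classes > dim:
        raise ValueError("n_classes must be in [2, 2**n_qubits]")
    probs = np.abs(batch) ** 2
    probs /= probs.sum(axis=-1, keepdims=True)
    classes = np.arange(dim) % n_classes
    if shots is None:
        out = np.zeros((batch.shape[0], n_classes))
        np.add.at(out.T, classes, probs.T)
    else:
        if shots < 1:
            raise ValueError("shots must be >= 1")
        if rng is None:
            raise ValueError("shots mode requires a seeded rng")
        out = np.zeros((batch.shape[0], n_classes))
        for i in range(batch.shape[0]):
            counts = rng.multinomial(shots, probs[i])
            np.add.at(out[i], classes, counts)
        out /= float(shots)
    return out[0] if squeeze else out


def parameter_shift_gradient(
    spec: CircuitSpec,
    encoding: np.ndarray,
    params: np.ndarray,
    observable_fn: Callable[[np.ndarray], float | np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Exact gradients of an expectation via the parameter-shift rule.

    ``observable_fn`` must map a statevector to a real scalar (or array of
    such expectations, each linear in the density matrix — every Z
    expectation and every exact class probability qualifies). Returns
    ``(d_params, d_encoding)`` with leading axes P and n respectively;
    encoding gradients are always produced so the preceding classical layer
    can be trained by the chain rule.
    """
    encoding = np.asarray(encoding, dtype=float)
    params = np.asarray(params, dtype=float)
    probe = np.asarray(observable_fn(run_circuit(spec, encoding, params)))
    if np.iscomplexobj(probe):
        raise ValueError("observable_fn must be real-valued")

    def ev(enc: np.ndarray, par: np.ndarray) -> np.ndarray:
        return np.asarray(observable_fn(run_circuit(spec, enc, par)), dtype=float)

    d_par = np.empty((spec.n_params,) + probe.shape)
    for k in range(spec.n_params):
        plus = params.copy()
        minus = params.copy()
        plus[k] += np.pi / 2
        minus[k] -= np.pi / 2
        d_par[k] = (ev(encoding, plus) - ev(encoding, minus)) / 2.0
    d_enc = np.empty((spec.n_encoding,) + probe.shape)
    for i in range(spec.n_encoding):
        plus = encoding.copy()
        minus = encoding.copy()
        plus[i] += np.pi / 2
        minus[i] -= np.pi / 2
        d_enc[i] = (ev(plus, params) - ev(minus, params)) / 2.0
    return d_par, d_enc


def _shift_runs(
    spec: CircuitSpec,
    enc: np.ndarray,
    params: np.ndarray,
    measure: Callable[[np.ndarray], np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Batched parameter-shift sweeps for a vector-valued measurement.

    ``enc`` is (B, n); ``measure`` maps a (B, dim) state batch to (B, M).
    Returns (d_theta (B, M, P), d_phi (B, M, n)).
    """
    b = enc.shape[0]
    probe = measure(run_circuit(spec, enc, params))
    m = probe.shape[-1]
    d_theta = np.empty((b, m, spec.n_params))
    for k in range(spec.n_params):
        plus = params.copy()
        minus = params.copy()
        plus[k] += np.pi / 2
        minus[k] -= np.pi / 2
        d_theta[:, :, k] = (
            measure(run_circuit(spec, enc, plus)) - measure(run_circuit(spec, enc, minus))
        ) / 2.0
    d_phi = np.empty((b, m, spec.n_encoding))
    for i in range(spec.n_encoding):
        plus = enc.copy()
        minus = enc.copy()
        plus[:, i] += np.pi / 2
        minus[:, i] -= np.pi / 2
        d_phi[:, :, i] = (
            measure(run_circuit(spec, plus, params)) - measure(run_circuit(spec, minus, params))
        ) / 2.0
    return d_theta, d_phi


def z_expectation_jacobians(
    spec: CircuitSpec, encoding: np.ndarray, params: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched Z expectations and their parameter-shift Jacobians.

    Returns ``(z (B, n), d_theta (B, n, P), d_phi (B, n, n))``.
    """
    enc = np.atleast_2d(np.asarray(encoding, dtype=float))
    z = measure_z_expectations(run_circuit(spec, enc, params))
    d_theta, d_phi = _shift_runs(spec, enc, params, measure_z_expectations)
    return z, d_theta, d_phi


def class_probability_jacobians(
    spec: CircuitSpec, encoding: np.ndarray, params: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched exact class probabilities and their Jacobians.

    Returns ``(p (B, D), d_theta (B, D, P), d_phi (B, D, n))``.
    """
    enc = np.atleast_2d(np.asarray(encoding, dtype=float))

    def measure(state: np.ndarray) -> np.ndarray:
        return sample_class_probabilities(state, n_classes)

    p = measure(run_circuit(spec, enc, params))
    d_theta, d_phi = _shift_runs(spec, enc, params, measure)
    return p, d_theta, d_phi
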