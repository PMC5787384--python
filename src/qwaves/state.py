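"""Pure states of the qubit register.

Convention used across the package: qubit 0 is the *leftmost* character of a
Pauli word and the *most significant* bit of a computational-basis index, so
``|01⟩`` (qubit 0 in 0, qubit 1 in 1) is amplitude index 1 of a 2-qubit state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_NORM_TOL = 1e-10


@dataclass
class StateVector:
    """A normalized pure state of an ``n_qubits`` register.

    Parameters
    ----------
    amplitudes:
        Complex amplitudes of length ``2**n_qubits`` in the computational
        basis (qubit 0 most significant).
    n_qubits:
        Number of qubits; inferred from ``amplitudes`` when omitted.
    """

    amplitudes: np.ndarray
    n_qubits: int = field(default=-1)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex).ravel()
        dim = self.amplitudes.size
        n = int(dim).bit_length() - 1
        if dim != 2**n:
            raise ValueError(f"amplitude vector of length {dim} is not a qubit register")
        if self.n_qubits < 0:
            self.n_qubits = n
        elif self.n_qubits != n:
            raise ValueError(f"declared n_qubits={self.n_qubits} but got {dim} amplitudes")
        norm = np.linalg.norm(self.amplitudes)
        if abs(norm - 1.0) > _NORM_TOL:
            raise ValueError(f"state vector is not normalized (norm={norm!r})")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.amplitudes, dtype=dtype)


def basis_state(bits: str) -> StateVector:
    """Computational basis state from a bit string, e.g. ``"10"`` → |10⟩."""
    n = len(bits)
    if not set(bits) <= {"0", "1"}:
        raise ValueError(f"invalid bit string {bits!r}")
    amps = np.zeros(2**n, dtype=complex)
    amps[int(bits, 2)] = 1.0
    return StateVector(amps, n)


def as_amplitudes(psi) -> np.ndarray:
    """Coerce a StateVector or array-like to a flat complex array."""
    if isinstance(psi, StateVector):
        return psi.amplitudes
    return np.asarray(psi, dtype=complex).ravel()


def fidelity(a, b) -> float:
    """Squared overlap |⟨a|b⟩|² of two pure states."""
    va, vb = as_amplitudes(a), as_amplitudes(b)
    return float(abs(np.vdot(va, vb)) ** 2)


def subspace_fidelity(psi, basis) -> float:
    """Fidelity ⟨ψ|Π|ψ⟩ with the projector onto span(basis).

    ``basis`` is an iterable of orthonormal states; used for fidelities
    against degenerate eigen-subspaces.
    """
    v = as_amplitudes(psi)
    return float(sum(abs(np.vdot(as_amplitudes(b), v)) ** 2 for b in basis))
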