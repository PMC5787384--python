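"""The eigenstate-witness engine.

A single ancilla ("control") qubit in |+⟩ controls the time evolution
U = e^{−iHt} of the target register.  Tracing out the target leaves the
control in ρ_C with off-diagonal element ⟨Ψ|U|Ψ⟩/2, from which three
quantities follow:

* the energy estimator  E = −Arg[⟨Ψ|e^{−iHt}|Ψ⟩]/t,
* the purity            P = Tr[ρ_C²]  (1 exactly when |Ψ⟩ is an eigenstate),
* the von Neumann entropy S = −Tr[ρ_C ln ρ_C]  (the eigenstate witness).

The variational objective is F_obj = E − T·P, a free-energy-like trade-off
between energy and eigenstate-ness; in the high-T limit F_obj ≡ −P, which is
blind to the energy ordering and so can target excited states.  Tomography of
the control qubit is emulated with a binomial shot-noise model per Pauli basis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .pauli import PauliSum, pauli_sum_to_matrix
from .state import StateVector, as_amplitudes

_SIGMA = (
    np.array([[0, 1], [1, 0]], dtype=complex),
    np.array([[0, -1j], [1j, 0]], dtype=complex),
    np.array([[1, 0], [0, -1]], dtype=complex),
)

#: below this magnitude of ⟨U⟩ the Arg (hence E) is numerically undefined
ARG_TOL = 1e-12

#: sentinel temperature for the purity-only (high-T) objective
HIGH_T = math.inf


def evolution_operator(h: PauliSum, t: float) -> np.ndarray:
    """Exact U = e^{−iHt} by eigendecomposition (no Trotterization)."""
    mat = pauli_sum_to_matrix(h)
    vals, vecs = np.linalg.eigh(mat)
    return (vecs * np.exp(-1j * vals * t)) @ vecs.conj().T


def apply_controlled_evolution(psi: StateVector, h: PauliSum, t: float) -> StateVector:
    """Joint (control ⊗ target) state (|0⟩⊗|Ψ⟩ + |1⟩⊗U|Ψ⟩)/√2, control leading."""
    if psi.n_qubits != h.n_qubits:
        raise ValueError(
            f"state has {psi.n_qubits} qubits but Hamiltonian acts on {h.n_qubits}")
    if t <= 0:
        raise ValueError("evolution time must be positive")
    u = evolution_operator(h, t)
    amps = psi.amplitudes
    joint = np.concatenate([amps, u @ amps]) / math.sqrt(2.0)
    return StateVector(joint, psi.n_qubits + 1)


@dataclass
class ControlReducedState:
    """The 2×2 reduced density matrix of the control qubit."""

    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=complex)
        if self.rho.shape != (2, 2):
            raise ValueError("control state must be 2x2")

    @property
    def bloch(self) -> np.ndarray:
        return np.array([float(np.trace(self.rho @ s).real) for s in _SIGMA])

    @property
    def purity(self) -> float:
        return float(np.trace(self.rho @ self.rho).real)


def control_reduced_state(joint: StateVector) -> ControlReducedState:
    """Partial trace over the target register; ρ[1,0] = ⟨Ψ|U|Ψ⟩/2."""
    if joint.n_qubits < 2:
        raise ValueError("joint state needs a control plus at least one target qubit")
    block = joint.amplitudes.reshape(2, -1)
    return ControlReducedState(block @ block.conj().T)


@dataclass(frozen=True)
class TomographySettings:
    """Shot budget and seed for single-qubit control tomography.

    ``shots_per_basis = 0`` means analytic (infinite-shot) readout.  Shots are
    allocated equally to the σx, σy, σz bases.
    """

    shots_per_basis: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shots_per_basis < 0:
            raise ValueError("shots_per_basis must be >= 0")


def simulate_control_tomography(joint: StateVector,
                                settings: TomographySettings) -> ControlReducedState:
    """Reconstruct ρ_C from binomially sampled Pauli expectation values.

    For each basis, the up-outcome count is Binomial(shots, (1+r_i)/2); the
    Bloch vector is linearly inverted from the empirical frequencies and
    clipped to the unit ball so the reconstruction is physical.
    """
    exact = control_reduced_state(joint)
    if settings.shots_per_basis == 0:
        return exact
    rng = np.random.default_rng(settings.seed)
    shots = settings.shots_per_basis
    r = exact.bloch
    counts = rng.binomial(shots, (1.0 + r) / 2.0)
    r_hat = 2.0 * counts / shots - 1.0
    norm = np.linalg.norm(r_hat)
    if norm > 1.0:
        r_hat = r_hat / norm
    rho = 0.5 * (np.eye(2, dtype=complex)
                 + r_hat[0] * _SIGMA[0] + r_hat[1] * _SIGMA[1] + r_hat[2] * _SIGMA[2])
    return ControlReducedState(rho)


@dataclass
class WitnessRecord:
    """Witness quantities extracted from one control-qubit readout.

    ``energy`` is on the shifted scale (add the Hamiltonian's energy offset ℓ
    for absolute energies) and is NaN when |⟨U⟩| is numerically zero.
    ``objective`` is E − T·P, or −P in the high-T mode.
    """

    energy: float
    purity: float
    entropy: float
    objective: float
    temperature: float
    t: float
    shots_used: int = 0

    @property
    def energy_defined(self) -> bool:
        return math.isfinite(self.energy)


def map_to_branch(value: float, width: float, interval: tuple[float, float]) -> float:
    """Shift ``value`` by integer multiples of ``width`` into [lo, hi)."""
    lo, hi = interval
    if hi - lo < width - 1e-12:
        # narrower than one period: a candidate may not exist
        k = math.ceil((lo - value) / width)
        shifted = value + k * width
        if not (lo - 1e-12 <= shifted < hi + 1e-12):
            raise ValueError(f"no branch candidate for {value} in [{lo}, {hi})")
        return shifted
    shifted = value + math.ceil((lo - value) / width - 1e-12) * width
    return shifted


def witness_quantities(rho: ControlReducedState, t: float, temperature: float,
                       energy_branch_hint: tuple[float, float] | None = None,
                       shots_used: int = 0) -> WitnessRecord:
    """E, P, S and F_obj from the control qubit's reduced state.

    The energy is −Arg(2·ρ[1,0])/t, placed on the 2π/t-wide branch given by
    ``energy_branch_hint`` (default [0, 2π/t)).  With ``temperature = HIGH_T``
    the objective is −P and the (possibly undefined) energy is still reported.
    """
    if t <= 0:
        raise ValueError("evolution time must be positive")
    mat = rho.rho
    purity = rho.purity
    evals = np.clip(np.linalg.eigvalsh(mat).real, 0.0, 1.0)
    entropy = float(-sum(p * math.log(p) for p in evals if p > 0.0))
    overlap = 2.0 * mat[1, 0]
    width = 2.0 * math.pi / t
    if abs(overlap) < ARG_TOL:
        energy = math.nan
    else:
        energy = float(-np.angle(overlap)) / t
        energy = map_to_branch(energy, width, energy_branch_hint or (0.0, width))
    if temperature == HIGH_T:
        objective = -purity
    else:
        objective = energy - temperature * purity
    return WitnessRecord(energy=energy, purity=purity, entropy=entropy,
                         objective=objective, temperature=temperature, t=t,
                         shots_used=shots_used)


def default_evolution_time(h: PauliSum) -> float:
    """Conservative evolution time t = π/(2‖H‖₁), ‖·‖₁ the coefficient 1-norm.

    Keeps λt within half a branch for every eigenvalue.  Callers may override;
    the chlorophyll-dimer reproduction uses t = 26 (1/eV), which exceeds this
    bound deliberately to widen the purity span — a warning, not an error.
    """
    norm = h.one_norm
    if norm <= 0:
        raise ValueError("zero operator has no natural evolution time")
    return math.pi / (2.0 * norm)


def check_evolution_time(h: PauliSum, t: float) -> None:
    """Warn when t exceeds the conservative π/(2‖H‖₁) window."""
    if t > default_evolution_time(h) + 1e-12:
        warnings.warn(
            f"evolution time t={t} exceeds pi/(2*one_norm)={default_evolution_time(h):.4g}; "
            "energy branch aliasing is possible", stacklevel=2)
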