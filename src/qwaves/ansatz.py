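"""Trial-state preparation.

Three ansatz families are provided:

* the three-phase single-qubit chain A = e^{iφa} e^{iφb σz/2} e^{iφc σy/2}
  used for the exciton-dimer demonstration,
* "parameterized Hamiltonian" (PH) generators i(T + T†) built from the
  model's own one-/two-body terms (a deformation of the Hamiltonian that
  preserves its symmetries),
* unrestricted unitary coupled-cluster (UCC) generators (T − T†) over
  arbitrary orbital pairs/quadruples.

Generator ansätze act as exp(Σ θ_i Â_i)|Φ⟩ with anti-Hermitian Â_i (the
evolution-time factor of the exponential is absorbed into θ, which are
dimensionless angles).  Excited-state searches prepend excitation unitaries
E_ij(θ) = exp[θ(a_i†a_j − a_j†a_i)]; candidate (i, j) pairs can be read off
the one-particle reduced density matrix via natural orbitals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .models import FermionicModelSpec, fermionic_terms
from .pauli import (ANNIHILATE, CREATE, FermionTerm, PauliSum,
                    jordan_wigner, pauli_sum_to_matrix)
from .state import StateVector, as_amplitudes, basis_state

_ANTIHERM_TOL = 1e-10


@dataclass
class AnsatzSpec:
    """A parameterized family of preparable states.

    ``kind`` is ``"single_qubit"`` (parameters are the three phases
    φa, φb, φc) or ``"generator"`` (one parameter per anti-Hermitian
    generator).  ``parameter_ranges`` are the closed intervals of the uniform
    prior used by the swarm; for the single-qubit kind φa defaults to the
    degenerate range [0, 0] since a global phase on an uncontrolled
    preparation is unobservable.
    """

    kind: str
    reference: StateVector
    generators: list[PauliSum] = field(default_factory=list)
    parameter_ranges: list[tuple[float, float]] = field(default_factory=list)
    #: per-parameter flag: the coordinate is periodic with period = its range
    #: width (optimizers then do circular statistics around a reference)
    periodic: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("single_qubit", "generator"):
            raise ValueError(f"unknown ansatz kind {self.kind!r}")
        if self.kind == "single_qubit":
            if self.reference.n_qubits != 1:
                raise ValueError("single-qubit ansatz needs a 1-qubit reference")
            if not self.parameter_ranges:
                # unique Bloch-sphere cover: φa is an unobservable global phase
                # (pinned), φb the azimuth (periodic), φc ∈ [0, π] the polar
                # angle; wider φc ranges double-cover the sphere and give a
                # multi-well parameter landscape whose population mean is a
                # poor state
                self.parameter_ranges = [(0.0, 0.0), (-math.pi, math.pi),
                                         (0.0, math.pi)]
                self.periodic = [False, True, False]
        else:
            if not self.generators:
                raise ValueError("generator ansatz needs at least one generator")
            for g in self.generators:
                m = pauli_sum_to_matrix(g)
                if np.max(np.abs(m + m.conj().T)) > _ANTIHERM_TOL:
                    raise ValueError("generators must be anti-Hermitian")
            if not self.parameter_ranges:
                self.parameter_ranges = [(-math.pi, math.pi)] * len(self.generators)
        if len(self.parameter_ranges) != self.parameter_count:
            raise ValueError("parameter_ranges length mismatch")
        if not self.periodic:
            self.periodic = [False] * self.parameter_count
        if len(self.periodic) != self.parameter_count:
            raise ValueError("periodic length mismatch")

    @property
    def parameter_count(self) -> int:
        return 3 if self.kind == "single_qubit" else len(self.generators)

    @property
    def n_qubits(self) -> int:
        return self.reference.n_qubits


def single_qubit_ansatz(reference: StateVector | None = None) -> AnsatzSpec:
    """The experimental single-qubit ansatz acting on |0⟩."""
    return AnsatzSpec("single_qubit", reference or basis_state("0"))


def single_qubit_ansatz_state(phi_a: float, phi_b: float, phi_c: float) -> StateVector:
    """A(φ)|0⟩ = e^{iφa} e^{iφb σz/2} e^{iφc σy/2} |0⟩ (global phase retained)."""
    c, s = math.cos(phi_c / 2.0), math.sin(phi_c / 2.0)
    amps = np.array([c * np.exp(1j * phi_b / 2.0), -s * np.exp(-1j * phi_b / 2.0)])
    return StateVector(np.exp(1j * phi_a) * amps, 1)


@dataclass(frozen=True)
class ExcitationOp:
    """E_ij(θ) = exp[θ(a_i†a_j − a_j†a_i)]: move occupation from j to i."""

    occupied: int
    virtual: int
    angle: float = math.pi / 2.0

    def __post_init__(self) -> None:
        if self.occupied == self.virtual:
            raise ValueError("excitation needs distinct occupied/virtual indices")


def excitation_unitary(op: ExcitationOp, n_modes: int) -> np.ndarray:
    """Dense unitary of E_ij(θ) after Jordan–Wigner mapping."""
    if not (0 <= op.occupied < n_modes and 0 <= op.virtual < n_modes):
        raise ValueError("excitation index out of range")
    gen = jordan_wigner(
        [FermionTerm(1.0, [(op.virtual, CREATE), (op.occupied, ANNIHILATE)]),
         FermionTerm(-1.0, [(op.occupied, CREATE), (op.virtual, ANNIHILATE)])],
        n_modes)
    return scipy.linalg.expm(op.angle * pauli_sum_to_matrix(gen))


def exciton_perturbation() -> np.ndarray:
    """E_p = e^{iπσz/2} = iσz, the dimer's ground→excited perturbing unitary."""
    return np.diag([1j, -1j])


def _resolve_prepend(prepend, n_qubits: int) -> list[np.ndarray]:
    mats = []
    for item in prepend or []:
        if isinstance(item, ExcitationOp):
            mats.append(excitation_unitary(item, n_qubits))
        else:
            mats.append(np.asarray(item, dtype=complex))
    return mats


def apply_ansatz(spec: AnsatzSpec, theta, prepend=None) -> StateVector:
    """Prepare [∏ E_p] · exp(Σ θ_i Â_i) |Φ⟩ (or the single-qubit chain).

    ``prepend`` lists excitation unitaries (ExcitationOp or explicit matrices)
    applied after the parameterized block, first list element outermost.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.size != spec.parameter_count:
        raise ValueError(
            f"expected {spec.parameter_count} parameters, got {theta.size}")
    if spec.kind == "single_qubit":
        state = single_qubit_ansatz_state(*theta)
    else:
        gen = spec.generators[0].n_qubits
        total = PauliSum(gen)
        for th, g in zip(theta, spec.generators):
            total = total + float(th) * g
        u = scipy.linalg.expm(pauli_sum_to_matrix(total))
        state = StateVector(u @ spec.reference.amplitudes, spec.n_qubits)
    amps = state.amplitudes
    for mat in reversed(_resolve_prepend(prepend, spec.n_qubits)):
        amps = mat @ amps
    return StateVector(amps, spec.n_qubits)


# -- generator builders --------------------------------------------------------

def ph_generators(spec: FermionicModelSpec) -> list[PauliSum]:
    """PH-ansatz generators i(T + T†), one per distinct model term.

    One-body terms contribute i(a_i†a_j + a_j†a_i) for each unordered pair
    with h_ij ≠ 0 (diagonal terms give number-operator phase generators);
    each two-body coefficient contributes i(T + T†).  All generators are
    anti-Hermitian and particle-number conserving.
    """
    gens: list[PauliSum] = []
    n = spec.n_modes
    for i in range(n):
        for j in range(i, n):
            if abs(spec.one_body[i, j]) <= 0:
                continue
            terms = [FermionTerm(1j, [(i, CREATE), (j, ANNIHILATE)])]
            if i != j:
                terms.append(FermionTerm(1j, [(j, CREATE), (i, ANNIHILATE)]))
            gens.append(jordan_wigner(terms, n))
    for i, j, k, l, _ in spec.two_body:
        base = FermionTerm(1.0, [(i, CREATE), (j, CREATE), (k, ANNIHILATE), (l, ANNIHILATE)])
        gens.append(jordan_wigner(
            [FermionTerm(1j, base.ladder), FermionTerm(1j, base.dagger().ladder)], n))
    return [g for g in gens if len(g) > 0]


def ucc_singles_generators(n_modes: int) -> list[PauliSum]:
    """Unrestricted UCC single-excitation generators (a_i†a_j − a_j†a_i), i<j."""
    gens = []
    for j in range(n_modes):
        for i in range(j + 1, n_modes):
            gens.append(jordan_wigner(
                [FermionTerm(1.0, [(i, CREATE), (j, ANNIHILATE)]),
                 FermionTerm(-1.0, [(j, CREATE), (i, ANNIHILATE)])], n_modes))
    return [g for g in gens if len(g) > 0]


def ucc_double_generator(i: int, j: int, k: int, l: int, n_modes: int) -> PauliSum:
    """UCC double generator (a_i†a_j a_k†a_l − a_l†a_k a_j†a_i).

    All index quadruples are accepted and antisymmetrized; colliding indices
    may produce lower-rank (or vanishing) generators.
    """
    fwd = FermionTerm(1.0, [(i, CREATE), (j, ANNIHILATE), (k, CREATE), (l, ANNIHILATE)])
    return jordan_wigner([fwd, FermionTerm(-1.0, list(reversed(
        [(m, CREATE if kd == ANNIHILATE else ANNIHILATE) for m, kd in fwd.ladder])))],
        n_modes)


def pauli_word_generators(n_qubits: int, words: list[str] | None = None) -> list[PauliSum]:
    """Generic generators i·P for a list of Pauli words (default: all non-identity).

    exp(Σ θ_k i P_k) reaches all of SU(2^n) when the words span the Pauli
    basis, giving a maximally expressive ansatz for small random-Hamiltonian
    fixtures.
    """
    if words is None:
        words = []
        chars = "IXYZ"
        for idx in range(1, 4**n_qubits):
            digits = [(idx // 4**k) % 4 for k in range(n_qubits - 1, -1, -1)]
            words.append("".join(chars[d] for d in digits))
    return [PauliSum.from_dict(n_qubits, {w: 1j}) for w in words]


# -- natural orbitals ----------------------------------------------------------

@dataclass(frozen=True)
class NaturalExcitation:
    """A natural-orbital excitation candidate c_occ† ← c_vir (occupation transfer)."""

    occupied_orbital: int
    virtual_orbital: int
    transfer: float


def one_particle_rdm(psi: StateVector, n_modes: int) -> np.ndarray:
    """D_ij = ⟨Ψ|a_i†a_j|Ψ⟩, Hermitian PSD with trace = ⟨N̂⟩."""
    v = as_amplitudes(psi)
    d = np.zeros((n_modes, n_modes), dtype=complex)
    mats = {}
    for i in range(n_modes):
        for j in range(n_modes):
            key = (i, j)
            mats[key] = pauli_sum_to_matrix(jordan_wigner(
                [FermionTerm(1.0, [(i, CREATE), (j, ANNIHILATE)])], n_modes))
            d[i, j] = np.vdot(v, mats[key] @ v)
    return d


def natural_orbital_excitations(psi: StateVector, n_modes: int
                                ) -> tuple[np.ndarray, list[NaturalExcitation], np.ndarray]:
    """Diagonalize the 1-RDM and rank occupied→virtual excitation candidates.

    Returns ``(D, excitations, V)`` where columns of V are natural orbitals
    (c_k = Σ_p conj(V_pk) a_p) ordered by descending occupation, and the
    excitation list pairs more-occupied with less-occupied orbitals, ordered
    by descending occupation transfer.
    """
    d = one_particle_rdm(psi, n_modes)
    occ, vecs = np.linalg.eigh(d)
    order = np.argsort(occ)[::-1]
    occ, vecs = occ[order].real, vecs[:, order]
    excitations = []
    for p in range(n_modes):
        for q in range(n_modes):
            if occ[p] - occ[q] > 1e-10:
                excitations.append(NaturalExcitation(p, q, float(occ[p] - occ[q])))
    excitations.sort(key=lambda e: -e.transfer)
    return d, excitations, vecs


def natural_excitation_unitary(vecs: np.ndarray, exc: NaturalExcitation,
                               n_modes: int, angle: float = math.pi / 2.0) -> np.ndarray:
    """exp[θ(c_v†c_o − c_o†c_v)] in the original mode basis.

    ``vecs`` is the natural-orbital matrix from
    :func:`natural_orbital_excitations`; c_k† = Σ_p V_pk a_p†.
    """
    o, vtx = exc.occupied_orbital, exc.virtual_orbital
    terms = []
    for p in range(n_modes):
        for q in range(n_modes):
            c = vecs[p, vtx] * np.conj(vecs[q, o])
            if abs(c) > 1e-14:
                terms.append(FermionTerm(c, [(p, CREATE), (q, ANNIHILATE)]))
                terms.append(FermionTerm(-np.conj(c), [(q, CREATE), (p, ANNIHILATE)]))
    gen = jordan_wigner(terms, n_modes)
    return scipy.linalg.expm(angle * pauli_sum_to_matrix(gen))
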