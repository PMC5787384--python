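"""Model Hamiltonians.

The physical centerpiece is the single-exciton transfer Hamiltonian of a
chlorophyll dimer from a light-harvesting complex: two localized excitons
with on-site energy α coupled by a transition-dipole interaction β, compactly
mapped to one qubit as H = (α−ℓ)·I + β·σx after subtracting a reference
energy ℓ.  Toy fermionic models (user-supplied one-/two-body coefficients,
Jordan–Wigner mapped) and seeded random Pauli sums stand in for molecular
electronic-structure systems at desk scale; no molecular integrals are
computed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pauli import (CREATE, ANNIHILATE, FermionTerm, PauliSum, PauliTerm,
                    DEFAULT_QUBIT_CAP, jordan_wigner)
from .state import StateVector, basis_state

#: exciton energy of a single chlorophyll unit (eV)
CHLOROPHYLL_ALPHA = 1.46
#: inter-unit transition-dipole coupling (eV)
CHLOROPHYLL_BETA = 0.037
#: reference-energy shift used in the dimer demonstration (eV)
CHLOROPHYLL_ELL = 1.24


@dataclass(frozen=True)
class ExcitonDimerParams:
    """Parameters of the two-unit exciton transfer Hamiltonian (all in eV)."""

    alpha: float = CHLOROPHYLL_ALPHA
    beta: float = CHLOROPHYLL_BETA
    ell: float = CHLOROPHYLL_ELL

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "ell"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def build_exciton_hamiltonian(p: ExcitonDimerParams) -> PauliSum:
    """(α−ℓ)·I + β·σx on one qubit; ℓ is kept as the energy offset metadata.

    Eigenstates are |∓⟩ = (|0⟩∓|1⟩)/√2 with shifted eigenvalues α−ℓ∓β, so
    the ground state is |−⟩ and the gap is 2β, independent of ℓ.
    """
    return PauliSum(1, [PauliTerm(p.alpha - p.ell, "I"), PauliTerm(p.beta, "X")],
                    energy_offset=p.ell)


@dataclass
class FermionicModelSpec:
    """A toy interacting-fermion model given directly by its coefficients.

    ``one_body`` is the Hermitian matrix h_ij of Σ h_ij a_i†a_j; ``two_body``
    lists (i, j, k, l, t) contributions assembled as (t·a_i†a_j†a_k a_l + h.c.)/2,
    i.e. each listed coefficient is completed with its Hermitian-conjugate
    partner.  ``reference`` is the occupation bit pattern of the
    mean-field-like reference determinant |Φ⟩ (mode 0 leftmost).
    """

    n_modes: int
    one_body: np.ndarray
    two_body: list[tuple[int, int, int, int, complex]] = field(default_factory=list)
    reference: str = ""

    def __post_init__(self) -> None:
        self.one_body = np.asarray(self.one_body, dtype=complex)
        if self.one_body.shape != (self.n_modes, self.n_modes):
            raise ValueError("one_body must be n_modes x n_modes")
        if np.max(np.abs(self.one_body - self.one_body.conj().T)) > 1e-10:
            raise ValueError("one_body matrix must be Hermitian")
        if not self.reference:
            self.reference = "0" * self.n_modes
        if len(self.reference) != self.n_modes or not set(self.reference) <= {"0", "1"}:
            raise ValueError("reference must be a bit string of length n_modes")
        for i, j, k, l, _ in self.two_body:
            if not all(0 <= m < self.n_modes for m in (i, j, k, l)):
                raise ValueError("two_body mode index out of range")

    @property
    def reference_state(self) -> StateVector:
        return basis_state(self.reference)

    @classmethod
    def from_json(cls, path) -> "FermionicModelSpec":
        """Load from JSON with keys n_modes, one_body (re/im pairs), two_body, reference."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = json.load(fh)
        n = int(raw["n_modes"])
        ob = np.array([[complex(re, im) for re, im in row] for row in raw["one_body"]])
        tb = [(int(i), int(j), int(k), int(l), complex(re, im))
              for i, j, k, l, re, im in raw.get("two_body", [])]
        return cls(n, ob, tb, raw.get("reference", ""))

    def to_json(self, path) -> None:
        payload = {
            "n_modes": self.n_modes,
            "one_body": [[[float(z.real), float(z.imag)] for z in row]
                         for row in self.one_body],
            "two_body": [[i, j, k, l, float(t.real), float(t.imag)]
                         for i, j, k, l, t in self.two_body],
            "reference": self.reference,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def fermionic_terms(spec: FermionicModelSpec) -> list[FermionTerm]:
    """Second-quantized terms of the model, Hermitian by construction."""
    terms: list[FermionTerm] = []
    for i in range(spec.n_modes):
        for j in range(spec.n_modes):
            c = spec.one_body[i, j]
            if abs(c) > 0:
                terms.append(FermionTerm(c, [(i, CREATE), (j, ANNIHILATE)]))
    for i, j, k, l, t in spec.two_body:
        base = FermionTerm(0.5 * t, [(i, CREATE), (j, CREATE), (k, ANNIHILATE), (l, ANNIHILATE)])
        terms.append(base)
        terms.append(base.dagger())
    return terms


def build_fermionic_hamiltonian(spec: FermionicModelSpec) -> PauliSum:
    """Jordan–Wigner-mapped Hermitian qubit Hamiltonian of the model.

    Conserves total particle number ([H, N̂] = 0 in matrix form) because every
    term is a balanced ladder product.
    """
    return jordan_wigner(fermionic_terms(spec), spec.n_modes)


def number_operator(n_modes: int) -> PauliSum:
    """Total number operator N̂ = Σ a_i†a_i as a Pauli sum."""
    return jordan_wigner(
        [FermionTerm(1.0, [(i, CREATE), (i, ANNIHILATE)]) for i in range(n_modes)],
        n_modes)


_WORD_CHARS = np.array(list("IXYZ"))


def random_hamiltonian(n_qubits: int, term_density: float = 1.0, seed: int = 0,
                       cap: int = DEFAULT_QUBIT_CAP) -> PauliSum:
    """Seeded random Hermitian Pauli sum, a desk-scale stand-in fixture.

    Every Pauli word over ``n_qubits`` (the identity included) is kept with
    probability ``term_density`` and given an independent standard-normal real
    coefficient.  Deterministic for a given seed.
    """
    if n_qubits > cap:
        raise ValueError(f"n_qubits {n_qubits} above cap {cap}")
    if not 0.0 <= term_density <= 1.0:
        raise ValueError("term_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    terms = []
    for idx in range(4**n_qubits):
        keep = rng.random() < term_density
        coeff = rng.standard_normal()
        if not keep:
            continue
        digits = [(idx // 4**k) % 4 for k in range(n_qubits - 1, -1, -1)]
        terms.append(PauliTerm(coeff, "".join(_WORD_CHARS[d] for d in digits)))
    return PauliSum(n_qubits, terms)
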