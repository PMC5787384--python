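"""Pauli-sum operators, Jordan–Wigner mapping, and an exact diagonalization oracle.

A Hamiltonian (or an anti-Hermitian ansatz generator) is a weighted sum of
Pauli words over n qubits.  Words use the characters I, X, Y, Z with qubit 0
leftmost / most significant; coefficients are complex, real for Hermitian
operators.  Coefficients carry units of eV for Hamiltonians and are
dimensionless for generators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .state import StateVector

#: coefficients with magnitude below this are dropped when merging terms
MERGE_TOL = 1e-12

#: default hard cap on dense-matrix expansion (2**12 x 2**12)
DEFAULT_QUBIT_CAP = 12

_SINGLE = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}

# single-qubit Pauli products: (left, right) -> (phase, result)
_PRODUCT = {
    ("I", "I"): (1, "I"), ("I", "X"): (1, "X"), ("I", "Y"): (1, "Y"), ("I", "Z"): (1, "Z"),
    ("X", "I"): (1, "X"), ("X", "X"): (1, "I"), ("X", "Y"): (1j, "Z"), ("X", "Z"): (-1j, "Y"),
    ("Y", "I"): (1, "Y"), ("Y", "X"): (-1j, "Z"), ("Y", "Y"): (1, "I"), ("Y", "Z"): (1j, "X"),
    ("Z", "I"): (1, "Z"), ("Z", "X"): (1j, "Y"), ("Z", "Y"): (-1j, "X"), ("Z", "Z"): (1, "I"),
}


@dataclass(frozen=True)
class PauliTerm:
    """One weighted Pauli word, e.g. ``0.037 * XI``."""

    coefficient: complex
    word: str

    def __post_init__(self) -> None:
        if not self.word or not set(self.word) <= {"I", "X", "Y", "Z"}:
            raise ValueError(f"invalid Pauli word {self.word!r}")


class PauliSum:
    """A weighted sum of Pauli words over a fixed number of qubits.

    Terms with equal words are merged by coefficient addition and
    near-zero coefficients dropped, so equality of term dictionaries is a
    canonical operator equality.  ``energy_offset`` carries the reference
    energy shift ℓ (in eV) subtracted from a Hamiltonian at construction
    time, so absolute energies are recoverable as reported + ℓ; it does not
    participate in the algebra.
    """

    def __init__(self, n_qubits: int, terms: Iterable[PauliTerm] = (),
                 energy_offset: float = 0.0):
        if n_qubits < 1:
            raise ValueError("n_qubits must be positive")
        self.n_qubits = int(n_qubits)
        self.energy_offset = float(energy_offset)
        merged: dict[str, complex] = {}
        for term in terms:
            if len(term.word) != self.n_qubits:
                raise ValueError(
                    f"word {term.word!r} has length {len(term.word)}, expected {self.n_qubits}")
            merged[term.word] = merged.get(term.word, 0.0) + complex(term.coefficient)
        self._coeffs = {w: c for w, c in merged.items() if abs(c) > MERGE_TOL}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_dict(cls, n_qubits: int, coeffs: dict[str, complex], **kw) -> "PauliSum":
        return cls(n_qubits, [PauliTerm(c, w) for w, c in coeffs.items()], **kw)

    @classmethod
    def identity(cls, n_qubits: int, coefficient: complex = 1.0) -> "PauliSum":
        return cls.from_dict(n_qubits, {"I" * n_qubits: coefficient})

    # -- views ----------------------------------------------------------------

    @property
    def terms(self) -> list[PauliTerm]:
        """Terms in deterministic (word-sorted) order."""
        return [PauliTerm(self._coeffs[w], w) for w in sorted(self._coeffs)]

    @property
    def coeffs(self) -> dict[str, complex]:
        return dict(self._coeffs)

    @property
    def one_norm(self) -> float:
        """Σ|c_w|, an upper bound on the spectral norm ‖H‖."""
        return float(sum(abs(c) for c in self._coeffs.values()))

    @property
    def is_hermitian(self) -> bool:
        return all(abs(c.imag) <= MERGE_TOL for c in self._coeffs.values())

    def __len__(self) -> int:
        return len(self._coeffs)

    def __repr__(self) -> str:
        inner = " + ".join(f"({c:.6g})*{w}" for w, c in sorted(self._coeffs.items()))
        return f"PauliSum({self.n_qubits}q: {inner or '0'})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, PauliSum):
            return NotImplemented
        return (self.n_qubits == other.n_qubits
                and self._coeffs.keys() == other._coeffs.keys()
                and all(abs(self._coeffs[w] - other._coeffs[w]) <= 1e-10
                        for w in self._coeffs))

    # -- algebra ---------------------------------------------------------------

    def __add__(self, other: "PauliSum") -> "PauliSum":
        if self.n_qubits != other.n_qubits:
            raise ValueError("qubit-count mismatch in PauliSum addition")
        return PauliSum(self.n_qubits, self.terms + other.terms,
                        energy_offset=self.energy_offset)

    def __sub__(self, other: "PauliSum") -> "PauliSum":
        return self + (-1.0) * other

    def __rmul__(self, scalar: complex) -> "PauliSum":
        return PauliSum(self.n_qubits,
                        [PauliTerm(scalar * t.coefficient, t.word) for t in self.terms],
                        energy_offset=self.energy_offset)

    __mul__ = __rmul__

    def __matmul__(self, other: "PauliSum") -> "PauliSum":
        """Operator product, expanded word-by-word with Pauli phase algebra."""
        if self.n_qubits != other.n_qubits:
            raise ValueError("qubit-count mismatch in PauliSum product")
        out: list[PauliTerm] = []
        for wa, ca in self._coeffs.items():
            for wb, cb in other._coeffs.items():
                phase = complex(1.0)
                chars = []
                for a, b in zip(wa, wb):
                    p, r = _PRODUCT[(a, b)]
                    phase *= p
                    chars.append(r)
                out.append(PauliTerm(ca * cb * phase, "".join(chars)))
        return PauliSum(self.n_qubits, out)

    def dagger(self) -> "PauliSum":
        return PauliSum(self.n_qubits,
                        [PauliTerm(np.conj(t.coefficient), t.word) for t in self.terms],
                        energy_offset=self.energy_offset)


def pauli_sum_to_matrix(h: PauliSum, cap: int = DEFAULT_QUBIT_CAP) -> np.ndarray:
    """Dense 2^n × 2^n matrix of a Pauli sum (qubit 0 = leftmost Kronecker factor)."""
    if h.n_qubits > cap:
        raise ValueError(f"refusing dense expansion of {h.n_qubits} qubits (cap {cap})")
    dim = 2**h.n_qubits
    out = np.zeros((dim, dim), dtype=complex)
    for term in h.terms:
        m = np.eye(1, dtype=complex)
        for ch in term.word:
            m = np.kron(m, _SINGLE[ch])
        out += term.coefficient * m
    return out


# -- fermions ------------------------------------------------------------------

#: ladder-operator kinds
CREATE, ANNIHILATE = "+", "-"


@dataclass(frozen=True)
class FermionTerm:
    """A weighted product of fermionic ladder operators, applied right-to-left.

    ``ladder`` is an ordered sequence of ``(mode, kind)`` with kind ``"+"``
    (creation) or ``"-"`` (annihilation); ``FermionTerm(1.0, [(0,'+'),(1,'-')])``
    is a₀†a₁.
    """

    coefficient: complex
    ladder: tuple[tuple[int, str], ...]

    def __init__(self, coefficient: complex, ladder: Sequence[tuple[int, str]]):
        object.__setattr__(self, "coefficient", complex(coefficient))
        object.__setattr__(self, "ladder", tuple((int(m), str(k)) for m, k in ladder))
        for mode, kind in self.ladder:
            if kind not in (CREATE, ANNIHILATE):
                raise ValueError(f"ladder kind must be '+' or '-', got {kind!r}")
            if mode < 0:
                raise ValueError("negative mode index")

    def dagger(self) -> "FermionTerm":
        flipped = [(m, CREATE if k == ANNIHILATE else ANNIHILATE)
                   for m, k in reversed(self.ladder)]
        return FermionTerm(np.conj(self.coefficient), flipped)


def jordan_wigner(op: Iterable[FermionTerm], n_modes: int) -> PauliSum:
    """Map fermionic ladder products to a Pauli sum on ``n_modes`` qubits.

    Uses a_j → (∏_{k<j} Z_k)(X_j + iY_j)/2 with mode j carried by qubit j
    (|0⟩ empty, |1⟩ occupied), which preserves the canonical anticommutation
    relations in matrix form.
    """
    total = PauliSum(n_modes)
    for term in op:
        for mode, _ in term.ladder:
            if mode >= n_modes:
                raise ValueError(f"mode index {mode} out of range for {n_modes} modes")
        acc = PauliSum.identity(n_modes, term.coefficient)
        # product applies right-to-left; build via left-multiplication in order
        for mode, kind in term.ladder:
            x_word = "Z" * mode + "X" + "I" * (n_modes - mode - 1)
            y_word = "Z" * mode + "Y" + "I" * (n_modes - mode - 1)
            sign = -0.5j if kind == CREATE else 0.5j
            ladder_ps = PauliSum(n_modes, [PauliTerm(0.5, x_word), PauliTerm(sign, y_word)])
            acc = acc @ ladder_ps
        total = total + acc
    return total


# -- exact diagonalization oracle ---------------------------------------------

@dataclass
class EigenSystem:
    """Full spectrum of a Hermitian Pauli sum, used as test/fidelity oracle.

    ``groups`` partitions eigen-indices into degenerate clusters (eigenvalues
    equal within the requested tolerance) so fidelities can be computed
    against subspace projectors.
    """

    eigenvalues: np.ndarray
    eigenvectors: list[StateVector]
    groups: list[list[int]]

    def group_of(self, index: int) -> list[int]:
        for g in self.groups:
            if index in g:
                return g
        raise IndexError(index)

    def subspace(self, index: int) -> list[StateVector]:
        """Orthonormal basis of the degenerate subspace containing ``index``."""
        return [self.eigenvectors[i] for i in self.group_of(index)]


def exact_eigensystem(h: PauliSum, degeneracy_tol: float = 1e-9,
                      cap: int = DEFAULT_QUBIT_CAP) -> EigenSystem:
    """Brute-force eigendecomposition of a Hermitian Pauli sum.

    Eigenvalues ascend; eigenvalues equal within ``degeneracy_tol`` (eV)
    share a degeneracy group.
    """
    if not h.is_hermitian:
        raise ValueError("exact_eigensystem requires a Hermitian PauliSum")
    mat = pauli_sum_to_matrix(h, cap=cap)
    vals, vecs = np.linalg.eigh(mat)
    groups: list[list[int]] = []
    for i, v in enumerate(vals):
        if groups and v - vals[groups[-1][0]] <= degeneracy_tol:
            groups[-1].append(i)
        else:
            groups.append([i])
    states = [StateVector(vecs[:, i], h.n_qubits) for i in range(len(vals))]
    return EigenSystem(vals, states, groups)


# -- text format ----------------------------------------------------------------

def parse_pauli_text(text: str) -> PauliSum:
    """Parse the one-term-per-line format ``<real> [<imag>] <word>``.

    ``#`` starts a comment; blank lines are ignored.  Round-trips with
    :func:`format_pauli_text` bit-exactly at 17 significant digits.
    """
    terms: list[PauliTerm] = []
    n_qubits = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) == 2:
            coeff_parts, word = parts[:1], parts[1]
        elif len(parts) == 3:
            coeff_parts, word = parts[:2], parts[2]
        else:
            raise ValueError(f"line {lineno}: expected '<real> [<imag>] <word>', got {raw!r}")
        try:
            coeff = complex(float(coeff_parts[0]),
                            float(coeff_parts[1]) if len(coeff_parts) == 2 else 0.0)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric coefficient in {raw!r}") from exc
        if not set(word) <= {"I", "X", "Y", "Z"}:
            raise ValueError(f"line {lineno}: invalid Pauli word {word!r}")
        if n_qubits is None:
            n_qubits = len(word)
        elif len(word) != n_qubits:
            raise ValueError(f"line {lineno}: word length {len(word)} != {n_qubits}")
        terms.append(PauliTerm(coeff, word))
    if n_qubits is None:
        raise ValueError("no Pauli terms found")
    return PauliSum(n_qubits, terms)


def format_pauli_text(h: PauliSum) -> str:
    lines = []
    for term in h.terms:
        c = complex(term.coefficient)
        if c.imag == 0.0:
            lines.append(f"{c.real:.17g} {term.word}")
        else:
            lines.append(f"{c.real:.17g} {c.imag:.17g} {term.word}")
    return "\n".join(lines) + "\n"


def load_pauli_file(path) -> PauliSum:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_pauli_text(fh.read())


def save_pauli_file(h: PauliSum, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(format_pauli_text(h))
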