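import math

import numpy as np
import pytest

from qwaves import (ExcitonDimerParams, build_exciton_hamiltonian,
                    exact_eigensystem, single_qubit_ansatz)


@pytest.fixture(scope="session")
def exciton():
    """The chlorophyll-dimer Hamiltonian with the shifted reference energy."""
    return build_exciton_hamiltonian(ExcitonDimerParams(1.46, 0.037, 1.24))


@pytest.fixture(scope="session")
def exciton_eigensystem(exciton):
    return exact_eigensystem(exciton)


@pytest.fixture(scope="session")
def exciton_branch():
    # 2π/t-wide energy branch centered on the mean-field reference α−ℓ
    return (0.22 - math.pi / 26.0, 0.22 + math.pi / 26.0)


@pytest.fixture()
def qubit_ansatz():
    return single_qubit_ansatz()


# ---- independent occupation-number-basis oracle for fermionic operators ----

def annihilation_matrix(mode: int, n_modes: int) -> np.ndarray:
    """a_mode in the occupation basis with the Jordan–Wigner sign convention.

    Basis index has mode 0 as the most significant bit; a_j carries the
    parity factor (−1)^{Σ_{k<j} n_k}.
    """
    dim = 2**n_modes
    mat = np.zeros((dim, dim), dtype=complex)
    for idx in range(dim):
        occ = [(idx >> (n_modes - 1 - k)) & 1 for k in range(n_modes)]
        if occ[mode] == 1:
            sign = (-1) ** sum(occ[:mode])
            target = idx & ~(1 << (n_modes - 1 - mode))
            mat[target, idx] = sign
    return mat


def ladder_matrix(ladder, n_modes: int) -> np.ndarray:
    """Matrix of an ordered ladder product, applied right-to-left."""
    out = np.eye(2**n_modes, dtype=complex)
    for mode, kind in ladder:
        a = annihilation_matrix(mode, n_modes)
        out = out @ (a.conj().T if kind == "+" else a)
    return out
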