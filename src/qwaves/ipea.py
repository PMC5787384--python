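"""Iterative phase estimation (IPEA) with eigenstate projection.

Kitaev-style bitwise readout of the eigenphase of U = e^{−iHt}: bits are
extracted least-significant first using controlled-U^{2^{k−1}} with a phase
feedback rotation conditioned on the already-measured lower bits, and
reported most-significant first.  An eigenstate |λ⟩ carries the phase
ϕ = (−λt) mod 2π.  The target register is a single quantum trajectory: every
control measurement collapses it, so an imperfect variational input is
progressively projected onto the nearest eigenstate while its eigenphase is
read out — the refinement stage that follows the variational search.

U^{2^{k−1}} is computed by direct exponentiation exp(−iH·t·2^{k−1}) (one
eigendecomposition, rescaled phases), never by cascading multiplications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pauli import PauliSum, pauli_sum_to_matrix
from .state import StateVector, as_amplitudes
from .witness import map_to_branch

#: relative double-precision phase error tolerated at the deepest bit
_PHASE_SAFETY = 0.01


@dataclass
class IPEAResult:
    """Bitwise eigenphase readout.

    ``bits`` is most-significant first, so ``phase = 2π·0.b₁b₂…``;
    ``energy`` includes the reference-shift re-offset ℓ.  ``per_bit_counts``
    records (shots, majority count) in readout order (least-significant bit
    first); ``post_state`` is the collapsed target register after the final
    measurement.
    """

    bits: str
    phase: float
    energy: float
    per_bit_counts: list[tuple[int, int]]
    post_state: StateVector

    @property
    def n_bits(self) -> int:
        return len(self.bits)


def phase_to_energy(phase: float, t: float, ell: float = 0.0,
                    branch_hint: tuple[float, float] | None = None) -> float:
    """Invert ϕ = (−λ't) mod 2π to λ' on the chosen branch, then add ℓ.

    The branch is a 2π/t-wide energy interval (default [0, 2π/t)); a
    ``branch_hint`` narrower than 2π/t that contains no candidate raises.
    """
    if not 0.0 <= phase < 2.0 * math.pi + 1e-12:
        raise ValueError("phase must lie in [0, 2*pi)")
    width = 2.0 * math.pi / t
    lam = ((-phase) % (2.0 * math.pi)) / t
    return map_to_branch(lam, width, branch_hint or (0.0, width)) + ell


def run_ipea(prepare, h: PauliSum, t: float, n_bits: int,
             shots_per_bit: int = 1, seed: int = 0, ell: float | None = None,
             branch_hint: tuple[float, float] | None = None) -> IPEAResult:
    """Run the IPEA on a variationally prepared state.

    ``prepare`` is a zero-argument state factory or a StateVector.
    ``shots_per_bit = 0`` selects the deterministic noiseless mode: each bit
    is thresholded on its exact probability (ties break toward 0) and the
    register collapses onto the majority branch.  With sampling, shots must
    be odd so per-bit majority voting cannot tie; the target register evolves
    as one trajectory across all shots and bits, and the returned post-state
    is the register after the final shot of the last (most significant) bit.

    ``ell = None`` uses the Hamiltonian's stored energy offset.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    if t <= 0:
        raise ValueError("evolution time must be positive")
    if shots_per_bit < 0 or (shots_per_bit > 0 and shots_per_bit % 2 == 0):
        raise ValueError("shots_per_bit must be 0 (noiseless) or odd")
    if 2.0**n_bits * h.one_norm * t * np.finfo(float).eps > _PHASE_SAFETY:
        raise ValueError(
            f"{n_bits} bits exceed double-precision phase accuracy for this H and t")
    if ell is None:
        ell = h.energy_offset

    psi = as_amplitudes(prepare() if callable(prepare) else prepare).copy()
    mat = pauli_sum_to_matrix(h)
    evals, evecs = np.linalg.eigh(mat)
    psi_eig = evecs.conj().T @ psi  # work in the eigenbasis: U^m is diagonal

    rng = np.random.default_rng(seed)
    bits = [0] * (n_bits + 1)  # bits[k] = b_k, 1-indexed, MSB = b_1
    per_bit_counts: list[tuple[int, int]] = []
    for k in range(n_bits, 0, -1):
        # accumulated feedback −2π·(0.0 b_{k+1} … b_m)
        feedback = -2.0 * math.pi * sum(
            bits[j] * 2.0 ** (k - j - 1) for j in range(k + 1, n_bits + 1))
        phases = np.exp(1j * (-(evals * t * 2.0 ** (k - 1)) + feedback))
        branch0 = 0.5 * (psi_eig + phases * psi_eig)  # control measured 0
        branch1 = 0.5 * (psi_eig - phases * psi_eig)  # control measured 1
        if shots_per_bit == 0:
            p1 = float(np.vdot(branch1, branch1).real)
            outcome = 1 if p1 > 0.5 else 0
            chosen = branch1 if outcome else branch0
            psi_eig = chosen / np.linalg.norm(chosen)
            per_bit_counts.append((0, 0))
            bits[k] = outcome
        else:
            ones = 0
            for _ in range(shots_per_bit):
                phases_now = np.exp(1j * (-(evals * t * 2.0 ** (k - 1)) + feedback))
                b0 = 0.5 * (psi_eig + phases_now * psi_eig)
                b1 = 0.5 * (psi_eig - phases_now * psi_eig)
                p1 = float(np.vdot(b1, b1).real)
                outcome = int(rng.random() < p1)
                chosen = b1 if outcome else b0
                psi_eig = chosen / np.linalg.norm(chosen)
                ones += outcome
            bits[k] = int(ones > shots_per_bit / 2)
            per_bit_counts.append((shots_per_bit, max(ones, shots_per_bit - ones)))

    bitstring = "".join(str(bits[k]) for k in range(1, n_bits + 1))
    phase = 2.0 * math.pi * sum(bits[k] * 2.0 ** (-k) for k in range(1, n_bits + 1))
    energy = phase_to_energy(phase, t, ell=ell, branch_hint=branch_hint)
    post = StateVector(evecs @ psi_eig, h.n_qubits)
    return IPEAResult(bits=bitstring, phase=phase, energy=energy,
                      per_bit_counts=per_bit_counts, post_state=post)


def rounded_phase_bits(phase: float, n_bits: int) -> str:
    """The n-bit rounded binary-fraction expansion of ϕ/2π (mod 1), MSB first."""
    frac = (phase / (2.0 * math.pi)) % 1.0
    code = round(frac * 2.0**n_bits) % 2**n_bits
    return format(code, f"0{n_bits}b")


def ipea_energy_resolution(t: float, n_bits: int) -> float:
    """Worst-case energy quantization (branch width)/2^bits = 2π/(t·2^bits), eV."""
    return 2.0 * math.pi / (t * 2.0**n_bits)
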