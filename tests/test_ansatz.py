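import math

import numpy as np
import pytest

from qwaves import (AnsatzSpec, ExcitationOp, FermionicModelSpec, StateVector,
                    apply_ansatz, basis_state, excitation_unitary,
                    exciton_perturbation, fidelity, natural_excitation_unitary,
                    natural_orbital_excitations, number_operator,
                    one_particle_rdm, pauli_sum_to_matrix, ph_generators,
                    pauli_word_generators, single_qubit_ansatz,
                    single_qubit_ansatz_state, ucc_singles_generators,
                    ucc_double_generator)


def random_state(n_qubits, seed):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(2**n_qubits) + 1j * rng.standard_normal(2**n_qubits)
    return StateVector(v / np.linalg.norm(v), n_qubits)


class TestSingleQubitAnsatz:
    def test_identity_angles(self):
        assert np.allclose(single_qubit_ansatz_state(0, 0, 0).amplitudes, [1, 0])

    def test_plus_minus_preparation(self):
        minus = single_qubit_ansatz_state(0, 0, math.pi / 2)
        plus = single_qubit_ansatz_state(0, 0, -math.pi / 2)
        assert np.allclose(minus.amplitudes, [1 / math.sqrt(2), -1 / math.sqrt(2)])
        assert np.allclose(plus.amplitudes, [1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_global_phase_retained(self):
        st = single_qubit_ansatz_state(0.7, 0, 0)
        assert st.amplitudes[0] == pytest.approx(np.exp(0.7j))

    def test_default_ranges_pin_global_phase(self, qubit_ansatz):
        assert qubit_ansatz.parameter_count == 3
        assert qubit_ansatz.parameter_ranges[0] == (0.0, 0.0)
        assert qubit_ansatz.periodic == [False, True, False]


class TestApplyAnsatz:
    def test_zero_theta_returns_reference(self):
        spec = AnsatzSpec("generator", basis_state("10"),
                          ucc_singles_generators(2))
        out = apply_ansatz(spec, [0.0])
        assert np.allclose(out.amplitudes, basis_state("10").amplitudes)

    @pytest.mark.parametrize("seed", range(3))
    def test_output_normalized_for_random_theta(self, seed):
        spec = AnsatzSpec("generator", basis_state("00"), pauli_word_generators(2))
        rng = np.random.default_rng(seed)
        out = apply_ansatz(spec, rng.uniform(-math.pi, math.pi, spec.parameter_count))
        assert np.linalg.norm(out.amplitudes) == pytest.approx(1.0, abs=1e-10)

    def test_rejects_hermitian_generators(self):
        from qwaves import PauliSum
        with pytest.raises(ValueError, match="anti-Hermitian"):
            AnsatzSpec("generator", basis_state("0"),
                       [PauliSum.from_dict(1, {"X": 1.0})])

    def test_parameter_count_mismatch(self, qubit_ansatz):
        with pytest.raises(ValueError, match="parameters"):
            apply_ansatz(qubit_ansatz, [0.1, 0.2])

    def test_number_conservation_of_ph_ansatz(self):
        spec_f = FermionicModelSpec(3, [[-1.0, -0.4, 0.0],
                                        [-0.4, 0.2, -0.3],
                                        [0.0, -0.3, 0.8]], reference="100")
        gens = ph_generators(spec_f)
        nmat = pauli_sum_to_matrix(number_operator(3))
        for g in gens:
            gm = pauli_sum_to_matrix(g)
            assert np.linalg.norm(gm @ nmat - nmat @ gm) < 1e-10
        spec = AnsatzSpec("generator", spec_f.reference_state, gens)
        rng = np.random.default_rng(0)
        out = apply_ansatz(spec, rng.uniform(-1, 1, spec.parameter_count))
        n_expect = np.vdot(out.amplitudes, nmat @ out.amplitudes).real
        assert n_expect == pytest.approx(1.0, abs=1e-10)

    def test_ucc_doubles_generator_antihermitian_and_number_conserving(self):
        g = ucc_double_generator(0, 1, 2, 3, 4)
        gm = pauli_sum_to_matrix(g)
        nmat = pauli_sum_to_matrix(number_operator(4))
        assert np.linalg.norm(gm + gm.conj().T) < 1e-10
        assert np.linalg.norm(gm @ nmat - nmat @ gm) < 1e-10


class TestExcitationUnitary:
    def test_zero_angle_is_identity(self):
        u = excitation_unitary(ExcitationOp(0, 1, 0.0), 2)
        assert np.allclose(u, np.eye(4))

    def test_transfers_occupation(self):
        u = excitation_unitary(ExcitationOp(occupied=0, virtual=1), 2)
        out = u @ basis_state("10").amplitudes
        assert abs(np.vdot(basis_state("01").amplitudes, out)) ** 2 == \
            pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("theta", [0.3, math.pi / 2, 1.9])
    def test_unitary_and_number_conserving(self, theta):
        u = excitation_unitary(ExcitationOp(1, 2, theta), 3)
        assert np.linalg.norm(u.conj().T @ u - np.eye(8)) < 1e-10
        nmat = pauli_sum_to_matrix(number_operator(3))
        assert np.linalg.norm(u @ nmat - nmat @ u) < 1e-10

    def test_exciton_perturbation_maps_minus_to_plus(self):
        minus = np.array([1, -1]) / math.sqrt(2)
        plus = np.array([1, 1]) / math.sqrt(2)
        out = exciton_perturbation() @ minus
        # e^{iπσz/2}|−⟩ = i|+⟩
        assert np.allclose(out, 1j * plus)
        assert abs(np.vdot(plus, out)) ** 2 == pytest.approx(1.0)

    def test_same_index_rejected(self):
        with pytest.raises(ValueError):
            ExcitationOp(1, 1)


class TestNaturalOrbitals:
    def test_product_reference(self):
        d, excs, vecs = natural_orbital_excitations(basis_state("10"), 2)
        assert np.allclose(d, np.diag([1.0, 0.0]))
        assert excs[0].transfer == pytest.approx(1.0)
        # natural orbitals coincide with the original modes
        assert np.allclose(np.abs(vecs), np.eye(2))

    @pytest.mark.parametrize("seed", range(3))
    def test_trace_equals_expected_particle_number(self, seed):
        psi = random_state(3, seed)
        d = one_particle_rdm(psi, 3)
        nmat = pauli_sum_to_matrix(number_operator(3))
        n_expect = np.vdot(psi.amplitudes, nmat @ psi.amplitudes).real
        assert np.trace(d).real == pytest.approx(n_expect, abs=1e-10)

    def test_two_mode_superposition_rdm(self):
        # a|10⟩ + b|01⟩: diagonal entries are the mode occupations |a|², |b|²,
        # the coherence D01 = a·b̄ is maximal, and the natural-orbital
        # occupations are exactly {1, 0} — the state is one Slater
        # determinant in a rotated orbital basis
        a, b = math.sqrt(0.7), math.sqrt(0.3)
        v = a * basis_state("10").amplitudes + b * basis_state("01").amplitudes
        d, _, _ = natural_orbital_excitations(StateVector(v, 2), 2)
        assert np.diag(d).real == pytest.approx([0.7, 0.3], abs=1e-10)
        assert d[0, 1] == pytest.approx(a * b, abs=1e-10)
        occ = sorted(np.linalg.eigvalsh(d).real)
        assert occ == pytest.approx([0.0, 1.0], abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_occupations_within_fermionic_bounds(self, seed):
        d = one_particle_rdm(random_state(3, seed + 10), 3)
        occ = np.linalg.eigvalsh(d).real
        assert occ.min() >= -1e-10 and occ.max() <= 1 + 1e-10

    def test_natural_excitation_matches_mode_excitation_for_product_state(self):
        _, excs, vecs = natural_orbital_excitations(basis_state("10"), 2)
        u_nat = natural_excitation_unitary(vecs, excs[0], 2)
        out = u_nat @ basis_state("10").amplitudes
        assert abs(np.vdot(basis_state("01").amplitudes, out)) ** 2 == \
            pytest.approx(1.0, abs=1e-10)
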