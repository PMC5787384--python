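import math

import numpy as np
import pytest

from qwaves import (HIGH_T, PauliSum, StateVector, TomographySettings,
                    apply_controlled_evolution, basis_state,
                    control_reduced_state, default_evolution_time,
                    exact_eigensystem, random_hamiltonian,
                    simulate_control_tomography, witness_quantities)


def random_state(n_qubits, seed):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(2**n_qubits) + 1j * rng.standard_normal(2**n_qubits)
    return StateVector(v / np.linalg.norm(v), n_qubits)


class TestControlledEvolution:
    def test_zero_hamiltonian_gives_plus_product(self):
        joint = apply_controlled_evolution(basis_state("0"), PauliSum(1), t=1.3)
        expect = np.array([1, 0, 1, 0]) / math.sqrt(2)
        assert np.allclose(joint.amplitudes, expect)

    def test_eigenstate_input_stays_product(self, exciton, exciton_eigensystem):
        lam = exciton_eigensystem.eigenvalues[0]
        v = exciton_eigensystem.eigenvectors[0]
        joint = apply_controlled_evolution(v, exciton, t=5.0)
        expect = np.concatenate([v.amplitudes,
                                 np.exp(-1j * lam * 5.0) * v.amplitudes]) / math.sqrt(2)
        assert np.allclose(joint.amplitudes, expect)

    def test_exciton_overlap_closed_form(self, exciton):
        # |⟨0|e^{−iHt}|0⟩| = |cos(βt)| for H = cI + βX
        joint = apply_controlled_evolution(basis_state("0"), exciton, t=26.0)
        rho = control_reduced_state(joint)
        assert abs(2 * rho.rho[1, 0]) == pytest.approx(abs(math.cos(0.037 * 26)), abs=1e-12)

    def test_dimension_mismatch(self, exciton):
        with pytest.raises(ValueError, match="qubits"):
            apply_controlled_evolution(basis_state("00"), exciton, t=1.0)


class TestReducedState:
    def test_eigenstate_gives_pure_control(self, exciton, exciton_eigensystem):
        joint = apply_controlled_evolution(exciton_eigensystem.eigenvectors[1],
                                           exciton, t=26.0)
        rho = control_reduced_state(joint).rho
        assert np.linalg.norm(rho @ rho - rho) < 1e-10

    def test_plus_product_reduces_to_plus_projector(self):
        psi = random_state(2, 3)
        joint = StateVector(np.concatenate([psi.amplitudes, psi.amplitudes])
                            / math.sqrt(2), 3)
        rho = control_reduced_state(joint).rho
        assert np.allclose(rho, np.full((2, 2), 0.5))

    def test_pi_phase_superposition_is_maximally_mixed(self, exciton,
                                                       exciton_eigensystem):
        # equal superposition of the two eigenstates with (λ1−λ0)·t = π
        es = exciton_eigensystem
        t = math.pi / (es.eigenvalues[1] - es.eigenvalues[0])
        v = (es.eigenvectors[0].amplitudes + es.eigenvectors[1].amplitudes) / math.sqrt(2)
        joint = apply_controlled_evolution(StateVector(v, 1), exciton, t)
        assert np.allclose(control_reduced_state(joint).rho, np.eye(2) / 2, atol=1e-10)


class TestTomography:
    def test_zero_shots_is_exact(self, exciton):
        joint = apply_controlled_evolution(random_state(1, 1), exciton, 26.0)
        exact = control_reduced_state(joint)
        rho = simulate_control_tomography(joint, TomographySettings(0))
        assert np.allclose(rho.rho, exact.rho)

    def test_seeded_determinism(self, exciton):
        joint = apply_controlled_evolution(random_state(1, 2), exciton, 26.0)
        a = simulate_control_tomography(joint, TomographySettings(500, seed=9))
        b = simulate_control_tomography(joint, TomographySettings(500, seed=9))
        assert np.array_equal(a.rho, b.rho)

    def test_binomial_concentration(self, exciton):
        # |r̂_i − r_i| ≤ 4/√shots in at least 99% of seeded repetitions
        joint = apply_controlled_evolution(random_state(1, 4), exciton, 26.0)
        r = control_reduced_state(joint).bloch
        shots = 10_000
        hits = 0
        for seed in range(1000):
            rho = simulate_control_tomography(joint, TomographySettings(shots, seed))
            hits += np.all(np.abs(rho.bloch - r) <= 4.0 / math.sqrt(shots))
        assert hits >= 990

    def test_reconstruction_is_physical(self, exciton, exciton_eigensystem):
        # near-pure states: the clipped Bloch vector keeps eigenvalues in [0,1]
        joint = apply_controlled_evolution(exciton_eigensystem.eigenvectors[0],
                                           exciton, 26.0)
        for seed in range(50):
            rho = simulate_control_tomography(joint, TomographySettings(200, seed))
            evals = np.linalg.eigvalsh(rho.rho)
            assert evals.min() >= -1e-12 and evals.max() <= 1 + 1e-12


class TestWitnessQuantities:
    def test_eigenstate_witness_is_zero(self, exciton, exciton_eigensystem):
        joint = apply_controlled_evolution(exciton_eigensystem.eigenvectors[0],
                                           exciton, 26.0)
        rec = witness_quantities(control_reduced_state(joint), 26.0, 1.25)
        assert rec.purity == pytest.approx(1.0, abs=1e-10)
        assert rec.entropy == pytest.approx(0.0, abs=1e-10)

    def test_maximally_mixed_control(self):
        from qwaves import ControlReducedState
        rec = witness_quantities(ControlReducedState(np.eye(2) / 2), 1.0, HIGH_T)
        assert rec.purity == pytest.approx(0.5)
        assert rec.entropy == pytest.approx(math.log(2))
        assert rec.objective == pytest.approx(-0.5)
        assert not rec.energy_defined

    def test_exciton_ground_energy_and_objective(self, exciton, exciton_eigensystem,
                                                 exciton_branch):
        joint = apply_controlled_evolution(exciton_eigensystem.eigenvectors[0],
                                           exciton, 26.0)
        rec = witness_quantities(control_reduced_state(joint), 26.0, 1.25,
                                 exciton_branch)
        assert rec.energy == pytest.approx(0.183, abs=1e-9)
        assert rec.objective == pytest.approx(0.183 - 1.25, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_control_qubit_bounds(self, seed):
        # any pure joint state: 1/2 ≤ P ≤ 1 and 0 ≤ S ≤ ln 2
        h = random_hamiltonian(2, 0.8, seed=seed)
        if len(h) == 0:
            pytest.skip("empty draw")
        joint = apply_controlled_evolution(random_state(2, seed), h,
                                           default_evolution_time(h))
        rec = witness_quantities(control_reduced_state(joint), 1.0, HIGH_T)
        assert 0.5 - 1e-10 <= rec.purity <= 1 + 1e-10
        assert -1e-12 <= rec.entropy <= math.log(2) + 1e-10
        # linear entropy lower-bounds the von Neumann entropy for a qubit
        assert 1 - rec.purity <= rec.entropy + 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_eigenstate_energy_recovers_eigenvalue(self, seed):
        h = random_hamiltonian(2, 0.8, seed=seed + 50)
        if len(h) == 0:
            pytest.skip("empty draw")
        es = exact_eigensystem(h)
        t = default_evolution_time(h)
        lam = es.eigenvalues[1]
        joint = apply_controlled_evolution(es.eigenvectors[1], h, t)
        rec = witness_quantities(control_reduced_state(joint), t, 1.0,
                                 (-math.pi / t, math.pi / t))
        assert rec.energy == pytest.approx(lam, abs=1e-9)


class TestEvolutionTime:
    def test_exciton_default(self, exciton):
        assert default_evolution_time(exciton) == pytest.approx(math.pi / (2 * 0.257))

    def test_pauli_z(self):
        assert default_evolution_time(PauliSum.from_dict(1, {"Z": 1.0})) == \
            pytest.approx(math.pi / 2)

    def test_scaling_homogeneity(self, exciton):
        assert default_evolution_time(3.0 * exciton) == \
            pytest.approx(default_evolution_time(exciton) / 3.0)

    def test_zero_operator_rejected(self):
        with pytest.raises(ValueError):
            default_evolution_time(PauliSum(1))

    def test_long_time_warns(self, exciton):
        from qwaves.witness import check_evolution_time
        with pytest.warns(UserWarning, match="aliasing"):
            check_evolution_time(exciton, 26.0)
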