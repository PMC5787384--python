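# Methods

## Model and conventions

Operators are weighted Pauli sums over n qubits.  Qubit 0 is the leftmost
character of a Pauli word and the most significant bit of a basis index; all
dense expansions use this Kronecker order, with a configurable cap of 12
qubits.  Duplicate words merge by coefficient addition and coefficients below
1e−12 in magnitude are dropped, so term dictionaries are canonical.
Hamiltonian coefficients are in eV, evolution times in 1/eV (ħ = 1).

Fermionic operators enter through the Jordan–Wigner mapping
a_j → (∏_{k<j} Z_k)(X_j + iY_j)/2, mode j on qubit j, |0⟩ = empty.  The
mapping is verified in matrix form against an independent occupation-basis
construction of the ladder operators for every one- and two-body term on up
to four modes.  The Z-string convention (modes strictly below the ladder
index) is the standard one; any consistent choice gives isospectral
operators.

The exciton-transfer dimer is mapped compactly to one qubit,
Ĥ = (α−ℓ)Î + βσ̂x, with α = 1.46 eV (on-site exciton energy),
β = 0.037 eV (transition-dipole coupling) and a reference shift
ℓ = 1.24 eV carried as metadata so absolute energies are recoverable as
reported + ℓ.  Shifting by ℓ matters for the bitwise readout: the smaller
the magnitude of the eigenvalues, the more of the fixed-length binary
expansion is spent on signal.  No molecular integrals are computed anywhere;
many-fermion systems enter only as user-supplied one-/two-body coefficient
files (each listed two-body coefficient t contributes (t·a_i†a_j†a_k a_l +
h.c.)/2, so Hermiticity never depends on the user listing conjugate pairs).
Degenerate eigenvalues are grouped at a 1e−9 eV tolerance — far below the
smallest model gap used here (2β = 0.074 eV) — and fidelities against
degenerate levels use subspace projectors.

## Witness quantities

The control qubit's reduced state after the controlled evolution has
off-diagonal element ⟨Ψ|e^{−iĤt}|Ψ⟩/2.  The energy estimator takes the
argument of that coherence, E = −Arg(2ρ₁₀)/t, and is therefore defined only
modulo the branch width 2π/t; callers supply a branch interval and energies
are shifted into it by whole branch widths (default [0, 2π/t)).  The
objective uses the purity P = Tr[ρ_C²] rather than the von Neumann entropy
(computed and logged as a diagnostic, natural logarithm): the linear entropy
1 − P is the lowest-order surrogate of S and needs no eigendecomposition of
the reconstructed state.

The conservative default evolution time is t = π/(2‖Ĥ‖₁) with ‖·‖₁ the
coefficient one-norm, which keeps every eigenphase within half a branch.
The dimer reproduction honors t = 26 (1/eV) — chosen for its purity span —
even though it exceeds that window; the code warns rather than refuses.  At
t = 26 the excited eigenvalue wraps past 2π, so the packaged configuration
centers the branch on the known mean-field reference α − ℓ
(hint (α−ℓ) ± π/t); both shifted eigenvalues then resolve unaliased and the
objective orders them correctly.

Tomography is emulated per Pauli basis: the up-outcome count is
Binomial(shots, (1+r_i)/2) for each Bloch component, shots split equally
across σx, σy, σz; the reconstruction is the linear inversion clipped to the
unit Bloch ball (the simplest physical projection — no maximum-likelihood
step).  `shots_per_basis = 0` short-circuits to the exact partial trace.
One consequence of clipping matters downstream: near-pure states report
P̂ = 1 exactly with probability approaching one half, so purity readouts
saturate rather than scatter symmetrically.

## The variational search

The search must minimize a noisy objective whose landscape, on the dimer,
has two basins — one per eigenstate — whose depths differ by only
2β·(1 + T·∂P/∂E-mixing) ≈ 0.074 eV while each basin is ~0.5 eV deep.  The
budget of the reproduction (10 particles × 15 epochs, one objective readout
per particle per epoch) leaves no room for averaging; the optimizer is built
around three observations:

1. *Basins must be refined before they can be compared.*  The first 40% of
   the epoch budget is a bank of independent adaptive stochastic descents:
   each particle proposes a Gaussian step of its own scale and keeps the
   move only if the measured F_obj beats its cached value.  Scales follow a
   1/5-success rule (shrink ×0.7 on rejection, grow ×0.7⁻³ on acceptance,
   per-coordinate width-proportional, floored and capped); half the walkers
   carry a reduced cap so that a long lucky jump into a deeper foreign basin
   can never capture the whole population.  Ties accept the proposal —
   because clipped purity readouts saturate at P̂ = 1, a cached saturated
   value must not freeze a particle — and with probability 0.15 (doubled in
   the final third) a particle re-measures its position instead of moving,
   folding the readout into a running cache average so lucky noise-low
   caches wash out as 1/√k.
2. *The witness energy arbitrates basins far better than the objective.*
   One arbitration epoch measures every particle fresh; E and P come from
   the same readout.  Within a basin, E stays pinned near that basin's
   eigenvalue whatever the purity refinement, so clusters (greedy
   extraction around the best particles, 20% of each range width, periodic
   coordinates unwrapped) are compared by the energy of their most refined
   member: the margin is the eigenvalue gap against ~1 meV of phase noise,
   rather than the refinement-dependent F_obj gap.  Excited searches —
   whose purity-only objective is eigenstate-blind — instead keep the
   cluster nearest their initialization, which is what the perturbing
   unitary Ê_p was for.  Losing particles are scattered (not cloned) around
   winner members with invalidated caches; the polish step size is set from
   the winner's own measured purity, P = (E − F)/T, so an unrefined
   low-energy winner restarts with exploration-grade steps.  Subsequent
   descent is confined to a trust region (25% of each range width) sliding
   with the best particle, preventing re-capture by the losing basin.
3. *The answer is in all the data, not the final population.*  The reported
   parameters are the objective-weighted circular mean of the final
   population (softmax with temperature set by the spread of the better
   half of the caches, so stragglers are exponentially suppressed), refined
   by a locally weighted least-squares quadratic fit to every readout the
   run logged near the optimum.  The fitted stationary point is accepted
   only if the curvature is positive semidefinite (flat directions of
   overparameterized ansätze are projected out) and the step stays inside
   the trust region; the fit averages tens of readouts and locates the
   minimum well below the single-readout shot-noise floor.

All randomness flows from one integer seed through a single generator;
identical configurations reproduce bitwise-identical traces.  The
per-epoch trace records the population mean/std, the best and mean measured
objective, the analytic E and P of the mean state, and (when an exact
eigensystem is attached for diagnostics) the fidelity of the mean state
with the target eigen-subspace.

Parameterizations: the single-qubit chain A = e^{iφa}e^{iφbσz/2}e^{iφcσy/2}
is searched over the unique Bloch cover φb ∈ [−π, π] (periodic azimuth),
φc ∈ [0, π] (polar), with the unobservable global phase φa pinned at 0 —
wider ranges double-cover the sphere and make population means meaningless.
Generator ansätze exp(Σθ_i Â_i)|Φ⟩ take any anti-Hermitian Pauli-sum
generators; builders are provided for the Hamiltonian-deformation family
i(T + T†) over the model's own terms, unrestricted coupled-cluster singles
(a_i†a_j − a_j†a_i) and doubles, and complete Pauli-word bases i·P.  The
trailing evolution-time factor of the generator exponential is absorbed
into θ (dimensionless angles).

## Phase estimation

The IPEA extracts the eigenphase ϕ = (−λt) mod 2π of U = e^{−iĤt} least
significant bit first with the textbook feedback rotation −2π(0.0b_{k+1}…b_m)
on the control, reporting bits most significant first.  U^{2^k} is computed
by direct exponentiation of the eigendecomposition (never cascaded
multiplication); a guard refuses depths where 2^m·‖Ĥ‖₁·t approaches the
relative precision of double arithmetic (32 bits on the dimer uses about
3×10⁻⁶ rad of the 10⁻² rad headroom).  The target register is one quantum
trajectory: every shot's measurement collapses it, so an imperfect
variational input projects onto a single eigenstate with Born-rule
probability while its phase is read out.  Sampled runs require an odd shot
count per bit so majority votes cannot tie; the noiseless mode thresholds
the exact probability at 1/2 (ties toward 0) and is deterministic.  Energy
readout inverts the phase on the caller's branch and re-adds the reference
shift ℓ.  The reported resolution is the branch width over 2^bits —
2π/(26·2³²) ≈ 5.6×10⁻¹¹ eV at the dimer settings; note this formula-based
figure is what the package reports, full stop.

Near-degenerate spectra are out of scope: when two eigenvalues differ by
less than a few readout codes, the projection contract only completes once
the bit depth resolves the splitting.

## Synthetic fixtures: what they emulate and what they do not

`random_hamiltonian` draws every Pauli word independently (standard-normal
real coefficients, keep-probability = density), giving Hermitian operators
with generic, occasionally near-degenerate spectra.  The fermionic toy
models are one-body Hamiltonians in a rotated orbital basis with one bound
orbital, so the global ground state lies in the one-particle sector
reachable from the |100⟩ reference by number-conserving singles.  These
fixtures exercise every code path of the protocol — mapping, witness,
search, arbitration, projection — on spectra with random eigenbases, but
they are not molecular electronic structure: there are no two-body
correlations in the fixture Hamiltonians' ground states, no basis-set
effects, and the perturbing unitaries for their excited searches come from
an oracle (random sums) or the exact orbital basis (fermionic models)
rather than from a self-consistent mean-field calculation.  Passing these
tests shows the machinery recovers eigenstates it can represent; it says
nothing about ansatz adequacy for correlated chemistry.

Problem sizes used throughout the suite: the dimer reproduction at its
published settings (10 particles, 15 epochs, 10⁴ shots/basis, 50 seeds);
fixtures at 1–4 qubits with 10–16 particles and 15–25 epochs.  The whole
test suite runs in well under a minute on one core.

## Known limitations

- Dense linear algebra throughout; the qubit cap (12) is a memory/time
  guard, not a scalability claim.
- The optimizer's arbitration relies on the witness energy; for Hamiltonians
  whose spectral range exceeds the branch width at the chosen t, the branch
  hint must cover the spectrum or E-ordering can alias.
- High-dimensional generator ansätze (≳10 parameters) exceed what the
  published per-run budget can refine; the quadratic readout then falls back
  to the weighted population mean.
- Mixed-state targets, hardware noise beyond measurement shot noise, and
  Trotterized evolutions are not modeled.
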