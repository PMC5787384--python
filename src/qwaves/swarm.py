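"""Particle-swarm variational search over ansatz parameters.

Each epoch spends one (noisy) witness-objective evaluation per particle.
The search runs in three stages:

1. **parallel descent** — every particle performs an adaptive stochastic
   descent: it proposes a Gaussian step of its own scale and keeps the move
   only if the measured F_obj improves on its cached value (scales adapt by
   a 1/5-success-style rule; occasional re-measurements average the cache so
   a lucky noise-low readout cannot freeze a particle).  Every basin of the
   objective the prior covered is refined simultaneously.
2. **arbitration** — one epoch measures all particles fresh and picks the
   winning basin.  Ground searches choose by the witness energy E, which
   stays pinned near a basin's eigenvalue whatever the purity refinement and
   so separates basins with far more margin than F_obj; excited searches
   (where F ≡ −P is blind between eigenstates) keep the basin closest to
   their initialization.  Losing particles are scattered around winner
   members and the descent continues, polishing the winner with a full
   population of distinct walkers.
3. **response-surface readout** — the final parameters are the
   objective-weighted population mean, refined by a least-squares quadratic
   fit to every readout the search logged near the optimum
   (:func:`quadratic_refit`), which averages tens of measurements and
   locates the minimum well below the single-readout shot-noise floor.

Ground-state searches start from a uniform prior over the ansatz parameter
ranges and minimize F_obj = E − T·P; excited-state searches start from a
Gaussian around the perturbed ground solution and minimize −P (the high-T
limit).  Runs are bitwise reproducible from the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ansatz import AnsatzSpec, apply_ansatz, _resolve_prepend
from .pauli import EigenSystem, PauliSum
from .state import StateVector, subspace_fidelity
from .witness import (HIGH_T, TomographySettings, apply_controlled_evolution,
                      check_evolution_time, default_evolution_time,
                      simulate_control_tomography, witness_quantities)

GROUND, EXCITED = "ground", "excited"


@dataclass
class SearchConfig:
    """Knobs of the variational search.

    ``temperature`` is the energy/purity trade-off T of F_obj = E − T·P
    (ignored in excited mode, which always uses the high-T limit F ≡ −P).
    ``contraction`` is the per-rejection factor a ∈ (0, 1) by which a
    particle's step scale shrinks (growing by a⁻³ on acceptance, the
    1/5-success rule); ``initial_step`` and ``step_cap`` bound that scale as
    fractions of each parameter's range width (mode-dependent default);
    ``mutation_floor`` is the absolute step size (radians) the largest-range
    coordinate never drops below, keeping a little diffusion at the noise
    floor.  ``remeasure_prob`` is the chance a particle spends its epoch
    re-measuring its cache instead of moving (doubled in the final third of
    the run); ``exploration_fraction`` is the share of epochs spent in pure
    parallel descent before the one-time basin arbitration;
    ``elite_fraction`` restricts the final objective-weighted parameter mean
    to the best fraction of particles (1.0 = all); ``convergence_tol`` > 0
    enables early stopping on trace(covariance); ``t = None`` uses π/(2‖H‖₁);
    ``init_spread`` is the per-coordinate σ (radians) of the excited-mode
    Gaussian initialization.
    """

    mode: str = GROUND
    n_particles: int = 10
    n_epochs: int = 15
    temperature: float = 1.25
    tomography: TomographySettings = field(default_factory=TomographySettings)
    contraction: float = 0.7
    initial_step: float | None = None
    step_cap: float = 0.2
    mutation_floor: float = 0.02
    elite_fraction: float = 1.0
    remeasure_prob: float = 0.15
    exploration_fraction: float = 0.4
    convergence_tol: float = 0.0
    t: float | None = None
    energy_branch_hint: tuple[float, float] | None = None
    init_spread: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (GROUND, EXCITED):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if not 0.0 < self.contraction < 1.0:
            raise ValueError("contraction must be in (0, 1)")
        if not 0.0 < self.elite_fraction <= 1.0:
            raise ValueError("elite_fraction must be in (0, 1]")
        if self.initial_step is None:
            # ground searches start from a range-wide prior and need wide
            # first steps; excited searches start inside a tight cloud around
            # the perturbed ground solution and refine locally from the start
            self.initial_step = 0.1 if self.mode == GROUND else 0.03


@dataclass
class EpochRecord:
    epoch: int
    mean_objective: float
    best_objective: float
    mean_energy: float
    mean_purity: float
    fidelity: float | None
    param_mean: np.ndarray
    param_std: np.ndarray


@dataclass
class SwarmState:
    """The particle population at one epoch.

    ``objectives`` caches each particle's current measured F_obj (None before
    the first evaluation; a running average when the particle re-measures),
    ``mutation_scales`` its adaptive step multiplier, and ``cache_counts``
    how many readouts the cache averages.
    """

    particles: np.ndarray  # N x d
    weights: np.ndarray    # nonnegative, sum 1
    epoch: int = 0
    objectives: np.ndarray | None = None
    mutation_scales: np.ndarray | None = None  # per-particle step multiplier
    cache_counts: np.ndarray | None = None  # readouts averaged into each cache
    trace: list[EpochRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.particles = np.atleast_2d(np.asarray(self.particles, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-12 or (self.weights < 0).any():
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def n_particles(self) -> int:
        return self.particles.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.weights @ self.particles

    @property
    def covariance(self) -> np.ndarray:
        diff = self.particles - self.mean
        return (self.weights[:, None] * diff).T @ diff

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


def initialize_swarm(spec: AnsatzSpec, config: SearchConfig,
                     base_theta=None, rng: np.random.Generator | None = None) -> SwarmState:
    """Uniform prior over the parameter ranges (ground) or a Gaussian around
    the supplied ground solution (excited)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, d = config.n_particles, spec.parameter_count
    if config.mode == EXCITED:
        if base_theta is None:
            raise ValueError("excited-mode initialization requires the ground solution")
        base = np.asarray(base_theta, dtype=float).ravel()
        if base.size != d:
            raise ValueError("base_theta length mismatch")
        particles = base + config.init_spread * rng.standard_normal((n, d))
        # pinned coordinates (degenerate ranges, e.g. a global phase) stay pinned
        for k, (lo, hi) in enumerate(spec.parameter_ranges):
            if hi - lo == 0.0:
                particles[:, k] = lo
    else:
        lows = np.array([lo for lo, _ in spec.parameter_ranges])
        highs = np.array([hi for _, hi in spec.parameter_ranges])
        particles = lows + (highs - lows) * rng.random((n, d))
    return SwarmState(particles, np.full(n, 1.0 / n))



def _exploration_epochs(config: SearchConfig) -> int:
    """Number of pure-descent epochs before the one-time arbitration epoch."""
    return max(1, int(round(config.exploration_fraction * config.n_epochs)))




def _unwrap(particles: np.ndarray, reference: np.ndarray,
            spec: AnsatzSpec) -> np.ndarray:
    """Map periodic coordinates into the period window centered on ``reference``.

    A cluster straddling a periodic boundary (e.g. an azimuth at ±π) has a
    meaningless arithmetic mean; unwrapping around a reference particle makes
    means, covariances and contractions well-defined circular statistics.
    """
    out = np.array(particles, dtype=float, copy=True)
    for k, ((lo, hi), per) in enumerate(zip(spec.parameter_ranges, spec.periodic)):
        width = hi - lo
        if per and width > 0:
            out[:, k] = reference[k] + np.mod(
                out[:, k] - reference[k] + width / 2.0, width) - width / 2.0
    return out


def _step_caps(n: int, config: SearchConfig) -> np.ndarray:
    # heterogeneous mobility: even-indexed walkers stay local (their basin
    # refinement cannot be lost to a long lucky jump into a deeper basin),
    # odd-indexed walkers keep the full step cap and travel fast
    local = min(0.6 * config.step_cap, config.step_cap)
    caps = np.where(np.arange(n) % 2 == 0, local, config.step_cap)
    return caps


def _base_widths(spec: AnsatzSpec, config: SearchConfig) -> np.ndarray:
    # the step geometry follows the declared parameter ranges in both modes:
    # an excited search must be able to walk back from an imperfect ground
    # solution, not merely jitter within the initialization cloud
    return np.array([hi - lo for lo, hi in spec.parameter_ranges])



def _eval_pair(evaluate, theta) -> tuple[float, float]:
    """Call an objective closure; normalize to (F_obj, energy).

    Closures may return a bare objective (energy reported as NaN) or an
    (objective, energy) pair — the witness objective from
    :func:`make_objective` reports both, since the control qubit's readout
    yields E and P together.
    """
    res = evaluate(theta)
    if isinstance(res, tuple):
        return float(res[0]), float(res[1])
    return float(res), math.nan


def _arbitrate(particles: np.ndarray, finite: np.ndarray, objectives: np.ndarray,
               energies: np.ndarray, spec: AnsatzSpec, config: SearchConfig,
               rng: np.random.Generator, base_theta=None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """One-time basin arbitration at the descent→consolidation boundary.

    The descent phase refined every basin the prior covered, so the
    population now sits in a few tight clusters (plus stragglers).  Clusters
    are extracted greedily: the best remaining particle seeds a cluster of
    everything within 20% of each parameter range (shortest way around for
    periodic coordinates).  In ground mode the winning cluster is the one
    whose seed reports the lowest witness energy E — within a basin E stays
    pinned near that basin's eigenvalue whatever the purity refinement, so
    the energy separates basins long before F_obj does, and with far more
    noise margin.  (Without energy readings the seeds' F_obj decides.)
    All other particles are scattered around winner members (distinct
    positions, invalidated caches) so the polish phase keeps a full
    population of independent walkers in the winning basin.
    """
    n = particles.shape[0]
    widths = np.array([hi - lo for lo, hi in spec.parameter_ranges])
    unassigned = list(range(n))
    clusters: list[np.ndarray] = []
    while unassigned:
        idx = np.array(unassigned)
        seed = idx[int(np.argmin(finite[idx]))]
        rel = np.abs(_unwrap(particles[idx], particles[seed], spec) - particles[seed])
        rel = np.where(widths > 0, rel / np.where(widths > 0, widths, 1.0), 0.0)
        members = idx[np.max(rel, axis=1) < 0.2]
        clusters.append(members)
        unassigned = [i for i in unassigned if i not in set(members.tolist())]
    seeds = [int(c[np.argmin(finite[c])]) for c in clusters]
    seed_e = np.array([energies[s] for s in seeds])
    if config.mode == EXCITED and base_theta is not None:
        # the excited target is defined by the perturbed ground solution the
        # search was initialized around (F ≡ −P is blind between eigenstates,
        # so a cluster that drifted to a different eigenstate must lose):
        # the cluster whose seed stays closest to the initialization wins
        base = np.asarray(base_theta, dtype=float).ravel()
        dists = []
        for s in seeds:
            rel = np.abs(_unwrap(particles[s][None, :], base, spec)[0] - base)
            rel = np.where(widths > 0, rel / np.where(widths > 0, widths, 1.0), 0.0)
            dists.append(float(np.max(rel)))
        winner = int(np.argmin(dists))
    elif config.mode == GROUND and np.isfinite(seed_e).all():
        winner = int(np.argmin(seed_e))
    else:
        winner = int(np.argmin([finite[s] for s in seeds]))
    members = clusters[winner]
    order = members[np.argsort(finite[members])]
    member_set = set(members.tolist())
    # losers are scattered (not cloned) around winner members so the polish
    # phase keeps N distinct walkers whose residual errors average out in the
    # population mean; their caches are invalidated for a fresh readout
    scatter = 0.03 * widths
    for i in range(n):
        if i not in member_set:
            src = int(order[i % len(order)])
            particles[i] = particles[src] + scatter * rng.standard_normal(widths.size)
            finite[i] = finite[src]
            objectives[i] = np.nan
    # the winner seed's control purity, recovered from its own readout
    # (F = E − T·P in ground mode, F = −P in the high-T limit): it tells how
    # refined the winning basin already is
    s_best = seeds[winner]
    if config.mode == GROUND and np.isfinite(energies[s_best]):
        purity = float((energies[s_best] - finite[s_best]) / config.temperature)
    else:
        purity = float(-finite[s_best])
    purity = min(max(purity, 0.0), 1.0)
    return particles, finite, objectives, purity


def swarm_epoch(swarm: SwarmState, evaluate, config: SearchConfig,
                rng: np.random.Generator,
                spec: AnsatzSpec | None = None,
                base_theta=None) -> tuple[SwarmState, np.ndarray]:
    """Advance the swarm by one epoch (one objective evaluation per particle).

    The first epoch evaluates the initial particles in place; descent epochs
    run the bank of adaptive accept-if-better stochastic descents (with
    occasional cache re-measurement); the single arbitration epoch at the end
    of the exploration phase measures everything fresh, picks the winning
    basin and relocates the losers (see :func:`_arbitrate`).  Deterministic
    given (swarm, rng state).
    """
    n = swarm.n_particles
    particles = swarm.particles.copy()

    if swarm.epoch == _exploration_epochs(config):
        # arbitration epoch: every particle is measured fresh (objective and
        # witness energy together), the basins the descent phase refined are
        # clustered, the lowest-energy basin wins, and the losers are
        # relocated onto winner members; the remaining epochs polish the
        # winner with further descent
        if spec is None:
            raise ValueError("the arbitration epoch needs the ansatz spec")
        pairs = [_eval_pair(evaluate, x) for x in particles]
        objectives = np.array([p[0] for p in pairs])
        energies = np.array([p[1] for p in pairs])
        if not np.isfinite(objectives).any():
            raise RuntimeError("all particle objectives are non-finite")
        finite = np.where(np.isfinite(objectives), objectives,
                          np.nanmax(objectives[np.isfinite(objectives)]))
        particles, finite, objectives, purity = _arbitrate(
            particles, finite, objectives, energies, spec, config, rng,
            base_theta=base_theta)
        # polish steps sized by how refined the winner already is: a pure
        # (P ≈ 1) winner only needs floor-scale moves, while an unrefined
        # low-energy region restarts with exploration-grade steps so the
        # remaining epochs can still descend into its basin
        polish_step = 0.03 + (1.0 - purity) * (config.initial_step * 3.0)
        successor = SwarmState(particles, np.full(n, 1.0 / n), swarm.epoch + 1,
                               objectives=finite,
                               mutation_scales=np.full(n, min(polish_step,
                                                              config.step_cap)),
                               cache_counts=np.ones(n), trace=swarm.trace)
        return successor, objectives

    # descent epoch: a bank of independent adaptive stochastic descents
    if swarm.objectives is None:
        objectives = np.array([_eval_pair(evaluate, x)[0] for x in particles])
        scales = np.full(n, config.initial_step)
        counts = np.ones(n)
    else:
        if spec is None:
            raise ValueError("descent epochs need the ansatz spec for range widths")
        widths = _base_widths(spec, config)
        scales = (swarm.mutation_scales if swarm.mutation_scales is not None
                  else np.full(n, config.initial_step)).copy()
        counts = (swarm.cache_counts if swarm.cache_counts is not None
                  else np.ones(n)).copy()
        objectives = swarm.objectives.copy()
        ref = np.max(np.abs(widths)) if np.max(np.abs(widths)) > 0 else 1.0
        floor = config.mutation_floor / ref
        # implicit averaging: sometimes a particle spends its evaluation
        # re-measuring its current position and folds the readout into a
        # running cache average — a lucky (noise-low) cached value cannot
        # freeze its particle's descent forever, it washes out as 1/√k.
        # Late epochs re-measure twice as often: near the shot-noise floor
        # unbiased caches matter more than further movement
        pr = config.remeasure_prob
        if swarm.epoch >= int(math.ceil(2.0 * config.n_epochs / 3.0)):
            pr = min(0.5, 2.0 * pr)
        remeasure = rng.random(n) < pr
        sigma = scales[:, None] * widths
        steps = sigma * rng.standard_normal(particles.shape)
        proposals = np.where(remeasure[:, None], particles, particles + steps)
        proposed = np.array([_eval_pair(evaluate, x)[0] for x in proposals])
        if swarm.epoch > _exploration_epochs(config):
            # post-arbitration confinement: the basin has been chosen, so
            # proposals that leave the neighborhood of the current best
            # particle are vetoed — a deep optimum of a *different* basin
            # must not re-capture the walkers while this one refines.  The
            # region slides with the best particle as it descends.
            anchor = particles[int(np.nanargmin(objectives))]
            rel = np.abs(_unwrap(proposals, anchor, spec) - anchor)
            rel = np.where(widths > 0, rel / np.where(widths > 0, widths, 1.0), 0.0)
            proposed = np.where(np.max(rel, axis=1) <= 0.25, proposed, np.nan)
        for i in range(n):
            if not np.isfinite(proposed[i]):
                if not remeasure[i]:
                    # vetoed or undefined proposal counts as a rejection
                    scales[i] = scales[i] * config.contraction
                continue
            if remeasure[i]:
                if np.isfinite(objectives[i]):
                    objectives[i] = (objectives[i] * counts[i] + proposed[i]) / (counts[i] + 1)
                    counts[i] += 1
                else:
                    objectives[i], counts[i] = proposed[i], 1
            else:
                # ties accept the proposal: purity readouts of near-eigenstates
                # saturate at the clipped P̂ = 1, and acceptance on the
                # saturated tie still drifts the right way (saturation is
                # likelier the better the state)
                if not np.isfinite(objectives[i]) or proposed[i] <= objectives[i]:
                    particles[i] = proposals[i]
                    objectives[i], counts[i] = proposed[i], 1
                    scales[i] = scales[i] * config.contraction**-3
                else:
                    scales[i] = scales[i] * config.contraction
        scales = np.clip(scales, floor, _step_caps(n, config))
    if not np.isfinite(objectives).any():
        raise RuntimeError("all particle objectives are non-finite")
    finite = np.where(np.isfinite(objectives), objectives,
                      np.nanmax(objectives[np.isfinite(objectives)]))
    successor = SwarmState(particles, np.full(n, 1.0 / n), swarm.epoch + 1,
                           objectives=finite, mutation_scales=scales,
                           cache_counts=counts, trace=swarm.trace)
    return successor, objectives


@dataclass
class SearchResult:
    theta: np.ndarray
    swarm: SwarmState
    trace: list[EpochRecord]
    mean_state: StateVector
    #: fidelity of the final state with the oracle target subspace, when an
    #: oracle was attached for diagnostics
    final_fidelity: float | None = None


def make_objective(h: PauliSum, spec: AnsatzSpec, config: SearchConfig,
                   prepend=None, rng: np.random.Generator | None = None):
    """The parameter-vector → noisy F_obj closure used by the search.

    Each call prepares the ansatz state, runs the controlled evolution,
    performs (possibly shot-noisy) control tomography with a seed drawn from
    ``rng``, and returns the witness objective.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    t = config.t if config.t is not None else default_evolution_time(h)
    check_evolution_time(h, t)
    temperature = HIGH_T if config.mode == EXCITED else config.temperature
    mats = _resolve_prepend(prepend, spec.n_qubits)
    shots = config.tomography.shots_per_basis

    log: list[tuple[np.ndarray, float]] = []

    def evaluate(theta) -> float:
        state = apply_ansatz(spec, theta, prepend=mats)
        joint = apply_controlled_evolution(state, h, t)
        settings = TomographySettings(shots, int(rng.integers(2**31)) if shots else 0)
        rho = simulate_control_tomography(joint, settings)
        rec = witness_quantities(rho, t, temperature, config.energy_branch_hint,
                                 shots_used=3 * shots)
        if math.isfinite(rec.objective):
            log.append((np.asarray(theta, dtype=float).copy(), rec.objective))
        return rec.objective, rec.energy

    evaluate.log = log
    return evaluate


def quadratic_refit(log: list[tuple[np.ndarray, float]], ref: np.ndarray,
                    spec: AnsatzSpec, radius: float = 0.15,
                    min_points: int | None = None) -> np.ndarray | None:
    """Response-surface refinement of the optimizer's solution.

    Every objective readout the search made near the converged region is
    reused to fit a local quadratic model F(θ) ≈ c + gᵀδ + δᵀHδ/2 by least
    squares (δ = θ − ref on the non-pinned coordinates, periodic coordinates
    unwrapped around ref, points within ``radius`` of each range width).
    The fitted stationary point −H⁻¹g is returned when the fit is
    well-conditioned, convex and inside the trust region — averaging tens of
    measurements, it locates the minimum far below the single-readout noise
    floor.  Returns None when the data cannot support the fit (too few local
    points, indefinite curvature, or an out-of-region minimizer).
    """
    widths = np.array([hi - lo for lo, hi in spec.parameter_ranges])
    free = np.nonzero(widths > 0)[0]
    d = free.size
    ncoef = 1 + d + d * (d + 1) // 2
    if not log or d == 0:
        return None
    pts = np.array([p for p, _ in log])
    vals = np.array([v for _, v in log])
    pts = _unwrap(pts, ref, spec)
    rel = np.abs(pts[:, free] - ref[free]) / widths[free]
    mask = np.max(rel, axis=1) < radius
    if mask.sum() < (2 * ncoef if min_points is None else max(min_points, ncoef + 2)):
        return None
    delta = pts[mask][:, free] - ref[free]
    y = vals[mask]
    cols = [np.ones(delta.shape[0])]
    cols.extend(delta[:, k] for k in range(d))
    for a in range(d):
        for b in range(a, d):
            cols.append(delta[:, a] * delta[:, b] * (0.5 if a == b else 1.0))
    design = np.column_stack(cols)
    # locally weighted fit: points near the trust-region boundary count less,
    # which suppresses the cubic/quartic model bias they would otherwise
    # leak into the fitted minimizer
    r2 = np.sum((delta / (radius * widths[free])) ** 2, axis=1)
    w = np.sqrt(np.exp(-2.0 * r2))
    coef, *_ = np.linalg.lstsq(design * w[:, None], y * w, rcond=None)
    g = coef[1:1 + d]
    hess = np.zeros((d, d))
    k = 1 + d
    for a in range(d):
        for b in range(a, d):
            hess[a, b] = hess[b, a] = coef[k]
            k += 1
    evals, evecs = np.linalg.eigh(hess)
    if evals.max() <= 0 or evals.min() < -0.05 * evals.max():
        return None
    # pseudo-inverse step: overparameterized ansätze have flat directions
    # (e.g. a rotation about the prepared state's own axis), where the
    # curvature is legitimately ~0 and the minimizer moves nothing
    keep = evals > 1e-3 * evals.max()
    inv = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
    step = -(evecs * inv) @ (evecs.T @ g)
    if np.any(np.abs(step) / widths[free] > radius):
        return None
    out = ref.copy()
    out[free] = ref[free] + step
    return out


def run_variational_search(h: PauliSum, spec: AnsatzSpec, config: SearchConfig,
                           excitation=None, base_theta=None,
                           oracle: EigenSystem | None = None,
                           target_index: int | None = None) -> SearchResult:
    """The full witness-assisted variational search.

    Ground mode minimizes F_obj = E − T·P from a uniform prior; excited mode
    minimizes −P starting from a Gaussian around ``base_theta`` with the
    ``excitation`` unitaries prepended.  When an ``oracle`` eigen-system is
    attached, the per-epoch trace logs the fidelity of the swarm-mean state
    with the target eigen-subspace (index 0 for ground unless overridden;
    degenerate groups are handled by projector fidelity).
    """
    master = np.random.default_rng(config.seed)
    swarm = initialize_swarm(spec, config, base_theta=base_theta, rng=master)
    evaluate = make_objective(h, spec, config, prepend=excitation, rng=master)
    t = config.t if config.t is not None else default_evolution_time(h)
    temperature = HIGH_T if config.mode == EXCITED else config.temperature

    fidelity_basis = None
    if oracle is not None:
        if target_index is None:
            target_index = 0 if config.mode == GROUND else _closest_group(
                oracle, apply_ansatz(spec, swarm.mean, prepend=excitation))
        fidelity_basis = oracle.subspace(target_index)

    def population_mean(population: SwarmState) -> np.ndarray:
        # circular-safe, objective-weighted mean: periodic coordinates are
        # unwrapped around the best-cached particle, and particles are
        # softmax-weighted by their cached objectives so unconverged
        # stragglers do not drag the reported solution
        if population.objectives is None:
            return population.weights @ population.particles
        finite = np.where(np.isfinite(population.objectives), population.objectives,
                          np.nanmax(population.objectives))
        ref_idx = int(np.argmin(finite))
        unwrapped = _unwrap(population.particles, population.particles[ref_idx], spec)
        # objective-weighted mean: unconverged stragglers are exponentially
        # suppressed while the converged core still averages its noise down.
        # The temperature is the spread of the better half of the caches, so
        # a heavy straggler tail cannot inflate it and dodge suppression.
        half = np.sort(finite)[: max(2, finite.size // 2)]
        tau = max(float(half[-1] - half[0]), 1e-12)
        weights = np.exp(-(finite - finite.min()) / tau)
        if config.elite_fraction < 1.0:
            keep = max(2, int(math.ceil(config.elite_fraction * finite.size)))
            cutoff = np.sort(finite)[keep - 1]
            weights = np.where(finite <= cutoff, weights, 0.0)
        return (weights / weights.sum()) @ unwrapped

    def log_epoch(objectives: np.ndarray, population: SwarmState) -> None:
        mean_theta = population_mean(population)
        mean_state = apply_ansatz(spec, mean_theta, prepend=excitation)
        from .witness import control_reduced_state
        rho = control_reduced_state(apply_controlled_evolution(mean_state, h, t))
        rec = witness_quantities(rho, t, temperature, config.energy_branch_hint)
        fid = subspace_fidelity(mean_state, fidelity_basis) if fidelity_basis else None
        population.trace.append(EpochRecord(
            epoch=population.epoch, mean_objective=float(np.nanmean(objectives)),
            best_objective=float(np.nanmin(objectives)), mean_energy=rec.energy,
            mean_purity=rec.purity, fidelity=fid,
            param_mean=mean_theta.copy(), param_std=population.std.copy()))

    for _ in range(config.n_epochs):
        swarm, objectives = swarm_epoch(swarm, evaluate, config, master, spec=spec,
                                        base_theta=base_theta)
        log_epoch(objectives, swarm)
        if config.convergence_tol > 0 and np.trace(swarm.covariance) < config.convergence_tol:
            break

    theta = population_mean(swarm)
    log = getattr(evaluate, "log", [])
    best = (swarm.particles[int(np.nanargmin(swarm.objectives))]
            if swarm.objectives is not None else theta)
    if config.tomography.shots_per_basis == 0:
        # analytic readouts: bias-limited — prefer tight regions, and accept
        # sparse support since every point is exact
        attempts = ((best, 0.06, 0), (best, 0.1, 0), (theta, 0.1, 0),
                    (best, 0.15, 0))
    else:
        # shot noise: a wider region keeps enough points to average it down
        attempts = ((theta, 0.15, None), (best, 0.15, None), (best, 0.08, None))
    for center, radius, min_pts in attempts:
        refined = quadratic_refit(log, np.asarray(center, dtype=float), spec,
                                  radius=radius, min_points=min_pts)
        if refined is not None:
            theta = refined
            break
    mean_state = apply_ansatz(spec, theta, prepend=excitation)
    final_fid = (subspace_fidelity(mean_state, fidelity_basis)
                 if fidelity_basis else None)
    return SearchResult(theta=theta, swarm=swarm, trace=swarm.trace,
                        mean_state=mean_state, final_fidelity=final_fid)


def _closest_group(oracle: EigenSystem, psi: StateVector) -> int:
    overlaps = [subspace_fidelity(psi, [oracle.eigenvectors[i] for i in g])
                for g in oracle.groups]
    return oracle.groups[int(np.argmax(overlaps))][0]
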