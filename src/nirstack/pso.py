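"""Binary particle-swarm optimization for wavelength selection.

Particles carry a binary position (one bit per wavelength channel, 1 =
selected) and a real velocity. Each iteration: evaluate fitness, update
personal bests (strict improvement) and the swarm best, update velocities

    v_ij <- w*v_ij + c1*q*(x_pb_ij - x_ij)/dt + c2*r*(x_sb_ij - x_ij)/dt

with q, r ~ Uniform[0,1] drawn once per particle per iteration, clamp to
[-v_max, v_max], and resample each bit through the logistic transform of its
velocity: x_ij = 1 iff r_ij <= S(v_ij). When velocities saturate while the
swarm has collapsed onto one position, a *reset* redraws velocities and
rebuilds positions from a mixture of each particle's personal best, the
swarm best, and fresh random bits — personal and global bests survive the
reset, so the best-so-far trajectory is monotone.

The default fitness is the wrapper objective

    J(mask) = alpha * P(mask) + (1 - alpha) * (1 - N_f / N_t)

where P is the cross-validated variety-classification accuracy of a stacked
classifier restricted to the masked channels, N_f the selected channel count
and N_t the total; alpha (default 0.5) trades classifier performance against
subset compactness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import FeatureMask, SpectraDataset, apply_feature_mask
from .models import StackSpec, ModelSpec, cv_accuracy

__all__ = [
    "PSOConfig",
    "Particle",
    "Swarm",
    "sigmoid",
    "subset_fitness",
    "make_subset_fitness",
    "init_swarm",
    "update_personal_best",
    "update_global_best",
    "update_velocity",
    "update_position",
    "detect_premature_convergence",
    "reset_swarm",
    "run_pso",
    "exhaustive_best_subset",
]


@dataclass
class PSOConfig:
    """Swarm settings. Defaults follow the tuned study values (50 particles,
    10 iterations, alpha 0.5) with standard binary-PSO dynamics elsewhere
    (w=0.9, c1=c2=2, dt=1, v_max=6)."""

    n_particles: int = 50
    n_iterations: int = 10
    w: float = 0.9
    c1: float = 2.0
    c2: float = 2.0
    dt: float = 1.0
    alpha: float = 0.5
    v_max: float = 6.0
    reset_enabled: bool = True
    seed: int = 0
    fitness_folds: int = 5
    paper_literal_sigmoid: bool = False
    per_coordinate_qr: bool = False
    diversity_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.v_max <= 0:
            raise ValueError("v_max must be > 0")


@dataclass
class Particle:
    position: np.ndarray  # int8 bits
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float


@dataclass
class Swarm:
    particles: list[Particle]
    best_position: np.ndarray
    best_fitness: float
    iteration: int = 0


def sigmoid(v, literal: bool = False):
    """Logistic transform of velocity, overflow-safe.

    The increasing convention S(v) = 1/(1+e^{-v}) is the default; ``literal``
    flips the sign (a decreasing transform some formulations print)."""
    v = np.asarray(v, dtype=float)
    z = -v if not literal else v
    out = np.empty_like(v, dtype=float)
    pos = z <= 0
    out[pos] = 1.0 / (1.0 + np.exp(z[pos]))
    ez = np.exp(-z[~pos])
    out[~pos] = ez / (1.0 + ez)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Fitness


def subset_fitness(
    mask: FeatureMask,
    dataset: SpectraDataset,
    stack: StackSpec | ModelSpec,
    alpha: float = 0.5,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Wrapper objective J = alpha*P + (1-alpha)*(1 - N_f/N_t).

    P is the k-fold CV variety-classification accuracy of ``stack`` (a
    stacked classifier, or a single model spec for the plain-classifier
    baseline) on the masked channels. An all-zero mask is defined-invalid
    and scores -inf so it can never become a best."""
    if mask.n_selected == 0:
        return float("-inf")
    import sklearn

    masked = apply_feature_mask(dataset, mask)
    X, y = masked.reflectance, masked.variety
    with sklearn.config_context(assume_finite=True):  # hot path: skip input checks
        if isinstance(stack, StackSpec):
            p = cv_accuracy(stack, X, y, folds=folds, seed=seed)
        else:
            p = _single_model_cv_accuracy(stack, X, y, folds=folds, seed=seed)
    return alpha * p + (1.0 - alpha) * (1.0 - mask.n_selected / len(mask))


def _single_model_cv_accuracy(spec: ModelSpec, X, y, folds: int, seed: int) -> float:
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    est = spec.to_estimator(seed=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    return float(cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean())


def make_subset_fitness(
    dataset: SpectraDataset,
    stack: StackSpec | ModelSpec,
    alpha: float = 0.5,
    folds: int = 5,
    seed: int = 0,
    cache: bool = True,
):
    """Build a (mask, dataset) -> score fitness callable, memoized per mask.

    The fitness is deterministic given its own seed, so memoization by the
    mask's bit pattern is exact and saves refits when the swarm revisits a
    subset."""
    store: dict[bytes, float] = {}

    def fitness(mask: FeatureMask, ds: SpectraDataset = dataset) -> float:
        key = mask.bits.tobytes()
        if cache and key in store:
            return store[key]
        value = subset_fitness(mask, ds, stack, alpha=alpha, folds=folds, seed=seed)
        if cache:
            store[key] = value
        return value

    fitness.cache = store
    return fitness


# ---------------------------------------------------------------------------
# Swarm mechanics


def _repair_all_zero(bits: np.ndarray, probs: np.ndarray | None, rng: np.random.Generator) -> np.ndarray:
    """Re-draw an all-zero position once, then force the most likely bit on."""
    if bits.any():
        return bits
    if probs is None:
        probs = np.full(bits.size, 0.5)
    redraw = (rng.uniform(size=bits.size) <= probs).astype(np.int8)
    if redraw.any():
        return redraw
    redraw[int(np.argmax(probs))] = 1
    return redraw


def init_swarm(config: PSOConfig, D: int, rng: np.random.Generator, fitness=None, dataset=None) -> Swarm:
    """Random swarm: Bernoulli(0.5) bits (all-zero re-drawn), uniform velocities.

    When a fitness callable is given, personal bests are evaluated and the
    global best set; otherwise fitnesses start at -inf."""
    if D < 1:
        raise ValueError("D must be >= 1")
    particles = []
    for _ in range(config.n_particles):
        bits = (rng.uniform(size=D) < 0.5).astype(np.int8)
        while not bits.any():
            bits = (rng.uniform(size=D) < 0.5).astype(np.int8)
        vel = rng.uniform(-config.v_max, config.v_max, size=D)
        f = float("-inf")
        if fitness is not None:
            f = fitness(FeatureMask(bits), dataset)
        particles.append(Particle(bits, vel, bits.copy(), f))
    best = max(particles, key=lambda p: p.best_fitness)
    return Swarm(particles, best.best_position.copy(), best.best_fitness)


def update_personal_best(particle: Particle, fitness: float) -> Particle:
    """x_pb <- x_i iff f(x_i) > f(x_pb) — strict improvement only."""
    if fitness > particle.best_fitness:
        particle.best_position = particle.position.copy()
        particle.best_fitness = fitness
    return particle


def update_global_best(swarm: Swarm) -> Swarm:
    """x_sb <- best personal best; strict improvement, ties keep the incumbent."""
    for p in swarm.particles:
        if p.best_fitness > swarm.best_fitness:
            swarm.best_fitness = p.best_fitness
            swarm.best_position = p.best_position.copy()
    return swarm


def update_velocity(
    particle: Particle, best_position: np.ndarray, config: PSOConfig, rng: np.random.Generator
) -> Particle:
    """Inertia + cognitive + social velocity update, clamped to [-v_max, v_max]."""
    if config.per_coordinate_qr:
        q = rng.uniform(size=particle.velocity.size)
        r = rng.uniform(size=particle.velocity.size)
    else:
        q = rng.uniform()
        r = rng.uniform()
    v = (
        config.w * particle.velocity
        + config.c1 * q * (particle.best_position - particle.position) / config.dt
        + config.c2 * r * (best_position - particle.position) / config.dt
    )
    particle.velocity = np.clip(v, -config.v_max, config.v_max)
    return particle


def update_position(particle: Particle, rng: np.random.Generator, config: PSOConfig | None = None) -> Particle:
    """Resample bits: x_ij = 1 iff r_ij <= S(v_ij); all-zero repaired."""
    literal = bool(config.paper_literal_sigmoid) if config is not None else False
    s = sigmoid(particle.velocity, literal=literal)
    r = rng.uniform(size=s.size)
    bits = (r <= s).astype(np.int8)
    particle.position = _repair_all_zero(bits, s, rng)
    return particle


def diversity(swarm: Swarm) -> float:
    """Mean pairwise Hamming distance between positions, normalized by D."""
    P = np.array([p.position for p in swarm.particles], dtype=float)
    n = P.shape[0]
    if n < 2:
        return 0.0
    m = P.mean(axis=0)
    # mean pairwise Hamming = 2n/(n-1) * mean_j m_j(1-m_j)
    return float(2.0 * n / (n - 1) * np.mean(m * (1.0 - m)))


def detect_premature_convergence(swarm: Swarm, config: PSOConfig) -> bool:
    """Saturated velocities plus collapsed position diversity."""
    vmax_hit = any(np.max(np.abs(p.velocity)) >= config.v_max for p in swarm.particles)
    return vmax_hit and diversity(swarm) < config.diversity_threshold


def reset_swarm(swarm: Swarm, rng: np.random.Generator, config: PSOConfig) -> Swarm:
    """Redraw velocities; rebuild positions from {x_pb, x_sb, random bit} with
    probabilities (0.25, 0.25, 0.5). Personal and global bests are preserved."""
    for p in swarm.particles:
        D = p.position.size
        p.velocity = rng.uniform(-config.v_max, config.v_max, size=D)
        choice = rng.uniform(size=D)
        random_bits = (rng.uniform(size=D) < 0.5).astype(np.int8)
        bits = np.where(
            choice < 0.25,
            p.best_position,
            np.where(choice < 0.5, swarm.best_position, random_bits),
        ).astype(np.int8)
        p.position = _repair_all_zero(bits, None, rng)
    return swarm


def run_pso(
    dataset: SpectraDataset, fitness, config: PSOConfig
) -> tuple[FeatureMask, list[float]]:
    """Full binary-PSO wavelength search.

    ``fitness`` is a callable (FeatureMask, SpectraDataset) -> float, larger
    is better (see :func:`make_subset_fitness`). Returns the best mask found
    and the per-iteration global-best fitness history (monotone by elitism).
    All randomness flows from ``config.seed``."""
    if dataset.n_spectra == 0:
        raise ValueError("dataset is empty")
    D = dataset.n_channels
    rng = np.random.default_rng(config.seed)
    swarm = init_swarm(config, D, rng, fitness=fitness, dataset=dataset)
    history = [swarm.best_fitness]
    for _ in range(config.n_iterations):
        for p in swarm.particles:
            update_velocity(p, swarm.best_position, config, rng)
            update_position(p, rng, config)
            f = fitness(FeatureMask(p.position), dataset)
            update_personal_best(p, f)
        update_global_best(swarm)
        if config.reset_enabled and detect_premature_convergence(swarm, config):
            reset_swarm(swarm, rng, config)
        swarm.iteration += 1
        history.append(swarm.best_fitness)
    return FeatureMask(swarm.best_position), history


def exhaustive_best_subset(dataset: SpectraDataset, fitness) -> FeatureMask:
    """Brute-force oracle: evaluate all 2^D - 1 non-empty masks (D <= 16).

    Masks are enumerated in increasing integer order with channel 0 as the
    least-significant bit; strict improvement keeps the first of any tied
    group, so ties resolve to the smallest selected-channel indices (a
    size-only objective returns the channel-0 singleton)."""
    D = dataset.n_channels
    if D > 16:
        raise ValueError("exhaustive search is limited to D <= 16 channels")
    best_mask, best_f = None, float("-inf")
    for code in range(1, 2**D):
        bits = np.array([(code >> j) & 1 for j in range(D)], dtype=np.int8)
        f = fitness(FeatureMask(bits), dataset)
        if f > best_f:
            best_f, best_mask = f, bits
    return FeatureMask(best_mask)
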