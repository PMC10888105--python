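"""Particle swarm optimization of simplex-constrained ensemble weights.

Each particle is a candidate weight vector ``beta`` on the probability
simplex.  Velocities and positions follow the classic update

    v' = w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)
    x' = x + v'

with inertia ``w``, cognitive/social coefficients ``c1``/``c2`` and fresh
uniform draws ``r1``/``r2`` per dimension per update.  After every move a
position is repaired back onto the simplex (clip negatives, renormalize).
The fitness is the multiclass log loss of the weighted ensemble.

The swarm is seeded deterministically at the M simplex corners plus the
uniform vector before random initialization, which makes the optimized
ensemble's loss provably no worse than the best single model's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble import PredictionSet, WeightVector, log_loss, validate_labels
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSOConfig:
    """Hyperparameters of the swarm.

    Defaults follow the reference schedule for this problem: 100 particles,
    1000 iterations, inertia 0.7 and cognitive/social coefficients 1.5.
    ``v_max`` caps per-dimension speed (weights live in [0, 1], so a cap of
    0.2 prevents overshoot oscillation across the simplex).  ``patience``
    optionally stops early after that many iterations without improvement
    of the global best; by default the full schedule runs.
    """

    n_particles: int = 100
    max_iterations: int = 1000
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    v_max: float = 0.2
    seed: int = 0
    eps: float = 1e-15
    patience: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.inertia <= 1:
            raise ValidationError(f"inertia must be in (0, 1], got {self.inertia}")
        if self.cognitive <= 0 or self.social <= 0:
            raise ValidationError("cognitive and social coefficients must be positive")
        if self.n_particles < 2:
            raise ValidationError(f"need at least 2 particles, got {self.n_particles}")
        if self.v_max <= 0:
            raise ValidationError(f"v_max must be positive, got {self.v_max}")
        if self.max_iterations < 0:
            raise ValidationError("max_iterations must be non-negative")
        if not 0 < self.eps < 0.5:
            raise ValidationError(f"eps must be in (0, 0.5), got {self.eps}")
        if self.patience is not None and self.patience < 1:
            raise ValidationError("patience must be a positive count or None")


@dataclass
class SwarmState:
    """Positions, velocities and bests of the whole swarm, stored as arrays.

    ``positions``/``velocities``/``pbest_positions`` have shape (P, M);
    ``pbest_losses`` has shape (P,).  ``rng`` carries the generator so a
    state can be advanced reproducibly.
    """

    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_losses: np.ndarray
    gbest_position: np.ndarray
    gbest_loss: float
    iteration: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)


def repair_simplex(raw: np.ndarray) -> np.ndarray:
    """Project raw weights back onto the simplex: clip negatives, L1-normalize.

    Works on a single vector or a (P, M) batch.  A vector whose entries all
    clip to zero maps to the uniform vector.  Idempotent on feasible input.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValidationError("non-finite weight entries cannot be repaired")
    clipped = np.clip(raw, 0.0, None)
    sums = clipped.sum(axis=-1, keepdims=True)
    m = raw.shape[-1]
    uniform = np.full(m, 1.0 / m)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, clipped / np.where(sums > 0, sums, 1.0), uniform)
    return out


def update_velocity(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    cfg: PSOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One velocity update, vectorized over a swarm or a single particle.

    r1 and r2 are drawn fresh per dimension per call from U(0, 1); the
    result is clamped to [-v_max, v_max] per dimension.
    """
    r1 = rng.uniform(size=np.shape(position))
    r2 = rng.uniform(size=np.shape(position))
    v_new = (
        cfg.inertia * velocity
        + cfg.cognitive * r1 * (pbest - position)
        + cfg.social * r2 * (gbest - position)
    )
    return np.clip(v_new, -cfg.v_max, cfg.v_max)


def update_position(position: np.ndarray, velocity: np.ndarray) -> np.ndarray:
    """Step ``x + v`` followed by simplex repair."""
    return repair_simplex(position + velocity)


def _true_class_probs(preds: PredictionSet, labels: np.ndarray) -> np.ndarray:
    """(M, N) matrix of each model's probability on the true class."""
    y = validate_labels(labels, preds.n_classes, preds.n_samples)
    return preds.probabilities[:, np.arange(preds.n_samples), y]


def _swarm_losses(positions: np.ndarray, true_probs: np.ndarray, eps: float) -> np.ndarray:
    # ensemble true-class prob per sample is linear in the weights, so the
    # whole swarm evaluates as one (P, M) @ (M, N) product
    p_true = positions @ true_probs
    return -np.mean(np.log(np.clip(p_true, eps, 1.0 - eps)), axis=1)


def init_swarm(preds: PredictionSet, labels: np.ndarray, cfg: PSOConfig) -> SwarmState:
    """Initialize the swarm: M corner particles, one uniform, rest Dirichlet.

    Corners guarantee every single model is evaluated, so the global best
    starts at least as good as the best individual model.  Velocities start
    at zero; personal bests are the initial positions.
    """
    m = preds.n_models
    if cfg.n_particles < m + 1:
        raise ValidationError(
            f"n_particles={cfg.n_particles} too small for M={m} models: "
            f"need at least M+1={m + 1} to seed corners plus the uniform vector"
        )
    rng = np.random.default_rng(cfg.seed)
    positions = np.empty((cfg.n_particles, m))
    positions[:m] = np.eye(m)
    positions[m] = 1.0 / m
    n_random = cfg.n_particles - m - 1
    if n_random:
        positions[m + 1:] = rng.dirichlet(np.ones(m), size=n_random)
    velocities = np.zeros_like(positions)
    true_probs = _true_class_probs(preds, labels)
    losses = _swarm_losses(positions, true_probs, cfg.eps)
    best = int(np.argmin(losses))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_losses=losses.copy(),
        gbest_position=positions[best].copy(),
        gbest_loss=float(losses[best]),
        iteration=0,
        rng=rng,
    )


def step_swarm(state: SwarmState, true_probs: np.ndarray, cfg: PSOConfig) -> SwarmState:
    """One full sweep: evaluate, update bests, then move and repair in place."""
    losses = _swarm_losses(state.positions, true_probs, cfg.eps)
    improved = losses < state.pbest_losses
    state.pbest_losses[improved] = losses[improved]
    state.pbest_positions[improved] = state.positions[improved]
    best = int(np.argmin(state.pbest_losses))
    if state.pbest_losses[best] < state.gbest_loss:
        state.gbest_loss = float(state.pbest_losses[best])
        state.gbest_position = state.pbest_positions[best].copy()
    state.velocities = update_velocity(
        state.velocities,
        state.positions,
        state.pbest_positions,
        state.gbest_position,
        cfg,
        state.rng,
    )
    state.positions = update_position(state.positions, state.velocities)
    state.iteration += 1
    return state


def optimize_weights(
    preds: PredictionSet,
    labels: np.ndarray,
    cfg: PSOConfig | None = None,
) -> tuple[WeightVector, float, np.ndarray]:
    """Fit simplex-constrained ensemble weights by PSO.

    Returns the global best weight vector, its log loss, and the
    per-iteration global-best-loss trace (entry 0 is the loss after
    initialization).  The trace is non-increasing, and the returned loss
    never exceeds the best single model's loss thanks to corner seeding.
    Fixed seed gives bit-identical output.
    """
    cfg = cfg or PSOConfig()
    if preds.n_samples == 0 or preds.n_models == 0:
        raise ValidationError("empty prediction set")
    true_probs = _true_class_probs(preds, labels)
    state = init_swarm(preds, labels, cfg)
    trace = [state.gbest_loss]
    stale = 0
    for it in range(cfg.max_iterations):
        prev = state.gbest_loss
        step_swarm(state, true_probs, cfg)
        trace.append(state.gbest_loss)
        level = logging.INFO if (it + 1) % 50 == 0 else logging.DEBUG
        logger.log(level, "iteration %d: global best loss %.8f", it + 1, state.gbest_loss)
        if cfg.patience is not None:
            stale = 0 if state.gbest_loss < prev else stale + 1
            if stale >= cfg.patience:
                logger.info("early stop after %d stale iterations", stale)
                break
    return WeightVector(state.gbest_position), state.gbest_loss, np.asarray(trace)


def _lattice(m: int, k: int) -> np.ndarray:
    """All compositions of k into m parts, lexicographic by first part ascending."""
    if m == 1:
        return np.array([[k]])
    rows = []
    for first in range(k + 1):
        rest = _lattice(m - 1, k - first)
        rows.append(np.column_stack([np.full(len(rest), first), rest]))
    return np.vstack(rows)


def grid_oracle(
    preds: PredictionSet,
    labels: np.ndarray,
    step: float,
    eps: float = 1e-15,
) -> tuple[WeightVector, float]:
    """Brute-force minimizer over the simplex lattice with the given step.

    Test-scale verifier, independent of the swarm: enumerates every weight
    vector whose entries are multiples of ``step`` and returns the one with
    the lowest ensemble log loss.  Ties keep the earliest lattice point in
    first-weight-ascending order.  Restricted to M <= 4.
    """
    m = preds.n_models
    if m > 4:
        raise ValidationError(f"grid oracle supports M <= 4, got M={m}")
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9 or k < 1:
        raise ValidationError(f"step {step} must evenly divide 1")
    true_probs = _true_class_probs(preds, labels)
    points = _lattice(m, k) / k
    losses = _swarm_losses(points, true_probs, eps)
    best = int(np.argmin(losses))  # argmin keeps the first of tied minima
    return WeightVector(points[best]), float(losses[best])


def single_model_losses(preds: PredictionSet, labels: np.ndarray, eps: float = 1e-15) -> np.ndarray:
    """Log loss of each individual model, in model order."""
    return np.array(
        [log_loss(labels, preds.probabilities[i], eps) for i in range(preds.n_models)]
    )
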