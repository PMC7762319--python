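"""Particle-swarm search over MLP architectures and hyperparameters.

The mixed integer/categorical architecture space (layer widths, transfer
functions, trainer, learning-function tag) is relaxed to a continuous box;
particles fly in that box under the standard inertia + cognitive + social
velocity rule and are decoded to valid architectures by rounding (integer
dimensions) or flooring onto a vocabulary index (categorical dimensions).
Fitness of a particle is the validation MSE of its decoded network trained
on the training split; untrainable configurations score +inf instead of
aborting the search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, NirTasteError
from .mlp import (
    LEARN_FUNCTIONS,
    TRAIN_FUNCTIONS,
    TRANSFER_FUNCTIONS,
    MLPArchitecture,
    TrainedMLP,
    TrainingConfig,
    init_mlp,
    predict,
    train_mlp,
)

__all__ = [
    "HyperparamSpace",
    "PSOConfig",
    "Particle",
    "Swarm",
    "TuningResult",
    "encode_architecture",
    "decode_position",
    "pso_step",
    "pso_minimize",
    "tune_ann",
]

#: transfers searchable by default: hard-threshold units have zero gradient
#: almost everywhere, so they are available for evaluation but not searched.
DEFAULT_SEARCH_TRANSFERS = tuple(
    name for name, tf in TRANSFER_FUNCTIONS.items() if tf.smooth
)


@dataclass(frozen=True)
class HyperparamSpace:
    """Search box: 1-3 hidden layers, widths 1-25 / 0-25, named vocabularies."""

    transfers: tuple[str, ...] = DEFAULT_SEARCH_TRANSFERS
    trainers: tuple[str, ...] = TRAIN_FUNCTIONS
    learn_fns: tuple[str, ...] = LEARN_FUNCTIONS
    max_layers: int = 3
    first_layer_bounds: tuple[int, int] = (1, 25)
    other_layer_bounds: tuple[int, int] = (0, 25)

    def __post_init__(self) -> None:
        for name in self.transfers:
            if name not in TRANSFER_FUNCTIONS:
                raise ConfigError(f"unknown transfer {name!r} in space")
        for name in self.trainers:
            if name not in TRAIN_FUNCTIONS:
                raise ConfigError(f"unsupported trainer {name!r} in space")
        if self.max_layers != 3:
            raise ConfigError("the search space is defined for up to 3 hidden layers")

    @property
    def n_dims(self) -> int:
        # widths (3) + transfer per layer (3) + trainer + learn_fn
        return 8

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) of the continuous relaxation box."""
        eps = 1e-9
        lower = np.array(
            [self.first_layer_bounds[0], self.other_layer_bounds[0], self.other_layer_bounds[0],
             0.0, 0.0, 0.0, 0.0, 0.0]
        )
        upper = np.array(
            [self.first_layer_bounds[1], self.other_layer_bounds[1], self.other_layer_bounds[1],
             len(self.transfers) - eps, len(self.transfers) - eps, len(self.transfers) - eps,
             len(self.trainers) - eps, len(self.learn_fns) - eps]
        )
        return lower, upper


def decode_position(position: np.ndarray, space: HyperparamSpace) -> MLPArchitecture:
    """Clamp + round/floor a continuous position into a valid architecture."""
    lower, upper = space.bounds()
    x = np.clip(np.asarray(position, dtype=float), lower, upper)
    widths = [int(round(x[0])), int(round(x[1])), int(round(x[2]))]
    widths[0] = max(1, widths[0])
    if widths[1] == 0:
        widths[2] = 0
    while len(widths) > 1 and widths[-1] == 0:
        widths.pop()  # canonical form: no trailing absent layers
    t_idx = [min(int(np.floor(x[3 + i])), len(space.transfers) - 1) for i in range(len(widths))]
    transfers = tuple(space.transfers[i] for i in t_idx)
    trainer = space.trainers[min(int(np.floor(x[6])), len(space.trainers) - 1)]
    learn = space.learn_fns[min(int(np.floor(x[7])), len(space.learn_fns) - 1)]
    return MLPArchitecture(
        neurons=tuple(widths), transfer=transfers, train_fn=trainer, learn_fn=learn
    )


def encode_architecture(arch: MLPArchitecture, space: HyperparamSpace) -> np.ndarray:
    """Inverse of :func:`decode_position` for valid architectures (exact round-trip)."""
    widths = list(arch.neurons) + [0] * (3 - len(arch.neurons))
    transfers = list(arch.transfer) + [arch.transfer[-1]] * (3 - len(arch.transfer))
    try:
        t_idx = [space.transfers.index(t) for t in transfers]
        trainer_idx = space.trainers.index(arch.train_fn)
        learn_idx = space.learn_fns.index(arch.learn_fn)
    except ValueError as exc:
        raise ConfigError(f"architecture uses a name outside the search space: {exc}") from exc
    return np.array(
        [widths[0], widths[1], widths[2],
         t_idx[0] + 0.5, t_idx[1] + 0.5, t_idx[2] + 0.5,
         trainer_idx + 0.5, learn_idx + 0.5]
    )


@dataclass(frozen=True)
class PSOConfig:
    """Standard PSO constants (near-constriction defaults)."""

    swarm_size: int = 20
    iterations: int = 30
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    velocity_clamp: float = 0.2  # fraction of the box width
    fitness_reps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inertia <= 1:
            raise ConfigError("inertia must be in (0, 1]")
        if self.cognitive <= 0 or self.social <= 0:
            raise ConfigError("cognitive/social factors must be positive")
        if self.swarm_size < 1 or self.iterations < 1:
            raise ConfigError("swarm_size and iterations must be >= 1")
        if not 0 < self.velocity_clamp <= 1:
            raise ConfigError("velocity_clamp must be in (0, 1]")
        if self.fitness_reps < 1:
            raise ConfigError("fitness_reps must be >= 1")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    fitness: float
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class Swarm:
    particles: list[Particle]
    gbest_position: np.ndarray
    gbest_fitness: float


def _evaluate(f, position, rng):
    try:
        value = float(f(position, rng))
    except NirTasteError as exc:
        warnings.warn(f"particle evaluation failed, scored +inf: {exc}")
        return np.inf
    return value if np.isfinite(value) else np.inf


def init_swarm(
    f,
    lower,
    upper,
    cfg: PSOConfig,
    rng: np.random.Generator,
    warm_start: Sequence[np.ndarray] = (),
) -> Swarm:
    """Random swarm, optionally seeding the first particles at given positions.

    Warm-start positions (e.g. reference architectures) are evaluated like
    any other particle; they only matter if nothing in the random swarm
    beats them on fitness.
    """
    width = upper - lower
    vmax = cfg.velocity_clamp * width
    particles = []
    for i in range(cfg.swarm_size):
        if i < len(warm_start):
            pos = np.clip(np.asarray(warm_start[i], dtype=float), lower, upper)
        else:
            pos = rng.uniform(lower, upper)
        vel = rng.uniform(-vmax, vmax)
        fit = _evaluate(f, pos, rng)
        particles.append(Particle(pos, vel, fit, pos.copy(), fit))
    best = min(particles, key=lambda p: p.pbest_fitness)
    return Swarm(particles, best.pbest_position.copy(), best.pbest_fitness)


def pso_step(
    swarm: Swarm,
    f,
    lower: np.ndarray,
    upper: np.ndarray,
    cfg: PSOConfig,
    rng: np.random.Generator,
) -> Swarm:
    """One synchronous velocity/position update with pbest/gbest refresh."""
    width = upper - lower
    vmax = cfg.velocity_clamp * width
    for p in swarm.particles:
        u1 = rng.uniform(size=p.position.size)
        u2 = rng.uniform(size=p.position.size)
        p.velocity = (
            cfg.inertia * p.velocity
            + cfg.cognitive * u1 * (p.pbest_position - p.position)
            + cfg.social * u2 * (swarm.gbest_position - p.position)
        )
        p.velocity = np.clip(p.velocity, -vmax, vmax)
        p.position = np.clip(p.position + p.velocity, lower, upper)
        p.fitness = _evaluate(f, p.position, rng)
        if p.fitness < p.pbest_fitness:
            p.pbest_fitness = p.fitness
            p.pbest_position = p.position.copy()
            if p.fitness < swarm.gbest_fitness:
                swarm.gbest_fitness = p.fitness
                swarm.gbest_position = p.position.copy()
    return swarm


def pso_minimize(
    f,
    lower: Sequence[float],
    upper: Sequence[float],
    cfg: PSOConfig,
    rng: np.random.Generator | None = None,
    warm_start: Sequence[np.ndarray] = (),
) -> tuple[np.ndarray, float, list[float]]:
    """Minimise ``f(position, rng)`` over a box; returns (x*, f*, gbest history)."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or np.any(lower >= upper):
        raise ConfigError("lower bounds must be elementwise below upper bounds")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    swarm = init_swarm(f, lower, upper, cfg, rng, warm_start=warm_start)
    history = []
    for _ in range(cfg.iterations):
        pso_step(swarm, f, lower, upper, cfg, rng)
        history.append(swarm.gbest_fitness)
    return swarm.gbest_position, swarm.gbest_fitness, history


@dataclass
class TuningResult:
    best_architecture: MLPArchitecture
    best_fitness: float
    history: list[float]
    final_model: TrainedMLP


def tune_ann(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    space: HyperparamSpace | None = None,
    pso_cfg: PSOConfig | None = None,
    train_cfg: TrainingConfig | None = None,
    resplit: bool = True,
) -> TuningResult:
    """PSO search for the architecture minimising validation MSE.

    Each particle decodes to an architecture, which is trained on the
    training rows (``fitness_reps`` restarts averaged) and scored on the
    validation rows.  With ``resplit`` (default) every restart redraws the
    train/validation partition of the pooled tuning rows: early stopping
    already optimises against the validation split, so scoring a fixed
    split would systematically flatter high-capacity architectures.  The
    global best is retrained once more and returned with the gbest history.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    space = space if space is not None else HyperparamSpace()
    pso_cfg = pso_cfg if pso_cfg is not None else PSOConfig()
    train_cfg = train_cfg if train_cfg is not None else TrainingConfig(
        max_epochs=200, val_patience=25
    )
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    pool = np.concatenate([train_idx, val_idx])
    n_train = train_idx.size

    def fitness(position: np.ndarray, rng: np.random.Generator) -> float:
        arch = decode_position(position, space)
        mses = []
        for _ in range(pso_cfg.fitness_reps):
            seed = int(rng.integers(0, 2**31 - 1))
            if resplit:
                perm = np.random.default_rng(seed).permutation(pool)
                tr, va = perm[:n_train], perm[n_train:]
            else:
                tr, va = train_idx, val_idx
            Xt, Xv = X[tr], X[va]
            yt, yv = y[tr], y[va]
            net = train_mlp(init_mlp(arch, X.shape[1], seed=seed), Xt, yt, Xv, yv, train_cfg)
            mses.append(float(np.mean((predict(net, Xv) - yv) ** 2)))
        return float(np.mean(mses))

    # seed the swarm with reference designs: a minimal linear network and
    # the fixed selection-judge network; random particles must beat them
    warm = []
    for ref in (
        MLPArchitecture((1,), ("purelin",), "trainbfg", "learngd"),
        MLPArchitecture((18, 6), ("tansig", "tansig"), "trainrp", "learnk"),
    ):
        try:
            warm.append(encode_architecture(ref, space))
        except ConfigError:
            pass  # reference not representable in a restricted space
    lower, upper = space.bounds()
    rng = np.random.default_rng(pso_cfg.seed)
    best_pos, best_fit, history = pso_minimize(
        fitness, lower, upper, pso_cfg, rng, warm_start=warm
    )
    best_arch = decode_position(best_pos, space)
    final = train_mlp(
        init_mlp(best_arch, X.shape[1], seed=int(rng.integers(0, 2**31 - 1))),
        X[train_idx], y[train_idx], X[val_idx], y[val_idx], train_cfg,
    )
    return TuningResult(best_arch, best_fit, history, final)
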