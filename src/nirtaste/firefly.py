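"""Firefly-algorithm wavelength selection with an ANN brightness function.

A candidate solution is a fixed-size subset of wavelength-grid indices,
carried as a continuous position vector in index space.  Brightness is the
inverse of fitness: fitness is the validation MSE of a small fixed neural
network (or, for oracle work, a deterministic ridge regression) trained on
the candidate's channels, so dimmer fireflies fly towards brighter ones.
The search runs separately for each subset size k and the overall winner is
the best fitness with a parsimony tie-break (a smaller subset wins when it
is within 1% relative fitness of the minimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .data import WavelengthGrid
from .errors import ConfigError, SizeError
from .mlp import MLPArchitecture, TrainingConfig, init_mlp, predict, train_mlp

__all__ = [
    "Candidate",
    "FireflyConfig",
    "SelectionResult",
    "table_ann_spec",
    "make_ann_fitness",
    "make_ridge_fitness",
    "brightness",
    "move_firefly",
    "repair_position",
    "select_wavelengths",
    "exhaustive_select",
]

#: FitnessFn(indices, rng) -> validation MSE (lower is better).
FitnessFn = Callable[[np.ndarray, np.random.Generator], float]


@dataclass
class Candidate:
    """A subset of grid indices with its continuous position and fitness."""

    indices: np.ndarray
    position: np.ndarray
    fitness: float = math.inf


@dataclass(frozen=True)
class FireflyConfig:
    """Swarm hyperparameters.

    ``beta0`` is the attractiveness at zero distance, ``gamma`` the light
    absorption coefficient (distance is Euclidean in index space, so gamma
    should scale like 1/grid_length^2), ``alpha`` the randomisation scale in
    index units decaying by ``alpha_decay`` per iteration.
    """

    population: int = 20
    iterations: int = 50
    beta0: float = 1.0
    gamma: float | None = None  # default 1/len(grid)^2, filled at run time
    alpha: float = 0.5
    alpha_decay: float = 0.97
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    fitness_reps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ConfigError("population must be >= 2")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        for name, v in (("beta0", self.beta0), ("alpha", self.alpha)):
            if not v > 0:
                raise ConfigError(f"{name} must be positive")
        if self.gamma is not None and not self.gamma > 0:
            raise ConfigError("gamma must be positive")
        if not self.k_range or any(k < 1 or k > 20 for k in self.k_range):
            raise ConfigError("k_range entries must lie in [1, 20]")
        if self.fitness_reps < 1:
            raise ConfigError("fitness_reps must be >= 1")


@dataclass
class SelectionResult:
    """Winner of the per-k searches plus bookkeeping."""

    best_per_k: dict[int, Candidate]
    history_per_k: dict[int, list[float]]
    selected_k: int
    wavelengths_nm: np.ndarray
    fitness: float

    @property
    def history(self) -> list[float]:
        """Best-so-far fitness per iteration for the winning k."""
        return self.history_per_k[self.selected_k]

    @property
    def indices(self) -> np.ndarray:
        return self.best_per_k[self.selected_k].indices


def table_ann_spec() -> MLPArchitecture:
    """The fixed two-layer 18/6 tansig network used as the selection judge."""
    return MLPArchitecture(
        neurons=(18, 6), transfer=("tansig", "tansig"), train_fn="trainrp", learn_fn="learnk"
    )


# ---------------------------------------------------------------------------
# Fitness functions
# ---------------------------------------------------------------------------

def make_ann_fitness(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    ann_spec: MLPArchitecture | None = None,
    train_cfg: TrainingConfig | None = None,
    fitness_reps: int = 2,
) -> FitnessFn:
    """Validation-MSE fitness from training the judge ANN on the candidate.

    The MSE is averaged over ``fitness_reps`` restarts whose seeds come
    from the generator passed at call time, damping initialisation noise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    spec = ann_spec if ann_spec is not None else table_ann_spec()
    cfg = train_cfg if train_cfg is not None else TrainingConfig(max_epochs=150, val_patience=20)

    def fitness(indices: np.ndarray, rng: np.random.Generator) -> float:
        cols = np.asarray(indices, dtype=int)
        Xt, Xv = X[np.ix_(train_idx, cols)], X[np.ix_(val_idx, cols)]
        yt, yv = y[train_idx], y[val_idx]
        mses = []
        for _ in range(fitness_reps):
            seed = int(rng.integers(0, 2**31 - 1))
            net = train_mlp(init_mlp(spec, cols.size, seed=seed), Xt, yt, Xv, yv, cfg)
            mses.append(float(np.mean((predict(net, Xv) - yv) ** 2)))
        return float(np.mean(mses))

    return fitness


def make_ridge_fitness(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    alpha: float = 1e-3,
) -> FitnessFn:
    """Deterministic linear fitness: validation MSE of a ridge regression.

    Used as the oracle-friendly stand-in for the ANN judge; it ignores the
    rng argument entirely, so repeated evaluation is exactly reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    def fitness(indices: np.ndarray, rng: np.random.Generator) -> float:
        cols = np.asarray(indices, dtype=int)
        Xt, Xv = X[np.ix_(train_idx, cols)], X[np.ix_(val_idx, cols)]
        yt, yv = y[train_idx], y[val_idx]
        mu, sd = Xt.mean(axis=0), Xt.std(axis=0)
        sd[sd == 0] = 1.0
        Zt, Zv = (Xt - mu) / sd, (Xv - mu) / sd
        ym = yt.mean()
        A = Zt.T @ Zt + alpha * np.eye(cols.size)
        beta = np.linalg.solve(A, Zt.T @ (yt - ym))
        return float(np.mean((Zv @ beta + ym - yv) ** 2))

    return fitness


def brightness(
    candidate: Candidate,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    n_channels: int | None = None,
) -> float:
    """Evaluate and store a candidate's fitness (lower MSE = brighter)."""
    if n_channels is not None and candidate.indices.size > n_channels:
        raise ConfigError(
            f"candidate size {candidate.indices.size} exceeds channel count {n_channels}"
        )
    candidate.fitness = float(fitness_fn(candidate.indices, rng))
    return candidate.fitness


# ---------------------------------------------------------------------------
# Movement and repair
# ---------------------------------------------------------------------------

def repair_position(position: np.ndarray, n_channels: int) -> np.ndarray:
    """Round to grid indices, clamp, and resolve duplicates to nearest free.

    Guarantees k distinct in-bounds indices for any real-valued position.
    """
    raw = np.clip(np.rint(position).astype(int), 0, n_channels - 1)
    if raw.size > n_channels:
        raise ConfigError(f"k={raw.size} exceeds the {n_channels}-channel grid")
    used: set[int] = set()
    out = np.empty_like(raw)
    for slot, idx in enumerate(raw):
        if idx not in used:
            out[slot] = idx
            used.add(idx)
            continue
        for offset in range(1, n_channels):
            for cand in (idx - offset, idx + offset):
                if 0 <= cand < n_channels and cand not in used:
                    out[slot] = cand
                    used.add(cand)
                    break
            else:
                continue
            break
    return np.sort(out)


def move_firefly(
    i: Candidate,
    j: Candidate,
    cfg: FireflyConfig,
    rng: np.random.Generator,
    n_channels: int,
    alpha: float | None = None,
    gamma: float | None = None,
) -> Candidate:
    """Standard attraction move of firefly i towards a brighter firefly j.

    x_i <- x_i + beta0 * exp(-gamma r^2) (x_j - x_i) + alpha (u - 0.5)
    with r the Euclidean distance in index space, then round-and-repair.
    """
    a = cfg.alpha if alpha is None else alpha
    g = gamma if gamma is not None else (
        cfg.gamma if cfg.gamma is not None else 1.0 / n_channels**2
    )
    r2 = float(np.sum((i.position - j.position) ** 2))
    beta = cfg.beta0 * math.exp(-g * r2)
    u = rng.uniform(size=i.position.size)
    position = i.position + beta * (j.position - i.position) + a * (u - 0.5)
    position = np.clip(position, 0.0, n_channels - 1.0)
    return Candidate(indices=repair_position(position, n_channels), position=position)


# ---------------------------------------------------------------------------
# Search drivers
# ---------------------------------------------------------------------------

def _fa_single_k(
    k: int,
    n_channels: int,
    fitness_fn: FitnessFn,
    cfg: FireflyConfig,
    rng: np.random.Generator,
) -> tuple[Candidate, list[float]]:
    swarm: list[Candidate] = []
    for _ in range(cfg.population):
        idx = np.sort(rng.choice(n_channels, size=k, replace=False))
        cand = Candidate(indices=idx, position=idx.astype(float))
        brightness(cand, fitness_fn, rng, n_channels)
        swarm.append(cand)
    best = min(swarm, key=lambda c: c.fitness)
    best = Candidate(best.indices.copy(), best.position.copy(), best.fitness)
    history = []
    alpha = cfg.alpha
    for _ in range(cfg.iterations):
        for ii in range(cfg.population):
            moved = False
            for jj in range(cfg.population):
                if swarm[jj].fitness < swarm[ii].fitness:
                    swarm[ii] = Candidate(
                        indices=swarm[ii].indices,
                        position=move_firefly(
                            swarm[ii], swarm[jj], cfg, rng, n_channels, alpha=alpha
                        ).position,
                        fitness=swarm[ii].fitness,
                    )
                    moved = True
            if moved:
                swarm[ii].indices = repair_position(swarm[ii].position, n_channels)
                brightness(swarm[ii], fitness_fn, rng, n_channels)
            if swarm[ii].fitness < best.fitness:
                best = Candidate(
                    swarm[ii].indices.copy(), swarm[ii].position.copy(), swarm[ii].fitness
                )
        # the brightest firefly performs coordinate-wise random walks: one
        # coordinate is perturbed per walk so found channels are retained.
        # Half the walks are local (scale alpha), half resample the
        # coordinate uniformly so stray coordinates can cross the grid.
        bi = int(np.argmin([c.fitness for c in swarm]))
        for coord in list(range(k)) * 3:
            walk_pos = swarm[bi].position.copy()
            if rng.uniform() < 0.5:
                walk_pos[coord] = rng.uniform(0, n_channels - 1)
            else:
                walk_pos[coord] = np.clip(
                    walk_pos[coord] + alpha * (rng.uniform() - 0.5), 0, n_channels - 1
                )
            walker = Candidate(indices=repair_position(walk_pos, n_channels), position=walk_pos)
            brightness(walker, fitness_fn, rng, n_channels)
            if walker.fitness < swarm[bi].fitness:
                swarm[bi] = walker
            if walker.fitness < best.fitness:
                best = Candidate(walker.indices.copy(), walker.position.copy(), walker.fitness)
        history.append(best.fitness)
        alpha *= cfg.alpha_decay
    return best, history


def select_wavelengths(
    X: np.ndarray,
    y: np.ndarray,
    grid: WavelengthGrid,
    cfg: FireflyConfig,
    fitness_fn: FitnessFn | None = None,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
) -> SelectionResult:
    """Run the firefly search for every k in ``cfg.k_range``.

    When no fitness function is supplied, the production ANN judge is built
    from the given train/validation row indices (required in that case).
    The overall winner is the lowest fitness across k, with parsimony:
    among candidates within 1% relative fitness of the minimum, the
    smallest k wins.
    """
    n_channels = len(grid)
    if fitness_fn is None:
        if train_idx is None or val_idx is None:
            raise ConfigError("train_idx/val_idx required to build the ANN fitness")
        fitness_fn = make_ann_fitness(
            X, y, train_idx, val_idx, fitness_reps=cfg.fitness_reps
        )
    if max(cfg.k_range) > n_channels:
        raise ConfigError(
            f"k_range max {max(cfg.k_range)} exceeds {n_channels} channels"
        )
    rng = np.random.default_rng(cfg.seed)
    best_per_k: dict[int, Candidate] = {}
    history_per_k: dict[int, list[float]] = {}
    for k in sorted(set(cfg.k_range)):
        best, history = _fa_single_k(k, n_channels, fitness_fn, cfg, rng)
        best_per_k[k] = best
        history_per_k[k] = history
    fmin = min(c.fitness for c in best_per_k.values())
    tol = abs(fmin) * 0.01
    selected_k = min(k for k, c in best_per_k.items() if c.fitness <= fmin + tol)
    winner = best_per_k[selected_k]
    return SelectionResult(
        best_per_k=best_per_k,
        history_per_k=history_per_k,
        selected_k=selected_k,
        wavelengths_nm=grid.values[winner.indices],
        fitness=winner.fitness,
    )


def exhaustive_select(
    X: np.ndarray,
    y: np.ndarray,
    grid: WavelengthGrid,
    k: int,
    fitness_fn: FitnessFn,
    budget: int = 100_000,
    seed: int = 0,
) -> Candidate:
    """Enumerate every k-subset and return the global fitness optimum."""
    n_channels = len(grid)
    total = math.comb(n_channels, k)
    if total > budget:
        raise SizeError(f"C({n_channels},{k}) = {total} exceeds the budget of {budget}")
    rng = np.random.default_rng(seed)
    best: Candidate | None = None
    for combo in combinations(range(n_channels), k):
        idx = np.array(combo, dtype=int)
        f = float(fitness_fn(idx, rng))
        if best is None or f < best.fitness:
            best = Candidate(indices=idx, position=idx.astype(float), fitness=f)
    assert best is not None
    return best
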