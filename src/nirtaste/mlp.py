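"""From-scratch multilayer perceptron regression.

The network vocabulary mirrors the classic neural-network toolbox naming
used throughout shallow-ANN chemometrics: elementwise *transfer functions*
(``tansig``, ``logsig``, ``purelin``, ...), batch *training functions*
(``traingd``, ``trainrp``, ``trainbfg``, ...) and *weight/bias learning
function* names, the last of which are carried as metadata only (batch
trainers do not consult them).

Architecture: one to three hidden layers of 1-25 neurons each, followed by
a single linear output unit.  Inputs and the target are z-score
standardised internally using training-split statistics; predictions are
returned on the original scale.  Training minimises mean squared error on
the standardised target with early stopping on a validation split.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigError, RegistryError, ShapeError, TrainingError

__all__ = [
    "TRANSFER_FUNCTIONS",
    "TRAIN_FUNCTIONS",
    "LEARN_FUNCTIONS",
    "transfer_apply",
    "MLPArchitecture",
    "TrainingConfig",
    "TrainedMLP",
    "init_mlp",
    "train_mlp",
    "predict",
]


# ---------------------------------------------------------------------------
# Transfer-function registry.  Each entry: forward(n) -> a and a backward
# rule mapping (n, a, upstream grad wrt a) -> grad wrt n.
# ---------------------------------------------------------------------------

class Transfer:
    def __init__(self, name: str, forward: Callable, backward: Callable, smooth: bool = True):
        self.name = name
        self.forward = forward
        self.backward = backward
        #: False for hard-threshold transfers whose derivative is 0 a.e.
        self.smooth = smooth


def _elem(df: Callable) -> Callable:
    def backward(n, a, g):
        return g * df(n, a)
    return backward


def _radbasn_forward(n):
    r = np.exp(-np.square(n))
    s = r.sum(axis=-1, keepdims=True)
    return r / np.maximum(s, 1e-300)


def _radbasn_backward(n, a, g):
    # a_i = r_i / sum(r); dr_i/dn_i = -2 n_i r_i.  Chain rule over the
    # normalisation couples all units of the layer.
    rprime_over_s = -2.0 * n * a
    dot = np.sum(g * a, axis=-1, keepdims=True)
    return rprime_over_s * (g - dot)


TRANSFER_FUNCTIONS: dict[str, Transfer] = {
    "tansig": Transfer("tansig", np.tanh, _elem(lambda n, a: 1.0 - a * a)),
    "logsig": Transfer(
        "logsig",
        lambda n: 1.0 / (1.0 + np.exp(-n)),
        _elem(lambda n, a: a * (1.0 - a)),
    ),
    "purelin": Transfer("purelin", lambda n: n, _elem(lambda n, a: np.ones_like(n))),
    "poslin": Transfer(
        "poslin", lambda n: np.maximum(0.0, n), _elem(lambda n, a: (n > 0).astype(float))
    ),
    "satlin": Transfer(
        "satlin",
        lambda n: np.clip(n, 0.0, 1.0),
        _elem(lambda n, a: ((n > 0) & (n < 1)).astype(float)),
    ),
    "satlins": Transfer(
        "satlins",
        lambda n: np.clip(n, -1.0, 1.0),
        _elem(lambda n, a: ((n > -1) & (n < 1)).astype(float)),
    ),
    "hardlim": Transfer(
        "hardlim",
        lambda n: (n >= 0).astype(float),
        _elem(lambda n, a: np.zeros_like(n)),
        smooth=False,
    ),
    "hardlims": Transfer(
        "hardlims",
        lambda n: np.where(n >= 0, 1.0, -1.0),
        _elem(lambda n, a: np.zeros_like(n)),
        smooth=False,
    ),
    "tribas": Transfer(
        "tribas",
        lambda n: np.maximum(0.0, 1.0 - np.abs(n)),
        _elem(lambda n, a: np.where(np.abs(n) < 1, -np.sign(n), 0.0)),
    ),
    "radbas": Transfer(
        "radbas", lambda n: np.exp(-np.square(n)), _elem(lambda n, a: -2.0 * n * a)
    ),
    "radbasn": Transfer("radbasn", _radbasn_forward, _radbasn_backward),
    "netinv": Transfer(
        "netinv",
        lambda n: 1.0 / np.where(n == 0, np.finfo(float).tiny, n),
        _elem(lambda n, a: -a * a),
    ),
    "elliotsig": Transfer(
        "elliotsig",
        lambda n: n / (1.0 + np.abs(n)),
        _elem(lambda n, a: 1.0 / np.square(1.0 + np.abs(n))),
    ),
}

#: Batch trainers implemented by :func:`train_mlp`.
TRAIN_FUNCTIONS = ("traingd", "traingdm", "trainrp", "trainbfg", "trainbr")

#: Weight/bias learning-function names accepted as architecture metadata.
LEARN_FUNCTIONS = (
    "learncon", "learngd", "learngdm", "learnh", "learnhd", "learnis",
    "learnk", "learnlv1", "learnlv2", "learnos", "learnp", "learnpn",
    "learnsom", "learnsomb", "learnwh",
)


def transfer_apply(name: str, x):
    """Evaluate the named transfer function elementwise on ``x``."""
    if name not in TRANSFER_FUNCTIONS:
        raise RegistryError(
            f"unknown transfer function {name!r}; supported: {sorted(TRANSFER_FUNCTIONS)}"
        )
    x = np.asarray(x, dtype=float)
    if name == "radbasn" and x.ndim == 0:
        x = x.reshape(1)
        return float(TRANSFER_FUNCTIONS[name].forward(x)[0])
    out = TRANSFER_FUNCTIONS[name].forward(x)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Architecture / configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPArchitecture:
    """Hidden-layer sizes plus the named transfer/trainer/learning functions.

    ``neurons`` lists the hidden layers only (a linear output unit is always
    appended); a zero entry means "layer absent" and forces all deeper
    entries to zero as well.
    """

    neurons: tuple[int, ...]
    transfer: tuple[str, ...]
    train_fn: str = "trainrp"
    learn_fn: str = "learngd"

    def __post_init__(self) -> None:
        neurons = tuple(int(n) for n in self.neurons)
        transfer = tuple(self.transfer)
        object.__setattr__(self, "neurons", neurons)
        object.__setattr__(self, "transfer", transfer)
        if not 1 <= len(neurons) <= 3:
            raise ConfigError(f"1-3 hidden layers required, got {len(neurons)}")
        if len(transfer) != len(neurons):
            raise ConfigError("one transfer function per hidden layer required")
        if not 1 <= neurons[0] <= 25:
            raise ConfigError(f"first layer must have 1-25 neurons, got {neurons[0]}")
        seen_zero = False
        for k, n in enumerate(neurons):
            if k > 0 and not 0 <= n <= 25:
                raise ConfigError(f"layer {k + 1} must have 0-25 neurons, got {n}")
            if seen_zero and n != 0:
                raise ConfigError("a zero-width layer cannot be followed by a non-empty layer")
            if n == 0:
                seen_zero = True
        for name in transfer:
            if name not in TRANSFER_FUNCTIONS:
                raise RegistryError(
                    f"unknown transfer function {name!r}; supported: "
                    f"{sorted(TRANSFER_FUNCTIONS)}"
                )
        if self.train_fn not in TRAIN_FUNCTIONS:
            raise RegistryError(
                f"unsupported training function {self.train_fn!r}; "
                f"implemented: {TRAIN_FUNCTIONS}"
            )
        if self.learn_fn not in LEARN_FUNCTIONS:
            raise RegistryError(
                f"unknown learning function {self.learn_fn!r}; known: {LEARN_FUNCTIONS}"
            )

    @property
    def active_neurons(self) -> tuple[int, ...]:
        """Hidden-layer sizes with trailing zero (absent) layers dropped."""
        return tuple(n for n in self.neurons if n > 0)

    @property
    def active_transfer(self) -> tuple[str, ...]:
        return self.transfer[: len(self.active_neurons)]

    def to_dict(self) -> dict:
        return {
            "neurons": list(self.neurons),
            "transfer": list(self.transfer),
            "train_fn": self.train_fn,
            "learn_fn": self.learn_fn,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPArchitecture":
        return cls(
            neurons=tuple(d["neurons"]),
            transfer=tuple(d["transfer"]),
            train_fn=d["train_fn"],
            learn_fn=d["learn_fn"],
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters shared by all batch trainers.

    Rprop constants follow the usual (Delta0, Delta_min, Delta_max,
    eta_plus, eta_minus) convention; ``l2_grid`` is the penalty grid that
    the regularised trainer (``trainbr``) selects from on the validation
    split.
    """

    max_epochs: int = 1000
    val_patience: int = 30
    learning_rate: float = 0.05
    momentum: float = 0.9
    rprop_delta0: float = 0.07
    rprop_delta_min: float = 1e-6
    rprop_delta_max: float = 50.0
    rprop_eta_plus: float = 1.2
    rprop_eta_minus: float = 0.5
    l2_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "max_epochs": self.max_epochs,
            "val_patience": self.val_patience,
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "rprop_delta0": self.rprop_delta0,
            "rprop_delta_min": self.rprop_delta_min,
            "rprop_delta_max": self.rprop_delta_max,
            "rprop_eta_plus": self.rprop_eta_plus,
            "rprop_eta_minus": self.rprop_eta_minus,
        }
        for key, value in positive.items():
            if key == "max_epochs":
                if value < 0:
                    raise ConfigError("max_epochs must be >= 0")
            elif not value > 0:
                raise ConfigError(f"{key} must be positive, got {value}")


@dataclass
class TrainedMLP:
    """Network weights plus the training trace that produced them."""

    architecture: MLPArchitecture
    n_inputs: int
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0
    trace: list[tuple[int, float, float]] = field(default_factory=list)
    stopped_epoch: int = 0


# ---------------------------------------------------------------------------
# Forward / backward passes (on standardised data)
# ---------------------------------------------------------------------------

def _forward(weights, biases, transfers, X):
    """Return per-layer (pre-activation, activation) pairs; last layer linear."""
    a = X
    cache = []
    n_hidden = len(transfers)
    for l, (W, b) in enumerate(zip(weights, biases)):
        n = a @ W + b
        if l < n_hidden:
            a = TRANSFER_FUNCTIONS[transfers[l]].forward(n)
        else:
            a = n
        cache.append((n, a))
    return cache


def _loss_and_grads(weights, biases, transfers, X, y, l2: float = 0.0):
    cache = _forward(weights, biases, transfers, X)
    y_hat = cache[-1][1][:, 0]
    resid = y_hat - y
    m = X.shape[0]
    loss = float(np.mean(resid**2))
    if l2 > 0:
        loss += l2 * sum(float(np.sum(W * W)) for W in weights)
    gW = [None] * len(weights)
    gb = [None] * len(biases)
    # dL/dy_hat for MSE
    g = (2.0 / m) * resid[:, None]
    for l in range(len(weights) - 1, -1, -1):
        a_prev = X if l == 0 else cache[l - 1][1]
        gW[l] = a_prev.T @ g
        gb[l] = g.sum(axis=0)
        if l2 > 0:
            gW[l] = gW[l] + 2.0 * l2 * weights[l]
        if l > 0:
            g = g @ weights[l].T
            n_prev, act_prev = cache[l - 1]
            tf = TRANSFER_FUNCTIONS[transfers[l - 1]]
            g = tf.backward(n_prev, act_prev, g)
    return loss, gW, gb, y_hat


def _mse(weights, biases, transfers, X, y) -> float:
    cache = _forward(weights, biases, transfers, X)
    return float(np.mean((cache[-1][1][:, 0] - y) ** 2))


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def init_mlp(arch: MLPArchitecture, n_inputs: int, seed: int = 0) -> TrainedMLP:
    """Deterministic fan-in-scaled uniform initialisation.

    Weights of a layer with ``fan_in`` inputs are drawn from
    ``U(-1, 1) / sqrt(fan_in)``; biases start at zero.
    """
    if n_inputs < 1:
        raise ConfigError(f"n_inputs must be >= 1, got {n_inputs}")
    rng = np.random.default_rng(seed)
    sizes = [n_inputs, *arch.active_neurons, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-1.0, 1.0, size=(fan_in, fan_out)) / np.sqrt(fan_in))
        biases.append(np.zeros(fan_out))
    return TrainedMLP(architecture=arch, n_inputs=n_inputs, weights=weights, biases=biases)


# ---------------------------------------------------------------------------
# Trainers
# ---------------------------------------------------------------------------

def _pack(weights, biases):
    return np.concatenate([w.ravel() for w in weights] + [b.ravel() for b in biases])


def _unpack(theta, weights, biases):
    out_w, out_b = [], []
    pos = 0
    for W in weights:
        out_w.append(theta[pos : pos + W.size].reshape(W.shape))
        pos += W.size
    for b in biases:
        out_b.append(theta[pos : pos + b.size].reshape(b.shape))
        pos += b.size
    return out_w, out_b


def _run_epochs(step, mlp, transfers, Xt, yt, Xv, yv, cfg, l2=0.0):
    """Generic epoch loop with early stopping on validation MSE."""
    weights = [W.copy() for W in mlp.weights]
    biases = [b.copy() for b in mlp.biases]
    best = (np.inf, [W.copy() for W in weights], [b.copy() for b in biases], 0)
    trace: list[tuple[int, float, float]] = []
    since_best = 0
    state: dict = {}
    for epoch in range(1, cfg.max_epochs + 1):
        loss, gW, gb, _ = _loss_and_grads(weights, biases, transfers, Xt, yt, l2=l2)
        if not np.isfinite(loss):
            raise TrainingError(f"training diverged (non-finite loss) at epoch {epoch}")
        step(weights, biases, gW, gb, state)
        train_mse = _mse(weights, biases, transfers, Xt, yt)
        val_mse = _mse(weights, biases, transfers, Xv, yv) if Xv is not None else train_mse
        trace.append((epoch, train_mse, val_mse))
        if val_mse < best[0]:
            best = (val_mse, [W.copy() for W in weights], [b.copy() for b in biases], epoch)
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.val_patience:
                break
    if best[3] == 0:  # max_epochs == 0
        return weights, biases, trace, 0
    return best[1], best[2], trace, best[3]


def _step_gd(cfg):
    def step(weights, biases, gW, gb, state):
        for W, g in zip(weights, gW):
            W -= cfg.learning_rate * g
        for b, g in zip(biases, gb):
            b -= cfg.learning_rate * g
    return step


def _step_gdm(cfg):
    def step(weights, biases, gW, gb, state):
        if "vW" not in state:
            state["vW"] = [np.zeros_like(W) for W in weights]
            state["vb"] = [np.zeros_like(b) for b in biases]
        for W, g, v in zip(weights, gW, state["vW"]):
            v *= cfg.momentum
            v -= cfg.learning_rate * g
            W += v
        for b, g, v in zip(biases, gb, state["vb"]):
            v *= cfg.momentum
            v -= cfg.learning_rate * g
            b += v
    return step


def _step_rprop(cfg):
    # Rprop without weight-backtracking (iRprop-): step sizes adapt per
    # parameter from the sign agreement of successive gradients.
    def step(weights, biases, gW, gb, state):
        params = weights + biases
        grads = gW + gb
        if "delta" not in state:
            state["delta"] = [np.full_like(p, cfg.rprop_delta0) for p in params]
            state["prev"] = [np.zeros_like(p) for p in params]
        for p, g, delta, prev in zip(params, grads, state["delta"], state["prev"]):
            sign = np.sign(g * prev)
            delta[sign > 0] = np.minimum(delta[sign > 0] * cfg.rprop_eta_plus, cfg.rprop_delta_max)
            delta[sign < 0] = np.maximum(delta[sign < 0] * cfg.rprop_eta_minus, cfg.rprop_delta_min)
            g = np.where(sign < 0, 0.0, g)
            p -= np.sign(g) * delta
            prev[...] = g
    return step


def _train_bfgs(mlp, transfers, Xt, yt, Xv, yv, cfg, l2=0.0):
    """BFGS via scipy.optimize with a per-iteration validation checkpoint."""
    theta0 = _pack(mlp.weights, mlp.biases)
    shapes_w, shapes_b = mlp.weights, mlp.biases

    def objective(theta):
        w, b = _unpack(theta, shapes_w, shapes_b)
        loss, gW, gb, _ = _loss_and_grads(w, b, transfers, Xt, yt, l2=l2)
        return loss, _pack(gW, gb)

    trace: list[tuple[int, float, float]] = []
    best = {"val": np.inf, "theta": theta0.copy(), "epoch": 0}
    counter = {"epoch": 0}

    def callback(theta):
        counter["epoch"] += 1
        w, b = _unpack(theta, shapes_w, shapes_b)
        train_mse = _mse(w, b, transfers, Xt, yt)
        val_mse = _mse(w, b, transfers, Xv, yv) if Xv is not None else train_mse
        trace.append((counter["epoch"], train_mse, val_mse))
        if val_mse < best["val"]:
            best.update(val=val_mse, theta=theta.copy(), epoch=counter["epoch"])

    if cfg.max_epochs > 0:
        # exact BFGS keeps a dense inverse Hessian (O(n^2) memory, O(n^3)
        # update); above a few hundred parameters the memory-limited variant
        # is the standard choice and optimises the same objective.
        if theta0.size <= 400:
            method, options = "BFGS", {"maxiter": cfg.max_epochs, "gtol": 1e-10}
        else:
            method, options = "L-BFGS-B", {"maxiter": cfg.max_epochs, "gtol": 1e-10}
        minimize(
            objective,
            theta0,
            jac=True,
            method=method,
            callback=callback,
            options=options,
        )
    weights, biases = _unpack(best["theta"], shapes_w, shapes_b)
    return [W.copy() for W in weights], [b.copy() for b in biases], trace, best["epoch"]


_STEPPERS = {"traingd": _step_gd, "traingdm": _step_gdm, "trainrp": _step_rprop}


def train_mlp(
    mlp: TrainedMLP,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    cfg: TrainingConfig = TrainingConfig(),
) -> TrainedMLP:
    """Train a freshly initialised network with its architecture's trainer.

    Returns a new :class:`TrainedMLP` holding the weights of the epoch with
    the best validation MSE (training MSE when no validation split is
    given), the full training trace and the stopping epoch.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if X_train.ndim != 2 or X_train.shape[0] != y_train.size:
        raise ShapeError("X_train must be 2-D with one row per y_train entry")
    if X_train.shape[1] != mlp.n_inputs:
        raise ShapeError(
            f"network expects {mlp.n_inputs} inputs, got {X_train.shape[1]} features"
        )

    # Standardise with training-split statistics.
    x_mean = X_train.mean(axis=0)
    x_scale = X_train.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(y_train.mean())
    y_scale = float(y_train.std()) or 1.0
    Xt = (X_train - x_mean) / x_scale
    yt = (y_train - y_mean) / y_scale
    if X_val is not None:
        X_val = np.asarray(X_val, dtype=float)
        y_val = np.asarray(y_val, dtype=float).ravel()
        Xv = (X_val - x_mean) / x_scale
        yv = (y_val - y_mean) / y_scale
    else:
        Xv = yv = None

    transfers = mlp.architecture.active_transfer
    train_fn = mlp.architecture.train_fn

    if train_fn in _STEPPERS:
        weights, biases, trace, stopped = _run_epochs(
            _STEPPERS[train_fn](cfg), mlp, transfers, Xt, yt, Xv, yv, cfg
        )
    elif train_fn == "trainbfg":
        weights, biases, trace, stopped = _train_bfgs(mlp, transfers, Xt, yt, Xv, yv, cfg)
    elif train_fn == "trainbr":
        # Rprop with an L2 weight penalty; the penalty strength is picked on
        # the validation split from a small grid.
        results = []
        for l2 in cfg.l2_grid:
            w, b, tr, st = _run_epochs(
                _step_rprop(cfg), mlp, transfers, Xt, yt, Xv, yv, cfg, l2=l2
            )
            score = min(t[2] for t in tr) if tr else np.inf
            results.append((score, w, b, tr, st))
        _, weights, biases, trace, stopped = min(results, key=lambda r: r[0])
    else:  # pragma: no cover - guarded by MLPArchitecture validation
        raise RegistryError(f"unsupported training function {train_fn!r}")

    return TrainedMLP(
        architecture=mlp.architecture,
        n_inputs=mlp.n_inputs,
        weights=weights,
        biases=biases,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        trace=trace,
        stopped_epoch=stopped,
    )


def predict(mlp: TrainedMLP, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass, de-standardised to the original y scale."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != mlp.n_inputs:
        raise ShapeError(f"expected shape (n, {mlp.n_inputs}), got {X.shape}")
    if mlp.x_mean is not None:
        X = (X - mlp.x_mean) / mlp.x_scale
    cache = _forward(mlp.weights, mlp.biases, mlp.architecture.active_transfer, X)
    y_std = cache[-1][1][:, 0]
    return y_std * mlp.y_scale + mlp.y_mean
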