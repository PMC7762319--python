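"""Replicated 60/10/30 evaluation protocol and its summary statistics.

Each replication draws a fresh random train/validation/test partition,
fits the model specification (a fixed-architecture ANN or a PLSR whose
component count is picked on the validation split) and computes the five
standard calibration metrics (R, R2, MSE, RMSE, MAE) on the held-out test
split.  Replications are summarised by mean +/- sample sd per metric and by
the "best state" (the replication with minimum RMSE); per-sample mean
predictions over the test memberships support the aggregate correlation
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    CoverageError,
    DegenerateInputError,
    NirTasteError,
    ProtocolError,
)
from .mlp import MLPArchitecture, TrainingConfig, init_mlp, predict, train_mlp
from .plsr import fit_plsr, predict_plsr, select_ncomp

__all__ = [
    "MetricSet",
    "ReplicationReport",
    "SummaryStats",
    "AnnModelSpec",
    "PlsrModelSpec",
    "compute_metrics",
    "random_split",
    "run_replications",
    "summarize",
    "aggregate_mean_predictions",
    "reports_to_frame",
]

METRIC_NAMES = ("r", "r2", "mse", "rmse", "mae")


@dataclass(frozen=True)
class MetricSet:
    """The five calibration criteria; R2 is defined as the square of Pearson R."""

    r: float
    r2: float
    mse: float
    rmse: float
    mae: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ConfigError("y_true and y_pred must share a length >= 2")
    if np.ptp(y_true) == 0:
        raise DegenerateInputError("correlation undefined: y_true is constant")
    resid = y_pred - y_true
    mse = float(np.mean(resid**2))
    if np.ptp(y_pred) == 0:
        r = 0.0  # constant predictor carries no linear association
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return MetricSet(r=r, r2=r * r, mse=mse, rmse=float(np.sqrt(mse)),
                     mae=float(np.mean(np.abs(resid))))


def random_split(n: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random 60/10/30 partition of range(n): sizes round(.6n), round(.1n), rest."""
    if n < 10:
        raise ConfigError(f"need n >= 10 for a non-empty 60/10/30 split, got {n}")
    n_train = int(round(0.6 * n))
    n_val = int(round(0.1 * n))
    if n_train < 1 or n_val < 1 or n - n_train - n_val < 1:
        raise ConfigError(f"n = {n} leaves an empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    return (
        np.sort(perm[:n_train]),
        np.sort(perm[n_train : n_train + n_val]),
        np.sort(perm[n_train + n_val :]),
    )


def selection_split(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """60/40 train/validation split used by the selection and tuning stages.

    Wavelength selection and architecture search compare thousands of
    candidates on the same validation data, so they get a larger validation
    share than the 60/10/30 modelling protocol to keep the comparison
    stable; the replication loop afterwards re-splits 60/10/30.
    """
    if n < 5:
        raise ConfigError(f"need n >= 5 for a selection split, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    cut = int(round(0.6 * n))
    return np.sort(perm[:cut]), np.sort(perm[cut:])


@dataclass(frozen=True)
class AnnModelSpec:
    """Fixed-architecture neural model, retrained per replication."""

    architecture: MLPArchitecture
    train_cfg: TrainingConfig = field(default_factory=TrainingConfig)


@dataclass(frozen=True)
class PlsrModelSpec:
    """PLSR whose component count is re-selected on each validation split."""

    max_components: int = 10


ModelSpec = Union[AnnModelSpec, PlsrModelSpec]


@dataclass
class ReplicationReport:
    index: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    metrics: MetricSet
    test_predictions: np.ndarray


def _fit_predict(spec: ModelSpec, X, y, tr, va, te, seed: int) -> np.ndarray:
    if isinstance(spec, AnnModelSpec):
        net = init_mlp(spec.architecture, X.shape[1], seed=seed)
        net = train_mlp(net, X[tr], y[tr], X[va], y[va], spec.train_cfg)
        return predict(net, X[te])
    if isinstance(spec, PlsrModelSpec):
        ncomp = select_ncomp(X[tr], y[tr], X[va], y[va], spec.max_components)
        model = fit_plsr(X[tr], y[tr], ncomp)
        return predict_plsr(model, X[te])
    raise ConfigError(f"unknown model spec {type(spec).__name__}")


def run_replications(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_reps: int,
    base_seed: int = 0,
) -> list[ReplicationReport]:
    """Run ``n_reps`` split/fit/score replications.

    Replication r uses seed ``base_seed + r`` for both the split and the
    model initialisation.  Failed replications are logged and skipped; more
    than 10% failures aborts with a protocol error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    reports: list[ReplicationReport] = []
    failures = 0
    for r in range(n_reps):
        seed = base_seed + r
        tr, va, te = random_split(y.size, seed)
        try:
            y_hat = _fit_predict(spec, X, y, tr, va, te, seed)
            metrics = compute_metrics(y[te], y_hat)
        except NirTasteError as exc:
            failures += 1
            warnings.warn(f"replication {r} failed and was excluded: {exc}")
            continue
        reports.append(
            ReplicationReport(index=r, train_idx=tr, val_idx=va, test_idx=te,
                              metrics=metrics, test_predictions=y_hat)
        )
    if failures > 0.1 * n_reps:
        raise ProtocolError(f"{failures}/{n_reps} replications failed (> 10%)")
    return reports


@dataclass
class SummaryStats:
    mean: dict[str, float]
    sd: dict[str, float]
    best_index: int
    best: MetricSet

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "best_index": self.best_index,
            "best": self.best.as_dict(),
        }


def summarize(reports: Sequence[ReplicationReport]) -> SummaryStats:
    """Mean +/- sample sd of every metric, plus the minimum-RMSE best state.

    With a single replication the sd is reported as 0 by convention.
    """
    if not reports:
        raise ConfigError("summarize needs at least one replication report")
    table = {name: np.array([getattr(r.metrics, name) for r in reports])
             for name in METRIC_NAMES}
    mean = {name: float(v.mean()) for name, v in table.items()}
    sd = {name: float(v.std(ddof=1)) if len(reports) > 1 else 0.0
          for name, v in table.items()}
    best_pos = int(np.argmin(table["rmse"]))
    return SummaryStats(mean=mean, sd=sd, best_index=reports[best_pos].index,
                        best=reports[best_pos].metrics)


def aggregate_mean_predictions(
    reports: Sequence[ReplicationReport], y: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-sample mean test-split prediction and its correlation with y.

    A sample contributes only from replications in which it was in the test
    split; a sample never tested raises a coverage error naming it.
    """
    y = np.asarray(y, dtype=float).ravel()
    sums = np.zeros(y.size)
    counts = np.zeros(y.size)
    for rep in reports:
        sums[rep.test_idx] += rep.test_predictions
        counts[rep.test_idx] += 1
    never = np.flatnonzero(counts == 0)
    if never.size:
        raise CoverageError(f"samples never in any test split: {never.tolist()}")
    mean_pred = sums / counts
    r = float(np.corrcoef(y, mean_pred)[0, 1])
    return mean_pred, r


def reports_to_frame(reports: Sequence[ReplicationReport]) -> pd.DataFrame:
    """One row per replication with all five metrics (audit/persistence table)."""
    rows = [{"replication": r.index, **r.metrics.as_dict()} for r in reports]
    return pd.DataFrame(rows, columns=["replication", *METRIC_NAMES])
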