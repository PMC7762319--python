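"""Configuration-driven end-to-end run: simulate/load -> preprocess ->
select wavelengths -> tune the ANN -> replicated ANN & PLSR evaluation ->
stage statistics, with every intermediate artifact persisted.

Selection and tuning run once, on a dedicated tuning split drawn from the
base seed, before the replication loop; the replication loop then
re-splits per replication with seeds derived from the base seed.  A
manifest records the configuration hash and seeds so a run can be
reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .data import (
    ChemistryTable,
    SpectralDataset,
    join_chemistry,
    read_chemistry_csv,
    read_spectra_csv,
)
from .errors import ConfigError
from .evaluate import (
    AnnModelSpec,
    PlsrModelSpec,
    aggregate_mean_predictions,
    reports_to_frame,
    run_replications,
    selection_split,
    summarize,
)
from .firefly import FireflyConfig, make_ann_fitness, make_ridge_fitness, select_wavelengths
from .mlp import TrainingConfig
from .preprocess import PreprocessConfig, preprocess
from .pso import HyperparamSpace, PSOConfig, tune_ann
from .stats import one_way_anova, tukey_lsd, two_sample_t
from .synthetic import SyntheticConfig, simulate_dataset, tiny_config

__all__ = ["RunConfig", "load_config", "run_pipeline"]

_TARGETS = ("ta", "taste_index")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one end-to-end run."""

    target: str = "ta"
    spectra_path: str | None = None
    chemistry_path: str | None = None
    simulate: str | None = None            # None | tiny | default | hard
    seed: int = 0
    reps: int = 300
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: FireflyConfig = field(default_factory=FireflyConfig)
    selection_fitness: str = "ann"         # ann | linear
    tune: bool = True
    pso: PSOConfig = field(default_factory=PSOConfig)
    train: TrainingConfig = field(default_factory=TrainingConfig)
    plsr_max_components: int = 10
    out_dir: str = "run"

    def __post_init__(self) -> None:
        if self.target not in _TARGETS:
            raise ConfigError(f"target must be one of {_TARGETS}, got {self.target!r}")
        if self.reps < 1:
            raise ConfigError("reps must be >= 1")
        if self.selection_fitness not in ("ann", "linear"):
            raise ConfigError("selection_fitness must be 'ann' or 'linear'")
        if self.simulate is not None and self.simulate not in ("tiny", "default", "hard"):
            raise ConfigError("simulate must be tiny, default or hard")
        if self.simulate is None and (self.spectra_path is None or self.chemistry_path is None):
            raise ConfigError("either simulate or both input paths must be given")


_SECTION_TYPES = {
    "preprocess": PreprocessConfig,
    "selection": FireflyConfig,
    "pso": PSOConfig,
    "train": TrainingConfig,
}


def _build_section(cls, mapping: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config keys under {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in mapping.items():
        target_type = fields[key].type
        if isinstance(value, list):
            value = tuple(value)
        if isinstance(value, bool) and "bool" not in str(target_type):
            raise ConfigError(f"type mismatch at {path}.{key}: unexpected boolean")
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration, filling defaults and rejecting unknowns."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o).__name__)

    blob = json.dumps(dataclasses.asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(cfg: RunConfig) -> tuple[SpectralDataset, ChemistryTable]:
    if cfg.simulate is not None:
        if cfg.simulate == "tiny":
            sim_cfg = tiny_config(cfg.seed)
        elif cfg.simulate == "default":
            sim_cfg = SyntheticConfig(seed=cfg.seed)
        else:
            sim_cfg = SyntheticConfig(seed=cfg.seed, scatter_sd=0.1, noise_sd=0.01)
        ds, chem, _ = simulate_dataset(sim_cfg)
        return ds, chem
    for label, path in (("spectra", cfg.spectra_path), ("chemistry", cfg.chemistry_path)):
        if not Path(path).exists():
            raise ConfigError(f"{label} file not found: {path}")
    return read_spectra_csv(cfg.spectra_path), read_chemistry_csv(cfg.chemistry_path)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full flow and return the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, chem = _load_inputs(cfg)
    pre = preprocess(ds, cfg.preprocess)
    X, y, stage = join_chemistry(pre, chem, cfg.target)

    # --- wavelength selection on a dedicated tuning split ---------------
    sel_train, sel_val = selection_split(X.shape[0], cfg.seed)
    if cfg.selection_fitness == "linear":
        fitness = make_ridge_fitness(X, y, sel_train, sel_val)
    else:
        fitness = make_ann_fitness(X, y, sel_train, sel_val,
                                   fitness_reps=cfg.selection.fitness_reps)
    selection = select_wavelengths(X, y, pre.grid, cfg.selection, fitness_fn=fitness)
    with open(out / "selected_wavelengths.json", "w") as fh:
        json.dump(
            {
                "target": cfg.target,
                "k": selection.selected_k,
                "wavelengths_nm": selection.wavelengths_nm.tolist(),
                "fitness": selection.fitness,
                "history": selection.history,
            },
            fh, indent=2,
        )
        fh.write("\n")
    Xsel = X[:, selection.indices]

    # --- architecture tuning (optional) ---------------------------------
    if cfg.tune:
        tuning = tune_ann(Xsel, y, sel_train, sel_val,
                          pso_cfg=cfg.pso, train_cfg=cfg.train)
        arch = tuning.best_architecture
        with open(out / "tuned_architecture.json", "w") as fh:
            json.dump(arch.to_dict() | {"fitness": tuning.best_fitness}, fh, indent=2)
            fh.write("\n")
        np.savetxt(out / "gbest_history.csv", np.asarray(tuning.history),
                   header="gbest_mse", comments="", delimiter=",")
    else:
        from .firefly import table_ann_spec
        arch = table_ann_spec()

    # --- replicated evaluation ------------------------------------------
    results = {}
    for label, spec in (
        ("ann", AnnModelSpec(architecture=arch, train_cfg=cfg.train)),
        ("plsr", PlsrModelSpec(max_components=cfg.plsr_max_components)),
    ):
        reports = run_replications(spec, Xsel, y, cfg.reps, base_seed=cfg.seed)
        frame = reports_to_frame(reports)
        frame.to_csv(out / f"replications_{label}.csv", index=False)
        summary = summarize(reports)
        mean_pred, agg_r = aggregate_mean_predictions(reports, y)
        results[label] = {"summary": summary.as_dict(), "aggregated_r": agg_r}
        np.savetxt(
            out / f"aggregated_predictions_{label}.csv",
            np.column_stack([y, mean_pred]),
            header="y_true,y_mean_pred", comments="", delimiter=",",
        )
        results[label]["mean_predictions"] = mean_pred

    with open(out / "summary.json", "w") as fh:
        json.dump(
            {label: {"summary": r["summary"], "aggregated_r": r["aggregated_r"]}
             for label, r in results.items()},
            fh, indent=2,
        )
        fh.write("\n")

    # --- stage statistics -------------------------------------------------
    groups = [y[stage == s] for s in (1, 2, 3)]
    anova = one_way_anova(groups)
    posthoc = tukey_lsd(groups)
    ttests = {
        label: dataclasses.asdict(
            two_sample_t(y, results[label]["mean_predictions"], equal_var=True)
        )
        for label in results
    }
    with open(out / "stats.json", "w") as fh:
        json.dump(
            {
                "anova": dataclasses.asdict(anova),
                "posthoc": [dataclasses.asdict(p) for p in posthoc],
                "ttests": ttests,
            },
            fh, indent=2,
        )
        fh.write("\n")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "reps": cfg.reps,
        "target": cfg.target,
        "config_hash": _config_hash(cfg),
        "selected_k": selection.selected_k,
        "architecture": arch.to_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return out
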