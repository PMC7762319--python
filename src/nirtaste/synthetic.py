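"""Synthetic Gala-apple-like Vis-NIR datasets with known ground truth.

The generator emulates the study design this toolkit targets: 150 fruit in
three harvest stages of 50, destructively measured TA and taste index with
stage means/spreads matching the published chemistry, and reflectance
spectra on a 200-1100 nm grid in which narrow Gaussian absorption bands
carry the chemistry.  Each property is encoded the way key-wavelength
selection assumes real NIR data works: one band whose amplitude tracks the
property plus interfering bands driven by latent nuisance factors that
also bleed into the property band.  Predicting the property therefore
requires exactly the planted set of channels (signal band + its
interferents), which makes recovery tests sharp.

Corruptions applied on top of the clean reflectance: per-sample
multiplicative scatter (log-normal), a global smooth background, and
additive Gaussian noise.  Scatter is multiplicative in reflectance, i.e.
an additive offset in absorbance, which SNV removes exactly - mirroring
what the preprocessing chain is for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data import (
    ChemistryRecord,
    ChemistryTable,
    SpectralDataset,
    WavelengthGrid,
    default_grid,
    write_chemistry_csv,
    write_spectra_csv,
)
from .errors import ConfigError

__all__ = [
    "Band",
    "SyntheticConfig",
    "GroundTruth",
    "default_bands",
    "tiny_config",
    "simulate_chemistry",
    "simulate_spectra",
    "simulate_dataset",
    "make_fixture",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band.

    ``sensitivity`` maps latent names to linear amplitude coefficients;
    latents are the standardised chemistry (``"ta"``, ``"taste_index"``) and
    nuisance factors ``"u1"``, ``"u2"``, ...  Amplitude (absorbance units):
    ``base_amplitude + sum_l sensitivity[l] * z_l``.
    """

    center_nm: float
    width_nm: float
    base_amplitude: float
    sensitivity: dict[str, float] = field(default_factory=dict)


def default_bands() -> list[Band]:
    """Planted bands echoing the third-overtone region findings.

    TA information sits near 865 nm with interferents near 872 and 890 nm
    (planted TA channels: ~865/872/890); taste-index information sits near
    982 nm with interferents near 942/958/967/974 nm (planted taste
    channels: ~942/958/967/974/982).  Centres are snapped onto the default
    1.2 nm grid so each planted channel is a well-defined grid index.
    """
    return [
        Band(864.8, 1.5, 0.25, {"ta": 0.10, "u1": 0.06, "u2": 0.05}),
        Band(872.0, 1.5, 0.20, {"u1": 0.08}),
        Band(890.0, 1.5, 0.20, {"u2": 0.08}),
        Band(981.2, 1.5, 0.25, {"taste_index": 0.10, "u3": 0.06, "u4": 0.06,
                                "u5": 0.06, "u6": 0.06}),
        Band(941.6, 1.5, 0.18, {"u3": 0.08}),
        Band(958.4, 1.5, 0.18, {"u4": 0.08}),
        Band(966.8, 1.5, 0.18, {"u5": 0.08}),
        Band(974.0, 1.5, 0.18, {"u6": 0.08}),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the generator.

    Stage means follow the published chemistry table (TA 0.5557 / 0.5649 /
    0.5808; taste index 22.12 / 22.62 / 21.24); within-stage sds follow the
    published within-group mean squares (sqrt(0.018) ~ 0.134 for TA,
    sqrt(56.49) ~ 7.52 for taste index), which makes the stage effect
    statistically non-significant by design.
    """

    n_per_stage: int = 50
    grid_lo: float = 200.0
    grid_hi: float = 1100.0
    grid_step: float = 1.2
    ta_means: tuple[float, float, float] = (0.5557, 0.5649, 0.5808)
    ta_sd: float = 0.134
    taste_means: tuple[float, float, float] = (22.12, 22.62, 21.24)
    taste_sd: float = 7.52
    bands: tuple[Band, ...] = tuple(default_bands())
    scatter_sd: float = 0.05      # sd of log multiplicative scatter factor
    baseline_slope_range: tuple[float, float] = (0.0, 0.0)  # per-sample absorbance slope
    noise_sd: float = 0.002       # additive reflectance noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_stage < 2:
            raise ConfigError("n_per_stage must be >= 2")
        if not (self.ta_sd > 0 and self.taste_sd > 0):
            raise ConfigError("stage sds must be positive")
        for b in self.bands:
            if not self.grid_lo <= b.center_nm <= self.grid_hi:
                raise ConfigError(f"band center {b.center_nm} nm outside the grid")

    def grid(self) -> WavelengthGrid:
        return default_grid(self.grid_lo, self.grid_hi, self.grid_step)


@dataclass
class GroundTruth:
    """What the generator knows and analysis pipelines try to recover."""

    informative_channels: dict[str, list[int]]   # per property, grid indices
    informative_wavelengths: dict[str, list[float]]
    bands: tuple[Band, ...]
    scatter_factors: np.ndarray
    latents: dict[str, np.ndarray]
    clean_reflectance: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "informative_channels": self.informative_channels,
            "informative_wavelengths": self.informative_wavelengths,
            "bands": [
                {
                    "center_nm": b.center_nm,
                    "width_nm": b.width_nm,
                    "base_amplitude": b.base_amplitude,
                    "sensitivity": b.sensitivity,
                }
                for b in self.bands
            ],
            "scatter_factors": self.scatter_factors.tolist(),
        }


def _truncated_normal(rng, mean, sd, lower, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, lower + 1e-9)


def simulate_chemistry(cfg: SyntheticConfig, rng: np.random.Generator
                       ) -> tuple[ChemistryTable, np.ndarray]:
    """Draw per-sample TA and taste index by stage; TSS := taste_index * TA.

    TA is truncated above 0.05 and taste index above 1 to keep the
    chemistry physical, so the TSS/TA identity holds by construction.
    """
    records = []
    stages = []
    counter = 0
    for stage in (1, 2, 3):
        ta = _truncated_normal(rng, cfg.ta_means[stage - 1], cfg.ta_sd, 0.05,
                               cfg.n_per_stage)
        taste = _truncated_normal(rng, cfg.taste_means[stage - 1], cfg.taste_sd, 1.0,
                                  cfg.n_per_stage)
        for i in range(cfg.n_per_stage):
            counter += 1
            records.append(
                ChemistryRecord(
                    sample_id=f"s{counter:03d}",
                    ta=float(ta[i]),
                    tss=float(taste[i] * ta[i]),
                )
            )
            stages.append(stage)
    return ChemistryTable(records), np.array(stages, dtype=int)


def _background(grid_nm: np.ndarray) -> np.ndarray:
    """Smooth sample-independent absorbance background (pigment + water)."""
    lam = grid_nm
    return (
        0.35
        + 0.00025 * (lam - 200.0)
        + 0.30 * np.exp(-((lam - 450.0) ** 2) / (2 * 60.0**2))
        + 0.22 * np.exp(-((lam - 680.0) ** 2) / (2 * 30.0**2))
        + 0.15 * np.exp(-((lam - 1020.0) ** 2) / (2 * 45.0**2))
    )


def simulate_spectra(
    chem: ChemistryTable,
    stages: np.ndarray,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[SpectralDataset, GroundTruth]:
    """Render reflectance spectra from chemistry via the planted band model."""
    grid = cfg.grid()
    lam = grid.values
    n = len(chem)

    # standardised chemistry latents + nuisance latents
    ta = chem.values("ta")
    taste = chem.values("taste_index")
    latents: dict[str, np.ndarray] = {
        "ta": (ta - np.mean(cfg.ta_means)) / cfg.ta_sd,
        "taste_index": (taste - np.mean(cfg.taste_means)) / cfg.taste_sd,
    }
    nuisance_names = sorted(
        {name for b in cfg.bands for name in b.sensitivity if name.startswith("u")}
    )
    for name in nuisance_names:
        latents[name] = rng.normal(0.0, 1.0, size=n)

    absorbance = np.tile(_background(lam), (n, 1))
    lo_slope, hi_slope = cfg.baseline_slope_range
    if hi_slope > lo_slope:
        slopes = rng.uniform(lo_slope, hi_slope, size=n)
    else:
        slopes = np.full(n, lo_slope)
    absorbance += slopes[:, None] * (lam - lam.mean())[None, :] / (lam[-1] - lam[0])
    for band in cfg.bands:
        shape = np.exp(-((lam - band.center_nm) ** 2) / (2.0 * band.width_nm**2))
        amp = np.full(n, band.base_amplitude)
        for name, coef in band.sensitivity.items():
            amp = amp + coef * latents[name]
        absorbance += np.outer(amp, shape)

    # absorbance outside [-10, 10] is unphysical; clip before exponentiating
    clean_reflectance = np.power(10.0, -np.clip(absorbance, -10.0, 10.0))
    scatter = np.exp(rng.normal(0.0, cfg.scatter_sd, size=n))
    noisy = scatter[:, None] * clean_reflectance
    if cfg.noise_sd > 0:
        noisy = noisy + rng.normal(0.0, cfg.noise_sd, size=noisy.shape)
    noisy = np.maximum(noisy, 1e-6)

    informative: dict[str, list[int]] = {"ta": [], "taste_index": []}
    for prop in ("ta", "taste_index"):
        signal_bands = [b for b in cfg.bands if prop in b.sensitivity]
        channels = set()
        for sb in signal_bands:
            channels.add(grid.index_of(sb.center_nm))
            for nuis in sb.sensitivity:
                if not nuis.startswith("u"):
                    continue
                for other in cfg.bands:
                    if other is not sb and nuis in other.sensitivity:
                        channels.add(grid.index_of(other.center_nm))
        informative[prop] = sorted(channels)

    ds = SpectralDataset(
        grid=grid,
        intensities=noisy,
        sample_ids=[r.sample_id for r in chem.records],
        stage=np.asarray(stages, dtype=int),
        state="reflectance",
    )
    truth = GroundTruth(
        informative_channels=informative,
        informative_wavelengths={
            prop: [float(grid.values[i]) for i in idx] for prop, idx in informative.items()
        },
        bands=cfg.bands,
        scatter_factors=scatter,
        latents=latents,
        clean_reflectance=clean_reflectance,
    )
    return ds, truth


def simulate_dataset(cfg: SyntheticConfig, seed: int | None = None
                     ) -> tuple[SpectralDataset, ChemistryTable, GroundTruth]:
    """Chemistry + spectra in one call from a single seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chem, stages = simulate_chemistry(cfg, rng)
    ds, truth = simulate_spectra(chem, stages, cfg, rng)
    return ds, chem, truth


def tiny_config(seed: int = 0) -> SyntheticConfig:
    """3x6 samples on a 10-channel grid for enumeration-scale oracle tests.

    Grid 850-895 nm at 5 nm.  TA: signal at 865 nm (index 3), interferent
    at 885 nm (index 7).  Taste index: signal at 890 nm (index 8),
    interferent at 855 nm (index 1).
    """
    return SyntheticConfig(
        n_per_stage=6,
        grid_lo=850.0,
        grid_hi=895.0,
        grid_step=5.0,
        bands=(
            Band(865.0, 2.0, 0.25, {"ta": 0.10, "u1": 0.06}),
            Band(885.0, 2.0, 0.20, {"u1": 0.08}),
            Band(890.0, 2.0, 0.25, {"taste_index": 0.10, "u2": 0.06}),
            Band(855.0, 2.0, 0.20, {"u2": 0.08}),
        ),
        scatter_sd=0.005,
        noise_sd=0.001,
        seed=seed,
    )


_FIXTURE_KINDS = ("tiny", "default", "hard")


def make_fixture(kind: str, seed: int, out_dir) -> dict[str, Path]:
    """Write a complete fixture bundle (spectra, chemistry, ground truth).

    ``tiny``: 18 samples / 10 channels; ``default``: 3x50 on the full grid;
    ``hard``: the default design with heavy scatter and noise.  Same seed,
    same bytes.
    """
    if kind not in _FIXTURE_KINDS:
        raise ConfigError(f"fixture kind must be one of {_FIXTURE_KINDS}, got {kind!r}")
    if kind == "tiny":
        cfg = tiny_config(seed)
    elif kind == "default":
        cfg = SyntheticConfig(seed=seed)
    else:
        cfg = SyntheticConfig(seed=seed, scatter_sd=0.1, noise_sd=0.01)
    ds, chem, truth = simulate_dataset(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": out / "spectra.csv",
        "chemistry": out / "chemistry.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_spectra_csv(ds, paths["spectra"])
    write_chemistry_csv(chem, paths["chemistry"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
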