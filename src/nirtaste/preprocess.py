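"""Three-stage spectral pre-processing: absorbance, SNV, median smoothing.

Raw reflectance from a fibre-optic probe carries multiplicative scatter
(sample size/surface effects), baseline drift and spike noise.  The chain
implemented here is the conventional remedy: convert to absorbance
``A = log10(1/R)`` (linearises concentration effects via Beer-Lambert),
apply the standard normal variate transform per spectrum (removes additive
offset and multiplicative scatter), then median-filter along the wavelength
axis (suppresses spikes without smearing band shapes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .data import SpectralDataset, WavelengthGrid
from .errors import ConfigError, DegenerateInputError, DomainError

__all__ = [
    "PreprocessConfig",
    "reflectance_to_absorbance",
    "snv",
    "median_smooth",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Switches and parameters for the preprocessing chain.

    ``median_window`` must be odd; window 1 is the identity.  ``trim_lo`` /
    ``trim_hi`` (nm) optionally crop noisy grid edges before anything else.
    """

    apply_absorbance: bool = True
    apply_snv: bool = True
    median_window: int = 5
    trim_lo: float | None = None
    trim_hi: float | None = None

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ConfigError(f"median_window must be odd and >= 1, got {self.median_window}")
        if (
            self.trim_lo is not None
            and self.trim_hi is not None
            and not self.trim_lo < self.trim_hi
        ):
            raise ConfigError("trim_lo must be < trim_hi")


def reflectance_to_absorbance(spectrum: np.ndarray) -> np.ndarray:
    """Elementwise ``A = log10(1 / R)``; rejects non-positive reflectance."""
    r = np.asarray(spectrum, dtype=float)
    bad = np.nonzero(r <= 0)
    if bad[0].size:
        idx = tuple(int(b[0]) for b in bad)
        raise DomainError(f"reflectance must be > 0 for absorbance; first offender at index {idx}")
    return -np.log10(r)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to mean 0, sd 1.

    Uses the sample (n-1) standard deviation.  A constant spectrum has zero
    variance and is rejected.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size < 2:
        raise DomainError("snv needs a spectrum of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("snv undefined for a constant spectrum (zero variance)")
    return (x - x.mean()) / sd


def median_smooth(spectrum: np.ndarray, window: int) -> np.ndarray:
    """Running median along the wavelength axis with reflect padding."""
    x = np.asarray(spectrum, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"median window must be odd and >= 1, got {window}")
    if window > x.size:
        raise ConfigError(f"median window {window} exceeds spectrum length {x.size}")
    if window == 1:
        return x.copy()
    return median_filter(x, size=window, mode="reflect")


def preprocess(ds: SpectralDataset, cfg: PreprocessConfig = PreprocessConfig()) -> SpectralDataset:
    """Apply trim, then absorbance -> SNV -> median smoothing, per sample.

    Each output row depends only on the corresponding input row, so the
    chain commutes with sample reordering.  The result carries
    ``state="preprocessed"``.
    """
    grid = ds.grid
    matrix = ds.intensities
    if cfg.trim_lo is not None or cfg.trim_hi is not None:
        lo = cfg.trim_lo if cfg.trim_lo is not None else -np.inf
        hi = cfg.trim_hi if cfg.trim_hi is not None else np.inf
        mask = (grid.values >= lo) & (grid.values <= hi)
        if mask.sum() < 2:
            raise ConfigError("trim bounds leave fewer than 2 wavelengths")
        grid = WavelengthGrid(grid.values[mask])
        matrix = matrix[:, mask]

    out = np.empty_like(matrix)
    for i in range(matrix.shape[0]):
        row = matrix[i]
        try:
            if cfg.apply_absorbance:
                if ds.state != "reflectance":
                    raise DomainError(
                        f"absorbance conversion requires reflectance input, state={ds.state!r}"
                    )
                row = reflectance_to_absorbance(row)
            if cfg.apply_snv:
                row = snv(row)
            if cfg.median_window > 1:
                row = median_smooth(row, cfg.median_window)
        except (DomainError, DegenerateInputError) as exc:
            raise type(exc)(f"sample {ds.sample_ids[i]!r}: {exc}") from exc
        out[i] = row
    return ds.copy_with(out, state="preprocessed", grid=grid)
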