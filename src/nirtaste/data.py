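"""Core data containers for Vis-NIR spectra and wet-chemistry references.

A :class:`SpectralDataset` holds one reflectance (or derived) spectrum per
fruit sample on a shared wavelength grid; a :class:`ChemistryTable` holds the
destructively measured titratable acidity (TA), total soluble solids (TSS)
and the derived taste index (TSS/TA) for the same samples.  CSV round-trip
and the spectra/chemistry join used to assemble supervised regression
problems live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, JoinError

__all__ = [
    "WavelengthGrid",
    "SpectralDataset",
    "ChemistryRecord",
    "ChemistryTable",
    "compute_taste_index",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_chemistry_csv",
    "write_chemistry_csv",
    "join_chemistry",
]

SpectraState = Literal["reflectance", "absorbance", "preprocessed"]

#: Valid instrument range (nm) for grids handled by the toolkit.
_GRID_LO, _GRID_HI = 100.0, 2500.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise DomainError("wavelength grid must be a 1-D vector of length >= 2")
        if not np.all(np.diff(values) > 0):
            raise DomainError("wavelength grid must be strictly increasing")
        if values[0] < _GRID_LO or values[-1] > _GRID_HI:
            raise DomainError(
                f"wavelengths must lie within [{_GRID_LO}, {_GRID_HI}] nm, "
                f"got [{values[0]}, {values[-1]}]"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid point closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.values - wavelength_nm)))


def default_grid(lo: float = 200.0, hi: float = 1100.0, step: float = 1.2) -> WavelengthGrid:
    """The default 200-1100 nm axis at 1.2 nm resolution (751 points)."""
    n = int(round((hi - lo) / step)) + 1
    return WavelengthGrid(lo + step * np.arange(n))


@dataclass
class SpectralDataset:
    """Sample-indexed spectra on a shared grid with harvest-stage labels."""

    grid: WavelengthGrid
    intensities: np.ndarray
    sample_ids: list[str]
    stage: np.ndarray
    state: SpectraState = "reflectance"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.stage = np.asarray(self.stage, dtype=int)
        if self.intensities.ndim != 2:
            raise DomainError("intensities must be a 2-D matrix")
        n, p = self.intensities.shape
        if p != len(self.grid):
            raise DomainError(
                f"intensity matrix has {p} columns but grid has {len(self.grid)} points"
            )
        if len(self.sample_ids) != n or self.stage.shape != (n,):
            raise DomainError("sample_ids/stage length must match the number of rows")
        if len(set(self.sample_ids)) != n:
            raise DomainError("sample_ids must be unique")
        if not np.all(np.isin(self.stage, (1, 2, 3))):
            raise DomainError("stage labels must be in {1, 2, 3}")
        if self.state == "reflectance" and np.any(self.intensities <= 0):
            bad = int(np.argwhere(self.intensities <= 0)[0][0])
            raise DomainError(
                f"reflectance must be strictly positive (sample {self.sample_ids[bad]!r})"
            )

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.intensities.shape[1]

    def copy_with(self, intensities: np.ndarray, state: SpectraState,
                  grid: WavelengthGrid | None = None) -> "SpectralDataset":
        return SpectralDataset(
            grid=grid if grid is not None else self.grid,
            intensities=np.asarray(intensities, dtype=float),
            sample_ids=list(self.sample_ids),
            stage=self.stage.copy(),
            state=state,
        )


def compute_taste_index(tss: float, ta: float) -> float:
    """Taste index = TSS / TA, the standard sweetness-to-acidity ripeness ratio.

    Parameters
    ----------
    tss : total soluble solids in degrees Brix (> 0).
    ta : titratable acidity on the titration scale (> 0).
    """
    if not tss > 0:
        raise DomainError(f"tss must be positive, got {tss}")
    if not ta > 0:
        raise DomainError(f"ta must be positive, got {ta}")
    return tss / ta


@dataclass(frozen=True)
class ChemistryRecord:
    """Wet-chemistry reference values for one sample."""

    sample_id: str
    ta: float
    tss: float
    taste_index: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.ta > 0:
            raise DomainError(f"ta must be positive, got {self.ta} ({self.sample_id})")
        if not self.tss > 0:
            raise DomainError(f"tss must be positive, got {self.tss} ({self.sample_id})")
        expected = self.tss / self.ta
        if self.taste_index is None:
            object.__setattr__(self, "taste_index", expected)
        elif abs(self.taste_index - expected) > 1e-9 * max(1.0, abs(expected)):
            raise DomainError(
                f"taste_index {self.taste_index} inconsistent with tss/ta = {expected} "
                f"({self.sample_id})"
            )


@dataclass
class ChemistryTable:
    """Collection of chemistry records with unique sample ids."""

    records: list[ChemistryRecord]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DomainError("chemistry sample_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, ChemistryRecord]:
        return {r.sample_id: r for r in self.records}

    def values(self, target: str) -> np.ndarray:
        """Vector of ``ta``, ``tss`` or ``taste_index`` in record order."""
        if target not in ("ta", "tss", "taste_index"):
            raise DomainError(f"unknown chemistry target {target!r}")
        return np.array([getattr(r, target) for r in self.records], dtype=float)


# ---------------------------------------------------------------------------
# CSV I/O.  Wide layout: sample_id,stage,<wavelength>,...  Chemistry:
# sample_id,ta,tss (taste_index is always derived, never stored).
# ---------------------------------------------------------------------------

def read_spectra_csv(path) -> SpectralDataset:
    try:
        df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    except ValueError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if list(df.columns[:2]) != ["sample_id", "stage"]:
        raise FormatError("spectra CSV must start with columns sample_id,stage")
    try:
        wavelengths = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavelength header in {path}: {exc}") from exc
    if wavelengths.size >= 2 and not np.all(np.diff(wavelengths) > 0):
        raise FormatError("wavelength headers must be strictly increasing")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r} in {path}")
    matrix = df.iloc[:, 2:].to_numpy()
    try:
        matrix = matrix.astype(float)
    except ValueError:
        obj = df.iloc[:, 2:]
        for col in obj.columns:
            bad = pd.to_numeric(obj[col], errors="coerce").isna() & obj[col].notna()
            if bad.any():
                row = int(np.argmax(bad.to_numpy()))
                raise FormatError(
                    f"non-numeric cell at row {row}, column {col!r} in {path}"
                ) from None
        raise
    if not np.all(np.isfinite(matrix)):
        raise FormatError(f"missing or non-finite intensity values in {path}")
    return SpectralDataset(
        grid=WavelengthGrid(wavelengths),
        intensities=matrix,
        sample_ids=df["sample_id"].tolist(),
        stage=df["stage"].to_numpy(dtype=int),
        state="reflectance",
    )


def write_spectra_csv(ds: SpectralDataset, path) -> None:
    """Write a dataset in the wide CSV layout at full float precision."""
    header = ["sample_id", "stage"] + [repr(float(v)) for v in ds.grid.values]
    with open(path, "w", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for i in range(ds.n_samples):
            row = [ds.sample_ids[i], str(int(ds.stage[i]))]
            row += [repr(float(v)) for v in ds.intensities[i]]
            fh.write(",".join(row) + "\n")


def read_chemistry_csv(path) -> ChemistryTable:
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    required = {"sample_id", "ta", "tss"}
    if not required.issubset(df.columns):
        raise FormatError(f"chemistry CSV must have columns {sorted(required)}")
    records = [
        ChemistryRecord(sample_id=row.sample_id, ta=float(row.ta), tss=float(row.tss))
        for row in df.itertuples()
    ]
    return ChemistryTable(records)


def write_chemistry_csv(chem: ChemistryTable, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("sample_id,ta,tss\n")
        for r in chem.records:
            fh.write(f"{r.sample_id},{r.ta!r},{r.tss!r}\n")


def join_chemistry(
    ds: SpectralDataset, chem: ChemistryTable, target: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align chemistry to spectra row order, returning ``(X, y, stage)``.

    ``target`` is ``"ta"`` or ``"taste_index"``; row order of the chemistry
    table is irrelevant, only the id mapping matters.
    """
    if target not in ("ta", "taste_index"):
        raise DomainError(f"target must be 'ta' or 'taste_index', got {target!r}")
    lookup = chem.by_id()
    missing = [sid for sid in ds.sample_ids if sid not in lookup]
    if missing:
        raise JoinError(f"chemistry table is missing sample_ids: {missing}")
    y = np.array([getattr(lookup[sid], target) for sid in ds.sample_ids], dtype=float)
    return ds.intensities.copy(), y, ds.stage.copy()
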