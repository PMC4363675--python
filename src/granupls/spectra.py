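"""Core containers for diffuse-reflectance NIR data.

Spectra live on a shared wavenumber grid (canonically 10000 -> 4000 cm^-1,
descending, matching FT-NIR instrument output) and carry log(1/R) apparent
absorbance. A :class:`SpectraSet` bundles a spectra matrix with per-row
reference concentrations (mg g^-1), sieve-mesh granularity labels, sample
identifiers and, for raw data, replicate indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = ["WavenumberGrid", "Spectrum", "SpectraSet", "DEFAULT_GRID"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis in cm^-1.

    The canonical convention is descending storage (``start > stop``,
    10000 -> 4000 cm^-1); ascending grids (``start < stop``) are accepted
    and flagged via :attr:`ascending`. ``step`` is the unsigned spacing.
    """

    start: float = 10000.0
    stop: float = 4000.0
    step: float = 1.928

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be > 0, got {self.step}")
        if self.start == self.stop:
            raise ValueError("grid start and stop coincide")
        if self.n_points < 8:
            raise ValueError(
                f"grid must have at least 8 points, got {self.n_points}"
            )

    @property
    def ascending(self) -> bool:
        return self.start < self.stop

    @property
    def n_points(self) -> int:
        # tolerant floor: span/step may sit a few ulp below an integer
        return int(np.floor(abs(self.start - self.stop) / self.step + 1e-9)) + 1

    @property
    def wavenumbers(self) -> np.ndarray:
        sign = 1.0 if self.ascending else -1.0
        return self.start + sign * self.step * np.arange(self.n_points)

    def to_descending(self) -> "WavenumberGrid":
        """Canonical descending orientation of this grid."""
        if not self.ascending:
            return self
        last = self.wavenumbers[-1]
        return replace(self, start=last, stop=self.start)

    def __len__(self) -> int:
        return self.n_points


#: The instrument grid: 10000-4000 cm^-1 at a 1.928 cm^-1 data interval.
DEFAULT_GRID = WavenumberGrid()


@dataclass
class Spectrum:
    """One spectrum: a wavenumber grid plus log(1/R) intensities."""

    grid: WavenumberGrid
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("intensity must be one-dimensional")
        if len(self.intensity) != self.grid.n_points:
            raise ValueError(
                f"intensity length {len(self.intensity)} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.wavenumbers


def _as_array(values, n: int, name: str, dtype=float) -> np.ndarray:
    arr = np.asarray(values, dtype=dtype)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have length {n}, got shape {arr.shape}")
    return arr


@dataclass
class SpectraSet:
    """Spectra matrix with concentrations, granularity labels and identity.

    ``replicate`` is ``None`` once replicates have been averaged; raw sets
    carry a 0-based replicate index per row. Rows with equal
    ``(sample_id, mesh)`` are replicate measurements of the same powder.
    """

    grid: WavenumberGrid
    intensities: np.ndarray          # (n_rows, n_points)
    concentrations: np.ndarray       # mg g^-1, one per row
    mesh: np.ndarray                 # sieve mesh label per row
    sample_ids: np.ndarray           # str per row
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        n, p = self.intensities.shape
        if p != self.grid.n_points:
            raise ValueError(
                f"intensities have {p} columns but grid has "
                f"{self.grid.n_points} points"
            )
        self.concentrations = _as_array(self.concentrations, n, "concentrations")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        self.mesh = _as_array(self.mesh, n, "mesh", dtype=int)
        self.sample_ids = np.asarray(self.sample_ids)
        if self.sample_ids.shape != (n,):
            raise ValueError("sample_ids length mismatch")
        if self.replicate is not None:
            self.replicate = _as_array(self.replicate, n, "replicate", dtype=int)

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def is_averaged(self) -> bool:
        return self.replicate is None

    @property
    def mesh_classes(self) -> np.ndarray:
        return np.unique(self.mesh)

    def subset(self, indices) -> "SpectraSet":
        idx = np.asarray(indices)
        return SpectraSet(
            grid=self.grid,
            intensities=self.intensities[idx],
            concentrations=self.concentrations[idx],
            mesh=self.mesh[idx],
            sample_ids=self.sample_ids[idx],
            replicate=None if self.replicate is None else self.replicate[idx],
        )

    def select_mesh(self, mesh: int) -> "SpectraSet":
        return self.subset(np.flatnonzero(self.mesh == mesh))

    def spectrum(self, row: int) -> Spectrum:
        return Spectrum(self.grid, self.intensities[row])
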