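"""Granularity-sensitivity analysis of NIR spectra.

Particle size modulates diffuse reflectance through the scatter
coefficient S of Kubelka-Munk theory, F(R) = (1 - R)^2 / (2 R) = K/S, and
the effect is wavelength dependent. This module quantifies it as the
relative standard deviation (RSD) of mean log(1/R) intensity across
granularity classes, per wavenumber, summarised over the three standard
NIR regions:

* SCOT, second combination-overtone, 10000-7100 cm^-1 (least affected)
* FCOT, first combination-overtone, 7100-5000 cm^-1
* CR, combination region, 5000-4000 cm^-1 (most affected)

Boundary wavenumbers are assigned to the lower-wavenumber region.
Sensitivity labels follow the conventional cut-points: mean region RSD
below 0.015 is "low", 0.015-0.035 "medium", above 0.035 "high".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SpectraSet, Spectrum, WavenumberGrid

__all__ = [
    "SpectralRegion",
    "DEFAULT_REGIONS",
    "RSDProfile",
    "kubelka_munk",
    "class_mean_spectra",
    "region_rsd",
    "classify_sensitivity",
]


@dataclass(frozen=True)
class SpectralRegion:
    """A named wavenumber interval, bounds given [high, low] in cm^-1."""

    name: str
    high: float
    low: float

    def __post_init__(self) -> None:
        if self.high <= self.low:
            raise ValueError("region high bound must exceed low bound")

    def mask(self, wavenumbers: np.ndarray, include_low: bool = False) -> np.ndarray:
        nu = np.asarray(wavenumbers, dtype=float)
        m = (nu > self.low) & (nu <= self.high)
        if include_low:
            m |= nu == self.low
        return m


DEFAULT_REGIONS = (
    SpectralRegion("SCOT", 10000.0, 7100.0),
    SpectralRegion("FCOT", 7100.0, 5000.0),
    SpectralRegion("CR", 5000.0, 4000.0),
)

#: Cut-points on mean region RSD for sensitivity labels.
RSD_LOW_MAX = 0.015
RSD_MEDIUM_MAX = 0.035


def kubelka_munk(R):
    """Kubelka-Munk remission function F(R) = (1 - R)^2 / (2 R) = K/S.

    Maps diffuse reflectance (fraction in (0, 1]) to the ratio of the
    absorption to the scatter coefficient. Vectorised; rejects
    non-physical reflectance.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0) or np.any(R > 1):
        raise ValueError("reflectance must lie in (0, 1]")
    return (1.0 - R) ** 2 / (2.0 * R)


def class_mean_spectra(data: SpectraSet) -> list[Spectrum]:
    """Mean spectrum per granularity class, ordered by mesh."""
    out = []
    for mesh in data.mesh_classes:
        sub = data.select_mesh(int(mesh))
        out.append(Spectrum(data.grid, sub.intensities.mean(axis=0),
                            meta={"mesh": int(mesh)}))
    return out


@dataclass
class RSDProfile:
    """Per-wavenumber RSD across granularity classes with region summaries.

    ``reliable`` flags points where the across-class mean intensity is
    large enough for the ratio to be meaningful; unreliable points are
    excluded from region summaries rather than reported as huge values.
    """

    wavenumbers: np.ndarray
    rsd: np.ndarray
    reliable: np.ndarray
    region_summary: pd.DataFrame  # index = region name; mean/min/max RSD


def region_rsd(
    spectra: list[Spectrum] | np.ndarray,
    regions=DEFAULT_REGIONS,
    grid: WavenumberGrid | None = None,
    min_mean: float = 1e-6,
) -> RSDProfile:
    """RSD of intensity across granularity classes, per wavenumber.

    ``spectra`` holds one mean spectrum per class (>= 2), either as
    :class:`Spectrum` objects on a common grid or as a matrix plus
    ``grid``. RSD = sample SD (n-1) across classes / mean across classes.
    Regions tile the grid; the boundary point goes to the
    lower-wavenumber region, and the lowest region keeps its low endpoint.
    """
    if isinstance(spectra, (list, tuple)):
        if len(spectra) < 2:
            raise ValueError("need at least 2 granularity classes")
        grids = {s.grid for s in spectra}
        if len(grids) != 1:
            raise ValueError("class spectra must share a common grid")
        grid = spectra[0].grid
        M = np.vstack([s.intensity for s in spectra])
    else:
        M = np.asarray(spectra, dtype=float)
        if grid is None:
            raise ValueError("grid required when passing a matrix")
        if M.ndim != 2 or M.shape[0] < 2:
            raise ValueError("need a (n_classes >= 2, n_points) matrix")

    nu = grid.wavenumbers
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    reliable = np.abs(mean) > min_mean
    rsd = np.zeros_like(mean)
    rsd[reliable] = sd[reliable] / np.abs(mean[reliable])

    lowest = min(r.low for r in regions)
    rows = {}
    for region in regions:
        m = region.mask(nu, include_low=region.low == lowest) & reliable
        if not m.any():
            rows[region.name] = dict(mean=np.nan, min=np.nan, max=np.nan,
                                     n_points=0)
            continue
        vals = rsd[m]
        rows[region.name] = dict(mean=vals.mean(), min=vals.min(),
                                 max=vals.max(), n_points=int(m.sum()))
    summary = pd.DataFrame.from_dict(rows, orient="index")
    return RSDProfile(nu, rsd, reliable, summary)


def classify_sensitivity(profile: RSDProfile) -> dict[str, str]:
    """Label each region low/medium/high by its mean RSD.

    low: mean RSD < 0.015; medium: 0.015 <= RSD <= 0.035; high: > 0.035.
    """
    labels = {}
    for name, row in profile.region_summary.iterrows():
        m = row["mean"]
        if np.isnan(m):
            labels[name] = "undefined"
        elif m < RSD_LOW_MAX:
            labels[name] = "low"
        elif m <= RSD_MEDIUM_MAX:
            labels[name] = "medium"
        else:
            labels[name] = "high"
    return labels
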