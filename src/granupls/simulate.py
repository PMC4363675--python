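"""Synthetic diffuse-reflectance NIR spectra with a granularity effect.

The generator emulates a ground-herb calibration study in which the same
powdered material is sieved to four finenesses (40/65/80/100 mesh) and each
portion is measured in triplicate on a 10000-4000 cm^-1 grid. Clean
absorbance follows a Beer-Lambert Gaussian-band model: a few fixed matrix
bands plus analyte bands whose amplitude is linear in the analyte
concentration (mg g^-1). Particle size enters as a smooth, region-weighted
multiplicative gain plus additive offset, both linear in nominal particle
size — the minimal form consistent with Kubelka-Munk theory, in which the
scatter coefficient (and hence log(1/R)) grows with particle size, more
strongly at lower wavenumbers. Default magnitudes place the across-class
relative standard deviation of intensity near 0.045 in the combination
region (CR, 5000-4000 cm^-1), 0.030 in the first combination-overtone
region (FCOT, 7100-5000 cm^-1) and 0.010 in the second combination-overtone
region (SCOT, 10000-7100 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra import DEFAULT_GRID, SpectraSet, Spectrum, WavenumberGrid

__all__ = [
    "GranularityClass",
    "BandSpec",
    "GranularityEffect",
    "SimulationConfig",
    "DEFAULT_CLASSES",
    "DEFAULT_BANDS",
    "generate_concentrations",
    "generate_spectrum",
    "generate_dataset",
]

#: Particle-size anchor (um) against which scatter scales are expressed.
REFERENCE_PARTICLE_SIZE_UM = 250.0


@dataclass(frozen=True)
class GranularityClass:
    """A sieve-mesh fraction and its nominal particle size.

    ``scatter_scale`` is the particle size relative to a 250 um anchor;
    it is strictly decreasing in mesh (finer sieve, smaller particles).
    """

    mesh: int
    nominal_particle_size_um: float

    def __post_init__(self) -> None:
        if self.nominal_particle_size_um <= 0:
            raise ValueError("particle size must be positive")

    @property
    def scatter_scale(self) -> float:
        return self.nominal_particle_size_um / REFERENCE_PARTICLE_SIZE_UM


#: Standard sieve openings for 40/65/80/100 mesh.
DEFAULT_CLASSES = (
    GranularityClass(40, 425.0),
    GranularityClass(65, 230.0),
    GranularityClass(80, 180.0),
    GranularityClass(100, 150.0),
)


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian absorption band.

    ``amplitude`` is absorbance per mg g^-1 for analyte bands
    (``analyte=True``) or a fixed absorbance for matrix bands.
    """

    center: float
    width: float
    amplitude: float
    analyte: bool = False

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((wavenumbers - self.center) / self.width) ** 2)


# Matrix bands loosely follow typical plant-powder NIR structure (O-H first
# overtone ~6900, water combination ~5200, C-H combination ~4300 cm^-1);
# analyte bands sit in FCOT and CR, where the method looks for signal.
DEFAULT_BANDS = (
    BandSpec(8700.0, 250.0, 0.04),
    BandSpec(6900.0, 180.0, 0.25),
    BandSpec(5200.0, 140.0, 0.30),
    BandSpec(4750.0, 120.0, 0.15),
    BandSpec(4300.0, 90.0, 0.20),
    BandSpec(5800.0, 100.0, 0.012, analyte=True),
    BandSpec(4400.0, 80.0, 0.018, analyte=True),
)


@dataclass(frozen=True)
class GranularityEffect:
    """Magnitude and spectral weighting of the particle-size effect.

    ``multiplicative`` and ``additive`` scale the gain and offset applied
    per unit relative particle-size deviation; ``region_weights`` shape the
    wavelength dependence (largest in CR, smallest in SCOT), blended
    smoothly across region boundaries over ``transition_width`` cm^-1.
    """

    multiplicative: float = 0.08
    additive: float = 0.004
    region_weights: tuple[float, float, float] = (0.22, 0.66, 1.0)  # SCOT, FCOT, CR
    transition_width: float = 60.0

    def weight(self, wavenumbers: np.ndarray) -> np.ndarray:
        w_scot, w_fcot, w_cr = self.region_weights
        tau = self.transition_width

        def logistic(x):
            return 1.0 / (1.0 + np.exp(-x))

        nu = np.asarray(wavenumbers, dtype=float)
        w = w_scot + (w_fcot - w_scot) * logistic((7100.0 - nu) / tau)
        w += (w_cr - w_fcot) * logistic((5000.0 - nu) / tau)
        return w

    @property
    def is_null(self) -> bool:
        return self.multiplicative == 0.0 and self.additive == 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults reproduce the emulated study: 90 samples measured in
    triplicate, analyte concentrations from a truncated normal with mean
    3.695 and SD 1.452 mg g^-1 clipped to [1.476, 8.162] mg g^-1, on the
    full instrument grid.
    """

    grid: WavenumberGrid = DEFAULT_GRID
    n_samples: int = 90
    replicates: int = 3
    concentration_mean: float = 3.695
    concentration_sd: float = 1.452
    concentration_range: tuple[float, float] = (1.476, 8.162)
    granularity_effect: GranularityEffect = field(default_factory=GranularityEffect)
    noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.concentration_range
        if lo >= hi:
            raise ValueError(
                f"degenerate concentration range [{lo}, {hi}]: min must be < max"
            )
        if not (lo <= self.concentration_mean <= hi):
            raise ValueError("concentration mean must lie inside the range")
        if self.concentration_sd < 0:
            raise ValueError("concentration SD must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


def generate_concentrations(
    n: int, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` reference concentrations (mg g^-1).

    Sampling is a truncated normal with the configured parent mean/SD,
    clipped to the configured range (truncation shifts the realised mean
    slightly above the parent mean; see the methods note). ``sd == 0``
    degenerates to the mean.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.concentration_range
    if cfg.concentration_sd == 0:
        return np.full(n, cfg.concentration_mean)
    a = (lo - cfg.concentration_mean) / cfg.concentration_sd
    b = (hi - cfg.concentration_mean) / cfg.concentration_sd
    return stats.truncnorm.rvs(
        a, b,
        loc=cfg.concentration_mean,
        scale=cfg.concentration_sd,
        size=n,
        random_state=rng,
    )


def clean_absorbance(
    wavenumbers: np.ndarray, concentration: float, bands=DEFAULT_BANDS
) -> np.ndarray:
    """Noise-free, granularity-free log(1/R): baseline + bands.

    Linear (Beer-Lambert) in concentration by construction.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    # gentle sloped baseline, higher towards low wavenumbers
    out = 0.20 + 2.0e-5 * (10000.0 - nu)
    for band in bands:
        amp = band.amplitude * concentration if band.analyte else band.amplitude
        out = out + amp * band.profile(nu)
    return out


def generate_spectrum(
    concentration: float,
    gran: GranularityClass,
    cfg: SimulationConfig,
    bands=DEFAULT_BANDS,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """One noisy spectrum of a sample at the given granularity.

    intensity = clean * (1 + m_eff * w(nu) * delta) + a_eff * w(nu) * delta
    + noise, with delta the relative particle-size deviation from the
    250 um anchor, so coarser powder reads systematically higher log(1/R),
    most strongly in CR and least in SCOT.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    nu = cfg.grid.wavenumbers
    clean = clean_absorbance(nu, concentration, bands)
    eff = cfg.granularity_effect
    delta = gran.scatter_scale - 1.0
    w = eff.weight(nu)
    intensity = clean * (1.0 + eff.multiplicative * w * delta)
    intensity = intensity + eff.additive * w * delta
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=nu.shape)
    return Spectrum(cfg.grid, intensity, meta={"mesh": gran.mesh})


def generate_dataset(
    cfg: SimulationConfig,
    classes=DEFAULT_CLASSES,
    bands=DEFAULT_BANDS,
) -> SpectraSet:
    """Full raw dataset: every sample measured at every granularity.

    The same material is sieved to each fineness, so one concentration
    vector is shared across classes; each (sample, class) cell holds
    ``cfg.replicates`` replicate spectra. Rows are ordered sample-major,
    then class, then replicate. Deterministic under ``cfg.seed``.
    Averaged spectra are obtained with
    :func:`granupls.sampling.average_replicates`.
    """
    if len(classes) < 1:
        raise ValueError("need at least one granularity class")
    rng = np.random.default_rng(cfg.seed)
    conc = generate_concentrations(cfg.n_samples, cfg, rng)

    rows, concs, meshes, ids, reps = [], [], [], [], []
    width = max(3, len(str(cfg.n_samples)))
    for i in range(cfg.n_samples):
        sid = f"S{i + 1:0{width}d}"
        for gran in classes:
            for r in range(cfg.replicates):
                spec = generate_spectrum(conc[i], gran, cfg, bands, rng)
                rows.append(spec.intensity)
                concs.append(conc[i])
                meshes.append(gran.mesh)
                ids.append(sid)
                reps.append(r)
    return SpectraSet(
        grid=cfg.grid,
        intensities=np.array(rows),
        concentrations=np.array(concs),
        mesh=np.array(meshes),
        sample_ids=np.array(ids),
        replicate=np.array(reps),
    )
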