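"""Scatter correction, derivatives and smoothing for NIR spectra.

Operators act on a 2-D matrix of spectra (rows = samples, columns = the
wavenumber grid) and never resample the grid. Pipelines are written as the
field's conventional labels ("MSC + 1D + SG", "RAW", ...), parsed
whitespace-insensitively, and obey a fit-on-calibration / apply-to-both
contract: any learned statistic (the MSC reference spectrum) comes from the
calibration set only.

Derivatives are taken with respect to wavenumber and scaled by the physical
grid step, so magnitudes do not depend on grid resolution and the sign is
correct for descending (10000 -> 4000 cm^-1) storage. When a derivative is
combined with Savitzky-Golay smoothing the two are executed as a single
derivative convolution, avoiding double smoothing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .spectra import WavenumberGrid

__all__ = [
    "msc",
    "snv",
    "savitzky_golay",
    "norris_derivative",
    "PipelineParams",
    "PreprocessPipeline",
    "FittedPipeline",
    "apply_pipeline",
    "TABLE_PIPELINES",
]

#: The eight pipeline labels of the preprocessing grid.
TABLE_PIPELINES = (
    "RAW",
    "MSC",
    "1D + SG",
    "2D + SG",
    "MSC + 1D + SG",
    "MSC + 2D + SG",
    "MSC + 1D + ND",
    "MSC + 2D + ND",
)

_SCATTER = {"MSC", "SNV"}
_DERIV = {"1D": 1, "2D": 2}
_SMOOTH = {"SG", "ND"}


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("expected a spectrum or a matrix of spectra")
    return X


def msc(X, reference="mean"):
    """Multiplicative scatter correction.

    Each spectrum x is regressed on the reference (x ~ a*ref + b, ordinary
    least squares) and replaced by (x - b)/a, removing per-spectrum affine
    scatter. ``reference="mean"`` uses the mean spectrum of ``X``.

    Returns ``(corrected, reference)`` so the fitted reference can be
    reused on validation data.
    """
    X = _as_matrix(X)
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError(f"unknown reference {reference!r}")
        ref = X.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float).ravel()
        if ref.shape[0] != X.shape[1]:
            raise ValueError("reference length does not match spectra")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise ValueError("zero-variance MSC reference: slope undefined")
    slopes = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(slopes == 0):
        raise ValueError("zero MSC slope: spectrum uncorrelated with reference")
    intercepts = X.mean(axis=1) - slopes * ref.mean()
    return (X - intercepts[:, None]) / slopes[:, None], ref


def snv(X):
    """Standard normal variate: per-spectrum standardisation to mean 0, SD 1.

    Uses the sample SD (n-1). Constant spectra are rejected. Affine
    transforms a*x + b (a > 0) map to the same output as x.
    """
    X = _as_matrix(X)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant spectrum (SD = 0)")
    return (X - mu) / sd


def _deriv_sign(grid: WavenumberGrid, deriv: int) -> float:
    # stored index order runs opposite to wavenumber on a descending grid
    return (-1.0) ** deriv if not grid.ascending else 1.0


def savitzky_golay(X, grid: WavenumberGrid, window: int = 11, polyorder: int = 2,
                   deriv: int = 0):
    """Savitzky-Golay local-polynomial smoothing / derivative filter.

    Units of the output are absorbance * cm^deriv (derivative with respect
    to wavenumber, scaled by the grid step). Edges are handled by
    evaluating the polynomial fitted to the truncated terminal window.
    """
    X = _as_matrix(X)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not (window > polyorder >= deriv):
        raise ValueError("require window > polyorder >= deriv")
    if window > X.shape[1]:
        raise ValueError(
            f"window {window} exceeds spectrum length {X.shape[1]}"
        )
    out = savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=grid.step, axis=-1, mode="interp",
    )
    return out * _deriv_sign(grid, deriv)


def norris_derivative(X, grid: WavenumberGrid, segment: int = 5, gap: int = 5,
                      deriv: int = 1):
    """Norris derivative filter: segment averaging then gap differencing.

    First each spectrum is smoothed with a centred ``segment``-point moving
    average; the first derivative at point i is then
    (s[i+gap] - s[i-gap]) / (2 * gap * step) with respect to wavenumber, and
    the second derivative (s[i+gap] - 2 s[i] + s[i-gap]) / (gap * step)^2.
    Edge points without a full gap are filled with the nearest interior
    value (``deriv=0`` returns the segment-smoothed spectra).
    """
    X = _as_matrix(X)
    if segment < 1 or segment % 2 == 0:
        raise ValueError("segment must be a positive odd integer")
    if gap < 1:
        raise ValueError("gap must be >= 1")
    if deriv not in (0, 1, 2):
        raise ValueError("deriv must be 0, 1 or 2")
    n = X.shape[1]
    if 2 * gap >= n:
        raise ValueError("gap too large for spectrum length")
    s = uniform_filter1d(X, size=segment, axis=-1, mode="nearest")
    if deriv == 0:
        return s
    out = np.empty_like(s)
    core = slice(gap, n - gap)
    if deriv == 1:
        out[:, core] = _deriv_sign(grid, 1) * (
            s[:, 2 * gap:] - s[:, :n - 2 * gap]
        ) / (2.0 * gap * grid.step)
    else:
        out[:, core] = (
            s[:, 2 * gap:] - 2.0 * s[:, core] + s[:, :n - 2 * gap]
        ) / (gap * grid.step) ** 2
    # nearest-valid edge fill
    out[:, :gap] = out[:, gap:gap + 1]
    out[:, n - gap:] = out[:, n - gap - 1:n - gap]
    return out


@dataclass(frozen=True)
class PipelineParams:
    """Filter parameters shared by a pipeline run."""

    sg_window: int = 11
    sg_polyorder: int = 2
    nd_segment: int = 5
    nd_gap: int = 5


@dataclass(frozen=True)
class PreprocessPipeline:
    """An ordered preprocessing chain parsed from its conventional label.

    Valid tokens: MSC, SNV (scatter correction, at most one), 1D, 2D
    (derivative order, at most one), SG, ND (smoother, at most one).
    "RAW" is the identity. Execution order is scatter correction ->
    derivative -> smoother, with "1D + SG" run as one SG convolution with
    deriv=1 and "1D + ND" as the Norris derivative filter at order 1.
    """

    scatter: str | None = None
    deriv: int = 0
    smoother: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def parse(cls, label: str, params: PipelineParams | None = None
              ) -> "PreprocessPipeline":
        params = params or PipelineParams()
        tokens = [t for t in re.split(r"\+", label.upper()) if t.strip()]
        tokens = [t.strip() for t in tokens]
        if tokens == ["RAW"]:
            return cls(params=params)
        scatter, deriv, smoother = None, 0, None
        for tok in tokens:
            if tok in _SCATTER:
                if scatter is not None:
                    raise ValueError(f"duplicate scatter-correction step {tok!r}")
                scatter = tok
            elif tok in _DERIV:
                if deriv:
                    raise ValueError(f"duplicate derivative step {tok!r}")
                deriv = _DERIV[tok]
            elif tok in _SMOOTH:
                if smoother is not None:
                    raise ValueError(f"duplicate smoothing step {tok!r}")
                smoother = tok
            else:
                raise ValueError(f"unknown pipeline token {tok!r} in {label!r}")
        return cls(scatter=scatter, deriv=deriv, smoother=smoother, params=params)

    @property
    def label(self) -> str:
        parts = []
        if self.scatter:
            parts.append(self.scatter)
        if self.deriv:
            parts.append(f"{self.deriv}D")
        if self.smoother:
            parts.append(self.smoother)
        return " + ".join(parts) if parts else "RAW"

    def fit(self, calibration, grid: WavenumberGrid) -> "FittedPipeline":
        cal = _as_matrix(calibration)
        msc_ref = None
        if self.scatter == "MSC":
            _, msc_ref = msc(cal, "mean")
        return FittedPipeline(self, grid, msc_ref)


@dataclass(frozen=True)
class FittedPipeline:
    """A pipeline with its calibration-set statistics frozen."""

    pipeline: PreprocessPipeline
    grid: WavenumberGrid
    msc_reference: np.ndarray | None = None

    def transform(self, X) -> np.ndarray:
        X = _as_matrix(X)
        pp = self.pipeline
        prm = pp.params
        if pp.scatter == "MSC":
            X, _ = msc(X, self.msc_reference)
        elif pp.scatter == "SNV":
            X = snv(X)
        if pp.deriv:
            if pp.smoother == "ND":
                X = norris_derivative(X, self.grid, prm.nd_segment, prm.nd_gap,
                                      deriv=pp.deriv)
            elif pp.smoother == "SG":
                X = savitzky_golay(X, self.grid, prm.sg_window, prm.sg_polyorder,
                                   deriv=pp.deriv)
            else:
                # bare derivative: pure gap-1 difference, no smoothing
                X = norris_derivative(X, self.grid, 1, 1, deriv=pp.deriv)
        elif pp.smoother == "SG":
            X = savitzky_golay(X, self.grid, prm.sg_window, prm.sg_polyorder,
                               deriv=0)
        elif pp.smoother == "ND":
            X = norris_derivative(X, self.grid, prm.nd_segment, prm.nd_gap,
                                  deriv=0)
        return X


def apply_pipeline(pipeline, calibration, new, grid: WavenumberGrid,
                   params: PipelineParams | None = None):
    """Fit a pipeline on the calibration spectra and transform both sets.

    ``pipeline`` may be a label string or a :class:`PreprocessPipeline`.
    Returns ``(calibration_t, new_t, fitted)``; ``new`` may be ``None``.
    """
    if isinstance(pipeline, str):
        pipeline = PreprocessPipeline.parse(pipeline, params)
    fitted = pipeline.fit(calibration, grid)
    cal_t = fitted.transform(calibration)
    new_t = None if new is None else fitted.transform(new)
    return cal_t, new_t, fitted
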