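"""Sample management: replicate averaging, Kennard-Stone splitting and
outlier screening.

The Kennard-Stone algorithm builds a representative calibration set by
deterministic max-min Euclidean selection; the outlier screen applies the
classical Dixon Q-test (gap/range, variant chosen by n, two-tailed
critical values after Rorabacher, Anal. Chem. 1991) to the reference
concentrations before calibration, with a Grubbs alternative for large n
or by explicit choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .spectra import SpectraSet

__all__ = [
    "average_replicates",
    "SplitResult",
    "kennard_stone_split",
    "OutlierReport",
    "dixon_outlier_screen",
]

log = logging.getLogger(__name__)


def average_replicates(data: SpectraSet) -> SpectraSet:
    """Average replicate spectra per (sample, granularity) cell.

    Returns an averaged set (``replicate=None``) with one row per cell, in
    first-appearance order. Cells with fewer replicates than the mode are
    averaged over what is available and logged.
    """
    if data.is_averaged:
        return data
    keys = list(zip(data.sample_ids.tolist(), data.mesh.tolist()))
    order: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        order.setdefault(k, []).append(i)
    counts = {len(v) for v in order.values()}
    if len(counts) > 1:
        log.warning("uneven replicate counts %s; averaging available replicates",
                    sorted(counts))
    rows, concs, meshes, ids = [], [], [], []
    for (sid, mesh), idx in order.items():
        rows.append(data.intensities[idx].mean(axis=0))
        concs.append(data.concentrations[idx[0]])
        meshes.append(mesh)
        ids.append(sid)
    return SpectraSet(
        grid=data.grid,
        intensities=np.array(rows),
        concentrations=np.array(concs),
        mesh=np.array(meshes),
        sample_ids=np.array(ids),
        replicate=None,
    )


@dataclass(frozen=True)
class SplitResult:
    """Calibration/validation row indices from a deterministic split."""

    calibration: np.ndarray
    validation: np.ndarray
    selection_order: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        cal = set(self.calibration.tolist())
        val = set(self.validation.tolist())
        if cal & val:
            raise ValueError("calibration and validation overlap")


def kennard_stone_split(X, n_cal: int) -> SplitResult:
    """Kennard-Stone max-min calibration selection.

    The first two picks are the pair at maximum Euclidean distance; each
    subsequent pick maximises its minimum distance to the already selected
    samples. Fully deterministic: all ties break towards the lowest row
    index, so duplicate rows are handled reproducibly.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n = X.shape[0]
    if not (2 <= n_cal < n):
        raise ValueError(f"need 2 <= n_cal < n_samples, got n_cal={n_cal}, n={n}")

    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)

    iu, ju = np.triu_indices(n, k=1)
    best = np.argmax(d2[iu, ju])  # first maximum = smallest (i, j) pair
    selected = [int(iu[best]), int(ju[best])]
    if d2[iu[best], ju[best]] == 0:
        log.warning("all pairwise distances zero; tie rule selects rows 0, 1")

    min_d = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_d))  # argmax takes the lowest index on ties
        selected.append(nxt)
        min_d = np.minimum(min_d, d2[nxt])
        min_d[nxt] = -np.inf

    cal = np.sort(np.array(selected))
    val = np.setdiff1d(np.arange(n), cal)
    return SplitResult(cal, val, tuple(selected))


# Two-tailed Dixon Q critical values (Rorabacher 1991), alpha in rows.
# r10: n = 3..7; r11: n = 8..10; r21: n = 11..13; r22: n = 14..30.
_Q_CRIT = {
    0.10: {
        3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507,
        8: 0.554, 9: 0.512, 10: 0.477,
        11: 0.576, 12: 0.546, 13: 0.521,
        14: 0.546, 15: 0.525, 16: 0.507, 17: 0.490, 18: 0.475, 19: 0.462,
        20: 0.450, 21: 0.440, 22: 0.430, 23: 0.421, 24: 0.413, 25: 0.406,
        26: 0.399, 27: 0.393, 28: 0.387, 29: 0.381, 30: 0.376,
    },
    0.05: {
        3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
        8: 0.608, 9: 0.564, 10: 0.530,
        11: 0.619, 12: 0.583, 13: 0.557,
        14: 0.586, 15: 0.565, 16: 0.546, 17: 0.529, 18: 0.514, 19: 0.501,
        20: 0.489, 21: 0.478, 22: 0.468, 23: 0.459, 24: 0.451, 25: 0.443,
        26: 0.436, 27: 0.429, 28: 0.423, 29: 0.417, 30: 0.412,
    },
    0.01: {
        3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680,
        8: 0.717, 9: 0.672, 10: 0.635,
        11: 0.709, 12: 0.660, 13: 0.638,
        14: 0.670, 15: 0.647, 16: 0.627, 17: 0.610, 18: 0.594, 19: 0.580,
        20: 0.567, 21: 0.555, 22: 0.544, 23: 0.535, 24: 0.526, 25: 0.517,
        26: 0.510, 27: 0.502, 28: 0.495, 29: 0.489, 30: 0.483,
    },
}


def _dixon_q(sorted_vals: np.ndarray, test_max: bool) -> float:
    """Dixon ratio for the extreme value, variant chosen by n."""
    x = sorted_vals
    n = len(x)
    if not test_max:
        x = -x[::-1]  # mirror so the candidate is always the maximum
    if n <= 7:
        num, den = x[-1] - x[-2], x[-1] - x[0]
    elif n <= 10:
        num, den = x[-1] - x[-2], x[-1] - x[1]
    elif n <= 13:
        num, den = x[-1] - x[-3], x[-1] - x[1]
    else:
        num, den = x[-1] - x[-3], x[-1] - x[2]
    return 0.0 if den == 0 else num / den


def _grubbs_gcrit(n: int, alpha: float) -> float:
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t ** 2 / (n - 2 + t ** 2))


@dataclass
class OutlierReport:
    """Result of an iterative outlier screen."""

    retained: np.ndarray                       # original indices, order kept
    outliers: list[int] = field(default_factory=list)
    details: list[dict] = field(default_factory=list)


def dixon_outlier_screen(values, alpha: float = 0.05, max_removals: int = 1,
                         variant: str = "dixon") -> OutlierReport:
    """Iterative single-extreme outlier screen on reference values.

    Each pass tests the value farthest from the mean: with
    ``variant="dixon"`` the Dixon Q ratio (gap/range, n-dependent variant)
    against the tabulated two-tailed critical value at ``alpha``; with
    ``variant="grubbs"`` the Grubbs statistic. n > 30 always falls back to
    Grubbs (the Q table ends at 30). Stops at the first non-rejection or
    after ``max_removals``. All-equal values yield no outliers.
    """
    if variant not in ("dixon", "grubbs"):
        raise ValueError(f"unknown variant {variant!r}")
    if alpha not in _Q_CRIT and variant == "dixon":
        raise ValueError(f"alpha must be one of {sorted(_Q_CRIT)} for Dixon")
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or len(vals) < 3:
        raise ValueError("need at least 3 one-dimensional values")

    idx = np.arange(len(vals))
    outliers: list[int] = []
    details: list[dict] = []
    while len(outliers) < max_removals and len(idx) >= 3:
        x = vals[idx]
        mean = x.mean()
        cand_local = int(np.argmax(np.abs(x - mean)))
        test_max = x[cand_local] >= mean
        n = len(x)
        use_grubbs = variant == "grubbs" or n > 30
        if use_grubbs:
            sd = x.std(ddof=1)
            if sd == 0:
                break
            stat = abs(x[cand_local] - mean) / sd
            crit = _grubbs_gcrit(n, alpha)
            kind = "grubbs"
        else:
            order = np.argsort(x, kind="stable")
            stat = _dixon_q(x[order], test_max)
            crit = _Q_CRIT[alpha][n]
            kind = "dixon"
        reject = stat > crit
        details.append(dict(index=int(idx[cand_local]), statistic=float(stat),
                            critical=float(crit), test=kind, n=n,
                            rejected=bool(reject)))
        if not reject:
            break
        outliers.append(int(idx[cand_local]))
        idx = np.delete(idx, cand_local)
    return OutlierReport(retained=idx, outliers=outliers, details=details)
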