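"""NIPALS partial least squares regression and calibration metrics.

PLS1 (single response) fitted by the nonlinear iterative partial least
squares algorithm with mean-centering of X and y (no variance scaling by
default). Latent-variable (LV) choice follows the PRESS criterion under
cross-validation, optionally guarded against overfitting by requiring
RMSECV close to RMSEP. Evaluation metrics are the standard chemometric
set: RMSEC, RMSECV, RMSEP, Pearson correlations R_CV / R_P, and

    RPD = SD(reference values of the evaluated set) / RMSEP,

with sample SD (n-1); RPD above ~2.5 conventionally marks a usable
quantitative NIR model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PLSModel",
    "fit_pls",
    "predict",
    "predict_per_lv",
    "PressCurve",
    "press_curve",
    "cv_folds",
    "select_lv",
    "MetricsReport",
    "evaluate",
    "rpd",
    "rmse",
    "save_model",
    "load_model",
]


@dataclass
class PLSModel:
    """A fitted PLS1 model.

    Weights ``W`` (p x k), loadings ``P`` (p x k), y-loadings ``q`` (k,)
    and scores ``T`` (n x k) come from NIPALS on the centered data;
    ``coef`` is the equivalent regression vector in the original feature
    space, so predictions are ``(X - x_mean) @ coef + y_mean``.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray | None
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    coef: np.ndarray
    meta: dict = field(default_factory=dict)

    def coef_for(self, k: int) -> np.ndarray:
        """Regression vector using only the first ``k`` components."""
        if not (1 <= k <= self.n_lv):
            raise ValueError(f"k must be in [1, {self.n_lv}]")
        Wk, Pk, qk = self.W[:, :k], self.P[:, :k], self.q[:k]
        return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def _center(X, y, scale: bool):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be (n_samples, n_features) matching y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite (no missing values)")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    x_scale = None
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xc = Xc / x_scale
    return Xc, y - y_mean, x_mean, y_mean, x_scale


def fit_pls(X, y, n_lv: int, scale: bool = False,
            tol: float = 1e-12, max_iter: int = 500) -> PLSModel:
    """Fit PLS1 by NIPALS with ``n_lv`` latent variables.

    Components are extracted by the weight/score/loading iteration with X
    and y deflation; for a single response the inner iteration converges
    in one pass, but the loop is still bounded by ``max_iter`` with
    convergence tolerance ``tol`` on the weight vector. If the residual X
    is exhausted before ``n_lv`` components the model is truncated and
    flagged in ``meta``.
    """
    Xc, yc, x_mean, y_mean, x_scale = _center(X, y, scale)
    n, p = Xc.shape
    if np.allclose(yc, 0):
        raise ValueError("zero-variance y: nothing to regress")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(
            f"n_lv must be in [1, min(n_samples - 1, n_features)] = "
            f"[1, {min(n - 1, p)}], got {n_lv}"
        )

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    truncated = False
    k_eff = n_lv
    for k in range(n_lv):
        # inner weight iteration; for a single response u stays proportional
        # to the y residual, so this converges on the second pass
        u = yc
        w = None
        converged = False
        for _ in range(max_iter):
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm < 1e-14:
                w = None
                converged = True
                break
            w_new = w_new / norm
            if w is not None and np.linalg.norm(w_new - w) < tol:
                w = w_new
                converged = True
                break
            w = w_new
            t = Xc @ w
            tt = t @ t
            if tt < 1e-28:
                w = None
                converged = True
                break
            qk = (yc @ t) / tt
            u = yc / qk if qk != 0 else yc
        if not converged:
            raise RuntimeError(
                f"NIPALS inner iteration did not converge for component {k + 1}"
            )
        if w is None:
            truncated = True
            k_eff = k
            break
        t = Xc @ w
        tt = t @ t
        if tt < 1e-28:
            truncated = True
            k_eff = k
            break
        qk = (yc @ t) / tt
        p_k = Xc.T @ t / tt
        W[:, k], P[:, k], q[k], T[:, k] = w, p_k, qk, t
        Xc = Xc - np.outer(t, p_k)
        yc = yc - qk * t
    if truncated:
        W, P, q, T = W[:, :k_eff], P[:, :k_eff], q[:k_eff], T[:, :k_eff]
        if k_eff == 0:
            raise ValueError("X has no variance: cannot extract components")

    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_lv=k_eff, x_mean=x_mean, y_mean=y_mean, x_scale=x_scale,
        W=W, P=P, q=q, T=T, coef=coef,
        meta={"truncated": truncated, "requested_lv": n_lv},
    )


def predict(model: PLSModel, X_new, n_lv: int | None = None) -> np.ndarray:
    """Predict concentrations for new spectra.

    Centered projection through the regression vector plus the y mean;
    accepts a single spectrum or a matrix. ``n_lv`` restricts the model
    to its first components.
    """
    X_new = np.asarray(X_new, dtype=float)
    single = X_new.ndim == 1
    if single:
        X_new = X_new[None, :]
    if X_new.shape[1] != len(model.x_mean):
        raise ValueError(
            f"feature mismatch: model has {len(model.x_mean)} features, "
            f"input has {X_new.shape[1]}"
        )
    coef = model.coef if n_lv is None else model.coef_for(n_lv)
    Xc = X_new - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    out = Xc @ coef + model.y_mean
    return out[0] if single else out


def predict_per_lv(model: PLSModel, X_new) -> np.ndarray:
    """Predictions at every LV count 1..n_lv; returns (n_samples, n_lv)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Xc = X_new - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    n = Xc.shape[0]
    out = np.empty((n, model.n_lv))
    yhat = np.full(n, model.y_mean)
    for k in range(model.n_lv):
        t = Xc @ model.W[:, k]
        yhat = yhat + model.q[k] * t
        Xc = Xc - np.outer(t, model.P[:, k])
        out[:, k] = yhat
    return out


def cv_folds(n: int, scheme="loo", seed: int | None = None) -> list[np.ndarray]:
    """Cross-validation fold indices.

    ``scheme`` is ``"loo"`` (default, deterministic), ``("kfold", k)`` for
    contiguous blocks, or ``("kfold-shuffled", k)`` with a seeded shuffle.
    """
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    kind, k = scheme
    if k < 2 or k > n:
        raise ValueError(f"k-fold requires 2 <= k <= n, got k={k}, n={n}")
    idx = np.arange(n)
    if kind == "kfold-shuffled":
        idx = np.random.default_rng(seed).permutation(n)
    elif kind != "kfold":
        raise ValueError(f"unknown CV scheme {scheme!r}")
    return [np.sort(f) for f in np.array_split(idx, k)]


@dataclass
class PressCurve:
    """PRESS and RMSECV per LV count, with the CV predictions behind them."""

    press: np.ndarray        # (max_lv,)
    rmsecv: np.ndarray       # sqrt(press / n)
    cv_predictions: np.ndarray  # (n, max_lv)
    max_lv: int

    def r_cv(self, y, k: int) -> float:
        """Pearson correlation of CV predictions at k LVs with y."""
        return float(np.corrcoef(self.cv_predictions[:, k - 1],
                                 np.asarray(y, float))[0, 1])


def press_curve(X, y, max_lv: int, cv="loo", seed: int | None = None,
                scale: bool = False) -> PressCurve:
    """PRESS(k) = sum over held-out samples of (y - yhat_{-i,k})^2.

    Default scheme is leave-one-out (deterministic). ``max_lv`` is capped
    at what the smallest training fold supports. RMSECV(k) =
    sqrt(PRESS(k)/n).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    folds = cv_folds(n, cv, seed)
    min_train = min(n - len(f) for f in folds)
    cap = min(max_lv, min_train - 1, X.shape[1])
    if cap < max_lv:
        import logging
        logging.getLogger(__name__).info(
            "max_lv capped from %d to %d by fold sizes", max_lv, cap)
    if cap < 1:
        raise ValueError("not enough samples for even one latent variable")

    preds = np.empty((n, cap))
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        model = fit_pls(X[train], y[train], cap, scale=scale)
        pk = predict_per_lv(model, X[fold])
        if model.n_lv < cap:  # rank-deficient fold: extend with last column
            pk = np.hstack([pk, np.repeat(pk[:, -1:], cap - model.n_lv, axis=1)])
        preds[fold] = pk
    press = ((preds - y[:, None]) ** 2).sum(axis=0)
    return PressCurve(press=press, rmsecv=np.sqrt(press / n),
                      cv_predictions=preds, max_lv=cap)


def select_lv(curve: PressCurve, rmsep_per_lv=None, tolerance: float = 0.10,
              guard: float | None = None) -> int:
    """Choose the latent-variable count from a PRESS curve.

    Primary rule: global PRESS minimum, ties broken towards fewer
    components. When per-LV RMSEP on a validation set is supplied, the
    anti-overfit guard applies: among LV counts whose RMSECV is within
    ``tolerance`` (relative) of the minimum RMSECV, the smallest count
    with |RMSECV - RMSEP| / RMSEP below ``guard`` (default = tolerance)
    wins; if none qualifies the PRESS minimum stands.
    """
    if curve.max_lv < 1 or len(curve.press) == 0:
        raise ValueError("empty PRESS curve")
    base = int(np.argmin(curve.press)) + 1  # argmin takes first = fewest LVs
    if rmsep_per_lv is None:
        return base
    rmsep_per_lv = np.asarray(rmsep_per_lv, dtype=float)
    if len(rmsep_per_lv) != curve.max_lv:
        raise ValueError("rmsep_per_lv length must match the curve")
    guard = tolerance if guard is None else guard
    rmin = curve.rmsecv.min()
    for k in range(1, curve.max_lv + 1):
        if curve.rmsecv[k - 1] <= (1 + tolerance) * rmin:
            rp = rmsep_per_lv[k - 1]
            if rp > 0 and abs(curve.rmsecv[k - 1] - rp) / rp <= guard:
                return k
    return base


def rmse(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def rpd(y_sd: float, rmsep: float) -> float:
    """Relative predictive determinant: SD of reference values / RMSEP."""
    if rmsep == 0:
        return float("inf")
    return y_sd / rmsep


@dataclass
class MetricsReport:
    """Calibration / validation metrics for one model on one set."""

    rmsec: float | None = None
    rmsecv: float | None = None
    rmsep: float | None = None
    r_cv: float | None = None
    r_p: float | None = None
    rpd: float | None = None
    press: np.ndarray | None = None
    n_lv: int | None = None
    flags: list[str] = field(default_factory=list)


def evaluate(model: PLSModel, X_val, y_val) -> MetricsReport:
    """Test-set validation: RMSEP, Pearson R_P and RPD.

    RPD uses the sample SD (n-1) of the evaluated set's reference values.
    With fewer than 2 validation samples R and RPD are undefined and
    reported absent; perfect prediction yields RPD = inf with a flag.
    """
    y_val = np.asarray(y_val, dtype=float).ravel()
    yhat = predict(model, X_val)
    rep = MetricsReport(n_lv=model.n_lv)
    rep.rmsep = rmse(y_val, yhat)
    if len(y_val) < 2:
        rep.flags.append("n_val < 2: R_P and RPD undefined")
        return rep
    if np.std(yhat) == 0 or np.std(y_val) == 0:
        rep.flags.append("degenerate correlation (constant values)")
    else:
        rep.r_p = float(np.corrcoef(yhat, y_val)[0, 1])
    rep.rpd = rpd(float(np.std(y_val, ddof=1)), rep.rmsep)
    if not np.isfinite(rep.rpd):
        rep.flags.append("RMSEP = 0: RPD infinite")
    return rep


def save_model(model: PLSModel, path) -> None:
    """Serialise a model to a self-describing JSON document."""
    doc = {
        "format": "granupls-pls-model",
        "version": 1,
        "n_lv": model.n_lv,
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "x_scale": None if model.x_scale is None else model.x_scale.tolist(),
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "coef": model.coef.tolist(),
        "meta": {k: v for k, v in model.meta.items()
                 if isinstance(v, (str, int, float, bool, type(None)))},
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> PLSModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "granupls-pls-model":
        raise ValueError("not a granupls PLS model document")
    return PLSModel(
        n_lv=doc["n_lv"],
        x_mean=np.array(doc["x_mean"]),
        y_mean=doc["y_mean"],
        x_scale=None if doc["x_scale"] is None else np.array(doc["x_scale"]),
        W=np.array(doc["W"]),
        P=np.array(doc["P"]),
        q=np.array(doc["q"]),
        T=np.zeros((0, doc["n_lv"])),
        coef=np.array(doc["coef"]),
        meta=dict(doc.get("meta", {}), loaded=True),
    )
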