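"""Pollen-climate transfer functions: WA-PLS and the modern analogue technique.

Both calibration methods are exposed as scikit-learn style regressors that
map pollen percentage assemblages (samples x taxa) to a climate variable
(mean annual temperature in degrees C or precipitation in mm).  Per-sample
prediction errors under leave-one-out cross-validation are the raw material
for the inflection-point analysis downstream: assemblages whose composition
is decoupled from climate by human disturbance cannot be predicted well, so
their cross-validated residuals are systematically larger.

WA-PLS (weighted-averaging partial least squares) estimates taxon scores as
abundance-weighted averages of the environmental residual, forms sample
scores as abundance-weighted averages of taxon scores, orthogonalizes
successive components, and deshrinks with a final weighted least-squares
regression of the environment on the component scores.  With one component
it reduces exactly to classic weighted averaging with inverse deshrinking.

The modern analogue technique predicts the unweighted mean environment of
the k compositionally nearest reference samples under squared-chord
distance d(p, q) = sum_j (sqrt(p_j) - sqrt(q_j))^2 on proportions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import ModernDataset

__all__ = [
    "WAPLSRegressor",
    "ModernAnalogueRegressor",
    "CVResult",
    "PerformanceStats",
    "loo_cross_validate",
    "performance_stats",
    "select_components",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# WA-PLS core

def _wapls_fit_core(Y: np.ndarray, x: np.ndarray, K: int):
    """Fit WA-PLS on abundances Y (n x m) and environment x (n).

    Returns the arrays needed for prediction: per-component taxon scores U
    (K x m), orthogonalization coefficients C (K x K lower-triangular), the
    weighted mean of x, and the deshrinking regression coefficients beta
    ((K+1),) for the design [1, f_1 .. f_K].

    Columns with zero total abundance are harmless: their taxon scores are
    set to 0 and they contribute nothing to any sample score.
    """
    n, m = Y.shape
    row = Y.sum(axis=1)
    col = Y.sum(axis=0)
    total = row.sum()
    w = row / total  # sample weights
    xbar = float(w @ x)
    r = x - xbar

    U = np.zeros((K, m))
    C = np.zeros((K, K))
    F = np.empty((n, K))
    safe_col = np.where(col > 0, col, 1.0)
    for a in range(K):
        u = (Y.T @ r) / safe_col
        u[col <= 0] = 0.0
        U[a] = u
        s = (Y @ u) / row
        for b in range(a):
            fb = F[:, b]
            denom = float(w @ (fb * fb))
            cab = float(w @ (s * fb)) / denom
            C[a, b] = cab
            s = s - cab * fb
        var = float(w @ (s * s))
        if var <= 1e-14 * max(1.0, float(w @ (r * r))):
            raise ValueError(
                f"WA-PLS component {a + 1} has no variance; reduce n_components "
                "(environment may be constant or the design degenerate)"
            )
        F[:, a] = s
        # weighted LS regression of x on components 1..a (deshrinking)
        A = np.column_stack([np.ones(n), F[:, : a + 1]])
        Aw = A * w[:, None]
        beta, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ x, rcond=None)
        fitted = A @ beta
        r = x - fitted
    return {"U": U, "C": C, "beta": beta, "x_mean": xbar, "F": F, "fitted": fitted}


def _wapls_scores(Y: np.ndarray, U: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Component scores for new assemblages given fitted taxon scores."""
    row = Y.sum(axis=1)
    if (row <= 0).any():
        bad = np.flatnonzero(row <= 0)
        raise ValueError(f"assemblage row(s) {bad.tolist()} sum to zero; weighted average undefined")
    K = U.shape[0]
    S = np.empty((Y.shape[0], K))
    for a in range(K):
        s = (Y @ U[a]) / row
        for b in range(a):
            s = s - C[a, b] * S[:, b]
        S[:, a] = s
    return S


class WAPLSRegressor(RegressorMixin, BaseEstimator):
    """Weighted-averaging partial least squares calibration.

    Parameters
    ----------
    n_components : int, default=2
        Number of WA-PLS components K.  K=1 reproduces classic weighted
        averaging with inverse deshrinking.
    sqrt_transform : bool, default=False
        Apply a square-root transform to the percentages before fitting
        (downweights dominant taxa).

    Attributes
    ----------
    taxon_scores_ : ndarray of shape (n_components, n_taxa)
        Per-component abundance-weighted taxon scores.
    ortho_coefs_ : ndarray of shape (n_components, n_components)
        Lower-triangular orthogonalization coefficients.
    coef_ : ndarray of shape (n_components,)
        Deshrinking regression coefficients on the component scores.
    intercept_ : float
    x_mean_ : float
        Abundance-weighted mean of the training environment.
    fitted_values_ : ndarray of shape (n_samples,)
        In-sample deshrunk predictions.
    """

    def __init__(self, n_components: int = 2, sqrt_transform: bool = False):
        self.n_components = n_components
        self.sqrt_transform = sqrt_transform

    def _prepare(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x taxa)")
        if (X < 0).any():
            raise ValueError("negative abundances")
        return np.sqrt(X) if self.sqrt_transform else X

    def fit(self, X, y):
        Y = self._prepare(X)
        y = np.asarray(y, dtype=float).ravel()
        n, m = Y.shape
        K = int(self.n_components)
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if n <= K + 1:
            raise ValueError(f"need n > n_components + 1 samples (got n={n}, K={K})")
        if y.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if np.ptp(y) == 0:
            raise ValueError("environment is constant: no gradient to calibrate against")
        dead = np.flatnonzero(Y.sum(axis=0) <= 0)
        if dead.size:
            warnings.warn(
                f"{dead.size} taxa have zero total abundance and are ignored in the fit",
                UserWarning,
                stacklevel=2,
            )
        core = _wapls_fit_core(Y, y, K)
        self.n_features_in_ = m
        self.taxon_scores_ = core["U"]
        self.ortho_coefs_ = core["C"]
        self.x_mean_ = core["x_mean"]
        self.intercept_ = float(core["beta"][0])
        self.coef_ = np.asarray(core["beta"][1:], dtype=float)
        self.fitted_values_ = core["fitted"]
        return self

    def predict(self, X):
        check_is_fitted(self, "taxon_scores_")
        Y = self._prepare(X)
        if Y.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Y.shape[1]} taxa but the model was fitted on "
                f"{self.n_features_in_}; harmonize taxa first"
            )
        S = _wapls_scores(Y, self.taxon_scores_, self.ortho_coefs_)
        return self.intercept_ + S @ self.coef_


def squared_chord(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Pairwise squared-chord distances between proportion matrices.

    P (a x m) and Q (b x m) hold proportions in [0, 1]; returns (a x b).
    """
    sp, sq = np.sqrt(P), np.sqrt(Q)
    # sum (sp - sq)^2 = |sp|^2 + |sq|^2 - 2 sp.sq
    d = (sp * sp).sum(axis=1)[:, None] + (sq * sq).sum(axis=1)[None, :] - 2.0 * sp @ sq.T
    return np.maximum(d, 0.0)


class ModernAnalogueRegressor(RegressorMixin, BaseEstimator):
    """Modern analogue technique: k-nearest assemblages by squared chord.

    The prediction for a new assemblage is the unweighted mean environment
    of its ``k`` nearest reference assemblages.  Percentages are converted
    to proportions internally.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D and aligned with y")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds the {X.shape[0]} reference samples")
        row = X.sum(axis=1)
        if (row <= 0).any():
            raise ValueError("reference assemblage with zero pollen sum")
        self.reference_props_ = X / row[:, None]
        self.reference_env_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def _distances(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("X taxa do not match the reference matrix; harmonize taxa first")
        row = X.sum(axis=1)
        if (row <= 0).any():
            raise ValueError("assemblage with zero pollen sum")
        return squared_chord(X / row[:, None], self.reference_props_)

    def predict(self, X):
        check_is_fitted(self, "reference_props_")
        d = self._distances(X)
        idx = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        return self.reference_env_[idx].mean(axis=1)

    def loo_predict(self):
        """Leave-one-out predictions over the reference set itself.

        Each reference sample is predicted from its k nearest neighbours
        excluding itself; requires k <= n_reference - 1.
        """
        check_is_fitted(self, "reference_props_")
        n = self.reference_props_.shape[0]
        if self.k > n - 1:
            raise ValueError(f"k={self.k} exceeds n-1={n - 1} available analogues under LOO")
        d = squared_chord(self.reference_props_, self.reference_props_)
        np.fill_diagonal(d, np.inf)
        idx = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        return self.reference_env_[idx].mean(axis=1)


# ---------------------------------------------------------------------------
# Cross-validation and performance

@dataclass(frozen=True)
class CVResult:
    """Per-sample observed/predicted pairs from cross-validation."""

    sample_ids: tuple
    observed: np.ndarray
    predicted: np.ndarray
    variable: str
    method: str
    hyperparam: int  # n_components for WA-PLS, k for the analogue technique

    def __post_init__(self):
        object.__setattr__(self, "observed", np.asarray(self.observed, dtype=float))
        object.__setattr__(self, "predicted", np.asarray(self.predicted, dtype=float))

    @property
    def residual(self) -> np.ndarray:
        """Signed residuals, predicted - observed."""
        return self.predicted - self.observed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "observed": self.observed,
                "predicted": self.predicted,
                "residual": self.residual,
                "variable": self.variable,
                "method": self.method,
                "hyperparam": self.hyperparam,
            }
        )


@dataclass(frozen=True)
class PerformanceStats:
    """RMSEP and R^2 for a cross-validated calibration model."""

    rmsep: float
    r2: float
    per_level: pd.DataFrame | None = None  # per-K (or per-k) table


def performance_stats(cv: CVResult, per_level: pd.DataFrame | None = None) -> PerformanceStats:
    """RMSEP = sqrt(mean squared residual); R^2 = squared Pearson correlation."""
    res = cv.residual
    if res.size < 3:
        raise ValueError("need at least 3 samples for performance statistics")
    if np.ptp(cv.observed) == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    rmsep = float(np.sqrt(np.mean(res**2)))
    r = stats.pearsonr(cv.observed, cv.predicted).statistic
    return PerformanceStats(rmsep=rmsep, r2=float(r**2), per_level=per_level)


def _make_estimator(method: str, hyperparam: int, sqrt_transform: bool = False):
    if method == "wapls":
        return WAPLSRegressor(n_components=hyperparam, sqrt_transform=sqrt_transform)
    if method == "analog":
        return ModernAnalogueRegressor(k=hyperparam)
    raise ValueError(f"unknown method {method!r} (expected 'wapls' or 'analog')")


def loo_cross_validate(
    ds: ModernDataset,
    variable: str,
    method: str = "wapls",
    hyperparam: int = 2,
    sqrt_transform: bool = False,
) -> CVResult:
    """Leave-one-out cross-validation of a calibration over a modern dataset.

    For each sample i the model is refit (or the analogue pool formed)
    without i and then predicts i.  Residuals are stored signed.  The
    sample order of the dataset does not affect any sample's residual.
    """
    if ds.pollen.basis != "percentages":
        raise ValueError("calibration expects a percentage pollen matrix")
    n = ds.n_samples
    if n < 10:
        raise ValueError(f"need at least 10 samples for cross-validation (got {n})")
    Y = ds.pollen.values
    x = ds.meta.variable(variable)
    pred = np.empty(n)
    if method == "analog":
        est = ModernAnalogueRegressor(k=hyperparam).fit(Y, x)
        pred = est.loo_predict()
    elif method == "wapls":
        Yt = np.sqrt(Y) if sqrt_transform else Y
        K = int(hyperparam)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            try:
                core = _wapls_fit_core(Yt[mask], x[mask], K)
            except Exception as exc:  # noqa: BLE001 - reported with context
                raise RuntimeError(
                    f"LOO refit failed when leaving out sample {ds.pollen.sample_ids[i]!r}: {exc}"
                ) from exc
            S = _wapls_scores(Yt[i : i + 1], core["U"], core["C"])
            pred[i] = core["beta"][0] + S[0] @ core["beta"][1:]
            mask[i] = True
    else:
        raise ValueError(f"unknown method {method!r} (expected 'wapls' or 'analog')")
    return CVResult(
        sample_ids=ds.pollen.sample_ids,
        observed=x,
        predicted=pred,
        variable=variable,
        method=method,
        hyperparam=int(hyperparam),
    )


def select_components(
    ds: ModernDataset,
    variable: str,
    K_max: int = 5,
    rel_tol: float = 0.05,
    sqrt_transform: bool = False,
):
    """Choose the WA-PLS component count by a 5% parsimony rule.

    Returns ``(K_star, stats)`` where K* is the smallest K whose LOO RMSEP
    lies within ``rel_tol`` of the global minimum over 1..K_max, and stats
    carries the per-K RMSEP/R^2 table.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    rows = []
    cvs = {}
    for K in range(1, K_max + 1):
        cv = loo_cross_validate(ds, variable, "wapls", K, sqrt_transform=sqrt_transform)
        ps = performance_stats(cv)
        cvs[K] = cv
        rows.append({"K": K, "rmsep": ps.rmsep, "r2": ps.r2})
    table = pd.DataFrame(rows)
    best = table["rmsep"].min()
    ok = table[table["rmsep"] <= best * (1.0 + rel_tol)]
    K_star = int(ok["K"].iloc[0])
    stats_out = performance_stats(cvs[K_star], per_level=table)
    return K_star, stats_out
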