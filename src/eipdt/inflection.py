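"""Inflection-point detection on probit-scale cumulative error curves.

The working hypothesis: cross-validated transfer-function errors from
native, secondary and artificial vegetation belong to distinct random
populations.  Plotting the cumulative fraction of error mass F(h) against
the Human Influence Index h on a probability-percentage (probit) vertical
scale renders each population as an approximately straight line, so the
boundaries between vegetation systems appear as intersections of fitted
linear segments — the inflection points (IPs).

The segmented fit is a continuous piecewise-linear least-squares regression
in (HII, probit) space.  Breakpoints are located by exhaustive grid search
at 0.5-HII resolution followed by golden-section refinement, with ties
broken toward the leftmost breakpoints.  The number of segments (1-3) can
be chosen by BIC on the curve alone (:func:`select_n_segments`), but when
the per-sample (HII, |residual|) pairs are available the preferred route is
a permutation test (:func:`select_segments_from_samples`): empirical
cumulative curves carry strongly autocorrelated sampling noise that an
iid-noise BIC mistakes for extra segments, whereas permuting residual
magnitudes across samples (which is exactly the one-system null hypothesis)
yields an honest null distribution for the misfit of the simpler model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .calibration import CVResult, loo_cross_validate
from .datasets import ModernDataset, SiteMeta
from .geo import RadiusSpec, subset_by_radius

__all__ = [
    "ErrorCurve",
    "SegmentedModel",
    "SegmentedRegression",
    "IPEstimate",
    "build_error_curve",
    "fit_segments",
    "select_n_segments",
    "select_segments_from_samples",
    "estimate_ips",
]

logger = logging.getLogger(__name__)

PROBIT_EPS = 1e-3  # clipping bound for the normal quantile
MAX_SEGMENTS = 3
GRID_STEP = 0.5  # HII resolution of the exhaustive breakpoint search
MIN_POINTS_PER_SEGMENT = 2
# an integer-HII bin must hold this fraction of all samples before its curve
# point enters the fit (1/300 = 5 samples at the default n = 1500); a
# fraction, not a count, so duplicating every sample leaves the fit unchanged
MIN_BIN_FRACTION = 1.0 / 300.0
# mean-squared-residual floor so BIC stays finite on exactly-linear data
_MSR_FLOOR = 1e-20


# ---------------------------------------------------------------------------
# Error curve

@dataclass(frozen=True)
class ErrorCurve:
    """Cumulative error fraction vs HII with its probit transform.

    ``fit_mask`` marks interior points (PROBIT_EPS <= F <= 1 - PROBIT_EPS)
    that enter the segmented fit; the terminal F = 1 point is always
    excluded because its probit is infinite.
    """

    hii_grid: np.ndarray
    cum_fraction: np.ndarray
    probit: np.ndarray
    fit_mask: np.ndarray
    weighting: str
    variable: str = ""
    method: str = ""

    def __post_init__(self):
        h = np.asarray(self.hii_grid, dtype=float)
        f = np.asarray(self.cum_fraction, dtype=float)
        if not (np.diff(h) > 0).all():
            raise ValueError("hii_grid must be strictly ascending")
        if (np.diff(f) < -1e-12).any():
            raise ValueError("cumulative fraction must be nondecreasing")
        if abs(f[-1] - 1.0) > 1e-9:
            raise ValueError("cumulative fraction must reach 1 at the top of the grid")
        object.__setattr__(self, "hii_grid", h)
        object.__setattr__(self, "cum_fraction", f)
        object.__setattr__(self, "probit", np.asarray(self.probit, dtype=float))
        object.__setattr__(self, "fit_mask", np.asarray(self.fit_mask, dtype=bool))

    @property
    def fit_points(self):
        """(HII, probit) coordinates that enter the segmented fit."""
        return self.hii_grid[self.fit_mask], self.probit[self.fit_mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hii": self.hii_grid,
                "cum_fraction": self.cum_fraction,
                "probit": self.probit,
                "in_fit": self.fit_mask,
                "weighting": self.weighting,
                "variable": self.variable,
                "method": self.method,
            }
        )


def _curve_from_arrays(
    hii: np.ndarray,
    abs_residual: np.ndarray,
    weighting: str,
    variable: str = "",
    method: str = "",
) -> ErrorCurve:
    hii = np.asarray(hii, dtype=float)
    mass = np.abs(np.asarray(abs_residual, dtype=float))
    if weighting == "error_mass":
        w = mass
        if w.sum() <= 0:
            raise ValueError(
                "all cross-validated residuals are zero; error-mass weighting is "
                "undefined — use weighting='count'"
            )
    elif weighting == "count":
        w = np.ones_like(mass)
    else:
        raise ValueError(f"unknown weighting {weighting!r} (expected error_mass|count)")
    grid_vals = np.round(hii).astype(int)
    grid, inverse, counts = np.unique(grid_vals, return_inverse=True, return_counts=True)
    totals = np.bincount(inverse, weights=w, minlength=grid.size)
    F = np.cumsum(totals) / totals.sum()
    F[-1] = 1.0
    probit = stats.norm.ppf(np.clip(F, PROBIT_EPS, 1.0 - PROBIT_EPS))
    # fit only interior points whose bin has real sample support: sparse
    # tail bins have huge leverage on probability paper but carry no
    # information
    fit_mask = (
        (F >= PROBIT_EPS)
        & (F <= 1.0 - PROBIT_EPS)
        & (counts >= MIN_BIN_FRACTION * hii.size)
    )
    return ErrorCurve(grid.astype(float), F, probit, fit_mask, weighting, variable, method)


def build_error_curve(cv: CVResult, meta: SiteMeta, weighting: str = "error_mass") -> ErrorCurve:
    """Cumulative probability curve of regression error against HII.

    Samples are pooled on an integer HII grid.  Under ``error_mass``
    weighting each sample contributes its absolute cross-validated residual
    as mass at its HII value, F(h) = sum_{hii_i <= h} |r_i| / sum |r_i|;
    under ``count`` weighting each sample contributes equally.
    """
    if cv.sample_ids != meta.sample_ids:
        raise ValueError("CV result and metadata are not aligned")
    n = len(cv.sample_ids)
    if n < 30:
        raise ValueError(f"need at least 30 samples to build an error curve (got {n})")
    if np.unique(np.round(meta.hii)).size < 10:
        raise ValueError("need at least 10 distinct (integer) HII values")
    return _curve_from_arrays(meta.hii, cv.residual, weighting, cv.variable, cv.method)


# ---------------------------------------------------------------------------
# Continuous piecewise-linear least squares

def _design(x: np.ndarray, knots) -> np.ndarray:
    cols = [np.ones_like(x), x]
    for k in knots:
        cols.append(np.maximum(x - k, 0.0))
    return np.column_stack(cols)


def _rss_for_knots(x, y, knots):
    A = _design(x, knots)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return float(resid @ resid), beta

def _batched_rss(x, y, knot_sets: np.ndarray) -> np.ndarray:
    """RSS of the continuous piecewise fit for many candidate knot vectors.

    knot_sets has shape (n_cand, n_knots).  Solves the normal equations in
    a single batched call.
    """
    n_cand, n_knots = knot_sets.shape
    npts = x.size
    A = np.empty((n_cand, npts, 2 + n_knots))
    A[:, :, 0] = 1.0
    A[:, :, 1] = x
    for j in range(n_knots):
        A[:, :, 2 + j] = np.maximum(x[None, :] - knot_sets[:, j : j + 1], 0.0)
    AtA = np.einsum("cip,ciq->cpq", A, A)
    Aty = np.einsum("cip,i->cp", A, y)
    # regularize singular candidates negligibly instead of failing
    AtA += 1e-12 * np.eye(2 + n_knots)[None]
    beta = np.linalg.solve(AtA, Aty[..., None])[..., 0]
    fitted = np.einsum("cip,cp->ci", A, beta)
    resid = y[None, :] - fitted
    return np.einsum("ci,ci->c", resid, resid)


def _candidate_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Candidate knot vectors at GRID_STEP resolution, leftmost-first order."""
    lo = np.ceil(x.min() / GRID_STEP) * GRID_STEP + GRID_STEP
    hi = np.floor(x.max() / GRID_STEP) * GRID_STEP - GRID_STEP
    grid = np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)
    # a knot must leave MIN_POINTS_PER_SEGMENT data points on each side
    def interior(k):
        return (
            (x < k).sum() >= MIN_POINTS_PER_SEGMENT
            and (x >= k).sum() >= MIN_POINTS_PER_SEGMENT
        )

    grid = np.array([k for k in grid if interior(k)])
    if grid.size == 0:
        raise ValueError("no admissible breakpoint candidates inside the data range")
    if n_knots == 1:
        return grid[:, None]
    pairs = [
        (k1, k2)
        for i, k1 in enumerate(grid)
        for k2 in grid[i + 1 :]
        if ((x >= k1) & (x < k2)).sum() >= MIN_POINTS_PER_SEGMENT
    ]
    if not pairs:
        raise ValueError("no admissible breakpoint pairs inside the data range")
    return np.array(pairs)


def _refine_knots(x, y, knots, half_width=GRID_STEP):
    """Golden-section refinement of each knot around its grid estimate."""
    knots = list(knots)
    for _ in range(2):  # two coordinate passes
        for j in range(len(knots)):
            lo = knots[j] - half_width
            hi = knots[j] + half_width
            if j > 0:
                lo = max(lo, knots[j - 1] + 1e-6)
            if j < len(knots) - 1:
                hi = min(hi, knots[j + 1] - 1e-6)
            lo = max(lo, float(x.min()) + 1e-6)
            hi = min(hi, float(x.max()) - 1e-6)
            if hi <= lo:
                continue

            def rss_of(k, _j=j):
                trial = list(knots)
                trial[_j] = k
                return _rss_for_knots(x, y, trial)[0]

            res = optimize.minimize_scalar(
                rss_of, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            if res.fun <= rss_of(knots[j]) + 1e-15:
                knots[j] = float(res.x)
    return knots


@dataclass(frozen=True)
class SegmentedModel:
    """A fitted continuous piecewise-linear model on the probit curve."""

    n_segments: int
    breakpoints: tuple  # HII values, ascending; empty for one segment
    slopes: tuple  # per-segment slope in probit units per HII
    intercepts: tuple  # per-segment intercept (y at HII = 0, extrapolated)
    rss: float
    bic: float
    n_points: int

    def predict(self, h):
        h = np.asarray(h, dtype=float)
        A = _design(h, self.breakpoints)
        # reconstruct spline coefficients from slopes/intercepts
        beta = [self.intercepts[0], self.slopes[0]]
        for s0, s1 in zip(self.slopes, self.slopes[1:]):
            beta.append(s1 - s0)
        return A @ np.asarray(beta)


def _bic(rss: float, n: int, n_segments: int) -> float:
    p = 2 * n_segments + (n_segments - 1) + 1
    msr = max(rss / n, _MSR_FLOOR)
    return n * np.log(msr) + p * np.log(n)


class SegmentedRegression(RegressorMixin, BaseEstimator):
    """Continuous piecewise-linear least squares with free breakpoints.

    Parameters
    ----------
    n_segments : int, default=2
        Number of linear segments (1-3).  With one segment this is ordinary
        simple linear regression.

    Attributes
    ----------
    breakpoints_ : ndarray
        Fitted breakpoint locations (ascending), length n_segments - 1.
    slopes_, intercepts_ : ndarray
        Per-segment line parameters; adjacent segments meet at breakpoints.
    rss_ : float
    bic_ : float
    """

    def __init__(self, n_segments: int = 2):
        self.n_segments = n_segments

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        s = int(self.n_segments)
        if s < 1 or s > MAX_SEGMENTS:
            raise ValueError(f"n_segments must be in 1..{MAX_SEGMENTS}")
        if x.size != y.size:
            raise ValueError("x and y lengths differ")
        if x.size < 4 * s:
            raise ValueError(f"need at least {4 * s} points for {s} segments (got {x.size})")
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        if s == 1:
            rss, beta = _rss_for_knots(x, y, [])
            knots = []
        else:
            cand = _candidate_knots(x, s - 1)
            if s == 3:
                # guarantee RSS(3) <= RSS(2): include pairs built from the
                # refined 2-segment knot, whose design nests the 2-segment fit
                sub = SegmentedRegression(2).fit(x, y)
                kf = float(sub.breakpoints_[0])
                singles = np.unique(cand.ravel())
                extra = np.array(
                    [sorted((kf, g)) for g in singles if abs(g - kf) > 1e-6]
                )
                if extra.size:
                    cand = np.vstack([cand, extra])
            rss_all = _batched_rss(x, y, cand)
            best = rss_all.min()
            first = int(np.argmax(rss_all <= best + 1e-12 * (1.0 + best)))
            knots = _refine_knots(x, y, cand[first])
            rss, beta = _rss_for_knots(x, y, knots)
        slopes = np.cumsum(np.concatenate([[beta[1]], beta[2:]]))
        intercepts = [beta[0]]
        for j, k in enumerate(knots):
            # segment j+1 passes through the same point at the knot
            yk = intercepts[j] + slopes[j] * k
            intercepts.append(yk - slopes[j + 1] * k)
        self.breakpoints_ = np.asarray(knots, dtype=float)
        self.slopes_ = slopes
        self.intercepts_ = np.asarray(intercepts, dtype=float)
        self.rss_ = float(rss)
        self.bic_ = _bic(self.rss_, x.size, s)
        self.n_points_ = int(x.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "breakpoints_")
        return self.to_model().predict(np.asarray(X, dtype=float).ravel())

    def to_model(self) -> SegmentedModel:
        check_is_fitted(self, "breakpoints_")
        return SegmentedModel(
            n_segments=int(self.n_segments),
            breakpoints=tuple(self.breakpoints_),
            slopes=tuple(self.slopes_),
            intercepts=tuple(self.intercepts_),
            rss=self.rss_,
            bic=self.bic_,
            n_points=self.n_points_,
        )


def fit_segments(curve: ErrorCurve, n_segments: int) -> SegmentedModel:
    """Fit a continuous piecewise-linear model to the curve's interior points."""
    x, y = curve.fit_points
    return SegmentedRegression(n_segments=n_segments).fit(x, y).to_model()


def select_n_segments(curve: ErrorCurve, max_segments: int = MAX_SEGMENTS) -> SegmentedModel:
    """Fit 1..max_segments and return the BIC-minimizing model."""
    x, y = curve.fit_points
    best = None
    for s in range(1, max_segments + 1):
        if x.size < 4 * s:
            break
        try:
            m = fit_segments(curve, s)
        except ValueError:
            continue
        if best is None or m.bic < best.bic:
            best = m
    if best is None:
        raise ValueError("curve has too few interior points for any segmented fit")
    return best


def _rank_cusum_pvalue(
    hii: np.ndarray,
    absres: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    min_side: int = 20,
) -> float:
    """Permutation changepoint test for an |residual|-vs-HII association.

    Samples are ordered by HII and their residual magnitudes converted to
    ranks; the statistic is the maximum standardized CUSUM of centered
    ranks over interior split points (a Wilcoxon-type changepoint scan).
    Under the null hypothesis that error magnitude is exchangeable with
    respect to HII — one homogeneous error population — permuting the
    ranks gives the exact null distribution.  Monte Carlo p-value:
    (1 + #{null >= obs}) / (n_perm + 1).
    """
    n = hii.size
    if n < 2 * min_side + 1:
        return 1.0
    order = np.argsort(hii, kind="stable")
    ranks = stats.rankdata(absres[order])
    k = np.arange(1, n)
    lo, hi = min_side, n - min_side
    scale = np.sqrt(k * (n - k) / n)

    def stat(r):
        c = np.cumsum(r - r.mean())[:-1]
        return float(np.max(np.abs(c[lo - 1 : hi]) / scale[lo - 1 : hi]))

    obs = stat(ranks)
    exceed = 0
    for _ in range(n_perm):
        exceed += stat(rng.permutation(ranks)) >= obs
    return (1 + exceed) / (n_perm + 1)


def select_segments_from_samples(
    hii: np.ndarray,
    abs_residual: np.ndarray,
    weighting: str = "error_mass",
    n_perm: int = 199,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> SegmentedModel:
    """Choose the segment count by sequential changepoint tests, then fit.

    Breakpoint *location* always comes from the continuous piecewise-linear
    least-squares fit on the probit curve; the *number* of segments is
    decided by rank-CUSUM permutation tests on the per-sample residual
    magnitudes (see :func:`_rank_cusum_pvalue`), which are exactly valid
    under the one-population null — unlike an iid-noise BIC on the curve
    points, whose strongly autocorrelated sampling noise mimics extra
    segments.

    Stage 1 scans the full HII range; if no association is found the curve
    is one segment.  Otherwise a 2-segment model is fitted and the scan is
    repeated separately below and above its breakpoint (Bonferroni over
    the two sides); a remaining association escalates to three segments.
    """
    rng = np.random.default_rng(rng)
    hii = np.asarray(hii, dtype=float)
    absres = np.abs(np.asarray(abs_residual, dtype=float))
    curve = _curve_from_arrays(hii, absres, weighting)

    p1 = _rank_cusum_pvalue(hii, absres, n_perm, rng)
    if p1 >= alpha:
        return fit_segments(curve, 1)
    model2 = fit_segments(curve, 2)
    split = hii > model2.breakpoints[0]
    p_lo = _rank_cusum_pvalue(hii[~split], absres[~split], n_perm, rng)
    p_hi = _rank_cusum_pvalue(hii[split], absres[split], n_perm, rng)
    if 2.0 * min(p_lo, p_hi) >= alpha:
        return model2
    try:
        return fit_segments(curve, 3)
    except ValueError:
        return model2


# ---------------------------------------------------------------------------
# IP estimation across radii, variables, and bootstrap replicates

@dataclass(frozen=True)
class IPEstimate:
    """Pooled inflection-point estimates with uncertainty.

    ip1 separates native from secondary vegetation; ip2 (absent in regions
    without an artificial system) separates secondary from artificial.
    ``fits`` retains every individual fitted breakpoint (per radius,
    variable, and bootstrap replicate) so alternative pooling conventions
    can be applied by the user.
    """

    ip1: float
    ip1_sd: float
    ip2: float | None
    ip2_sd: float | None
    n_boot: int
    fits: pd.DataFrame

    def __post_init__(self):
        if not (0.0 < self.ip1 < 64.0):
            raise ValueError("ip1 outside (0, 64)")
        if self.ip2 is not None and not (self.ip1 < self.ip2 < 64.0):
            raise ValueError("ip2 must lie in (ip1, 64)")
        for sd in (self.ip1_sd, self.ip2_sd):
            if sd is not None and sd < 0:
                raise ValueError("negative sd")

    def per_radius_ip1(self) -> pd.Series:
        """Mean first breakpoint per radius (point fits and bootstrap pooled)."""
        t = self.fits.dropna(subset=["bp1"])
        return t.groupby("radius_km")["bp1"].mean()


def estimate_ips(
    ds: ModernDataset,
    spec: RadiusSpec,
    variables=("mat", "map"),
    n_boot: int = 200,
    seed: int | None = None,
    method: str = "wapls",
    hyperparam: int = 2,
    weighting: str = "error_mass",
) -> IPEstimate:
    """Detect HII inflection points across the radius ladder.

    For every radius x variable the pipeline runs LOO cross-validation,
    builds the cumulative error curve, and selects a segmented model by
    sequential permutation testing (see
    :func:`select_segments_from_samples`).  Fitted breakpoints are pooled
    over radii, variables and seeded bootstrap replicates (resampling the
    per-sample (HII, |residual|) pairs); ip1 is the mean +/- sd of first
    breakpoints, ip2 likewise when a majority of point fits find three
    segments.
    """
    rng = np.random.default_rng(seed)
    rows = []
    point_nseg = []
    for r in spec.radii_km:
        sub = subset_by_radius(ds, spec, r)
        for var in variables:
            cv = loo_cross_validate(sub, var, method=method, hyperparam=hyperparam)
            curve = build_error_curve(cv, sub.meta, weighting=weighting)
            model = select_segments_from_samples(
                sub.meta.hii, np.abs(cv.residual), weighting=weighting, rng=rng
            )
            bps = list(model.breakpoints) + [np.nan] * (2 - len(model.breakpoints))
            rows.append(
                {
                    "radius_km": r, "variable": var, "kind": "point",
                    "n_segments": model.n_segments,
                    "bp1": bps[0], "bp2": bps[1],
                }
            )
            point_nseg.append(model.n_segments)
            hii = sub.meta.hii
            absres = np.abs(cv.residual)
            n = hii.size
            for _ in range(n_boot):
                idx = rng.integers(0, n, size=n)
                try:
                    bcurve = _curve_from_arrays(hii[idx], absres[idx], weighting)
                    bmodel = fit_segments(bcurve, model.n_segments)
                except ValueError:
                    continue  # degenerate resample
                bb = list(bmodel.breakpoints) + [np.nan] * (2 - len(bmodel.breakpoints))
                rows.append(
                    {
                        "radius_km": r, "variable": var, "kind": "boot",
                        "n_segments": bmodel.n_segments,
                        "bp1": bb[0], "bp2": bb[1],
                    }
                )
    fits = pd.DataFrame(rows)
    seg_counts = pd.Series(point_nseg).value_counts()
    logger.info("segment-count votes across radius x variable fits: %s", seg_counts.to_dict())
    bp1 = fits["bp1"].dropna()
    if bp1.empty:
        raise ValueError("no fit found more than one segment; no inflection point detected")
    ip1 = float(bp1.mean())
    ip1_sd = float(bp1.std(ddof=1)) if bp1.size > 1 else 0.0
    majority_three = (np.asarray(point_nseg) == 3).sum() > len(point_nseg) / 2
    ip2 = ip2_sd = None
    if majority_three:
        bp2 = fits["bp2"].dropna()
        if not bp2.empty:
            ip2 = float(bp2.mean())
            ip2_sd = float(bp2.std(ddof=1)) if bp2.size > 1 else 0.0
    return IPEstimate(ip1=ip1, ip1_sd=ip1_sd, ip2=ip2, ip2_sd=ip2_sd, n_boot=n_boot, fits=fits)
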