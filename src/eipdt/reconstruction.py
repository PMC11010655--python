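"""Native-calibration paleoclimate reconstruction with bootstrap errors.

The central consequence of the inflection-point analysis: transfer
functions trained only on native-vegetation samples (HII <= ip1) should
out-perform those trained on progressively more disturbed calibration sets.
``compare_training_sets`` quantifies this over the subset x radius grid;
``reconstruct`` applies the winning calibration to the fossil record, and
samples classified as nonnative are flagged unreliable but never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    WAPLSRegressor,
    loo_cross_validate,
    performance_stats,
)
from .datasets import ModernDataset, PollenMatrix
from .discriminant import FossilClassification
from .geo import RadiusSpec, subset_by_radius
from .inflection import IPEstimate

__all__ = [
    "TrainingComparison",
    "ReconstructedClimate",
    "compare_training_sets",
    "reconstruct",
    "bootstrap_errors",
]

MIN_SUBSET_N = 30


@dataclass(frozen=True)
class TrainingComparison:
    """LOO performance over the HII-subset x radius x variable grid.

    ``table`` has one row per cell (rmsep/r2/n, NaN where unavailable);
    ``winners`` maps each variable to its best (subset, radius) by lowest
    RMSEP, ties broken by higher R^2 then smaller subset.
    """

    table: pd.DataFrame
    winners: dict


def _subset_defs(ds: ModernDataset, ips):
    ip1 = float(ips.ip1) if hasattr(ips, "ip1") else float(ips[0])
    ip2 = ips.ip2 if hasattr(ips, "ip2") else ips[1]
    defs = [(f"hii<={ip1:g}", ds.meta.hii <= ip1)]
    if ip2 is not None:
        defs.append((f"hii<={float(ip2):g}", ds.meta.hii <= float(ip2)))
    defs.append(("all", np.ones(ds.n_samples, dtype=bool)))
    return defs


def compare_training_sets(
    ds: ModernDataset,
    ips,
    spec: RadiusSpec,
    variables=("mat", "map"),
    method: str = "wapls",
    hyperparam: int = 2,
) -> TrainingComparison:
    """LOO RMSEP/R^2 for every HII subset x radius x variable cell.

    Subsets with fewer than 30 samples are marked unavailable rather than
    failing.  The winner per variable is recorded with its radius.
    """
    rows = []
    for r in spec.radii_km:
        sub_r = subset_by_radius(ds, spec, r)
        for name, mask in _subset_defs(sub_r, ips):
            sub = sub_r.select_samples(mask)
            for var in variables:
                row = {"subset": name, "radius_km": r, "variable": var, "n": sub.n_samples}
                if sub.n_samples < MIN_SUBSET_N:
                    row.update({"rmsep": np.nan, "r2": np.nan, "available": False})
                else:
                    cv = loo_cross_validate(sub, var, method=method, hyperparam=hyperparam)
                    ps = performance_stats(cv)
                    row.update({"rmsep": ps.rmsep, "r2": ps.r2, "available": True})
                rows.append(row)
    table = pd.DataFrame(rows)
    winners = {}
    for var in variables:
        t = table[(table["variable"] == var) & table["available"]]
        if t.empty:
            continue
        t = t.sort_values(
            ["rmsep", "r2", "n"], ascending=[True, False, True], kind="stable"
        )
        best = t.iloc[0]
        winners[var] = {
            "subset": best["subset"],
            "radius_km": float(best["radius_km"]),
            "rmsep": float(best["rmsep"]),
            "r2": float(best["r2"]),
            "n": int(best["n"]),
        }
    return TrainingComparison(table=table, winners=winners)


@dataclass(frozen=True)
class ReconstructedClimate:
    """Per-fossil-sample climate estimates with errors and reliability flags.

    Nothing is deleted: samples from nonnative vegetation keep their
    estimates but carry ``reliable = False`` (the dotted-line convention).
    """

    sample_ids: tuple
    age: np.ndarray
    mat_est: np.ndarray
    mat_err: np.ndarray
    map_est: np.ndarray
    map_err: np.ndarray
    reliable: np.ndarray

    def __post_init__(self):
        for name in ("age", "mat_est", "mat_err", "map_est", "map_err"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "reliable", np.asarray(self.reliable, dtype=bool))
        if (self.mat_err < 0).any() or (self.map_err < 0).any():
            raise ValueError("negative reconstruction errors")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "age_calbp": self.age,
                "mat_c": self.mat_est,
                "mat_err": self.mat_err,
                "map_mm": self.map_est,
                "map_err": self.map_err,
                "reliable": self.reliable,
            }
        )


def reconstruct(
    models: dict,
    fossil: PollenMatrix,
    ages,
    fc: FossilClassification,
    errors: dict | None = None,
) -> ReconstructedClimate:
    """Apply fitted calibrations to the fossil record.

    ``models`` maps "mat" and "map" to fitted regressors over the fossil's
    (harmonized) taxa; ``errors`` optionally maps each variable to a
    per-sample error array or scalar (e.g. from :func:`bootstrap_errors`).
    The reliable flag is False exactly where the discriminant call is
    nonnative.
    """
    if fossil.sample_ids != fc.sample_ids:
        raise ValueError("fossil matrix and classification are not aligned")
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != fossil.n_samples:
        raise ValueError("ages are not aligned with the fossil samples")
    errors = errors or {}
    est, err = {}, {}
    for var in ("mat", "map"):
        if var not in models:
            raise KeyError(f"models must provide a fitted calibration for {var!r}")
        est[var] = np.asarray(models[var].predict(fossil.values), dtype=float)
        e = errors.get(var, 0.0)
        err[var] = np.broadcast_to(np.asarray(e, dtype=float), est[var].shape).copy()
    reliable = np.array([c == "native" for c in fc.call])
    return ReconstructedClimate(
        sample_ids=fossil.sample_ids,
        age=ages,
        mat_est=est["mat"],
        mat_err=err["mat"],
        map_est=est["map"],
        map_err=err["map"],
        reliable=reliable,
    )


def bootstrap_errors(
    ds_subset: ModernDataset,
    variable: str,
    fossil: PollenMatrix,
    n_boot: int = 500,
    seed: int | None = None,
    hyperparam: int = 2,
    rmsep: float | None = None,
) -> np.ndarray:
    """Sample-specific reconstruction errors by training-set bootstrap.

    The training set is resampled with replacement ``n_boot`` times, the
    WA-PLS calibration refit and the fossil record re-predicted; the error
    for each fossil sample is the standard deviation of its bootstrap
    predictions combined in quadrature with the model RMSEP (computed by
    LOO on the subset when not supplied).  With n_boot = 1 the bootstrap
    spread is zero and the error equals the RMSEP exactly.
    """
    if rmsep is None:
        cv = loo_cross_validate(ds_subset, variable, method="wapls", hyperparam=hyperparam)
        rmsep = performance_stats(cv).rmsep
    rng = np.random.default_rng(seed)
    Y = ds_subset.pollen.values
    x = ds_subset.meta.variable(variable)
    n = Y.shape[0]
    preds = np.empty((n_boot, fossil.n_samples))
    for b in range(n_boot):
        for attempt in range(10):
            idx = rng.integers(0, n, size=n)
            try:
                m = WAPLSRegressor(n_components=hyperparam).fit(Y[idx], x[idx])
                preds[b] = m.predict(fossil.values)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                f"bootstrap replicate {b} failed 10 consecutive degenerate draws"
            )
    spread = preds.std(axis=0, ddof=0) if n_boot > 1 else np.zeros(fossil.n_samples)
    return np.sqrt(spread**2 + float(rmsep) ** 2)
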