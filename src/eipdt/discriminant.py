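"""Group assignment from HII thresholds and linear discriminant classification.

Once the inflection points ip1 (native/secondary) and ip2
(secondary/artificial) are known, modern samples fall into a priori groups
by their HII (group 1: HII <= ip1; group 2: ip1 < HII < ip2; group 3:
HII >= ip2).  A linear discriminant rule fitted on the modern assemblages
with these labels is then applied to fossil spectra to decide, sample by
sample, whether each assemblage came from native (group 1) or nonnative
(groups 2 + 3) vegetation.

The discriminant itself is pooled-covariance Gaussian (classic LDA) on
square-root-transformed percentages, after dropping rare taxa and applying
an orthogonal variance-reduction projection that retains 90% of variance —
a guard against singular covariances when taxa are many and collinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .datasets import PollenMatrix, SiteMeta

__all__ = [
    "GroupLabels",
    "PollenDiscriminant",
    "ConfusionMatrix",
    "FossilClassification",
    "assign_groups",
    "fit_lda",
    "loo_confusion",
    "classify_fossil",
    "call_phases",
]


@dataclass(frozen=True)
class GroupLabels:
    """Per-sample a priori vegetation-system groups and the rule used."""

    sample_ids: tuple
    group: np.ndarray  # values in {1, 2, 3}
    rule: tuple  # (ip1, ip2-or-None)

    def __post_init__(self):
        g = np.asarray(self.group, dtype=int)
        if not np.isin(g, (1, 2, 3)).all():
            raise ValueError("groups must be 1, 2 or 3")
        object.__setattr__(self, "group", g)


def _extract_ips(ips):
    """Accept an IPEstimate-like object or a plain (ip1, ip2) pair."""
    if hasattr(ips, "ip1"):
        return float(ips.ip1), (None if ips.ip2 is None else float(ips.ip2))
    ip1, ip2 = ips
    return float(ip1), (None if ip2 is None else float(ip2))


def assign_groups(meta: SiteMeta, ips) -> GroupLabels:
    """Threshold HII into groups: <= ip1 -> 1; >= ip2 -> 3; between -> 2.

    Both boundaries follow the convention that ip1 is inclusive for group 1
    and ip2 inclusive for group 3.  With no ip2, everything above ip1 is
    group 2.
    """
    ip1, ip2 = _extract_ips(ips)
    g = np.full(meta.n_samples, 2, dtype=int)
    g[meta.hii <= ip1] = 1
    if ip2 is not None:
        g[meta.hii >= ip2] = 3
    return GroupLabels(meta.sample_ids, g, (ip1, ip2))


class PollenDiscriminant(ClassifierMixin, BaseEstimator):
    """LDA on pollen percentages with rare-taxon filtering and PCA guarding.

    Parameters
    ----------
    sqrt_transform : bool, default=True
        Square-root transform the percentages (variance stabilization).
    min_presence : float, default=0.01
        Drop taxa present (abundance > 0) in fewer than this fraction of
        training samples.
    var_retained : float, default=0.90
        Fraction of variance kept by the orthogonal projection before LDA.
    priors : {"equal", "proportional"}, default="equal"
        Group prior probabilities.
    """

    def __init__(
        self,
        sqrt_transform: bool = True,
        min_presence: float = 0.01,
        var_retained: float = 0.90,
        priors: str = "equal",
    ):
        self.sqrt_transform = sqrt_transform
        self.min_presence = min_presence
        self.var_retained = var_retained
        self.priors = priors

    def _transform_raw(self, X):
        X = np.asarray(X, dtype=float)
        return np.sqrt(X) if self.sqrt_transform else X

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D and aligned with y")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 groups for discriminant analysis")
        self.keep_mask_ = (X > 0).mean(axis=0) >= self.min_presence
        if not self.keep_mask_.any():
            raise ValueError("no taxa pass the presence filter")
        Z = self._transform_raw(X)[:, self.keep_mask_]
        self.pca_ = PCA(n_components=self.var_retained, svd_solver="full").fit(Z)
        P = self.pca_.transform(Z)
        dim = P.shape[1]
        if (counts < dim + 2).any():
            small = classes[counts < dim + 2]
            raise ValueError(
                f"group(s) {small.tolist()} have fewer than retained-dimension + 2 "
                f"= {dim + 2} samples; reduce var_retained"
            )
        pri = None if self.priors == "proportional" else np.full(classes.size, 1.0 / classes.size)
        self.lda_ = LinearDiscriminantAnalysis(solver="svd", priors=pri)
        try:
            self.lda_.fit(P, y)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular pooled covariance after reduction; lower var_retained"
            ) from exc
        self.classes_ = self.lda_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _project(self, X):
        check_is_fitted(self, "lda_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} taxa, model expects {self.n_features_in_}; "
                "harmonize taxa first"
            )
        return self.pca_.transform(self._transform_raw(X)[:, self.keep_mask_])

    def predict(self, X):
        return self.lda_.predict(self._project(X))

    def predict_proba(self, X):
        return self.lda_.predict_proba(self._project(X))


def fit_lda(pollen: PollenMatrix, labels: GroupLabels, **config) -> PollenDiscriminant:
    """Fit the discriminant on a percentage pollen matrix with group labels."""
    if pollen.basis != "percentages":
        raise ValueError("discriminant expects a percentage pollen matrix")
    if pollen.sample_ids != labels.sample_ids:
        raise ValueError("pollen and labels are not aligned")
    return PollenDiscriminant(**config).fit(pollen.values, labels.group)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Leave-one-out confusion counts and per-group correct percentages."""

    counts: pd.DataFrame  # index = observed group, columns = predicted group
    per_group_pct: pd.Series

    def __post_init__(self):
        if ((self.per_group_pct < 0) | (self.per_group_pct > 100)).any():
            raise ValueError("percentages outside [0, 100]")


def loo_confusion(pollen: PollenMatrix, labels: GroupLabels, **config) -> ConfusionMatrix:
    """Leave-one-out refit-and-classify confusion matrix.

    The whole pipeline (presence filter, projection, LDA) is refit for
    every left-out sample.
    """
    if pollen.basis != "percentages":
        raise ValueError("discriminant expects a percentage pollen matrix")
    X = pollen.values
    y = labels.group
    n = X.shape[0]
    template = PollenDiscriminant(**config)
    pred = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        est = clone(template).fit(X[mask], y[mask])
        pred[i] = est.predict(X[i : i + 1])[0]
        mask[i] = True
    groups = np.unique(y)
    counts = pd.DataFrame(0, index=groups, columns=groups)
    for obs, pr in zip(y, pred):
        counts.loc[obs, pr] += 1
    pct = pd.Series(
        {g: 100.0 * counts.loc[g, g] / counts.loc[g].sum() for g in groups}, name="correct_pct"
    )
    return ConfusionMatrix(counts=counts, per_group_pct=pct)


@dataclass(frozen=True)
class FossilClassification:
    """Per-fossil-sample group posteriors and the native/nonnative call."""

    sample_ids: tuple
    posteriors: pd.DataFrame  # columns = group labels
    call: tuple  # "native" | "nonnative"

    def __post_init__(self):
        p = self.posteriors.to_numpy()
        if (p < -1e-12).any() or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posteriors must be nonnegative and sum to 1 per sample")

    @property
    def native_posterior(self) -> np.ndarray:
        return self.posteriors[1].to_numpy()

    @property
    def nonnative_posterior(self) -> np.ndarray:
        cols = [c for c in self.posteriors.columns if c != 1]
        return self.posteriors[cols].to_numpy().sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = self.posteriors.copy()
        df.columns = [f"p_group{c}" for c in df.columns]
        df.insert(0, "sample_id", list(self.sample_ids))
        df["native_posterior"] = self.native_posterior
        df["nonnative_posterior"] = self.nonnative_posterior
        df["call"] = list(self.call)
        return df


def classify_fossil(model: PollenDiscriminant, fossil: PollenMatrix) -> FossilClassification:
    """Posterior group membership for fossil spectra; native iff P(group 1) > 0.5."""
    if fossil.basis != "percentages":
        raise ValueError("fossil matrix must be in percentages, harmonized to the model taxa")
    proba = model.predict_proba(fossil.values)
    post = pd.DataFrame(proba, columns=list(model.classes_))
    if 1 not in post.columns:
        raise ValueError("the fitted model has no group 1 (native) class")
    native = post[1].to_numpy()
    call = tuple("native" if p > 0.5 else "nonnative" for p in native)
    return FossilClassification(fossil.sample_ids, post, call)


def call_phases(fc: FossilClassification, ages, min_run: int = 2) -> pd.DataFrame:
    """Merge per-sample calls into contiguous phases along the age axis.

    Runs shorter than ``min_run`` samples are absorbed into the longer
    neighbouring run (ties go to the older neighbour).  Returns a table
    with one row per phase: call, age_start (younger bound), age_end,
    n_samples.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != len(fc.sample_ids):
        raise ValueError("ages are not aligned with the classified samples")
    calls = list(fc.call)

    def runs_of(seq):
        out = []
        start = 0
        for i in range(1, len(seq) + 1):
            if i == len(seq) or seq[i] != seq[start]:
                out.append([seq[start], start, i])  # [call, begin, end)
                start = i
        return out

    runs = runs_of(calls)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for j, (call, b, e) in enumerate(runs):
            if e - b >= min_run:
                continue
            left = runs[j - 1] if j > 0 else None
            right = runs[j + 1] if j < len(runs) - 1 else None
            if left is None:
                target = right
            elif right is None:
                target = left
            else:
                llen, rlen = left[2] - left[1], right[2] - right[1]
                # longer neighbour wins; tie -> older phase (larger ages, i.e.
                # the run later in the record since age increases with depth)
                target = left if llen > rlen else right if rlen > llen else right
            for i in range(b, e):
                calls[i] = target[0]
            runs = runs_of(calls)
            changed = True
            break
    rows = []
    for call, b, e in runs:
        rows.append(
            {
                "call": call,
                "age_start": float(ages[b:e].min()),
                "age_end": float(ages[b:e].max()),
                "n_samples": e - b,
            }
        )
    return pd.DataFrame(rows)
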