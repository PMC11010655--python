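import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from eipdt.datasets import PollenMatrix, SiteMeta
from eipdt.discriminant import (
    FossilClassification,
    GroupLabels,
    PollenDiscriminant,
    assign_groups,
    call_phases,
    classify_fossil,
    fit_lda,
    loo_confusion,
)


def meta_with_hii(hii):
    n = len(hii)
    ids = tuple(f"s{i}" for i in range(n))
    return SiteMeta(ids, np.zeros(n), np.zeros(n), np.full(n, 10.0),
                    np.full(n, 500.0), np.asarray(hii, dtype=float))


def two_blob_percentages(rng, n_per=40, sep=8.0, m=6):
    """Two well-separated compositional groups."""
    base1 = np.abs(rng.normal(10, 1, m))
    base2 = base1.copy()
    base2[:2] += sep
    rows, labels = [], []
    for g, base in ((1, base1), (2, base2)):
        for _ in range(n_per):
            v = np.abs(base + 0.5 * rng.standard_normal(m))
            rows.append(100 * v / v.sum())
            labels.append(g)
    X = np.array(rows)
    ids = tuple(f"s{i}" for i in range(len(rows)))
    pm = PollenMatrix(ids, tuple(f"T{j}" for j in range(m)), X, "percentages")
    return pm, GroupLabels(ids, np.array(labels), (22.0, None))


class TestAssignGroups:
    def test_three_groups(self):
        labels = assign_groups(meta_with_hii([10, 30, 50]), (22.0, 38.0))
        np.testing.assert_array_equal(labels.group, [1, 2, 3])

    def test_boundaries_inclusive(self):
        labels = assign_groups(meta_with_hii([22.0, 38.0]), (22.0, 38.0))
        np.testing.assert_array_equal(labels.group, [1, 3])

    def test_two_group_rule_without_ip2(self):
        labels = assign_groups(meta_with_hii([10, 50]), (22.0, None))
        np.testing.assert_array_equal(labels.group, [1, 2])

    def test_accepts_ip_estimate_like_object(self):
        class FakeIPs:
            ip1, ip2 = 22.0, 38.0

        labels = assign_groups(meta_with_hii([25.0]), FakeIPs())
        assert labels.group[0] == 2


class TestDiscriminantFit:
    def test_separated_groups_resubstitution_perfect(self, rng):
        pm, labels = two_blob_percentages(rng)
        model = fit_lda(pm, labels)
        assert (model.predict(pm.values) == labels.group).all()

    def test_permuted_labels_near_chance(self, rng):
        pm, labels = two_blob_percentages(rng, n_per=30)
        shuffled = GroupLabels(labels.sample_ids, rng.permutation(labels.group), labels.rule)
        cm = loo_confusion(pm, shuffled)
        accuracy = np.diag(cm.counts).sum() / cm.counts.to_numpy().sum()
        # binomial 95% band around 0.5 for n=60
        assert 0.5 - 2 * np.sqrt(0.25 / 60) - 0.1 < accuracy < 0.5 + 2 * np.sqrt(0.25 / 60) + 0.1

    def test_duplicating_samples_keeps_boundary(self, rng):
        pm, labels = two_blob_percentages(rng)
        model1 = fit_lda(pm, labels)
        doubled = PollenMatrix(
            tuple(list(pm.sample_ids) + [f"d{i}" for i in range(pm.n_samples)]),
            pm.taxa, np.vstack([pm.values, pm.values]), "percentages",
        )
        labels2 = GroupLabels(doubled.sample_ids, np.tile(labels.group, 2), labels.rule)
        model2 = fit_lda(doubled, labels2)
        query = pm.values[::7]
        np.testing.assert_allclose(
            model1.predict_proba(query), model2.predict_proba(query), atol=1e-8
        )

    def test_column_order_invariance(self, rng):
        pm, labels = two_blob_percentages(rng)
        model = fit_lda(pm, labels)
        perm = rng.permutation(pm.n_taxa)
        pm2 = PollenMatrix(pm.sample_ids, tuple(pm.taxa[j] for j in perm),
                           pm.values[:, perm], "percentages")
        model2 = fit_lda(pm2, labels)
        p1 = model.predict_proba(pm.values)
        p2 = model2.predict_proba(pm2.values)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_single_group_rejected(self, rng):
        pm, labels = two_blob_percentages(rng)
        same = GroupLabels(labels.sample_ids, np.ones(pm.n_samples, dtype=int), labels.rule)
        with pytest.raises(ValueError, match="at least 2 groups"):
            fit_lda(pm, same)


class TestLOOConfusion:
    def test_matches_independent_oracle(self, rng):
        pm, labels = two_blob_percentages(rng, n_per=20, sep=3.0)
        cm = loo_confusion(pm, labels)
        # independently composed pipeline: sqrt -> presence filter -> PCA -> LDA
        X, y = pm.values, labels.group
        pred = np.empty(len(y), dtype=int)
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            keep = (X[mask] > 0).mean(axis=0) >= 0.01
            Z = np.sqrt(X[mask][:, keep])
            pca = PCA(n_components=0.90, svd_solver="full").fit(Z)
            lda = LinearDiscriminantAnalysis(solver="svd", priors=[0.5, 0.5])
            lda.fit(pca.transform(Z), y[mask])
            pred[i] = lda.predict(pca.transform(np.sqrt(X[i : i + 1][:, keep])))[0]
        oracle = pd.crosstab(y, pred)
        for g_obs in cm.counts.index:
            for g_pred in cm.counts.columns:
                want = oracle.loc[g_obs, g_pred] if g_pred in oracle.columns else 0
                assert cm.counts.loc[g_obs, g_pred] == want

    def test_perfectly_separated_diagonal(self, rng):
        pm, labels = two_blob_percentages(rng, sep=12.0)
        cm = loo_confusion(pm, labels)
        assert np.diag(cm.counts).sum() == pm.n_samples
        assert (cm.per_group_pct == 100.0).all()


class TestFossilClassification:
    def test_posteriors_normalized_and_call_threshold(self, rng):
        pm, labels = two_blob_percentages(rng)
        model = fit_lda(pm, labels)
        fc = classify_fossil(model, pm)
        p = fc.posteriors.to_numpy()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        for call, native_p in zip(fc.call, fc.native_posterior):
            assert (call == "native") == (native_p > 0.5)
        np.testing.assert_allclose(fc.native_posterior + fc.nonnative_posterior, 1.0, atol=1e-9)

    def test_group_mean_sample_called_native(self, rng):
        pm, labels = two_blob_percentages(rng)
        model = fit_lda(pm, labels)
        mean1 = pm.values[labels.group == 1].mean(axis=0, keepdims=True)
        mean1 = 100 * mean1 / mean1.sum()
        fossil = PollenMatrix(("f1",), pm.taxa, mean1, "percentages")
        fc = classify_fossil(model, fossil)
        assert fc.native_posterior[0] > 0.5

    def test_equidistant_point_has_posterior_half(self, rng):
        """With equal priors and pooled covariance, the midpoint of the two
        class centroids in discriminant space is Mahalanobis-equidistant and
        must score exactly 0.5."""
        pm, labels = two_blob_percentages(rng, sep=6.0)
        model = fit_lda(pm, labels)
        mid = model.lda_.means_.mean(axis=0, keepdims=True)
        proba = model.lda_.predict_proba(mid)
        np.testing.assert_allclose(proba, [[0.5, 0.5]], atol=1e-9)


class TestCallPhases:
    def _fc(self, calls):
        n = len(calls)
        post = pd.DataFrame(
            {1: [0.9 if c == "native" else 0.1 for c in calls],
             2: [0.1 if c == "native" else 0.9 for c in calls]}
        )
        return FossilClassification(tuple(f"f{i}" for i in range(n)), post, tuple(calls))

    def test_three_phases(self):
        fc = self._fc(["native", "native", "nonnative", "nonnative", "native", "native"])
        phases = call_phases(fc, [10, 20, 30, 40, 50, 60])
        assert len(phases) == 3
        assert list(phases["call"]) == ["native", "nonnative", "native"]
        assert phases.loc[1, "age_start"] == 30

    def test_all_native_single_phase(self):
        fc = self._fc(["native"] * 5)
        phases = call_phases(fc, np.arange(5) * 100.0)
        assert len(phases) == 1
        assert phases.loc[0, "n_samples"] == 5

    def test_short_run_absorbed(self):
        fc = self._fc(["native", "native", "nonnative", "native", "native"])
        phases = call_phases(fc, np.arange(5) * 10.0, min_run=2)
        assert len(phases) == 1
        assert phases.loc[0, "call"] == "native"

    def test_tie_goes_to_older_phase(self):
        # single 'nonnative' between equal-length native runs -> absorbed into
        # the older (deeper) neighbour, which is itself native here; use
        # asymmetric calls so the tie is observable
        fc = self._fc(["native", "nonnative", "nonnative", "native", "nonnative", "nonnative"])
        phases = call_phases(fc, np.arange(6) * 10.0, min_run=2)
        # the lone leading native (length 1 < 2) joins its only neighbour
        assert phases.iloc[0]["call"] == "nonnative"
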