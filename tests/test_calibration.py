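import numpy as np
import pytest

from eipdt.calibration import (
    CVResult,
    ModernAnalogueRegressor,
    WAPLSRegressor,
    loo_cross_validate,
    performance_stats,
    select_components,
    squared_chord,
)
from eipdt.datasets import ModernDataset, PollenMatrix, SiteMeta


def gaussian_world(n=50, m=10, seed=42, noise=0.0):
    """Percentages from Gaussian responses along a single gradient."""
    rng = np.random.default_rng(seed)
    opt = rng.uniform(0, 20, m)
    x = np.sort(rng.uniform(0, 20, n))
    Y = np.exp(-0.5 * ((x[:, None] - opt[None, :]) / 4.0) ** 2) + 0.01
    if noise:
        Y *= np.exp(noise * rng.standard_normal(Y.shape))
    Y = 100.0 * Y / Y.sum(axis=1, keepdims=True)
    return Y, x


def wa_inverse_deshrinking(Y, x):
    """Independent classic weighted-averaging oracle."""
    optima = (Y * x[:, None]).sum(axis=0) / Y.sum(axis=0)
    wa = (Y @ optima) / Y.sum(axis=1)
    b1, b0 = np.polyfit(wa, x, 1)
    return b0 + b1 * wa


def as_dataset(Y, x):
    n = Y.shape[0]
    ids = tuple(f"s{i}" for i in range(n))
    pm = PollenMatrix(ids, tuple(f"T{j}" for j in range(Y.shape[1])), Y, "percentages")
    meta = SiteMeta(ids, np.zeros(n), np.zeros(n), x, np.full(n, 500.0), np.full(n, 5.0))
    return ModernDataset(pm, meta)


class TestWAPLS:
    def test_one_component_equals_classic_wa(self):
        Y, x = gaussian_world()
        model = WAPLSRegressor(n_components=1).fit(Y, x)
        np.testing.assert_allclose(model.predict(Y), wa_inverse_deshrinking(Y, x), atol=1e-8)

    def test_two_complementary_taxa_reproduce_linear_gradient(self):
        x = np.linspace(1, 9, 30)
        Y = np.column_stack([10 * x, 100 - 10 * x])
        model = WAPLSRegressor(n_components=1).fit(Y, x)
        np.testing.assert_allclose(model.predict(Y), x, atol=1e-6)

    def test_constant_environment_rejected(self):
        Y, _ = gaussian_world(n=20)
        with pytest.raises(ValueError, match="constant"):
            WAPLSRegressor(1).fit(Y, np.full(20, 7.0))

    def test_single_taxon_degenerate_design_rejected(self):
        Y = np.full((20, 1), 100.0)
        x = np.linspace(0, 10, 20)
        with pytest.raises(ValueError):
            WAPLSRegressor(1).fit(Y, x)

    def test_zero_column_warns_and_is_ignored(self):
        Y, x = gaussian_world(n=30, m=5)
        Y = np.column_stack([Y, np.zeros(30)])
        with pytest.warns(UserWarning, match="zero total abundance"):
            model = WAPLSRegressor(1).fit(Y, x)
        ref = WAPLSRegressor(1).fit(Y[:, :5] / Y[:, :5].sum(1, keepdims=True) * 100, x)
        np.testing.assert_allclose(model.predict(Y), ref.predict(Y[:, :5]), atol=1e-8)

    def test_predict_on_training_equals_fitted(self):
        Y, x = gaussian_world(noise=0.2)
        model = WAPLSRegressor(2).fit(Y, x)
        np.testing.assert_allclose(model.predict(Y), model.fitted_values_, atol=1e-9)

    def test_duplicated_row_duplicated_prediction(self):
        Y, x = gaussian_world()
        model = WAPLSRegressor(2).fit(Y, x)
        two = model.predict(np.vstack([Y[3], Y[3]]))
        assert two[0] == pytest.approx(two[1], abs=1e-12)

    def test_zero_row_prediction_rejected(self):
        Y, x = gaussian_world()
        model = WAPLSRegressor(2).fit(Y, x)
        with pytest.raises(ValueError, match="zero"):
            model.predict(np.zeros((1, Y.shape[1])))

    def test_taxa_mismatch_rejected(self):
        Y, x = gaussian_world()
        model = WAPLSRegressor(2).fit(Y, x)
        with pytest.raises(ValueError, match="harmonize"):
            model.predict(Y[:, :4])


class TestAnalogue:
    def test_exact_reference_match_k1(self):
        Y, x = gaussian_world(noise=0.3)
        model = ModernAnalogueRegressor(k=1).fit(Y, x)
        np.testing.assert_allclose(model.predict(Y[7:8]), x[7])

    def test_equidistant_pair_gives_midpoint(self):
        refs = np.array([[100.0, 0.0], [0.0, 100.0]])
        env = np.array([2.0, 8.0])
        model = ModernAnalogueRegressor(k=2).fit(refs, env)
        assert model.predict(np.array([[50.0, 50.0]]))[0] == pytest.approx(5.0)

    def test_matches_brute_force_sort(self, rng):
        refs = rng.dirichlet(np.ones(6), size=5) * 100
        env = rng.uniform(0, 10, 5)
        query = rng.dirichlet(np.ones(6), size=3) * 100
        model = ModernAnalogueRegressor(k=3).fit(refs, env)
        got = model.predict(query)
        d = squared_chord(query / 100, refs / 100)
        for i in range(3):
            nearest = np.argsort(d[i], kind="stable")[:3]
            assert got[i] == pytest.approx(env[nearest].mean(), abs=1e-12)

    def test_k_exceeding_references_rejected(self):
        with pytest.raises(ValueError, match="k=9"):
            ModernAnalogueRegressor(k=9).fit(np.eye(3) * 100, np.arange(3.0))

    def test_predictions_are_convex_combinations(self, rng):
        refs = rng.dirichlet(np.ones(8), size=30) * 100
        env = rng.uniform(0, 10, 30)
        model = ModernAnalogueRegressor(k=5).fit(refs, env)
        pred = model.predict(rng.dirichlet(np.ones(8), size=20) * 100)
        assert (pred >= env.min() - 1e-12).all() and (pred <= env.max() + 1e-12).all()


class TestLOOCrossValidation:
    def test_matches_naive_refit_oracle(self):
        Y, x = gaussian_world(n=30, noise=0.3)
        ds = as_dataset(Y, x)
        cv = loo_cross_validate(ds, "mat", "wapls", 2)
        for i in [0, 7, 29]:
            mask = np.ones(30, dtype=bool)
            mask[i] = False
            naive = WAPLSRegressor(2).fit(Y[mask], x[mask]).predict(Y[i : i + 1])[0]
            assert cv.predicted[i] == pytest.approx(naive, abs=1e-10)

    def test_analog_loo_excludes_self(self):
        Y, x = gaussian_world(n=30, noise=0.3)
        ds = as_dataset(Y, x)
        cv = loo_cross_validate(ds, "mat", "analog", 3)
        d = squared_chord(Y / 100, Y / 100)
        np.fill_diagonal(d, np.inf)
        for i in [0, 15]:
            nearest = np.argsort(d[i], kind="stable")[:3]
            assert cv.predicted[i] == pytest.approx(x[nearest].mean(), abs=1e-12)

    def test_noiseless_linear_two_taxa_near_zero_residuals(self):
        x = np.linspace(1, 9, 30)
        Y = np.column_stack([10 * x, 100 - 10 * x])
        cv = loo_cross_validate(as_dataset(Y, x), "mat", "wapls", 1)
        assert np.abs(cv.residual).max() < 1e-6

    def test_permutation_invariance(self, rng):
        Y, x = gaussian_world(n=25, noise=0.3)
        ds = as_dataset(Y, x)
        cv = loo_cross_validate(ds, "mat", "wapls", 2)
        perm = rng.permutation(25)
        cv_p = loo_cross_validate(ds.select_samples(perm), "mat", "wapls", 2)
        by_id = dict(zip(cv_p.sample_ids, cv_p.residual))
        for sid, res in zip(cv.sample_ids, cv.residual):
            assert by_id[sid] == pytest.approx(res, abs=1e-12)

    def test_loo_rmsep_not_below_insample_rmse(self):
        Y, x = gaussian_world(n=40, noise=0.4)
        ds = as_dataset(Y, x)
        cv = loo_cross_validate(ds, "mat", "wapls", 2)
        model = WAPLSRegressor(2).fit(Y, x)
        rmse_in = np.sqrt(np.mean((model.fitted_values_ - x) ** 2))
        assert performance_stats(cv).rmsep >= rmse_in - 1e-9

    def test_small_n_rejected(self):
        Y, x = gaussian_world(n=8)
        with pytest.raises(ValueError, match="at least 10"):
            loo_cross_validate(as_dataset(Y, x), "mat", "wapls", 1)


class TestPerformanceStats:
    def _cv(self, observed, predicted):
        n = len(observed)
        return CVResult(tuple(f"s{i}" for i in range(n)), observed, predicted, "mat", "wapls", 1)

    def test_rmsep_arithmetic(self):
        cv = self._cv([0.0, 1.0, 2.0], [3.0, -3.0, 4.0])
        # residuals 3, -4, 2 -> rmse = sqrt(29/3)
        assert performance_stats(cv).rmsep == pytest.approx(np.sqrt(29 / 3))

    def test_perfect_prediction(self):
        obs = np.array([1.0, 2.0, 5.0])
        ps = performance_stats(self._cv(obs, obs))
        assert ps.rmsep == 0.0 and ps.r2 == pytest.approx(1.0)

    def test_constant_offset_keeps_r2(self):
        obs = np.array([1.0, 2.0, 5.0])
        ps = performance_stats(self._cv(obs, obs + 2.0))
        assert ps.r2 == pytest.approx(1.0)
        assert ps.rmsep == pytest.approx(2.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            performance_stats(self._cv([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))


class TestSelectComponents:
    def test_parsimony_rule_consistent_with_table(self):
        Y, x = gaussian_world(n=40, noise=0.3)
        K_star, stats_out = select_components(as_dataset(Y, x), "mat", K_max=3)
        table = stats_out.per_level
        best = table["rmsep"].min()
        eligible = table[table["rmsep"] <= best * 1.05]["K"]
        assert K_star == int(eligible.iloc[0])
        assert stats_out.rmsep == pytest.approx(
            float(table.loc[table["K"] == K_star, "rmsep"].iloc[0])
        )
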