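import numpy as np
import pytest

from gonadnmr.chemometrics import (
    CVResult, ScalingSpec, classification_metrics, cross_validate,
    fit_pls_nipals, mccv, scale_matrix, vip_scores,
)


class TestScaling:
    def test_autoscale_unit_variance(self):
        X = np.array([[1.0], [3.0]])
        Xs, _ = scale_matrix(X, ScalingSpec(scale="auto"))
        np.testing.assert_allclose(Xs.ravel(), [-0.7071, 0.7071], atol=1e-4)

    def test_pareto_sqrt_rule(self):
        col = np.array([0.0, 8.0])  # sample sd 4sqrt(2)... use explicit sd 4
        col = np.array([-4.0, 4.0]) / np.sqrt(2)  # sample sd = 4
        X = col.reshape(-1, 1)
        Xs, _ = scale_matrix(X, ScalingSpec(scale="pareto"))
        np.testing.assert_allclose(Xs.ravel(), (col - col.mean()) / 2.0)

    def test_train_stats_applied_to_held_out(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        _, stats = scale_matrix(X, ScalingSpec(scale="auto"))
        row = X.mean(axis=0, keepdims=True)
        Xs, _ = scale_matrix(row, ScalingSpec(scale="auto"), train_stats=stats)
        np.testing.assert_allclose(Xs, 0.0, atol=1e-12)

    def test_zero_variance_column_dropped_with_warning(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            Xs, stats = scale_matrix(X, ScalingSpec(scale="auto"))
        assert Xs.shape[1] == 1
        assert stats.kept.tolist() == [False, True]


class TestNipals:
    def test_perfect_predictor_r2y(self):
        y = np.array([-1, -1, -1, 1, 1, 1])
        X = y.astype(float).reshape(-1, 1)
        Xs, _ = scale_matrix(X, ScalingSpec(scale="auto"))
        model = fit_pls_nipals(Xs, y, 1)
        assert model.r2y[0] == pytest.approx(1.0, abs=1e-10)

    def test_printed_variance_accounting(self):
        # cumulative R2 over two LVs is the plain sum of the per-LV values
        r2x = [0.1837, 0.3028, 0.0641, 0.0515, 0.0423, 0.0427]
        r2y = [0.7525, 0.0479, 0.0830, 0.0504, 0.0189, 0.0075]
        assert round(sum(r2x[:2]), 4) == 0.4865
        assert round(sum(r2y[:2]), 4) == 0.8004

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_oracle_equivalence_sklearn(self, seed):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 8))
        y = np.repeat([-1, 1], 10)[rng.permutation(20)]
        Xc, _ = scale_matrix(X, ScalingSpec(scale="none"))
        model = fit_pls_nipals(Xc, y, 3)
        yhat = Xc @ model.regression_vector() + model.y_mean

        oracle = PLSRegression(n_components=3, scale=False).fit(X, y.astype(float))
        yhat_o = oracle.predict(X).ravel()
        np.testing.assert_allclose(yhat, yhat_o, atol=1e-8)
        # scores agree up to component sign
        np.testing.assert_allclose(np.abs(model.T), np.abs(oracle.x_scores_),
                                   atol=1e-8)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_score_orthogonality_and_r2_bounds(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 30))
        y = np.repeat([-1, 1], [7, 8])
        Xs, _ = scale_matrix(X, ScalingSpec(scale="pareto"))
        model = fit_pls_nipals(Xs, y, 5)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()
        assert (model.r2x >= -1e-12).all() and (model.r2y >= -1e-12).all()
        assert model.r2x.sum() <= 1 + 1e-8 and model.r2y.sum() <= 1 + 1e-8

    def test_rank_exhaustion_truncates_with_warning(self):
        y = np.array([-1.0, -1, 1, 1])
        X = np.column_stack([y, 2 * y])  # rank 1
        with pytest.warns(RuntimeWarning, match="truncated"):
            model = fit_pls_nipals(X, y, 3)
        assert model.A < 3

    def test_non_binary_y_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="binary"):
            fit_pls_nipals(X, np.array([0, 1, 2, 0, 1, 2]), 2)


class TestVIP:
    def test_single_variable_vip_is_one(self):
        y = np.array([-1.0, -1, 1, 1])
        X = (y + np.array([0.1, -0.1, 0.05, -0.05])).reshape(-1, 1)
        Xs, _ = scale_matrix(X, ScalingSpec(scale="auto"))
        model = fit_pls_nipals(Xs, y, 1)
        assert vip_scores(model)[0] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_mean_squared_vip_is_one(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(18, 25))
        y = np.repeat([-1, 1], 9)
        Xs, _ = scale_matrix(X, ScalingSpec(scale="auto"))
        model = fit_pls_nipals(Xs, y, 3)
        assert np.mean(vip_scores(model) ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_seeded_discriminant_attains_max_vip(self, effect_matrix_factory):
        hits = 0
        for rep in range(20):
            X, y = effect_matrix_factory(12, 12, 51, effect_idx=(17,),
                                         log2fc=1.0, seed=100 + rep)
            Xs, _ = scale_matrix(X, ScalingSpec(scale="auto"))
            model = fit_pls_nipals(Xs, y, 2)
            if np.argmax(vip_scores(model)) == 17:
                hits += 1
        assert hits >= 18


class TestMetrics:
    def test_error_one_of_34(self):
        y = np.array([-1] * 18 + [1] * 16)
        pred = y.copy()
        pred[0] = 1
        error, *_ = classification_metrics(y, pred)
        assert round(error, 4) == 0.0294

    def test_confusion_ratios(self):
        y = np.array([1] * 16 + [-1] * 16)
        pred = np.array([1] * 16 + [-1] * 15 + [1])
        _, sens, spec, _ = classification_metrics(y, pred)
        assert sens == 1.0
        assert spec == pytest.approx(0.9375)

    def test_auc_extremes_and_ties(self):
        y = np.array([-1, -1, 1, 1])
        perfect = np.array([0.1, 0.2, 0.8, 0.9])
        assert classification_metrics(y, y, perfect)[3] == 1.0
        assert classification_metrics(y, y, -perfect)[3] == 0.0
        assert classification_metrics(y, y, np.zeros(4))[3] == 0.5

    def test_single_class_rates_absent(self):
        y = np.array([1, 1, 1])
        _, sens, spec, auc = classification_metrics(y, np.array([1, 1, -1]))
        assert sens is not None and spec is None and auc is None


class TestCrossValidation:
    def test_separable_cohort_reaches_zero_error(self, effect_matrix_factory):
        X, y = effect_matrix_factory(12, 12, 20, effect_idx=(0, 1, 2),
                                     log2fc=3.0, cv=0.05, noise_sd=0.01, seed=4)
        res = cross_validate(X, y, ScalingSpec(scale="pareto"), A_max=4, k=5)
        assert res.error_min == 0.0
        assert res.optLV <= 3

    def test_permuted_labels_give_chance_error(self, effect_matrix_factory):
        rng = np.random.default_rng(0)
        errs = []
        for rep in range(20):
            X, y = effect_matrix_factory(10, 10, 30, seed=200 + rep)
            yp = rng.permutation(y)
            res = cross_validate(X, yp, ScalingSpec(scale="auto"), A_max=3, k=5)
            errs.append(res.error_min)
        assert 0.4 <= np.mean(errs) <= 0.6

    def test_leave_one_out_curve_length(self, effect_matrix_factory):
        X, y = effect_matrix_factory(6, 6, 10, seed=3)
        res = cross_validate(X, y, ScalingSpec(scale="auto"), A_max=4, k=len(y))
        assert res.scheme == "kfold"
        assert len(res.error_curve) == 4

    def test_optlv_is_smallest_argmin(self):
        res = CVResult("kfold", np.array([0.3, 0.1, 0.1, 0.2]), 0, 0, None,
                       None, None)
        assert int(np.argmin(res.error_curve)) + 1 == 2


class TestMCCV:
    def test_seed_determinism(self, effect_matrix_factory):
        X, y = effect_matrix_factory(10, 8, 15, effect_idx=(0,), seed=6)
        a = mccv(X, y, ScalingSpec(scale="auto"), A_max=3, n_reps=30, seed=5)
        b = mccv(X, y, ScalingSpec(scale="auto"), A_max=3, n_reps=30, seed=5)
        np.testing.assert_array_equal(a.error_curve, b.error_curve)

    def test_separable_cohort_low_error(self, effect_matrix_factory):
        X, y = effect_matrix_factory(12, 12, 20, effect_idx=(0, 1, 2),
                                     log2fc=3.0, cv=0.05, noise_sd=0.01, seed=8)
        res = mccv(X, y, ScalingSpec(scale="auto"), A_max=3, n_reps=50, seed=1)
        assert res.error_min <= 0.05

    def test_invalid_split_fraction(self, effect_matrix_factory):
        X, y = effect_matrix_factory(6, 6, 5, seed=0)
        with pytest.raises(ValueError):
            mccv(X, y, ScalingSpec(scale="auto"), split_fraction=1.5)


class TestLeakageGuard:
    def test_supervised_selection_leakage_shows_optimistic_bias(
            self, effect_matrix_factory):
        """Selecting variables on the full data before CV biases null error
        downward; with in-fold-only statistics the error stays at chance."""
        proper, leaky = [], []
        for rep in range(15):
            X, y = effect_matrix_factory(10, 10, 120, seed=400 + rep)
            spec = ScalingSpec(scale="auto")
            proper.append(
                cross_validate(X, y, spec, A_max=2, k=5).error_min)
            # deliberate leakage: rank variables by VIP fitted on ALL samples
            Xs, _ = scale_matrix(X, spec)
            vip = vip_scores(fit_pls_nipals(Xs, y, 2))
            top = np.argsort(-vip)[:5]
            leaky.append(
                cross_validate(X[:, top], y, spec, A_max=2, k=5).error_min)
        bias = np.mean(proper) - np.mean(leaky)
        assert bias > 0.1, f"leakage bias not measurable: {bias:.3f}"
        assert 0.35 <= np.mean(proper) <= 0.65
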