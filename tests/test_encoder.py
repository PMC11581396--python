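"""Lagged design construction, ridge closed form, nested CV behavior."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

from lagcoder.encoder import (DEFAULT_LAMBDA_GRID, LaggedRidge, LagSpec,
                              NestedEncoder, RidgeConfig, build_lagged_design,
                              fisher_mean, nested_cv, pearson_by_column,
                              ridge_fit, single_lag_profile, zscore_apply,
                              zscore_fit, zscore_self)
from lagcoder.synth import (SessionSpec, accuracy_ceiling, gen_feature_bank,
                            gen_kernels, synthesize_eeg)


class TestLaggedDesign:
    def test_lag_count_from_range_and_rate(self):
        lags = LagSpec(0.0, 0.75, 32.0)
        assert lags.n_lags == 25  # 0.75 * 32 + 1
        D = build_lagged_design(np.random.default_rng(0).standard_normal(100),
                                lags)
        assert D.shape == (100, 25)

    def test_impulse_shifts_by_lag(self):
        x = np.zeros(40)
        x[10] = 1.0
        D = build_lagged_design(x, LagSpec(0.0, 0.25, 32.0))
        for j in range(9):
            col = D[:, j]
            assert np.flatnonzero(col).tolist() == [10 + j]

    def test_zero_feature_zero_design(self):
        D = build_lagged_design(np.zeros((50, 3)), LagSpec())
        assert not D.any()

    def test_lags_exceeding_run_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            build_lagged_design(np.zeros(10), LagSpec(0.0, 0.75, 32.0))


class TestZscore:
    def test_columns_standardized(self, rng):
        runs = [rng.standard_normal((50, 3)) * 4 + 2 for _ in range(3)]
        stats = zscore_fit(runs)
        pooled = np.concatenate([zscore_apply(r, stats) for r in runs])
        assert np.allclose(pooled.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(pooled.std(axis=0), 1, atol=1e-10)

    def test_constant_column_left_at_zero(self, rng, caplog):
        x = rng.standard_normal((50, 2))
        x[:, 1] = 7.0
        out = zscore_self(x)
        assert np.allclose(out[:, 1], 0.0)

    def test_train_stats_on_train_equal_joint_zscore(self, rng):
        runs = [rng.standard_normal((40, 2)) for _ in range(2)]
        stats = zscore_fit(runs)
        joint = zscore_self(np.concatenate(runs))
        applied = np.concatenate([zscore_apply(r, stats) for r in runs])
        assert np.allclose(joint, applied)


class TestRidge:
    def test_matches_closed_form_oracle(self, rng):
        X = rng.standard_normal((200, 10))
        Y = rng.standard_normal((200, 3))
        W = ridge_fit(X, Y, 1.0)
        oracle = np.linalg.inv(X.T @ X + np.eye(10)) @ X.T @ Y
        assert np.allclose(W, oracle, atol=1e-8)

    def test_matches_sklearn(self, rng):
        X = rng.standard_normal((300, 20))
        Y = rng.standard_normal((300, 4))
        for lam in (0.1, 10.0, 1e4):
            W = ridge_fit(X, Y, lam)
            sk = Ridge(alpha=lam, fit_intercept=False).fit(X, Y)
            assert np.allclose(W, sk.coef_.T, atol=1e-8)

    def test_shrinkage_monotone_in_lambda(self, rng):
        X = rng.standard_normal((100, 8))
        Y = rng.standard_normal((100, 2))
        norms = [np.linalg.norm(ridge_fit(X, Y, lam))
                 for lam in DEFAULT_LAMBDA_GRID]
        assert np.all(np.diff(norms) < 0)

    def test_orthonormal_design_ols_limit(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((50, 5)))
        Y = rng.standard_normal((50, 2))
        W = ridge_fit(Q, Y, 1e-12)
        assert np.allclose(W, Q.T @ Y, atol=1e-8)

    def test_nonfinite_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        X[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            ridge_fit(X, np.zeros((20, 1)), 1.0)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            RidgeConfig((1.0, 0.1))


class TestFisherMean:
    def test_identical_values_fixed_point(self):
        assert fisher_mean([0.4, 0.4]) == pytest.approx(0.4)

    def test_antisymmetric_pair_is_zero(self):
        assert fisher_mean([0.5, -0.5]) == pytest.approx(0.0, abs=1e-12)

    def test_against_numeric_oracle(self):
        # oracle: tanh((arctanh .3 + arctanh .9) / 2) evaluated directly
        oracle = np.tanh((np.arctanh(0.3) + np.arctanh(0.9)) / 2)
        assert oracle == pytest.approx(0.7118, abs=5e-5)
        assert fisher_mean([0.3, 0.9]) == pytest.approx(oracle, abs=1e-12)
        assert fisher_mean([0.3, 0.9]) != pytest.approx(0.6, abs=1e-3)


class TestLaggedRidgeEstimator:
    def test_sklearn_contract(self, rng):
        est = LaggedRidge(alpha=2.0)
        assert est.get_params()["alpha"] == 2.0
        est.set_params(alpha=5.0)
        X = rng.standard_normal((100, 2))
        y = rng.standard_normal((100, 3))
        est.fit(X, y)
        assert est.coef_.shape == (2 * 25, 3)
        assert est.weights_.shape == (2, 25, 3)
        assert est.predict(X).shape == (100, 3)
        assert np.isfinite(est.score(X, y))

    def test_recovers_pure_delay(self, rng):
        x = rng.standard_normal(2000)
        y = np.zeros(2000)
        y[5:] = x[:-5]  # EEG = stimulus delayed by 5 samples
        est = LaggedRidge(alpha=1e-6).fit(x, y)
        assert np.argmax(np.abs(est.weights_[0, :, 0])) == 5


def _tiny_session(seed, snr=None, n_runs=5, run_len_s=40.0, n_channels=3):
    spec = SessionSpec(n_runs=n_runs, run_len_s=run_len_s,
                       n_channels=n_channels)
    lags = LagSpec()
    bank = gen_feature_bank("envelope_like", spec, seed)
    K = gen_kernels(spec, lags, seed, n_features=2)
    if snr is None:  # effectively noiseless
        recs, _ = synthesize_eeg([bank], [K], 1e9, spec, seed)
    else:
        recs, _ = synthesize_eeg([bank], [K], snr, spec, seed)
    return [b.data for b in bank], [r.data for r in recs], K


class TestNestedCV:
    def test_noiseless_recovery(self):
        X, Y, _ = _tiny_session(0)
        res = nested_cv(X, Y)
        assert res.scalp_mean_r > 0.95

    def test_null_features_score_zero(self, rng):
        X = [rng.standard_normal((800, 2)) for _ in range(5)]
        Y = [rng.standard_normal((800, 3)) for _ in range(5)]
        res = nested_cv(X, Y)
        se = 1.0 / np.sqrt(800)
        assert abs(res.per_run_r.mean()) < 3 * se

    def test_snr_one_hits_analytic_ceiling(self):
        X, Y, _ = _tiny_session(1, snr=1.0, n_runs=6, run_len_s=120.0)
        res = nested_cv(X, Y)
        assert res.mean_r == pytest.approx(accuracy_ceiling(1.0), abs=0.05)

    def test_rotation_covers_each_run_once(self):
        from lagcoder.encoder import _rotations
        n = 7
        tests = [t for _, _, t in _rotations(n)]
        tunes = [tu for _, tu, _ in _rotations(n)]
        assert sorted(tests) == list(range(n))
        assert sorted(tunes) == list(range(n))
        for train, tune, test in _rotations(n):
            assert len(train) == n - 2 and tune != test

    def test_shuffled_test_run_scores_zero(self, rng):
        """Time-shuffling one held-out run's EEG must drive its r to chance
        without affecting the other runs (no leakage across runs)."""
        X, Y, _ = _tiny_session(2, snr=4.0)
        res_intact = nested_cv(X, Y)
        Y_shuf = [y.copy() for y in Y]
        Y_shuf[3] = Y_shuf[3][rng.permutation(Y_shuf[3].shape[0])]
        res = nested_cv(X, Y_shuf)
        se = 1.0 / np.sqrt(Y[3].shape[0])
        assert abs(res.per_run_r[3].mean()) < 3 * se
        others = [i for i in range(5) if i != 3]
        # the shuffled run also serves once as tuning data; every other
        # run's accuracy stays at its intact level
        assert np.allclose(res.per_run_r[others].mean(axis=1),
                           res_intact.per_run_r[others].mean(axis=1),
                           atol=0.05)

    def test_fewer_than_three_runs_rejected(self, rng):
        X = [rng.standard_normal((100, 1))] * 2
        Y = [rng.standard_normal((100, 1))] * 2
        with pytest.raises(ValueError, match="3 runs"):
            nested_cv(X, Y)

    def test_accuracy_monotone_in_snr(self):
        """Spearman rho = 1 between SNR level and accuracy, per seed."""
        from lagcoder.stats import spearman
        snrs = [0.1, 0.5, 1.0, 4.0, 16.0]
        rhos = []
        for seed in range(3):
            accs = []
            for snr in snrs:
                X, Y, _ = _tiny_session(seed + 10, snr=snr)
                accs.append(nested_cv(X, Y).scalp_mean_r)
            rhos.append(spearman(snrs, accs))
        assert np.mean(rhos) == pytest.approx(1.0)


class TestSingleLagProfile:
    def test_pure_delay_kernel_peaks_at_delay(self):
        spec = SessionSpec(n_runs=4, run_len_s=40.0, n_channels=2)
        lags = LagSpec()
        bank = gen_feature_bank("envelope_like", spec, 5, n_dims=1)
        K = np.zeros((1, lags.n_lags, 2))
        K[0, 7, :] = 1.0  # pure delay of 7 samples
        recs, _ = synthesize_eeg([bank], [K], 1e9, spec, 5)
        prof = single_lag_profile([b.data for b in bank],
                                  [r.data for r in recs], lags)
        assert prof.shape == (25,)
        assert np.argmax(prof) == 7

    def test_two_peak_kernel_shows_two_local_maxima(self):
        spec = SessionSpec(n_runs=4, run_len_s=60.0, n_channels=2)
        lags = LagSpec()
        bank = gen_feature_bank("envelope_like", spec, 6, n_dims=1)
        K = np.zeros((1, lags.n_lags, 2))
        K[0, 4, :] = 1.0
        K[0, 18, :] = 1.0  # two separated delay peaks
        recs, _ = synthesize_eeg([bank], [K], 1e9, spec, 6)
        prof = single_lag_profile([b.data for b in bank],
                                  [r.data for r in recs], lags)
        local_max = [j for j in range(1, 24)
                     if prof[j] >= prof[j - 1] and prof[j] >= prof[j + 1]]
        assert 4 in local_max or 5 in local_max or 3 in local_max
        assert any(j in local_max for j in (17, 18, 19))

    def test_zero_kernel_flat_profile(self, rng):
        spec = SessionSpec(n_runs=4, run_len_s=30.0, n_channels=2)
        bank = gen_feature_bank("envelope_like", spec, 7, n_dims=1)
        Y = [rng.standard_normal((spec.n_samples, 2)) for _ in range(4)]
        prof = single_lag_profile([b.data for b in bank], Y)
        assert np.abs(prof).max() < 3.0 / np.sqrt(spec.n_samples)
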