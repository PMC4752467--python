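import numpy as np
import pytest

from fingerqc.chemometrics import (
    evaluate_on_test,
    fit_opls,
    fit_pls,
    jackknife_ci,
    pca,
    train_test_split,
)
from fingerqc.errors import DegenerateInputError, DimensionError, ValidationError
from fingerqc.synthetic import default_spec, generate_activity, generate_fingerprints


def _linear_data(rng, n=20, p=10, noise_sd=0.05):
    X = rng.lognormal(3.0, 0.4, size=(n, p))
    beta = rng.normal(0, 1, size=p) / 100.0
    y = 1.0 + X @ beta + rng.normal(0, noise_sd, size=n)
    return X, y, beta


class TestPLS:
    def test_single_predictor_exact(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = 2.0 * x.ravel()
        model = fit_pls(x, y, n_components=1, cross_validate=False)
        assert model.coefficients[0] == pytest.approx(2.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)
        assert model.r2 == pytest.approx(1.0)
        assert model.rmsee == pytest.approx(0.0, abs=1e-10)

    def test_full_rank_equals_least_squares(self, rng):
        X, y, _ = _linear_data(rng, n=15, p=5)
        model = fit_pls(X, y, n_components=5, cross_validate=False)
        A = np.column_stack([np.ones(len(y)), X])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        ols_pred = A @ coef
        assert np.allclose(model.predict(X), ols_pred, atol=1e-8)

    def test_parameter_recovery(self, rng):
        X, y, beta = _linear_data(rng, n=20, p=10, noise_sd=0.02)
        model = fit_pls(X, y, n_components=6, seed=3)
        r = np.corrcoef(model.coefficients, beta)[0, 1]
        assert r > 0.95

    def test_q2_not_above_r2(self, rng):
        X, y, _ = _linear_data(rng)
        model = fit_pls(X, y, n_components=3, seed=0)
        assert model.q2 <= model.r2

    def test_constant_column_warns_not_fails(self, rng):
        X, y, _ = _linear_data(rng, n=12, p=4)
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant column"):
            model = fit_pls(X, y, n_components=2, cross_validate=False)
        assert np.isfinite(model.coefficients).all()

    def test_constant_response_rejected(self, rng):
        X, _, _ = _linear_data(rng, n=10, p=3)
        with pytest.raises(DegenerateInputError):
            fit_pls(X, np.ones(10), n_components=1)

    def test_too_many_components(self, rng):
        X, y, _ = _linear_data(rng, n=5, p=3)
        with pytest.raises(DimensionError):
            fit_pls(X, y, n_components=5)

    def test_cv_is_seeded_and_deterministic(self, rng):
        X, y, _ = _linear_data(rng)
        a = fit_pls(X, y, n_components=2, seed=42)
        b = fit_pls(X, y, n_components=2, seed=42)
        assert a.q2 == b.q2 and a.rmsecv == b.rmsecv


class TestOPLS:
    def test_zero_orthogonal_equals_pls1(self, rng):
        X, y, _ = _linear_data(rng)
        pls1 = fit_pls(X, y, n_components=1, cross_validate=False)
        opls = fit_opls(X, y, n_orthogonal=0, cross_validate=False)
        assert np.allclose(opls.predict(X), pls1.predict(X), atol=1e-10)

    def test_orthogonal_direction_absorbed(self, rng):
        # plant structured variation orthogonal to y: OPLS(1+1) should fit
        # training data at least as well as PLS(1)
        X, y, _ = _linear_data(rng, n=24, p=6, noise_sd=0.02)
        ortho = rng.normal(0, 1, size=24)
        ortho -= (ortho @ (y - y.mean())) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
        X = np.column_stack([X, 50.0 + 10.0 * ortho])
        pls1 = fit_pls(X, y, n_components=1, cross_validate=False)
        opls = fit_opls(X, y, n_orthogonal=1, cross_validate=False)
        assert opls.r2 >= pls1.r2 - 1e-12

    def test_q2_not_above_r2(self, rng):
        X, y, _ = _linear_data(rng)
        model = fit_opls(X, y, n_orthogonal=1, seed=5)
        assert model.q2 <= model.r2

    def test_too_many_orthogonal(self, rng):
        X, y, _ = _linear_data(rng, n=5, p=3)
        with pytest.raises(DimensionError):
            fit_opls(X, y, n_orthogonal=4)


class TestJackknife:
    def test_zero_noise_degenerate_width(self, rng):
        X = rng.lognormal(3.0, 0.3, size=(10, 2))
        y = 1.0 + X @ np.array([0.5, -0.2])
        fit = lambda Xi, yi: fit_pls(Xi, yi, n_components=2, cross_validate=False)
        ci = jackknife_ci(fit, X, y)
        assert np.all(ci[:, 1] - ci[:, 0] < 1e-6)

    def test_matches_brute_force_loo(self, rng):
        X, y, _ = _linear_data(rng, n=12, p=3)
        fit = lambda Xi, yi: fit_pls(Xi, yi, n_components=2, cross_validate=False)
        ci = jackknife_ci(fit, X, y, level=0.95)
        # independent leave-one-out recomputation of the jackknife interval
        from scipy import stats
        n = len(y)
        reps = np.array([
            fit(np.delete(X, i, axis=0), np.delete(y, i)).coefficients for i in range(n)
        ])
        se = np.sqrt((n - 1) / n * ((reps - reps.mean(0)) ** 2).sum(0))
        full = fit(X, y).coefficients
        tq = stats.t.ppf(0.975, n - 1)
        assert np.allclose(ci[:, 0], full - tq * se, rtol=1e-10)
        assert np.allclose(ci[:, 1], full + tq * se, rtol=1e-10)

    def test_null_coefficient_coverage(self):
        # predictors 2 and 4 have true beta 0; their intervals should cover 0
        # in most seeded repetitions (reduced replicate count for speed)
        hits = total = 0
        for seed in range(15):
            r = np.random.default_rng(seed)
            X = r.lognormal(3.0, 0.4, size=(18, 5))
            beta = np.array([0.02, -0.015, 0.0, 0.01, 0.0])
            y = 1.0 + X @ beta + r.normal(0, 0.3, size=18)
            fit = lambda Xi, yi: fit_pls(Xi, yi, n_components=4, cross_validate=False)
            ci = jackknife_ci(fit, X, y)
            for j in (2, 4):
                total += 1
                hits += ci[j, 0] <= 0.0 <= ci[j, 1]
        assert hits / total >= 0.8

    def test_too_few_samples(self, rng):
        with pytest.raises(ValidationError):
            jackknife_ci(lambda X, y: fit_pls(X, y, 1), rng.random((4, 2)), rng.random(4))


class TestEvaluateOnTest:
    def test_exact_fit_zero_rmsep(self, rng):
        X = rng.lognormal(3.0, 0.3, size=(8, 2))
        y = 2.0 + X @ np.array([0.3, 0.1])
        model = fit_pls(X, y, n_components=2, cross_validate=False)
        rmsep, rel = evaluate_on_test(model, X, y)
        assert rmsep == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rel, 0.0, atol=1e-7)

    def test_seeded_split_rmsep_within_noise(self, rng):
        noise_sd = 0.05
        X, y, _ = _linear_data(rng, n=21, p=8, noise_sd=noise_sd)
        train, test = train_test_split(21, n_test=5, seed=9)
        model = fit_pls(X[train], y[train], n_components=4, seed=9)
        rmsep, _ = evaluate_on_test(model, X[test], y[test])
        assert rmsep < 3 * noise_sd

    def test_dimension_mismatch(self, rng):
        X, y, _ = _linear_data(rng, n=10, p=3)
        model = fit_pls(X, y, n_components=2, cross_validate=False)
        with pytest.raises(DimensionError):
            evaluate_on_test(model, np.ones((2, 5)), np.ones(2))

    def test_excluding_outliers_helps_prediction(self):
        # training with the planted composition-shifted batches included
        # should usually predict the clean batches worse
        wins = 0
        seeds = range(10)
        for seed in seeds:
            spec = default_spec(seed=seed, activity_noise_sd=0.003)
            mats, truth = generate_fingerprints(spec)
            y, _, _ = generate_activity(spec, mats, truth)
            X = mats[260].areas
            clean = np.setdiff1d(np.arange(23), [20, 22])
            train, test = train_test_split(len(clean), n_test=5, seed=seed)
            tr_clean, te = clean[train], clean[test]
            tr_all = np.concatenate([tr_clean, [20, 22]])
            # a 1-component model cannot isolate the outliers in their own
            # latent direction, so their biased response rotates the fit
            m_clean = fit_pls(X[tr_clean], y[tr_clean], n_components=1, seed=seed,
                              cross_validate=False)
            m_all = fit_pls(X[tr_all], y[tr_all], n_components=1, seed=seed,
                            cross_validate=False)
            r_clean, _ = evaluate_on_test(m_clean, X[te], y[te])
            r_all, _ = evaluate_on_test(m_all, X[te], y[te])
            wins += r_clean <= r_all
        assert wins / len(seeds) >= 0.8


class TestPCA:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 6)
        X = np.outer(t, [1.0, 2.0, 3.0])
        res = pca(X, k=2, scale="center")
        assert res.explained_variance_pct[0] == pytest.approx(100.0)

    def test_diagonal_line_loading(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        res = pca(X, k=1, scale="center")
        direction = np.abs(res.loadings[:, 0])
        assert np.allclose(direction, 1 / np.sqrt(2))

    def test_scores_loadings_reconstruct(self, rng):
        X = rng.lognormal(3.0, 0.3, size=(8, 4))
        res = pca(X, k=4, scale="center")
        approx = res.scores @ res.loadings.T + X.mean(axis=0)
        assert np.allclose(approx, X, atol=1e-8)

    def test_planted_outliers_flagged(self, default_dataset):
        _, mats, _ = default_dataset
        res = pca(mats[260].areas, k=2, confidence=0.95)
        assert set(np.flatnonzero(res.outlier_flags)) == {20, 22}

    def test_k_too_large(self, rng):
        with pytest.raises(DimensionError):
            pca(rng.random((4, 3)), k=4)

    def test_needs_three_batches(self, rng):
        with pytest.raises(ValidationError):
            pca(rng.random((2, 3)), k=1)


class TestSplit:
    def test_disjoint_and_complete(self):
        train, test = train_test_split(21, 5, seed=1)
        assert len(train) == 16 and len(test) == 5
        assert np.intersect1d(train, test).size == 0
        assert np.union1d(train, test).size == 21

    def test_invalid_sizes(self):
        with pytest.raises(ValidationError):
            train_test_split(5, 5, seed=0)
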