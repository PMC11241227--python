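"""mPLS regression, cross-validation and latent-factor selection."""

import warnings

import numpy as np
import pytest

from mircoag.mpls import (
    CvResult,
    MPLSRegression,
    cross_validate,
    load_model,
    make_folds,
    save_model,
    select_latent_factors,
)


def _random_problem(rng, n=30, p=50, n_informative=5, noise=0.1):
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:n_informative] = rng.standard_normal(n_informative)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestFit:
    def test_rank_one_exact_fit(self, rng):
        direction = rng.standard_normal(20)
        t = rng.standard_normal(40)
        X = np.outer(t, direction)
        y = 2.0 * t
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MPLSRegression(n_components=1).fit(X, y)
        assert np.abs(model.predict(X) - y).max() < 1e-10

    def test_predict_mean_spectrum_gives_mean_trait(self, rng):
        X, y = _random_problem(rng)
        model = MPLSRegression(n_components=4).fit(X, y)
        assert model.predict(model.x_mean_[None, :])[0] == pytest.approx(model.y_mean_)

    def test_sample_order_invariance(self, rng):
        X, y = _random_problem(rng)
        model = MPLSRegression(n_components=5).fit(X, y)
        perm = rng.permutation(len(y))
        permuted = MPLSRegression(n_components=5).fit(X[perm], y[perm])
        assert np.abs(model.coef_ - permuted.coef_).max() < 1e-10

    def test_batch_predict_equals_per_sample_loop(self, rng):
        X, y = _random_problem(rng)
        Xnew = rng.standard_normal((7, 50))
        model = MPLSRegression(n_components=4).fit(X, y)
        batch = model.predict(Xnew)
        loop = np.array([model.predict(Xnew[i])[0] for i in range(7)])
        assert np.abs(batch - loop).max() < 1e-12

    def test_reduces_to_nipals_pls1_without_standardization(self, rng):
        """With residual standardization off, coefficients must match an
        independent NIPALS PLS1 implementation (sklearn's)."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_problem(rng, n=30, p=50)
        for k in (1, 3, 7):
            ours = MPLSRegression(n_components=k, standardize_residuals=False).fit(X, y)
            oracle = PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.abs(ours.coef_ - oracle.coef_.ravel()).max() < 1e-8
            assert np.abs(ours.predict(X) - oracle.predict(X).ravel()).max() < 1e-8

    def test_standardization_changes_later_factors(self, rng):
        X, y = _random_problem(rng, n=60, p=40, noise=0.5)
        on = MPLSRegression(n_components=5, standardize_residuals=True).fit(X, y)
        off = MPLSRegression(n_components=5, standardize_residuals=False).fit(X, y)
        # first factor is identical; the modification only rescales residuals
        assert np.abs(on.x_weights_[:, 0] - off.x_weights_[:, 0]).max() < 1e-12
        assert np.abs(on.coef_ - off.coef_).max() > 1e-8

    def test_training_sec_non_increasing_in_factors(self, rng):
        X, y = _random_problem(rng, n=60, p=40, noise=0.5)
        model = MPLSRegression(n_components=8).fit(X, y)
        rss = [np.sum((model.predict_path(X)[:, k] - y) ** 2)
               for k in range(model.n_components_)]
        assert all(rss[k + 1] <= rss[k] + 1e-10 for k in range(len(rss) - 1))

    def test_constant_y_rejected(self, rng):
        X = rng.standard_normal((20, 10))
        with pytest.raises(ValueError, match="constant"):
            MPLSRegression(n_components=2).fit(X, np.ones(20))

    def test_rank_deficiency_truncates_with_warning(self, rng):
        t = rng.standard_normal((30, 2))
        X = t @ rng.standard_normal((2, 15))
        y = t[:, 0] + 0.5 * t[:, 1]
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = MPLSRegression(n_components=10).fit(X, y)
        assert model.n_components_ <= 3

    def test_scores_match_transform(self, rng):
        X, y = _random_problem(rng)
        model = MPLSRegression(n_components=4).fit(X, y)
        assert np.abs(model.transform(X) - model.scores_).max() < 1e-8


class TestCrossValidation:
    def test_folds_partition_samples(self):
        folds = make_folds(47, 15, np.random.default_rng(0))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(folds)) == list(range(47))

    def test_noiseless_rank_one_selects_one_factor(self, rng):
        direction = rng.standard_normal(30)
        t = rng.standard_normal(60)
        X = np.outer(t, direction)
        y = 3.0 * t
        cv = cross_validate(X, y, n_folds=5, max_factors=4, seed=0)
        assert cv.n_factors == 1
        assert cv.secv[0] < 1e-8

    def test_secv_matches_brute_force_fold_loop(self, rng):
        X, y = _random_problem(rng, n=45, p=20, noise=0.3)
        cv = cross_validate(X, y, n_folds=5, max_factors=4, seed=7)
        for k in range(1, len(cv.secv) + 1):
            sq = np.empty_like(y)
            for fold in cv.folds:
                mask = np.ones(len(y), dtype=bool)
                mask[fold] = False
                model = MPLSRegression(n_components=k).fit(X[mask], y[mask])
                sq[fold] = (model.predict(X[fold]) - y[fold]) ** 2
            assert abs(np.sqrt(sq.mean()) - cv.secv[k - 1]) < 1e-10

    def test_cv_is_seed_reproducible(self, rng):
        X, y = _random_problem(rng, n=40, p=15)
        a = cross_validate(X, y, n_folds=5, max_factors=3, seed=11)
        b = cross_validate(X, y, n_folds=5, max_factors=3, seed=11)
        assert np.array_equal(a.secv, b.secv) and a.n_factors == b.n_factors

    def test_too_many_folds_rejected(self, rng):
        X, y = _random_problem(rng, n=10, p=5)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, y, n_folds=11, max_factors=2, seed=0)

    def test_latent_rank_recovery(self):
        """CV-selected factor count lands within +/-2 of the true latent rank
        in at least 80% of seeded replicates."""
        true_rank = 5
        hits = 0
        n_reps = 10
        for seed in range(n_reps):
            gen = np.random.default_rng(100 + seed)
            T = gen.standard_normal((80, true_rank))
            P = gen.standard_normal((true_rank, 40))
            X = T @ P + 0.05 * gen.standard_normal((80, 40))
            y = T @ gen.standard_normal(true_rank) + 0.05 * gen.standard_normal(80)
            cv = cross_validate(X, y, n_folds=5, max_factors=10, seed=seed)
            hits += abs(cv.n_factors - true_rank) <= 2
        assert hits >= 0.8 * n_reps


class TestFactorSelection:
    def test_first_count_within_two_percent_band(self):
        secv = np.array([10.0, 5.0, 1.02, 1.01, 1.0, 1.0])
        assert select_latent_factors(secv) == 3  # 1.02 <= 1.02 * 1.0

    def test_unique_minimum_at_one(self):
        assert select_latent_factors(np.array([1.0, 2.0, 3.0])) == 1

    def test_cap_limits_candidates(self):
        secv = np.linspace(10, 1, 20)   # strictly decreasing
        assert select_latent_factors(secv, cap=16) == 16


class TestSerialization:
    def test_round_trip_predictions_identical(self, rng, tmp_path):
        X, y = _random_problem(rng)
        model = MPLSRegression(n_components=5).fit(X, y)
        path = tmp_path / "model.json"
        save_model(model, path, metadata={"trait": "a30"})
        loaded, meta = load_model(path)
        assert meta["trait"] == "a30"
        Xnew = rng.standard_normal((6, 50))
        assert np.array_equal(model.predict(Xnew), loaded.predict(Xnew))
        assert np.array_equal(model.predict_path(Xnew), loaded.predict_path(Xnew))
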