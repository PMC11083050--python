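import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier

from milletspec import (
    ClassifierSpec,
    elimination_percent,
    fit_pca,
    sfs_select,
    transform_pca,
)


def _eigh_oracle(x, k):
    """Brute-force covariance eigendecomposition (independent PCA oracle)."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    return vals[:k] / vals.sum(), vecs[:, :k]


class TestPCA:
    def test_rank_two_data_has_full_cumulative_variance(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 8))
        x = rng.normal(size=(50, 2)) @ basis + rng.normal(size=8)
        res = fit_pca(x, k=2)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 6)) * np.array([3.0, 2.0, 1.0, 0.5, 0.2, 0.1])
        res = fit_pca(x, k=3)
        ratios, vecs = _eigh_oracle(x, 3)
        np.testing.assert_allclose(res.explained_variance_ratio, ratios, atol=1e-8)
        for j in range(3):
            dot = abs(float(res.loadings[:, j] @ vecs[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_isotropic_noise_ratio_near_uniform(self):
        rng = np.random.default_rng(2)
        n_bands = 10
        x = rng.normal(size=(20000, n_bands))
        res = fit_pca(x, k=1)
        ratios, _ = _eigh_oracle(x, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(ratios[0], abs=1e-10)
        assert res.explained_variance_ratio[0] == pytest.approx(1 / n_bands, rel=0.05)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 5))
        res = fit_pca(x, k=5)
        recon = res.center + res.scores @ res.loadings.T
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(4)
        res = fit_pca(rng.normal(size=(25, 7)), k=4)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(4), atol=1e-8)
        for j in range(4):
            col = res.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_ratios_non_increasing_in_unit_interval(self):
        rng = np.random.default_rng(5)
        res = fit_pca(rng.normal(size=(30, 6)), k=5)
        r = res.explained_variance_ratio
        assert np.all((0 <= r) & (r <= 1)) and np.all(np.diff(r) <= 1e-12)
        assert r.sum() <= 1 + 1e-12

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((4, 3)), k=4)


class TestTransform:
    def test_training_rows_reproduce_scores(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(20, 5))
        res = fit_pca(x, k=2)
        np.testing.assert_allclose(transform_pca(res, x), res.scores, atol=1e-10)

    def test_center_maps_to_origin(self):
        rng = np.random.default_rng(7)
        res = fit_pca(rng.normal(size=(20, 5)), k=2)
        np.testing.assert_allclose(transform_pca(res, res.center), 0.0, atol=1e-10)

    def test_linearity_under_concatenation(self):
        rng = np.random.default_rng(8)
        res = fit_pca(rng.normal(size=(20, 5)), k=2)
        a, b = rng.normal(size=(4, 5)), rng.normal(size=(3, 5))
        joint = transform_pca(res, np.vstack([a, b]))
        np.testing.assert_allclose(joint, np.vstack([transform_pca(res, a), transform_pca(res, b)]))

    def test_band_mismatch_rejected(self):
        res = fit_pca(np.random.default_rng(9).normal(size=(10, 5)), k=2)
        with pytest.raises(ValueError, match="band"):
            transform_pca(res, np.zeros((2, 4)))


def _planted_band_data(seed=0, n_per_class=30, n_bands=12, signal_band=7):
    """Only one band carries class signal; all others are pure noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1, 2], n_per_class)
    x = rng.normal(0, 1, size=(y.size, n_bands))
    x[:, signal_band] = y * 4.0 + rng.normal(0, 0.3, y.size)
    return x, y


class TestSFS:
    est = KNeighborsClassifier(5)

    def test_planted_band_selected_first(self):
        x, y = _planted_band_data()
        res = sfs_select(x, y, k=2, estimator=self.est, rng_seed=0)
        assert res.selected_band_indices[0] == 7
        # oracle: brute-force single-band CV accuracy sweep
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        scores = [
            np.mean(cross_val_score(KNeighborsClassifier(5), x[:, [b]], y, cv=cv))
            for b in range(x.shape[1])
        ]
        assert int(np.argmax(scores)) == 7
        assert res.cv_score_trace[0] == pytest.approx(max(scores))

    def test_greedy_selection_is_prefix_nested(self):
        x, y = _planted_band_data(seed=3)
        r3 = sfs_select(x, y, k=3, estimator=self.est, rng_seed=1)
        r4 = sfs_select(x, y, k=4, estimator=self.est, rng_seed=1)
        assert r4.selected_band_indices[:3] == r3.selected_band_indices

    def test_k_equals_n_bands_selects_all(self):
        x, y = _planted_band_data(seed=4, n_bands=6, signal_band=2)
        res = sfs_select(x, y, k=6, estimator=self.est, rng_seed=0)
        assert sorted(res.selected_band_indices) == list(range(6))
        assert len(res.cv_score_trace) == 6

    def test_trace_reproducible_from_recorded_subsets(self):
        x, y = _planted_band_data(seed=5)
        res = sfs_select(x, y, k=3, estimator=self.est, rng_seed=2)
        cv = StratifiedKFold(5, shuffle=True, random_state=2)
        for i in range(3):
            cols = res.selected_band_indices[: i + 1]
            score = np.mean(cross_val_score(KNeighborsClassifier(5), x[:, cols], y, cv=cv))
            assert res.cv_score_trace[i] == pytest.approx(score)

    def test_k_out_of_range_rejected(self):
        x, y = _planted_band_data()
        with pytest.raises(ValueError, match="k"):
            sfs_select(x, y, k=0, estimator=self.est)

    def test_default_estimator_is_gradient_boosting(self):
        x, y = _planted_band_data(n_per_class=10, n_bands=3, signal_band=1)
        res = sfs_select(x, y, k=1, estimator=ClassifierSpec("GTB", {"n_estimators": 5, "max_depth": 2}))
        assert res.estimator_spec.name == "GTB"


class TestEliminationPercent:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(5, 254, 98.03), (15, 254, 94.09), (30, 254, 88.19), (254, 254, 0.0), (0, 254, 100.0)],
    )
    def test_two_decimal_reporting(self, k, n, expected):
        assert elimination_percent(k, n) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            elimination_percent(300, 254)
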