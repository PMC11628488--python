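"""Features, shrinkage-LDA, chronological CV, ITR and binomial threshold."""

import math

import numpy as np
import pandas as pd
import pytest

from asmebci.decoding import (
    ShrinkageLDA,
    binary_auc_cv,
    extract_features,
    information_transfer_rate,
    significance_threshold,
)
from asmebci.erp import EpochSet

from conftest import build_epochset


def feature_epochs(values: np.ndarray, n_ch: int = 64) -> EpochSet:
    """EpochSet at 250 Hz spanning [-0.1, 1.2) with given per-epoch data."""
    n = values.shape[0]
    labels = pd.DataFrame(
        {
            "label": ["target" if i % 2 else "nontarget" for i in range(n)],
            "role": ["deviant" if i % 2 else "standard" for i in range(n)],
            "stimulus_id": ["D1" if i % 2 else "S1" for i in range(n)],
            "stream": 1,
            "run": 0,
            "trial": 0,
        }
    )
    return build_epochset(values, labels=labels,
                          channels=tuple(f"ch{i}" for i in range(n_ch)))


class TestExtractFeatures:
    def test_dimension_is_640(self):
        eps = feature_epochs(np.zeros((6, 64, 325)))
        assert extract_features(eps).X.shape == (6, 640)

    def test_constant_epoch_gives_constant_features(self):
        eps = feature_epochs(np.full((3, 64, 325), 2.5))
        assert np.allclose(extract_features(eps).X, 2.5)

    def test_linear_ramp_interval_means(self):
        fs = 250.0
        times = -0.1 + np.arange(325) / fs
        a = 3.0
        eps = feature_epochs(np.tile(a * times, (2, 64, 1)))
        X = extract_features(eps).X
        # oracle: mean of a*t over the samples of each 0.1 s interval
        for k in range(10):
            sel = (times >= k * 0.1 - 1e-9) & (times < (k + 1) * 0.1 - 1e-9)
            expected = a * times[sel].mean()
            assert X[0, k] == pytest.approx(expected, abs=1e-12)

    def test_short_epoch_rejected(self):
        eps = feature_epochs(np.zeros((2, 64, 200)))  # ends at 0.7 s
        with pytest.raises(ValueError):
            extract_features(eps)

    def test_labels_mapped_to_plus_minus_one(self):
        feats = extract_features(feature_epochs(np.zeros((4, 64, 325))))
        assert set(feats.y) == {-1, 1}


class TestShrinkageLDA:
    @staticmethod
    def _gaussian_classes(n, d, delta, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, d))
        y = np.where(rng.random(n) < 0.5, 1, -1)
        X[y == 1] += delta
        return X, y

    def test_forced_full_shrinkage_aligns_with_mean_difference(self):
        X, y = self._gaussian_classes(400, 20, 0.5)
        clf = ShrinkageLDA(shrinkage=1.0).fit(X, y)
        mu_diff = X[y == 1].mean(0) - X[y == -1].mean(0)
        d = X.shape[1]
        cov = np.cov(np.vstack([X[y == 1] - X[y == 1].mean(0),
                                X[y == -1] - X[y == -1].mean(0)]).T, ddof=0)
        expected = mu_diff / (np.trace(cov) / d)
        assert np.allclose(clf.w, expected, rtol=1e-10)

    def test_spherical_classes_recover_direction(self):
        # with identity covariance the closed form is w ∝ μ₊ − μ₋
        delta = np.zeros(10)
        delta[0] = 1.0
        X, y = self._gaussian_classes(2000, 10, delta, seed=1)
        clf = ShrinkageLDA().fit(X, y)
        mu_diff = X[y == 1].mean(0) - X[y == -1].mean(0)
        cos = clf.w @ mu_diff / (np.linalg.norm(clf.w) * np.linalg.norm(mu_diff))
        assert math.degrees(math.acos(min(cos, 1.0))) < 5.0

    def test_midpoint_has_zero_decision_value(self):
        X, y = self._gaussian_classes(300, 8, 1.0, seed=2)
        clf = ShrinkageLDA().fit(X, y)
        mid = (X[y == 1].mean(0) + X[y == -1].mean(0)) / 2
        assert clf.decision_function(mid[None, :])[0] == pytest.approx(0.0, abs=1e-10)
        assert clf.predict(X[y == 1].mean(0)[None, :])[0] == 1

    def test_matches_sklearn_lsqr_with_fixed_shrinkage(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 12))
        y = np.where(np.arange(200) % 2 == 0, 1, -1)  # balanced classes
        X[y == 1, 0] += 1.0
        ours = ShrinkageLDA(shrinkage=0.3).fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.3).fit(X, y)
        assert np.allclose(ours.coef_, ref.coef_, rtol=1e-6)
        assert np.allclose(ours.intercept_, ref.intercept_, rtol=1e-6, atol=1e-8)

    def test_estimated_gamma_in_unit_interval(self):
        X, y = self._gaussian_classes(50, 100, 0.5, seed=4)  # n < d
        clf = ShrinkageLDA().fit(X, y)
        assert 0.0 < clf.shrinkage_ <= 1.0

    def test_zero_shrinkage_singular_covariance_rejected(self):
        X, y = self._gaussian_classes(30, 64, 0.5, seed=5)
        with pytest.raises(np.linalg.LinAlgError):
            ShrinkageLDA(shrinkage=0.0).fit(X, y)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            ShrinkageLDA().fit(np.zeros((6, 3)), np.array([0, 1, 2, 0, 1, 2]))


class TestBinaryAucCV:
    @staticmethod
    def _feats(X, y, n=None):
        from asmebci.decoding import FeatureSet

        n = len(y)
        return FeatureSet(
            X=X, y=y, run=np.zeros(n, dtype=int), trial=np.zeros(n, dtype=int),
            deviant_class=np.array([""] * n), n_intervals=10,
            channels=tuple(f"c{i}" for i in range(X.shape[1] // 10)),
        )

    def test_separable_features_give_auc_one(self):
        rng = np.random.default_rng(0)
        n = 200
        y = np.where(rng.random(n) < 0.3, 1, -1)
        X = rng.standard_normal((n, 20)) * 0.01
        X[:, 0] += 10.0 * y
        res = binary_auc_cv(self._feats(X, y), n_folds=4)
        assert res.per_fold == [1.0] * 4

    def test_chronological_blocks_are_contiguous(self):
        # fold identity leaks through a time-varying feature: with a drifting
        # mean, contiguous folds give different AUCs than shuffled ones would
        n = 120
        y = np.tile([1, -1], n // 2)
        X = np.zeros((n, 10))
        X[:, 0] = y * 1000.0 + np.arange(n)  # strong signal + drift
        res = binary_auc_cv(self._feats(X, y), n_folds=4)
        assert len(res.per_fold) == 4
        assert res.mean == 1.0

    def test_fold_without_both_classes_skipped(self):
        y = np.concatenate([np.tile([1, -1], 15), [-1] * 10])  # last fold one-class
        X = np.random.default_rng(1).standard_normal((40, 8))
        res = binary_auc_cv(self._feats(X, y), n_folds=4)
        assert res.skipped_folds == [3]
        assert len(res.per_fold) == 3

    def test_auc_invariant_under_monotone_transform(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.standard_normal(100)
        y01 = rng.integers(0, 2, 100)
        a = roc_auc_score(y01, scores)
        b = roc_auc_score(y01, np.exp(3 * scores) + 7)
        assert a == pytest.approx(b)


class TestItr:
    def test_perfect_four_class_is_two_bits(self):
        assert information_transfer_rate(1.0, 4).R == pytest.approx(2.0)

    def test_chance_gives_zero_bits(self):
        for N in (2, 4, 8):
            assert information_transfer_rate(1.0 / N, N).R == pytest.approx(0.0)

    def test_bits_per_minute_scales_with_speed(self):
        res = information_transfer_rate(0.86, 4, V=60.0 / 90.0)
        assert res.B == pytest.approx(res.R * 60.0 / 90.0)
        assert 0.0 < res.R < 2.0

    def test_monotone_on_grid_above_chance(self):
        ps = np.linspace(0.25 + 1e-6, 1.0, 1000)
        rs = [information_transfer_rate(p, 4).R for p in ps]
        assert np.all(np.diff(rs) > 0)
        assert rs[-1] == pytest.approx(2.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            information_transfer_rate(1.2, 4)
        with pytest.raises(ValueError):
            information_transfer_rate(0.5, 1)
        with pytest.raises(ValueError):
            information_transfer_rate(0.5, 4, V=0.0)


class TestSignificanceThreshold:
    def test_reference_value_24_trials_4_classes(self):
        assert significance_threshold(24, 4, 0.05).value == 0.42

    def test_binary_case_matches_exhaustive_binomial_sum(self):
        # oracle: direct tail sums of C(24, j) / 2^24
        n = 24
        tail = lambda k: sum(math.comb(n, j) for j in range(k + 1, n + 1)) / 2**n
        expected_k = next(k for k in range(n + 1) if tail(k) < 0.05)
        res = significance_threshold(n, 2, 0.05)
        assert res.k == expected_k
        assert res.exact == pytest.approx(expected_k / n)

    def test_alpha_near_one_accepts_any_nonzero_accuracy(self):
        res = significance_threshold(24, 4, 0.999)
        assert res.exact < 1 / 24

    def test_monotone_in_trials_and_classes(self):
        t_by_n = [significance_threshold(n, 4).exact for n in (12, 24, 48, 96)]
        assert all(a >= b - 1e-12 for a, b in zip(t_by_n, t_by_n[1:]))
        # more classes -> lower chance level -> lower threshold
        t_by_c = [significance_threshold(24, c).exact for c in (2, 3, 4, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(t_by_c, t_by_c[1:]))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(24, 4, 0.0)
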