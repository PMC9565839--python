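"""Exploratory factor analysis: recovery, rotation, scores, correlations."""

import numpy as np
import pandas as pd
import pytest

from hdlatent.efa import (
    _principal_axis,
    factor_associations,
    factor_variable_correlations,
    fit_efa,
    parallel_analysis,
    score_subjects,
)


def _planted_two_factor(n=200, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    L = np.zeros((10, 2))
    L[:5, 0] = 0.8
    L[5:, 1] = 0.7
    F = rng.standard_normal((n, 2))
    X = F @ L.T + noise * rng.standard_normal((n, 10))
    return X, L


def _congruence(a, b):
    return abs(a @ b) / np.sqrt((a @ a) * (b @ b))


class TestFitEfa:
    def test_rank_one_matrix_single_factor(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.standard_normal(60), rng.uniform(0.5, 1.5, 6))
        X += 1e-4 * rng.standard_normal(X.shape)
        m = fit_efa(X, n_factors=1)
        # one factor explains essentially all common variance
        assert m.communalities.mean() > 0.99

    def test_planted_loadings_recovered_with_high_congruence(self):
        X, L = _planted_two_factor()
        m = fit_efa(pd.DataFrame(X), n_factors=2, seed=0)
        cmat = np.array(
            [[_congruence(L[:, i], m.loadings[:, j]) for j in range(2)] for i in range(2)]
        )
        # best assignment of recovered to planted factors
        assert max(min(cmat[0, 0], cmat[1, 1]), min(cmat[0, 1], cmat[1, 0])) >= 0.95

    def test_auto_factor_count_by_parallel_analysis(self):
        X, _ = _planted_two_factor()
        m = fit_efa(X, n_factors="auto", seed=3)
        assert m.n_factors == 2

    def test_too_many_factors_rejected(self):
        X, _ = _planted_two_factor()
        with pytest.raises(ValueError, match="n_factors"):
            fit_efa(X, n_factors=10)

    def test_zero_variance_columns_dropped_with_warning(self):
        X, _ = _planted_two_factor()
        X = np.hstack([X, np.ones((len(X), 1))])
        with pytest.warns(UserWarning, match="zero-variance"):
            m = fit_efa(X, n_factors=2)
        assert m.dropped_columns == ["pc10"]

    def test_varimax_preserves_communalities(self):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        X, _ = _planted_two_factor(noise=0.5)
        z = (X - X.mean(0)) / X.std(0, ddof=1)
        corr = np.corrcoef(z, rowvar=False)
        unrot, h2, _, _ = _principal_axis(corr, 2)
        rot, _ = rotate_factors(unrot, "varimax")
        assert np.allclose((rot**2).sum(axis=1), (unrot**2).sum(axis=1), atol=1e-8)

    def test_rotation_preserves_model_fit(self):
        # LL' + uniqueness reproduces the correlation matrix equally
        # well before and after varimax (rotation invariance of fit)
        from statsmodels.multivariate.factor_rotation import rotate_factors

        X, _ = _planted_two_factor(noise=0.5)
        z = (X - X.mean(0)) / X.std(0, ddof=1)
        corr = np.corrcoef(z, rowvar=False)
        unrot, h2, _, _ = _principal_axis(corr, 2)
        rot, _ = rotate_factors(unrot, "varimax")

        def fit_err(L):
            model = L @ L.T + np.diag(1.0 - (L**2).sum(axis=1))
            return np.linalg.norm(model - corr)

        assert abs(fit_err(rot) - fit_err(unrot)) <= 1e-8

    def test_recovery_rate_across_replicates(self):
        # parallel analysis retains the planted k=2 in >= 90% of 50
        # seeded replicates at moderate noise
        hits = 0
        for rep in range(50):
            X, _ = _planted_two_factor(n=150, noise=0.4, seed=100 + rep)
            m = fit_efa(X, n_factors="auto", seed=rep)
            hits += m.n_factors == 2
        assert hits >= 45


class TestScores:
    def test_fitting_sample_scores_have_zero_mean(self):
        X, _ = _planted_two_factor()
        m = fit_efa(X, n_factors=2)
        assert np.abs(m.scores.mean(axis=0)).max() < 1e-6

    def test_pure_subject_scores_highest_on_own_factor(self):
        X, L = _planted_two_factor(noise=0.1)
        m = fit_efa(X, n_factors=2)
        # synthetic subject loaded purely on planted factor 1
        row = L[:, 1] * 3.0
        s = score_subjects(m, row[None, :] + X.mean(0))
        assert np.argmax(np.abs(s[0])) == np.argmax(
            [abs(_congruence(L[:, 1], m.loadings[:, j])) for j in range(2)]
        )

    def test_duplicate_rows_identical_scores(self):
        X, _ = _planted_two_factor()
        m = fit_efa(X, n_factors=2)
        s = score_subjects(m, np.vstack([X[3], X[3]]))
        assert np.array_equal(s[0], s[1])

    def test_column_mismatch_rejected(self):
        X, _ = _planted_two_factor()
        m = fit_efa(pd.DataFrame(X), n_factors=2)
        bad = pd.DataFrame(X[:, :9])
        with pytest.raises(ValueError):
            score_subjects(m, bad)


class TestAssociations:
    def test_threshold_classification_and_bipolar_flag(self):
        X, _ = _planted_two_factor()
        m = fit_efa(X, n_factors=2)
        m.loadings[:, 0] = 0.0
        m.loadings[0, 0] = 0.8
        m.loadings[1, 0] = -0.5
        m.loadings[2, 0] = 0.1
        a = factor_associations(m, threshold=0.4)
        assert a.loc["F0", "positive"] == ["pc0"]
        assert a.loc["F0", "negative"] == ["pc1"]
        assert a.loc["F0", "bipolar"]

    def test_subthreshold_factor_flagged_empty(self):
        X, _ = _planted_two_factor()
        m = fit_efa(X, n_factors=2)
        m.loadings[:, 1] = 0.05
        a = factor_associations(m, threshold=0.4)
        assert a.loc["F1", "empty"]

    def test_planted_bipolar_factor_detected(self):
        rng = np.random.default_rng(5)
        L = np.zeros((8, 1))
        L[:4, 0] = 0.8
        L[4:, 0] = -0.8
        X = rng.standard_normal((300, 1)) @ L.T + 0.2 * rng.standard_normal((300, 8))
        m = fit_efa(X, n_factors=1)
        a = factor_associations(m)
        assert a.loc["F0", "bipolar"]


class TestCorrelations:
    def test_perfect_linear_relationship(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal((50, 1))
        v = pd.DataFrame({"y": 2.0 * s[:, 0]})
        full, masked = factor_variable_correlations(s, v)
        assert full.loc["y", "F0_r"] == pytest.approx(1.0)
        assert masked.loc["y", "F0"] == pytest.approx(1.0)

    def test_binary_indicator_point_biserial(self):
        g = np.repeat([0.0, 1.0], 25)
        s = g[:, None].copy()
        full, _ = factor_variable_correlations(s, pd.DataFrame({"g": g}), binary={"g"})
        assert full.loc["g", "F0_r"] == pytest.approx(1.0)

    def test_null_variables_masked_at_alpha(self):
        # independent noise variables: ~95% masked at alpha = 0.05
        rng = np.random.default_rng(7)
        s = rng.standard_normal((300, 1))
        v = pd.DataFrame(rng.standard_normal((300, 400)),
                         columns=[f"v{i}" for i in range(400)])
        _, masked = factor_variable_correlations(s, v)
        rate = masked["F0"].isna().mean()
        assert 0.92 <= rate <= 0.98

    def test_constant_variable_masked(self):
        s = np.random.default_rng(1).standard_normal((30, 1))
        _, masked = factor_variable_correlations(s, pd.DataFrame({"c": np.ones(30)}))
        assert np.isnan(masked.loc["c", "F0"])


class TestParallelAnalysis:
    def test_threshold_shape_and_determinism(self):
        a = parallel_analysis(100, 8, seed=2)
        b = parallel_analysis(100, 8, seed=2)
        assert np.array_equal(a, b) and len(a) == 8
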