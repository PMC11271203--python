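"""VAR(1) causality estimation: recovery, oracles, conditioning behavior."""

import logging

import numpy as np
import pytest

from restcause import (
    GroundTruth,
    dominant_source_truth,
    fit_all_subjects,
    fit_var1,
    generate_var_timeseries,
    suggest_ridge,
)


class TestFitVar1:
    def test_white_noise_coefficients_are_small(self):
        t = 2000
        bound = 3 / np.sqrt(t)
        hits = total = 0
        for seed in range(10):
            tc = np.random.default_rng(seed).normal(size=(t, 3))
            coeffs = fit_var1(tc).coeffs
            hits += int(np.sum(np.abs(coeffs) < bound))
            total += coeffs.size
        assert hits / total >= 0.99

    def test_recovers_single_cross_coefficient(self):
        a = np.zeros((2, 2))
        a[0, 1] = 0.5
        ts, _ = generate_var_timeseries(1, 5000, 2, GroundTruth(a, seed=17))
        coeffs = fit_var1(ts.data[0]).coeffs
        assert coeffs[0, 1] == pytest.approx(0.5, abs=0.05)
        assert coeffs[1, 0] == pytest.approx(0.0, abs=0.05)

    def test_study_shape_gives_114_square_matrix(self, caplog):
        tc = np.random.default_rng(1).normal(size=(144, 114))
        with caplog.at_level(logging.WARNING, logger="restcause.granger"):
            m = fit_var1(tc)
        assert m.coeffs.shape == (114, 114)
        assert np.all(np.isfinite(m.coeffs))
        # near-square design must announce its condition number
        assert any("condition number" in r.message for r in caplog.records)

    def test_matches_per_target_ols_oracle(self, rng):
        tc = rng.normal(size=(300, 5))
        coeffs = fit_var1(tc).coeffs
        c = tc - tc.mean(axis=0)
        x, y = c[:-1], c[1:]
        for j in range(5):
            beta = np.linalg.solve(x.T @ x, x.T @ y[:, j])
            assert np.max(np.abs(coeffs[:, j] - beta)) < 1e-8

    def test_matches_statsmodels_var(self, rng):
        from statsmodels.tsa.api import VAR

        tc = rng.normal(size=(400, 4)).cumsum(axis=0) * 0.01 + rng.normal(size=(400, 4))
        coeffs = fit_var1(tc).coeffs
        sm_fit = VAR(tc - tc.mean(axis=0)).fit(maxlags=1, trend="n")
        # statsmodels stores target-major; ours is source-major
        assert np.allclose(coeffs, sm_fit.coefs[0].T, atol=1e-6)

    def test_ridge_shrinks_toward_zero(self, rng):
        tc = rng.normal(size=(100, 5))
        free = fit_var1(tc, ridge_lambda=0.0).coeffs
        shrunk = fit_var1(tc, ridge_lambda=1e4).coeffs
        assert np.abs(shrunk).sum() < np.abs(free).sum()
        assert np.abs(shrunk).max() < 0.05

    def test_scale_equivariance(self, rng):
        tc = rng.normal(size=(200, 4))
        base = fit_var1(tc).coeffs
        c = 3.0
        scaled = tc.copy()
        scaled[:, 1] *= c
        out = fit_var1(scaled).coeffs
        expected = base.copy()
        expected[1, :] /= c   # component 1 as lagged predictor
        expected[:, 1] *= c   # component 1 as response
        expected[1, 1] = base[1, 1]
        assert np.allclose(out, expected, atol=1e-8)

    def test_constant_column_rejected(self, rng):
        tc = rng.normal(size=(50, 3))
        tc[:, 2] = 1.0
        with pytest.raises(ValueError, match=r"component index \[2\]"):
            fit_var1(tc)

    def test_negative_ridge_rejected(self, rng):
        with pytest.raises(ValueError, match="nonnegative"):
            fit_var1(rng.normal(size=(50, 3)), ridge_lambda=-1)

    def test_rmse_decreases_with_series_length(self):
        truth = dominant_source_truth(4, coupling=0.4, seed=31)
        rmses = []
        for t in (200, 1000, 5000):
            errs = []
            for rep in range(5):
                gt = dominant_source_truth(4, coupling=0.4, seed=31 + 100 * rep)
                ts, _ = generate_var_timeseries(1, t, 4, gt)
                est = fit_var1(ts.data[0]).coeffs
                errs.append(np.sqrt(np.mean((est - truth.true_matrix) ** 2)))
            rmses.append(np.mean(errs))
        assert rmses[2] < rmses[1] < rmses[0]


class TestFitAllSubjects:
    def test_identical_subjects_give_identical_matrices(self):
        from restcause import ComponentTimeSeriesSet

        tc = np.random.default_rng(2).normal(size=(100, 3))
        ts = ComponentTimeSeriesSet(data=np.stack([tc, tc, tc]))
        mats = fit_all_subjects(ts)
        assert len(mats) == 3
        assert np.array_equal(mats[0].coeffs, mats[1].coeffs)
        assert np.array_equal(mats[1].coeffs, mats[2].coeffs)

    def test_group_mean_is_nearly_unbiased_under_jitter(self):
        truth = dominant_source_truth(4, coupling=0.4, subject_jitter_sd=0.05, seed=41)
        ts, _ = generate_var_timeseries(63, 1000, 4, truth)
        mats = fit_all_subjects(ts)
        mean_est = np.mean([m.coeffs for m in mats], axis=0)
        unjittered = dominant_source_truth(4, coupling=0.4, seed=41).true_matrix
        assert np.max(np.abs(mean_est - unjittered)) < 0.02

    def test_failure_is_subject_labeled(self):
        from restcause import ComponentTimeSeriesSet

        data = np.random.default_rng(3).normal(size=(2, 50, 2))
        data[1, :, 0] = 7.0
        ts = ComponentTimeSeriesSet(data=data)
        with pytest.raises(ValueError, match="sub-02"):
            fit_all_subjects(ts)
        mats = fit_all_subjects(ts, skip_failures=True)
        assert len(mats) == 1 and mats[0].subject_id == "sub-01"


def test_suggest_ridge_is_positive_for_short_series(rng):
    tc = rng.normal(size=(40, 20))
    lam = suggest_ridge(tc)
    assert lam > 0
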