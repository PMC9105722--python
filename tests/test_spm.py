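"""Metrics and 1D SPM: t-fields, smoothness, RFT thresholds, clusters."""

import numpy as np
import pytest
from scipy import stats as scistats

from gaitforce.spm import (
    DegenerateFieldError,
    estimate_fwhm,
    paired_t_field,
    pearson_r,
    percent_error_curve,
    rft_threshold,
    rmse,
    spm_paired_test,
    subject_level_spm,
)
from tests.conftest import smooth_gaussian_fields


class TestBasicMetrics:
    def test_perfect_prediction(self):
        x = np.sin(np.linspace(0, np.pi, 101))
        assert rmse(x, x) == 0.0
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_negated_prediction(self):
        x = np.sin(np.linspace(0, np.pi, 101)) + 0.3
        assert pearson_r(-x, x) == pytest.approx(-1.0)

    def test_constant_offset(self):
        x = np.sin(np.linspace(0, np.pi, 101))
        assert rmse(x + 0.1, x) == pytest.approx(0.1)
        assert pearson_r(x + 0.1, x) == pytest.approx(1.0)

    def test_constant_input_rejected_for_r(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r(np.ones(101), np.linspace(0, 1, 101))


class TestPercentError:
    def test_zero_for_perfect_prediction(self):
        true = np.sin(np.pi * np.linspace(0, 1, 101))[None, :]
        err = percent_error_curve(true, true)
        assert np.all(err.mean_pct == 0.0)

    def test_constant_offset_of_ten_percent_range(self):
        true = np.sin(np.pi * np.linspace(0, 1, 101))[None, :]  # range 1
        pred = true + 0.1
        err = percent_error_curve(pred, true)
        assert np.abs(err.mean_pct - 10.0).max() < 1e-12
        assert np.all(err.sd_pct == 0.0)

    def test_symmetric_offsets_mean_ten_sd_zero(self):
        true = np.vstack([np.sin(np.pi * np.linspace(0, 1, 101))] * 2)
        pred = true + np.array([[0.1], [-0.1]])
        err = percent_error_curve(pred, true)
        assert np.abs(err.mean_pct - 10.0).max() < 1e-12
        assert np.abs(err.sd_pct).max() < 1e-12

    def test_zero_range_steps_excluded(self):
        true = np.vstack([np.sin(np.pi * np.linspace(0, 1, 101)), np.ones(101)])
        pred = true + 0.1
        err = percent_error_curve(pred, true)
        assert err.n_steps == 1 and err.n_excluded == 1

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        true = rng.normal(size=(4, 101))
        pred = true + rng.normal(size=(4, 101)) * 0.2
        e1 = percent_error_curve(pred, true)
        e2 = percent_error_curve(3.0 * pred + 1.0, 3.0 * true + 1.0)
        assert np.allclose(e1.mean_pct, e2.mean_pct, atol=1e-10)


class TestPairedTField:
    def test_hand_computed_example(self):
        # paired differences {1, 2, 3} at every node: t = 2*sqrt(3)
        a = np.array([[1.0], [2.0], [3.0]]) * np.ones((3, 101))
        b = np.zeros((3, 101))
        t, df, resid = paired_t_field(a, b)
        assert df == 2
        assert np.allclose(t, 2.0 * np.sqrt(3.0))
        assert resid.shape == (3, 101)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(2, 10, 101))
        t_ab, _, _ = paired_t_field(a, b)
        t_ba, _, _ = paired_t_field(b, a)
        assert np.array_equal(t_ab, -t_ba)

    def test_shift_direction(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 101))
        b = a + 1.0 + 0.3 * rng.normal(size=(10, 101))
        t, _, _ = paired_t_field(a, b)
        assert t.mean() < 0

    def test_identical_samples_degenerate(self):
        a = np.random.default_rng(3).normal(size=(5, 101))
        with pytest.raises(DegenerateFieldError):
            paired_t_field(a, a.copy())

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_t_field(np.zeros((2, 101)), np.ones((2, 101)))


class TestFWHM:
    @pytest.mark.parametrize("true_fwhm", [5.0, 10.0, 20.0])
    def test_recovers_kernel_smoothness(self, true_fwhm):
        rng = np.random.default_rng(int(true_fwhm))
        ests = []
        for _ in range(10):
            R = smooth_gaussian_fields(50, 101, true_fwhm, rng)
            ests.append(estimate_fwhm(R - R.mean(axis=0)))
        assert abs(np.mean(ests) - true_fwhm) / true_fwhm < 0.15

    def test_white_noise_is_rough(self):
        rng = np.random.default_rng(9)
        rough = estimate_fwhm(rng.standard_normal((50, 101)))
        smooth = estimate_fwhm(smooth_gaussian_fields(50, 101, 5.0, rng))
        assert rough < 4.0
        assert rough < smooth

    def test_all_zero_residuals_rejected(self):
        with pytest.raises(ValueError):
            estimate_fwhm(np.zeros((5, 101)))


class TestRFTThreshold:
    def test_decreasing_in_smoothness(self):
        us = [rft_threshold(0.05, 17, 101, w) for w in (2.0, 5.0, 15.0, 50.0)]
        assert np.all(np.diff(us) < 0)

    def test_stricter_alpha_raises_threshold(self):
        assert rft_threshold(0.01, 17, 101, 10.0) > rft_threshold(0.05, 17, 101, 10.0)

    def test_never_below_pointwise_quantile(self):
        for df in (5, 17, 40):
            for w in (2.0, 10.0, 100.0):
                u = rft_threshold(0.05, df, 101, w)
                assert u >= scistats.t.ppf(1 - 0.025, df)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rft_threshold(0.0, 17)
        with pytest.raises(ValueError):
            rft_threshold(0.05, 0)
        with pytest.raises(ValueError):
            rft_threshold(0.05, 17, fwhm=0.5)


class TestSPMPairedTest:
    def test_large_shift_gives_full_length_cluster(self):
        rng = np.random.default_rng(4)
        a = smooth_gaussian_fields(18, 101, 10.0, rng)
        b = a + 10.0 + smooth_gaussian_fields(18, 101, 10.0, rng)
        res = spm_paired_test(a, b)
        assert res.significant
        assert res.clusters == [(0, 101)]

    def test_localized_shift_gives_localized_cluster(self):
        rng = np.random.default_rng(5)
        a = smooth_gaussian_fields(18, 101, 10.0, rng)
        b = a + smooth_gaussian_fields(18, 101, 10.0, rng) * 0.3
        shift = np.zeros(101)
        shift[70:] = 8.0
        b = b + shift
        res = spm_paired_test(a, b)
        assert res.significant
        for on, off in res.clusters:
            assert on >= 65  # confined to the shifted late-stance region +/- 5
        covered = set()
        for on, off in res.clusters:
            covered.update(range(on, off))
        assert len(covered & set(range(75, 101))) > 10

    def test_degenerate_field_reports_no_clusters(self):
        a = np.random.default_rng(6).normal(size=(6, 101))
        res = spm_paired_test(a, a.copy())
        assert res.degenerate and not res.significant


class TestSubjectLevelSPM:
    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(7)
        pred = rng.normal(size=(40, 101))
        true = pred + 0.5 + rng.normal(size=(40, 101))
        r1 = subject_level_spm(pred, true, n_steps=18, seed=3)
        r2 = subject_level_spm(pred, true, n_steps=18, seed=3)
        assert np.array_equal(r1.t_field, r2.t_field)

    def test_subsample_size_and_df(self):
        rng = np.random.default_rng(8)
        pred = rng.normal(size=(40, 101))
        true = pred + rng.normal(size=(40, 101))
        res = subject_level_spm(pred, true, n_steps=18, seed=0)
        assert res.df == 17

    def test_fewer_steps_uses_all_with_warning(self, caplog):
        rng = np.random.default_rng(9)
        pred = rng.normal(size=(7, 101))
        true = pred + rng.normal(size=(7, 101))
        with caplog.at_level("WARNING"):
            res = subject_level_spm(pred, true, n_steps=18, seed=0)
        assert res.df == 6
        assert "using all" in caplog.text
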