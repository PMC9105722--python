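"""Preprocessing: rotation, filtering, sync, segmentation, normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from gaitforce.containers import GRAVITY
from gaitforce.preprocess import (
    PreprocessConfig,
    SyncError,
    detect_steps,
    extract_steps,
    lowpass_filter,
    preprocess_trial,
    rotate_grf_to_gravity,
    sum_regions,
    synchronize_streams,
    time_normalize,
)


class TestRotation:
    def test_zero_slope_is_identity(self):
        rng = np.random.default_rng(0)
        grf = rng.normal(size=(50, 3))
        assert np.allclose(rotate_grf_to_gravity(grf, 0.0), grf)

    def test_pure_normal_force_splits_by_slope_angle(self):
        F = 1000.0
        grf = np.array([[F, 0.0, 0.0]])
        out = rotate_grf_to_gravity(grf, 6.0)
        assert out[0, 0] == pytest.approx(F * np.cos(np.deg2rad(6.0)))
        assert out[0, 1] == pytest.approx(F * np.sin(np.deg2rad(6.0)))

    def test_norm_preserved(self):
        rng = np.random.default_rng(1)
        grf = rng.normal(size=(200, 3))
        out = rotate_grf_to_gravity(grf, -6.0)
        n_in = np.linalg.norm(grf, axis=1)
        n_out = np.linalg.norm(out, axis=1)
        assert np.abs(n_in - n_out).max() < 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rotate_grf_to_gravity(np.array([[np.nan, 0, 0]]), 6.0)


class TestFilter:
    def test_dc_gain_unity(self):
        x = np.full(4000, 3.7)
        assert np.allclose(lowpass_filter(x, 2400.0), x, atol=1e-9)

    def test_sinusoid_attenuation_matches_butterworth_response(self):
        # 100 Hz at fs 2400 with 50 Hz cutoff, two passes: 1/(1+(f/fc)^6)
        fs, f = 2400.0, 100.0
        t = np.arange(int(fs * 4)) / fs
        y = lowpass_filter(np.sin(2 * np.pi * f * t), fs)
        mid = slice(2000, -2000)
        ratio = np.abs(y[mid]).max()
        assert ratio == pytest.approx(1.0 / 65.0, rel=0.02)

    def test_zero_phase_no_peak_shift(self):
        fs = 2400.0
        t = np.arange(4800) / fs
        x = np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
        y = lowpass_filter(x, fs)
        assert abs(int(np.argmax(y)) - int(np.argmax(x))) == 0

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 3000))
        lhs = lowpass_filter(2.0 * x + 3.0 * y, 2400.0)
        rhs = 2.0 * lowpass_filter(x, 2400.0) + 3.0 * lowpass_filter(y, 2400.0)
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.ones(5), 2400.0)
        with pytest.raises(ValueError):
            lowpass_filter(np.ones(100), 80.0, cutoff=50.0)


class TestSync:
    def test_recovers_planted_lag(self, rendered_trial):
        trial, truth, cfg = rendered_trial
        vert_f = lowpass_filter(
            rotate_grf_to_gravity(trial.grf, 0.0)[:, 0], trial.fs_grf
        )
        total = sum_regions(trial.pressure).sum(axis=1)
        assert synchronize_streams(vert_f, total, 2400.0, 100.0) == 37

    def test_negative_lag_recovered(self, noisefree_trial):
        trial, truth, cfg = noisefree_trial
        total = sum_regions(trial.pressure).sum(axis=1)
        vert_f = lowpass_filter(
            rotate_grf_to_gravity(trial.grf, 0.0)[:, 0], trial.fs_grf
        )
        assert synchronize_streams(vert_f, total, 2400.0, 100.0) == -21

    def test_ambiguous_signal_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(SyncError):
            synchronize_streams(
                rng.normal(size=24000), rng.normal(size=1000), 2400.0, 100.0
            )

    def test_noninteger_rate_ratio_rejected(self):
        with pytest.raises(ValueError):
            synchronize_streams(np.ones(2400), np.ones(100), 2400.0, 70.0)


class TestDetect:
    def test_counts_match_ledger(self, rendered_trial):
        trial, truth, cfg = rendered_trial
        vert_f = lowpass_filter(
            rotate_grf_to_gravity(trial.grf, 0.0)[:, 0], trial.fs_grf
        )
        iv = detect_steps(vert_f, 2400.0, start_index=int(4.5 * 2400))
        assert len(iv) == cfg.steps_per_trial

    def test_boundaries_within_one_sample_of_ledger(self, rendered_trial):
        trial, truth, cfg = rendered_trial
        vert_f = lowpass_filter(
            rotate_grf_to_gravity(trial.grf, 0.0)[:, 0], trial.fs_grf
        )
        iv = np.array(detect_steps(vert_f, 2400.0, start_index=int(4.5 * 2400)))
        tiv = np.array(truth["detection_intervals"])
        assert np.abs(iv - tiv).max() <= 1

    def test_all_zero_signal_gives_empty_list(self):
        assert detect_steps(np.zeros(5000), 2400.0) == []

    def test_short_subthreshold_dip_is_bridged(self):
        fs = 2400.0
        x = np.zeros(3000)
        x[500:1300] = 500.0  # 333 ms stance
        x[880:928] = 10.0  # 20 ms dip below the 20 N threshold
        iv = detect_steps(x, fs)
        assert iv == [(500, 1300)]

    def test_flight_noise_blips_rejected(self):
        fs = 2400.0
        x = np.zeros(6000)
        x[1000:1600] = 800.0
        x[3000:3040] = 30.0  # 17 ms noise blip above threshold
        iv = detect_steps(x, fs)
        assert iv == [(1000, 1600)]


class TestRegionsAndNodes:
    def test_uniform_frame_sums_to_sensor_counts(self):
        sums = sum_regions(np.ones(99))
        assert sums.sum() == 99
        assert np.array_equal(sums, [19, 20, 20, 21, 19])

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(size=(30, 99))
        sums = sum_regions(frames)
        assert np.abs(sums.sum(axis=1) - frames.sum(axis=1)).max() < 1e-12

    def test_wrong_sensor_count_rejected(self):
        with pytest.raises(ValueError):
            sum_regions(np.ones(98))

    def test_time_normalize_constant_and_ramp(self):
        assert np.allclose(time_normalize(np.full(25, 2.0)), 2.0)
        ramp = np.linspace(-1.0, 4.0, 33)
        out = time_normalize(ramp)
        assert out[0] == ramp[0] and out[-1] == ramp[-1]
        assert np.allclose(out, np.linspace(-1.0, 4.0, 101), atol=1e-12)

    def test_time_normalize_half_sine_accuracy(self):
        x = np.sin(np.pi * np.linspace(0, 1, 25))
        out = time_normalize(x)
        ref = np.sin(np.pi * np.linspace(0, 1, 101))
        assert np.abs(out - ref).max() < 0.005  # < 0.5 % of unit peak

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            time_normalize(np.array([1.0]))


class TestExtract:
    def _steps(self, trial, cfg):
        return preprocess_trial(
            trial, PreprocessConfig(analysis_start_s=cfg.run_start_s - 0.5)
        )

    def test_steps_have_101_nodes_and_nonnegative_channels(self, rendered_trial):
        trial, truth, cfg = rendered_trial
        steps = self._steps(trial, cfg)
        assert len(steps) == cfg.steps_per_trial
        for s in steps:
            assert s.pr.shape == (5, 101)
            assert s.grf_vert.shape == (101,)
            assert np.all(s.pr >= 0.0)
            assert np.all(s.grf_vert >= 0.0)

    def test_noisefree_round_trip_matches_ledger_exactly(self, noisefree_trial):
        trial, truth, cfg = noisefree_trial
        steps = self._steps(trial, cfg)
        vert_nf = np.array(truth["vert_nf"])
        for k, s in enumerate(steps):
            assert np.abs(s.grf_vert - vert_nf[k]).max() < 1e-10

    def test_reconstruction_within_one_percent_of_peak(self, rendered_trial):
        trial, truth, cfg = rendered_trial
        steps = self._steps(trial, cfg)
        vert_nf = np.array(truth["vert_nf"])
        for k, s in enumerate(steps):
            err = np.abs(s.grf_vert - vert_nf[k]).max() / vert_nf[k].max()
            assert err < 0.01

    def test_idempotent(self, rendered_trial):
        trial, truth, cfg = rendered_trial
        s1 = self._steps(trial, cfg)
        s2 = self._steps(trial, cfg)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.pr, b.pr)
            assert np.array_equal(a.grf_vert, b.grf_vert)

    def test_mass_normalization_algebra(self, noisefree_trial):
        import copy

        from gaitforce.containers import SubjectMeta

        trial, truth, cfg = noisefree_trial
        steps1 = self._steps(trial, cfg)
        heavy = copy.copy(trial)
        heavy.subject = SubjectMeta(
            trial.subject.subject_id, 2.0 * trial.subject.mass,
            trial.subject.footstrike,
        )
        steps2 = self._steps(heavy, cfg)
        for a, b in zip(steps1, steps2):
            assert np.allclose(b.pr, a.pr / 2.0, atol=1e-12)
            assert np.allclose(b.grf_vert, a.grf_vert / 2.0, atol=1e-12)

    def test_out_of_range_interval_dropped(self, noisefree_trial):
        trial, truth, cfg = noisefree_trial
        n = trial.grf.shape[0]
        steps = extract_steps(trial, [(n - 300, n - 10)], lag=10**4)
        assert steps == []
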