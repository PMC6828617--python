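import numpy as np
import pandas as pd
import pytest

import fcmvpa as f
from fcmvpa.denoise import build_confound_matrix, build_task_regressors
from fcmvpa.synthetic import Block, BlockDesign


def single_block_design(onset_s=10.0, tr=2.0, n_scans=60):
    block = Block(
        condition_label="joy", stimulus_type="face", onset_s=onset_s,
        n_trials=8, trial_dur_s=2.0, isi_s=0.5, post_block_task_s=2.0,
    )
    return BlockDesign(tr=tr, runs=[[block]], fixation_s=10.0, n_scans_per_run=n_scans)


class TestTaskRegressors:
    def test_support_starts_at_block_onset_and_peak_lags_by_hrf_delay(self):
        d = single_block_design(onset_s=10.0)
        regs = build_task_regressors(d, n_scans=60)
        col = regs["joy|face"].to_numpy()
        # independent oracle: discrete convolution of the boxcar with the HRF
        box = np.zeros(60)
        box[5:15] = 1.0  # 10 s onset / 2 s TR, 20 s span
        expect = np.convolve(box, f.canonical_hrf(2.0))[:60]
        assert np.allclose(col, expect)
        assert (col[:5] == 0).all()
        peak_lag_s = 2.0 * np.argmax(col) - 10.0
        assert 4.0 <= peak_lag_s <= 26.0  # peak inside the block+HRF window
        assert np.argmax(col) > 5  # strictly after onset

    def test_column_per_distinct_condition(self, small_design):
        regs = build_task_regressors(small_design)
        assert len(regs.columns) == len(small_design.condition_keys)

    def test_absent_condition_gives_zero_column_with_warning(self, small_design):
        with pytest.warns(UserWarning, match="absent"):
            regs = build_task_regressors(
                small_design, conditions=["joy|face", "nope|face"]
            )
        assert (regs["nope|face"] == 0).all()
        assert regs["joy|face"].abs().sum() > 0

    def test_all_rest_design_yields_zero_matrix(self):
        d = single_block_design()
        d.runs = [[]]
        with pytest.warns(UserWarning):
            regs = build_task_regressors(d, n_scans=60, conditions=["joy|face"])
        assert (regs.to_numpy() == 0).all()


class TestConfoundMatrix:
    def make_confounds(self, n_scans, n_motion=6, n_comp=5, seed=0):
        rng = np.random.default_rng(seed)
        cols = {f"m{i}": rng.standard_normal(n_scans) for i in range(n_motion)}
        cols.update({f"c{i}": rng.standard_normal(n_scans) for i in range(n_comp)})
        return pd.DataFrame(cols)

    def test_column_arithmetic(self):
        d = single_block_design()  # 1 condition cell
        cf = self.make_confounds(60)
        X = build_confound_matrix(cf, d, n_scans=60)
        # intercept + 6 motion + 5 components + trend + 1 task
        assert X.shape == (60, 1 + 6 + 5 + 1 + 1)
        assert X.columns[0] == "intercept"
        assert "linear_trend" in X.columns

    def test_three_conditions_gives_sixteen_columns(self, small_design):
        n = small_design.n_scans_per_run
        cf = self.make_confounds(n)
        X = build_confound_matrix(cf, small_design, n_scans=n)
        # 1 + 6 + 5 + 1 + 6 condition cells (3 emotions x 2 types)
        assert X.shape[1] == 1 + 6 + 5 + 1 + 6

    def test_linear_trend_is_centered_scan_index(self):
        d = single_block_design()
        X = build_confound_matrix(self.make_confounds(60), d, n_scans=60)
        expect = np.arange(60) - np.arange(60).mean()
        assert np.allclose(X["linear_trend"], expect)

    def test_collinear_duplicate_motion_raises(self):
        d = single_block_design()
        cf = self.make_confounds(60)
        cf["m_dup"] = cf["m0"]
        with pytest.raises(ValueError, match="rank"):
            build_confound_matrix(cf, d, n_scans=60)

    def test_length_mismatch_raises(self):
        d = single_block_design()
        with pytest.raises(ValueError, match="rows"):
            build_confound_matrix(self.make_confounds(50), d, n_scans=60)

    def test_duplicate_names_raise(self):
        d = single_block_design()
        cf = self.make_confounds(60)
        cf["intercept"] = np.arange(60.0)
        with pytest.raises(ValueError, match="duplicate"):
            build_confound_matrix(cf, d, n_scans=60)


class TestRegression:
    def test_exact_fit_leaves_zero_residual(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 4))
        ts = X @ rng.standard_normal((4, 3))
        resid = f.regress_confounds(ts, X)
        assert np.abs(resid).max() < 1e-8 * np.abs(ts).max()

    def test_residuals_orthogonal_to_every_column(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 5))
        ts = rng.standard_normal((80, 7))
        resid = f.regress_confounds(ts, X)
        dots = np.abs(X.T @ resid)
        scale = np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(resid, axis=0)
        assert (dots < 1e-6 * scale).all()

    def test_projection_reduces_variance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 6))
        ts = rng.standard_normal((100, 4))
        resid = f.regress_confounds(ts, X)
        assert (resid.var(axis=0) <= ts.var(axis=0) + 1e-12).all()

    def test_rank_deficient_raises(self):
        X = np.ones((30, 2))
        with pytest.raises(ValueError):
            f.regress_confounds(np.random.default_rng(0).standard_normal((30, 2)), X)


class TestBandpass:
    def sinusoid(self, hz, tr=2.0, n=400):
        t = np.arange(n) * tr
        return np.sin(2 * np.pi * hz * t)[:, None]

    def amplitude_ratio(self, hz):
        x = self.sinusoid(hz)
        y = f.bandpass_filter(x, tr=2.0)
        # compare spectral amplitude at the driving frequency
        fx = np.abs(np.fft.rfft(x[:, 0]))
        fy = np.abs(np.fft.rfft(y[:, 0]))
        k = np.argmax(fx)
        return fy[k] / fx[k]

    def test_passband_amplitude_preserved(self):
        assert 0.9 <= self.amplitude_ratio(0.05) <= 1.1

    def test_stopband_attenuated_20db(self):
        assert self.amplitude_ratio(0.2) < 0.1
        assert self.amplitude_ratio(0.004) < 0.1

    def test_constant_series_removed(self):
        y = f.bandpass_filter(np.full((200, 2), 7.0), tr=2.0)
        assert np.abs(y).mean() < 1e-6 * 7.0

    def test_band_validation(self):
        x = np.zeros((100, 1))
        with pytest.raises(ValueError):
            f.bandpass_filter(x, tr=2.0, low_hz=0.01, high_hz=0.3)  # >= Nyquist
        with pytest.raises(ValueError):
            f.bandpass_filter(x, tr=2.0, low_hz=0.2, high_hz=0.1)


class TestDenoisePipeline:
    def test_denoising_removes_motion_coupled_variance(self):
        """A strongly motion-coupled input loses its motion correlation after
        confound regression + filtering; what remains is chance-level
        alignment of the band-limited residual, not systematic leakage."""
        d = f.make_design(n_runs=1, stimulus_types=("face", "body"),
                          repetitions=2, seed=123)
        eff = f.EffectSpec(n_rois=6, base_covariance=np.eye(6))
        noise = f.NoiseSpec(motion_coupling_sd=3.0, thermal_sd=0.3)
        sub = f.simulate_subject(d, eff, noise, seed=4)
        den = f.denoise_subject(sub, d)

        def max_corr(y, m):
            yc = (y - y.mean(0)) / y.std(0)
            mc = (m - m.mean(0)) / m.std(0)
            return np.abs(mc.T @ yc / len(y)).max()

        motion = sub.confounds[0].iloc[:, :6].to_numpy()
        raw = max_corr(sub.timeseries[0], motion)
        cleaned = max_corr(den.timeseries[0], motion)
        assert raw > 0.5  # the injected coupling is visible before denoising
        assert cleaned < 0.35
        assert cleaned < raw / 1.5

    def test_shapes_preserved_no_nan(self, small_design):
        eff = f.EffectSpec(n_rois=5, base_covariance=np.eye(5))
        sub = f.simulate_subject(small_design, eff, f.NoiseSpec(), seed=8)
        den = f.denoise_subject(sub, small_design)
        for a, b in zip(sub.timeseries, den.timeseries):
            assert a.shape == b.shape
            assert np.all(np.isfinite(b))
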