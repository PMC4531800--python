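"""Frequency tracking, Dscore, noise decomposition, detrending, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mregaval.config import PipelineConfig
from mregaval.physio import (
    CleanSeries,
    ComponentSeries,
    FrequencyGrid,
    FrequencyTrajectory,
    band_power_fraction,
    clean_component,
    dscore,
    estimate_frequency_trajectory,
    estimate_spectrum,
    estimate_vasomotor,
    remove_periodic_noise,
)
from mregaval.synthetic import SynthParams, _reflected_walk, generate_component_series

FS = 10.0
RESP = FrequencyGrid(8, 24, 0.2)
CARDIAC = FrequencyGrid(45, 65, 0.4)


def constant_trajectory(freq_bpm: float, T: int, grid: FrequencyGrid):
    probs = np.zeros((T, grid.size))
    probs[:, int(np.argmin(np.abs(grid.freqs_bpm - freq_bpm)))] = 1.0
    return FrequencyTrajectory(
        freq_bpm=np.full(T, freq_bpm), mode_probs=probs, grid=grid
    )


class TestFrequencyGrid:
    def test_grid_frequencies(self):
        assert RESP.size == 81
        assert CARDIAC.size == 51
        np.testing.assert_allclose(RESP.freqs_bpm[:3], [8.0, 8.2, 8.4])

    def test_non_integral_span_rejected(self):
        with pytest.raises(ValueError):
            FrequencyGrid(8, 24.1, 0.2)


class TestFrequencyTracking:
    def test_recovers_stationary_sinusoid(self):
        t = np.arange(6000) / FS
        series = ComponentSeries(np.sin(2 * np.pi * 15.0 / 60.0 * t), FS)
        traj = estimate_frequency_trajectory(series, RESP)
        assert abs(traj.freq_bpm.mean() - 15.0) <= 0.2

    def test_mode_probability_rows_normalized(self):
        t = np.arange(800) / FS
        series = ComponentSeries(np.sin(2 * np.pi * 0.3 * t), FS)
        traj = estimate_frequency_trajectory(series, RESP)
        np.testing.assert_allclose(traj.mode_probs.sum(axis=1), 1.0, atol=1e-9)
        assert traj.freq_bpm.min() >= 8.0 and traj.freq_bpm.max() <= 24.0

    def test_white_noise_keeps_probabilities_spread(self, rng):
        series = ComponentSeries(rng.normal(0, 1, 3000), FS)
        traj = estimate_frequency_trajectory(series, RESP)
        ent = -np.sum(
            traj.mode_probs * np.log(np.maximum(traj.mode_probs, 1e-300)), axis=1
        )
        # no row may concentrate to less than ~40% of the uniform entropy
        assert ent.min() >= 0.4 * np.log(RESP.size)

    def test_single_mode_grid_constant(self):
        series = ComponentSeries(np.sin(np.arange(200.0)), FS)
        grid = FrequencyGrid(14.9, 15.1, 0.2)
        # degenerate two-point grid still works; a true 1-point grid warns
        traj = estimate_frequency_trajectory(series, grid)
        assert len(traj) == 200

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            ComponentSeries(np.array([1.0, np.nan, 2.0]), FS)

    def test_wandering_frequency_rmse_below_two_grid_steps(self):
        errs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            f = _reflected_walk(rng, 3000, 8, 24, 0.1)
            y = np.sin(2 * np.pi * np.cumsum(f / 60.0) / FS)
            y = y + rng.normal(0, 1 / 3, f.size)  # SNR 3
            traj = estimate_frequency_trajectory(ComponentSeries(y, FS), RESP)
            errs.append(np.sqrt(np.mean((traj.freq_bpm - f) ** 2)))
        assert max(errs) < 2 * RESP.step_bpm


class TestDscore:
    def test_constant_trajectory_scores_zero(self):
        traj = constant_trajectory(15.0, 100, RESP)
        rep = dscore(traj)
        assert rep.score == 0.0 and not rep.passed

    def test_two_point_alternation_approaches_one(self):
        T = 20000
        freqs = np.where(np.arange(T) % 2 == 0, 14.0, 16.0)
        probs = np.zeros((T, RESP.size))
        probs[np.arange(T), np.argmin(np.abs(RESP.freqs_bpm[None] - freqs[:, None]), axis=1)] = 1
        rep = dscore(FrequencyTrajectory(freqs.astype(float), probs, RESP))
        assert rep.score == pytest.approx(1.0, abs=1e-3)

    def test_linear_sweep_score(self):
        T = 20000
        freqs = np.linspace(8, 24, T)
        probs = np.full((T, RESP.size), 1.0 / RESP.size)
        rep = dscore(FrequencyTrajectory(freqs, probs, RESP))
        # SD of a uniform ramp: (24-8)/sqrt(12)
        assert rep.score == pytest.approx(16 / np.sqrt(12), rel=1e-3)
        assert rep.passed

    def test_discriminates_wandering_from_stuck(self):
        """Healthy wander passes; a tone outside the grid pegs the tracker
        at the boundary and fails."""
        t = np.arange(2000) / FS
        passed_wander, passed_stuck = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            f = _reflected_walk(rng, t.size, 8, 24, 0.1)
            y = np.sin(2 * np.pi * np.cumsum(f / 60.0) / FS) + rng.normal(0, 0.2, t.size)
            traj = estimate_frequency_trajectory(ComponentSeries(y, FS), RESP)
            passed_wander.append(dscore(traj).passed)
            y_stuck = np.sin(2 * np.pi * 30.0 / 60.0 * t) + rng.normal(0, 0.2, t.size)
            traj = estimate_frequency_trajectory(ComponentSeries(y_stuck, FS), RESP)
            passed_stuck.append(dscore(traj).passed)
        assert np.mean(passed_wander) >= 0.9
        assert np.mean(passed_stuck) <= 0.1


class TestNoiseDecomposition:
    def test_zero_input_all_zero(self):
        T = 500
        series = ComponentSeries(np.zeros(T), FS)
        d = remove_periodic_noise(series, None, constant_trajectory(60, T, CARDIAC))
        for comp in (d.cleaned, d.resp, d.cardiac, d.residual):
            np.testing.assert_allclose(comp, 0.0)

    def test_cardiac_tone_removed_ramp_preserved(self):
        T = 6000
        t = np.arange(T) / FS
        ramp = np.linspace(0, 2, T)
        y = ramp + 0.5 * np.sin(2 * np.pi * 1.0 * t)
        d = remove_periodic_noise(
            ComponentSeries(y, FS), None, constant_trajectory(60.0, T, CARDIAC)
        )
        from scipy.signal import periodogram

        f, pin = periodogram(y - y.mean(), fs=FS)
        f, pout = periodogram(d.cleaned - d.cleaned.mean(), fs=FS)
        band = (f > 0.95) & (f < 1.05)
        assert 1 - pout[band].sum() / pin[band].sum() >= 0.90
        assert np.corrcoef(d.cleaned, ramp)[0, 1] >= 0.95

    def test_conservation_exact(self, default_series):
        series, _ = default_series
        T = len(series)
        d = remove_periodic_noise(
            series,
            constant_trajectory(15, T, RESP),
            constant_trajectory(55, T, CARDIAC),
        )
        np.testing.assert_allclose(
            d.total(), series.values, atol=1e-8 * series.values.std()
        )

    def test_mismatched_trajectory_length_rejected(self):
        series = ComponentSeries(np.zeros(100), FS)
        with pytest.raises(ValueError):
            remove_periodic_noise(series, constant_trajectory(15, 99, RESP), None)


class TestVasomotor:
    def test_constant_reproduced(self):
        out = estimate_vasomotor(np.full(600, 3.7))
        np.testing.assert_allclose(out, 3.7)

    def test_quadratic_reproduced_everywhere(self):
        t = np.arange(700.0)
        y = 0.5 * t**2 - 3 * t + 2
        out = estimate_vasomotor(y)
        np.testing.assert_allclose(out, y, rtol=1e-9, atol=1e-6 * np.abs(y).max())

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            estimate_vasomotor(np.zeros(100))

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_linearity(self, a, b):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 600))
        lhs = estimate_vasomotor(a * x + b * y)
        rhs = a * estimate_vasomotor(x) + b * estimate_vasomotor(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9 * (1 + abs(a) + abs(b)))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_trend_estimate_spectrally_slow(self, config, seed):
        series, _ = generate_component_series(config, seed=seed)
        trend = estimate_vasomotor(series)
        psd = estimate_spectrum(trend, fs_hz=FS)
        assert band_power_fraction(psd, 0.01) >= 0.8


class TestCleanComponent:
    def test_trend_equal_to_cleaned_gives_zero(self):
        T = 600
        series = ComponentSeries(np.ones(T), FS)
        d = remove_periodic_noise(series, None, None)
        out = clean_component(series, d, d.cleaned)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_zero_trend_is_identity(self):
        T = 600
        series = ComponentSeries(np.sin(np.arange(T) / 30.0), FS)
        d = remove_periodic_noise(series, None, None)
        out = clean_component(series, d, np.zeros(T))
        np.testing.assert_allclose(out.values, d.cleaned)

    def test_length_mismatch_rejected(self):
        series = ComponentSeries(np.zeros(100), FS)
        d = remove_periodic_noise(series, None, None)
        with pytest.raises(ValueError):
            clean_component(series, d, np.zeros(99))

    def test_cleaning_improves_event_train_correlation(self, config, default_series):
        from mregaval.pipeline import process_component
        from mregaval.synthetic import _raised_cosine

        series, gt = default_series
        res = process_component(series, config)
        train = np.zeros(len(series))
        for tt, d_, a in zip(gt.event_times, gt.event_durations, gt.event_amplitudes):
            bump = a * _raised_cosine(d_)
            start = tt - int(np.argmax(bump))
            train[start : start + d_] += bump
        r_clean = np.corrcoef(res.clean.values, train)[0, 1]
        r_raw = np.corrcoef(series.values, train)[0, 1]
        assert r_clean > r_raw


class TestSpectrum:
    def test_sinusoid_argmax_bin(self):
        t = np.arange(4096) / FS
        psd = estimate_spectrum(np.sin(2 * np.pi * 0.25 * t), fs_hz=FS)
        assert psd.freqs_hz[np.argmax(psd.power)] == pytest.approx(0.25, abs=0.01)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            estimate_spectrum(np.ones(200), fs_hz=FS)

    def test_white_noise_flat_across_bands(self, rng):
        psd = estimate_spectrum(rng.normal(size=6000), fs_hz=FS)
        ratio = psd.band_mean(0.13, 0.4) / psd.band_mean(0.75, 1.08)
        assert 0.5 <= ratio <= 2.0

    def test_total_power_is_unit_variance(self, rng):
        psd = estimate_spectrum(rng.normal(size=6000), fs_hz=FS)
        total = np.trapezoid(psd.power, psd.freqs_hz)
        assert total == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize(
        "f_sig,expected", [(0.005, 1.0), (0.25, 0.0)]
    )
    def test_band_power_fraction_pure_tones(self, f_sig, expected):
        t = np.arange(20000) / FS
        psd = estimate_spectrum(np.sin(2 * np.pi * f_sig * t), fs_hz=FS)
        assert band_power_fraction(psd, 0.01) == pytest.approx(expected, abs=0.05)

    def test_band_power_fraction_equal_mixture(self):
        t = np.arange(40000) / FS
        y = np.sin(2 * np.pi * 0.005 * t) + np.sin(2 * np.pi * 0.25 * t)
        psd = estimate_spectrum(y, fs_hz=FS, nperseg=8192)
        assert band_power_fraction(psd, 0.01) == pytest.approx(0.5, abs=0.05)
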