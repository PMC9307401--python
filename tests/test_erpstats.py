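"""Task statistics: PT, feedback negativity, scalp maps, permutation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prestim.erpstats import (
    NoSeparationError,
    compute_pt,
    delta_amplitude,
    fit_gaussian_peak,
    gaussian_template,
    gls_scored_amplitude,
    group_stats,
    max_separation_time,
    mfn_latency,
    mfn_result,
    pattern_scored_amplitude,
    permutation_test,
    reward_parameter,
    shape_scored_amplitude,
    topomap,
)
from prestim.montage import positions_2d

from conftest import make_evoked


class TestRewardParameter:
    @pytest.mark.parametrize(
        "left,right,expected", [(25, 5, 5.0), (35, 5, 7.0), (50, 5, 10.0), (5, 5, 1.0)]
    )
    def test_ratio_rule(self, left, right, expected):
        assert reward_parameter(left, right) == expected

    def test_nonpositive_right_value_rejected(self):
        with pytest.raises(ValueError):
            reward_parameter(25, 0)


class TestDeltaAmplitude:
    @pytest.mark.parametrize(
        "loss,gain,expected",
        [(-0.34, 0.37, 0.71), (0.52, 2.04, 1.52), (0.32, 2.15, 1.83), (1.0, 1.0, 0.0)],
    )
    def test_absolute_difference(self, loss, gain, expected):
        assert delta_amplitude(loss, gain) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(-10, 10), b=st.floats(-10, 10), c=st.floats(-10, 10)
    )
    def test_symmetric_and_translation_invariant(self, a, b, c):
        assert delta_amplitude(a, b) == pytest.approx(delta_amplitude(b, a))
        assert delta_amplitude(a + c, b + c) == pytest.approx(
            delta_amplitude(a, b), abs=1e-9
        )


def pt_pair(fz_a, fz_b, fs=500.0):
    n = len(fz_a)
    times = np.arange(-(n - 1), 1) * 1000.0 / fs
    a = make_evoked(times, fz_a, condition="left")
    b = make_evoked(times, fz_b, condition="right")
    return a, b


def oracle_last_crossing(times, d):
    """Independent oracle: exhaustive scan over adjacent-sample sign changes."""
    crossings = []
    for k in range(d.size - 1):
        if d[k] == 0 or d[k + 1] == 0:
            continue
        if np.sign(d[k]) != np.sign(d[k + 1]):
            t = times[k] + (times[k + 1] - times[k]) * d[k] / (d[k] - d[k + 1])
            crossings.append(t)
    return crossings[-1] if crossings else None


class TestComputePT:
    def test_ramp_departing_at_minus_120(self):
        times = np.arange(-250, 1) * 2.0
        d = np.where(times > -120, -(times + 120) / 10.0, 0.0)
        a, b = pt_pair(np.zeros_like(times), -d)
        res = compute_pt(a, b)
        assert res.pt == pytest.approx(120.0, abs=2.1)
        assert res.persistence_ok

    def test_identical_waveforms_raise(self):
        times = np.arange(-250, 1) * 2.0
        a, b = pt_pair(np.sin(times / 50.0), np.sin(times / 50.0))
        with pytest.raises(NoSeparationError):
            compute_pt(a, b)

    def test_multiple_crossings_take_the_latest(self):
        # d crosses zero at -300 and -150 ms, then stays negative through 0
        times = np.arange(-250, 1) * 2.0
        d = -np.sin(np.pi * (times + 150) / 300.0)
        d[times > -150] = -np.abs(d[times > -150]) - 0.01
        a, b = pt_pair(d, np.zeros_like(d))
        res = compute_pt(a, b)
        assert res.pt == pytest.approx(150.0, abs=2.1)

    def test_single_signed_difference_reports_window_length(self):
        times = np.arange(-250, 1) * 2.0
        a, b = pt_pair(np.full(times.size, 2.0), np.zeros(times.size))
        res = compute_pt(a, b)
        assert res.pt == pytest.approx(500.0)
        assert not res.persistence_ok

    def test_matches_exhaustive_oracle_on_random_smooth_pairs(self):
        rng = np.random.default_rng(42)
        from scipy.ndimage import gaussian_filter1d

        for _ in range(100):
            n = int(rng.integers(50, 400))
            times = np.arange(-(n - 1), 1) * 2.0
            d = gaussian_filter1d(rng.standard_normal(n), 5.0)
            a, b = pt_pair(d, np.zeros_like(d))
            res = compute_pt(a, b, search_window=(times[0], 0.0))
            t_star = oracle_last_crossing(times, d)
            if t_star is None:
                assert res.pt == pytest.approx(times[-1] - times[0])
            else:
                assert res.crossing_time == pytest.approx(t_star, abs=1e-9)

    def test_tolerance_band_defines_separation(self):
        # below-tolerance wiggles before the final departure do not count
        times = np.arange(-250, 1) * 2.0
        d = 0.1 * np.sin(times / 10.0)
        d[times >= -100] = -5.0
        a, b = pt_pair(d, np.zeros_like(d))
        res = compute_pt(a, b, tol=0.5)
        assert res.pt == pytest.approx(102.0, abs=2.1)
        assert res.persistence_ok

    def test_window_must_end_at_zero(self):
        times = np.arange(-250, 1) * 2.0
        a, b = pt_pair(np.ones(times.size), np.zeros(times.size))
        with pytest.raises(ValueError):
            compute_pt(a, b, search_window=(-400.0, -100.0))


class TestMaxSeparation:
    def test_peak_at_minus_50(self):
        times = np.arange(-250, 1) * 2.0
        d = -np.exp(-((times + 50.0) ** 2) / (2 * 30.0**2))
        a, b = pt_pair(d, np.zeros_like(d))
        assert max_separation_time(a, b) == pytest.approx(50.0)

    def test_monotone_difference_peaks_at_boundary(self):
        times = np.arange(-250, 1) * 2.0
        a, b = pt_pair((times + 500.0) / 100.0, np.zeros(times.size))
        assert max_separation_time(a, b) == pytest.approx(0.0)

    def test_flat_difference_ties_to_earliest(self):
        times = np.arange(-250, 1) * 2.0
        a, b = pt_pair(np.ones(times.size), np.zeros(times.size))
        assert max_separation_time(a, b) == pytest.approx(500.0)


def feedback_pair(fz_loss, fz_gain, fs=500.0, n_t=301):
    times = (np.arange(n_t) - 50) * 1000.0 / fs
    loss = make_evoked(times, fz_loss, condition="loss", lock="feedback")
    gain = make_evoked(times, fz_gain, condition="gain", lock="feedback")
    return times, loss, gain


class TestMFN:
    def test_gaussian_bump_latency(self):
        times = (np.arange(301) - 50) * 2.0
        d = np.exp(-((times - 232.0) ** 2) / (2 * 25.0**2))
        _, loss, gain = feedback_pair(d, np.zeros_like(d))
        lat = mfn_latency(loss, gain)
        assert abs(lat.latency - 232.0) <= 2.0
        assert not lat.at_boundary

    def test_flat_difference_ties_to_earliest_sample(self):
        times = (np.arange(301) - 50) * 2.0
        _, loss, gain = feedback_pair(np.ones(times.size), np.zeros(times.size))
        assert mfn_latency(loss, gain).latency == pytest.approx(150.0)

    def test_peak_outside_window_flags_boundary(self):
        times = (np.arange(301) - 50) * 2.0
        d = np.exp(-((times - 100.0) ** 2) / (2 * 20.0**2))
        _, loss, gain = feedback_pair(d, np.zeros_like(d))
        assert mfn_latency(loss, gain).at_boundary

    def test_mfn_result_invariant(self):
        times = (np.arange(301) - 50) * 2.0
        bump = np.exp(-((times - 232.0) ** 2) / (2 * 25.0**2))
        _, loss, gain = feedback_pair(0.32 * bump, 2.15 * bump)
        res = mfn_result(loss, gain)
        assert res.delta == pytest.approx(
            abs(res.gain_amplitude - res.loss_amplitude)
        )
        assert res.delta == pytest.approx(1.83, abs=0.01)


class TestAmplitudeScoring:
    def test_shape_score_recovers_amplitude_under_drift(self):
        times = (np.arange(301) - 50) * 2.0
        tmpl = gaussian_template(times, 232.0, 25.0)
        wave = -1.7 * tmpl + 0.4 + 0.002 * times  # amplitude + drift
        ev = make_evoked(times, wave, lock="feedback")
        assert shape_scored_amplitude(ev, tmpl) == pytest.approx(-1.7, abs=1e-9)

    def test_gls_with_identity_covariance_matches_ols(self):
        rng = np.random.default_rng(0)
        times = (np.arange(301) - 50) * 2.0
        tmpl = gaussian_template(times, 232.0, 25.0)
        wave = 1.2 * tmpl + 0.1 * rng.standard_normal(times.size)
        ev = make_evoked(times, wave, lock="feedback")
        ols = shape_scored_amplitude(ev, tmpl)
        gls = gls_scored_amplitude(ev, tmpl, np.eye(times.size))
        assert gls == pytest.approx(ols, abs=1e-9)

    def test_pattern_score_pools_channels(self):
        times = (np.arange(301) - 50) * 2.0
        tmpl = gaussian_template(times, 232.0, 25.0)
        names = ("F3", "Fz", "F4")
        pattern = np.vstack([0.5 * tmpl, 1.0 * tmpl, -0.5 * tmpl])
        ev = make_evoked(times, tmpl, channel_names=names, lock="feedback")
        ev.data = 0.8 * pattern
        assert pattern_scored_amplitude(ev, pattern) == pytest.approx(0.8)

    def test_gaussian_peak_fit_recovers_parameters(self):
        times = (np.arange(301) - 50) * 2.0
        wave = -1.5 * gaussian_template(times, 240.0, 22.0) + 0.3
        a, t0, w = fit_gaussian_peak(times, wave)
        assert a == pytest.approx(-1.5, abs=0.01)
        assert t0 == pytest.approx(240.0, abs=0.5)
        assert w == pytest.approx(22.0, abs=0.5)


class TestTopomap:
    channels = ("Fp1", "Fpz", "Fp2", "F3", "Fz", "F4", "Cz", "Pz", "Oz", "VEOG")

    def _evoked(self, values):
        times = np.array([-2.0, 0.0, 2.0])
        data = np.zeros((len(self.channels), 3))
        data[:, 1] = values
        from prestim.containers import EvokedWaveform

        return EvokedWaveform(
            data=data, times=times, channel_names=self.channels, n=5,
            condition="a",
        )

    def test_uniform_values_give_uniform_map(self):
        pos = positions_2d(self.channels)
        values = np.zeros(len(self.channels))
        values[:-1] = 3.0  # EEG channels
        topo = topomap(self._evoked(values), 0.0, pos)
        inside = np.isfinite(topo.grid)
        assert inside.any()
        assert np.allclose(topo.grid[inside], 3.0, atol=1e-6)

    def test_single_hot_channel_peaks_at_its_position(self):
        pos = positions_2d(self.channels)
        values = np.zeros(len(self.channels))
        cz = self.channels.index("Cz")
        values[cz] = 10.0
        topo = topomap(self._evoked(values), 0.0, pos)
        grid = np.where(np.isfinite(topo.grid), topo.grid, -np.inf)
        # the grid maximum equals the hot channel's value, and the grid
        # node closest to that channel carries it (nearest-channel
        # extrapolation may tie outside the electrode hull)
        assert np.max(grid) == pytest.approx(10.0, abs=1e-3)
        iy = np.argmin(np.abs(topo.grid_y[:, 0] - pos[cz, 1]))
        ix = np.argmin(np.abs(topo.grid_x[0] - pos[cz, 0]))
        assert grid[iy, ix] == pytest.approx(10.0, abs=0.01)

    def test_linear_in_channel_values(self):
        rng = np.random.default_rng(5)
        pos = positions_2d(self.channels)
        va = rng.standard_normal(len(self.channels))
        vb = rng.standard_normal(len(self.channels))
        ta = topomap(self._evoked(va), 0.0, pos).grid
        tb = topomap(self._evoked(vb), 0.0, pos).grid
        tab = topomap(self._evoked(va - vb), 0.0, pos).grid
        mask = np.isfinite(ta)
        assert np.allclose(tab[mask], (ta - tb)[mask], atol=1e-9)

    def test_off_axis_latency_rejected(self):
        pos = positions_2d(self.channels)
        with pytest.raises(ValueError):
            topomap(self._evoked(np.zeros(len(self.channels))), 37.0, pos)


class TestGroupStats:
    def test_identical_groups_are_not_significant(self):
        x = np.arange(10.0)
        p = permutation_test(x, x.copy())
        assert p >= 0.9

    def test_separated_groups_reach_permutation_floor(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 10.0
        assert permutation_test(a, b) <= 0.001
        assert permutation_test(a, b, statistic="rank") <= 0.001

    def test_paired_sign_flip_detects_consistent_shift(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(12)
        b = a + 1.0 + 0.01 * rng.standard_normal(12)
        assert permutation_test(a, b, paired=True) <= 0.001

    def test_mean_and_sd_match_hand_computation(self):
        summary = group_stats({"x": np.array([1.0, 2.0, 3.0]),
                               "y": np.array([2.0, 2.0, 2.0])})
        assert summary.means["x"] == pytest.approx(2.0)
        assert summary.sds["x"] == pytest.approx(1.0)
        assert summary.sds["y"] == pytest.approx(0.0)
        assert ("x", "y") in summary.pairwise_p

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0, 3.0])
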