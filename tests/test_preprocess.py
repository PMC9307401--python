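"""Preprocessing chain: each stage against an explicit oracle."""

import numpy as np
import pytest

from prestim.containers import Epochs, EventList, Event
from prestim.preprocess import (
    average_epochs,
    average_reference,
    baseline_correct,
    detect_blinks,
    extract_epochs,
    lowpass_filter,
    reject_epochs,
    reject_ocular_epochs,
    remove_dc,
    remove_ocular,
)
from prestim.pipeline import preprocess_session
from prestim.synth import EffectSpec, generate_session

from conftest import make_raw, make_small_config


def make_epochs(data, sampling_rate=500.0, t0_index=None, labels=None,
                channel_names=("Fz", "Cz")):
    data = np.asarray(data, dtype=float)
    n_t = data.shape[2]
    if t0_index is None:
        t0_index = n_t - 1
    times = (np.arange(n_t) - t0_index) * 1000.0 / sampling_rate
    if labels is None:
        labels = ["a"] * data.shape[0]
    return Epochs(
        data=data,
        times=times,
        channel_names=channel_names,
        labels=np.asarray(labels, dtype=object),
        sampling_rate=sampling_rate,
    )


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        ep = make_epochs(np.full((2, 2, 100), 7.5))
        out = baseline_correct(ep, (-100, 0))
        assert np.allclose(out.data, 0.0)

    def test_linear_ramp_oracle(self):
        # oracle: explicit mean subtraction over the window
        ep = make_epochs(np.tile(np.arange(100.0), (1, 2, 1)))
        window = (-60.0, -40.0)
        out = baseline_correct(ep, window)
        mask = (ep.times >= window[0]) & (ep.times <= window[1])
        expected = ep.data - ep.data[:, :, mask].mean(axis=2, keepdims=True)
        assert np.allclose(out.data, expected)

    def test_idempotent_on_zero_mean(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((3, 2, 50)))
        once = baseline_correct(ep, (-40, 0))
        twice = baseline_correct(once, (-40, 0))
        assert np.allclose(once.data, twice.data)

    def test_empty_window_rejected(self):
        ep = make_epochs(np.zeros((1, 2, 50)))
        with pytest.raises(ValueError):
            baseline_correct(ep, (500.0, 600.0))


class TestDetectBlinks:
    def _raw(self, veog):
        n = veog.size
        data = np.zeros((3, n))
        data[2] = veog
        return make_raw(data, ("Fz", "Cz", "VEOG"), sampling_rate=250.0)

    def test_flat_veog_gives_no_blinks(self):
        assert detect_blinks(self._raw(np.zeros(2500))) == []

    def test_transient_detected_at_its_time(self):
        veog = np.zeros(2500)
        veog[1250:1275] = 200.0  # t = 5.0 .. 5.1 s
        (iv,) = detect_blinks(self._raw(veog))
        assert iv[0] <= 5.0 <= iv[1]

    def test_nearby_transients_merge(self):
        # oracle: merge rule applied by hand -- 50 ms gap < 100 ms merges
        veog = np.zeros(2500)
        veog[500:510] = 150.0
        veog[522:532] = 150.0  # 12 samples = 48 ms later
        assert len(detect_blinks(self._raw(veog))) == 1

    def test_missing_channel_is_an_error(self):
        with pytest.raises(KeyError):
            detect_blinks(self._raw(np.zeros(100)), veog_channel="HEOG")


@pytest.fixture(scope="module")
def blink_recording():
    """Small recording with strong blink contamination for ICA tests."""
    config = make_small_config(n_trials=20, sampling_rate=250.0, seed=31)
    effects = EffectSpec(noise_rms_uv=3.0, blink_rate_per_min=15.0,
                         bad_block_rate_per_min=0.0)
    raw, events, _ = generate_session(config, effects)
    return raw, events


class TestRemoveOcular:
    def test_blink_free_recording_roundtrips(self):
        config = make_small_config(n_trials=20, sampling_rate=250.0, seed=32)
        effects = EffectSpec(noise_rms_uv=3.0, blink_rate_per_min=0.0,
                             bad_block_rate_per_min=0.0)
        raw, _, _ = generate_session(config, effects)
        cleaned, removed = remove_ocular(raw)
        assert removed == 0
        assert np.max(np.abs(cleaned.data - raw.data)) < 1.0

    def test_blinks_removed_and_veog_correlation_reduced(self, blink_recording):
        raw, _ = blink_recording
        veog = raw.get_channel("VEOG")
        fz_before = raw.get_channel("Fz")
        corr_before = abs(np.corrcoef(fz_before, veog)[0, 1])
        cleaned, removed = remove_ocular(raw)
        corr_after = abs(np.corrcoef(cleaned.get_channel("Fz"), veog)[0, 1])
        assert removed >= 1
        assert corr_after < corr_before

    def test_vacuous_threshold_removes_nothing(self, blink_recording):
        raw, _ = blink_recording
        cleaned, removed = remove_ocular(raw, corr_threshold=1.0)
        assert removed == 0
        assert np.max(np.abs(cleaned.data - raw.data)) < 1.0

    def test_rank_deficient_data_is_diagnosed(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 2000))
        data[1] = data[0]  # duplicated channel
        raw = make_raw(data, ("Fz", "Cz", "Pz", "VEOG"))
        from prestim.preprocess import DecompositionError

        with pytest.raises(DecompositionError, match="rank"):
            remove_ocular(raw)


class TestExtractEpochs:
    def test_sample_count_includes_both_endpoints(self, noiseless_session):
        _, _, (raw, events, _) = noiseless_session  # 500 Hz
        epochs = extract_epochs(raw, events, "decision", (-500, 0))
        assert epochs.data.shape[2] == 251
        assert epochs.times[-1] == 0.0

    def test_marker_sample_alignment(self, noiseless_session):
        _, _, (raw, events, _) = noiseless_session
        epochs = extract_epochs(raw, events, "decision", (-500, 0))
        k0 = np.argmin(np.abs(epochs.times))
        for j, ev in enumerate(list(events)[:5]):
            assert np.allclose(epochs.data[j, :, k0], raw.data[:, ev.sample])

    def test_zero_events_yield_empty_epochs(self, noiseless_session):
        _, _, (raw, _, _) = noiseless_session
        empty = EventList(events=[], sampling_rate=raw.sampling_rate)
        epochs = extract_epochs(raw, empty, "decision", (-500, 0))
        assert epochs.n_trials == 0

    def test_edge_event_flagged(self):
        data = np.zeros((2, 1000))
        raw = make_raw(data, ("Fz", "VEOG"))
        events = EventList(
            events=[Event(10, "left", "gain", 5.0),
                    Event(500, "right", "loss", 5.0)],
            sampling_rate=250.0,
        )
        epochs = extract_epochs(raw, events, "decision", (-500, 0))
        assert epochs.rejected[0] and epochs.reject_reason[0] == "edge"
        assert not epochs.rejected[1]


class TestRejectEpochs:
    def test_clean_epochs_keep_everything(self):
        ep = make_epochs(np.zeros((4, 2, 400)), t0_index=150)
        assert reject_epochs(ep).n_kept == 4

    def test_exactly_the_offending_trial_is_flagged(self):
        # oracle: brute-force scan -- only trial 1 exceeds the threshold
        # inside the scan window
        data = np.zeros((3, 2, 400))
        ep = make_epochs(data, t0_index=150)
        k100 = np.argmin(np.abs(ep.times - 100))
        data[1, 0, k100] = 101.0
        ep = make_epochs(data, t0_index=150)
        out = reject_epochs(ep)
        assert list(out.rejected) == [False, True, False]
        assert out.reject_reason[1] == "amplitude"

    def test_excursion_outside_scan_window_is_ignored(self):
        data = np.zeros((1, 2, 400))
        ep = make_epochs(data, t0_index=150)
        k = np.argmin(np.abs(ep.times - (-300)))
        data[0, 0, k] = 101.0
        ep = make_epochs(data, t0_index=150)
        out = reject_epochs(ep, scan_window=(-200, 500))
        assert out.n_kept == 1

    def test_rejection_count_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(60 * rng.standard_normal((30, 2, 200)), t0_index=100)
        counts = [
            int(reject_epochs(ep, amplitude_threshold=thr).rejected.sum())
            for thr in (40, 80, 120, 160)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_veog_channel_not_scanned(self):
        data = np.zeros((1, 2, 400))
        data[0, 1, 200] = 500.0  # second channel is VEOG below
        ep = make_epochs(data, t0_index=150, channel_names=("Fz", "VEOG"))
        assert reject_epochs(ep, scan_window=None).n_kept == 1


class TestRejectOcularEpochs:
    def test_trial_overlapping_blink_dropped(self):
        raw = make_raw(np.zeros((2, 5000)), ("Fz", "VEOG"))
        events = EventList(
            events=[Event(1000, "left", "gain", 5.0),
                    Event(3000, "right", "loss", 5.0)],
            sampling_rate=250.0,
        )
        epochs = extract_epochs(raw, events, "decision", (-500, 0))
        # first epoch spans 3.5-4.0 s (decision at sample 1000 = 4.0 s)
        out = reject_ocular_epochs(epochs, events, [(3.2, 3.4)])
        assert list(out.rejected) == [False, False]
        out = reject_ocular_epochs(epochs, events, [(3.6, 3.7)])
        assert list(out.rejected) == [True, False]
        assert out.reject_reason[0] == "ocular"


class TestAverageEpochs:
    def test_matches_naive_two_loop_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((12, 3, 40))
        labels = ["left"] * 7 + ["right"] * 5
        ep = make_epochs(data, labels=labels, channel_names=("Fz", "Cz", "Pz"))
        avg = average_epochs(ep, "left")
        # naive summation, one trial and one sample at a time
        expected = np.zeros((3, 40))
        for j in range(7):
            for i in range(40):
                expected[:, i] += data[j, :, i]
        expected /= 7
        assert np.max(np.abs(avg.data - expected)) < 1e-9
        assert avg.n == 7

    def test_constants_average_to_their_mean(self):
        data = np.stack([np.full((2, 10), v) for v in (1.0, 2.0, 3.0)])
        ep = make_epochs(data)
        assert np.allclose(average_epochs(ep, "a").data, 2.0)

    def test_rejected_trials_do_not_contribute(self):
        data = np.stack([np.full((2, 10), v) for v in (1.0, 2.0, 100.0)])
        ep = make_epochs(data)
        ep.rejected[2] = True
        assert np.allclose(average_epochs(ep, "a").data, 1.5)

    def test_zero_kept_trials_is_an_error(self):
        ep = make_epochs(np.zeros((2, 2, 10)))
        with pytest.raises(ValueError, match="nope"):
            average_epochs(ep, "nope")


class TestLowpass:
    def _gain(self, freq, fs=500.0, cutoff=30.0):
        t = np.arange(int(fs * 4)) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_filter(x, fs, cutoff)
        # FFT amplitude ratio at the stimulus frequency
        f = np.fft.rfftfreq(t.size, 1 / fs)
        k = np.argmin(np.abs(f - freq))
        return np.abs(np.fft.rfft(y))[k] / np.abs(np.fft.rfft(x))[k]

    def test_dc_preserved(self):
        x = np.full(1000, 3.0)
        assert np.max(np.abs(lowpass_filter(x, 500.0) - 3.0)) < 1e-6

    def test_passband_5hz_within_5_percent(self):
        assert self._gain(5.0) == pytest.approx(1.0, abs=0.05)

    def test_stopband_60hz_attenuated_24db(self):
        assert 20 * np.log10(self._gain(60.0)) <= -24.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), 100.0, cutoff=60.0)


class TestAverageReference:
    names = ("Fz", "Cz", "Pz", "VEOG")

    def test_channel_sum_zero_everywhere(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((4, 200))
        out = average_reference(data, self.names)
        assert np.allclose(out[:3].sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out[3], data[3])  # VEOG untouched

    def test_identical_channels_become_zero(self):
        data = np.tile(np.arange(50.0), (4, 1))
        out = average_reference(data, self.names)
        assert np.allclose(out[:3], 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 100))
        once = average_reference(data, self.names)
        assert np.allclose(average_reference(once, self.names), once)

    def test_single_eeg_channel_rejected(self):
        with pytest.raises(ValueError):
            average_reference(np.zeros((2, 10)), ("Fz", "VEOG"))


class TestFullChain:
    def test_noiseless_chain_recovers_templates_within_filter_ripple(
        self, noiseless_session
    ):
        config, effects, (raw, events, truth) = noiseless_session
        res = preprocess_session(raw, events)
        gain = res.evokeds[("feedback", "gain")]
        fz = gain.channel_index("Fz")
        k = np.argmin(np.abs(gain.times - truth.mfn_latency))
        assert gain.data[fz, k] == pytest.approx(
            truth.gain_amplitude, rel=0.02
        )
        assert res.n_rejected["decision"] == 0
        # only the final trial may drop out (its feedback epoch ends exactly
        # at the recording boundary)
        assert res.n_rejected["feedback"] <= 1

    def test_dc_offsets_removed(self):
        data = np.full((2, 1000), 1500.0)
        raw = make_raw(data, ("Fz", "VEOG"))
        out = remove_dc(raw)
        assert np.allclose(out.data, 0.0)
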