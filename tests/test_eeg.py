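"""EEG preprocessing, wavelets, time-point selection and features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from icdecode import synth
from icdecode.eeg import (BandDef, DEFAULT_BANDS, EpochSet, WaveletParams,
                          band_power_envelope, baseline_correct,
                          build_eeg_features, detect_artifacts,
                          morlet_spectrogram, morlet_wavelet, normalize_power,
                          preprocess_continuous, segment_epochs,
                          select_timepoints)
from icdecode.pipeline import _trial_spectrogram_power

RATE = 250.0


def _sinusoid(freq, seconds=8.0, amp=1.0, rate=RATE):
    t = np.arange(int(seconds * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)[None, :]


class TestPreprocess:
    # long signals with generous edge exclusion: the 0.1 Hz high-pass rings
    # for seconds, which is a property of the filter, not of the notch
    def test_mains_notch_attenuates_40db(self):
        x = _sinusoid(60.0, seconds=30.0)
        y = preprocess_continuous(x, RATE)
        core = slice(2500, -2500)
        assert np.sqrt((y[0, core] ** 2).mean()) <= 0.01 * np.sqrt(
            (x[0, core] ** 2).mean())

    def test_passband_preserved(self):
        x = _sinusoid(10.0, seconds=30.0)
        y = preprocess_continuous(x, RATE)
        core = slice(2500, -2500)
        ratio = np.sqrt((y[0, core] ** 2).mean() / (x[0, core] ** 2).mean())
        assert abs(ratio - 1.0) < 0.03

    def test_dc_removed(self):
        x = np.full((1, 4000), 7.0)
        y = preprocess_continuous(x, RATE)
        assert np.abs(y).max() < 0.5

    def test_nyquist_violation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_continuous(np.zeros((1, 1000)), 150.0, hi=100.0)


class TestSegmentation:
    def _recording(self, n_events=5, gap=4.0):
        onsets = 2.0 + gap * np.arange(n_events)
        dur = onsets[-1] + 4.0
        data = np.random.default_rng(0).standard_normal(
            (3, int(dur * RATE)))
        events = pd.DataFrame({"onset": onsets, "duration": 1.0,
                               "trial_type": (["B", "DB"] * 3)[:n_events],
                               "response_time": 1.0})
        return data, events

    def test_epoch_length_750_samples(self):
        data, events = self._recording()
        es = segment_epochs(data, RATE, events)
        assert es.n_samples == 750
        assert es.n_trials == len(events)

    def test_event_near_start_dropped_with_reason(self):
        data, events = self._recording()
        events.loc[0, "onset"] = 0.1  # pre-window would underrun
        es = segment_epochs(data, RATE, events)
        assert es.n_trials == len(events) - 1
        assert 0 in es.exclusion_reasons

    def test_all_events_kept_when_clear_of_edges(self):
        data, events = self._recording(n_events=4)
        es = segment_epochs(data, RATE, events)
        assert es.n_trials == 4
        assert list(es.labels) == list(events["trial_type"])


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        es = EpochSet(data=np.full((2, 3, 750), 4.2),
                      labels=np.array(["B", "DB"]), sampling_rate=RATE,
                      t0_offset=-500.0)
        out = baseline_correct(es)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_shift_by_baseline_mean(self):
        es = EpochSet(data=np.full((1, 1, 750), 3.0),
                      labels=np.array(["B"]), sampling_rate=RATE,
                      t0_offset=-500.0)
        es.data[0, 0, :100] += 1.0  # perturb outside the baseline window
        out = baseline_correct(es)
        win = (es.times_ms >= -100) & (es.times_ms < 0)
        np.testing.assert_allclose(out.data[0, 0, win], 0.0, atol=1e-12)

    def test_random_input_baseline_mean_zero(self):
        rng = np.random.default_rng(1)
        es = EpochSet(data=rng.standard_normal((4, 2, 750)),
                      labels=np.array(["B", "DB", "B", "DB"]),
                      sampling_rate=RATE, t0_offset=-500.0)
        out = baseline_correct(es)
        win = (es.times_ms >= -100) & (es.times_ms < 0)
        assert np.abs(out.data[:, :, win].mean(axis=-1)).max() < 1e-10


class TestArtifacts:
    def test_injected_ramp_flagged(self, flat_epochs):
        synth.inject_ramp(flat_epochs, trial=3, channel=2,
                          slope_uv_per_ms=20.0, start_ms=0.0, dur_ms=400.0)
        out, report = detect_artifacts(flat_epochs)
        assert out.bad_channel_mask[3, 2]
        assert report["n_flagged"] >= 1

    def test_all_zero_data_clean(self, flat_epochs):
        out, report = detect_artifacts(flat_epochs)
        assert report["n_flagged"] == 0
        assert report["excluded_channels"] == []
        assert report["excluded_trials"] == []

    def test_channel_excluded_above_error_fraction(self, flat_epochs):
        for t in range(5):  # 5 of 20 trials = 25% > 20%
            synth.inject_blink(flat_epochs, trial=t, channel=1,
                               peak_uv=500.0, center_ms=600.0)
        out, report = detect_artifacts(flat_epochs)
        assert 1 in report["excluded_channels"]

    def test_data_never_modified(self, flat_epochs):
        synth.inject_blink(flat_epochs, trial=0, channel=0, peak_uv=500.0,
                           center_ms=600.0)
        before = flat_epochs.data.copy()
        detect_artifacts(flat_epochs)
        np.testing.assert_array_equal(flat_epochs.data, before)


class TestMorlet:
    def test_peak_at_signal_frequency(self):
        spec = morlet_spectrogram(_sinusoid(10.0, seconds=3.0), RATE)
        avg = spec.power[0].mean(axis=-1)
        assert spec.freqs[np.argmax(avg)] == 10.0

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 500))
        a = morlet_spectrogram(x, RATE)
        b = morlet_spectrogram(2 * x, RATE)
        np.testing.assert_allclose(b.power, 4 * a.power, rtol=1e-12)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(600)
        spec = morlet_spectrogram(x, RATE,
                                  WaveletParams(freq_range=(5.0, 40.0),
                                                freq_step=5.0))
        for fi, f in enumerate(spec.freqs):
            atom = morlet_wavelet(f, RATE)
            direct = np.abs(np.convolve(x, atom[::-1].conj(), mode="same")) ** 2
            interior = ~spec.edge_mask[fi]
            rel = np.abs(spec.power[0, fi] - direct) / np.maximum(direct, 1e-300)
            assert rel[interior].max() < 1e-6

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_spectrogram(np.zeros(500), RATE,
                               WaveletParams(freq_range=(1.0, 130.0)))

    def test_batch_helper_matches_per_trial_path(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((3, 2, 400))
        band = DEFAULT_BANDS["gamma"]
        freqs = band.freqs()
        batch = _trial_spectrogram_power(data, RATE, freqs, WaveletParams())
        for i in range(3):
            spec = normalize_power(morlet_spectrogram(data[i], RATE,
                                                      freqs=freqs))
            np.testing.assert_allclose(batch[i], spec.power, rtol=1e-9)


class TestNormalize:
    def test_constant_power_becomes_one(self):
        from icdecode.eeg import Spectrogram
        spec = Spectrogram(power=np.full((1, 2, 100), 4.0),
                           freqs=np.array([10.0, 11.0]),
                           times=np.arange(100.0))
        out = normalize_power(spec)
        np.testing.assert_allclose(out.power, 1.0)

    def test_time_mean_is_one_and_idempotent(self):
        rng = np.random.default_rng(5)
        from icdecode.eeg import Spectrogram
        spec = Spectrogram(power=rng.random((2, 3, 80)) + 0.1,
                           freqs=np.arange(3.0), times=np.arange(80.0))
        out = normalize_power(spec)
        np.testing.assert_allclose(out.power.mean(axis=-1), 1.0, atol=1e-10)
        again = normalize_power(out)
        np.testing.assert_allclose(again.power, out.power, atol=1e-10)

    def test_zero_signal_rejected(self):
        from icdecode.eeg import Spectrogram
        spec = Spectrogram(power=np.zeros((1, 1, 10)),
                           freqs=np.array([5.0]), times=np.arange(10.0))
        with pytest.raises(ValueError):
            normalize_power(spec)


class TestTimepointSelection:
    def _power(self, n_trials, n_chan=2, n_freq=3, n_time=50, value=1.0):
        return np.full((n_trials, n_chan, n_freq, n_time), value)

    def test_identical_classes_degenerate_tiebreak(self):
        power = self._power(8)
        labels = np.array(["B"] * 4 + ["DB"] * 4)
        band = BandDef("x", 0.0, 10.0)
        sel = select_timepoints(power, labels, band, np.array([1.0, 2.0, 3.0]),
                                np.arange(50.0))
        assert sel.degenerate
        assert sel.f_B_value == 0.0 and sel.f_DB_value == 0.0
        assert sel.t_B == 0.0 and sel.chan_B == 0  # earliest time, lowest chan

    def test_label_swap_swaps_selections(self, small_eeg):
        cfg, epochs, _ = small_eeg
        band = DEFAULT_BANDS["gamma"]
        freqs = band.freqs()
        power = _trial_spectrogram_power(epochs.data, RATE, freqs,
                                         WaveletParams())
        sel = select_timepoints(power, epochs.labels, band, freqs,
                                epochs.times_ms)
        swapped = np.where(epochs.labels == "B", "DB", "B")
        sel2 = select_timepoints(power, swapped, band, freqs, epochs.times_ms)
        assert (sel.t_B, sel.chan_B) == (sel2.t_DB, sel2.chan_DB)
        assert (sel.t_DB, sel.chan_DB) == (sel2.t_B, sel2.chan_B)

    def test_planted_latency_recovered(self, small_eeg):
        cfg, epochs, truth = small_eeg
        band = DEFAULT_BANDS["gamma"]
        freqs = band.freqs()
        power = _trial_spectrogram_power(epochs.data, RATE, freqs,
                                         WaveletParams())
        sel = select_timepoints(power, epochs.labels, band, freqs,
                                epochs.times_ms)
        assert abs(sel.t_B - truth.discriminative_latency_B) <= 100.0
        assert abs(sel.t_DB - truth.discriminative_latency_DB) <= 100.0

    def test_single_class_rejected(self):
        power = self._power(4)
        with pytest.raises(ValueError):
            select_timepoints(power, np.array(["B"] * 4),
                              BandDef("x", 0.0, 10.0),
                              np.array([1.0, 2.0, 3.0]), np.arange(50.0))


class TestBandPower:
    def test_alpha_sinusoid_energy(self):
        x = _sinusoid(10.0, seconds=4.0, amp=2.0)[None, :, :]
        env = band_power_envelope(x, RATE, DEFAULT_BANDS["alpha"])
        core = slice(250, -250)
        assert abs(env[0, 0, core].mean() - 2.0**2 / 2) / (2.0**2 / 2) < 0.05

    def test_out_of_band_sinusoid_rejected(self):
        # long signal so the narrow delta band-pass transient dies out
        x = _sinusoid(10.0, seconds=40.0)[None, :, :]
        in_band = band_power_envelope(x, RATE, DEFAULT_BANDS["alpha"])
        out_band = band_power_envelope(x, RATE, DEFAULT_BANDS["delta"])
        core = slice(2500, -2500)
        assert out_band[0, 0, core].mean() < 0.01 * in_band[0, 0, core].mean()

    def test_zero_signal_zero_envelope(self):
        env = band_power_envelope(np.zeros((1, 2, 1000)), RATE,
                                  DEFAULT_BANDS["beta"])
        np.testing.assert_allclose(env, 0.0, atol=1e-20)

    def test_hilbert_envelope_smooth_upper_bound(self):
        x = _sinusoid(10.0, seconds=4.0)[None, :, :]
        sq = band_power_envelope(x, RATE, DEFAULT_BANDS["alpha"], "square")
        hb = band_power_envelope(x, RATE, DEFAULT_BANDS["alpha"], "hilbert")
        core = slice(250, -250)
        assert (hb[0, 0, core] >= sq[0, 0, core] - 1e-9).all()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power_envelope(np.zeros((1, 1, 100)), 80.0,
                                DEFAULT_BANDS["gamma"])


class TestFeatureAssembly:
    def _selection(self, band="gamma", t_B=600.0, t_DB=1100.0):
        from icdecode.eeg import TimepointSelection
        return TimepointSelection(band=DEFAULT_BANDS[band], t_B=t_B, chan_B=0,
                                  f_B_value=1.0, t_DB=t_DB, chan_DB=1,
                                  f_DB_value=1.0)

    @pytest.mark.parametrize("n_chan,n_bands,expected", [
        (8, 1, 16), (8, 5, 80), (256, 1, 512), (256, 5, 2560),
    ])
    def test_feature_count(self, n_chan, n_bands, expected):
        source = np.ones((3, n_chan, 750))
        sels = [self._selection(b) for b in
                list(DEFAULT_BANDS)[:n_bands]]
        times = -500.0 + 4.0 * np.arange(750)
        tab = build_eeg_features(source, sels, times,
                                 np.array(["B", "DB", "B"]))
        assert tab.X.shape == (3, expected)
        assert len(tab.meta) == expected

    def test_sample_time_outside_epoch_rejected(self):
        source = np.ones((2, 2, 100))
        sel = self._selection(t_B=5000.0)
        with pytest.raises(ValueError, match="outside the epoch"):
            build_eeg_features(source, sel, np.arange(100.0),
                               np.array(["B", "DB"]))

    def test_values_sampled_at_selected_times(self):
        rng = np.random.default_rng(6)
        source = rng.random((4, 3, 100))
        times = np.arange(100.0)
        sel = self._selection(t_B=20.0, t_DB=70.0)
        tab = build_eeg_features(source, sel, times,
                                 np.array(["B", "DB", "B", "DB"]))
        np.testing.assert_array_equal(tab.X[:, 0], source[:, 0, 20])
        np.testing.assert_array_equal(tab.X[:, 3], source[:, 0, 70])


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_band_definitions_cover_all_frequencies(seed):
    """Any frequency in (0.1, 45) belongs to exactly one default band."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.11, 44.9)
    hits = [b for b in DEFAULT_BANDS.values() if b.lo <= f < b.hi]
    assert len(hits) == 1
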