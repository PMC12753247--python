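"""LFP preprocessing, VEP amplitudes, cycle windows and spectral summaries."""

import numpy as np
import pytest

from famosc import synthgen
from famosc.lfp import (CycleWindows, EpochTrace, band_power_summary,
                        derive_cycle_windows, morlet_spectrogram,
                        preprocess_lfp, select_channel_and_average,
                        vep_cycle_amplitudes)
from famosc.presets import WT_LIKE
from famosc.types import RecordingSession, TrialLayout, ValidationError

FS_RAW = 20000.0


def _tone(freq, fs=FS_RAW, dur=4.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    @pytest.mark.parametrize("freq, bound, kind", [
        (10.0, 0.99, "min"),    # deep passband: amplitude preserved to 1%
        (60.0, 0.1, "max"),     # notch target
        (2000.0, 0.01, "max"),  # far stopband
    ])
    def test_magnitude_response(self, freq, bound, kind):
        out = preprocess_lfp(_tone(freq), FS_RAW)[0]
        # measure away from filter edge transients
        amp = np.abs(out[500:-500]).max()
        if kind == "min":
            assert amp >= bound and amp <= 1.01
        else:
            assert amp < bound

    def test_rate_and_latency(self):
        x = _tone(10.0)
        out = preprocess_lfp(x, FS_RAW)
        assert out.shape[1] == x.size // 20  # decimated to 1 kHz
        # zero-phase: the 10 Hz peak near t=0.025 s stays put
        peak_raw = np.argmax(x[:int(0.05 * FS_RAW)]) / FS_RAW
        peak_out = np.argmax(out[0][:50]) / 1000.0
        assert abs(peak_raw - peak_out) < 0.002

    def test_undersampled_source_rejected(self):
        with pytest.raises(ValidationError, match="cutoff"):
            preprocess_lfp(np.zeros(1000), source_rate=500.0)

    def test_non_integer_decimation_rejected(self):
        with pytest.raises(ValidationError, match="integer multiple"):
            preprocess_lfp(np.zeros(1000), source_rate=1500.0)


def _session_from_epochs(epochs, fs, layout):
    """Build a session whose continuous LFP is the concatenated epochs."""
    n_trials, n_ch, n_samp = epochs.shape
    lfp = epochs.transpose(1, 0, 2).reshape(n_ch, n_trials * n_samp)
    onsets = np.arange(n_trials) * (n_samp / fs) + layout.onset_in_epoch
    return RecordingSession(layout=layout, trial_onsets=onsets,
                            trial_directions=np.full(n_trials, 60.0),
                            lfp=lfp, lfp_rate=fs)


class TestChannelSelection:
    layout = TrialLayout(epoch_length=1.0, sampling_rate_lfp=1000.0,
                        n_trials=3)

    def _epochs(self, deflections):
        fs = 1000.0
        n = int(self.layout.epoch_length * fs)
        epochs = np.zeros((self.layout.n_trials, len(deflections), n))
        i0 = int(0.55 * fs)
        for c, d in enumerate(deflections):
            epochs[:, c, i0] = d
        return epochs

    def test_most_negative_channel_wins(self):
        epochs = self._epochs([-5.0, -50.0, -5.0])
        trace, chan = select_channel_and_average(
            _session_from_epochs(epochs, 1000.0, self.layout), self.layout)
        assert chan == 1
        assert trace.values.min() == -50.0

    def test_tie_breaks_to_lowest_index(self):
        epochs = self._epochs([-50.0, -50.0, -5.0])
        _, chan = select_channel_and_average(
            _session_from_epochs(epochs, 1000.0, self.layout), self.layout)
        assert chan == 0

    def test_identical_trials_average_to_single_trial(self):
        epochs = self._epochs([-5.0, -50.0, -5.0])
        trace, chan = select_channel_and_average(
            _session_from_epochs(epochs, 1000.0, self.layout), self.layout)
        np.testing.assert_allclose(trace.values, epochs[0, chan], atol=1e-9)

    def test_short_trial_rejected(self):
        epochs = self._epochs([-5.0, -50.0])
        sess = _session_from_epochs(epochs, 1000.0, self.layout)
        sess.trial_onsets = sess.trial_onsets + 0.5  # last epoch now too long
        with pytest.raises(ValidationError, match=r"trials \[2\]"):
            select_channel_and_average(sess, self.layout)


class TestVepAmplitudes:
    def test_constructed_extremes(self):
        fs = 1000.0
        v = np.zeros(1000)
        v[100] = 3.0
        v[150] = -5.0
        trace = EpochTrace(v, fs)
        amps = vep_cycle_amplitudes(trace, CycleWindows([(0.05, 0.25)]))
        assert amps[0] == pytest.approx(8.0)

    def test_flat_trace_zero_everywhere(self):
        trace = EpochTrace(np.full(1000, 3.7), 1000.0)
        wins = CycleWindows([(0.0, 0.2), (0.3, 0.5), (0.6, 0.9)])
        np.testing.assert_array_equal(vep_cycle_amplitudes(trace, wins),
                                      np.zeros(3))

    def test_full_cycle_sine_gives_twice_amplitude(self):
        fs, a, f = 1000.0, 2.5, 5.0
        t = np.arange(int(fs)) / fs
        trace = EpochTrace(a * np.sin(2 * np.pi * f * t), fs)
        amps = vep_cycle_amplitudes(trace, CycleWindows([(0.0, 1.0 / f)]))
        assert amps[0] == pytest.approx(2 * a, rel=1e-3)

    def test_offset_invariance(self, rng):
        fs = 1000.0
        v = rng.standard_normal(2000)
        trace = EpochTrace(v, fs)
        shifted = EpochTrace(v + 123.4, fs)
        wins = CycleWindows([(0.1, 0.3), (0.5, 0.8), (1.2, 1.9)])
        np.testing.assert_allclose(vep_cycle_amplitudes(trace, wins),
                                   vep_cycle_amplitudes(shifted, wins),
                                   atol=1e-9)

    def test_empty_window_rejected(self):
        trace = EpochTrace(np.zeros(100), 1000.0)
        with pytest.raises(ValidationError, match="no samples"):
            vep_cycle_amplitudes(trace, CycleWindows([(0.5, 0.5004)]))


def _vep_template(f=6.5, n_cycles=5, fs=1000.0, epoch=2.5, amp=100.0,
                  tau=0.8):
    t = np.arange(int(epoch * fs)) / fs
    d = t - 0.5
    live = (d >= 0) & (d <= n_cycles / f)
    return EpochTrace(np.where(live, -amp * np.exp(-d / tau)
                               * np.sin(2 * np.pi * f * d), 0.0), fs)


class TestCycleWindows:
    def test_noiseless_template_five_windows(self):
        f = 6.0
        trace = _vep_template(f=f, n_cycles=5)
        cw = derive_cycle_windows(trace, expected_n=5)
        assert cw.complete and len(cw.windows) == 5
        centers = [(a + b) / 2 for a, b in cw.windows]
        # troughs of the VEP sit 1/f apart
        np.testing.assert_allclose(np.diff(centers), 1.0 / f, atol=0.01)
        # first trough (quarter cycle after onset) inside the stimulus window
        assert 0.5 <= centers[0] <= 0.7

    def test_flat_trace_warns_and_returns_nothing(self):
        trace = EpochTrace(np.zeros(2500), 1000.0)
        with pytest.warns(UserWarning, match="no post-onset troughs"):
            cw = derive_cycle_windows(trace, expected_n=5)
        assert cw.windows == [] and not cw.complete

    def test_fewer_cycles_than_requested_capped_with_warning(self):
        trace = _vep_template(f=4.5, n_cycles=2)
        with pytest.warns(UserWarning, match="only 2 troughs"):
            cw = derive_cycle_windows(trace, expected_n=5)
        assert len(cw.windows) == 2 and not cw.complete

    def test_amplitudes_recover_template_decay(self):
        trace = _vep_template()
        cw = derive_cycle_windows(trace, expected_n=5)
        amps = vep_cycle_amplitudes(trace, cw)
        assert np.all(np.diff(amps) < 0)  # decaying envelope


class TestMorlet:
    def test_pure_tone_row_argmax(self):
        fs, f0 = 1000.0, 6.0
        t = np.arange(int(3.0 * fs)) / fs
        trace = EpochTrace(np.sin(2 * np.pi * f0 * t), fs)
        freqs = np.linspace(4.0, 12.0, 17)
        power, fr, _ = morlet_spectrogram(trace, freqs,
                                          baseline_window=None)
        mid = power[:, power.shape[1] // 2]
        assert abs(fr[np.argmax(mid)] - f0) <= 0.5

    def test_silence_is_uniform(self):
        trace = EpochTrace(np.zeros(3000), 1000.0)
        power, _, _ = morlet_spectrogram(trace, np.linspace(4, 20, 9))
        np.testing.assert_allclose(power, 0.0, atol=1e-6)

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        fs, dur = 1000.0, 4.0
        t = np.arange(int(dur * fs)) / fs
        f0, f1 = 4.0, 10.0
        phase = 2 * np.pi * (f0 * t + (f1 - f0) * t ** 2 / (2 * dur))
        trace = EpochTrace(np.sin(phase), fs)
        freqs = np.linspace(4.0, 12.0, 33)
        power, fr, times = morlet_spectrogram(trace, freqs,
                                              baseline_window=None)
        interior = (times > 1.2) & (times < dur - 1.2)
        ridge = fr[np.argmax(power[:, interior], axis=0)]
        inst = f0 + (f1 - f0) * times[interior] / dur
        assert np.all(np.abs(ridge - inst) <= 1.0)
        # ridge increases monotonically up to one frequency-step of jitter
        step = fr[1] - fr[0]
        assert np.all(np.diff(ridge) >= -step - 1e-9)
        assert ridge[-1] > ridge[0] + 2.0

    def test_nyquist_rejected(self):
        trace = EpochTrace(np.zeros(3000), 1000.0)
        with pytest.raises(ValidationError, match="frequencies"):
            morlet_spectrogram(trace, np.array([600.0]))

    def test_overlong_wavelet_rejected(self):
        trace = EpochTrace(np.zeros(1000), 1000.0)
        with pytest.raises(ValidationError, match="longer"):
            morlet_spectrogram(trace, np.array([2.0]), baseline_window=None)


class TestBandPower:
    @pytest.mark.parametrize("f0, band", [
        (6.0, (4.0, 8.0)), (10.0, (8.0, 12.0)),
        (20.0, (12.0, 30.0)), (35.0, (30.0, 40.0))])
    def test_tone_maps_to_band(self, f0, band):
        fs = 1000.0
        t = np.arange(int(2.5 * fs)) / fs
        trace = EpochTrace(np.sin(2 * np.pi * f0 * t), fs)
        assert band_power_summary(trace).argmax_band == band

    def test_two_tone_power_ratio(self):
        fs = 1000.0
        t = np.arange(int(2.5 * fs)) / fs
        x = 2.0 * np.sin(2 * np.pi * 6.0 * t) + np.sin(2 * np.pi * 20.0 * t)
        summ = band_power_summary(EpochTrace(x, fs))
        ratio = summ.band_power[(4.0, 8.0)] / summ.band_power[(12.0, 30.0)]
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_parseval_total_power_matches_variance(self):
        from scipy.signal import periodogram
        fs = 1000.0
        t = np.arange(int(2.0 * fs)) / fs
        x = (np.sin(2 * np.pi * 6 * t) + 0.5 * np.sin(2 * np.pi * 21 * t)
             + 0.25 * np.sin(2 * np.pi * 35 * t))
        f, pxx = periodogram(x, fs=fs, window="hann", detrend="constant",
                             scaling="density")
        total = np.sum(pxx) * (f[1] - f[0])
        assert total == pytest.approx(np.var(x), rel=0.01)

    def test_short_window_rejected(self):
        trace = EpochTrace(np.zeros(2500), 1000.0)
        with pytest.raises(ValidationError, match="shorter than one period"):
            band_power_summary(trace, window=(0.5, 0.7))


class TestPipelineRecovery:
    """End-to-end: generated LFP -> preprocess -> channel -> spectra."""

    @pytest.mark.parametrize("f0", [5.0, 6.0, 7.0])
    def test_theta_frequency_recovered(self, f0):
        from dataclasses import replace
        preset = replace(WT_LIKE,
                         lfp=replace(WT_LIKE.lfp, osc_frequency=f0))
        sess = synthgen.gen_lfp_session(preset, seed=11)
        clean = preprocess_lfp(sess.lfp, sess.lfp_rate)
        sess2 = RecordingSession(
            layout=sess.layout, trial_onsets=sess.trial_onsets,
            trial_directions=sess.trial_directions, lfp=clean,
            lfp_rate=1000.0, channel_depths_um=sess.channel_depths_um)
        trace, _ = select_channel_and_average(sess2)
        summ = band_power_summary(trace)
        assert summ.argmax_band == (4.0, 8.0)
        assert abs(summ.peak_frequency_hz - f0) <= 0.7  # 1.5 s window bins
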