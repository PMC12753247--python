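"""Generator contracts: determinism, template shape, preset orderings."""

from dataclasses import replace

import numpy as np
import pytest

from famosc import synthgen
from famosc.behavior import chamber_metrics, days_to_expert, training_score
from famosc.presets import (CON_LIKE, FX_LIKE, WT_LIKE, OscillationParams,
                            load_preset_registry)
from famosc.types import TrialLayout, ValidationError


class TestDeterminism:
    def test_lfp_session_bit_identical(self):
        a = synthgen.gen_lfp_session(WT_LIKE, seed=42)
        b = synthgen.gen_lfp_session(WT_LIKE, seed=42)
        np.testing.assert_array_equal(a.lfp, b.lfp)
        np.testing.assert_array_equal(a.trial_onsets, b.trial_onsets)

    def test_spike_session_bit_identical(self):
        a = synthgen.gen_spike_session(FX_LIKE, n_units=5, seed=42)
        b = synthgen.gen_spike_session(FX_LIKE, n_units=5, seed=42)
        for ta, tb in zip(a.spike_trains, b.spike_trains):
            np.testing.assert_array_equal(ta.times, tb.times)
            assert ta.trough_to_peak_ms == tb.trough_to_peak_ms

    def test_behavior_and_trajectory_bit_identical(self, geometry):
        a = synthgen.gen_behavior_sessions(CON_LIKE, n_sessions=3, seed=7)
        b = synthgen.gen_behavior_sessions(CON_LIKE, n_sessions=3, seed=7)
        for sa, sb in zip(a, b):
            assert sa == sb
        ta = synthgen.gen_trajectory(CON_LIKE, geometry, duration_s=10, seed=7)
        tb = synthgen.gen_trajectory(CON_LIKE, geometry, duration_s=10, seed=7)
        np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_different_seeds_differ(self):
        a = synthgen.gen_lfp_session(WT_LIKE, seed=1)
        b = synthgen.gen_lfp_session(WT_LIKE, seed=2)
        assert not np.array_equal(a.lfp, b.lfp)


class TestLfpTemplate:
    def test_noiseless_trace_has_exactly_n_cycles_maxima(self):
        preset = replace(WT_LIKE,
                         lfp=OscillationParams(6.0, 5, 100.0, 0.8,
                                               noise_sd=0.0))
        sess = synthgen.gen_lfp_session(preset, seed=0, n_channels=3)
        fs = sess.lfp_rate
        epoch = sess.lfp[0, :int(2.5 * fs)].astype(float)
        interior = np.flatnonzero((epoch[1:-1] > epoch[:-2])
                                  & (epoch[1:-1] > epoch[2:])) + 1
        post = interior[interior / fs > 0.5]
        assert post.size == 5

    def test_designated_channel_carries_largest_deflection(self):
        preset = replace(WT_LIKE, lfp=replace(WT_LIKE.lfp, noise_sd=0.0))
        sess = synthgen.gen_lfp_session(preset, seed=0, best_channel=7)
        stim_min = sess.lfp[:, :int(2.5 * sess.lfp_rate)].min(axis=1)
        assert np.argmin(stim_min) == 7

    def test_epoch_too_short_for_template_rejected(self):
        layout = TrialLayout(epoch_length=0.8)
        with pytest.raises(ValidationError, match="epoch too short"):
            synthgen.gen_lfp_session(WT_LIKE, layout, seed=0)

    def test_invalid_layout_names_violated_invariant(self):
        with pytest.raises(ValidationError, match="baseline must precede"):
            TrialLayout(baseline_window=(0.0, 0.6),
                        stimulus_window=(0.5, 0.7))


class TestSpikeGenerator:
    def test_thinning_preserves_mean_rates(self):
        """Time-rescaling sanity: empirical trial rate matches the integral
        of the generating intensity."""
        preset = replace(WT_LIKE, rate=OscillationParams(6.5, 5, 8.0, 0.8))
        layout = TrialLayout(epoch_length=1.3, n_trials=400)
        sess = synthgen.gen_spike_session(preset, layout, n_units=1, seed=3,
                                          baseline_jitter_sd=0.0)
        n_spikes = sess.spike_trains[0].times.size
        p = preset.rate
        # expected integral: baseline + transient + rectified decaying sine
        t = np.linspace(0, 1.3, 26001)
        d = t - 0.5
        osc = np.where((d >= 0) & (d <= p.n_cycles / p.osc_frequency),
                       p.peak_amplitude * np.exp(-d / p.decay_tau)
                       * np.sin(2 * np.pi * p.osc_frequency * d), 0.0)
        rate = np.maximum(10.0 + osc + 6.0 * ((d >= 0) & (d <= 0.2)), 0.0)
        expected = np.trapezoid(rate, t) * layout.n_trials
        assert n_spikes == pytest.approx(expected, rel=0.05)

    def test_zero_amplitude_expectation_rate_is_flat(self):
        """Null case: with no oscillation the expected rate has no
        post-stimulus peaks (detection on the expectation-level trace)."""
        from conftest import make_unit_response
        from famosc.units import detect_oscillation_peaks
        t = (np.arange(130) + 0.5) * 0.01
        d = t - 0.5
        ev = synthgen._evoked(d, 6.5, 0, 0.0, 0.8)  # amplitude 0, 0 cycles
        assert detect_oscillation_peaks(
            make_unit_response(ev)).n_peaks == 0

    def test_unit_metadata_ranges(self):
        sess = synthgen.gen_spike_session(WT_LIKE, n_units=100, seed=8)
        depths = np.array([t.depth_um for t in sess.spike_trains])
        widths = np.array([t.trough_to_peak_ms for t in sess.spike_trains])
        assert depths.min() >= 0 and depths.max() <= 950
        assert np.all(widths > 0)
        assert {True, False} == set(w < 0.45 for w in widths)  # both classes

    def test_n_units_validated(self):
        with pytest.raises(ValidationError, match="n_units"):
            synthgen.gen_spike_session(WT_LIKE, n_units=0, seed=0)


class TestBehaviorGenerator:
    def test_equal_hit_and_fa_probs_center_ts_on_zero(self):
        flat = [0.5] * 6
        sessions = synthgen.gen_behavior_sessions(
            WT_LIKE, n_sessions=6, trials_per_session=400, seed=3,
            hit_probs=flat, fa_probs=flat)
        scores = [training_score(s) for s in sessions]
        assert abs(np.mean(scores)) < 0.15

    def test_certain_hit_probability_touches_every_go_trial(self):
        sessions = synthgen.gen_behavior_sessions(
            WT_LIKE, n_sessions=1, trials_per_session=100, seed=0,
            hit_probs=[1.0], fa_probs=[0.0])
        s = sessions[0]
        hits = sum(t.trial_type == "Go" and t.touched for t in s.trials)
        assert hits == s.n_go == 50
        assert not any(t.trial_type == "NoGo" and t.touched for t in s.trials)

    def test_fast_learner_reaches_expert_before_flat_preset(self):
        flat = replace(FX_LIKE, hit_learning_rate=0.0, fa_learning_rate=0.0)
        wins = 0
        for seed in range(20):
            fast_days, _ = days_to_expert([
                training_score(s) for s in synthgen.gen_behavior_sessions(
                    WT_LIKE, n_sessions=12, seed=seed)])
            flat_scores = [training_score(s)
                           for s in synthgen.gen_behavior_sessions(
                               flat, n_sessions=12, seed=1000 + seed)]
            flat_days, censored = days_to_expert(flat_scores)
            wins += fast_days < flat_days + (1000 if censored else 0)
        assert wins >= 18  # >= 90% of seeds

    def test_median_latency_decreases_with_training(self):
        sessions = synthgen.gen_behavior_sessions(WT_LIKE, n_sessions=8,
                                                  trials_per_session=200,
                                                  seed=5)
        from famosc.behavior import response_times
        medians = [response_times(s)[1] for s in sessions]
        assert medians[-1] < medians[0]


class TestTrajectoryGenerator:
    def test_full_partner_preference_dwells_partner_side(self, geometry):
        p1 = replace(WT_LIKE, side_preference=1.0)
        track = synthgen.gen_trajectory(p1, geometry, duration_s=120, seed=2)
        m = chamber_metrics(track, geometry, zone_span_s=None)
        p = m["chamber_proportions"]
        assert p["partner"] > p["toy"]
        assert p["partner"] > 0.5

    def test_positions_confined_to_arena(self, geometry):
        track = synthgen.gen_trajectory(FX_LIKE, geometry, duration_s=60,
                                        seed=11)
        minx, miny, maxx, maxy = geometry.arena.bounds
        assert track.positions[:, 0].min() >= minx
        assert track.positions[:, 0].max() <= maxx
        assert track.positions[:, 1].min() >= miny
        assert track.positions[:, 1].max() <= maxy

    def test_scripted_override_bypasses_walk(self, geometry):
        pos = np.array([[30.0, 20.0]] * 10)
        track = synthgen.gen_trajectory(WT_LIKE, geometry, seed=0,
                                        scripted_positions=pos)
        np.testing.assert_array_equal(track.positions, pos)


class TestPresetRegistry:
    def test_default_orderings_mirror_phenotypes(self):
        assert (FX_LIKE.rate.osc_frequency < CON_LIKE.rate.osc_frequency
                <= WT_LIKE.rate.osc_frequency)
        assert FX_LIKE.rate.n_cycles < WT_LIKE.rate.n_cycles
        assert FX_LIKE.hit_learning_rate < WT_LIKE.hit_learning_rate
        assert FX_LIKE.intertrial_touch_rate > WT_LIKE.intertrial_touch_rate

    def test_toml_roundtrip(self, tmp_path):
        doc = """
[presets.custom]
tuning_concentration = 2.0
hit_learning_rate = 0.9
fa_learning_rate = 0.8
intertrial_touch_rate = 12.0
side_preference = 0.6
[presets.custom.lfp]
osc_frequency = 5.5
n_cycles = 3
peak_amplitude = 80.0
decay_tau = 0.5
[presets.custom.rate]
osc_frequency = 5.5
n_cycles = 3
peak_amplitude = 6.0
decay_tau = 0.5
"""
        path = tmp_path / "presets.toml"
        path.write_text(doc)
        reg = load_preset_registry(path)
        assert reg["custom"].lfp.osc_frequency == 5.5
        assert reg["custom"].side_preference == 0.6

    def test_toml_missing_field_named(self, tmp_path):
        path = tmp_path / "bad.toml"
        path.write_text("[presets.x]\nhit_learning_rate = 1.0\n"
                        "[presets.x.lfp]\nosc_frequency = 5.0\n")
        with pytest.raises(ValidationError, match="missing|incomplete"):
            load_preset_registry(path)
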