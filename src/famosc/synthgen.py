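"""Synthetic recordings, behavior logs and trajectories under genotype presets.

The generators emulate the statistical structure the analysis assumes —
stimulus-locked decaying theta-band oscillations in LFP and population
firing rates whose frequency/amplitude/cycle count differ by preset,
direction-tuned units with narrow/broad waveforms, logistic Go/No-Go
learning curves, and three-chamber random-walk trajectories with a
configurable side preference. Every generator is bit-reproducible under a
fixed seed.

Evoked template
---------------
``A · exp(−Δ/τ) · sin(2πfΔ)`` for Δ = t − onset in [0, n_cycles/f], zero
elsewhere; the LFP uses the sign-flipped template so the first deflection is
the VEP trough. The sine phase keeps the waveform continuous at onset (no
step for the smoothing/filtering stages to smear) and still produces exactly
``n_cycles`` local maxima after onset.

Tuning enters as a von Mises gain ``exp(κ(cos(θ−θ_pref)−1))`` applied to the
evoked (oscillation + transient) component in 12-direction protocols. In
single-direction familiar-stimulus protocols the gain is 1 for every unit:
those sessions model the population response to the familiarized stimulus,
which is what the oscillation pipeline consumes (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .behavior import CHAMBER_ORDER, ChamberGeometry
from .presets import GenotypePreset
from .types import (BehaviorSession, BehaviorTrial, RecordingSession,
                    SpikeTrain, TrajectoryRecord, TrialLayout,
                    ValidationError, _require)

FAMILIAR_DIRECTION_DEG = 60.0
#: Fraction of generated units given a narrow (FS-like) waveform.
FS_FRACTION = 0.15
#: Amplitude (Hz) of the tuned stimulus-window transient in the rate model.
STIMULUS_TRANSIENT_HZ = 6.0


def _evoked(delta: np.ndarray, f: float, n_cycles: int, amp: float,
            tau: float) -> np.ndarray:
    """Decaying sine evoked template evaluated at Δ = t − onset (vectorized)."""
    out = amp * np.exp(-delta / tau) * np.sin(2 * np.pi * f * delta)
    live = (delta >= 0) & (delta <= n_cycles / f if f > 0 else False)
    return np.where(live, out, 0.0)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                fs: float) -> np.ndarray:
    """Unit-variance 1/f-power noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spec *= scale
    pink = np.fft.irfft(spec, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    return pink / np.where(sd > 0, sd, 1.0)


def _trial_directions(layout: TrialLayout,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-trial direction labels: the familiar direction when the layout
    names none, otherwise ``n_trials`` of each listed direction in a
    pseudorandom order."""
    if not layout.directions:
        return np.full(layout.n_trials, FAMILIAR_DIRECTION_DEG)
    dirs = np.repeat(np.asarray(layout.directions, float), layout.n_trials)
    rng.shuffle(dirs)
    return dirs


def gen_lfp_session(preset: GenotypePreset,
                    layout: TrialLayout | None = None,
                    seed: int = 0, n_channels: int = 16,
                    best_channel: int | None = None,
                    pink_fraction: float = 0.0) -> RecordingSession:
    """Multichannel LFP session with one designated strongest channel.

    Per-trial, per-channel traces are the evoked decaying sine (parameters
    from ``preset.lfp``, μV) scaled by a depth profile that peaks at
    ``best_channel`` (default: the channel nearest 400 μm, i.e. layer 4),
    plus additive Gaussian noise (``pink_fraction`` of the noise SD can be
    1/f-shaped). The LFP is generated at ``layout.sampling_rate_lfp`` and is
    meant to be fed through :func:`famosc.lfp.preprocess_lfp`.
    """
    from .types import PROBE_DEPTH_UM

    layout = layout or TrialLayout(epoch_length=2.5)
    _require(layout.stimulus_window[0] + preset.lfp.span_s
             <= layout.epoch_length + 1e-9,
             f"epoch too short for {preset.lfp.n_cycles} cycles at "
             f"{preset.lfp.osc_frequency:g} Hz")
    rng = np.random.default_rng(seed)
    fs = layout.sampling_rate_lfp
    n_epoch = int(round(layout.epoch_length * fs))
    n_total = n_epoch * layout.n_trials
    depths = np.linspace(0, PROBE_DEPTH_UM, n_channels)
    if best_channel is None:
        best_channel = int(np.argmin(np.abs(depths - 400.0)))
    # smooth depth profile of the evoked response, maximum at best_channel
    gain = 0.2 + 0.8 * np.exp(-0.5 * ((np.arange(n_channels) - best_channel)
                                      / (n_channels / 5)) ** 2)
    gain[best_channel] = 1.0

    t_epoch = np.arange(n_epoch) / fs
    evoked = _evoked(t_epoch - layout.onset_in_epoch,
                     preset.lfp.osc_frequency, preset.lfp.n_cycles,
                     preset.lfp.peak_amplitude, preset.lfp.decay_tau)
    lfp = np.tile(-evoked, layout.n_trials)[None, :] * gain[:, None]
    if preset.lfp.noise_sd > 0:
        w = np.sqrt(1.0 - pink_fraction)
        noise = w * rng.standard_normal((n_channels, n_total))
        if pink_fraction > 0:
            noise += np.sqrt(pink_fraction) * _pink_noise(
                rng, (n_channels, n_total), fs)
        lfp = lfp + preset.lfp.noise_sd * noise
    onsets = (np.arange(layout.n_trials) * layout.epoch_length
              + layout.onset_in_epoch)
    return RecordingSession(
        layout=layout, trial_onsets=onsets,
        trial_directions=_trial_directions(layout, rng),
        lfp=lfp.astype(np.float32), lfp_rate=fs, channel_depths_um=depths,
        group=preset.label)


def gen_spike_session(preset: GenotypePreset,
                      layout: TrialLayout | None = None,
                      n_units: int = 30, seed: int = 0,
                      baseline_jitter_sd: float = 0.2,
                      stimulus_transient_hz: float = STIMULUS_TRANSIENT_HZ,
                      ) -> RecordingSession:
    """Spiking session: inhomogeneous-Poisson units with tuned evoked rates.

    Each unit's instantaneous rate is ``b_u + g_u(θ)·(osc(Δ) + transient(Δ))``
    clipped at 0 (documented contract), where ``b_u`` is a log-normally
    jittered baseline around the preset's mean rate, ``osc`` the decaying
    sine with the preset's rate parameters (Hz), ``transient`` a
    ``stimulus_transient_hz`` boxcar over the 200 ms stimulus, and ``g_u``
    the von Mises direction gain (1 in single-direction protocols). Spikes
    are drawn by thinning a homogeneous Poisson process, so mean rates are
    oracle-checkable. Units carry a narrow (FS-like) or broad (RS-like)
    trough-to-peak width and a uniform depth over the probe span.
    """
    from .types import PROBE_DEPTH_UM

    _require(n_units >= 1, "n_units must be >= 1")
    layout = layout or TrialLayout(epoch_length=1.3)
    rng = np.random.default_rng(seed)
    p = preset.rate
    tuned_protocol = bool(layout.directions)

    directions = _trial_directions(layout, rng)
    n_trials = directions.size
    onsets = (np.arange(n_trials) * layout.epoch_length
              + layout.onset_in_epoch)
    trial_starts = onsets - layout.onset_in_epoch

    base = preset.baseline_rate_hz * np.exp(
        baseline_jitter_sd * rng.standard_normal(n_units)
        - baseline_jitter_sd ** 2 / 2)
    pref = rng.choice(np.arange(0.0, 360.0, 30.0), size=n_units)
    is_fs = rng.random(n_units) < FS_FRACTION
    t2p = np.where(is_fs,
                   np.clip(rng.normal(0.27, 0.04, n_units), 0.1, 0.40),
                   np.clip(rng.normal(0.75, 0.10, n_units), 0.50, 1.20))
    depth = rng.uniform(0.0, PROBE_DEPTH_UM, n_units)

    evoked_max = p.peak_amplitude + stimulus_transient_hz
    lam_max = base + evoked_max  # per-unit thinning envelope
    T = layout.epoch_length
    kappa = preset.tuning_concentration

    trains: list[SpikeTrain] = []
    theta = np.deg2rad(directions)
    for u in range(n_units):
        n_cand = rng.poisson(lam_max[u] * T, size=n_trials)
        total = int(n_cand.sum())
        tt = rng.uniform(0.0, T, size=total)  # epoch-clock candidate times
        trial_idx = np.repeat(np.arange(n_trials), n_cand)
        if tuned_protocol:
            g = np.exp(kappa * (np.cos(theta[trial_idx]
                                       - np.deg2rad(pref[u])) - 1.0))
        else:
            g = 1.0
        delta = tt - layout.onset_in_epoch
        ev = _evoked(delta, p.osc_frequency, p.n_cycles, p.peak_amplitude,
                     p.decay_tau)
        ev = ev + stimulus_transient_hz * ((delta >= 0.0) & (delta <= 0.2))
        rate = np.maximum(base[u] + g * ev, 0.0)
        keep = rng.uniform(0.0, lam_max[u], size=total) < rate
        times = np.sort(tt[keep] + trial_starts[trial_idx[keep]])
        trains.append(SpikeTrain(
            unit_id=f"u{u:04d}", times=times,
            trough_to_peak_ms=float(t2p[u]), depth_um=float(depth[u])))
    return RecordingSession(
        layout=layout, trial_onsets=onsets, trial_directions=directions,
        spike_trains=trains, group=preset.label)


def gen_behavior_sessions(preset: GenotypePreset, n_sessions: int = 14,
                          trials_per_session: int = 60, seed: int = 0,
                          hit_probs: list[float] | None = None,
                          fa_probs: list[float] | None = None,
                          ) -> list[BehaviorSession]:
    """Go/No-Go training days with logistic-in-session learning curves.

    Hit probability rises as ``0.5 + 0.45·expit(k_hit·s − 3)`` and the
    false-alarm probability falls as ``0.5 − 0.45·expit(k_fa·s − 3)`` with
    the preset's learning-rate slopes (``hit_probs``/``fa_probs`` override
    both curves for scripted scenarios). Trials split evenly Go/No-Go in a
    shuffled order; touches are Bernoulli per trial, Go-touch latencies
    log-normal around a median that decays with training, and inter-trial
    touches Poisson with the preset's rate.
    """
    from scipy.special import expit

    _require(n_sessions >= 1 and trials_per_session >= 2,
             "need >= 1 session and >= 2 trials per session")
    if hit_probs is not None:
        _require(len(hit_probs) == n_sessions, "one hit prob per session")
    if fa_probs is not None:
        _require(len(fa_probs) == n_sessions, "one FA prob per session")
    rng = np.random.default_rng(seed)
    n_go = trials_per_session // 2
    n_nogo = trials_per_session - n_go
    sessions: list[BehaviorSession] = []
    for s in range(1, n_sessions + 1):
        hp = (hit_probs[s - 1] if hit_probs is not None
              else 0.5 + 0.45 * expit(preset.hit_learning_rate * s - 3.0))
        fp = (fa_probs[s - 1] if fa_probs is not None
              else 0.5 - 0.45 * expit(preset.fa_learning_rate * s - 3.0))
        median_lat = 0.5 + 2.5 * np.exp(
            -0.4 * preset.hit_learning_rate * (s - 1))
        types = np.array(["Go"] * n_go + ["NoGo"] * n_nogo)
        rng.shuffle(types)
        trials: list[BehaviorTrial] = []
        for tt in types:
            p_touch = hp if tt == "Go" else fp
            touched = bool(rng.random() < p_touch)
            lat = None
            if touched:
                lat = float(rng.lognormal(np.log(median_lat), 0.4))
            trials.append(BehaviorTrial(str(tt), touched, lat))
        sessions.append(BehaviorSession(
            session_day=s, trials=trials,
            intertrial_touches=int(rng.poisson(preset.intertrial_touch_rate))))
    return sessions


def gen_trajectory(preset: GenotypePreset, geometry: ChamberGeometry,
                   duration_s: float = 600.0, fps: float = 30.0,
                   seed: int = 0, bias_strength: float = 0.5,
                   scripted_positions: np.ndarray | None = None,
                   ) -> TrajectoryRecord:
    """Biased random walk over the three-chamber arena.

    The walk moves in visit bouts: at each bout the mouse draws a target
    cage — partner with probability ``side_preference``, toy otherwise —
    and takes Gaussian steps of SD = arena width / 100 per frame with a
    drift of ``bias_strength`` step-SDs toward the target; the target is
    redrawn with a small per-frame hazard (mean bout ≈ 7 s), producing
    alternating chamber visits whose dwell ratio tracks the preference.
    Reflecting boundaries keep the walk inside the arena.
    ``scripted_positions`` bypasses the walk entirely (hand-checkable
    fixtures) while still validating the record.
    """
    _require(fps > 0, "fps must be > 0")
    if geometry.arena.area <= 0:
        raise ValidationError("zero-area chamber geometry rejected")
    if scripted_positions is not None:
        return TrajectoryRecord(fps=fps,
                                positions=np.asarray(scripted_positions, float))
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = geometry.arena.bounds
    width = maxx - minx
    step_sd = width / 100.0
    n = int(round(duration_s * fps))
    p_partner = preset.side_preference
    targets = {name: np.asarray(geometry.cages[name][0], float)
               for name in ("toy", "partner")}
    switch_hazard = 1.0 / (7.0 * fps)  # mean bout length ~7 s
    pos = np.empty((n, 2))
    cur = np.array([(minx + maxx) / 2.0, (miny + maxy) / 2.0])
    steps = rng.standard_normal((n, 2)) * step_sd
    switches = rng.random(n) < switch_hazard
    choices = rng.random(n)
    target = targets["partner" if choices[0] < p_partner else "toy"]
    for i in range(n):
        if switches[i]:
            target = targets["partner" if choices[i] < p_partner else "toy"]
        d = target - cur
        dist = np.hypot(*d)
        drift = (bias_strength * step_sd / dist) * d if dist > 1e-9 else 0.0
        cur = cur + steps[i] + drift
        # reflect off the rectangular bounds
        for k, (lo, hi) in enumerate(((minx, maxx), (miny, maxy))):
            if cur[k] < lo:
                cur[k] = lo + (lo - cur[k])
            if cur[k] > hi:
                cur[k] = hi - (cur[k] - hi)
            cur[k] = float(np.clip(cur[k], lo, hi))
        pos[i] = cur
    return TrajectoryRecord(fps=fps, positions=pos)
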