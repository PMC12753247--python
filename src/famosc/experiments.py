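"""Reusable simulation studies: parameter recovery, preset-ordering checks,
tuning sweeps, learning-curve comparisons and dispatch calibration.

Each study generates data with :mod:`famosc.synthgen`, runs the relevant
pipeline stage end to end, and returns a plain dict of summary numbers. The
analysis drivers, the test suite and ``scripts/acceptance.py`` all call
these functions, so reported numbers always come from the same code path.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import behavior as bhv
from . import lfp as lfp_mod
from . import synthgen
from . import tuning as tuning_mod
from . import units as units_mod
from .presets import FX_LIKE, WT_LIKE, GenotypePreset, recovery_preset
from .stats import GroupSample, compare_groups
from .types import DEFAULT_SPIKE_LAYOUT, TrialLayout


def _session_population_features(session) -> "units_mod.OscillationFeatures":
    responses = units_mod.session_unit_responses(session)
    pop = units_mod.population_zscore(responses)
    feats = units_mod.detect_oscillation_peaks(pop)
    return units_mod.oscillation_dynamics(feats)


def oscillation_recovery(freqs_hz=(4.0, 5.0, 6.0, 7.0), cycle_counts=(2, 3, 5),
                         n_seeds: int = 100, n_units: int = 60,
                         seed: int = 0,
                         freq_tol_hz: float = 0.5, cycle_tol: int = 1) -> dict:
    """Recover (frequency, cycle count) from high-SNR synthetic spiking.

    Two design choices isolate the estimand. The epoch is sized so the
    post-stimulus window exactly spans the oscillation (0.5 s baseline +
    n_cycles/f): the estimate then measures the pipeline, not the silent
    tail. And the boxcar stimulus transient is disabled: its falling edge
    (0.2 s after onset) superposes with oscillation peaks that happen to
    fall near it and drags them off their true times, which would measure
    the interference rather than the oscillation. Population z traces over
    ``n_units`` units at 20 trials are fed through detection + dynamics.
    """
    rows = []
    run = 0
    for f in freqs_hz:
        for c in cycle_counts:
            layout = TrialLayout(epoch_length=0.5 + c / f)
            preset = recovery_preset(f, c)
            for s in range(n_seeds):
                sess = synthgen.gen_spike_session(
                    preset, layout, n_units=n_units, seed=seed + 7919 * run,
                    stimulus_transient_hz=0.0)
                feats = _session_population_features(sess)
                rows.append({
                    "f_true": f, "c_true": c, "seed": s,
                    "f_est": feats.frequency_hz, "n_peaks": feats.n_peaks,
                    "duration_s": feats.duration_s})
                run += 1
    f_ok = [abs(r["f_est"] - r["f_true"]) <= freq_tol_hz
            if np.isfinite(r["f_est"]) else False for r in rows]
    c_ok = [abs(r["n_peaks"] - r["c_true"]) <= cycle_tol for r in rows]
    both = [a and b for a, b in zip(f_ok, c_ok)]
    return {
        "rows": rows,
        "n_runs": len(rows),
        "freq_recovery_rate": float(np.mean(f_ok)),
        "cycle_recovery_rate": float(np.mean(c_ok)),
        "joint_recovery_rate": float(np.mean(both)),
        "freq_abs_err_mean": float(np.nanmean(
            [abs(r["f_est"] - r["f_true"]) for r in rows])),
    }


def genotype_ordering_study(n_seeds: int = 100, n_units: int = 600,
                            seed: int = 0,
                            preset_hi: GenotypePreset = WT_LIKE,
                            preset_lo: GenotypePreset = FX_LIKE) -> dict:
    """Pooled-population oscillation metrics under two presets, per seed.

    Checks that cycle count, duration and frequency all order
    ``preset_hi > preset_lo`` (the WT-like over FX-like contrast), seed by
    seed, at the pooled-unit scale where the 0.1-z threshold is selective.
    """
    agree = {"n_peaks": [], "duration": [], "frequency": [], "all": []}
    per_preset = {preset_hi.label: [], preset_lo.label: []}
    for s in range(n_seeds):
        feats = {}
        for k, preset in enumerate((preset_hi, preset_lo)):
            sess = synthgen.gen_spike_session(
                preset, DEFAULT_SPIKE_LAYOUT, n_units=n_units,
                seed=seed + 2 * s + k)
            feats[preset.label] = _session_population_features(sess)
            per_preset[preset.label].append(feats[preset.label])
        hi, lo = feats[preset_hi.label], feats[preset_lo.label]
        ok_n = hi.n_peaks > lo.n_peaks
        ok_d = hi.duration_s > lo.duration_s
        ok_f = (np.isfinite(hi.frequency_hz) and np.isfinite(lo.frequency_hz)
                and hi.frequency_hz > lo.frequency_hz)
        agree["n_peaks"].append(ok_n)
        agree["duration"].append(ok_d)
        agree["frequency"].append(ok_f)
        agree["all"].append(ok_n and ok_d and ok_f)
    out = {f"ordering_rate_{k}": float(np.mean(v)) for k, v in agree.items()}
    for label, fs in per_preset.items():
        out[f"mean_n_peaks_{label}"] = float(np.mean([f.n_peaks for f in fs]))
        out[f"mean_duration_{label}"] = float(
            np.mean([f.duration_s for f in fs]))
        out[f"mean_frequency_{label}"] = float(
            np.nanmean([f.frequency_hz for f in fs]))
    out["n_seeds"] = n_seeds
    return out


def lfp_band_ordering(n_seeds: int = 10, seed: int = 0,
                      preset_hi: GenotypePreset = WT_LIKE,
                      preset_lo: GenotypePreset = FX_LIKE) -> dict:
    """Full LFP pipeline on both presets: preprocess at the source rate,
    select the strongest channel, band-power summary. Verifies the argmax
    band is theta (4–8 Hz) for both and theta power orders hi > lo."""
    argmax_theta, power_ordered = [], []
    theta = (4.0, 8.0)
    for s in range(n_seeds):
        powers = {}
        for k, preset in enumerate((preset_hi, preset_lo)):
            sess = synthgen.gen_lfp_session(preset, seed=seed + 2 * s + k)
            clean = lfp_mod.preprocess_lfp(sess.lfp, sess.lfp_rate)
            sess2 = replace_lfp(sess, clean, 1000.0)
            trace, _chan = lfp_mod.select_channel_and_average(sess2)
            summ = lfp_mod.band_power_summary(trace)
            powers[preset.label] = summ
        argmax_theta.append(
            powers[preset_hi.label].argmax_band == theta
            and powers[preset_lo.label].argmax_band == theta)
        power_ordered.append(
            powers[preset_hi.label].band_power[theta]
            > powers[preset_lo.label].band_power[theta])
    return {"argmax_theta_rate": float(np.mean(argmax_theta)),
            "theta_power_ordered_rate": float(np.mean(power_ordered)),
            "n_seeds": n_seeds}


def replace_lfp(session, new_lfp, new_rate):
    """Copy of a recording session with a preprocessed LFP block."""
    from dataclasses import replace as dc_replace
    return dc_replace(session, lfp=new_lfp, lfp_rate=new_rate)


def dsi_concentration_sweep(kappas=(0.0, 1.0, 4.0), n_units: int = 100,
                            n_trials_per_direction: int = 20,
                            seed: int = 0) -> dict:
    """Mean DSI as a function of the von Mises tuning concentration κ.

    All units with a defined DSI enter the mean (the sweep isolates the DSI
    statistic; the direction-preference inclusion rule is studied
    separately).
    """
    layout = TrialLayout(epoch_length=1.3,
                         n_trials=n_trials_per_direction,
                         directions=tuple(float(d) for d in range(0, 360, 30)))
    means = {}
    for i, kappa in enumerate(kappas):
        preset = replace(WT_LIKE, tuning_concentration=float(kappa))
        sess = synthgen.gen_spike_session(preset, layout, n_units=n_units,
                                          seed=seed + i)
        results = tuning_mod.session_tuning(sess)
        summ = tuning_mod.tuning_summary({"all": results},
                                         responsive_only=False)
        means[float(kappa)] = summ["all"]["mean_dsi"]
    ks = sorted(means)
    return {"mean_dsi_by_kappa": means,
            "strictly_increasing": bool(
                all(means[a] < means[b] for a, b in zip(ks, ks[1:])))}


def behavior_learning_study(n_seeds: int = 100, seed: int = 0,
                            fast: GenotypePreset = WT_LIKE,
                            slow: GenotypePreset = FX_LIKE,
                            n_sessions: int = 14) -> dict:
    """Days-to-expert and inter-trial-touch orderings across seeds.

    ``fast`` should reach TS ≥ 2 on an earlier day than ``slow``; ``slow``
    (FX-like) should log more inter-trial touches. A censored
    days-to-expert (threshold never reached) counts as later than any
    reached day.
    """
    fewer_days, more_touches = [], []
    days = {fast.label: [], slow.label: []}
    for s in range(n_seeds):
        per = {}
        for k, preset in enumerate((fast, slow)):
            sessions = synthgen.gen_behavior_sessions(
                preset, n_sessions=n_sessions, seed=seed + 2 * s + k)
            scores = [bhv.training_score(x) for x in sessions]
            day, censored = bhv.days_to_expert(scores)
            touches = sum(bhv.intertrial_activity(sessions).values())
            per[preset.label] = (day + (1000 if censored else 0), touches)
            days[preset.label].append(day if not censored else np.nan)
        fewer_days.append(per[fast.label][0] < per[slow.label][0])
        more_touches.append(per[slow.label][1] > per[fast.label][1])
    return {
        "fewer_days_rate": float(np.mean(fewer_days)),
        "more_touches_rate": float(np.mean(more_touches)),
        "mean_days_fast": float(np.nanmean(days[fast.label])),
        "mean_days_slow": float(np.nanmean(days[slow.label])),
        "n_seeds": n_seeds,
    }


def dispatch_calibration(n_sims: int = 1000, n: int = 50,
                         seed: int = 0) -> dict:
    """Fraction of Normal/Normal sample pairs routed to the parametric path.

    With independent Shapiro-Wilk gates at α each sample passes with
    probability 1 − α, so the expected parametric rate is (1 − α)² ≈ 0.9025.
    """
    rng = np.random.default_rng(seed)
    parametric = 0
    for _ in range(n_sims):
        a = GroupSample("a", rng.standard_normal(n))
        b = GroupSample("b", rng.standard_normal(n))
        res = compare_groups(a, b)
        parametric += res.test == "anova+tukey"
    return {"parametric_rate": parametric / n_sims, "expected": 0.9025,
            "n_sims": n_sims}


def social_preference_study(n_seeds: int = 20, duration_s: float = 600.0,
                            seed: int = 0,
                            preset: GenotypePreset = WT_LIKE) -> dict:
    """Partner-over-toy chamber preference of the biased walk across seeds."""
    geom = bhv.ChamberGeometry.three_box()
    partner_gt_toy = []
    partner_prop = []
    for s in range(n_seeds):
        track = synthgen.gen_trajectory(preset, geom, duration_s=duration_s,
                                        seed=seed + s)
        m = bhv.chamber_metrics(track, geom, zone_span_s=60.0)
        p = m["chamber_proportions"]
        partner_gt_toy.append(p["partner"] > p["toy"])
        partner_prop.append(p["partner"])
    return {"partner_gt_toy_rate": float(np.mean(partner_gt_toy)),
            "mean_partner_proportion": float(np.mean(partner_prop)),
            "n_seeds": n_seeds}
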