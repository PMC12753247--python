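"""Z-scored PSTHs, oscillation dynamics, FS/RS classification and layers.

The PSTH convention throughout: 10 ms bins over the epoch, trial-averaged
rate in Hz, smoothed with a 30 ms standard-deviation Gaussian kernel
(sampled kernel truncated at ±4σ and renormalized, reflection at the edges),
then z-scored against the mean/SD of the 0–0.5 s baseline of the *smoothed*
trace. Peak detection uses a minimum height of 0.1 z-units and a minimum
separation of 100 ms; when two candidates violate the spacing the higher is
kept (earlier on ties).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .types import (OscillationFeatures, RecordingSession, SpikeTrain,
                    TrialLayout, UnitResponse, ValidationError, _require)

PSTH_BIN_S = 0.010
PSTH_SMOOTH_SIGMA_S = 0.030
PEAK_MIN_HEIGHT_Z = 0.1
PEAK_MIN_SEPARATION_S = 0.100
ACTIVITY_THRESHOLD_Z = 2.0
FS_RS_THRESHOLD_MS = 0.45

#: Cortical layer boundaries (μm): a depth d belongs to the deepest layer
#: whose lower edge is <= d (boundary values belong to the deeper layer).
LAYER_BOUNDARIES_UM: tuple[tuple[str, float, float], ...] = (
    ("L1", 0.0, 100.0), ("L2/3", 100.0, 350.0), ("L4", 350.0, 450.0),
    ("L5", 450.0, 700.0), ("L6", 700.0, 950.0))


def epoch_spike_times(times: np.ndarray, onsets: np.ndarray,
                      layout: TrialLayout) -> list[np.ndarray]:
    """Split session-clock spike times into per-trial epoch-clock arrays."""
    out = []
    for onset in np.asarray(onsets, dtype=float):
        start = onset - layout.onset_in_epoch
        sel = times[(times >= start) & (times < start + layout.epoch_length)]
        out.append(sel - start)
    return out


def _bin_counts(trial_spikes: list[np.ndarray], layout: TrialLayout,
                bin_s: float) -> np.ndarray:
    n_bins = int(round(layout.epoch_length / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    pooled = (np.concatenate(trial_spikes) if trial_spikes
              else np.empty(0))
    return np.histogram(pooled, bins=edges)[0].astype(float)


def compute_psth_zscore(trial_spikes: list[np.ndarray], layout: TrialLayout,
                        unit_id: str = "unit",
                        trough_to_peak_ms: float = float("nan"),
                        depth_um: float = float("nan"),
                        bin_s: float = PSTH_BIN_S,
                        smooth_sigma_s: float = PSTH_SMOOTH_SIGMA_S,
                        ) -> UnitResponse:
    """Trial-averaged, smoothed, baseline-z-scored PSTH of one unit.

    ``trial_spikes`` holds epoch-clock spike times per trial. A unit whose
    smoothed baseline is constant (SD = 0, e.g. a silent baseline) cannot be
    z-scored; it is returned with ``valid=False`` and a zero trace rather
    than dividing by zero, and is excluded from downstream averages.
    """
    _require(len(trial_spikes) >= 1, "at least one trial required")
    counts = _bin_counts(trial_spikes, layout, bin_s)
    rate = counts / (len(trial_spikes) * bin_s)  # Hz
    smoothed = gaussian_filter1d(rate, sigma=smooth_sigma_s / bin_s,
                                 mode="reflect", truncate=4.0)
    centers = (np.arange(smoothed.size) + 0.5) * bin_s
    b0, b1 = layout.baseline_window
    base = smoothed[(centers >= b0) & (centers < b1)]
    mu, sd = float(base.mean()), float(base.std())
    if sd == 0.0:
        return UnitResponse(unit_id, centers, np.zeros_like(smoothed), mu, sd,
                            trough_to_peak_ms, depth_um, valid=False)
    z = (smoothed - mu) / sd
    return UnitResponse(unit_id, centers, z, mu, sd,
                        trough_to_peak_ms, depth_um, valid=True)


def unit_response(train: SpikeTrain, session: RecordingSession,
                  layout: TrialLayout | None = None,
                  direction_deg: float | None = None) -> UnitResponse:
    """PSTH z-score of one sorted unit, optionally restricted to trials of a
    single stimulus direction."""
    layout = layout or session.layout
    onsets = session.trial_onsets
    if direction_deg is not None:
        onsets = onsets[session.trial_directions == direction_deg]
        _require(onsets.size >= 1, f"no trials at direction {direction_deg}°")
    resp = compute_psth_zscore(
        epoch_spike_times(train.times, onsets, layout), layout,
        unit_id=train.unit_id, trough_to_peak_ms=train.trough_to_peak_ms,
        depth_um=train.depth_um)
    resp.cell_class = classify_fs_rs(train.trough_to_peak_ms)
    resp.layer = assign_layer(train.depth_um)
    return resp


def session_unit_responses(session: RecordingSession,
                           layout: TrialLayout | None = None
                           ) -> list[UnitResponse]:
    """PSTH z-scores for every sorted unit of a session."""
    return [unit_response(tr, session, layout) for tr in session.spike_trains]


def population_zscore(responses: list[UnitResponse]) -> UnitResponse:
    """Across-unit average of valid z traces (the population line plot).

    Averaging N independent unit traces shrinks baseline noise by ~1/sqrt(N)
    while the stimulus-locked oscillation survives, which is what makes the
    fixed 0.1-z peak threshold selective on pooled traces.
    """
    valid = [r for r in responses if r.valid]
    _require(len(valid) >= 1, "no valid unit responses to average")
    z = np.mean([r.zscore for r in valid], axis=0)
    return UnitResponse("population", valid[0].bin_centers.copy(), z,
                        float("nan"), float("nan"), valid=True)


def detect_oscillation_peaks(resp: UnitResponse,
                             search_window: tuple[float, float] | None = None,
                             min_height: float = PEAK_MIN_HEIGHT_Z,
                             min_separation_s: float = PEAK_MIN_SEPARATION_S,
                             ) -> OscillationFeatures:
    """Oscillation peaks of a z trace under the height/separation rules.

    Candidates are strict local maxima of the full trace (so a peak sitting
    exactly at the window edge is still seen in its neighborhood) whose time
    falls inside ``search_window`` (default: stimulus onset at 0.5 s to the
    end of the epoch) and whose height is at least ``min_height`` z-units.
    Candidates are then accepted greedily in order of decreasing height
    (earlier first on exact ties); a candidate closer than
    ``min_separation_s`` to any accepted peak is discarded. An empty result
    is valid.
    """
    z, t = resp.zscore, resp.bin_centers
    if search_window is None:
        search_window = (0.5, float(t[-1]) + PSTH_BIN_S)
    interior = np.flatnonzero((z[1:-1] > z[:-2]) & (z[1:-1] > z[2:])) + 1
    cand = [i for i in interior
            if search_window[0] <= t[i] <= search_window[1]
            and z[i] >= min_height]
    order = sorted(cand, key=lambda i: (-z[i], t[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(t[i] - t[j]) >= min_separation_s for j in kept):
            kept.append(i)
    kept.sort()
    return OscillationFeatures(peak_times=t[kept], n_peaks=len(kept))


def oscillation_dynamics(features: OscillationFeatures,
                         frequency_from: str = "mean") -> OscillationFeatures:
    """Fill in duration and frequency from detected peak times.

    duration = last − first peak time; frequency = 1 / mean successive
    inter-peak interval (``frequency_from="median"`` for the robust variant).
    With fewer than two peaks the duration is 0 and the frequency flagged
    NaN.
    """
    pt = features.peak_times
    if pt.size < 2:
        return OscillationFeatures(pt, features.n_peaks, duration_s=0.0,
                                   frequency_hz=float("nan"))
    gaps = np.diff(pt)
    agg = np.median if frequency_from == "median" else np.mean
    return OscillationFeatures(pt, features.n_peaks,
                               duration_s=float(pt[-1] - pt[0]),
                               frequency_hz=float(1.0 / agg(gaps)))


def classify_fs_rs(trough_to_peak_ms: float,
                   threshold_ms: float = FS_RS_THRESHOLD_MS) -> str:
    """Putative fast-spiking vs regular-spiking from waveform width.

    Narrow waveforms (trough-to-peak below the threshold, default 0.45 ms)
    are FS; broader ones RS. Non-positive or non-finite widths are
    unclassified.
    """
    if not np.isfinite(trough_to_peak_ms) or trough_to_peak_ms <= 0:
        return "unclassified"
    return "FS" if trough_to_peak_ms < threshold_ms else "RS"


def assign_layer(depth_um: float,
                 boundaries: tuple[tuple[str, float, float], ...]
                 = LAYER_BOUNDARIES_UM) -> str:
    """Cortical layer lookup; a boundary depth belongs to the deeper layer."""
    if not np.isfinite(depth_um):
        return ""
    lo = boundaries[0][1]
    hi = boundaries[-1][2]
    if not (lo <= depth_um <= hi):
        raise ValidationError(f"depth {depth_um} μm outside [{lo}, {hi}]")
    for name, a, b in reversed(boundaries):
        if depth_um >= a:
            return name
    raise AssertionError("unreachable")


def stimulus_max_z(resp: UnitResponse,
                   stimulus_window: tuple[float, float] = (0.5, 0.7)) -> float:
    """Maximum z within the stimulus window (the activity statistic)."""
    m = ((resp.bin_centers >= stimulus_window[0])
         & (resp.bin_centers <= stimulus_window[1]))
    return float(resp.zscore[m].max())


def active_unit_fraction(responses: list[UnitResponse],
                         cell_class: str | None = None,
                         threshold_z: float = ACTIVITY_THRESHOLD_Z,
                         stimulus_window: tuple[float, float] = (0.5, 0.7),
                         ) -> float:
    """Fraction of (optionally class-filtered) valid units whose
    stimulus-window max z reaches the activity threshold.

    An empty class is undefined and raises :class:`ValidationError`.
    """
    pool = [r for r in responses if r.valid
            and (cell_class is None or r.cell_class == cell_class)]
    if not pool:
        raise ValidationError(
            f"no valid units of class {cell_class!r} to assess")
    n_active = sum(stimulus_max_z(r, stimulus_window) >= threshold_z
                   for r in pool)
    return n_active / len(pool)


def qc_report(responses: list[UnitResponse]) -> dict:
    """Machine-readable exclusion report for a set of unit responses."""
    excluded = [r.unit_id for r in responses if not r.valid]
    return {
        "n_units": len(responses),
        "n_valid": len(responses) - len(excluded),
        "excluded": sorted(excluded),
        "exclusion_reason": "zero baseline SD (silent or constant baseline)",
    }
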