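"""Direction tuning: preferred direction, realigned curves and the DSI.

Responses are the stimulus-window (0.5–0.7 s) maximum z per direction,
computed from direction-restricted PSTHs. DSI = (R_pref − R_ortho) /
(R_pref + R_ortho) with R_ortho the mean response of the two directions at
±90° from preferred (a single-sided variant is available); negative z
responses are floored at 0 by default so the DSI stays in [−1, 1].
"""

from __future__ import annotations

import numpy as np

from .types import (DIRECTIONS_DEG, RecordingSession, TrialLayout,
                    TuningResult, ValidationError, _require)
from .units import ACTIVITY_THRESHOLD_Z, stimulus_max_z, unit_response


def preferred_direction(responses: np.ndarray,
                        directions_deg: np.ndarray | None = None,
                        ) -> tuple[float, np.ndarray]:
    """Argmax direction and the curve cyclically rotated so it sits at 0°.

    Ties break toward the smallest angle. Non-finite responses are rejected.
    """
    responses = np.asarray(responses, dtype=float)
    if directions_deg is None:
        directions_deg = np.asarray(DIRECTIONS_DEG, dtype=float)
    _require(responses.shape == directions_deg.shape,
             "one response per direction required")
    if not np.all(np.isfinite(responses)):
        raise ValidationError("non-finite entries in the response vector")
    k = int(np.argmax(responses))  # argmax returns the first (smallest angle)
    return float(directions_deg[k]), np.roll(responses, -k)


def dsi(responses: np.ndarray, preferred_deg: float,
        directions_deg: np.ndarray | None = None,
        ortho: str = "both", floor_at_zero: bool = True) -> float:
    """Direction selectivity index (R_pref − R_ortho)/(R_pref + R_ortho).

    ``ortho="both"`` (default) averages the two directions at ±90° from
    preferred; ``"plus"``/``"minus"`` use a single side. A zero denominator
    is undefined: NaN is returned and the unit excluded from DSI averages.
    """
    responses = np.asarray(responses, dtype=float)
    if directions_deg is None:
        directions_deg = np.asarray(DIRECTIONS_DEG, dtype=float)
    if floor_at_zero:
        responses = np.maximum(responses, 0.0)
    lookup = {d % 360.0: r for d, r in zip(directions_deg, responses)}
    r_pref = lookup[preferred_deg % 360.0]
    o_plus = lookup[(preferred_deg + 90.0) % 360.0]
    o_minus = lookup[(preferred_deg - 90.0) % 360.0]
    r_ortho = {"both": (o_plus + o_minus) / 2.0,
               "plus": o_plus, "minus": o_minus}[ortho]
    denom = r_pref + r_ortho
    if denom == 0.0:
        return float("nan")
    return float((r_pref - r_ortho) / denom)


def unit_tuning(train, session: RecordingSession,
                layout: TrialLayout | None = None,
                stimulus_window: tuple[float, float] = (0.5, 0.7),
                activity_threshold_z: float = ACTIVITY_THRESHOLD_Z,
                **dsi_kwargs) -> TuningResult:
    """Full tuning result for one unit of a 12-direction session.

    A unit "shows direction preference" (``responsive=True``) when its
    stimulus-window max z at the preferred direction reaches the activity
    threshold; only such units enter group DSI averages.
    """
    layout = layout or session.layout
    dirs = np.asarray(sorted(set(session.trial_directions.tolist())))
    _require(dirs.size == 12, f"expected 12 directions, got {dirs.size}")
    resp = np.empty(dirs.size)
    for i, d in enumerate(dirs):
        r = unit_response(train, session, layout, direction_deg=float(d))
        resp[i] = stimulus_max_z(r, stimulus_window) if r.valid else np.nan
    if not np.all(np.isfinite(resp)):
        raise ValidationError(
            f"unit {train.unit_id}: unscorable response at some direction")
    pref, curve = preferred_direction(resp, dirs)
    value = dsi(resp, pref, dirs, **dsi_kwargs)
    return TuningResult(
        unit_id=train.unit_id, directions_deg=dirs, responses=resp,
        preferred_direction_deg=pref, realigned_curve=curve, dsi=value,
        responsive=bool(resp[int(np.argmax(resp))] >= activity_threshold_z))


def session_tuning(session: RecordingSession,
                   layout: TrialLayout | None = None,
                   **kwargs) -> list[TuningResult]:
    return [unit_tuning(tr, session, layout, **kwargs)
            for tr in session.spike_trains]


def tuning_summary(groups: dict[str, list[TuningResult]],
                   responsive_only: bool = True) -> dict[str, dict]:
    """Per-group mean realigned curve and the DSI sample for statistics.

    Only units with a defined DSI (non-NaN denominator) and — by default —
    passing the direction-preference criterion enter the DSI sample. Empty
    groups are omitted with a warning entry rather than raising.
    """
    out: dict[str, dict] = {}
    for label, results in groups.items():
        pool = [r for r in results
                if np.isfinite(r.dsi) and (r.responsive or not responsive_only)]
        if not pool:
            out[label] = {"warning": "no units with a defined DSI", "n": 0}
            continue
        out[label] = {
            "n": len(pool),
            "mean_realigned_curve": np.mean(
                [r.realigned_curve for r in pool], axis=0),
            "dsi_values": np.array([r.dsi for r in pool]),
            "mean_dsi": float(np.mean([r.dsi for r in pool])),
        }
    return out
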