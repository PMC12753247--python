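"""Go/No-Go touchscreen scoring and three-chamber social-preference metrics.

Training score (TS) is the signal-detection d′: probit(hit rate) −
probit(false-alarm rate), with rates clamped to [1/(2n), 1 − 1/(2n)] so the
quantile stays finite (standard log-linear correction; the underlying task
defines no rule for perfect sessions). TS ≥ 2 defines "expert".

Chamber metrics come from a single tracked body point tested against the
three chamber polygons (inclusive edges, fixed claim order toy → middle →
partner) and against circular interaction zones around the two cages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy.stats import norm
from shapely.geometry import Polygon

from .types import (BehaviorSession, TrajectoryRecord, ValidationError,
                    _require)

EXPERT_TS = 2.0
CHAMBER_ORDER = ("toy", "middle", "partner")
#: Interaction-zone radius as a multiple of the cage radius.
ZONE_RADIUS_FACTOR = 1.5


@dataclass
class ChamberGeometry:
    """Three-chamber apparatus: arena bounds, chamber polygons, cage circles.

    ``chambers`` maps each name in :data:`CHAMBER_ORDER` to a shapely
    polygon; the polygons must be disjoint (interiors) and jointly cover the
    arena. ``cages`` maps ``toy``/``partner`` to (center_xy, radius); the
    interaction zone of a cage is a concentric circle of radius
    ``ZONE_RADIUS_FACTOR ×`` the cage radius.
    """

    arena: Polygon
    chambers: dict[str, Polygon]
    cages: dict[str, tuple[tuple[float, float], float]]

    def __post_init__(self) -> None:
        _require(self.arena.area > 0, "zero-area arena rejected")
        _require(set(self.chambers) == set(CHAMBER_ORDER),
                 f"chambers must be exactly {CHAMBER_ORDER}")
        for name, poly in self.chambers.items():
            _require(poly.area > 0, f"zero-area chamber {name!r} rejected")
        names = list(CHAMBER_ORDER)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = self.chambers[a].intersection(self.chambers[b]).area
                _require(inter < 1e-9 * self.arena.area,
                         f"chambers {a!r} and {b!r} overlap")
        union = shapely.union_all(list(self.chambers.values()))
        _require(union.area >= 0.999 * self.arena.area,
                 "chambers must cover the arena")
        for name, (c, r) in self.cages.items():
            _require(r > 0, f"cage {name!r} must have positive radius")
            _require(self.chambers[name].contains(shapely.Point(c)),
                     f"cage {name!r} center outside its chamber")

    def zone_radius(self, cage: str) -> float:
        return ZONE_RADIUS_FACTOR * self.cages[cage][1]

    @classmethod
    def three_box(cls, width: float = 60.0, height: float = 40.0,
                  cage_radius: float = 4.0) -> "ChamberGeometry":
        """Standard rectangular apparatus: three equal chambers side by side,
        cages centered in the left (toy) and right (partner) chambers.
        Units: cm."""
        w3 = width / 3.0
        boxes = {
            "toy": Polygon([(0, 0), (w3, 0), (w3, height), (0, height)]),
            "middle": Polygon([(w3, 0), (2 * w3, 0), (2 * w3, height),
                               (w3, height)]),
            "partner": Polygon([(2 * w3, 0), (width, 0), (width, height),
                                (2 * w3, height)]),
        }
        arena = Polygon([(0, 0), (width, 0), (width, height), (0, height)])
        cages = {"toy": ((w3 / 2, height / 2), cage_radius),
                 "partner": ((width - w3 / 2, height / 2), cage_radius)}
        return cls(arena, boxes, cages)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "arena": list(self.arena.exterior.coords),
            "chambers": {k: list(v.exterior.coords)
                         for k, v in self.chambers.items()},
            "cages": {k: {"center": list(c), "radius": r}
                      for k, (c, r) in self.cages.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChamberGeometry":
        doc = json.loads(Path(path).read_text())
        try:
            return cls(
                arena=Polygon(doc["arena"]),
                chambers={k: Polygon(v) for k, v in doc["chambers"].items()},
                cages={k: (tuple(v["center"]), float(v["radius"]))
                       for k, v in doc["cages"].items()},
            )
        except KeyError as exc:
            raise ValidationError(f"{path}: missing geometry field {exc}")


def _clamped_rate(k: int, n: int) -> float:
    _require(n >= 1, "at least one trial of each type required")
    return float(np.clip(k / n, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))


def ts_from_rates(hit_rate: float, fa_rate: float) -> float:
    """TS from already-clamped rates: Φ⁻¹(H) − Φ⁻¹(FA)."""
    _require(0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0,
             "rates must lie strictly inside (0, 1); clamp first")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def training_score(session: BehaviorSession) -> float:
    """Signal-detection training score of one session.

    H = hits/n_go and FA = false alarms/n_nogo, each clamped to
    [1/(2n), 1 − 1/(2n)] for its own trial count; TS = probit(H) −
    probit(FA). Sessions missing either trial type are undefined.
    """
    hits = sum(t.trial_type == "Go" and t.touched for t in session.trials)
    fas = sum(t.trial_type == "NoGo" and t.touched for t in session.trials)
    if session.n_go == 0 or session.n_nogo == 0:
        raise ValidationError(
            f"day {session.session_day}: TS undefined without both Go and "
            "No-Go trials")
    return ts_from_rates(_clamped_rate(hits, session.n_go),
                         _clamped_rate(fas, session.n_nogo))


def days_to_expert(scores: list[float],
                   threshold: float = EXPERT_TS) -> tuple[int, bool]:
    """First day (1-based) with TS ≥ threshold.

    Returns ``(day, censored)``; when the threshold is never reached the
    last day is recorded with ``censored=True``.
    """
    _require(len(scores) >= 1, "at least one day of scores required")
    for i, s in enumerate(scores, start=1):
        if s >= threshold:
            return i, False
    return len(scores), True


def response_times(session: BehaviorSession) -> tuple[np.ndarray, float]:
    """Latencies of touched Go trials and their median.

    No-Go touches never contribute. A session with no touched Go trials has
    an undefined median (NaN, flagged by the empty latency array).
    """
    lat = np.array([t.latency_s for t in session.trials
                    if t.trial_type == "Go" and t.touched], dtype=float)
    if np.any(lat < 0):
        raise ValidationError("negative latency in trial log")
    median = float(np.median(lat)) if lat.size else float("nan")
    return lat, median


def intertrial_activity(sessions: list[BehaviorSession]) -> dict[int, int]:
    """Per-day total inter-trial touch count (the hyperactivity metric)."""
    out: dict[int, int] = {}
    for s in sessions:
        out[s.session_day] = out.get(s.session_day, 0) + s.intertrial_touches
    return out


def _chamber_membership(track: TrajectoryRecord,
                        geom: ChamberGeometry) -> np.ndarray:
    """Per-frame chamber index into CHAMBER_ORDER (first claim wins on
    boundaries), −1 for frames outside every chamber."""
    x, y = track.positions[:, 0], track.positions[:, 1]
    member = np.full(x.size, -1, dtype=int)
    for k in range(len(CHAMBER_ORDER) - 1, -1, -1):
        inside = shapely.intersects_xy(geom.chambers[CHAMBER_ORDER[k]], x, y)
        member[inside] = k  # earlier names overwrite later -> first claim
    return member


def chamber_metrics(track: TrajectoryRecord, geom: ChamberGeometry,
                    span_s: float | None = None,
                    zone_span_s: float | None = 60.0) -> dict:
    """Dwell proportions, interaction-zone dwell and chamber entry counts.

    ``span_s`` bounds the chamber-proportion analysis (default: the full
    track, matching the 10 min convention when the track is 10 min long);
    ``zone_span_s`` bounds zone dwell *and* entry counting (default 60 s,
    the first minute of the test). Dwell is frames-in-region / frames-in-span;
    an entry is a frame transition from outside a chamber to inside it.
    Positions outside the arena are rejected with the offending frames.
    """
    x, y = track.positions[:, 0], track.positions[:, 1]
    valid = np.isfinite(x) & np.isfinite(y)  # NaN frames = excluded gaps
    outside = valid & ~shapely.intersects_xy(geom.arena, x, y)
    if outside.any():
        frames = np.flatnonzero(outside)[:20].tolist()
        raise ValidationError(f"positions outside the arena at frames {frames}")
    n_frames = track.positions.shape[0]
    if span_s is None:
        span_s = n_frames / track.fps
    for name, s in (("span_s", span_s), ("zone_span_s", zone_span_s)):
        if s is not None and s > n_frames / track.fps + 0.5 / track.fps:
            raise ValidationError(
                f"{name}={s} s exceeds the recorded {n_frames / track.fps:g} s")

    member = _chamber_membership(track, geom)
    n_span = min(int(round(span_s * track.fps)), n_frames)
    n_span_valid = max(int(valid[:n_span].sum()), 1)
    prop = {name: float(np.sum(member[:n_span] == k)) / n_span_valid
            for k, name in enumerate(CHAMBER_ORDER)}

    n_zone = (min(int(round(zone_span_s * track.fps)), n_frames)
              if zone_span_s is not None else n_frames)
    n_zone_valid = max(int(valid[:n_zone].sum()), 1)
    zone_dwell: dict[str, float] = {}
    for cage, (center, _r) in geom.cages.items():
        d2 = ((x[:n_zone] - center[0]) ** 2 + (y[:n_zone] - center[1]) ** 2)
        zone_dwell[cage] = float(
            np.sum(d2[valid[:n_zone]] <= geom.zone_radius(cage) ** 2)
        ) / n_zone_valid

    entries: dict[str, int] = {}
    mz = member[:n_zone]
    for k, name in enumerate(CHAMBER_ORDER):
        inside = mz == k
        entries[name] = int(np.sum(inside[1:] & ~inside[:-1]))
    return {"chamber_proportions": prop, "zone_dwell": zone_dwell,
            "entries": entries, "span_s": span_s, "zone_span_s": zone_span_s}


def fill_tracking_gaps(positions: np.ndarray, max_gap: int = 2) -> np.ndarray:
    """Linearly interpolate NaN gaps of at most ``max_gap`` frames.

    Longer gaps stay NaN (their frames are excluded from dwell denominators
    by the caller); leading/trailing NaNs are never filled.
    """
    out = positions.astype(float).copy()
    bad = np.isnan(out).any(axis=1)
    i = 0
    n = out.shape[0]
    while i < n:
        if not bad[i]:
            i += 1
            continue
        j = i
        while j < n and bad[j]:
            j += 1
        if 0 < i and j < n and (j - i) <= max_gap:
            for k in range(i, j):
                w = (k - (i - 1)) / (j - (i - 1))
                out[k] = (1 - w) * out[i - 1] + w * out[j]
        i = j
    return out
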