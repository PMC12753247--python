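"""Core domain containers shared across the pipeline.

All containers are plain dataclasses with eager invariant checks: analysis
operations may assume any object they receive is internally consistent
(sorted spike times, depths within the probe span, windows inside the epoch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Probe insertion depth in μm; unit/channel depths must lie in [0, PROBE_DEPTH_UM].
PROBE_DEPTH_UM = 950.0

#: The 12 drifting-grating directions, degrees, in 30° increments.
DIRECTIONS_DEG = tuple(range(0, 360, 30))


class ValidationError(ValueError):
    """An object violated one of its declared invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class TrialLayout:
    """Timing of one trial epoch and the session's trial structure.

    The epoch clock starts 0.5 s before stimulus onset: baseline occupies
    [0, 0.5) s, the 200 ms stimulus [0.5, 0.7] s, and the post-stimulus
    analysis window runs from onset to ``epoch_length``.
    """

    epoch_length: float = 1.3
    baseline_window: tuple[float, float] = (0.0, 0.5)
    stimulus_window: tuple[float, float] = (0.5, 0.7)
    n_trials: int = 20
    sampling_rate_lfp: float = 2000.0
    directions: tuple[float, ...] = ()  # empty -> single familiar direction (60°)

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        s0, s1 = self.stimulus_window
        _require(0.0 <= b0 < b1, "baseline_window must be a non-empty interval")
        _require(b1 <= s0 < s1, "baseline must precede the stimulus window")
        _require(s1 <= self.epoch_length, "stimulus window must lie within the epoch")
        _require(self.n_trials >= 1, "n_trials must be >= 1")
        _require(self.sampling_rate_lfp > 0, "sampling_rate_lfp must be > 0")
        for d in self.directions:
            _require(
                d in DIRECTIONS_DEG,
                f"direction {d}° not in 30° grid {DIRECTIONS_DEG}",
            )

    @property
    def onset_in_epoch(self) -> float:
        """Stimulus onset time on the epoch clock (s)."""
        return self.stimulus_window[0]

    @property
    def post_window(self) -> tuple[float, float]:
        """Default post-stimulus analysis window: onset to epoch end."""
        return (self.stimulus_window[0], self.epoch_length)


# Layout used for LFP sessions: long enough for the 0.5–2.0 s spectral window.
DEFAULT_LFP_LAYOUT = TrialLayout(epoch_length=2.5)
# Layout used for spiking sessions: post-stimulus window sized to the evoked
# oscillation (see docs/methods.md on the silent-tail trade-off).
DEFAULT_SPIKE_LAYOUT = TrialLayout(epoch_length=1.3)


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit plus its waveform/depth metadata."""

    unit_id: str
    times: np.ndarray  # seconds on the session clock, sorted, non-negative
    trough_to_peak_ms: float
    depth_um: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        _require(self.times.ndim == 1, f"unit {self.unit_id}: spike times must be 1-D")
        if self.times.size:
            _require(
                float(self.times.min()) >= 0.0,
                f"unit {self.unit_id}: negative spike times",
            )
            _require(
                bool(np.all(np.diff(self.times) >= 0)),
                f"unit {self.unit_id}: spike times not sorted",
            )
        _require(
            0.0 <= self.depth_um <= PROBE_DEPTH_UM,
            f"unit {self.unit_id}: depth {self.depth_um} μm outside [0, {PROBE_DEPTH_UM}]",
        )


@dataclass
class RecordingSession:
    """Trial-aligned recording from one animal/condition.

    Either (or both) of the LFP block and the spike trains may be present.
    ``trial_onsets`` are stimulus-onset times on the session clock; the epoch
    of trial *i* spans ``trial_onsets[i] - 0.5`` to ``+ epoch_length - 0.5``.
    """

    layout: TrialLayout
    trial_onsets: np.ndarray  # seconds, strictly increasing
    trial_directions: np.ndarray  # degrees, one per trial
    lfp: Optional[np.ndarray] = None  # channels × samples, μV
    lfp_rate: Optional[float] = None  # Hz
    channel_depths_um: Optional[np.ndarray] = None
    spike_trains: list[SpikeTrain] = field(default_factory=list)
    animal_id: str = "synthetic"
    condition: str = "post"  # {pre, post}
    group: str = "WT-like"

    def __post_init__(self) -> None:
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        self.trial_directions = np.asarray(self.trial_directions, dtype=float)
        _require(self.trial_onsets.ndim == 1 and self.trial_onsets.size >= 1,
                 "at least one trial onset required")
        _require(bool(np.all(np.diff(self.trial_onsets) > 0)),
                 "trial_onsets must be strictly increasing")
        _require(self.trial_directions.shape == self.trial_onsets.shape,
                 "one direction label per trial required")
        if self.lfp is not None:
            self.lfp = np.asarray(self.lfp, dtype=np.float32)
            _require(self.lfp.ndim == 2, "lfp must be channels × samples")
            _require(self.lfp_rate is not None and self.lfp_rate > 0,
                     "lfp_rate required alongside lfp")
            if self.channel_depths_um is not None:
                self.channel_depths_um = np.asarray(self.channel_depths_um, float)
                _require(self.channel_depths_um.size == self.lfp.shape[0],
                         "one depth per LFP channel required")
                _require(bool(np.all((self.channel_depths_um >= 0)
                                     & (self.channel_depths_um <= PROBE_DEPTH_UM))),
                         f"channel depths must lie in [0, {PROBE_DEPTH_UM}] μm")

    @property
    def n_trials(self) -> int:
        return int(self.trial_onsets.size)


@dataclass
class UnitResponse:
    """Per-unit z-scored PSTH with waveform metadata.

    ``zscore`` is the trial-averaged, Gaussian-smoothed firing rate in 10 ms
    bins, standardized by the mean/SD of the 0–0.5 s baseline of the smoothed
    trace. ``valid`` is False when the baseline SD is zero (silent baseline);
    such units are excluded downstream and counted in QC reports.
    """

    unit_id: str
    bin_centers: np.ndarray  # seconds on the epoch clock
    zscore: np.ndarray  # z-units, same length as bin_centers
    baseline_mean_hz: float
    baseline_sd_hz: float
    trough_to_peak_ms: float = float("nan")
    depth_um: float = float("nan")
    cell_class: str = "unclassified"  # {FS, RS, unclassified}
    layer: str = ""  # {L1, L2/3, L4, L5, L6}
    valid: bool = True


@dataclass
class OscillationFeatures:
    """Detected oscillation peaks and the cycle-count/duration/frequency trio.

    ``frequency_hz`` is NaN (flagged) when fewer than two peaks were found.
    """

    peak_times: np.ndarray  # seconds, sorted, pairwise gaps >= min separation
    n_peaks: int
    duration_s: float = 0.0
    frequency_hz: float = float("nan")

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        _require(self.n_peaks == self.peak_times.size,
                 "n_peaks must equal the number of peak times")
        if self.peak_times.size > 1:
            _require(bool(np.all(np.diff(self.peak_times) > 0)),
                     "peak_times must be strictly increasing")


@dataclass
class TuningResult:
    """12-direction response vector and the direction-selectivity summary."""

    unit_id: str
    directions_deg: np.ndarray
    responses: np.ndarray  # stimulus-window max z per direction
    preferred_direction_deg: float
    realigned_curve: np.ndarray  # cyclic rotation with preferred at index 0
    dsi: float  # NaN when undefined (zero denominator)
    responsive: bool = True  # passes the activity threshold at preferred dir


@dataclass
class BehaviorTrial:
    trial_type: str  # {Go, NoGo}
    touched: bool
    latency_s: Optional[float] = None  # present only when touched

    def __post_init__(self) -> None:
        _require(self.trial_type in ("Go", "NoGo"),
                 f"unknown trial type {self.trial_type!r}")
        if self.touched:
            _require(self.latency_s is not None and self.latency_s >= 0,
                     "touched trials must carry a non-negative latency")
        else:
            _require(self.latency_s is None, "latency present on an untouched trial")


@dataclass
class BehaviorSession:
    """One day of Go/No-Go touchscreen training."""

    session_day: int  # 1-based
    trials: list[BehaviorTrial]
    intertrial_touches: int = 0

    def __post_init__(self) -> None:
        _require(self.intertrial_touches >= 0, "intertrial_touches must be >= 0")

    @property
    def n_go(self) -> int:
        return sum(t.trial_type == "Go" for t in self.trials)

    @property
    def n_nogo(self) -> int:
        return sum(t.trial_type == "NoGo" for t in self.trials)


@dataclass
class TrajectoryRecord:
    """Pose track of the tested mouse (single tracked body point)."""

    fps: float
    positions: np.ndarray  # frames × 2 (x, y), arena coordinates (cm)

    def __post_init__(self) -> None:
        _require(self.fps > 0, "fps must be > 0")
        self.positions = np.asarray(self.positions, dtype=float)
        _require(self.positions.ndim == 2 and self.positions.shape[1] == 2,
                 "positions must be frames × 2")

    @property
    def duration_s(self) -> float:
        return self.positions.shape[0] / self.fps
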