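"""Genotype-like parameter presets for the synthetic-data generator.

The presets encode the *qualitative orderings* observed across wild-type
(WT-like), Fmr1-knockout (FX-like) and PV-restricted-rescue (CON-like)
phenotypes — FX-like oscillates slower, with fewer cycles and lower
amplitude, learns the Go/No-Go task more slowly and touches the screen more
between trials; CON-like sits between the two. Every numeric magnitude here
is an invented default (the source recordings are not public), chosen so the
generated data are realistic for mouse V1 and documented in docs/methods.md.

A registry can also be loaded from a TOML file; see ``load_preset_registry``.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

from .types import ValidationError, _require


@dataclass(frozen=True)
class OscillationParams:
    """Decaying-sinusoid template for the evoked oscillation.

    The evoked waveform is ``A · exp(−Δ/decay_tau) · sin(2πf·Δ)`` for
    Δ = t − onset within [0, n_cycles/f] (sign-flipped for LFP so the first
    deflection is the VEP trough). Amplitude units are μV for LFP templates
    and Hz (firing-rate modulation) for rate templates; ``noise_sd`` shares
    the amplitude's units.
    """

    osc_frequency: float  # Hz
    n_cycles: int
    peak_amplitude: float  # μV (LFP) or Hz (rate)
    decay_tau: float  # seconds
    onset_time: float = 0.5  # seconds from epoch start
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        _require(self.osc_frequency > 0, "osc_frequency must be > 0")
        _require(self.n_cycles >= 0, "n_cycles must be >= 0")
        _require(self.decay_tau > 0, "decay_tau must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")

    @property
    def span_s(self) -> float:
        """Duration of the truncated oscillation (s)."""
        return self.n_cycles / self.osc_frequency


@dataclass(frozen=True)
class GenotypePreset:
    """All generator knobs for one genotype-like condition."""

    label: str
    lfp: OscillationParams
    rate: OscillationParams
    tuning_concentration: float  # von Mises κ, dimensionless >= 0
    hit_learning_rate: float  # per-session logistic slope
    fa_learning_rate: float  # per-session logistic slope
    intertrial_touch_rate: float  # expected touches per session (Poisson)
    side_preference: float  # P(attraction toward the partner side), [0, 1]
    baseline_rate_hz: float = 10.0  # mean spontaneous unit firing rate

    def __post_init__(self) -> None:
        _require(0.0 <= self.side_preference <= 1.0,
                 "side_preference must lie in [0, 1]")
        _require(self.tuning_concentration >= 0,
                 "tuning_concentration must be >= 0")
        _require(self.intertrial_touch_rate >= 0,
                 "intertrial_touch_rate must be >= 0")
        _require(self.baseline_rate_hz > 0, "baseline_rate_hz must be > 0")


WT_LIKE = GenotypePreset(
    label="WT-like",
    lfp=OscillationParams(6.5, 5, 120.0, 0.8, noise_sd=25.0),
    rate=OscillationParams(6.5, 5, 8.0, 0.8),
    tuning_concentration=4.0,
    hit_learning_rate=1.0,
    fa_learning_rate=1.0,
    intertrial_touch_rate=15.0,
    side_preference=0.70,
)

FX_LIKE = GenotypePreset(
    label="FX-like",
    lfp=OscillationParams(4.5, 2, 60.0, 0.4, noise_sd=25.0),
    rate=OscillationParams(4.5, 2, 5.0, 0.4),
    tuning_concentration=1.0,
    hit_learning_rate=0.4,
    fa_learning_rate=0.4,
    intertrial_touch_rate=60.0,
    side_preference=0.50,
)

CON_LIKE = GenotypePreset(
    label="CON-like",
    lfp=OscillationParams(6.0, 4, 90.0, 0.6, noise_sd=25.0),
    rate=OscillationParams(6.0, 4, 7.0, 0.6),
    tuning_concentration=3.0,
    hit_learning_rate=0.7,
    fa_learning_rate=0.7,
    intertrial_touch_rate=25.0,
    side_preference=0.65,
)

DEFAULT_REGISTRY: dict[str, GenotypePreset] = {
    p.label: p for p in (WT_LIKE, FX_LIKE, CON_LIKE)
}


def recovery_preset(frequency_hz: float, n_cycles: int,
                    amplitude_hz: float = 10.0,
                    decay_tau_s: float = 1.0) -> GenotypePreset:
    """High-SNR single-cell preset for parameter-recovery experiments.

    Large rate-modulation amplitude and slow decay so every cycle clears the
    detection threshold; all behavioral fields are inert placeholders.
    """
    osc = OscillationParams(frequency_hz, n_cycles, amplitude_hz, decay_tau_s)
    return replace(
        WT_LIKE,
        label=f"recovery-{frequency_hz:g}Hz-{n_cycles}cyc",
        lfp=OscillationParams(frequency_hz, n_cycles, 120.0, decay_tau_s,
                              noise_sd=0.0),
        rate=osc,
    )


_OSC_FIELDS = ("osc_frequency", "n_cycles", "peak_amplitude", "decay_tau",
               "onset_time", "noise_sd")


def load_preset_registry(path: str | Path) -> dict[str, GenotypePreset]:
    """Load a preset registry from a TOML file.

    Layout: one ``[presets.<label>]`` table per preset with scalar fields and
    nested ``lfp``/``rate`` tables carrying the oscillation parameters.
    Labels must be unique (enforced by the TOML table structure) and each
    table complete; missing fields raise :class:`ValidationError`.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    tables = doc.get("presets")
    if not isinstance(tables, dict) or not tables:
        raise ValidationError(f"{path}: no [presets.*] tables found")
    registry: dict[str, GenotypePreset] = {}
    for label, tab in tables.items():
        try:
            lfp = OscillationParams(**{k: tab["lfp"][k] for k in _OSC_FIELDS
                                       if k in tab["lfp"]})
            rate = OscillationParams(**{k: tab["rate"][k] for k in _OSC_FIELDS
                                        if k in tab["rate"]})
            registry[label] = GenotypePreset(
                label=label,
                lfp=lfp,
                rate=rate,
                tuning_concentration=float(tab["tuning_concentration"]),
                hit_learning_rate=float(tab["hit_learning_rate"]),
                fa_learning_rate=float(tab["fa_learning_rate"]),
                intertrial_touch_rate=float(tab["intertrial_touch_rate"]),
                side_preference=float(tab["side_preference"]),
                baseline_rate_hz=float(tab.get("baseline_rate_hz", 10.0)),
            )
        except KeyError as exc:
            raise ValidationError(
                f"{path}: preset {label!r} missing field {exc}") from exc
        except TypeError as exc:
            raise ValidationError(
                f"{path}: preset {label!r} incomplete oscillation table "
                f"({exc})") from exc
    return registry


def expected_zscore_amplitude(preset: GenotypePreset, n_trials: int,
                              bin_s: float = 0.010,
                              smooth_sigma_s: float = 0.030) -> float:
    """Expected z-units of the first rate-oscillation peak after the PSTH
    pipeline (10 ms bins, 30 ms Gaussian smoothing, baseline z-scoring).

    Used in docs and tests to translate the Hz-amplitude convention into the
    z-units the analysis sees: the Gaussian kernel attenuates a sinusoid at
    frequency f by exp(−(2πfσ)²/2), and the per-unit baseline noise SD of the
    smoothed trace is ≈ sqrt(r·binwidth·n_trials)/(n_trials·binwidth) scaled
    by the kernel's variance-reduction factor.
    """
    f = preset.rate.osc_frequency
    atten = math.exp(-0.5 * (2 * math.pi * f * smooth_sigma_s) ** 2)
    sigma_bins = smooth_sigma_s / bin_s
    var_reduction = 1.0 / (2 * sigma_bins * math.sqrt(math.pi))
    rate_sd = math.sqrt(preset.baseline_rate_hz / (bin_s * n_trials))
    baseline_sd = rate_sd * math.sqrt(var_reduction)
    return preset.rate.peak_amplitude * atten / baseline_sd
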