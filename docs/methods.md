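# Methods

This note records the models, conventions and numerical choices behind
`famosc`, and what the synthetic-data experiments do and do not establish.

## Scope and data model

The package quantifies visual-familiarity-evoked theta oscillations in
mouse V1 and the behavioral phenotypes that accompany them, across three
genotype-like groups: wild-type (WT), Fmr1-knockout (FX, the Fragile X
model), and a conditional rescue with FMRP restored in PV+ interneurons
(CON). The original recordings are not publicly deposited, so every stage
is exercised against a synthetic generator that reproduces the *structure*
of the data — not its magnitudes, which are free parameters.

All trial-aligned analyses share one epoch clock: baseline 0–0.5 s, 200 ms
drifting-grating stimulus at 0.5–0.7 s, post-stimulus analysis window from
onset to the end of the epoch. Spiking epochs default to 1.3 s and LFP
epochs to 2.5 s (so the 0.5–2.0 s spectral window fits); the reasoning for
the short spiking epoch is under *Silent-tail trade-off* below.

## LFP pipeline

Raw multichannel LFP (≥ 2 kHz) is low-passed at 300 Hz (Butterworth order
4), decimated to 1 kHz, and notch-filtered at 60 Hz (IIR, Q = 30). All
filtering is forward-backward (zero-phase) so evoked-potential latencies
never shift; the filter family and orders are conventional defaults and are
exposed as arguments.

The analysis channel is the one whose trial-averaged trace has the most
negative deflection in the stimulus window, ties broken toward the lowest
channel index. Visually evoked potential (VEP) amplitudes are max − min
within per-cycle windows. Cycle windows are derived automatically from the
averaged trace: local minima with prominence ≥ 20 % of the trace's
peak-to-peak range (below that, averaged-trace noise ripple masquerades as
troughs), anchored on the deepest trough inside the stimulus window — the
same extremum that drives channel selection — with width equal to the
median inter-trough interval, clipped at midpoints, capped at the expected
cycle count. Fewer troughs than expected produce fewer windows plus a
warning flag rather than an error.

Spectral summaries: Morlet wavelet transform (6-cycle wavelets, log-spaced
grid whose slowest wavelet fits the trace; delegated to MNE-Python's
`tfr_array_morlet`) with per-frequency baseline dB normalization for maps,
and a Hann-tapered one-sided periodogram (density scaling) for band power.
"Band power" is the maximum density at any bin inside 4–8, 8–12, 12–30, or
30–40 Hz. The analysis window defaults to 0.5–2.0 s; the 0.7–2.0 s variant
used in some figure conventions is supported by passing `window=(0.7, 2.0)`
— both are documented because the two conventions appear side by side in
the literature this package serves, and no interpolation between them is
attempted.

## Spiking pipeline

Per-unit PSTHs use 10 ms bins, trial-averaged rates in Hz, smoothed with a
30 ms-SD Gaussian kernel (sampled, truncated at ±4σ, renormalized,
reflection at the edges), then z-scored by the mean/SD of the 0–0.5 s
baseline of the *smoothed* trace. Units with zero baseline SD cannot be
z-scored; they are flagged, excluded from averages, and counted in the QC
report.

Oscillation peaks are strict local maxima of the z trace with height
≥ 0.1 z and pairwise separation ≥ 100 ms, accepted greedily by decreasing
height (earlier first on exact ties). Candidate maxima are found on the
full trace and then restricted to the search window so a peak at the window
edge keeps its true neighborhood. Cycle count is the number of accepted
peaks, duration is last − first peak time (the simplest defensible
definition; adding one period was considered and rejected), and frequency
is the reciprocal mean inter-peak interval, with a median-based variant
exposed for robustness against a single spurious late peak.

The 0.1-z threshold is only selective on *pooled* traces: any single unit's
z trace has baseline noise SD ≈ 1 by construction, so population analyses
average the valid unit z traces first (noise shrinks as 1/√N) and detect
peaks on that average.

FS/RS classification thresholds the waveform trough-to-peak width at
0.45 ms (narrow = putative fast-spiking); layers use a standard mouse-V1
depth table (L1 0–100, L2/3 100–350, L4 350–450, L5 450–700, L6 700–950 μm,
boundary depths belonging to the deeper layer); a unit is "active" when its
stimulus-window max z reaches 2.0. All three rules are package choices —
the field uses no single standard — and all are configurable.

## Direction tuning

Responses are stimulus-window max z per direction over the 12 directions in
30° steps. The preferred direction is the argmax (ties toward the smallest
angle); curves are realigned cyclically with preferred at 0°. DSI =
(R_pref − R_ortho)/(R_pref + R_ortho) with R_ortho the mean of the two
directions at ±90° (single-sided variants available) and responses floored
at zero so the index stays in [−1, 1]. Units enter group DSI averages only
when the preferred-direction response reaches the 2.0-z activity threshold
and the denominator is non-zero.

## Behavior

Training score is the signal-detection d′: TS = Φ⁻¹(H) − Φ⁻¹(FA), with the
hit and false-alarm rates clamped to [1/(2n), 1 − 1/(2n)] per trial type
(the standard log-linear correction for perfect sessions; the probit is the
natural reading of "inverse cumulative distribution" in the d′ tradition).
Expert = first day with TS ≥ 2 (inclusive); never reaching it yields a
censored flag with the last day. Response times use touched Go trials only.
Inter-trial touches sum per day as the hyperactivity metric.

Three-chamber metrics test the single tracked body point against chamber
polygons with inclusive edges and a fixed claim order (toy, middle,
partner). Chamber time proportions default to the full 10 min span;
interaction-zone dwell and entry counts to the first 60 s, following the
convention that early-test behavior best reflects social novelty. Zones are
circles of 1.5× the cage radius ("small area" has no standard size; the
factor is a config knob). Dwell is frames-in-region / valid frames; NaN
tracking gaps of ≤ 2 frames are linearly filled, longer gaps excluded from
denominators.

## Statistics

Every two-group contrast runs through one dispatch rule: Shapiro-Wilk on
each sample at α = 0.05; both normal → parametric path (ANOVA F; for VEP
amplitudes a two-way group × cycle ANOVA with Tukey-HSD per cycle),
otherwise two-sided Mann-Whitney U. Sample shapes are compared with the
two-sample KS test, paired designs with the Wilcoxon signed-rank (zero
differences dropped). Rank tests use exact p-values up to n = 25 without
ties, asymptotic with continuity correction beyond. No multiple-testing
correction is applied beyond Tukey within the ANOVA, matching the
single-contrast reporting style of the field; a global Benjamini-Hochberg
pass can be layered on by the caller. Every report discloses which path the
gate chose.

## Synthetic generator

**Evoked template.** `A·exp(−Δ/τ)·sin(2πfΔ)` for Δ ∈ [0, n_cycles/f], zero
elsewhere; the LFP uses the sign-flipped template so the first deflection
is the VEP trough. The sine phase (rather than cosine) keeps the waveform
continuous at stimulus onset: a cosine would start at its maximum, and
zero-phase filtering or PSTH smoothing smears that step across the onset,
shifting the first detected peak by more than a bin. The sine still yields
exactly `n_cycles` local maxima after onset. Noise is additive white
Gaussian by default with an optional 1/f-shaped component.

**Rates.** Units are inhomogeneous Poisson (thinning of a homogeneous
envelope, so mean rates are analytically checkable): baseline (log-normally
jittered across units around 10 Hz) + a von Mises direction gain
`exp(κ(cosθ−1))` applied to the evoked component (oscillation + a 6 Hz
boxcar transient over the stimulus). Negative instantaneous rates clip at
zero (documented contract). In single-direction familiar-stimulus protocols
the direction gain is 1 for every unit: those sessions model the population
response to the familiarized stimulus, which is what the oscillation
pipeline consumes; 12-direction protocols apply the gain per trial.
Rate-template amplitudes are in Hz; the expected z-amplitude after the PSTH
pipeline is `amp · exp(−(2πfσ)²/2) / SD_baseline` with σ = 30 ms
(`presets.expected_zscore_amplitude` computes it).

**Waveforms and depths.** 15 % of units get a narrow template
(trough-to-peak 0.27 ± 0.04 ms, clipped to ≤ 0.40) and the rest a broad one
(0.75 ± 0.10 ms, clipped to ≥ 0.50); the gap around the 0.45 ms threshold
makes classifier accuracy exactly measurable. Depths are uniform over the
950 μm probe span.

**Behavior.** Hit probability rises as `0.5 + 0.45·expit(k·s − 3)` per
session s, false alarms mirror it downward; latencies are log-normal with a
training-decaying median; inter-trial touches are Poisson. The walk in the
three-chamber arena moves in visit bouts (mean ≈ 7 s): each bout targets
the partner cage with probability `side_preference`, with Gaussian steps of
SD = width/100 per frame, a drift of half a step-SD toward the target, and
reflecting walls.

**Presets.** All magnitudes are invented (the study's recordings are not
public); what the presets encode is the *direction* of every group
contrast: WT-like 6.5 Hz / 5 cycles / 120 µV / τ 0.8 s, FX-like 4.5 Hz /
2 cycles / 60 µV / τ 0.4 s, CON-like between (6 Hz / 4 cycles / 90 µV),
with learning-rate slopes 1.0 / 0.4 / 0.7, inter-trial touch rates 15 / 60
/ 25 per session, and side preferences 0.70 / 0.50 / 0.65. A TOML registry
loader accepts user-defined preset sets.

## Study conditions and the silent-tail trade-off

Pooled-population oscillation studies use 600 units and 20 trials per
session (the scale at which such datasets pool units per group). The
spiking epoch is 1.3 s — 0.5 s baseline plus a 0.8 s post-stimulus window
that just covers the longest evoked oscillation (5 cycles at 6.5 Hz =
0.77 s). The window is deliberately tight: on a 600-unit pooled trace the
baseline noise SD is 1/√600 ≈ 0.041 z, so the fixed 0.1-z threshold sits
near 2.4σ of the pooled noise and an upcrossing calculation puts spurious
noise peaks at a small but non-zero rate per second of signal-free trace.
A long silent tail would therefore contaminate cycle counts and durations
with noise peaks; a window matched to the response keeps the detector
measuring the oscillation. The parameter-recovery grid goes one step
further and sizes each cell's epoch as 0.5 s + n_cycles/f exactly, and
disables the boxcar stimulus transient: its falling edge 0.2 s after onset
superposes with any oscillation peak that lands near it (e.g. the second
peak of a 6 Hz oscillation at 0.208 s) and drags the detected peak off its
true time — the recovery experiment is designed to measure the oscillation
estimator, not that interference.

## What the simulations show — and what they do not

The generator emulates stimulus-locked decaying oscillations with
genotype-ordered parameters, tuned Poisson units, logistic learning and
biased-walk trajectories. It does not emulate electrode drift, correlated
(shared) noise across units, non-Poisson spiking statistics, cell-type-
specific oscillation phase, session-to-session variability within an
animal, or video tracking artifacts beyond simple NaN gaps. Passing
recovery and ordering tests therefore establishes that the *pipeline*
faithfully measures what the data model contains — not that real
recordings satisfy the model.

Known limitations worth stating plainly:

* The z-score convention smooths before baselining, so a strong stimulus
  response leaks backwards across the 0.5 s boundary (±120 ms kernel
  support) and inflates the baseline SD at strongly driven conditions.
  Together with the positive bias of a stimulus-window *max* statistic on
  noise traces, this caps the realized DSI in the κ → ∞ limit near ≈ 0.8
  rather than 1.0.
* The baseline window supports only ~7 effectively independent samples
  after smoothing, so per-unit z amplitudes fluctuate by tens of percent
  around their expectation; population averages absorb this.
* Automatic cycle-window derivation needs the evoked response to dominate
  averaged-trace noise (prominence ≥ 20 % of peak-to-peak); at very low
  SNR it returns fewer windows with a warning instead of guessing.
* `days_to_expert` on a censored series reports the last observed day with
  a flag; comparisons treat censored as "later than any reached day",
  which is a ranking convention, not a survival model.

## Reproducibility

Every generator takes an explicit seed and is bit-reproducible under it.
`scripts/acceptance.py --seed N --out results/acceptance.json` reruns the
full set of studies — recovery grid (12 cells × 100 seeds), genotype
ordering (100 seeds × 2 presets × 600 units), LFP band ordering, DSI
concentration sweep, learning and hyperactivity orderings (100 seeds),
social-preference walk (20 seeds), dispatch calibration (1,000 pairs) — in
about a minute on one CPU and writes every number it computed.
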