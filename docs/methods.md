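# Methods

This note records the models, numerical choices and limitations behind
kneemon, in the order data flows through the pipeline.

## EMG conditioning

The package models the standard surface-EMG front end for knee-extension
monitoring as a digital cascade: high-pass at 10 Hz to remove motion
artifacts and electrode drift, low-pass at 500 Hz to bound the sEMG band,
and a notch at 50 Hz for power-line interference. The corner frequencies
are the conventional ones for this application; the realization is ours:

- **Topology.** 4th-order Butterworth high- and low-pass sections and a
  second-order IIR notch with quality factor 30 (≈1.7 Hz bandwidth),
  cascaded as second-order sections for numerical robustness. This meets
  a ≥20 dB rejection contract at DC and at the notch frequency while
  keeping passband ripple under 3 dB across 20–400 Hz (excluding ±2 Hz
  around the notch) — verified numerically in the tests rather than
  assumed from the design.
- **Causal by default.** Filtering is single-pass (`sosfilt`) so the same
  chain is usable in a real-time loop; a zero-phase forward–backward
  option exists for offline batch analysis and is recorded in the
  recording metadata, since it changes burst timing slightly.
- **Sampling rate.** The EMG rate is configurable with a 2000 Hz default:
  comfortably above twice the 500 Hz low-pass corner, and an exact
  multiple of the 10 Hz angle-sensor cadence.
- **Harmonic notches** at 100/150 Hz are off by default; they carve into
  the physiological band and are only worth it for heavily contaminated
  recordings.

## Features

MAV and RMS are computed per analysis window. The window length default
is 250 ms, non-overlapping — a common sEMG analysis choice, and an exact
multiple of the 100 ms angle cadence so windows align with kinematic
events. Per-repetition features average the windows whose midpoint falls
inside the repetition interval ("active-segment" mode); a whole-trial
mode exists for sensitivity checks, since averaging over rests dilutes
amplitudes roughly by the duty cycle. A trailing window shorter than half
the nominal length is dropped; a longer one is kept with its actual
sample count.

## Angle sensing and repetition detection

The knee angle is accelerometer tilt under a quasi-static assumption:
θ = atan2(√(ax² + ay²), az), with the z axis defined by the sitting
calibration pose. Samples whose magnitude falls below 0.5 g raise a
data-quality error (free fall / shake invalidates tilt); above 1.5 g a
warning is issued. Angles are clipped to [−15°, 105°], and values outside
that band in pre-fused input trigger a warning.

Repetition detection, which no standard defines for this protocol, works
on a lightly smoothed trace (3-sample moving average, i.e. 0.3 s):

1. The resting baseline θ_rest is the median of the first 2 s.
2. A Schmitt trigger marks a movement when θ rises above θ_rest + 10° and
   closes it when θ falls below θ_rest + 5°. The 10° start threshold
   deliberately echoes the clinical inclusion criterion of extension
   movement above 10°. Movements still open at the end of the trace are
   discarded: only completed repetitions count.
3. Each movement is extended outwards to the surrounding rest (the
   nearest samples within 2° of baseline), giving t_start/t_end.
4. θmax is the smoothed maximum over the interval (first attaining sample
   breaks plateau ties for t_peak); θmin is the **median of the rest
   window preceding the movement**, not the pointwise minimum — the
   minimum of ~20 noisy rest samples is biased low by about two noise
   standard deviations, which would bias every ROM high. With the median
   baseline and the smoothed maximum, mean ROM error at 0.5° angle noise
   is ≈0.55° (measured over 100 seeded sessions by the acceptance
   script).
5. Repetitions with ROM below 10° are discarded, mirroring the inclusion
   criterion; raising this floor can only reduce the count (tested).

**Phase durations** (rise, sustained hold, fall) come from a two-level
crossing analysis: the interpolated times at which θ crosses 25% and 75%
of the movement span on each edge give the ramp slope, each ramp is
extrapolated to its full rest-to-peak extent, and the hold is what
remains between the extrapolated ramp ends. For an ideal 2 s/4 s/2 s
trapezoid this returns (2, 4, 2) s essentially exactly, and a triangle
profile with no plateau returns a hold of 0. We chose this over the
simpler "time above a fraction of θmax" rule because any single-threshold
rule mixes ramp time into the hold (a 0.9·θmax threshold reports 1.8 s
rise and a 4.4 s hold for that same trapezoid) and is fragile to the
noise-inflated θmax estimate. Crossing times use linear interpolation
between samples; degenerate segments fall back to coarse peak-based
boundaries, and all durations are floored at one sample period.

## Session engine

`run_session` composes the stages: condition the EMG, detect repetitions
on the angle trace, attach active-segment features, average across
repetitions, and compare against targets. Decisions that were genuinely
open:

- **Pass direction and ties.** An average **meeting** its threshold
  passes (flag 1); for rehabilitation targets, reaching the target is
  success. A strict-comparison switch is exposed.
- **Channel conjunction.** The MAV and RMS families pass only when both
  VL and VM meet their thresholds — the conservative reading of a single
  per-family output; the alternative would let a strong VL mask a weak VM.
- **Hold duration** (target 3–6 s) is measured and reported per
  repetition but does not gate pass/fail; the pass criteria are the MAV,
  RMS and ROM thresholds only.
- **Early stop** (the safety stop during a test) truncates both streams
  at the stop instant and counts only repetitions completed before it;
  stopping after the last repetition is exactly the full-session result.
- Extra detected movements beyond the programmed count are ignored;
  multiple sets pool their repetitions into one average.

Determinism: identical inputs and configuration produce byte-identical
result files (fixed six-decimal formatting, ordered JSON keys).

## Simulator

The generator produces the study conditions the pipeline assumes, not
physiology: trapezoidal angle trajectories (2 s rise, 4 s hold within the
3–6 s protocol band, 2 s fall, 88° peak, 60 s rests — compressible to 2 s
so full-session tests run in seconds, with a lead-in rest equal to one
rest period) plus Gaussian angle noise (0.5° default); and EMG as
amplitude-modulated band-limited (20–450 Hz) unit-variance Gaussian
noise — the standard sEMG surrogate — with envelope
gain · (θ/θpeak)^p · fatigue, p = 1 by default since no quantitative
envelope–angle law is established for this protocol. Peak envelope gains
default to 0.19 V (VL) and 0.13 V (VM), the healthy-adult scale, with VL
strictly ≥ VM. An exponential fatigue factor (2%/s default) shrinks the
envelope during holds. Baseline white noise (5 mV std) and a 50 Hz
power-line sinusoid (10 mV amplitude, random phase) were chosen once as
realistic contamination levels visible to, and removable by, the
conditioning chain. Outputs are byte-deterministic per (seed, config);
angle and EMG use independent seeded streams so either can be regenerated
alone. Subject presets (`healthy`, `bone_joint`, `neuro`) vary peak
angle, gains and noise qualitatively; they are conveniences for
exercising the pipeline, not physiological claims.

What passing tests on simulator output do **not** show: robustness to
real-world artifacts the generator omits — electrode lift-off, crosstalk
between heads, non-trapezoidal or tremorous movements, accelerometer
dynamic acceleration during fast extensions, and inter-subject envelope
variability. Results on real recordings depend on those.

## Reporting

Subject summaries are means of session averages; group summaries are
field-wise arithmetic means over subjects (summed in sorted subject order
so aggregation is permutation-invariant bit-for-bit). Progress between
weeks is last − first per field with a three-way direction call; the
"unchanged" dead band is ±0.1° for angles and ±1 mV for EMG features, so
sub-resolution wiggles are not reported as change (a 1 mV shift in a
patient's VM MAV reads "unchanged", matching clinical intuition at this
measurement resolution). When computed means are compared against
printed table values in the tests, they are rounded half-to-even to the
precision of the printed cell, since the reference tables mix 1- to
6-decimal cells.

## Problem sizes

Defaults used by the test suite and acceptance script: sessions of 5
repetitions with rests compressed to 2 s (52 s of signal; 104 000 EMG
samples at 2 kHz, 520 angle samples at 10 Hz); detector-recovery
statistics over 100 seeded sessions; frequency-domain contracts checked
on 10 s sine simulations. The full suite runs in well under a minute.

## Known limitations

- The tilt model measures inclination only; it cannot distinguish knee
  extension from whole-leg rotation and degrades under dynamic
  acceleration.
- The detector assumes a single dominant movement per activation and a
  reasonably stationary baseline; slow baseline drift beyond a few
  degrees would need re-calibration.
- Phase-duration extrapolation assumes approximately linear ramps, as in
  the prescribed exercise; strongly curved trajectories bias rise/fall
  estimates.
- Group comparisons are descriptive means only; no hypothesis testing is
  performed.
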