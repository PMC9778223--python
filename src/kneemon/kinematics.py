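"""Knee-extension kinematics from an accelerometer-based angle sensor.

The knee angle theta is the inclination of the gravity vector relative to a
sitting reference pose: 0 deg = subject sitting with the shank vertical,
90 deg = fully stretched-out knee.  The sensor is read at 10 Hz (one sample
every 100 ms).  Range of motion for a movement is

    ROM = |theta_max - theta_min|

and a repetition is one rest -> rise -> sustained hold -> fall -> rest
cycle of the exercise.  Repetitions are detected with a Schmitt-trigger
hysteresis on the angle (start above rest + 10 deg, end below rest + 5 deg)
and phase durations are estimated from two-level (25%/75% of span) crossing
times, which extrapolate the ramps to their full extent so that rise /
sustained / fall reproduce the true trapezoid decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataQualityError

__all__ = [
    "AngleTrace",
    "Repetition",
    "DetectionParams",
    "PhaseDurations",
    "accel_to_angle",
    "extract_extrema",
    "compute_rom",
    "detect_repetitions",
    "segment_phases",
]

THETA_MIN_VALID = -15.0
THETA_MAX_VALID = 105.0


@dataclass
class AngleTrace:
    """Knee-extension angle theta(t), degrees, on the session clock."""

    timestamps_s: np.ndarray
    theta_deg: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        if self.timestamps_s.shape != self.theta_deg.shape:
            raise ConfigurationError("timestamps and angles differ in length")
        if len(self.timestamps_s) < 1:
            raise ConfigurationError("angle trace is empty")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        out = (self.theta_deg < THETA_MIN_VALID) | (self.theta_deg > THETA_MAX_VALID)
        if out.any():
            warnings.warn(
                f"{int(out.sum())} angle samples outside the plausible "
                f"[{THETA_MIN_VALID}, {THETA_MAX_VALID}] deg range",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return len(self.timestamps_s)

    @property
    def sample_period_s(self) -> float:
        if self.n_samples < 2:
            return float("nan")
        return float(np.median(np.diff(self.timestamps_s)))

    def slice_time(self, t_a: float, t_b: float) -> "AngleTrace":
        mask = (self.timestamps_s >= t_a) & (self.timestamps_s <= t_b)
        if not mask.any():
            raise ConfigurationError(f"no angle samples in [{t_a}, {t_b}] s")
        return AngleTrace(self.timestamps_s[mask], self.theta_deg[mask])


@dataclass(frozen=True)
class Repetition:
    """One segmented extension cycle with its kinematic summary."""

    index: int
    t_start_s: float
    t_peak_s: float
    t_end_s: float
    theta_max_deg: float
    theta_min_deg: float
    rom_deg: float
    sustained_s: float
    rise_s: float
    fall_s: float

    def __post_init__(self) -> None:
        if not self.t_start_s < self.t_peak_s < self.t_end_s:
            raise ConfigurationError(
                f"repetition {self.index}: require t_start < t_peak < t_end, got "
                f"({self.t_start_s}, {self.t_peak_s}, {self.t_end_s})"
            )
        if self.rom_deg < 0 or self.sustained_s < 0:
            raise ConfigurationError("rom_deg and sustained_s must be non-negative")
        if self.rise_s <= 0 or self.fall_s <= 0:
            raise ConfigurationError("rise_s and fall_s must be positive")


@dataclass(frozen=True)
class PhaseDurations:
    """Durations of the movement phases of one repetition, seconds."""

    pre_start_s: float
    rise_s: float
    sustained_s: float
    fall_s: float


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the hysteresis repetition detector.

    ``start_delta_deg``/``end_delta_deg`` are the Schmitt-trigger thresholds
    above the resting baseline; the 10 deg start threshold mirrors the
    clinical inclusion criterion of knee-extension movement above 10 deg.
    ``min_rom_deg`` discards movements below that same criterion.
    """

    start_delta_deg: float = 10.0
    end_delta_deg: float = 5.0
    min_rom_deg: float = 10.0
    rest_window_s: float = 2.0
    smooth_samples: int = 3
    onset_band_deg: float = 2.0
    # span fractions used for the two-level phase-timing estimate
    level_low_frac: float = 0.25
    level_high_frac: float = 0.75

    def __post_init__(self) -> None:
        if self.end_delta_deg >= self.start_delta_deg:
            raise ConfigurationError(
                "end_delta_deg must be below start_delta_deg (hysteresis)"
            )
        if self.smooth_samples < 1:
            raise ConfigurationError("smooth_samples must be >= 1")
        if not 0 < self.level_low_frac < self.level_high_frac < 1:
            raise ConfigurationError("require 0 < level_low_frac < level_high_frac < 1")


def accel_to_angle(
    accel_g: np.ndarray,
    timestamps_s: np.ndarray | None = None,
    sampling_period_s: float = 0.1,
) -> AngleTrace:
    """Knee angle from quasi-static 3-axis accelerometer samples (units g).

    The angle is the inclination of gravity relative to the sitting
    reference axis (sensor z): atan2(sqrt(ax^2 + ay^2), az), so (0,0,1) g
    maps to 0 deg and (1,0,0) g to 90 deg.  Assumes the shank moves slowly
    enough that gravity dominates; samples whose magnitude strays from 1 g
    violate that assumption.
    """
    a = np.atleast_2d(np.asarray(accel_g, dtype=float))
    if a.shape[1] != 3:
        raise ConfigurationError(f"expected Nx3 accelerations, got shape {a.shape}")
    mag = np.linalg.norm(a, axis=1)
    if np.any(mag < 0.5):
        bad = int(np.argmax(mag < 0.5))
        raise DataQualityError(
            f"acceleration magnitude {mag[bad]:.3f} g at sample {bad} is below "
            "0.5 g (free fall or shake); tilt angle is unreliable"
        )
    if np.any(mag > 1.5):
        warnings.warn(
            "acceleration magnitude above 1.5 g: motion is not quasi-static",
            stacklevel=2,
        )
    theta = np.degrees(np.arctan2(np.hypot(a[:, 0], a[:, 1]), a[:, 2]))
    theta = np.clip(theta, THETA_MIN_VALID, THETA_MAX_VALID)
    if timestamps_s is None:
        timestamps_s = np.arange(len(theta)) * sampling_period_s
    return AngleTrace(np.asarray(timestamps_s, dtype=float), theta)


def extract_extrema(trace: AngleTrace, t_a: float, t_b: float) -> tuple[float, float]:
    """(theta_max, theta_min) over [t_a, t_b], degrees."""
    mask = (trace.timestamps_s >= t_a) & (trace.timestamps_s <= t_b)
    if mask.sum() < 2:
        raise ConfigurationError(
            f"interval [{t_a}, {t_b}] s contains {int(mask.sum())} samples; need >= 2"
        )
    seg = trace.theta_deg[mask]
    return float(seg.max()), float(seg.min())


def compute_rom(theta_max_deg: float, theta_min_deg: float) -> float:
    """Range of motion: absolute difference of the extreme angles, degrees."""
    return abs(float(theta_max_deg) - float(theta_min_deg))


def _smooth(theta: np.ndarray, n: int) -> np.ndarray:
    if n <= 1 or len(theta) < n:
        return theta.astype(float)
    pad = n // 2
    padded = np.pad(theta.astype(float), pad, mode="edge")
    kernel = np.ones(n) / n
    sm = np.convolve(padded, kernel, mode="valid")
    return sm[: len(theta)] if len(sm) > len(theta) else sm


def _cross_time(t: np.ndarray, y: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time where y crosses `level` between i-1 and i."""
    if i == 0 or y[i] == y[i - 1]:
        return float(t[i])
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    frac = min(max(frac, 0.0), 1.0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _phase_times(
    t: np.ndarray,
    theta: np.ndarray,
    i_start: int,
    i_peak: int,
    i_end: int,
    theta_min: float,
    theta_max: float,
    params: DetectionParams,
    dt: float,
) -> tuple[float, float, float]:
    """(rise_s, sustained_s, fall_s) from two-level crossing analysis.

    Crossing times of the 25% and 75%-of-span levels give the ramp slopes;
    each ramp is extrapolated to its full rest-to-peak extent and the
    sustained (plateau) duration is what remains between the ramps.  A
    triangle profile with no plateau yields sustained ~ 0.
    """
    span = theta_max - theta_min
    if span <= 0:
        return dt, 0.0, dt
    lo = theta_min + params.level_low_frac * span
    hi = theta_min + params.level_high_frac * span
    width = params.level_high_frac - params.level_low_frac

    # rising edge: first crossings between i_start and i_peak
    t_lo_up = t_hi_up = None
    for i in range(i_start + 1, i_peak + 1):
        if t_lo_up is None and theta[i] >= lo:
            t_lo_up = _cross_time(t, theta, i, lo)
        if theta[i] >= hi:
            t_hi_up = _cross_time(t, theta, i, hi)
            break
    # falling edge: last crossings between i_peak and i_end (scan backwards)
    t_lo_dn = t_hi_dn = None
    for i in range(i_end, i_peak, -1):
        if t_lo_dn is None and theta[i - 1] >= lo:
            t_lo_dn = _cross_time(t, theta, i, lo)
        if theta[i - 1] >= hi:
            t_hi_dn = _cross_time(t, theta, i, hi)
            break
    if t_lo_up is None or t_hi_up is None or t_lo_dn is None or t_hi_dn is None:
        # degenerate segment; fall back to coarse boundaries
        rise = max(t[i_peak] - t[i_start], dt)
        fall = max(t[i_end] - t[i_peak], dt)
        return rise, 0.0, fall

    d_up = max(t_hi_up - t_lo_up, 0.0)
    d_dn = max(t_lo_dn - t_hi_dn, 0.0)
    rise = max(d_up / width, dt)
    fall = max(d_dn / width, dt)
    # extrapolate ramps up to the plateau; what remains is the hold
    plateau_on = t_hi_up + (1.0 - params.level_high_frac) * rise
    plateau_off = t_hi_dn - (1.0 - params.level_high_frac) * fall
    sustained = max(plateau_off - plateau_on, 0.0)
    return rise, sustained, fall


def detect_repetitions(
    trace: AngleTrace, params: DetectionParams | None = None
) -> list[Repetition]:
    """Segment an angle trace into extension repetitions.

    Hysteresis on the (lightly smoothed) angle relative to the resting
    baseline detects candidate movements; each is extended outwards to the
    surrounding rest, summarized (theta_max from the interval, theta_min
    from the preceding rest baseline) and kept if its ROM reaches
    ``min_rom_deg``.  Movements still in progress at the end of the trace
    are discarded: only completed repetitions count.
    """
    params = params or DetectionParams()
    t = trace.timestamps_s
    theta = _smooth(trace.theta_deg, params.smooth_samples)
    n = len(t)
    if n < 3:
        return []
    dt = trace.sample_period_s

    rest_mask = t <= t[0] + params.rest_window_s
    theta_rest = float(np.median(theta[rest_mask]))
    start_level = theta_rest + params.start_delta_deg
    end_level = theta_rest + params.end_delta_deg
    onset_level = theta_rest + params.onset_band_deg

    # hysteresis scan for core active intervals
    cores: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if theta[i] >= start_level:
            j = i
            while j + 1 < n and theta[j + 1] > end_level:
                j += 1
            if j + 1 < n:  # closed by a down-crossing: a completed movement
                cores.append((i, j + 1))
            i = j + 2
        else:
            i += 1

    reps: list[Repetition] = []
    prev_end_idx = 0
    for i_on, i_off in cores:
        # extend to surrounding rest within the onset band
        i_start = i_on
        while i_start > prev_end_idx and theta[i_start - 1] > onset_level:
            i_start -= 1
        if i_start > prev_end_idx:
            i_start -= 1  # last resting sample before the movement
        i_end = i_off
        while i_end + 1 < n and theta[i_end] > onset_level:
            i_end += 1

        seg = theta[i_start : i_end + 1]
        i_peak = i_start + int(np.argmax(seg))
        theta_max = float(seg.max())
        if not i_start < i_peak < i_end:
            continue  # no interior peak: not a plausible movement

        # baseline = median of the rest window just before the movement
        lo_t = max(t[prev_end_idx], t[i_start] - params.rest_window_s)
        base_mask = (t >= lo_t) & (t <= t[i_start])
        theta_min = (
            float(np.median(theta[base_mask])) if base_mask.any() else float(seg.min())
        )
        theta_min = min(theta_min, theta_max)

        rom = compute_rom(theta_max, theta_min)
        if rom < params.min_rom_deg:
            continue
        rise, sustained, fall = _phase_times(
            t, theta, i_start, i_peak, i_end, theta_min, theta_max, params, dt
        )
        reps.append(
            Repetition(
                index=len(reps) + 1,
                t_start_s=float(t[i_start]),
                t_peak_s=float(t[i_peak]),
                t_end_s=float(t[i_end]),
                theta_max_deg=theta_max,
                theta_min_deg=theta_min,
                rom_deg=rom,
                sustained_s=sustained,
                rise_s=rise,
                fall_s=fall,
            )
        )
        prev_end_idx = i_end
    return reps


def segment_phases(
    rep: Repetition,
    trace: AngleTrace,
    params: DetectionParams | None = None,
    t_prev_end_s: float | None = None,
) -> PhaseDurations:
    """Phase durations of one detected repetition.

    ``pre_start_s`` is the rest time between the previous activity (or the
    start of the trace) and the movement onset; rise/sustained/fall come
    from the two-level crossing estimate used by the detector.
    """
    params = params or DetectionParams()
    t = trace.timestamps_s
    theta = _smooth(trace.theta_deg, params.smooth_samples)
    dt = trace.sample_period_s
    mask = (t >= rep.t_start_s) & (t <= rep.t_end_s)
    idx = np.flatnonzero(mask)
    if len(idx) < 3:
        raise ConfigurationError("repetition interval holds fewer than 3 samples")
    i_start, i_end = int(idx[0]), int(idx[-1])
    i_peak = i_start + int(np.argmax(theta[i_start : i_end + 1]))
    i_peak = min(max(i_peak, i_start + 1), i_end - 1)
    rise, sustained, fall = _phase_times(
        t, theta, i_start, i_peak, i_end, rep.theta_min_deg, rep.theta_max_deg, params, dt
    )
    t_ref = t[0] if t_prev_end_s is None else t_prev_end_s
    return PhaseDurations(
        pre_start_s=max(rep.t_start_s - float(t_ref), 0.0),
        rise_s=rise,
        sustained_s=sustained,
        fall_s=fall,
    )
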