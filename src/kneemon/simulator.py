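"""Seeded generator of coupled knee-angle and two-channel EMG recordings.

The generator emulates the study protocol this package processes: per
session, `reps` trapezoidal knee extensions (rest -> linear rise to the
peak angle -> sustained hold of a few seconds -> linear fall -> rest, one
minute between repetitions), an angle sensor sampled every 100 ms with
Gaussian noise, and surface EMG whose envelope follows the normalized knee
angle.  The EMG stochastic model is the standard surrogate: amplitude-
modulated band-limited (20-450 Hz) unit-variance Gaussian noise, plus a
white baseline and a 50 Hz power-line sinusoid.  VL peak gain exceeds VM
(the lateral head works harder against the ankle load), and an optional
exponential fatigue decay shrinks the envelope during holds.

Outputs are byte-deterministic per (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .errors import ConfigurationError
from .features import EmgRecording
from .kinematics import AngleTrace, Repetition

__all__ = [
    "SimulationConfig",
    "PRESETS",
    "make_config",
    "simulate_angle",
    "simulate_emg",
    "simulate_session",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-protocol parameters of one simulated session.

    Defaults are the protocol conditions: 5 repetitions, 2 s rise, 3-6 s
    hold (4 s nominal), 2 s fall, 60 s rest (compressible for tests),
    ~90 deg peak, EMG peak envelopes on the healthy-subject scale.
    """

    seed: int = 0
    reps: int = 5
    rise_s: float = 2.0
    hold_s: float = 4.0
    fall_s: float = 2.0
    rest_s: float = 60.0
    lead_in_s: float | None = None  # rest before the first rep; default rest_s
    peak_deg: float = 88.0
    angle_noise_deg: float = 0.5
    emg_gain_vl_v: float = 0.19
    emg_gain_vm_v: float = 0.13
    envelope_exponent: float = 1.0
    fatigue_decay_per_s: float = 0.02
    baseline_noise_v: float = 0.005
    powerline_amp_v: float = 0.01
    emg_sampling_rate_hz: float = 2000.0
    angle_sampling_period_s: float = 0.1
    activation_lead_s: float = 0.0

    def __post_init__(self) -> None:
        if self.reps < 0:
            raise ConfigurationError("reps must be >= 0")
        if not (self.emg_gain_vl_v >= self.emg_gain_vm_v > 0):
            raise ConfigurationError(
                "require emg_gain_vl_v >= emg_gain_vm_v > 0 (VL exceeds VM)"
            )
        if not 10.0 < self.peak_deg <= 95.0:
            raise ConfigurationError(f"peak_deg must lie in (10, 95], got {self.peak_deg}")
        if min(self.rise_s, self.hold_s, self.fall_s) < 0 or self.rest_s < 0:
            raise ConfigurationError("phase durations must be non-negative")
        if self.envelope_exponent < 1.0:
            raise ConfigurationError("envelope_exponent must be >= 1")

    @property
    def lead_in(self) -> float:
        return self.rest_s if self.lead_in_s is None else self.lead_in_s

    @property
    def cycle_s(self) -> float:
        return self.rise_s + self.hold_s + self.fall_s + self.rest_s

    @property
    def total_duration_s(self) -> float:
        return self.lead_in + self.reps * self.cycle_s


# qualitative subject profiles: a fit healthy adult; a bone/joint patient
# (good motion command, weakened muscle output); a neurodegenerative/stroke
# patient (small, unstable EMG and reduced, noisier motion).  Conveniences
# for exercising the pipeline, not physiological claims.
PRESETS: dict[str, dict] = {
    "healthy": {},
    "bone_joint": {
        "peak_deg": 84.0,
        "emg_gain_vl_v": 0.10,
        "emg_gain_vm_v": 0.09,
        "angle_noise_deg": 1.0,
    },
    "neuro": {
        "peak_deg": 78.0,
        "emg_gain_vl_v": 0.045,
        "emg_gain_vm_v": 0.033,
        "angle_noise_deg": 2.0,
        "fatigue_decay_per_s": 0.05,
    },
}


def make_config(preset: str = "healthy", seed: int = 0, **overrides) -> SimulationConfig:
    """Build a SimulationConfig from a named subject profile."""
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    kwargs = {**PRESETS[preset], **overrides, "seed": seed}
    return SimulationConfig(**kwargs)


def _theta_true(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Noiseless trapezoidal angle profile at arbitrary times."""
    theta = np.zeros_like(t, dtype=float)
    for k in range(config.reps):
        on = config.lead_in + k * config.cycle_s
        r, h, f = config.rise_s, config.hold_s, config.fall_s
        if r > 0:
            seg = (t >= on) & (t < on + r)
            theta[seg] = config.peak_deg * (t[seg] - on) / r
        seg = (t >= on + r) & (t < on + r + h)
        theta[seg] = config.peak_deg
        if f > 0:
            seg = (t >= on + r + h) & (t < on + r + h + f)
            theta[seg] = config.peak_deg * (1.0 - (t[seg] - on - r - h) / f)
    return theta


def ground_truth_repetitions(config: SimulationConfig) -> list[Repetition]:
    """Exact phase boundaries of each simulated repetition."""
    reps = []
    for k in range(config.reps):
        on = config.lead_in + k * config.cycle_s
        reps.append(
            Repetition(
                index=k + 1,
                t_start_s=on,
                t_peak_s=on + config.rise_s,
                t_end_s=on + config.rise_s + config.hold_s + config.fall_s,
                theta_max_deg=config.peak_deg,
                theta_min_deg=0.0,
                rom_deg=config.peak_deg,
                sustained_s=config.hold_s,
                rise_s=config.rise_s,
                fall_s=config.fall_s,
            )
        )
    return reps


def simulate_angle(config: SimulationConfig) -> tuple[AngleTrace, list[Repetition]]:
    """Angle-sensor trace (10 Hz nominal) plus ground-truth repetitions."""
    rng = np.random.default_rng([config.seed % (2**31), 0])
    t = np.arange(0.0, config.total_duration_s, config.angle_sampling_period_s)
    if len(t) < 2:  # degenerate: still return a short rest trace
        t = np.arange(2) * config.angle_sampling_period_s
    theta = _theta_true(config, t)
    if config.angle_noise_deg > 0:
        theta = theta + rng.normal(0.0, config.angle_noise_deg, size=len(t))
    return AngleTrace(t, theta), ground_truth_repetitions(config)


def _fatigue_factor(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """exp(-decay * time_held) within each cycle; resets after the rest."""
    if config.fatigue_decay_per_s <= 0 or config.reps == 0:
        return np.ones_like(t)
    tau = t - config.lead_in
    in_protocol = tau >= 0
    phase = np.where(in_protocol, np.mod(tau, config.cycle_s), 0.0)
    held = np.clip(phase - config.rise_s, 0.0, config.hold_s)
    factor = np.exp(-config.fatigue_decay_per_s * held)
    return np.where(in_protocol, factor, 1.0)


def simulate_emg(config: SimulationConfig) -> EmgRecording:
    """Two-channel surface-EMG surrogate coupled to the angle profile."""
    fs = config.emg_sampling_rate_hz
    n = int(round(config.total_duration_s * fs))
    n = max(n, 1)
    t = np.arange(n) / fs
    theta = _theta_true(config, t + config.activation_lead_s)
    norm = np.clip(theta / config.peak_deg, 0.0, 1.0)
    shape = norm**config.envelope_exponent * _fatigue_factor(config, t)

    band = _sig.butter(4, [20.0, min(450.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    rng = np.random.default_rng([config.seed % (2**31), 1])
    channels = {}
    for name, gain in (("vl", config.emg_gain_vl_v), ("vm", config.emg_gain_vm_v)):
        carrier = _sig.sosfilt(band, rng.standard_normal(n))
        sd = carrier.std()
        if sd > 0:
            carrier /= sd
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x = gain * shape * carrier
        if config.baseline_noise_v > 0:
            x = x + rng.normal(0.0, config.baseline_noise_v, size=n)
        if config.powerline_amp_v > 0:
            x = x + config.powerline_amp_v * np.sin(2.0 * np.pi * 50.0 * t + phase)
        channels[name] = x
    return EmgRecording(
        vl=channels["vl"], vm=channels["vm"], sampling_rate_hz=fs, t0_s=0.0, filtered=False
    )


def simulate_session(
    config: SimulationConfig,
) -> tuple[EmgRecording, AngleTrace, list[Repetition]]:
    """Convenience: coupled EMG + angle for one session, plus ground truth."""
    angle, truth = simulate_angle(config)
    emg = simulate_emg(config)
    return emg, angle, truth
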