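"""Rehabilitation session engine.

Executes the monitoring workflow over synchronized EMG + angle inputs:
condition the EMG, detect the exercise repetitions on the angle trace,
attach windowed MAV/RMS features to each repetition, average across
repetitions, and compare the averages against clinician-set target
thresholds.  Pass flags follow bio-feedback convention: 1 = passing,
0 = not passing; an average meeting its threshold (ties included, by
default) passes, and the MAV/RMS families pass only when both the VL and
VM channels meet their thresholds.

The hold-duration target (3-6 s sustained contraction) is recorded per
repetition and reported, but does not gate pass/fail: the pass criteria
are the MAV, RMS and ROM thresholds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError
from .features import EmgRecording, WindowFeatures, windowed_features
from .filters import FilterChainSpec, apply_filter_chain, design_filter_chain
from .kinematics import AngleTrace, DetectionParams, Repetition, detect_repetitions

__all__ = [
    "Targets",
    "SessionConfig",
    "RepFeatures",
    "Averages",
    "PassFlags",
    "SessionResult",
    "run_session",
    "evaluate_targets",
    "early_stop",
]


@dataclass(frozen=True)
class Targets:
    """Per-family thresholds; MAV/RMS per channel (V), ROM in degrees."""

    mav_vl_v: float = 0.0
    mav_vm_v: float = 0.0
    rms_vl_v: float = 0.0
    rms_vm_v: float = 0.0
    rom_deg: float = 0.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ConfigurationError(f"target {name} must be non-negative, got {value}")


@dataclass(frozen=True)
class SessionConfig:
    """Definition of one rehabilitation test session.

    The default program: one set of five knee-extension repetitions, each
    holding the peak for 3-6 s, one minute rest between repetitions, a
    1 kg ankle sandbag.
    """

    subject_id: str = "anonymous"
    knee_side: str = "right"
    reps_per_set: int = 5
    n_sets: int = 1
    hold_target_s: tuple[float, float] = (3.0, 6.0)
    rest_between_reps_s: float = 60.0
    sandbag_kg: float = 1.0
    targets: Targets = field(default_factory=Targets)
    filter_chain: FilterChainSpec = field(default_factory=FilterChainSpec)
    window_s: float = 0.25
    hop_s: float | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    strict_comparison: bool = False  # True: averages must exceed thresholds
    features_on_raw: bool = False  # skip the filter chain (testing aid)
    whole_trial_features: bool = False  # average over the whole trial, not per rep

    def __post_init__(self) -> None:
        if self.knee_side not in ("left", "right"):
            raise ConfigurationError(f"knee_side must be 'left' or 'right', got {self.knee_side!r}")
        if self.reps_per_set < 1 or self.n_sets < 1:
            raise ConfigurationError("reps_per_set and n_sets must be >= 1")
        lo, hi = self.hold_target_s
        if not lo < hi:
            raise ConfigurationError(f"hold_target_s lower bound must be below upper, got {self.hold_target_s}")

    @property
    def target_rep_count(self) -> int:
        return self.reps_per_set * self.n_sets


@dataclass(frozen=True)
class RepFeatures:
    """One repetition with its EMG feature summary (V) and hold check."""

    repetition: Repetition
    mav_vl_v: float
    mav_vm_v: float
    rms_vl_v: float
    rms_vm_v: float
    hold_in_target: bool


@dataclass(frozen=True)
class Averages:
    avg_rom_deg: float = 0.0
    avg_mav_vl_v: float = 0.0
    avg_mav_vm_v: float = 0.0
    avg_rms_vl_v: float = 0.0
    avg_rms_vm_v: float = 0.0


@dataclass(frozen=True)
class PassFlags:
    """1 = passing, 0 = not passing, per target family."""

    mav_pass: int = 0
    rms_pass: int = 0
    rom_pass: int = 0


@dataclass(frozen=True)
class SessionResult:
    config: SessionConfig
    per_rep: tuple[RepFeatures, ...]
    averages: Averages
    pass_flags: PassFlags
    completed: bool
    emg_t0_s: float
    emg_duration_s: float


def evaluate_targets(
    averages: Averages, targets: Targets, strict: bool = False
) -> PassFlags:
    """Compare session averages against the thresholds.

    Non-strict (default): meeting the target exactly passes.  The MAV/RMS
    families require both channels to pass.
    """
    ok = (lambda v, thr: v > thr) if strict else (lambda v, thr: v >= thr)
    return PassFlags(
        mav_pass=int(
            ok(averages.avg_mav_vl_v, targets.mav_vl_v)
            and ok(averages.avg_mav_vm_v, targets.mav_vm_v)
        ),
        rms_pass=int(
            ok(averages.avg_rms_vl_v, targets.rms_vl_v)
            and ok(averages.avg_rms_vm_v, targets.rms_vm_v)
        ),
        rom_pass=int(ok(averages.avg_rom_deg, targets.rom_deg)),
    )


def _rep_features(
    rep: Repetition,
    windows: list[WindowFeatures],
    hold_target: tuple[float, float],
    whole_trial: bool,
) -> RepFeatures:
    if whole_trial:
        selected = windows
    else:
        selected = [w for w in windows if rep.t_start_s <= w.midpoint_s <= rep.t_end_s]
        if not selected:  # repetition shorter than one window: take overlapping
            selected = [
                w for w in windows
                if w.window_end_s > rep.t_start_s and w.window_start_s < rep.t_end_s
            ]
    if not selected:
        raise ConfigurationError(
            f"no EMG windows overlap repetition {rep.index} "
            f"[{rep.t_start_s}, {rep.t_end_s}] s"
        )
    lo, hi = hold_target
    return RepFeatures(
        repetition=rep,
        mav_vl_v=float(np.mean([w.mav_vl for w in selected])),
        mav_vm_v=float(np.mean([w.mav_vm for w in selected])),
        rms_vl_v=float(np.mean([w.rms_vl for w in selected])),
        rms_vm_v=float(np.mean([w.rms_vm for w in selected])),
        hold_in_target=bool(lo <= rep.sustained_s <= hi),
    )


def run_session(
    emg: EmgRecording, angle: AngleTrace, config: SessionConfig
) -> SessionResult:
    """Run the full monitoring pipeline over one session's recordings."""
    emg_end = emg.t0_s + emg.duration_s
    if emg_end <= angle.timestamps_s[0] or emg.t0_s >= angle.timestamps_s[-1]:
        raise ConfigurationError(
            "EMG and angle recordings do not overlap in time "
            f"(EMG [{emg.t0_s}, {emg_end:.3f}] s vs angle "
            f"[{angle.timestamps_s[0]}, {angle.timestamps_s[-1]}] s)"
        )

    if config.features_on_raw:
        conditioned = emg
    else:
        chain = design_filter_chain(config.filter_chain)
        conditioned = apply_filter_chain(chain, emg)

    reps = detect_repetitions(angle, config.detection)
    reps = reps[: config.target_rep_count]
    completed = len(reps) == config.target_rep_count

    if not reps:
        return SessionResult(
            config=config,
            per_rep=(),
            averages=Averages(),
            pass_flags=PassFlags(0, 0, 0),
            completed=False,
            emg_t0_s=emg.t0_s,
            emg_duration_s=emg.duration_s,
        )

    windows = windowed_features(conditioned, config.window_s, config.hop_s)
    per_rep = tuple(
        _rep_features(rep, windows, config.hold_target_s, config.whole_trial_features)
        for rep in reps
    )
    averages = Averages(
        avg_rom_deg=float(np.mean([r.repetition.rom_deg for r in per_rep])),
        avg_mav_vl_v=float(np.mean([r.mav_vl_v for r in per_rep])),
        avg_mav_vm_v=float(np.mean([r.mav_vm_v for r in per_rep])),
        avg_rms_vl_v=float(np.mean([r.rms_vl_v for r in per_rep])),
        avg_rms_vm_v=float(np.mean([r.rms_vm_v for r in per_rep])),
    )
    flags = evaluate_targets(averages, config.targets, config.strict_comparison)
    return SessionResult(
        config=config,
        per_rep=per_rep,
        averages=averages,
        pass_flags=flags,
        completed=completed,
        emg_t0_s=emg.t0_s,
        emg_duration_s=emg.duration_s,
    )


def early_stop(
    emg: EmgRecording,
    angle: AngleTrace,
    config: SessionConfig,
    stop_time_s: float,
) -> SessionResult:
    """Evaluate a session halted at ``stop_time_s`` (safety stop).

    Only repetitions completed before the stop instant count; data up to
    the stop are preserved.  Stopping after the final repetition is
    equivalent to running the full session.
    """
    if stop_time_s >= angle.timestamps_s[-1]:
        return run_session(emg, angle, config)
    if stop_time_s <= angle.timestamps_s[0]:
        return SessionResult(
            config=config,
            per_rep=(),
            averages=Averages(),
            pass_flags=PassFlags(0, 0, 0),
            completed=False,
            emg_t0_s=emg.t0_s,
            emg_duration_s=0.0,
        )
    angle_cut = angle.slice_time(angle.timestamps_s[0], stop_time_s)
    emg_cut = emg.slice_time(emg.t0_s, stop_time_s)
    return run_session(emg_cut, angle_cut, config)
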