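"""Time-domain surface-EMG features.

Two channels are carried everywhere: the vastus lateralis (VL) and the
vastus medialis (VM), the two quadriceps heads targeted in knee-extension
rehabilitation.  The features are the classical windowed mean absolute
value

    MAV = (1/N) * sum |x(n)|

and root-mean-square

    RMS = sqrt((1/N) * sum x(n)^2)

of the conditioned EMG signal x(n), with N samples per analysis window.
By the power-mean inequality RMS >= MAV >= 0 always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["EmgRecording", "WindowFeatures", "mav", "rms", "windowed_features"]


@dataclass
class EmgRecording:
    """Two-channel (VL, VM) EMG time series with uniform sampling.

    Amplitudes are in volts.  ``t0_s`` is the time of the first sample on
    the shared session clock, so EMG windows can be aligned to the angle
    trace by timestamp.
    """

    vl: np.ndarray
    vm: np.ndarray
    sampling_rate_hz: float
    t0_s: float = 0.0
    filtered: bool = False
    zero_phase: bool = False

    def __post_init__(self) -> None:
        self.vl = np.asarray(self.vl, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.vl.ndim != 1 or self.vm.ndim != 1:
            raise ConfigurationError("EMG channels must be one-dimensional")
        if len(self.vl) != len(self.vm):
            raise ConfigurationError(
                f"VL and VM channels differ in length ({len(self.vl)} vs {len(self.vm)})"
            )
        if len(self.vl) < 1:
            raise ConfigurationError("EMG recording is empty")
        if not self.sampling_rate_hz > 0:
            raise ConfigurationError(
                f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.vl)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sampling_rate_hz

    def channel(self, name: str) -> np.ndarray:
        if name.lower() == "vl":
            return self.vl
        if name.lower() == "vm":
            return self.vm
        raise KeyError(f"unknown channel {name!r}; expected 'vl' or 'vm'")

    def slice_time(self, t_a: float, t_b: float) -> "EmgRecording":
        """Sub-recording covering [t_a, t_b] on the session clock."""
        t = self.times_s
        mask = (t >= t_a) & (t <= t_b)
        if not mask.any():
            raise ConfigurationError(
                f"no EMG samples in interval [{t_a}, {t_b}] s"
            )
        i0 = int(np.argmax(mask))
        return replace(self, vl=self.vl[mask], vm=self.vm[mask], t0_s=float(t[i0]))


@dataclass(frozen=True)
class WindowFeatures:
    """MAV/RMS of one analysis window, both channels, volts."""

    window_start_s: float
    window_end_s: float
    n_samples: int
    mav_vl: float
    mav_vm: float
    rms_vl: float
    rms_vm: float

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.window_start_s + self.window_end_s)


def mav(window: np.ndarray) -> float:
    """Mean absolute value of a sample window, volts."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("MAV of an empty window is undefined")
    return float(np.mean(np.abs(x)))


def rms(window: np.ndarray) -> float:
    """Root mean square of a sample window, volts."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("RMS of an empty window is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def windowed_features(
    recording: EmgRecording,
    window_s: float = 0.25,
    hop_s: float | None = None,
) -> list[WindowFeatures]:
    """Tile the recording with analysis windows and compute MAV/RMS per window.

    Windows start at ``t0_s`` and advance by ``hop_s`` (default: ``window_s``,
    i.e. non-overlapping).  A trailing partial window shorter than half a
    window is dropped; a longer one is kept with its actual sample count.
    """
    if window_s <= 0:
        raise ConfigurationError(f"window_s must be positive, got {window_s}")
    hop_s = window_s if hop_s is None else hop_s
    if hop_s <= 0:
        raise ConfigurationError(f"hop_s must be positive, got {hop_s}")
    if recording.duration_s < window_s:
        raise ConfigurationError(
            f"recording of {recording.duration_s:.3f} s is shorter than one "
            f"window; at least {window_s:.3f} s are required"
        )

    fs = recording.sampling_rate_hz
    n = recording.n_samples
    out: list[WindowFeatures] = []
    k = 0
    while True:
        start = k * hop_s
        remaining = n / fs - start
        if remaining < window_s / 2 or remaining <= 0:
            break
        i0 = int(round(start * fs))
        i1 = min(int(round((start + window_s) * fs)), n)
        if i1 <= i0:
            break
        w_vl = recording.vl[i0:i1]
        w_vm = recording.vm[i0:i1]
        out.append(
            WindowFeatures(
                window_start_s=recording.t0_s + i0 / fs,
                window_end_s=recording.t0_s + i1 / fs,
                n_samples=i1 - i0,
                mav_vl=mav(w_vl),
                mav_vm=mav(w_vm),
                rms_vl=rms(w_vl),
                rms_vm=rms(w_vm),
            )
        )
        k += 1
    return out
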