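"""Digital EMG conditioning chain.

The acquisition hardware this package mirrors conditions each surface-EMG
channel with three analog stages before digitization: a 10 Hz high-pass
(motion artifacts, electrode drift), a 500 Hz low-pass (wide-band
environmental noise) and a 50 Hz notch (power-line interference).  Here the
chain is realized digitally: 4th-order Butterworth high-/low-pass sections
plus a second-order IIR notch (quality factor 30), applied causally per
channel so the pipeline remains usable sample-by-sample in real time.  A
zero-phase (forward-backward) option exists for offline batch analysis and
is flagged in the recording metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .features import EmgRecording

__all__ = ["FilterChainSpec", "FilterChain", "design_filter_chain", "apply_filter_chain"]


@dataclass(frozen=True)
class FilterChainSpec:
    """Parameters of the three-stage EMG conditioning chain.

    Cutoffs in Hz.  ``harmonic_notches`` adds notches at the 2nd and 3rd
    power-line harmonics (100/150 Hz) when they fall below Nyquist.
    """

    emg_sampling_rate_hz: float = 2000.0
    highpass_cutoff_hz: float = 10.0
    lowpass_cutoff_hz: float = 500.0
    notch_freq_hz: float = 50.0
    notch_quality: float = 30.0
    filter_order: int = 4
    harmonic_notches: bool = False
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if not self.emg_sampling_rate_hz > 0:
            raise ConfigurationError(
                f"emg_sampling_rate_hz must be positive, got {self.emg_sampling_rate_hz}"
            )
        nyq = self.emg_sampling_rate_hz / 2
        if self.lowpass_cutoff_hz >= nyq:
            raise ConfigurationError(
                f"lowpass_cutoff_hz={self.lowpass_cutoff_hz} violates Nyquist "
                f"(must be < {nyq} Hz at fs={self.emg_sampling_rate_hz} Hz)"
            )
        if self.notch_freq_hz >= nyq:
            raise ConfigurationError(
                f"notch_freq_hz={self.notch_freq_hz} violates Nyquist (must be < {nyq} Hz)"
            )
        if not 0 < self.highpass_cutoff_hz < self.lowpass_cutoff_hz:
            raise ConfigurationError(
                f"highpass_cutoff_hz={self.highpass_cutoff_hz} must lie in "
                f"(0, lowpass_cutoff_hz={self.lowpass_cutoff_hz})"
            )
        if not self.notch_quality > 0:
            raise ConfigurationError(
                f"notch_quality must be positive, got {self.notch_quality}"
            )
        if not (isinstance(self.filter_order, (int, np.integer)) and self.filter_order >= 1):
            raise ConfigurationError(
                f"filter_order must be a positive integer, got {self.filter_order!r}"
            )


@dataclass(frozen=True)
class FilterChain:
    """Designed coefficient sets (second-order sections) for one sampling rate."""

    spec: FilterChainSpec
    highpass_sos: np.ndarray
    lowpass_sos: np.ndarray
    notch_sos: np.ndarray  # stacked sections: fundamental plus optional harmonics

    @property
    def sos(self) -> np.ndarray:
        """Full cascade as one second-order-section array."""
        return np.vstack([self.highpass_sos, self.lowpass_sos, self.notch_sos])

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex response of the cascade at the given frequencies."""
        _, h = signal.sosfreqz(
            self.sos, worN=np.atleast_1d(freqs_hz), fs=self.spec.emg_sampling_rate_hz
        )
        return h

    def gain_db(self, freqs_hz) -> np.ndarray:
        h = np.abs(self.frequency_response(np.asarray(freqs_hz, dtype=float)))
        return 20.0 * np.log10(np.maximum(h, 1e-300))

    def is_stable(self) -> bool:
        """All poles strictly inside the unit circle."""
        _, poles, _ = signal.sos2zpk(self.sos)
        return bool(np.all(np.abs(poles) < 1.0))

    def filter(self, x: np.ndarray, zero_phase: bool | None = None) -> np.ndarray:
        zp = self.spec.zero_phase if zero_phase is None else zero_phase
        if zp:
            return signal.sosfiltfilt(self.sos, x)
        return signal.sosfilt(self.sos, x)


def design_filter_chain(spec: FilterChainSpec) -> FilterChain:
    """Design the high-pass / low-pass / notch cascade for ``spec``.

    Coefficients are fully reproducible from the spec; no state is stored.
    """
    fs = spec.emg_sampling_rate_hz
    hp = signal.butter(
        spec.filter_order, spec.highpass_cutoff_hz, btype="highpass", fs=fs, output="sos"
    )
    lp = signal.butter(
        spec.filter_order, spec.lowpass_cutoff_hz, btype="lowpass", fs=fs, output="sos"
    )
    notch_freqs = [spec.notch_freq_hz]
    if spec.harmonic_notches:
        notch_freqs += [
            k * spec.notch_freq_hz
            for k in (2, 3)
            if k * spec.notch_freq_hz < 0.95 * fs / 2
        ]
    notch_sections = []
    for f0 in notch_freqs:
        b, a = signal.iirnotch(f0, spec.notch_quality, fs=fs)
        notch_sections.append(signal.tf2sos(b, a))
    chain = FilterChain(
        spec=spec,
        highpass_sos=hp,
        lowpass_sos=lp,
        notch_sos=np.vstack(notch_sections),
    )
    if not chain.is_stable():  # pragma: no cover - Butterworth/iirnotch are stable
        raise ConfigurationError("designed filter chain is unstable")
    return chain


def apply_filter_chain(chain: FilterChain, recording: EmgRecording) -> EmgRecording:
    """Condition both EMG channels; returns a new recording flagged filtered."""
    if not np.isclose(chain.spec.emg_sampling_rate_hz, recording.sampling_rate_hz):
        raise ConfigurationError(
            f"chain designed for {chain.spec.emg_sampling_rate_hz} Hz but recording "
            f"is sampled at {recording.sampling_rate_hz} Hz"
        )
    return replace(
        recording,
        vl=chain.filter(recording.vl),
        vm=chain.filter(recording.vm),
        filtered=True,
        zero_phase=chain.spec.zero_phase,
    )
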