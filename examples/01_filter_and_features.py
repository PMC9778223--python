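"""Condition a noisy EMG signal and extract windowed MAV/RMS features.

Builds a 4 s synthetic EMG-like burst contaminated with 50 Hz power-line
interference and baseline drift, runs it through the digital conditioning
chain (10 Hz high-pass, 500 Hz low-pass, 50 Hz notch) and prints the
per-window features before and after filtering.
"""

import numpy as np

import kneemon as km

fs = 2000.0
t = np.arange(int(4 * fs)) / fs
rng = np.random.default_rng(0)

# 1 s burst of band-limited activity in the middle, like one contraction
envelope = np.where((t > 1.5) & (t < 2.5), 0.15, 0.0)
clean = envelope * rng.standard_normal(len(t))
contaminated = clean + 0.05 * np.sin(2 * np.pi * 50 * t) + 0.08  # mains + offset

raw = km.EmgRecording(vl=contaminated, vm=0.7 * contaminated, sampling_rate_hz=fs)
chain = km.design_filter_chain(km.FilterChainSpec(emg_sampling_rate_hz=fs))
print(f"chain gain at 50 Hz: {chain.gain_db(50.0)[0]:.1f} dB "
      f"(>=20 dB of mains rejection)")

filtered = km.apply_filter_chain(chain, raw)
for label, rec in (("raw", raw), ("filtered", filtered)):
    wins = km.windowed_features(rec, window_s=0.5)
    print(f"\n{label} MAV_VL per 0.5 s window (V):")
    print("  " + "  ".join(f"{w.mav_vl:.4f}" for w in wins))

# After filtering, the resting windows drop to ~0 (offset and mains removed)
# while the burst windows keep a ~0.08 V MAV: the contraction survives,
# the contamination does not.
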