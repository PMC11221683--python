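"""Recover the wing-beat frequency from a frequency-doubled sensor signal.

A proximity sensor with a unimodal distance response reports twice the
beat frequency when the wing stroke straddles the peak-response distance.
This script simulates a 200 Hz beat in that geometry, shows that the raw
spectral peak sits at 400 Hz, and that the estimator still reports the
200 Hz fundamental.
"""

import numpy as np
from scipy.signal import periodogram

from wingsync import SimConfig, detect_flight_bouts, \
    estimate_wingbeat_frequency, simulate_recording

cfg = SimConfig(beat_frequency_hz=200.0, rest_distance_mm=0.635,
                amplitude_mm=0.4, noise_sd=2.0, duration_s=10.0, seed=1)
rec = simulate_recording(cfg)

freqs, power = periodogram(rec.left.astype(float), fs=cfg.fs_hz,
                           detrend="constant")
raw_peak = freqs[np.argmax(power[1:]) + 1]
bouts = detect_flight_bouts(rec)
estimate = estimate_wingbeat_frequency(rec, bouts)

print(f"true beat frequency : {cfg.beat_frequency_hz:.1f} Hz")
print(f"raw spectral peak   : {raw_peak:.1f} Hz   (doubled by the sensor)")
print(f"estimator output    : {estimate:.1f} Hz   (doubling undone)")
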