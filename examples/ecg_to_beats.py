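"""Round trip: synthetic single-lead ECG -> R-peak detection -> beat series.

Renders a P-QRS-T template at each beat of a simulated rhythm, samples it at
1024 Hz, and recovers the beats with the derivative-square-integrate
detector.  Recovery should be well within 2 ms of the construction times.
"""

import numpy as np

from hrvsurv import RRSimSpec, detect_r_peaks, simulate_ecg, simulate_rr

beats = simulate_rr(RRSimSpec(seed=1))
trace = simulate_ecg(beats, sampling_rate=1024.0)
detected = detect_r_peaks(trace)

errors_ms = 1000.0 * np.abs(detected.beat_times - beats.beat_times)
print(f"ECG samples     : {trace.samples.size} at {trace.sampling_rate:.0f} Hz "
      f"({trace.duration:.1f} s)")
print(f"beats generated : {beats.n_beats}")
print(f"beats detected  : {detected.n_beats}")
print(f"max timing error: {errors_ms.max():.3f} ms (2 ms budget)")
print()
print("Sub-millisecond recovery means downstream spectral indices are")
print("indistinguishable whether computed from true or detected beats.")
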