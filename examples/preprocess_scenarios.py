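"""Compare the three preprocessing scenarios on a drift-heavy recording.

A: raw signal.  B: 0.1-20 Hz Butterworth bandpass only.  C: wavelet
baseline removal (10-level decomposition, deepest approximation
subtracted) followed by the same bandpass.
"""

import numpy as np
from scipy.signal import periodogram

from qeyed import SimConfig, apply_scenario, simulate_recording

rec = simulate_recording(SimConfig(seed=3, drift_amplitude=150.0))

for scen in ("A", "B", "C"):
    out = apply_scenario(rec, scen)
    f, p = periodogram(out.samples, fs=rec.fs)
    sub = p[f < 0.1].sum()
    print(f"scenario {scen}: sd={out.samples.std():7.2f} µV, "
          f"sub-0.1 Hz power={sub:12.1f} µV²")
# The sub-0.1 Hz power column shows what each stage removes: the bandpass
# already suppresses most drift; adding wavelet baseline subtraction (C)
# removes the residual wander the filter's slow roll-off lets through.
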