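"""Event-level scoring walkthrough: masks -> events -> tolerance matching.

Shows exactly how a predicted binary QE mask is converted to onset/offset
events and scored against the ground truth under the 100 ms rule.
"""

import numpy as np

from qeyed.event_eval import compute_metrics, extract_events, match_events

fs = 200.0
truth = np.zeros(1700, dtype=int)
truth[500:1100] = 1  # QE from 2.5 s to 5.5 s

pred = np.zeros(1700, dtype=int)
pred[512:1088] = 1  # onset 60 ms late, offset 60 ms early

t_ev = extract_events(truth, fs)
p_ev = extract_events(pred, fs)
print("truth events:", t_ev.events)
print("pred events: ", p_ev.events)

rep = match_events(p_ev, t_ev, tolerance=0.1)
print(f"onsets: TP={rep.tp_on} FP={rep.fp_on} FN={rep.fn_on}, "
      f"bias={rep.onset_biases[0] * 1000:+.0f} ms")
print(f"offsets: TP={rep.tp_off} FP={rep.fp_off} FN={rep.fn_off}, "
      f"bias={rep.offset_biases[0] * 1000:+.0f} ms")

metrics = compute_metrics([rep], [pred], [truth])
print(f"PPV={metrics.ppv:.2f} SEN={metrics.sen:.2f} F1={metrics.f1:.2f} "
      f"accuracy={metrics.accuracy:.3f} onset MAE={metrics.mae_onset_ms:.0f} ms")
# Both boundaries fall inside the tolerance, so both count as true
# positives; the signed biases (+60/-60 ms) carry the timing error that
# the MAE summarizes.
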