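"""Train a CNN-GRU Quiet-Eye detector on a small synthetic cohort and score
it at the event level.

Scaled down (8 participants, 30 epochs) so it runs in a couple of minutes
on a laptop CPU; the full study-scale recipe lives in qeyed.benchmarks.
"""

from qeyed import (
    ModelSpec,
    SimConfig,
    TrainConfig,
    apply_scenario,
    build,
    extract_segments,
    fit,
    predict,
    simulate_cohort,
)
from qeyed.event_eval import evaluate_masks

cohort = simulate_cohort(SimConfig(seed=5), n_participants=8)
clean = [apply_scenario(r, "C") for r in cohort]
segs = [s for r in clean for s in extract_segments(r)]

# hold out the last participant entirely
train_set = [s for s in segs if s.participant_id != "P08"]
test_set = [s for s in segs if s.participant_id == "P08"]
print(f"training on {len(train_set)} segments, testing on {len(test_set)} "
      f"from an unseen participant")

spec = ModelSpec("cnn_gru", params={"pool": 8})
cfg = TrainConfig(epochs=30, batch_size=16, seed=0, validation_fraction=0.0)
trained = fit(build(spec, 1700, seed=0), train_set, cfg)
print(f"final training loss {trained.history[-1]['loss']:.3f}, "
      f"per-sample accuracy {trained.history[-1]['acc']:.3f}")

traces = predict(trained, test_set)
rep = evaluate_masks([t.mask for t in traces], [s.mask for s in test_set],
                     fs=200.0, tolerance=0.1)
print(f"event PPV={rep.ppv:.2f} SEN={rep.sen:.2f} F1={rep.f1:.2f}; "
      f"onset MAE={rep.mae_onset_ms:.0f} ms, offset MAE={rep.mae_offset_ms:.0f} ms")
# F1 counts onset/offset events matched within the 100 ms tolerance; the
# MAEs say how far the matched event boundaries sit from the ground truth.
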