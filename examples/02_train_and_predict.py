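"""Train a desk-scale predictor and evaluate it on held-out sequences.

Trains the tiny configuration (stem 32, four 16-channel blocks) for three
epochs on 20,000 simulated rows with the soft-classification loss and
one-cycle schedule, then predicts the test set with test-time augmentation
and reports Pearson/Spearman against the simulator oracle with a bootstrap
interval. Expect a Pearson around 0.9 in a few CPU-minutes; the full-size
configurations train the same way, just slower.
"""

import numpy as np

import legnet as lg

ds = lg.simulate_dataset(lg.SimulatorConfig(n_sequences=20_000, n_test=1_000, seed=1))

train_cfg = lg.TrainConfig(batch_size=256, epochs=3, seed=7, frame_length=80)
model, log = lg.train_predictor(ds.train, train_cfg, lg.tiny_config())
for entry in log:
    print(f"epoch {entry['epoch']}: KL loss {entry['mean_loss']:.4f} "
          f"(lr {entry['lr']:.2e}, {entry['wall_time_s']:.0f}s)")

test_seqs = [r.insert for r in ds.test]
pred = lg.predict_with_tta(model, test_seqs)
truth = np.array([ds.truth[s] for s in test_seqs])

report = lg.bootstrap_correlations(pred.values, None, truth, resamples=10_000, seed=1)
ci = report.bootstrap_summary["pearson_a"]
print(f"\nheld-out Pearson {report.pearson:.3f} "
      f"[{ci['p2.5']:.3f}, {ci['p97.5']:.3f}] (10,000-resample bootstrap)")
print(f"held-out Spearman {report.spearman:.3f}")
print("-> the model recovers the planted sequence-to-expression grammar")
print("   from noisy single-cell sorting-bin measurements.")
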