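"""Score single-nucleotide variant effects by prediction differencing.

Trains a quick model, then estimates the effect of every possible
substitution at each position of one insert (a mutational scan) and prints
the strongest activating and repressing variants. The effect of a variant
is predict(alt) - predict(ref), both with test-time augmentation.
"""

import numpy as np

import legnet as lg

ds = lg.simulate_dataset(lg.SimulatorConfig(n_sequences=10_000, n_test=200, seed=2))
model, _ = lg.train_predictor(
    ds.train,
    lg.TrainConfig(batch_size=256, epochs=2, seed=3, frame_length=80),
    lg.tiny_config(),
)

ref = ds.test[0].insert
variants = []
for pos, base in enumerate(ref):
    for alt in "ACGT":
        if alt != base:
            variants.append(lg.VariantRecord(ref, ((pos, base, alt),)))

effects = lg.variant_effects_batch(model, variants)

order = np.argsort(effects)
print(f"reference insert: {ref}")
print(f"scanned {len(variants)} substitutions")
worst, best = variants[order[0]], variants[order[-1]]
print(f"strongest repressing variant : pos {worst.substitutions[0][0]:2d} "
      f"{worst.substitutions[0][1]}->{worst.substitutions[0][2]}  "
      f"delta = {effects[order[0]]:+.3f} bins")
print(f"strongest activating variant : pos {best.substitutions[0][0]:2d} "
      f"{best.substitutions[0][1]}->{best.substitutions[0][2]}  "
      f"delta = {effects[order[-1]]:+.3f} bins")
print(f"median |effect| = {np.median(np.abs(effects)):.3f} bins")
print("-> positions inside planted motifs show much larger effects than")
print("   background positions; the sign says whether the variant raises")
print("   or lowers predicted expression.")
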