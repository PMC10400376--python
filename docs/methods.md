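# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic data generator used for desk-scale
validation, and the numerical and design choices that were genuinely open.

## The measurement model and the soft-classification transform

The data the predictor consumes come from sorting-based reporter assays:
cells carrying a reporter driven by a short variable insert are sorted into
18 fluorescence bins (numbered 0–17), and a sequence's expression is the
mean bin number over the cells in which it was observed. Sequences seen in
a single cell ("singletons", a majority of a typical train table) have
integer expression values and carry the most measurement noise.

Instead of regressing the scalar directly, the measured expression *e* is
treated as an uncertain estimate of the true expression with

    true expression ~ Normal(mu = e + 0.5, sd = 0.5),

and the training target is the 18-vector of probabilities of that Gaussian
falling in each bin range: bin 0 ↦ (−∞, 1], bins 1–16 ↦ [i, i+1), bin 17 ↦
[17, ∞). The boundary bins absorb the tails, so the vector sums to exactly
1 and no renormalisation is applied (for e ≈ 0 the mass leaking below bin 0
is ≥ 2σ away and negligible; we do not renormalise). The loss is
KL(target ‖ model output), averaged over the batch — equal to cross-entropy
up to the target-entropy constant, with this direction chosen because the
target is the data-derived distribution. Scalar predictions are decoded by
soft-argmax, Σᵢ i·pᵢ. For integer and half-integer e in the interior the
decode is exact to ≤ 1e-6; over [3, 14] the absolute round-trip error is
below 0.005 (verified against a quadrature oracle in the tests).

## Architecture

The predictor is a stride-1, 'same'-padded, fully convolutional network on
6×L input frames (4 one-hot nucleotide channels + constant is_singleton and
is_reverse channels; L = 150 by default). Stem: kernel-7 convolution to 256
channels + BatchNorm + SiLU. Six blocks with output widths (128, 128, 64,
64, 64, 64), each:

1. pointwise expansion from the block input width I to E + BN + SiLU;
2. kernel-7 spatial convolution (grouped or depthwise) on E channels + BN + SiLU;
3. squeeze-and-excitation gate;
4. pointwise projection back to I + BN + SiLU;
5. channel concatenation of block input and projected branch (2I channels);
6. kernel-7 "resize" convolution to the block output width + BN + SiLU.

Head: pointwise convolution to 18 channels (optionally SiLU), channel-wise
global average pooling, softmax. Only the stem and the two kernel-7
convolutions per block widen the receptive field:
1 + 6 + 6·(6+6) = **79 bp**, matching the ~80-bp variable insert.

Two reference configurations:

* **original**: grouped spatial convolutions (16 channels per group),
  expansion E = 2·I, custom SE gate: squeeze by global average, a bilinear
  form whose (H, E, E) weight tensor is stored in rank-86 canonical
  polyadic factors (H = block output width // 11, no bias), SiLU, a
  bias-free linear back to E, sigmoid. Total trainable parameters:
  **1,852,846** exactly.
* **optimized**: depthwise spatial convolutions, EfficientNetV2 expansion
  policy (E = 4·I), standard EfficientNetV2 SE (hidden = I // 4, biased
  linears), no activation before the final pooling; ~2.13M parameters.

The internal widths of the original configuration are not uniquely
determined by the published description; the published parameter total was
treated as a binding constraint and the free knobs (expansion ratio, group
size, SE hidden width rule, CP rank, bias placement) were solved for it by
exhaustive search. The solution used here — ratio 2, group size 16,
H = out//11, rank 86, bias-free SE — also reproduces the ~2.1M total of
the optimized variant under its standard EfficientNetV2 options, which is
the main evidence this convention family is the intended one. Checkpoint
sidecars record these conventions. Parameter counting includes convolution,
linear and CP-factor weights, biases and BatchNorm affine terms; BatchNorm
running statistics are buffers, not parameters.

All layers are implemented in NumPy with hand-written backpropagation
(no deep-learning framework is assumed by the runtime environment); every
backward pass is verified against central finite differences in the test
suite. Convolutions run as one batched GEMM per kernel tap on a
channels-first layout. Initialisation follows the EfficientNetV2 scheme:
convolution weights ~ Normal(0, √(2/fan_out)), BatchNorm γ = 1 / β = 0,
linear weights uniform in ±1/√fan_out; all seeded, with every random
stream derived from a named substream of one user seed.

## Training

Defaults mirror the reference regime: AdamW (decoupled weight decay 0.01,
applied to weights only, not biases or normalisation terms), one-cycle
learning rate with exactly two cosine phases peaking at max_lr = 0.005
(start max_lr/25, final max_lr/1e4, warmup fraction 0.3 — the phase split
and endpoint divisors follow common one-cycle practice; only the peak,
phase count and cosine shape are prescribed), batches of 1024. Choosing the
Lion optimizer automatically applies its authors' 10-fold rules (lr/10,
weight decay ×10). ReduceLROnPlateau (factor 0.1) is available as the
alternative scheduler and requires a validation split; k-fold splits are
contiguous blocks of a seeded shuffle.

Orientation augmentation: each sampled sequence is encoded in forward or
reverse-complement orientation (is_reverse channel 0/1), randomly per
sample per epoch; both forms appear in expectation at half the memory of
strict doubling, and a strict-doubling mode exists for exactness. Within an
epoch, samples are drawn without replacement from permutation chunks.
Inference always sets is_singleton = 0 and averages the soft-argmax decodes
of both orientations (test-time augmentation). Note that TTA output is
invariant to reverse-complementing the *input* only for models insensitive
to the is_reverse channel; for general models the two orientation labels
swap, and only that weaker set-level symmetry holds.

Seed ensembles average the per-model TTA expression predictions.

## Variant effects

A variant record is a reference insert plus jointly applied substitutions
(0-based positions within the insert; the flank is fixed context and never
mutated). The effect is predict(alt) − predict(ref), positive when the
variant raises expression; antisymmetry and zero self-effect hold exactly
by construction. Drift-style evaluation groups (ref, alt, observed Δ) pairs
by substitution count and reports Pearson/Spearman per group, flagging
groups that are too small or degenerate instead of erroring.

## Cold-diffusion design

The degradation process is memoryless point substitution: an event picks a
position uniformly and replaces the current base with one of the other
three uniformly, with no protection against reverting earlier edits. After
k events on an L-mer the expected changed fraction is
(3/4)(1 − (1 − 4/(3L))^k) ≈ 0.745 for L = 80, k = 300 — the basis for the
300-mutation ceiling treated as "fully scrambled". The implementation
composes events as additive offsets in Z₄, which is distributionally
identical and vectorises.

The generator reuses the predictor trunk without the pooling head, emitting
per-position 4-way logits; conditioning (declared mutation count / 300,
expression / 17) enters as two constant channels that are concatenated to
the input *and re-injected at the input of every block* — the standard
practice for conditional denoisers, adopted here after desk-scale
experiments showed that input-only conditioning is progressively ignored as
the reconstruction loss converges (the copy signal dominates). The trunk
architecture for the generator is this package's design choice. Training
draws n ~ uniform{0..300}, corrupts, and minimises mean per-position
cross-entropy to the original sequence (reference regime: 200 epochs,
AdamW, lr 0.001, batch 1024, 1000 batches/epoch, 4:1 train:validation).
Large batches matter disproportionately for the generator at desk scale:
the expression channel contributes a weak, low-variance gradient that
small-batch noise drowns out, so desk-scale presets shrink batches per
epoch rather than the batch size.

Generation starts from a uniformly random insert with counter n =
iterations (default 100): denoise with declared count n, decrement, and —
unless finished — re-corrupt with max(n − shift, 0) substitutions (shift
30). Decoding is per-position argmax by default; a stochastic decode
(softmax sampling with a configurable temperature, 0.5 recommended) is
provided because argmax suppresses the small conditional logit shifts that
carry the expression conditioning once the denoiser becomes confident —
at desk scale the stochastic decode is what realises target steering. The schedule
declares `shift` more mutations than it re-introduces, deliberately
overstating the corruption so the model keeps editing; the loop ends when
the declared counter reaches 0 (default) or, under the alternative
`corruption` stop rule, as soon as the re-corruption count hits 0. Both
rules are implemented because the published loop description admits either
reading; "n−1−shift" is read as (n−1) − shift clamped at zero, since the
100-iteration/shift-30 run is otherwise impossible. Designs are verified by
scoring with an independently trained predictor.

## The synthetic assay

The simulator supplies ground truth the real assay cannot: a deterministic
oracle. Five position-weight matrices (length 6–10, sparse-Dirichlet
columns, so near-consensus sites score strongly) are drawn per seed with
signed effects (+2, +1.5, +1, −1, −1.5); an insert's raw score is the sum
of each motif's best sliding-window log-odds times its effect
(forward-strand only by default, so strand asymmetry is a real feature for
the is_reverse channel to exploit). An affine map calibrated once per seed
on a fixed 2048-sequence reference sample (mean → 8.5, ±3 sd → the full
range) converts scores to expression, clamped to [0, 17].

Measurement: a sequence is observed in m ~ 1 + Poisson(λ) cells; each cell
lands in bin clamp(round(e_true + Normal(0, 1)), 0, 17); the recorded value
is the mean bin. λ = 1.5 for train tables (singleton fraction e^−1.5 ≈ 0.223,
integer-valued singletons by construction) and λ = 20 for test tables,
mimicking high-replication held-out measurements. Round-to-nearest with
clamping is the simplest bin law consistent with the Gaussian noise
heuristic above. Train/test sequence sets are disjoint by construction and
the truth table is refused by the training-data reader (file-name guard).

What the simulator does **not** emulate: biological motif content, motif
interactions or saturation, chromatin or media effects, sorter gating
artefacts (the low-expression "wall" of real data), or the 10⁶–10⁷-row
scale. A green desk-scale test therefore establishes that the training
stack can recover a planted, additive, motif-based grammar from noisy
sorting-bin measurements — not that it reproduces published full-scale
correlations.

## Desk-scale budgets

CPU-only tests use the tiny configuration (stem 32, four 16-channel
blocks) or a micro variant, and train on the 80-bp inserts directly: the
default flank is an all-N policy region whose positions encode as all-zero
columns, so the 150-frame padding would add pure zeros at ~1.9× the
compute. The 150-bp frame contract itself is asserted in the codec and
architecture tests. The parameter-recovery check (tiny network, 50,000
rows, 5 epochs) reaches held-out Pearson ≈ 0.93 against the oracle in
single-digit CPU-minutes; the ensemble and generator properties run on
further scaled-down configurations because they are scale-free.

## Numerical choices and degenerate inputs

* Normal CDF via `scipy.special.ndtr`; bin targets sum to 1 to ≤ 1e-12.
* KL clamps model probabilities at 1e-12 (softmax outputs cannot be zero;
  hand-built inputs can) and defines 0·log 0 = 0.
* Correlations require n ≥ 3 and report NaN-with-reason for constant
  vectors; bootstrap resamples that become constant are dropped and
  counted. Spearman uses midranks. The paired bootstrap applies identical
  resample indices to both prediction sets.
* BatchNorm: eps 1e-5, momentum 0.1, biased variance for both batch and
  running estimates; float32 throughout.
* Training aborts with a diagnostic (step and learning rate) on a
  non-finite loss rather than continuing.
* Significance testing between dependent correlations is out of scope; the
  paired-bootstrap difference distribution is the provided alternative.

## Known limitations

* No GPU path; full-size configurations train impractically slowly in this
  NumPy implementation (they build, run forward/backward and are used for
  introspection; desk-scale configurations are for learning experiments).
* The exact internal widths of the historical challenge model are not
  public in the main text; the parameter-count-constrained reconstruction
  here is one valid solution, recorded in checkpoint sidecars.
* The generator's low-expression behaviour is weaker than its mid/high
  range, consistent with the scheme's known bias; no guarantee is made
  there.
* Desk-scale design quality is compute-limited: the expression
  conditioning is a weak learning signal that needs both the reference
  batch size (1024) and far more samples than a CPU test budget allows.
  At the bundled scale the target-vs-predicted correlation of the design
  loop falls short of the strong agreement reachable at full scale — the
  corresponding stress test in the acceptance suite documents the shortfall
  rather than hiding it, and the copy-task, loop-mechanics and
  reproducibility checks around it pass.
* Real-data file formats are supported (plain TSV tables, FASTA, variant
  TSV) but no attempt is made to reproduce published full-scale results.
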