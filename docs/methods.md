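# Methods

This note documents the model implemented by `neuroplast`, its assumptions,
the parameters that matter, and the numerical choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The degeneration-with-plasticity model

The simulation abstracts progressive cortical neurodegeneration as the
irreversible loss of synapses in a trained convolutional classifier, and
neuroplasticity as retraining of the surviving synapses between episodes of
loss.

**Eligible synapses.** A "synapse" is one entry of a multiplicative weight
tensor of a convolutional or dense layer. Biases and batch-norm affine
parameters are *not* ablatable under the default policy: they model
excitability offsets and gain control rather than connections. Because
full-scale parameter totals are sometimes quoted with all parameters
included, `count_parameters` exposes the eligibility policy as a switch
(`"conv_dense_weights"`, the default, vs `"all"`); for the bundled
VGG19-BN spec the two bases are 20,024,000 vs 20,040,522 — a 0.08%
difference that does not alter any schedule arithmetic at the reported
precision.

**Injury schedule.** Each iteration ablates `round(γ · surviving)`
coordinates drawn uniformly *without replacement from all eligible tensors
pooled* — a single global rate, not per-layer quotas, which is what "uniformly
dispersed" means here (a per-layer stratified mode is not provided; the
pooled draw already gives every coordinate identical marginal probability,
verified by a chi-square test). The cumulative injured fraction after *n*
iterations is `1 − (1−γ)^n` up to integer rounding; with ~10⁵ eligible
weights the deviation is below 10⁻⁴ per step. Rounding of the per-step count
is nearest-integer (Python's ties-to-even, the unbiased choice); `floor` and
`ceil` modes exist because the convention at full scale is not documented
anywhere authoritative.

**Irreversibility and pinning.** The `AblationMask` is monotone by
construction (asserted after every step). During retraining the pin is
two-sided: masked gradients are zeroed *and* masked weights are reset to
exactly 0.0 after every optimizer step. Either side alone is insufficient —
momentum buffers carry stale velocity through a gradient-only mask, and a
value-only reset changes the effective update of neighbouring coordinates.
Zero-pinning is re-asserted at every evaluation point of an experiment.

**Retraining.** Each injury step is followed by `TrainingConfig` retraining
with a *freshly created* optimizer (no velocity carried across injury
events), defaulting to 3 epochs at lr 0.001, momentum 0.9, batch 128 — the
same protocol as baseline training. The injured state is always evaluated
*before* the first retraining gradient, so the paired injured/retrained
curves bracket the contribution of plasticity at each iteration.

**Replication.** Replicates restore the pristine baseline checkpoint rather
than retraining from scratch; the replicate seed drives only the ablation
order (injury uses a dedicated RNG stream, independent of the training
stream). This isolates ablation-order randomness, which is the quantity the
replicate dispersion is meant to measure.

## Readouts

**RDM.** Dissimilarity is `1 − Pearson` between penultimate-layer activation
vectors ("penultimate" = input of the final dense transform, the standard RSA
readout point). Comparisons use Kendall's τ-b on strictly-upper-triangle
entries; τ-b handles the ties that quantized dissimilarities produce and is
the common RSA choice (the τ variant used at full scale is not documented;
this default is stated rather than guessed). A full test-set RDM is
quadratic in stimuli, so experiments use a fixed class-stratified subsample
(default 20 per class) chosen once per experiment — the statistic's
definition is unchanged, only its stimulus support. Constant activation rows
(possible at extreme injury) make Pearson undefined; such pairs are assigned
dissimilarity 1 with a warning, which is neutral for rank statistics.

**Neural predictivity.** Per region and split: PCA fit on the training
stimuli reduces activations to `min(1000, features, n_train−1)` components;
25-component PLS maps reduced activations to the recordings; per-neuron
Pearson on held-out stimuli is aggregated by the median; splits (default ten
random 90/10 partitions) are averaged; regions average into the composite.
Recordings are z-scored per neuron on the training split before the PLS fit,
which makes the score exactly invariant to per-neuron affine rescaling of
the recordings (Pearson invariance) — without it, multi-target PLS weights
neurons by variance and the invariance holds only approximately. The split
scheme and neuron aggregation statistic of the full-scale methodology are
not published in detail; the choices here (10 × 90/10, median) are the
common configuration and are configurable.

**Synthetic regions.** Because biological recordings are out of scope, each
"region" is a `RecordingsMatrix` generated as a fixed random linear readout
(plus Gaussian noise, default sd 0.1) of the *healthy* baseline's
activations at one depth — by default every pooling stage plus the
penultimate layer, giving a V1-like → IT-like hierarchy of four regions for
the desk-scale net. Scores against these fixtures measure recovery of the
healthy representational basis, not brain-likeness; absolute values are not
comparable to published neural-benchmark scores.

## The synthetic stimulus world

`generate_dataset` emulates the *structure* of the standard 10-class 32×32
RGB benchmark: balanced classes, fixed disjoint train/test split (disjoint
by construction — independent RNG streams), pixel values in [0, 1]. Class
identity is a procedural pattern family (disk, square, diamond, ring, cross,
two stripe frequencies, checkerboard, wedge, bar) with per-sample jitter in
position, scale, and orientation. Color is deliberately only weakly
class-linked — a wide hue jitter around overlapping class hue centers —
because a unique color per class makes the task solvable by channel means
alone (a pilot with class-locked colors gave a 100% baseline, structurally
unlike natural object recognition). Additive Gaussian pixel noise (default
sd 0.05 on the [0,1] scale, clipped) models sensor noise.

Desk-scale defaults, chosen once for a single-CPU budget: 150 training and
50 test images per class, 30 baseline epochs at the standard protocol. At
lock time this gave a 0.92 baseline test accuracy.

**What a green test does and does not establish.** The generator produces
linearly-separable-above-chance, CNN-learnable classes with controlled
difficulty; it does not produce natural-image statistics, within-class
texture diversity, or inter-class visual confusability beyond what the
shape families share. Consequently the *qualitative* decline-and-recovery
properties transfer, but quantitative values (baseline accuracy, recovery
margins, τ levels) are properties of this synthetic world, not predictions
for natural-image models.

**Known desk-scale deviation.** At full scale, a single 20% injury crashes
accuracy to chance (10%) before retraining. The desk-scale 3-conv-block
network does not reproduce this: injured accuracy settles around 0.2–0.3 in
early iterations. Corrupted activations compound multiplicatively with
depth, so a 16-conv-layer model collapses where a 3-layer model only
degrades; deepening the network or hardening the stimulus world would trade
this fidelity against the CPU budget and the stated desk-scale architecture.
The corresponding acceptance check is kept at its stated strength and is
expected to fail on this configuration; all other decline-and-recovery
properties (recovery dominance, RDM and predictivity recovery, the
compressed-baseline analogue) are asserted and pass at desk scale.

## The compressed baseline

Structured pruning removes whole conv filters / dense hidden units by
ascending L1 norm of their weights, greedily one unit at a time with FLOP
re-evaluation after each removal, never emptying a layer and never touching
the output layer. Dependency propagation on sequential graphs: removing a
conv filter deletes its bias, its batch-norm parameters and running
statistics, and the matching input channels (or flattened dense columns) of
the next weighted layer. FLOPs are counted as multiply-accumulates
(`k²·c_in·c_out·A` per conv, `in·out` per dense; pooling, normalization and
nonlinearities count zero). L1 norms are compared raw, the magnitude-pruning
convention; a size-normalized mode exists for architectures with very
unequal filter sizes. Pruning is one-shot followed by a single fine-tune
(default: the standard training config); whether full-scale compression
interleaved fine-tuning is undocumented, and an iterative mode is out of
scope.

## Numerical and engineering choices

* The CNN engine (`neuroplast._engine`) is plain NumPy with hand-derived
  backward passes (the target environment ships no autodiff framework).
  Convolutions are stride-1 im2col + GEMM with 2×2 max-pool downsampling;
  gradients are verified against central finite differences in the suite.
* float32 parameters by default; float64 available for gradient checking.
* Batch norm uses biased batch variance, momentum 0.1 running statistics,
  eps 1e-5; evaluation always uses running statistics, so accuracy, RDMs and
  predictivity are deterministic for fixed weights — including right after
  an injury step, when running statistics are deliberately stale (the
  injured network is read out as-is, without recalibration).
* Every stochastic component (weight init, batch shuffling, ablation order,
  stimulus generation, recordings, CV splits) draws from its own
  `SeedSequence`-derived stream, so runs are bitwise reproducible from the
  seed tuple and sub-seeds never collide.
* Determinism caveat: bitwise reproducibility holds per platform/BLAS; across
  platforms, floating-point reduction order may differ.

## Limitations

* Sequential architectures only (no residual/branching graphs) — both for
  pruning propagation and activation capture.
* No data augmentation, learning-rate schedules, or pretraining.
* Injury is binary and uniform; gradual weight decay (tau-pathology-like)
  and spatially structured lesions are out of scope.
* Desk-scale depth limits the injured-state collapse fidelity (see above).
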