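# Methods

## The task and the model

The package classifies fixed-length 41-bp promoter windows centred on a
candidate cytosine as genuine or spurious 5-methylcytosine (5mC) sites. The
classifier is a hybrid network:

1. **Feature coding.** Each window is encoded twice — one-hot (4 × 41, row
   order A, C, G, T) and nucleotide chemical property (NCP, 3 × 41, with
   A → (1,1,1), C → (0,1,0), G → (1,0,0), T → (0,0,1)) — and the two
   matrices are row-stacked into a 7 × 41 input. Note that re-deriving the
   NCP bits from the usual ring/functional-group/hydrogen-bond table with
   "strong H-bond (C,G) = 1" would give A = (1,1,0) and T = (0,0,0); the
   vectors above follow the established NCP convention in the 5mC-prediction
   literature and are what the downstream shapes assume. With `allow_n`, an
   `N` becomes an all-zero column in every scheme; by default non-ACGT
   characters are rejected.
2. **Local features: CBAM-augmented DenseNet.** The 7 × 41 matrix enters as
   a single-channel 2-D map (height = 7 encoding rows, width = 41
   positions); there is deliberately no initial convolution, so the first
   dense block consumes the raw coding directly. Each dense-block layer is
   batch-norm → ReLU → 3 × 3 same-padded convolution producing
   `growth_rate` new channels, followed by a CBAM attention module
   (channel attention: global max- and average-pooled channel vectors
   through one shared two-layer bottleneck, summed, logistic-gated; then
   spatial attention: channel-wise max and mean maps stacked, convolved to
   one map, logistic-gated). Layer *l* consumes the channel-concatenation of
   the block input and all previous layer outputs, so a block adds
   `L × growth_rate` channels. Between blocks a transition layer applies
   batch-norm, a 1 × 1 convolution compressing channels to
   `ceil(compression × C)`, and 2 × 2 average pooling.
3. **Global features: BiGRU + self-attention.** The final C × H × W map is
   read out width-major as a W-long sequence of (C·H)-dimensional vectors,
   passed through a bidirectional GRU (standard gating with distinct reset
   and update weights) and a scaled dot-product self-attention layer
   (Q/K/V linear maps, similarities scaled by 1/√d and softmax-normalised
   row-wise).
4. **Classification.** The attention context rows are mean-pooled over
   positions, passed through dropout and one fully connected layer, and
   softmax gives the two class probabilities; the class-1 probability is
   the model score, thresholded at 0.5 by default.

Training minimises class-weighted cross-entropy with Adam. The positive
weight defaults to the negative:positive count ratio of the training data
(`w_pos = n_neg / n_pos`, `w_neg = 1`; 7.6 on the reference benchmark
composition), which boosts the minority class in backpropagation instead of
resampling. Evaluation follows the usual confusion-matrix metrics (Sn, Sp,
Acc, MCC, F1), ROC-AUC with midrank tie handling, step-wise PR-AUC, and
stratified five-fold cross-validation whose summary is the arithmetic mean
of the fold reports.

## Numerical engine

No deep-learning framework is used: the network runs on a small tape-based
reverse-mode autodiff engine over numpy (`promoter5mc.autodiff`). Each
operation (elementwise arithmetic, matmul, im2col-based stride-1
convolution, ceiling-mode average pooling, reductions, softmax, the usual
activations) carries a vectorised backward rule; gradients of broadcast
operands are summed back to the operand shape. The engine is deliberately
transparent — every block is testable against scalar-loop reference
implementations, and the whole forward/backward path is deterministic for a
fixed seed on one platform. Parameters default to float64; the assembled
model casts itself to float32 (configurable via `ModelConfig.dtype`) for
throughput, and scalar constants adopt the graph dtype so no silent
promotion occurs.

## Architectural and numerical choices

- **2-D geometry.** The 3 × 3 convolutions and 2 × 2 pooling are inherently
  two-dimensional, so the merged matrix is treated as a 7-high, 41-wide map
  rather than a 7-channel 1-D signal. A 1-D variant would be a reasonable
  alternative; it is not implemented.
- **Ceiling-mode pooling.** Output sizes are `ceil(extent / 2)` and edge
  windows average only the cells that exist (a constant map pools to the
  same constant). Floor mode would collapse the 7-row height to zero after
  three transitions; ceiling mode yields 7 → 4 → 2 → 1, which is what makes
  a four-block architecture realisable on this input, and can never produce
  a zero-size map at any depth.
- **CBAM placement.** Attention is applied to the output of *every*
  convolutional layer inside a block (not once per block). `--no-cbam`
  (config `use_cbam=False`) disables it for ablation.
- **GRU gating.** Reset and update gates use distinct weight matrices
  (W_r/U_r vs W_z/U_z); a formulation in which the two gates share weights
  would make the reset gate redundant.
- **Attention scaling.** Similarities are scaled by 1/√(attention_dim) for
  numerical stability; `attn_scale=False` gives the plain dot product.
- **Pooling after attention** is a parameter-free mean over positions.
- **Batch normalisation** uses batch statistics (momentum 0.1 running
  averages) in training and the stored running statistics in evaluation;
  the transition's batch-norm sits before its 1 × 1 convolution.
- **Degenerate inputs.** The CBAM bottleneck width clamps to ≥ 1 channel;
  log-probabilities are clamped at 1e-12; metrics with zero denominators are
  0 by convention (MCC included); the stratified splitter rounds half-up per
  class with the remainder staying in train.

## Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| num_dense_blocks | 4 | selected by the block-count ablation (more blocks overfit) |
| layers_per_block | 4 | convolutional layers per dense block |
| growth_rate | 12 | channels added per layer |
| compression | 0.5 | transition channel-keep fraction |
| cbam_reduction | 8 | channel-attention bottleneck divisor |
| spatial_kernel | 7 | spatial-attention convolution size |
| gru_hidden | 64 | per-direction GRU width |
| attention_dim | 64 | Q/K/V dimension |
| dropout | 0.2 | on the pooled context |
| epochs / batch / lr | 30 / 64 / 1e-3 | Adam, early-stop patience 5 |

Only the dense-block count is dictated by the task; the rest follow common
DenseNet/CBAM practice and are config-overridable. `ModelConfig.small()`
(layers 2, growth 8, reduction 4, spatial kernel 3, GRU/attention width 24,
dropout 0.1; ~22k parameters) and `TrainSpec.small()` (5 epochs, batch 128)
are the CPU-scale defaults used by the test suite, the worked example and
the acceptance script; the full-size default configuration trains the same
way, only slower.

## Synthetic data: what it emulates and what it does not

`promoter5mc.synth` generates labelled windows with the structure the model
assumes: 41-bp windows whose centre base is forced to C in *both* classes
(as in the real task, where every window centres on a candidate cytosine —
this also prevents the centre base from becoming a degenerate shortcut
feature), a planted degenerate motif (PWM) present only in positives, i.i.d.
background elsewhere, optional label noise, and a configurable
negative:positive imbalance defaulting to 7.6 to mirror the reference
benchmark. The canonical fixture (`default_benchmark_spec`) is 800
positives / 6,080 negatives with a width-6 PWM (0.85 consensus weight per
column) at offset 10 on uniform background.

What it does **not** emulate: real promoter base composition and CpG-island
structure, sequence redundancy (the real benchmark is CD-HIT-filtered at
80 %), tissue effects, or distributed/contextual signal — the synthetic
class signal is a single local motif. Passing the end-to-end tests
therefore shows that the architecture, loss, weighting and protocol work as
specified and can extract a planted signal under realistic imbalance; it
says nothing about accuracy on real 5mC data, which requires the full
multi-million-window benchmark and much longer training. For the same
reason the full-scale headline metrics of large-benchmark studies are out
of reach at desk scale, and parameter counts here (≈ 2 × 10⁵ at the default
configuration, ≈ 2 × 10⁴ for `small()`) sit well below the millions used in
full-scale work.

## Problem sizes used by tests and the acceptance script

The end-to-end checks train `ModelConfig.small()` on the 6,880-window
fixture with an 8:2 stratified split (5,504 train / 1,376 held out), 5
epochs for the headline run and 2 epochs per arm for the weighted-versus-
unweighted sensitivity comparison over three seeds; cross-validation
protocol checks use a 120-window set with a two-block model for speed.
These sizes were chosen once as the package's standard desk-scale
experiment. Typical fixture results (seed 1): held-out AUC ≈ 0.99,
MCC ≈ 0.76, Sn ≈ 0.93.

## Known limitations

- Training is single-threaded numpy; wall-clock scales linearly with
  windows × epochs (~13 s per epoch on the fixture at `small()` size).
- The engine implements only what the model needs (stride-1 convolution,
  kernel-=-stride pooling); it is not a general framework.
- Determinism is guaranteed per platform/BLAS build, not bit-identical
  across different BLAS implementations.
- `run_cv` retrains from scratch per fold; no warm starting.
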