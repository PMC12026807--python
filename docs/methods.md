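# Methods

## Problem and model

The task is binary classification of sgRNA–target-DNA alignments: does
Cas9 cleave this candidate locus? Inputs are fixed-length alignments (L=23
for mismatch-only data; L=24 when the alignment carries an indel column,
gap symbol `_`), outputs are positive-class probabilities from a 2-way
softmax.

### Encoding

Channel order is fixed as `[A, T, C, G, _]` (index 0–4). Each strand is
one-hot encoded as an L×5 matrix; the fused L×7 matrix is the element-wise
OR of the two one-hot rows plus two direction bits. Direction convention:
`[1,0]` when the sgRNA symbol's channel index is lower than the DNA
symbol's, `[0,1]` when higher, `[0,0]` on a match. Any convention that
distinguishes the two orientations restores injectivity; this one is
chosen for being order-free to state and is verified exhaustively in the
tests (24 ordered symbol pairs map to 24 distinct 7-vectors). Sequences
are upper-cased on ingest and `U` is mapped to `T`, since guide sequences
are often provided as RNA.

Invariants: every one-hot row sums to 1; every fused row sums to 1 (match)
or 3 (mismatch/indel: two base bits plus one direction bit); a double-gap
column is rejected as an invalid alignment.

### Network

The encoded matrices are treated as single-channel 2-D grids of height L
and width 7 (the two 5-wide matrices are zero-padded), so the square
kernels of the convolutional blocks apply uniformly.

- **DT block** (one per matrix): 3×3 same-padded convolution with F
  filters → batch normalization → ReLU. F defaults to 32, giving a trunk
  of C = 3F = 96 channels after concatenation — divisible by the four gDP
  branches, as required. All widths are configuration-exposed.
- **gDP block**: four depthwise-separable branches (kernels 1/3/5/7);
  each branch's pointwise 1×1 convolution emits C/4 channels so the
  concatenation restores C for the residual addition. With zero branch
  weights the block is exactly the identity — a tested invariant.
- **CSAM block**: channel attention uses global average and max pooled
  channel descriptors through a shared two-layer perceptron with
  reduction ratio r=8 (the conventional value for this attention family),
  summed and passed through a sigmoid; spatial attention concatenates the
  channel-wise mean and max maps and applies a 7×7 same-padded
  convolution and sigmoid. The two reweighted maps are concatenated (2C),
  reduced to C by a 1×1 convolution, and residual-added; zero fusion
  weights again give the identity.
- **MLP head**: flatten → 80 (ReLU) → dropout 0.35 → 20 (ReLU) → dropout
  0.35 → 2. Dropout sits after the 80- and 20-unit layers. Training uses
  softmax cross-entropy on the logits.

At the defaults this network has 1,277,789 trainable parameters, dominated
by the flatten→80 layer; the count is reported by `count_parameters` and
checked against independent shape arithmetic, not asserted against any
external figure.

### Numerical core

`crispr_mfh.nn` is a small reverse-mode automatic-differentiation engine
over float32 NumPy arrays: broadcast-aware elementwise ops, matmul,
stride-1 same-padded 2-D and depthwise convolutions (evaluated as sums of
shifted batched products; the depthwise forward/backward are fused Numba
kernels with a pure-NumPy fallback), batch normalization (batch statistics
in training, running statistics — hence deterministic — in inference),
max/mean reductions (ties in max share gradient equally), inverted
dropout, and a fused softmax cross-entropy. Every operation's gradient is
finite-difference checked in the test suite. Weights are He-initialized
from a seeded generator; Adam (lr 1e-3 default) is the optimizer, as the
standard adaptive choice for this scale.

## Training protocol

Stratified five-fold cross-validation (scikit-learn's `StratifiedKFold`,
seeded); a fresh network per fold; per-fold metrics and their arithmetic
mean reported. Early stopping monitors the loss on a 10% stratified
validation split of the training fold — validation rather than training
loss, to avoid rewarding overfit — with patience 10, min_delta 0 (only a
strict decrease counts as improvement) and best-weight restoration. The
epoch cap defaults to 500.

The batch-size heuristic evaluates the quadratic and cubic polynomials
`y₂ = 8.35·10⁻⁸x² + 0.0042x − 278.33`,
`y₃ = −2.43·10⁻¹³x³ + 1.99·10⁻⁷x² − 0.01x + 79.84`
at the dataset size x and returns `round((y₂+y₃)/2)` clamped to
[16, x]. The clamp matters: the raw mean is negative below roughly 45,000
samples, which cannot be a batch size. The heuristic rises monotonically
up to its turning point near x ≈ 7.9·10⁵ and declines beyond; at
x = 132,914 it returns 1,725.

## Evaluation

PR-AUC is the area under the precision–recall curve by trapezoidal
integration over all distinct score thresholds (equal scores collapse to
one threshold); ROC-AUC, and threshold-0.5 precision, recall, F1 and
accuracy accompany it. Under imbalance ratios in the hundreds or
thousands, ROC-AUC saturates because the false-positive rate is diluted by
abundant negatives; PR-AUC directly measures positive-class retrieval and
is the metric that differentiates models here. The implementation is
scikit-learn-backed and is checked against an independently coded
confusion-matrix/trapezoid oracle to 1e-9 on a thousand random vectors.

## Synthetic data and what it shows

The generator emulates the structure of experimental off-target tables:
23-mer guides with NGG-compatible ends, mismatch counts per pair drawn
from a geometric-like distribution (P(0)=0.1, decaying over 1..6),
uniformly placed mismatched columns, optional gap-in-place indels (5% of
pairs by default), and exact control of the floored imbalance ratio by
subsampling the majority class (never duplicating minorities, which would
leak across CV folds). The planted activity rule assigns position weights
1 (positions 1–8, PAM-distal), 2 (9–12), 3 (13–20), 4 (21–23), doubles
them for indels, and labels a pair active iff the summed burden is ≤ 4 —
monotone in PAM-proximal mismatch burden, mirroring the position
dependence observed in real assays.

Indel handling: generated datasets stay at L=23 with the gap replacing the
substituted DNA base (the same single-column convention the sensitivity
sweep uses). True bulge alignments at L=24 are accepted throughout the I/O
and encoding layers but are not emitted by the generator, because a
dataset must be length-homogeneous and a 24-column alignment is undefined
for its gap-free pairs.

What passing tests show: that the pipeline can represent, learn and
evaluate a deterministic position-weighted rule under class imbalance.
What they do not show: performance on real assay data, whose label noise,
guide-composition biases, chromatin effects and assay-specific artifacts
the generator deliberately does not model.

## Sensitivity analysis

Baselines are perfect-match pairs (DNA = guide), 23-mers ending in `AGG`.
Every DNA position is substituted with each of the three alternative
nucleotides or a gap — 92 variants per baseline, all positions including
the PAM treated alike. The per-variant delta is
`score(variant) − score(baseline)`, so a positive delta means the
substitution raises the predicted off-target score; the sign is
configuration-flippable since the opposite convention is equally common.
Cells aggregate means over the baselines that can contribute: a baseline
whose position-p base equals the introduced symbol produces no variant
there, so base-category cells average over roughly three quarters of the
baselines while the indel column averages over all of them; per-cell
counts are recorded alongside the means.

## Problem sizes used in the checks

The cross-validated learnability check runs on 20,000 noiseless pairs at
imbalance ratio 9 with a reduced network (F=8, trunk 24 channels), batch
size 256, learning rate 2e-3 and a 6-epoch budget — sizes chosen so the
full five-fold run completes in minutes on a single CPU while the
deterministic planted rule remains comfortably learnable (fold PR-AUCs
≈ 0.98, against a 0.1 chance level). The sensitivity cardinality check
enumerates all 920,000 variants of 10,000 baselines but scores only small
probe sets, since cardinality is a counting property.

## Known limitations

- The engine supports stride-1 same-padded convolutions only — all this
  architecture needs, but not a general CNN substrate.
- Training at the full default width (F=32) on 10⁵-sample datasets is
  CPU-bound; the architecture is the contribution here, not throughput.
- `encoding_mode="embedding"` (a word-embedding alternative to one-hot) is
  reserved in the configuration but intentionally not implemented.
- The generator's label noise is symmetric flipping; real assay noise is
  structured and asymmetric.
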