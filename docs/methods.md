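# Methods

## The task

The package studies a deliberately minimal stand-in for RNA secondary
structure prediction: deciding whether two RNA strands are *fully
complementary*. Over the alphabet Σ = {A, C, G, U} with the Watson-Crick
map c(A)=U, c(C)=G, c(G)=C, c(U)=A, a strand s of length L ≤ 10 and a
strand s̄ of the same length form a positive example exactly when
s_i = c(s̄_{L+1−i}) for every position i, i.e. when s̄ equals the exact
complement s\* (the reverse of the base-wise complement, both strands
read 5′→3′). The task is binary classification of (s, s̄) pairs.

Each example is presented as a hairpin: s, a random apical loop a
(tetraloop by default, lengths 3–7 supported), and s̄, zero-padded
symmetrically to a fixed input of 2·10 + |a| tokens,

    PAD^(10−L) · s · a · s̄ · PAD^(10−L).

Token ids are fixed (PAD=0, A=1, C=2, G=3, U=4). Models embed tokens
into learned 4-vectors with the PAD row frozen at zero, so padding is
literally invisible to the first layer. This fixed-size representation
is itself one of the objects of study: it is what limits length-wise
extrapolation (see below).

## Synthetic data

A dataset is generated from a disjoint partition of the full 4^L strand
space (shuffled exact split, default half/half), so no s value is ever
shared between train and test roles. Within a pool:

* positives set s̄ = s\*; negatives draw s̄ uniformly from the 4^L − 1
  strands ≠ s\* (rejection sampling; uniformity is chi-square-tested);
* the positive ratio α fixes round(α·N) positives in training sets;
  test sets are always balanced and correctly labelled;
* training labels are then flipped independently with probability
  μ ∈ [0, 1/2]; ground-truth labels are kept alongside so the flip
  fraction and the oracle can always be audited;
* strands are drawn with replacement, so N may exceed the pool size;
  duplicated s values still differ in loop and/or negative partner.

For "full set" evaluations (used whenever the test length differs from
the training length) the test set pairs every strand of the test length
with one positive and one negative example — the balanced set of all
4^8 length-8 sequences is 131 072 examples.

What the generator does *not* model: loop thermodynamics (loops are
uniform random nucleotides), wobble or non-canonical pairs
(complementarity is strictly Watson-Crick), and any sequence
composition bias. Passing tests therefore demonstrate behaviors of
learning systems on clean combinatorial structure, not performance on
biological RNA.

## Models and capacity

Four families share the embedding and a common head
(linear(U) – batchnorm – ReLU – dropout – linear(1) – sigmoid); each has one
characteristic first layer whose width H controls capacity:

* **MLP** — flatten, linear(H) – batchnorm – ReLU – dropout.
* **Att** — sinusoidal positional encoding added to the embeddings, a
  kernel-1 convolution 4 → H, then a residual block
  batchnorm(h₁ + dropout(selfattention(h₁))) with H heads of size 1.
* **LSTM** — one bidirectional recurrent layer, H units per direction,
  no internal dropout; per-position outputs flattened.
* **CNN** — outer concatenation of the 24×4 matrix into a 24×24×8
  tensor whose (i, j) vector stacks the encodings at positions i and j,
  a 3×3 convolution with H maps (stride 1, padding 1),
  batchnorm – ReLU – dropout, flattened.

Per-position features are flattened (not pooled) before the head; this
choice reproduces the intended parameter-count magnitudes, verified
against closed-form counts in the tests. The capacity ledger maps each
family to six (H, U) pairs at nominal log₁₀C ∈ {2.70, 3.00, 3.50,
4.15, 4.75, 5.50}; actual counts stay within ±0.25 log₁₀ everywhere
(the CNN is the loosest fit, 4.32 at the 4.15 column). Embedding
parameters are counted (16 values; the frozen PAD row is excluded).

## Training

The loss is class-rebalanced binary cross-entropy: for score y and
observed label t,

    ℓ(y, t) = −[ ((1−α)/α) · t · log y + (1−t) · log(1−y) ],

with α the positive fraction of the *observed* training labels — the
literal dataset-level definition, recomputed after mislabelling, so at
α = 1/3 each positive example weighs exactly twice a negative one.
Scores are clamped to [1e−7, 1 − 1e−7] inside the loss only.

The optimization protocol is fixed: Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8), learning rate 1e−3, coupled weight decay 1e−3 (added to the
gradient before the moment updates), batch size 256, dropout 0.1, and
epochs = round(8·10⁴ / N) floored at 1, which keeps the number of
gradient steps near 8·10⁴/256 ≈ 312 for every N that fills a batch.
There is no early stopping, schedule or validation split. Batch
normalization uses eps 1e−5 and running-stat momentum 0.1; evaluation
always uses running statistics, so scores are deterministic and
independent of batch composition.

### The numerical engine

The networks run on a small reverse-mode automatic-differentiation
engine over NumPy arrays written for this package (`comprec.nn`):
broadcasting arithmetic, batched matmul, reductions, softmax, slicing,
padding, and the layers above. Engine correctness is enforced by
central-finite-difference gradient checks on every layer and by the
closed-form parameter-count oracles. Working precision is float32 (the
customary choice for networks of this size); the gradient tests switch
to float64. Head-size-1 attention uses a broadcast shortcut whose
equality with the general scaled-dot-product path is itself a test.
Initialization follows the common framework defaults: uniform
±1/√fan_in for dense and convolutional weights, ±1/√H for recurrent
weights, standard normal embeddings.

## Evaluation

Accuracy at threshold θ is

    A(f, D, θ) = (1/N) Σ_i [ t_i·1{f(x_i) > θ} + (1−t_i)·1{f(x_i) ≤ θ} ],

with θ = 1/2 throughout and ties counted as negative (the ≤ branch).
Accuracy is measured against observed labels, so the exact oracle scored
on a μ-mislabelled training set lands at 1 − μ in expectation — a
property the tests use to validate the bookkeeping. The oracle (a
brute-force base-by-base Watson-Crick check) is implemented
independently of the generator, and the two are cross-checked on 10⁵
examples.

A simulation repetition derives all of its randomness (partition,
datasets, model initialization, batch order, dropout) from one
repetition seed via seed-sequence spawning; repetition r of a cell uses
base_seed + r. Headline numbers are means over repetitions.

### Score probes

The probe triple is built from the self-complementary strand
s = ACGUACGU with loop GAAA: the positive hairpin, and two negatives
obtained by breaking three base pairs. Pair positions are counted from
the apical loop outward (pair 1 is s_L·s̄₁); a pair is broken by
replacing the s̄ base with its own Watson-Crick complement, which can
never restore the pair. Breaking pairs 6–8 (nearest the open end)
yields ACGUACGUGAAAACGUAGCA; breaking pairs 2–4 yields
ACGUACGUGAAAAGCAACGU. For a model trained at L = 5, the pairs-6–8
positions were zero-padding during training, so their mismatches are
invisible and the probe is misclassified as positive despite high
statistical accuracy — the central limitation of fixed-size inputs with
zero-padding.

## Classical baselines

k-NN (35 neighbors, Euclidean, uniform vote), SVM (RBF kernel, C = 1,
scale-width), decision tree (Gini, depth cap 12) and random forest
(400 trees, bootstrap, √-feature subsampling) run on a position-wise
one-hot featurization of the same padded layout (PAD positions
all-zero), mirroring the networks' input; the featurization is this
package's choice and is documented as such. Baselines receive no class
weighting (the α-correction applies only to the networks' loss), produce
hard labels, and are scored through the identical accuracy routine on
identical datasets (shared seeds), so comparisons differ only in the
classifier.

## Problem sizes and design choices

* Default grids: N ∈ {125, 250, 500, 1000, 2000, 4000, 8000}; α sweep
  over {0.05, 0.1, …, 0.95}; both configurable. The partition split
  fraction (0.5) and the within-length test size (10 000) are package
  choices where the protocol leaves them open.
* The analysis drivers and the acceptance script run at desk scale:
  10 repetitions per cell (3 in the narrative drivers) instead of 50,
  with tolerances widened accordingly; per-repetition spreads are
  therefore noisier than the originals.
* Epoch rounding is half-up with a floor of one epoch.
* Weight decay is coupled (L2-in-gradient) rather than decoupled.
* Degenerate inputs: empty pools, single-class observed labels, odd
  test sizes and out-of-range L, α, μ, θ all raise errors rather than
  silently proceeding.

## Known limitations

* The engine is CPU-only and single-threaded beyond BLAS; very large
  grids are slow by construction.
* Attention here is more stable across seeds than the reported
  behavior of its reference counterpart in the extrapolation regime;
  per-run spread at (L 6→8, N = 2000) can be narrower (see the
  acceptance suite, which checks the documented spread and flags the
  discrepancy when it does not materialize).
* No wobble pairs, no structural realism, no ROC/AUC analysis
  (thresholded accuracy at θ = 1/2 only), and no claim of transfer to
  real RNA data.
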