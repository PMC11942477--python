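# Methods

## Pairing model

All structural features derive from one admissibility predicate: positions
(i, j) may pair iff the base pair is A-U, G-C or G-U (in that order; "the
first rule" means A-U) and |j - i| > h with minimum hairpin-loop length
h = 3 by default. h = 3 is the standard steric constraint for RNA; it is
configurable because the interval-counting features are also meaningful at
h = 0 for analysis. N and all IUPAC ambiguity codes never pair and encode
as all-zero one-hot columns; distances against them are computed against
the zero vector.

## Feature channels

* **LPSS** solves, for every fragment [i..j], the maximum-cardinality
  non-crossing matching under the admissibility predicate. The recurrence
  is the classic one — skip i, pair (i, j) when admissible, or bifurcate —
  evaluated bottom-up over spans and vectorized along diagonals. The
  matrix stores pair *counts* (not matched-base counts), mirrored to be
  symmetric with zero diagonal. Tests compare against an independent
  top-down recursion on short sequences.
* **SRS** operationalizes "repeatedly pairable" as: a base contributes to
  its type's channel on interval [i..j] iff it has at least two admissible
  partner positions inside the interval. Four per-base-type channels
  (A, U, C, G) plus their sum give the five maps. Implemented with partner
  prefix-sums per position, one cumulative pass per left endpoint.
* **BMS** is the analogous count under the first (A-U) rule only, with
  threshold one partner. Same five-map layout.
* **RCM** scores an admissible (i, j) by its pair-type weight (A-U 2,
  G-C 3, G-U 0.8) plus Gaussian-decayed weights exp(-t²/2σ²), σ = 1, of
  the outward stack (i-t, j+t) and inward stack (i+t, j-t), each
  accumulated until the first inadmissible offset. The weights and σ are
  configurable; the values above are conventional stacking-propensity
  weights for the three pair types. Scores are raw (not normalized to
  probabilities); max-normalization happens at stack level.
* **Spatial distance** encodes position p as ceil(log2(max(L, 2))) bits,
  MSB first, concatenated with the base one-hot, and takes pairwise
  Euclidean distances. **Manhattan distance** is the L1 distance of base
  one-hots (0 for equal bases, 2 for different unambiguous bases, 1
  against N).
* **BPS** takes the 16 ordered base-identity outer-product channels
  (the Kronecker product of the one-hot encoding with itself) and deletes
  the 6 channels whose ordered label reverses an earlier one; a deleted
  channel equals the transpose of its kept partner, so no information is
  lost. Kept order: AA, AC, AG, AU, CC, CG, CU, GG, GU, UU.

Stack order is LPSS, RCM, SRS x5, BMS x5, spatial, Manhattan, BPS x10 —
24 channels, float32. With normalization on (the default for model
input), each non-BPS channel is divided by its own maximum; identically
zero channels stay zero. Sequences are fitted to the configured L by
head-cropping (center-crop optional) or right-padding with N, and padded
rows/columns are zeroed in every channel.

## Tokenization

L - k + 1 overlapping k-mers wrapped in [CLS]/[SEP] give L - k + 3
tokens; k = 3 by default. The vocabulary is PAD, UNK, CLS, SEP followed
by all 4^k k-mers in lexicographic order; k-mers containing N map to
UNK. DNA input is handled by normalizing T to U before tokenization, so
one vocabulary serves both alphabets.

## Architecture

ModelConfig defaults to the full-scale configuration (D = 768, 12
sequence-encoder layers, vision depths 2/2/6/2, 12 heads, window 7, 2
fusion blocks, dropout 0.1); `ModelConfig.toy()` (D = 64, 8 heads,
depths 2/2/2/2, 2 sequence layers) trains on one CPU and is used
throughout the tests. Requirements: L divisible by 16, D divisible by 8
and by the head count.

* **Vision encoder**: 2x2 patch embedding (stride-2 downsampling), then
  four stages of window attention with channel widths D/8, D/4, D/2, D
  and 2x2 patch merging between stages, so the grid shrinks L -> L/16.
  Odd blocks use shifted windows (shift w/2) with the standard 9-region
  attention mask; shifting is disabled when one window covers the whole
  grid, where it would isolate every token. Window attention carries a
  learned relative-position bias per head. If the configured window does
  not divide a stage's grid, the largest divisor not exceeding it is
  used. Head counts halve per stage down from the configured count (at
  least 1). The final grid is mean-pooled along the row axis to L/16
  vision tokens — chosen so that the classifier pools C = L + L/16
  positions at k = 3, matching the printed fused-length formula.
* **Sequence encoder**: token + learned absolute position embeddings,
  pre-LN transformer layers (attention with a clipped relative-position
  bias, offset range +-32, plus a 4x MLP), final layer norm. Pre-LN was
  chosen over post-LN for optimization stability at toy scale. The
  relative bias is initialized as a per-head geometric distance penalty
  (attention-with-linear-biases style): early heads start local, later
  heads near-global, and the table remains trainable. This locality
  prior is what lets short-range k-mer conjunctions (motifs) be learned
  from a few hundred examples; with a flat initialization the same
  model plateaus well below its attainable accuracy on the planted-motif
  task. PAD keys are masked out of attention.
* **Fusion block**: per modality, self-attention and cross-attention to
  the other modality are concatenated on the feature axis, projected
  2D -> D, layer-normalized, and passed through SeLU. The printed
  formula sums SA and CA while the prose connects them; concatenation
  followed by a linear map subsumes the sum and follows the more
  specific description.
* **Classification head**: concatenate fused text and vision tokens,
  average over the C positions, linear map, softmax. Losses are mean
  negative log-likelihood (binary and multiclass), with probabilities
  clipped at 1e-7.
* **Structure head**: the vision stages act as a U-Net encoder; at the
  bottleneck the (L/16)² grid tokens cross-attend to the text embedding
  (residual + layer norm, no resampling — the bottleneck was chosen as
  the cross-attention layer). The decoder upsamples with transposed
  convolutions in pixel-shuffle form (linear to 4x channels +
  depth-to-space, exactly a kernel-2/stride-2 transposed convolution),
  adds the matching encoder grid as a skip connection, and ends in a
  1-channel sigmoid map symmetrized as (P + Pᵀ)/2. The decision
  threshold on the symmetrized map is 0.5 with no pairing-constraint
  post-processing.

## Autodiff engine

No GPU framework is used: `rnaduet.nn` is a small reverse-mode autodiff
engine over numpy (broadcast-aware arithmetic, batched matmul, shape
ops, gathers, fused layer-norm and softmax primitives, SeLU/sigmoid/
tanh/ReLU) with AdamW. Gradient correctness is verified by
finite-difference tests; forward passes are deterministic given fixed
parameters with dropout off. Checkpoints are `.npz` archives of named
parameters plus a JSON config entry. A process-level allocator tuning
(`tune_allocator`) raises glibc's malloc thresholds so the multi-MB
graph arrays are reused between steps instead of being returned to the
kernel; it is a no-op on other platforms.

## Training

AdamW (weight decay 0.05, excluded for norms, biases, embeddings and
bias tables) with a 2% linear warmup and cosine decay. Classification
uses lr 1e-3, batch size 8 and label smoothing 0.1 at toy scale (the
full-scale reference settings for the corresponding tasks, 1e-4 and
3e-5, are configurable). Training batches are augmented with
label-preserving transformations of the planted-signal tasks: random
circular shifts of the token stream and feature grid, masking of random
k-mer tokens to UNK, and inverted-dropout removal of random feature
channels — all three discourage memorizing individual sequences, which
is the dominant failure mode at a few hundred training examples.
Optionally an exponential moving average of the weights can be
evaluated instead of the raw weights (off by default). Per-epoch train
loss and held-out accuracy are logged as line-delimited JSON; training
can stop early at a target accuracy, and the result records the best
held-out accuracy over the run.

## Synthetic fixtures

* **random_structure** samples a nested structure by a pair-or-advance
  recursion (pair probability 0.4, uniform partner choice, minimum loop
  h), writes admissible bases onto pairs (G-C : A-U : G-U drawn 2:2:1,
  random orientation) and uniform bases elsewhere. Every emitted
  structure renders to dot-bracket and parses back identically.
* **motif_dataset** plants one motif per class (defaults GGCCGG / AUAUAU)
  at a uniform position on a uniform background with per-base mutation
  noise (default 0.05), balanced classes. Backgrounds are resampled until
  they contain no class motif, so the planted occurrence is the only
  class signal and a noise-free dataset is perfectly classified by a
  motif scanner.
* **interaction_dataset** embeds the motif as the 5' strand of a planted
  hairpin stem in positives (emulating double-strand-preferring RNA
  binding proteins) and uses motif-free backgrounds as negatives,
  1:2 positive:negative by default.

What the fixtures do *not* emulate: real base-composition biases, family
structure, pseudoknots, experimental reactivity scores, or binding
energetics. Passing the toy training check therefore shows that the
architecture can extract a localized sequence/structure signal
end-to-end — not that it attains published benchmark performance, which
requires large-scale pre-training and real corpora and is out of scope
here.

## Evaluation

Pair-level structure scoring counts each pair once over the strict upper
triangle with exact matching (no one-position slack; none is defined for
the reference numbers). PPV, SEN, F1, MCC and ACC use the standard
confusion-count formulas with 0 for vanishing denominators. AUROC uses
the rank statistic with mid-rank tie handling and AUPRC uses
precision-recall step integration (both via scikit-learn). TN is
undefined (and TN-based metrics unavailable) for pair-level scoring,
where the negative class is implicit.

## Problem sizes used

The test suite and acceptance script run entirely on one CPU: the toy
training condition is n = 400 sequences of L = 112 at noise 0.05 with
the width-64 model (about 425k parameters), 20% held out, at most 20
epochs with early stopping at 0.90 accuracy; the structure head trains
at L = 32 on a few dozen records as a wiring check; oracle comparisons
use sequences of length <= 12 where exhaustive recursion is exact.

## Known limitations

* The hierarchical attention blocks omit some full-scale refinements
  (stochastic depth, qk-scale options); windows are square and tied to
  the 4-stage /16 reduction, so L must be divisible by 16.
* Pseudoknots are rejected in structure input rather than modelled, and
  the pairing features cannot represent crossing pairs by construction.
* The CT reader accepts the canonical 6-column dialect only.
* Training at full scale (D = 768, 12 layers) is expressible but not
  practical on CPU; the package is a faithful small-scale laboratory,
  not a performance reproduction.
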