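# Methods

This note documents the models, conventions and design choices behind
`capm7g`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and
which decisions were genuinely open.

## Sequence windows

Candidate sites are fixed-length RNA windows centered on a guanosine.
Coordinates are 0-based and point at the candidate nucleotide; the
default flank is 250 nt, giving 501-nt windows with the candidate at
index 250. Input is canonicalized by uppercasing and mapping T→U.
Residues outside {A, C, G, U, T} are rejected by default; an optional
`random-replace` policy substitutes seeded uniform bases and warns.
Sites closer than one flank to a sequence end are errors in
`extract_window` and are skipped with a warning in `extract_windows` —
no padding rule is defined, because padded windows would put fictitious
sequence into the encoder.

## Chaos-game encoding

The trajectory starts at the origin and moves halfway toward the corner
of each successive base: h(A)=(−1,1), h(U)=(1,1), h(C)=(−1,−1),
h(G)=(1,−1). Every point therefore lies strictly inside (−1,1)² and
encodes its full prefix, with the last k bases determining the point's
cell on a 2^k × 2^k grid.

Frequency-matrix (FCGR) conventions, fixed and pinned by tests:

* **All n points are binned**, including the first k−1 whose cells
  reflect shorter prefixes. This yields the conservation invariant
  `counts.sum() == len(sequence)`, and matches the behavior of the
  standard CGR-matrix implementations this encoding follows.
* **Orientation:** rows index y from the top, columns index x from the
  left, so A is top-left, U top-right, C bottom-left, G bottom-right.
  G-rich k-mers therefore live toward the bottom-right corner.
* **Half-open cells:** a coordinate exactly on an interior edge belongs
  to the higher-index cell. Trajectory coordinates never reach the outer
  edges, so no clipping is needed.
* **Grayscale normalization** divides counts by the per-image maximum
  (zeros stay zero). Per-image max-scaling preserves relative k-mer structure and
  keeps pixels in [0, 1]. It is a deliberate, configurable choice —
  log-scaling or a fixed divisor would also be defensible; changing it
  changes the pixel distribution the network sees, nothing else in the
  pipeline.

The default grid is N = 64 (6-mer cells). The desk-scale training
configuration uses N = 32; all invariants are grid-independent.

## Capsule network

Architecture (all hyperparameters in `CapsuleNetConfig`):

* Conv stage 1: 1→64 channels, 9×9 kernel, stride 1, ReLU.
* Conv stage 2: 64→256 channels, 9×9 kernel, stride 2, no activation;
  the 256 channels are read as 32 capsule channels × m = 8 dimensions
  and squashed into L primary capsules (L = 32·24·24 = 18432 at 64×64
  input). The conv front end is the canonical capsule-network geometry
  scaled to a 64×64 input, and it is entirely config-driven.
* Prediction vectors û_j|i = W_{i,j} uᵢ with a learnable (L, J, m, D)
  tensor, J = 2 digit capsules of dimension D = 32.
* Routing by agreement, r = 3 iterations: logits b start at zero; each
  iteration computes c_i = softmax_j(b_i), S_j = Σᵢ c_{ij} û_j|i,
  v_j = squash(S_j), and adds the agreement û_j|i·v_j to b on all but
  the last iteration (the final v comes from the final couplings).
  Logits are reset every forward pass; gradients flow through the
  unrolled iterations.
* Class probability p_j = ‖v_j‖ — the plain L2 norm. (Some capsule formulations square this
  norm; the plain Euclidean-length reading is used here, and the
  argmax decision is identical either way.)
* Decoder: 64 → 512 → 1024 → 4096 fully connected, ReLU/ReLU/sigmoid,
  reconstructing the input image from one masked capsule. During
  training the true-class capsule is reconstructed; at inference the
  highest-probability one.

Numerical details: squash is stabilized as
s·‖s‖²/((1+‖s‖²)·sqrt(‖s‖²+ε²)) with ε = 1e−8, so the zero vector maps
to zero without NaN while a unit-norm input still maps to norm 0.5 to
within ~1e−16. Weights use He initialization for conv/dense stages and
0.05·N(0,1) for the routing tensor; everything is seeded from
`config.seed` and two runs with the same seed are bit-identical.

### Losses

Margin loss per sample, summed over capsules and averaged over the
batch: T_k·max(0, m⁺−p_k)² + λ(1−T_k)·max(0, p_k−m⁻)², with
m⁺ = 0.9, m⁻ = 0.1, λ = 0.5 — the standard capsule-network constants, exposed in config.
Reconstruction loss is the mean squared error over all N pixels; the
total loss is margin + α·N·mse, i.e. α = 0.0005 acts on the per-pixel
**sum** scale, keeping reconstruction subordinate to the margin term.
α = 0 is exactly the without-reconstruction ablation (the decoder then
receives no gradient, which a test asserts).

### Ablation variants

* *without CGR:* one-hot 4×n strips replace FCGR images; the conv
  kernels become (4, k) then (1, k) so the same code path handles the
  strip geometry.
* *without CapsNet:* the same conv stack feeds a flatten → hidden →
  2-logit MLP head trained with cross-entropy (softmax probabilities).
* *without reconstruction:* α = 0.

### Decision rule and AUC

The predicted label is the argmax over the two capsule norms (ties →
positive); capsule norms are not calibrated probabilities and do not sum
to 1, so a fixed 0.5 threshold on p_positive would be arbitrary. ROC and
PR AUC are computed on p_positive alone by trapezoidal integration over
thresholds. A consequence worth knowing: early in training the
between-sample ranking of p_positive can be poor (even inverted) while
argmax accuracy is already above chance, because both norms share
nuisance variation; the two measures converge as the margin loss
saturates.

## Training protocol

Balanced datasets (negatives sampled without replacement from a
candidate pool of non-site G-centered windows), stratified 8:2
train/test split, stratified 4-fold cross-validation on the training
portion, Adam with lr 0.001, batch size 32. The checkpoint returned is the
epoch with the best validation MCC, MCC being the balanced metric the
evaluation emphasizes. Divergence (NaN loss)
aborts with a diagnostic. The full-scale protocol (64×64, 100 epochs)
ships as `configs/paper.yaml`; the test suite and examples use the
desk-scale preset (32×32 input, 8/32-channel convs, D = 16, ≤30
epochs), which trains a few hundred windows in tens of seconds on one
CPU. The evaluation metrics are implemented directly from the
confusion-matrix formulas (accuracy, recall, specificity,
F1 = 2TP/(2TP+FN+FP), MCC) and cross-checked in tests against brute
force enumeration and a pairwise-ranking AUC oracle.

## Synthetic benchmark generator

The generator emulates the *shape* of an m7G benchmark: balanced
classes, 501-nt windows, every window centered on a G. The
discriminative signal is planted motif context only — positives receive
in-place insertions of GGG, CU and UC (the patterns enriched around
genuine m7G sites) at seeded uniform positions within ±100 nt of the
center; negatives are pure background with a central G. This mirrors
the biological task (separating modified from unmodified guanosines by
context) and makes attribution claims checkable against the recorded
manifest of insertions.

Strength presets (insertions per positive window for GGG/CU/UC):
weak 2/1/1, medium 6/4/4, strong 16/10/10. The levels are the package's
chosen study conditions: no quantitative enrichment levels exist to copy
from real data, so they were calibrated once so that the desk-scale
model's discrimination spans chance (weak) to near-perfect (strong),
and are not tuned thereafter. Insertions overwrite background in place
(no length change), never overlap the central base, and later
insertions win on overlap; every insertion is recorded. Background is
uniform by default, with a mildly GC-skewed human-transcriptome-like
alternative (`GC_SKEWED_BACKGROUND`).

What passing tests on this generator do **not** show: performance on
real transcriptome data. Real m7G contexts carry correlated motifs,
secondary-structure signals, composition gradients and redundancy that
the generator deliberately omits; results on it certify the machinery
(encoding, optimization, evaluation, attribution), not the biology.

## Significance maps

The FCGR image is tiled into a 9×9 grid of near-equal contiguous
regions; 64 is not divisible by 9, so band sizes are (7×8, 8) along each
axis, fixed with the larger band last. Masked regions are set to zero
intensity — the natural baseline, since zero pixels mean "no such
k-mers". The estimator draws seeded random keep/mask patterns over the
81 regions (plus the all-kept and all-masked patterns), queries the
model, and fits an ordinary-least-squares surrogate
p(target) ≈ φ₀ + Σ φ_k·keep_k; φ_k is region k's attribution, positive
when masking the region tends to lower the target probability. A pure
occlusion mode (one region at a time, Δp) serves as a cheap independent
estimate; tests require sign agreement on strongly attributed regions.
The 9×9-region reading of the coarse attribution grid is implemented;
per-pixel masks would be a different (much more expensive) estimator
and are out of scope.

Latent features from the primary (L×m) or digit (J×D = 64 at full
scale) capsule layers are exported as labeled tables; clustering and
t-SNE themselves are standard library territory and intentionally not
reimplemented here.

## The autodiff engine

No deep-learning framework is part of the dependency set. The network
runs on a small reverse-mode automatic-differentiation engine over
float64 numpy arrays (`capm7g.autodiff`) providing exactly the required
operator set: broadcasting arithmetic, matmul, valid-mode 2-D
convolution with rectangular kernels/strides (im2col forward,
scatter-add backward), relu/sigmoid/exp/log/sqrt, axis reductions,
reshape/transpose and a max-shifted softmax. Every operator's gradient
is pinned by central-finite-difference tests, and the composed model
gradient is checked the same way. Adam follows the standard
bias-corrected moment updates.

## Known limitations

* Desk-scale training sizes (hundreds of windows, ≤30 epochs) are the
  tested regime; the full-scale 64×64/100-epoch configuration is
  provided and exercised for geometry, not trained in the test suite.
* Capsule norms are uncalibrated scores, not probabilities.
* Sense-strand RNA only; no genome-scale scanning, no reverse-strand
  handling, no sequence-redundancy reduction (an identity-filter hook
  would slot into dataset assembly before splitting).
* The significance estimator is a linear surrogate of a nonlinear
  model; attributions are region-level tendencies, not exact Shapley
  values.
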