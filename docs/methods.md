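# Methods

## Problem and model

Morphologic classification of stained bone-marrow cells suffers from
severe class imbalance: in the public 21-class benchmark the most
common class (segmented neutrophils) outnumbers the rarest (abnormal
eosinophils) by roughly four orders of magnitude. `cytosiam` follows
the similarity-learning route: a twin ("Siamese") network with shared
parameters maps each image to an encoding h, and a dense head maps a
pair of encodings to a probability g ∈ (0, 1) that the two images share
a class. Because training examples are *pairs* sampled class-balanced,
a class with ten images contributes as much gradient signal as one with
twenty thousand.

The encoder is a stack of up to four stages of 3×3 convolution (stride
1, zero padding (k−1)/2, so spatial size is preserved), ReLU, and
disjoint 2×2 max pooling with floor-and-drop for odd sizes. For the
canonical 50×50 input the spatial sizes go 50 → 25 → 12 → 6 → 3, so the
flatten sees a 3×3 map. Flattening is row-major (rows, then columns,
channels innermost) and a ReLU dense projection produces the encoding.
The head consumes the concatenation (h₁, h₂) — an absolute-difference
mode |h₁−h₂| is available as a config option since the triplet
formulation is distance-based — through five dense layers, ReLU hidden,
sigmoid on the final unit so g is a Bernoulli probability.

## Objectives and gradients

The default objective is the Bernoulli negative log-likelihood of the
similarity labels, L = −Σₘ [sₘ ln gₘ + (1−sₘ) ln(1−gₘ)], summed over
the batch; minimising it maximises the conditional likelihood
∏ gˢ(1−g)¹⁻ˢ. Its derivative with respect to g is −(s−g)/(g(1−g)),
which through the output sigmoid collapses to the numerically benign
g − s at the pre-activation. A margin triplet loss on raw encodings,
max(‖h_a−h_p‖² − ‖h_a−h_n‖² + ε, 0) with squared Euclidean distances
(margin ε default 0.2), is provided as an alternative objective; the
two are not combined. The clamp keeps satisfied triplets from
contributing gradient. Three distinct quantities conventionally share
the symbol ε — the triplet margin, a formal (unused) margin argument of
the head, and Adam's denominator stabiliser — and are housed as
`margin_triplet`, nothing, and `adam_eps` respectively. The head takes
no margin input: a probability head has no use for one, so the argument
is a documented no-op.

All gradients are derived by hand and implemented in numpy; there is no
autodiff dependency. Backpropagation runs dz = g − s through the head's
delta recursions δˡ = (Wˡ⁺¹)ᵀ δˡ⁺¹ ⊙ f′(zˡ), splits at the
concatenation into ∂L/∂h₁ and ∂L/∂h₂, and continues down both twin
branches (unpooling to the argmax positions, masking through ReLU,
correlating for the conv kernels); because the twins share weights, the
two branch contributions sum on every shared tensor. Correctness is
established three ways:

1. central finite differences (step 1e-5) over every parameter of a
   tiny network agree to better than 1e-4 relative (observed ~1e-10);
2. an independently written per-example implementation of the delta
   recursions for conv-free configurations agrees with the vectorised
   path to 1e-8;
3. closed-form cases (zero gradients at a perfect fit, identity
   kernels, constant images) hold exactly.

One numerical trap worth recording: with zero-initialised biases, a
ReLU unit whose active inputs are all zero has a pre-activation of
exactly 0, and a central difference straddles the kink, returning half
the one-sided slope. Gradient verification therefore jitters all
parameters (σ = 0.05) before differencing; the analytic code uses the
subgradient f′(0) = 0 throughout.

## Optimizer

Adam is implemented from scratch: V ← β₁V + (1−β₁)g,
S ← β₂S + (1−β₂)g⊙g, bias corrections V/(1−β₁ᵗ) and S/(1−β₂ᵗ), update
θ ← θ − η·V̂/(√Ŝ + ε). Defaults η = 1e-3, β₁ = 0.9, β₂ = 0.999,
ε = 1e-8. Two deliberate design points: the bias corrections use the
standard power-of-t form (a step-independent correction would
contradict the recursive indexing of the moment updates), and moments
are kept on the *total* gradient per shared tensor — the twin branches'
contributions are summed before the moment update rather than
normalised separately, and biases get the same Adam treatment as
weights. Closed forms are tested: the first step from a zero state has
magnitude η|g|/(|g|+ε); β₁ = β₂ = 0 reduces to sign-normalised descent;
a two-step constant-gradient unroll matches an independent scalar
recursion.

Initialisation is He-scaled Gaussian (std √(2/fan_in)) for all weights
and zero for all biases, deterministic per seed. All run-level
randomness derives from one root seed via named SeedSequence substreams
(initialisation, pairing, per-epoch shuffling, gallery sampling), which
makes full runs bitwise reproducible and lets a checkpoint-resumed run
continue identically to an uninterrupted one. On a non-finite loss the
loop aborts and returns the last completed epoch's parameters.

## Pairing rules

For every class with at least two members, `build_balanced_pairs` emits
exactly `pairs_per_class` similar pairs (both members in the class) and
the same number of dissimilar pairs whose partner class is drawn
*uniformly over the other classes* — not proportionally to frequency —
so rare classes appear in dissimilar pairs as often as common ones.
Sampling is with replacement, which is what makes the equal-count rule
satisfiable for very small classes (a two-member class simply reuses
its only similar pair). Singleton classes are skipped for both pair
kinds with a warning — emitting dissimilar-only pairs would break the
per-class balance invariant — though their images still appear as
partners of other classes. Pairs are ordered (a, b); the head is not
structurally symmetric, so reported similarities average both
orderings.

## Multiclass inference

The pairwise model does not output a class. `classify` compares a query
encoding against a gallery of k reference encodings per class (default
k = 10, sampled with replacement from the training split) and returns
the class with the highest mean symmetrised head similarity; ties break
to the lowest class index and are logged. This is the simplest faithful
use of the trained pairwise head for C-way decisions; prototype
averaging in encoding space or k-NN over distances would be
alternatives, but they bypass the learned head.

## Metrics

Per-class one-vs-rest counts give accuracy (TP+TN)/(TP+TN+FP+FN),
precision TP/(TP+FP), recall TP/(TP+FN), and F1 as their harmonic mean;
zero denominators report 0 with a warning. Reports carry per-class rows
plus overall accuracy and support-weighted averages, rounded to two
decimals for display with raw values retained. Two facts the test suite
pins down:

- Support-weighted recall equals trace accuracy *identically*
  (Σ n_c/N · diag_c/n_c = trace/N). Published report tables for the
  bone-marrow benchmark violate this identity (weighted recall 0.92
  against accuracy 0.91 on the training split), which is arithmetically
  impossible for a consistent table — recorded here as an erratum
  observation; this package asserts the identity on its own reports and
  does not replicate the inconsistency. A related published per-class
  row (precision 0.39 with recall 0.97 for the artefact class, against
  per-class counts implying 4931/12563 ≈ 0.39 *recall*) looks like
  transposed columns; flagged, not resolved.
- Arranging the published per-class (correct, total) counts on a
  confusion-matrix diagonal reproduces the published overall accuracies
  exactly: 99,705/109,670 = 0.909 → 0.91 (train) and 26,012/30,837 =
  0.843 → 0.84 (validation). Off-diagonal placement is arbitrary since
  accuracy only reads the diagonal and row sums.

## Synthetic data generator

Each class is a *phenotype*: nucleus radius fraction, eccentricity,
nucleus and cytoplasm RGB, granule count and radius, texture noise sd.
Rendering composites a pale background, a cytoplasm disc, granule
specks and a rotated nucleus ellipse with ~1 px soft (antialiased)
edges, then adds clipped Gaussian noise; every image is a pure function
of (phenotype, size, seed). Pixels are reals in [0, 1]; 8-bit
quantisation happens only at PNG write.

The `separation` knob (default 0.8) both shrinks class recipes toward a
library-wide random center by that factor and enforces a proportional
minimum pairwise feature distance by rejection sampling (at most 1000
attempts). The shrink is what makes the knob meaningful: a pure
minimum-distance constraint would leave typical random draws far apart
regardless, whereas shrinking makes low-separation libraries genuinely
confusable — a linear probe on raw pixels moves monotonically with the
knob, which a test checks at two settings.

What the generator does *not* emulate: staining variability between
laboratories, overlapping/touching cells, focus and illumination
gradients, intra-class morphological heterogeneity (each class is one
recipe plus noise), and the long-tailed artefact classes of real
scanners. Passing the synthetic benchmark therefore demonstrates that
the training and inference machinery works and that pair balancing
neutralises class imbalance *when classes are separable*; it does not
certify real-smear accuracy.

## The scaled imbalance benchmark

Full-corpus conditions (>170k images, hundreds of epochs) are not
desk-scale, so the standing benchmark is scaled down: 6 classes with
counts 400/200/100/50/20/10 (a 40:1 skew; the rarest class keeps 8
training images after the stratified 80/20 split with its round-up
minimum of one validation image per class), 32×32 images, encoder
widths (6, 12, 24), encoding 32, head (64, 32, 16, 8, 1), 18 epochs of
Adam at the defaults, 40 pairs per class, batch 32. One full run
(generate, train, gallery-evaluate, two baselines) takes well under a
minute on one CPU. The head widths deserve a note: early experiments
with a narrow (…, 8, 4, 1) head occasionally collapsed to a constant
predictor when the width-4 ReLU layer died for every input; widening
the head removed the failure mode across seeds, and the benchmark
config simply adopts the package's default head shape.

Baselines train on the *same* learned embeddings (a raw-pixel flag
exists): a max-margin classifier (RBF-kernel SVC) and gradient-boosted
trees (XGBoost), both fit on the imbalanced training split as a
practitioner would by default. The comparison of record is rare-class
F1 across three seeds, where the gallery classifier must meet or beat
both baselines in the majority — ties count as meeting, since on an
easily separable synthetic benchmark all methods can saturate.

## Defaults and knobs

| knob | default | meaning |
| --- | --- | --- |
| `input_size` | 50 | square image side, px |
| `conv_channels` | (8, 16, 32, 64) | channels per conv stage (0–4 stages) |
| `kernel_size` | 3 | odd conv kernel side |
| `encoding_dim` | 64 | encoding length |
| `dense_widths` | (64, 32, 16, 8, 1) | head layer widths, last = 1 |
| `margin_triplet` | 0.2 | triplet margin ε |
| `head_mode` | concat | head input: (h₁,h₂) or |h₁−h₂| |
| `eta, beta1, beta2, adam_eps` | 1e-3, 0.9, 0.999, 1e-8 | Adam |
| `pairs_per_class` | 32 | similar = dissimilar pairs per class |
| `val_fraction` | 0.2 | stratified split share |
| `gallery k_per_class` | 10 | references per class |
| `separation` | 0.8 | phenotype spread / distinguishability |

Degenerate inputs are contracts, not surprises: one-class datasets
cannot form dissimilar pairs (error); singleton classes skip pairs and
triplets (warning); empty batches error; g is clamped to
[1e-7, 1 − 1e-7] before logs; checkpoint loads refuse unknown format
versions and name the first mismatched tensor.

## Known limitations

- Pure-numpy training is CPU-bound; the implementation is meant for
  method-scale experiments and verification, not 170k-image corpora.
- The conv-free "dense reference" path exists for verification, not
  performance; it is deliberately per-example and slow.
- The gallery rule's accuracy depends on gallery quality; k_per_class
  below ~5 gets noisy for heterogeneous classes.
- The generator's classes are unimodal; real cytology classes are not.
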