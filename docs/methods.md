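# Methods

This note records the modeling and numerical choices behind `tdnas`,
what the synthetic fixtures do and do not emulate, and the known
limitations.

## Search space and encoding

A configuration is `(ln, dr, nn, ω₁, β)`: `ln` counts *all* fully
connected layers including the fixed output layer (whose width is the
class count and whose dropout is 0), so `ln − 1` hidden layers carry
searchable dropout rates and widths. The space is the finite grid in
the README; with the external level pinned (ω₁ = 1, β = 1) it holds
1 + 10·4 + 10²·4² = 1,641 configurations, and 29,538 with the external
grid searched.

The Gaussian-process surrogate needs numeric inputs, so configurations
are encoded as fixed-length vectors — one ordinal coordinate per grid
dimension, min–max scaled to [0, 1] over its value set:
`[ln, dr₁, dr₂, nn₁, nn₂, ω₁, β]` for the default space. Widths are
scaled on a log₂ axis (512…4096 are powers of two, so the grid is
geometrically uniform), and hidden-layer slots absent at small `ln`
are filled with sentinel 0; the `ln` coordinate itself lets the
surrogate separate architectures of different depth. The encoding is
injective over the full enumeration and `decode ∘ encode` is the
identity (both are tested exhaustively). An ordinal encoding was
preferred over one-hot because every value set is naturally ordered,
which makes kernel distances meaningful and keeps the input dimension
at 7.

Whether ω₁ and β should enter the surrogate at all is debatable —
scoring different trials under different criteria and then comparing
them by one argmax is internally inconsistent. We encode them as two
extra dimensions when the external level is searched, and the trial
log always records plain accuracy alongside jc so the inconsistency
is at least visible.

## Judgment criterion

`jc = ω₁·Acc + (1 − ω₁)·F_β` with F_β the weighted harmonic mean of
*macro-averaged* precision and recall. Macro averaging (equal class
weight) is the robust choice when fixtures are imbalanced; for the
balanced datasets this tool targets, macro and micro averages nearly
coincide. F_β is computed from the macro-averaged P and R, not as an
average of per-class F_β. Classes with zero predicted (or true)
samples contribute 0 to macro precision (recall). Higher F_β raises
jc, i.e. jc is maximized in both terms.

## Gaussian-process surrogate

Squared-exponential (isotropic) kernel over the encoded vectors; prior
mean = empirical mean of observed jc values (0 with no data); signal
variance = target variance (1.0 fallback for constant/empty targets).
The lengthscale is chosen deterministically by maximizing the log
marginal likelihood over a small grid — {0.1, 0.2, 0.5, 1, 2} × the
median pairwise training distance — rather than by gradient
optimization, which is fragile at the n < 100 sample sizes this loop
sees. The discrete space can propose duplicate inputs, so the kernel
matrix carries a diagonal jitter of 10⁻⁶, escalated ×10 (up to 10⁻²)
if the Cholesky factorization fails; duplicate inputs with conflicting
targets are thereby averaged rather than rejected. Posterior variance
is clamped at 0 after floating-point cancellation. A dense
explicit-inverse oracle reproduces the cached-factorization posterior
to 10⁻⁸ in tests, and an external GP implementation with the same
kernel agrees to the same tolerance.

## Acquisition

Closed-form expected improvement; at σ = 0 the limit max(Δ, 0) is
used. The candidate pool is the full enumeration when the space holds
at most 20,000 configurations (the default spaces do); larger spaces
get a seeded uniform sample of 5,000 unevaluated configurations per
iteration. Already-evaluated configurations are excluded, ties break
to the smallest enumeration index, and an empty pool signals the quit
logic rather than raising to the user.

## Search loop

Initialization draws `n_init = 5` configurations Latin-hypercube
style: the enumeration order is cut into five equal strata and one
index is drawn uniformly from each, giving distinct, spread-out seeds
for the surrogate. The loop then alternates fit → posterior → EI
argmax → train/evaluate → append until the dynamic quit fires:
candidate queue empty, iteration budget reached, or (disabled by
default) `no_improve_patience = 15` trials without a new incumbent.
A trial whose objective raises is recorded with jc = 0 — pessimistic
but informative, steering the surrogate away — and the search aborts
with a diagnostic if more than a quarter of trials fail. Aborted
(unpromising) trials likewise contribute their at-abort jc as an
observation rather than being dropped, keeping one observation per
iteration.

## Training and the frozen backbone

No GPU deep-learning stack is assumed: the package implements its
networks in NumPy. The convolutional backbone (templates A/B/D/E with
8/10/13/16 conv layers, or the 2-block `tiny` variant: 16 and 32
channels, 32×32 inputs) is a *frozen*, seeded random-projection
feature extractor — 3×3 He-initialized filters, ReLU, 2×2 max pooling
per block, forward pass only. Freezing is a deliberate design choice
with a practical consequence: every trial sees the identical feature
representation, so differences in jc are attributable to the head
being searched, and a trial costs seconds instead of minutes. The
searched head (hidden dense layers with inverted dropout, softmax
output) is trained by minibatch SGD: lr 0.01 (constant), momentum 0.9,
batch 32, cross-entropy, features standardized with training-set
statistics, 50 epochs by default (desk-scale runs use 5). Global
gradient-norm clipping at 5 keeps the widest heads (4096×2048) stable
at this learning rate in float32. Training is fully seeded:
initialization, shuffling, and dropout masks all derive from the trial
seed, and identical seeds reproduce identical traces.

What freezing does *not* emulate: end-to-end fine-tuning of the conv
stack, pretrained features, and the interaction between head dropout
and backbone learning. Conclusions about *search behavior* (surrogate
quality, pruning, budgets) transfer; absolute accuracies do not.

## Unpromising-trial detection

After each epoch, a trial's validation error is compared to the
reference curve — the per-epoch arithmetic mean of the error curves of
previously *completed* trials (aborted trials are excluded, and each
epoch of the reference records its support). The trial is aborted once
its error has exceeded reference + `margin` at each of the last
`patience` epochs where the reference is defined. Defaults
`margin = 0.02`, `patience = 3`: the margin absorbs seed-level noise
in the error curves, the patience requires the excess to be sustained
rather than a one-epoch blip. The first trials run unmonitored (empty
reference never aborts). The per-epoch-mean interpretation (rather
than comparing final errors only) preserves the epoch dimension that
makes early aborts possible at all.

## Synthetic data

The image generator emulates a small balanced multi-class crop-image
collection: each of the (default 8) classes has a fixed template — a
sinusoidal grating at a class-specific frequency/orientation plus a
Gaussian blob at a class-specific position — and a sample is its
template mixed with a random confuser class's template (mixing weight
|N(0, noise_sd)| capped at 0.9) plus N(0, noise_sd/2) pixel noise,
clipped to [0, 1]. At noise_sd = 0 a nearest-template classifier is
exact; template-oracle accuracy decreases monotonically in noise_sd
(≈0.90 at 0.3, ≈0.70 at 0.5 for 8 classes at 32×32). Defaults: 8
classes, 32×32 grayscale so the tiny backbone trains in seconds.
Not emulated: natural image statistics, backgrounds, lighting, class
imbalance, and intra-class shape variation — so a passing end-to-end
test demonstrates that the *search machinery* ranks heads sensibly on
a learnable task, not that any particular accuracy transfers to field
photographs.

The split follows the 7:2:1 train/validation/test protocol,
per-class stratified and seeded, floor-allocating the validation and
test counts and giving the remainder to training (1,000 images/class
→ exactly 700/200/100). Augmentation (factor k) keeps the originals
and adds (k−1) seeded copies per image, each transformed by one of
flip / shift (±3 px roll) / zoom (5–25% central crop-and-rescale);
factor 2 reproduces the doubling protocol exactly.

The analytic benchmarks are deterministic maps from the encoding to
[0, 1] whose global optimum is found by exhaustive enumeration at
construction: `smooth` is a single Gaussian basin (width 0.6 in
encoded units) peaking at 1 at an interior grid point; `deceptive`
adds a broad lower basin (amplitude 0.55, width 0.9) far from a
narrow global one (amplitude 0.75, width 0.35), with amplitudes
chosen so the sum stays below 1 and the argmax is unique; `noisy`
adds frozen seeded N(0, 0.01) observation noise per configuration.

## Problem sizes

The test and acceptance runs use desk-scale sizes chosen to exercise
every code path with comfortable margins: benchmark searches use the
1,641-configuration space, 20 paired seeds, budget 60; the pruning
mixture uses 100 traces of 20 epochs; the paired pruning searches use
50 images/class, 12 trials of 6 epochs; the end-to-end run uses 200
images/class, 15 trials of 5 epochs.

## Known limitations

- The GP is exact (O(n³)); the loop is intended for budgets of at most
  a few hundred trials, which matches the medium-sized problems
  Bayesian optimization suits.
- The surrogate treats the sentinel-0 slots of shallow architectures
  as ordinary coordinates; depth changes are mediated mainly by the
  `ln` dimension.
- Scoring trials under per-trial (ω₁, β) criteria while comparing them
  with one argmax is inherited as-is (see above).
- The frozen backbone caps attainable accuracy well below a trained
  conv stack; variants A/B/D/E are structurally faithful but
  impractically slow to *train* in NumPy and are used as feature
  extractors only.
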