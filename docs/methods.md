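# Methods

This note records the modelling and numerical choices behind the package:
what the bit-fusion combiner computes, which parameters matter and why
their defaults are what they are, what the synthetic generators do and do
not emulate, and where the design was genuinely open.

## Model

Let ω = {ω₁ … ω_p} be the class set and C₁ … C_l the base classifiers.
For an instance x, classifier j emits a soft support vector in [0,1]^p
summing to 1; stacked, these form the support slice ξ(x) ∈ [0,1]^{p×l}.
The combiner holds a weight matrix wt ∈ ℝ^{p×l}, one weight per
(class, classifier) pair, and computes

- activation F = ξ ⊙ wt (elementwise product — the only reading of the
  combining step consistent with wt having dimension p×l and with the
  entrywise threshold comparison that follows; a true inner product would
  collapse the axes the bit matrix needs);
- bit matrix B = [F > δ], strict inequality, δ ∈ (0,1);
- prediction ŷ = argmax_i Σ_j B_ij (most bits wins).

Training is online and perceptron-like. The target bit pattern for an
instance of class ω_i is Ω: the one-hot row pattern with row i all ones
(the class label broadcast across classifier columns — the label encoding
is a design choice; a p×l pattern is the only shape the bitwise
comparison admits). The error is E = ±(B − Ω) (sign convention below) and
each weight moves multiplicatively:

    Δwt = η · wt · μ · E,   wt ← wt + Δwt / n,

i.e. wt ← wt(1 + ημE/n), with n the number of training instances. One
epoch sweeps all instances in dataset order (the update granularity —
online versus batch — is open; online is chosen because it is the
perceptron-standard reading and makes each instance's error act
immediately). Per epoch the mean over instances of the mean squared entry
of E is recorded as the MSE trace φ; since E is ternary this is the mean
fraction of wrong bits, a decreasing curve when training succeeds. (The
trace has no role in optimization — it is a diagnostic; other published
scalings of the same quantity differ only by constant factors and are not
dimensionally coherent as printed, so the plain mean is used.)

## The two parameter regimes

Two published parameterizations contradict each other and are both
shipped as first-class configurations:

- **Literal regime** (`FusionConfig()` defaults): δ = 0.9, η = 0.71,
  μ = 1e-5, 100 epochs, initial weights i.i.d. uniform on [−0.5, 0.5],
  error sign E = B − Ω.
- **Trainable regime** (`FusionConfig.trainable()`): η = 0.5, μ = 0.2
  (the midpoint magnitudes of the per-dataset coefficient tables, which
  report η ∈ [0.1, 0.6], μ ∈ [0.1, 0.5]; per-dataset pairs are available
  via `FusionConfig.for_dataset`), error sign E = Ω − B, initial weights
  uniform on [0, 0.5].

The literal regime cannot learn, for three separable reasons that the
package's tests make explicit rather than hide:

1. With supports ≤ 1 and |wt| ≤ 0.5, no activation can reach δ = 0.9, so
   B ≡ 0 at initialization.
2. With B ≡ 0 and E = B − Ω, the true-class row of E is −1, which
   *shrinks* true-class weights toward zero — activations move away from
   δ, permanently. The opposite sign (E = Ω − B) grows a true-class
   weight until its activation crosses δ, then stops: a self-calibrating
   per-(class, classifier) threshold, which is the dynamic that makes the
   method work. Both signs are implemented; the choice is recorded in
   every run manifest.
3. The update is multiplicative in wt, so **a weight can never change
   sign** (for ημ|E|/n < 1, which all shipped configurations satisfy —
   this sign preservation is asserted in the test suite). A (class,
   classifier) weight initialized negative therefore can never produce a
   bit, regardless of η, μ or epochs. With a symmetric init roughly half
   of all pairs are permanently masked, and the fused decision degrades
   well below plain majority voting (measured: ≈0.68 vs ≈0.88 accuracy on
   the five-classifier, 70%-accuracy simulation). The trainable regime
   therefore draws initial weights from the positive half of the same
   interval; with it the combiner tracks majority voting to within half a
   point on that simulation while retaining its confidence weighting.

Per-epoch weight growth in the trainable regime is ≈ exp(ημ/p) per epoch
for an unfired true-class weight (the n in the damping cancels against
the n instances per epoch), so 100 epochs multiply a weight by ~e³ — enough
to recruit nearly all positive initial weights at δ = 0.9.

## Prediction fallback chain

At δ = 0.9 an all-zero or tied bit matrix provably occurs (e.g. at
initialization), and the bare argmax rule is silent about it. The
combiner resolves such instances by an ordered, deterministic chain,
reported per instance in the prediction diagnostics:

1. per-class bit counts — accepted only when the maximum is nonzero and
   unique;
2. per-class activation sums Σ_j F_ij — accepted only when the maximum is
   strictly positive and unique;
3. majority vote of the base classifiers' argmaxes — accepted when the
   mode is unique;
4. the lowest class index.

The strict-positivity condition in stage 2 is deliberate: weights can be
negative, and accepting a non-positive maximum would let a unanimous
ensemble be overruled by a row of zeros. With the condition, two
properties hold and are tested: *unanimity* (a hard-mode ensemble that
unanimously predicts c always yields c) and *closure* (the fused
prediction is always a class some base classifier predicted, unless the
chain falls through to stage 4).

## Preprocessing

- Min-max normalization maps each training column onto [0, 1]; the
  recorded extrema are reused for held-out folds (values outside [0, 1]
  are allowed there — no clipping). A constant column maps to all zeros
  with a warning, keeping the transform total.
- PCA eigen-decomposes the scatter matrix Z = (1/n) Σ xᵢxᵢᵀ of
  mean-centered rows. Centering and the 1/n (rather than 1/(n−1))
  normalization are explicit choices: the uncentered second-moment
  variant is available as `center=False`, and the eigenvalue scale does
  not affect components or fraction-based retention. Default retention is
  the smallest k capturing 95% of the eigenvalue mass (the published
  pipeline leaves k unstated). Eigenvector signs are fixed by making each
  vector's largest-magnitude entry positive.
- Both transforms are fit on training folds only and applied unchanged to
  test folds; the evaluation harness never lets test data influence them.

## Base-classifier layer

GaussianNB, CART (Gini, unlimited depth, seeded), RBF-SVM with
pairwise-coupled probability calibration for soft supports (optional
(C, γ) grid search over C ∈ 2⁻⁵…2⁵, γ ∈ 2⁻¹⁵…2⁻¹ by inner stratified CV;
off by default for speed), 10-NN with Euclidean distance (supports =
vote fractions), and a one-hidden-layer MLP with
max(4, ⌈(m+p)/2⌉) hidden units, learning rate 0.4 and momentum 0.5
(values inside the published per-dataset ranges; the architecture is
unspecified there and is this package's choice). Crisp predictions are
always the argmax of the soft supports with lowest-index tie-breaking —
one uniform rule everywhere, chosen over per-classifier tie heuristics so
that soft and hard outputs can never disagree.

The combiner's training tensor is built **out-of-fold** by default: an
internal 5-fold stratified split supplies each training instance with
supports from models not trained on it (standard stacking practice;
resubstitution outputs are available for literal replication but are
optimistically biased, which the test suite demonstrates on a memorizing
decision tree).

## Evaluation protocol

Stratified 10-fold cross-validation by default (plain k-fold when a class
is smaller than k, with a warning); error rate = 100 × mismatches / n.
The accuracy gain per fold is Acc_j = (P_j − S_j)/m — fused correct count
minus best-single-classifier correct count over fold size — averaged over
folds. "Best" means lowest cross-validated error across the whole run,
and the chosen comparator is recorded on the result. Fold sizes differ by
at most one for the unstratified splitter; the stratified splitter
guarantees per-class proportions within one instance per fold instead
(its total fold sizes can differ by slightly more on adversarial label
layouts — a property of per-class remainder placement).

## Synthetic generators

`make_gaussian_dataset` draws p isotropic unit-variance Gaussian clusters
whose centroids sit on a regular simplex scaled to the requested
separation (deterministic geometry; if the feature dimension is below
p−1 the simplex is truncated and distances become approximate). Balanced
classes, interleaved labels, fully seeded. It emulates the *shape* of the
benchmark tables (flat numeric features, few classes) but none of their
pathologies: no feature correlations, no class imbalance, no heavy tails,
no tiny-n/large-m regime. Passing benchmarks on it shows the pipeline's
mechanics are sound, not that published error rates on real repository
datasets are reproduced — those depend on external downloads and on
baseline implementations that were never specified, and are out of scope.

`make_synthetic_xi` simulates the base layer directly: per instance and
classifier, the argmax is the true class with the classifier's nominal
accuracy, wrong classes are uniform, and a shared latent coin (weight =
`correlation`) makes classifiers err on the same instances. Soft supports
are Dirichlet draws with concentration 10 on the winner and 1 elsewhere —
fixed, not configurable, to keep slices realistically peaked (winner mass
≈ 10/(p+9)); the maximal component is swapped onto the winner so nominal
accuracies are exact rather than slightly deflated. Real classifier
errors are of course not conditionally uniform, and real confidence is
not Dirichlet; the generator captures marginal accuracy and pairwise
error dependence, nothing finer.

## Problem sizes

The shipped benchmarks use n = 300 (10-fold, five base classifiers,
out-of-fold stacking) for the feature-table study and n = 5000 with a
50/50 train/test split for the support-tensor study — sizes at which the
Condorcet gap (≈18 points at five independent 70%-accurate voters over
three classes) and the combiner-vs-voting comparison are measured with
comfortable margins over their sampling noise.

## Known limitations

- No convergence theory: training runs a fixed epoch budget (100); the
  MSE trace is diagnostic only.
- The multiplicative update cannot recruit a zero or negative weight;
  the trainable regime works around this by construction rather than
  fixing the update rule.
- Baseline rules are literature-standard reconstructions of named
  methods; comparisons against any published numbers for those names are
  qualitative.
- δ is global; per-classifier or per-class thresholds (equivalently,
  rescaled weights) are not explored.
- Multi-label, missing values, categorical features and streaming input
  are out of scope.
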