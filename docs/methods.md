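# Methods

## Problem and scope

Cardiomegaly — enlargement of the cardiac silhouette, conventionally
quantified on a posteroanterior (PA) chest radiograph by the
cardiothoracic ratio (CTR: maximal transverse cardiac width over maximal
inner thoracic width) — is a binary screening target well suited to
studying hybrid classical–quantum image classifiers: the decision
evidence is a single, anatomically localized structure, so both
predictive metrics and saliency credibility can be assessed. This
package implements the full pipeline at desk scale: curation of
CheXpert-style manifests, a shared training protocol for classical and
quantum classifier heads, statevector simulation of the quantum layer
with exact gradients, evaluation and statistical comparison, Fisher
information/effective-dimension analysis, and Grad-CAM++ saliency with
automated trustworthiness rules. Real clinical images are optional;
everything is exercisable on a synthetic generator whose labels are
governed by the CTR.

## Quantum layer

The parameterized quantum circuit acts on n qubits (default 4),
initialized in |0…0⟩. Gates are restricted to {H, RY, CNOT}. The layout
is: H on every qubit; one RY(φ_i) data-encoding rotation per qubit;
then an ansatz of `depth` (default 4) blocks, each a linear CNOT chain
(control i → target i+1) followed by an RY(θ) rotation layer; plus an
initial and a final rotation layer. This yields P = n(depth+2)
trainable angles — 24 at the default size. The bracketing pre/post
rotation layers are a deliberate resolution of an ambiguity in how
"depth" maps to rotation-layer count; the package treats P = n(depth+2)
as the defining contract and pins it in tests.

Simulation is a dense statevector (2^n complex amplitudes; qubit 0 is
the most significant bit of the basis index — an arbitrary but
test-pinned convention). Two measurement modes exist:

* **expectation**: exact ⟨Z_i⟩ per qubit (the expectation head's n
  outputs);
* **sampling**: the basis-outcome distribution aggregated to D classes
  by `outcome mod D`, either exactly or as empirical frequencies of a
  seeded number of shots (default 10 when enabled). The modulo map is
  the simplest surjective assignment of 2^n outcomes to D classes; with
  n = 4 and D ∈ {2, 4} it partitions outcomes evenly.

Gradients use the parameter-shift rule, exact for RY angles:
∂E/∂a = [E(a+π/2) − E(a−π/2)]/2. Shifts are applied to all trainable
*and* all encoding angles, so the preceding classical layer can be
trained through the circuit by the chain rule. In shots mode, gradients
are still taken on the exact expectations: shot noise perturbs the
forward (prediction) pass only, which avoids 2P·shots extra circuit
draws per step and keeps training deterministic.

## Architecture and initialization

The tanh output of the compression layer lies in (−1, 1) and is scaled
by π/2 before use as encoding angles, making the feature-to-angle map
bijective on (−π/2, π/2). The two output logits pass through a softmax
(equivalent decision surface to a sigmoid under the cross-entropy
loss). Hidden linear layers initialize uniformly in ±1/√fan_in and PQC
angles uniformly in [0, 2π), all from one seed. The final output layer
is **zero-initialized**: every model then starts exactly at chance with
no class offset. This choice matters at desk scale — with the short
shared training budget, a randomly initialized output layer leaves the
narrow (n = 4) quantum bottleneck a residual common-mode logit bias
that 20 epochs at learning rate 1e-4 cannot unlearn, which would poison
threshold-based metrics while leaving ranking metrics perfect.

### Toy feature extractor

The default extractor is deliberately simple and fully deterministic
given its seed: the three (replicated) channels are collapsed to their
mean, average-pooled 4× to 56×56, convolved with a bank of random 5×5
unit-norm filters, passed through ReLU, and average-pooled onto a
grid×grid spatial grid whose cells are flattened into the feature
vector (default: 4 filters × 4×4 cells = f = 64; f = 1024/4096 mirrors
real backbones as 64/256 filters at the same grid). Two design choices
are load-bearing:

* **pool to a grid, not globally** — the discriminative structure (the
  cardiac silhouette) is localized, and global pooling of generic
  filter responses washes the class signal out of the features;
* **filters sign-aligned to a positive DC component** — zero-mean
  random filters behind a ReLU form a pure edge-detector bank: extended
  bright structure never activates map interiors and the dark
  background lights up through negative-DC filters. Pretrained CNN
  channels respond to extended structure; aligning each filter's sum to
  be positive reproduces that qualitative behaviour, which both the
  classification features and the saliency layer inherit.

The filters are trainable (they play the "pretrained layer" role in the
freezer protocol) but carry no pretrained knowledge; an external CNN
can be substituted through the same interface (images in, features out,
pooled maps exposed).

## Training protocol

All heads share one protocol so comparisons are on equal footing: Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), learning rate 1e-4, standard L2
weight decay 1e-4 folded into the gradient, batch size 8, cross-entropy
loss, 20 epochs. The "freezer" option trains the first 2 epochs with
the extractor frozen (classifier heads always train). Augmentation is a
reduced RandAugment — per image and epoch, 2 ops drawn from {rotate
±15°, translate ≤10%, brightness ±20%, contrast ±20%, autocontrast} —
followed by autocontrast with probability 0.5; it applies to the
training split only and is re-drawn each epoch. Magnitudes are fixed at
the listed bounds because the full 14-op policy is out of scope here.
The data-order/augmentation random stream is separate from
head-specific randomness, so classical and quantum runs with the same
seed see identical batch orders and augmentations; in exact-measurement
mode entire runs are bit-reproducible.

One engineering note: geometric augmentation operates on a cached
256×256 resize of each image rather than the raw resolution, followed
by the center crop and normalization. Rotation and translation at the
stated magnitudes commute with the resize to visual equivalence, and
the caching keeps an epoch over several hundred images in seconds.

Splits are stratified by default (the cohorts are balanced by
construction; stratification preserves that within folds): a 70/30
holdout for model exploration, loss curves and saliency, and
stratified 10-fold cross-validation for metric estimation.

## Evaluation and statistics

Seven metrics are reported: ROC AUC (Mann–Whitney rank statistic, ties
at half credit), accuracy, balanced accuracy, and per-class precision
and recall (precision 0 = negative predictive value, recall 0 =
specificity, recall 1 = sensitivity) at a 0.5 threshold on the class-1
probability. A precision whose denominator is empty is reported as NaN
with a flag, never as 0. Fold summaries give the mean and a 95%
confidence interval using the t-distribution with k−1 degrees of
freedom (k = 10 is too small for a normal interval). Model comparisons
use a two-sided paired t-test across folds; 2×2 contingency tables use
Pearson chi-square without continuity correction; demographic summaries
use Welch's t-test with Satterthwaite degrees of freedom. Scipy and
scikit-learn provide the statistical primitives; the package's tests
check them against brute-force enumeration and numeric-integration
oracles.

## Effective dimension

Trainability of the quantum layer is summarized by the normalized
global effective dimension. The model under analysis is the sampling
head's quantum layer: encoding angles x ∈ [−π/2, π/2]^n in, D-class
probabilities p(y|x;θ) out. The empirical Fisher matrix at θ averages
∇_θ log p ∇_θ log p^T over inputs and classes, class-weighted by
p(y|x;θ), with all gradients from the parameter-shift rule and
probabilities clamped at 1e-12 (flagged when the clamp fires). Matrices
are trace-normalized so the mean trace over θ-samples equals P, and

    d_eff(n) = 2 · log( E_θ √det(I + c_n F̂(θ)) ) / log c_n,
    c_n = γ n / (2π log n),  γ = 1,  NGED = d_eff / P.

"Global" means averaged over a uniform prior on [0, 2π)^P (30 θ-samples
and 30 input samples by default, both seeded), not evaluated at a
trained point. √det and the θ-average are computed through eigenvalue
log-sums and a log-sum-exp, so the curve stays finite to n = 10^6 and
beyond. The qualitative finding this package reproduces is an ordering:
the D = 4 head's NGED curve dominates the D = 2 head's over a wide range
of dataset sizes (the four-class partition of the basis distribution is
a finer coarse-graining, hence carries more Fisher information).
Absolute NGED values depend on the sampling configuration and carry no
calibrated meaning.

## Saliency and trustworthiness

Grad-CAM++ weights the channels of the extractor's last layer — its
pooled maps at native (grid×grid) resolution, where each pixel is
exactly one feature the head consumes — by

    α_ij^kc = (∂²Y/∂A_ij²) / (2 ∂²Y/∂A_ij² + Σ_ab A_ab ∂³Y/∂A_ij³),
    w_k = Σ_ij α_ij^kc · relu(∂Y/∂A_ij^k),
    L = relu(Σ_k w_k A^k),

bilinearly upsampled to the 224×224 input frame and max-normalized
(all-zero when the model offers no positive evidence). Derivatives are
taken on the pre-softmax class score. As in the method's reference
formulation, the curvature terms are those of the exponential of the
score (the common exp factor cancels in the α ratio); this leaves
piecewise-linear heads exactly where the raw formula puts them while
keeping α well-behaved through the smooth quantum layer. First
derivatives are analytic (reverse mode and parameter shift); the
diagonal second and third derivatives come from vectorized central
differences of the head score along each feature coordinate — exact for
piecewise-linear heads away from kinks, step 1e-2 otherwise. Where the
curvature terms vanish but the gradient does not, α falls back to the
uniform 1/Z weighting (Grad-CAM); where the gradient vanishes too,
α = 0.

The human review criterion — a heatmap is trustworthy when its hot zone
covers most of the cardiac silhouette — is operationalized with four
explicit thresholds: hot zone = connected components of pixels ≥ 0.5 ×
max; *not_visible* if empty; *extensive* if the hot area exceeds 0.5 of
the image; *multiple_zones* if the second-largest component is ≥ 0.5 of
the largest; *outside_cardiac* if the largest component covers < 0.5 of
the heart mask; else trustworthy. Verdicts are invariant to positive
rescaling of the raw heatmap. These rules are an automated stand-in for
blinded expert review: comparable in spirit, not in value.

## Synthetic data

The generator draws schematic PA-like radiographs: a bright thoracic
ellipse containing two darker lung fields, a brighter low-central
cardiac ellipse whose transverse width is exactly CTR × the inner
thoracic width (aspect ratio fixed, so heart-mask area scales as CTR²),
seeded placement jitter of ±1% of the image side, Gaussian noise
(σ = 0.03), and an optional effusion-like basal opacity placed
independently of class (probability 0.2) as a confounder. Controls draw
CTR ~ U(0.35, 0.45) and cardiomegaly cases CTR ~ U(0.55, 0.70),
mirroring the curation thresholds; the deliberate gap in (0.45, 0.55)
makes the classes separable by construction so that training checks are
stable (a `hard_mode` flag narrows the gap for stress testing). Each
record carries ground-truth heart and thorax masks; the measured CTR
(mask width ratio) round-trips the drawn value within 0.02. Manifest
demographics are filled from seeded distributions matching the real
cohort's summary shape (control age ~ N(54.4, 17.2), disease ~
N(62.9, 17.1), truncated to [18, 100]; male fraction 65% vs 59%), so the
summary-statistics operations have realistic fixtures.

What passing tests on this generator show: that the pipeline's
mechanics — gradients, protocol, metrics, saliency plumbing — behave as
specified when the class signal is a clean geometric quantity. What
they do not show: performance on real radiographs, where CTR
distributions overlap, labels are noisy, anatomy varies, and the
extractor's pretrained features matter. Synthetic AUC of 1.0 is a
property of the generator's separability, not a claim about clinical
accuracy.

## Curation operations

Manifest curation mirrors the study protocol: keep each patient's first
chronological frontal-PA row (rows with malformed view or order values
are dropped with a warning); optionally requalify labels against a CTR
column (positive labels with CTR ≤ 0.45 flip to control, negative
labels with CTR ≥ 0.55 flip to cardiomegaly, the doubtful band is left
intact — an idempotent operation); and balance classes by seeded
undersampling of the majority. CheXpert label semantics are preserved
verbatim through round trips (1/0/−1/blank as strings); the treatment
of uncertain (−1) labels is an explicit policy with `exclude` as the
default, since only 1 is unambiguously positive and {0, blank} negative.

## Problem sizes and degenerate inputs

Default analysis sizes are chosen for single-CPU work: 300 images per
class for end-to-end training studies, 30×30 Fisher samples for NGED,
a 17-point logarithmic dataset-size grid from 10² to 10⁶. Statevector
simulation is exact up to the tested n = 6; parameter-shift and
finite-difference gradients agree to 1e-6, and the simulator agrees
with explicit 2^n×2^n matrix products to 1e-10. Degenerate inputs have
defined contracts: single-class datasets, zero-variance paired
differences, zero contingency marginals, empty masks, all-zero Fisher
matrices and c_n = 1 all raise or flag rather than returning silent
values.

## Known limitations

* The toy extractor carries no pretrained knowledge; clinical-scale
  metric values (and the relative CC-vs-CQ saliency ordering seen on
  real data) are out of reach by design. On the synthetic cohort the
  classical head's heatmaps are at least as trustworthy as the quantum
  head's — with four generic filters the channel space is too small for
  the channel-reweighting mechanism of Grad-CAM++ to differentiate the
  heads the way it does on a 1024-channel backbone.
* Shot sampling models sampling noise only; there is no gate noise,
  decoherence or hardware model.
* The trustworthiness rules are fixed thresholds, not a learned or
  human-validated classifier; their defaults are declared, not fitted.
* The quantum layer's gradient cost scales as 2(P + n) circuit
  evaluations per batch; the implementation batches circuits over
  samples but n ≳ 10 qubits at depth 4 becomes slow on one CPU.
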