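# Methods

## Problem and model

The package targets binary (or generally C-class) classification of single-cell
cytology crops — the setting of urinary-cytology screening, where a classifier's
*confidence* matters as much as its accuracy because it feeds a clinical risk
assessment. Two failure modes of plain deep CNNs in this regime are addressed
jointly: poor data efficiency on small collections, and miscalibration
(confidences systematically exceeding empirical correctness rates).

**Multi-exit architecture.** The backbone is a VGG-style stack of macroblocks,
each one or more 3×3 convolution + ReLU layers followed by a 2×2 max-pool.
After every macroblock's pooling layer an *early exit* — a flatten + single
linear layer emitting C scores — can be attached; the backbone's own final
classifier is an additional flatten+linear head on the last block with its own
parameters, so a model with one exit per block has E = (number of blocks) + 1
heads. Each head i emits a softmax probability vector f̂ᵢ(x). The model's
decision comes from an adaptively learned combination

    t = Σᵢ wᵢ f̂ᵢ(x),      p(x) = softmax(t),

with w ∈ ℝᴱ trained jointly with everything else by backpropagation. The
training objective per sample is

    ℓ̃(y, x) = α ℓ(y, p(x)) + β Σᵢ ℓ(y, f̂ᵢ(x)),

with α = β = 1 by default; α = 0 recovers purely deeply-supervised training,
β = 0 trains only through the combiner. The per-sample loss ℓ is either the
cross-entropy or the focal loss −(1−p_y)^γ log p_y, whose γ > 0 factor
down-weights confidently-classified samples and acts as an entropy-raising
regularizer that improves calibration; γ = 0 recovers the cross-entropy
exactly. Default γ = 2 (the customary choice in the focal-loss literature);
the experiment driver can tune it over {1, 2, 3} on validation accuracy.

**Combination operand.** Whether the combiner should weight post-softmax
probabilities or raw head logits is genuinely open; each head is defined to end
in a softmax (it appears inside a cross-entropy term), so the default weights
the E probability vectors with a scalar each. Two alternatives are implemented
behind flags: weighting raw logits (`combine_on="logits"`), and a per-class
weight matrix w ∈ ℝ^{E×C} (`per_class_weights=True`). All three are covered by
the finite-difference gradient tests.

**The standard baseline** (no early exits) is the literal single-head path:
its combined score *is* the final head's logits. Realizing it instead as a
degenerate multi-exit model with w selecting the last head would, under
probability combining, evaluate softmax(softmax(z)) and squash the baseline's
confidences — harmless for accuracy (argmax is preserved; this equivalence is
tested) but distorting for its ECE, which the experiment grid must measure
honestly.

**Calibration.** A model is calibrated when P(ŷ = y | p̂ = p) = p. Post-hoc
temperature scaling replaces softmax(t) with softmax(t/T), T > 0 fitted by
minimizing mean cross-entropy on the validation split (bounded scalar
minimization on [0.05, 10], tolerance 1e-4, with a fallback to T = 1 if the
optimizer ever fails to improve on it). Scaling by a positive scalar preserves
the argmax, so accuracy is bit-identical before and after — asserted
throughout. The expected calibration error partitions (0, 1] into M = 10
equal-width bins ((m−1)/M, m/M] (zero confidence joins bin 1; empty bins are
excluded) and reports Σₘ (Bₘ/N) |acc(Bₘ) − conf(Bₘ)|, where confidence is the
maximum class probability of the evaluated output. Per-exit diagnostics
evaluate every head in isolation (accuracy and ECE), optionally after fitting
a separate temperature per head on the log head probabilities (a global shared
temperature is available by flag); a head's own temperature cannot change its
accuracy, and the suite asserts this.

## Data pipeline

Real data enter as a CSV manifest (path, label, patient_id) of RGB images.
Preprocessing: (1) every image is quartered from its center point — four
quadrant crops that tile an even-sized image exactly (odd dimensions drop the
center row/column; an overlapping-crops variant exists behind a flag); a
bilinear resize to a target size such as 128×128 is optional and off by
default, since the synthetic task uses native crop size; (2) *patients*, not
images, are shuffled by a seeded RNG and allocated ⌊0.6P⌋/⌊0.2P⌋/remainder to
train/validation/test, so all of a patient's crops land in one split and no
patient-level leakage can inflate test scores; (3) the training split only is
augmented with 90°/180°/270° rotations (4× the crops).

## Synthetic generator

Tests and the desk-scale experiment run on a built-in generator, so nothing
needs downloading. Each image holds one cell on a light stained background:
an elliptical cytoplasm and a concentric darker elliptical nucleus whose area
is a class-dependent fraction of the cell area. Class 1 ("abnormal") draws its
nucleus-to-cytoplasm area ratio from (0.55, 0.80) — above the 0.5 threshold
that flags atypical urothelial cells — and a darker nucleus intensity
(0.12, 0.38), a hyperchromasia analogue; class 0 ("normal") draws ratio
(0.15, 0.35) and intensity (0.25, 0.45). The nucleus is the cell ellipse
scaled by √ratio, so the drawn pixel-area ratio matches the target by
construction (verified against the generator's own masks in tests). Each
synthetic patient carries shared style offsets — background tint, cytoplasm
shade — across its images, and i.i.d. Gaussian pixel noise (σ = 0.25) is
added and clipped to [0, 1].

Default conditions: 40 patients × 20 images, balanced classes, 32×32 pixels
(16×16 quadrant crops). The noise level and the overlapping class intensity
ranges were chosen so that a desk-scale baseline lands in the high-80s/low-90s
accuracy band — the regime the method is designed for — rather than
saturating; with clearly disjoint intensity ranges the task collapses to a
mean-brightness threshold. What the generator does *not* emulate: Papanicolaou
stain chromatics, multiple or overlapping cells, debris and inflammation,
scanner artifacts, multi-grade labels. Passing tests therefore demonstrate
correctness of the machinery and the *direction* of the method's effects on a
controlled task, not clinical performance.

## Experiment grid

Eight variants: {standard, multiexit} × {cross-entropy, focal} × {TS off/on}.
Temperature scaling is post-hoc, so each (architecture, loss) pair is trained
once per run and evaluated twice; TS rows share their accuracy with non-TS
rows by construction. Training uses Adam (lr 1e-3) on shuffled minibatches of
32, with early stopping on the validation objective and restoration of the
best-validation checkpoint. Run r of n derives every seed (data generation,
patient split, weight init, batch shuffling) from master + r; a flag fixes the
data/split across runs so only training randomness varies. Results are
averaged over 5 independent runs (mean and SD reported).

Desk-scale defaults: backbone of 4 blocks, widths (8, 16, 32, 32), convs per
block (1, 1, 2, 2) — deliberately deep relative to the 16×16 crops so the
gradient-flow benefit of deep supervision, the regime the method targets, is
actually exercised — trained for up to 12 epochs with patience 4 (validation
loss typically plateaus within this budget at these sizes). A full-scale
preset (`vgg16_config()`) reproduces the 5-block VGG-16 shape with 6 heads
for 128×128 inputs.

## Numerical choices

* The network engine is pure NumPy (float64): im2col 3×3 convolutions, 2×2
  max-pool with argmax routing, dense heads, Adam. Backpropagation through the
  full graph — including the focal loss, each head's softmax and the
  probability-combining path — is hand-derived and verified against central
  finite differences to ~1e-8 relative error in the test suite.
* Probabilities are floored at 1e-12 inside logarithms; for γ < 1 the
  (1−p)^{γ−1} focal-gradient factor is floored likewise.
* Weight init: fan-in-scaled Gaussian (He), biases zero, combiner w = 1/E
  (a uniform ensemble at the start); all seeds explicit.
* argmax ties resolve to the lowest class index (NumPy convention).
* Checkpoints are .npz archives embedding a JSON description of the
  architecture, so they are self-describing.

## Known limitations

* The engine is CPU-bound and sized for desk-scale experiments; full VGG-16
  training on 128×128 crops is out of its intended range.
* Only temperature scaling is provided for recalibration (no histogram
  binning, isotonic regression or Platt scaling), and only equal-width bins
  for ECE.
* Per-input adaptive exit selection (inference speed-up) is not implemented;
  all heads are always evaluated.
* At desk scale the accuracy gap between the multi-exit and standard
  architectures is a few tenths of a percentage point per run under the focal
  loss; individual runs near the task's ceiling can tie or invert even though
  the mean direction is consistent.
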