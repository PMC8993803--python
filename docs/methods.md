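# Methods

This note records the models, numerical conventions and design choices
behind `mammowave`, and what the synthetic-data experiments do and do not
demonstrate.

## Image model and preprocessing

Images are single-channel float fields in [0, 1] (`GrayImage`); 8-bit
quantization happens only at the PNG boundary, NPY round-trips are lossless.
Color inputs collapse to luminance with ITU-R 601 weights. Min–max
normalization maps a constant image to zeros: a constant field carries no
contrast information, and zero is the less surprising fixed point for
downstream energy and wavelet operators.

**CLAHE** is delegated to scikit-image's `equalize_adapthist`. Parameters:
normalized clip limit (default 0.01) and tile grid (default 8×8), both
conservative common choices; the tile grid must not exceed the image.
Constant images bypass equalization unchanged.

**Gradient energy.** The per-pixel energy is |∂I/∂x| + |∂I/∂y| with central
differences on a replicate-padded image, one uniform rule everywhere
including borders. Replicate padding makes a constant image's energy exactly
zero and halves the border response relative to one-sided differences — an
acceptable bias given seams rarely hug borders of interest.

**Seam carving.** Classic dynamic programming over 8-connected steps
{−1, 0, +1}, accumulated bottom-up so the top-down walk is greedy. Ties
break to the smallest starting index, then the smallest index per step,
making every seam deterministic. The energy map is recomputed after every
removal (content awareness at desk-scale cost, O(n·HW) per direction).
Vertical seams are removed before horizontal ones; the order is fixed purely
for reproducibility. The default carving extent in the pipeline is 5% of
each dimension — enough to exercise the stage without visibly degrading
structures; it is configuration, not a claim about an optimal amount.

**Haar decomposition.** The orthonormal (1/√2) convention is used so that
one level conserves energy exactly (Parseval), giving the test suite a sharp
invariant; an alternative averaging convention would differ only by a
constant scale per level. Odd dimensions are replicate-padded to even on the
right/bottom, recorded per level and stripped on synthesis, so perfect
reconstruction holds for every shape. Band naming follows the separable
products: LH = wavelet along rows (horizontal detail), HL = wavelet along
columns (vertical detail); PyWavelets swaps these two labels, which the
cross-check test accounts for. The maximum depth is floor(log₂ min(m, n)).
The default pipeline depth is 2 — a 299×299 input yields a 75×75
approximation band, small enough to matter and large enough to train on.
The multilevel default is the Mallat pyramid (recurse on LL only); the full
packet tree is available (`wavedec2_packet`) but unused by default. The
deepest LL is min–max renormalized before entering the network. Note one
consequence observed on the synthetic fixture: renormalization plus CLAHE
removes absolute-brightness cues, so classification there relies on spatial
structure — see "What the synthetic experiments show" below.

## The wavelet activation

ψ(x) = cos(βx)·e^(−x²/2), elementwise, β > 0 a global hyperparameter
(default 0.5). It is bounded by the Gaussian envelope, smooth, and decays
below 1e−8 for |x| ≥ 6.5. For |x| > 40 the implementation returns exactly 0
(the envelope is < 1e−347 there; flushing avoids subnormal noise).
Non-finite inputs raise immediately rather than propagate. The backward pass
uses the analytic derivative

ψ′(x) = −β sin(βx) e^(−x²/2) − x cos(βx) e^(−x²/2),

validated against central finite differences (max deviation ~1e−10 over
[−4, 4]).

**Initialization.** Activations leaving ψ are compressed: for Z ~ N(0, 1),
Var[ψ(Z)] ≈ 0.0918 (and E[ψ(Z)] ≈ 0.664, since E[cos(bZ)e^(−Z²/2)] =
e^(−b²/4)/√2). With plain Glorot weights the signal variance collapses layer
by layer and deep ψ-stacks sit in the flat region where ψ′(x) ≈ −(β² + 1)x
is tiny — training stalls at chance. Convolutions feeding ψ therefore use
Glorot scaled by 1/√Var[ψ(Z)] ≈ 3.30, the analogue of He's √2 gain for ReLU.
This makes desk-scale training reliable across seeds. Even so, stacks of six
or more ψ layers remain hard to train without normalization layers — a known
limitation of the activation, noted below.

## Network architectures

Default topology (both CNN and wCNN): six blocks × three same-padded 3×3
convolutions with L2 factor 2·10⁻⁴ on kernels, each block closed by 2×2 max
pooling (stride 2, floor mode); flatten → dropout 0.5 → dense softmax.
Filter schedule [32, 64, 128, 256, 512, 512]: powers of two from 2⁵ to 2⁹
with the cap repeated for the sixth block. Default input 299×299×1. The two
architectures differ only in the activation (ReLU vs ψ), which carries no
parameters, so their parameter counts are identical by construction
(~15.0 M at the default spec).

Training: mini-batch categorical cross-entropy plus the L2 penalty, Adam
(default lr 1e−5, the full-size setting; the desk-scale experiments below
use 3e−4) or SGD, batch 64 default, 10 epochs default. Loss on softmax
probabilities with the exact softmax Jacobian in the backward pass. Shuffle
order, dropout masks and weight init all derive from explicit seeds; a
non-finite loss aborts with a diagnostic. With learning rate 0 the model is
provably unchanged (no normalization layers exist in the classifiers, so
training-mode statistics cannot leak).

The network input size follows the preprocessed sample's actual shape
rather than upsampling the approximation band back to 299 — interpolation
would blur exactly the features the decomposition isolated. An explicit
resize is available at the GAN boundary only (nearest-neighbor).

## DCGAN

Generator: 100-d Gaussian noise → dense projection to 4×4×F₀ → batch-norm +
ReLU → stride-2 fractionally strided 5×5 convolutions (batch-norm + ReLU)
→ final fractionally strided convolution to one channel with tanh and no
batch-norm. Discriminator: stride-2 5×5 convolutions (batch-norm +
LeakyReLU 0.2) down to 4×4, flatten, single sigmoid unit. All weights start
normal(0, 0.02). Losses: standard non-saturating adversarial objective;
Adam with generator lr 1e−5, discriminator lr 1e−4, β₁ = 0.5, β₂ = 0.999,
batch 32. One GAN is trained per class, sidestepping conditional machinery.
Images map [0,1] ↔ [−1,1] at the module boundary. The canonical ladder
4→8→…→output is used; output sizes must be powers of two reachable from
4×4. Desk-scale runs use 32–64 px outputs with small channel counts; the
full-size 256-px configuration is expressible through `GanSpec`.
Smoke-scale adversarial training (tens of steps) demonstrates mechanical
correctness — finite losses, live gradients — not sample quality; no
fidelity metric is computed.

## Evaluation metrics

Per-class one-vs-rest tallies feed the binary formulas (accuracy,
specificity, sensitivity, precision, recall, F1). Default averaging is
micro: counts are pooled before applying the formula, under which precision
= recall = F1 = accuracy for single-label multiclass data (the module
self-tests this identity). Macro averaging is available. Micro specificity
pools one-vs-rest true negatives and therefore inflates with class count; it
is reported as defined and flagged here rather than corrected. A metric with
a zero denominator is reported as 0 with a logged warning, never NaN. The
sensitivity/recall pair is intentionally duplicated — they are the same
formula and both are emitted for report completeness.

## Synthetic data generator

Each class adds a structure to a smooth low-contrast background (2–4
low-frequency cosine gratings around 0.4 plus Gaussian pixel noise,
σ = 0.02 default):

- N: background only;
- BM / M: 1–2 Gaussian blobs, M brighter (full lesion amplitude, default
  0.45) and ~40% larger than BM (0.55× amplitude);
- BC / CALC: cluster of 1–3 px speckles, 4–8 (BC) vs 12–24 (CALC);
- AD: 6–11 radial line segments converging on a focus;
- ASYM: monotone lateral ramp (0.6× amplitude) over the background.

Per-sample seeds derive from SHA-256 of (global seed, class, index), so
generation is order-independent and bit-reproducible; dataset ordering is a
seeded shuffle; train/val/test splits are stratified per class. The defaults
make the N-vs-M task separable by a single max-intensity threshold at ≥95%
accuracy (a tested property) — the point is a *learnable* fixture, not
realism.

**What the synthetic experiments show.** Passing tests demonstrate the
machinery: exact transforms, optimal seams, correct gradients, learnable
signal flow, deterministic orchestration. They do not show clinical
performance: the generator has no breast anatomy, no pectoral muscle or
labels, no scanner noise model, and its lesion contrast is a free knob not
calibrated to any screening corpus. One interaction worth knowing: CLAHE +
per-image renormalization removes absolute-intensity cues on this fixture,
so the pipeline's classifier learns spatial structure; with enough epochs it
still separates the classes (the worked example reaches ~96% test accuracy),
but comparisons between preprocessing variants on synthetic data say nothing
about their value on real mammograms.

## Desk-scale experiment sizes

The test suite and acceptance script size every stochastic experiment to a
single CPU: learnability uses a two-class 200/100-image fixture at 64×64
with a 2-block × 2-convolution wCNN (filters 8/16, Adam lr 3e−4, batch 8,
5 epochs); GAN smoke runs 50 steps at 64×64 with reduced channels; the
determinism check runs the full five-class pipeline (50 images/class,
depth-2 decomposition, 3 epochs) twice and compares artifacts byte for byte.
These sizes are the package's own scaled-experiment choices; the full-size
specs remain the library defaults.

## Known limitations

- Deep ψ-stacks (the full 18-convolution wCNN) train poorly without
  normalization layers even with the variance-preserving init; the default
  architecture is faithful to its description, but desk-scale demonstrations
  of learning use the shallow configuration above.
- Micro specificity inflates with class count (see above).
- Seam carving assumes the informative structure has high gradient energy;
  on flat synthetic backgrounds this holds by construction.
- The GAN is exercised mechanically only; augmentation quality is untested.
- No DICOM ingestion; PNG and NPY only.
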