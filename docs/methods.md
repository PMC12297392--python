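# Methods

This note records the scientific and numerical choices behind the
package: what each component assumes, which parameters matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open.

## Speckle model and preprocessing

Ultrasound speckle is multiplicative: the observed intensity is the
underlying echogenicity times a positive, unit-mean noise field. The
preprocessing chain therefore leads with an edge-preserving smoother
rather than a linear filter.

**Anisotropic diffusion.** The explicit 4-neighbour scheme
`I ← I + λ Σᵢ cᵢ·∇Iᵢ` is run for a fixed number of iterations with
reflective boundaries. The conduction function is Perona–Malik
exponential, `c = exp(−(∇I/κ)²)`, applied per direction: differences
well below κ diffuse freely, differences above κ (edges) are preserved.
Defaults: λ = 0.2 (hard cap 0.25 — the explicit scheme's stability limit
for a 4-neighbour stencil), κ = 0.1 on [0,1] intensities, 15 iterations.
Because the scheme is in divergence form with symmetric conduction
(c depends only on the shared difference), total intensity is conserved
to rounding; the tests assert ≤ 1e-6 relative drift.

**Histogram equalization and CLAHE.** Intensities are quantized to
L = 256 bins; the global transfer function is the normalized CDF. CLAHE
clips each tile's histogram at `clip_limit × tile_pixels / L`
(clip_limit expressed as a multiple of the uniform bin height),
redistributes the excess uniformly, and interpolates the per-tile
transfer functions bilinearly between tile centres. Two limits anchor
correctness: a single unclipped tile reduces exactly to global
equalization, and a constant image passes through unchanged. Defaults
(clip 2.0, 8×8 tiles) are conventional for 256² medical images; the
study never states the values it used, so they are configuration.

**Edges.** Sobel 3×3 gradients with reflective borders; orientation is
`arctan(∂I/∂y / ∂I/∂x)` in (−π/2, π/2], defined as 0 where both partials
vanish and +π/2 where only ∂I/∂x does. The refinement chain is
Canny-style but with every stage independently testable: optional
non-maximum suppression along the quantized orientation, then
dual-threshold hysteresis (strong seeds ≥ high; weak pixels in
[low, high) kept iff 8-connected to a seed). The hysteresis thresholds
are data-dependent and deliberately configuration-only.

**Coordinates.** Row-major, 0-based; ROI boxes half-open on the max
side. Closed-interval box descriptions are converted to half-open at the
implementation boundary.

## The T-Net and its NumPy engine

The architecture follows the published block table and layer enumeration
exactly. Both T-block branches (standard and dilation-2 convolution)
read the block *input*; the published connection cell for the second
branch lists the first branch, but its printed parameter count
(640 = 3·3·1·64 + 64 at the stem) is only consistent with
parallel-from-input wiring, which the block description also states. The
same accounting confirms the choice at every encoder level.

Other enumeration details worth recording:

- Batch-norm rows count 4·C parameters (scale, shift, and the two
  non-trainable moving statistics), matching common model-summary
  output.
- The published attention row "Dense … 524,544, output (None, 2048)" is
  internally inconsistent: 524,544 parameters is the first shared
  bottleneck layer (2048→256), while (None, 2048) is the width after the
  second. Both shared layers are implemented (Dense, Dense2); the
  verification checks the printed parameter count under the printed name
  and skips that row's shape.
- The enumeration terminates at (None, 64, 64, 1) with zero parameters.
  No convolution is parameter-free, so the strict head is implemented as
  channel-averaging + sigmoid (0 parameters) to honor the table. The
  training head (`full_resolution`) instead completes the final decoder
  T-block, upsamples twice (nearest-neighbour), and applies a 1×1
  convolution + sigmoid at full input resolution.

The engine (`tatha.nn`) is a small static-DAG executor with hand-written
backward passes for exactly the layer vocabulary the network needs.
Convolutions are computed as K² shifted BLAS matrix products (low peak
memory, no im2col buffer); the transposed convolution is zero-stuffing
followed by a same-padded convolution, with the standard
9·c_in·c_out + c_out parameter accounting. Batch-norm moving statistics
use momentum 0.99 with bias-corrected (debiased) exponential averages,
so evaluation-time normalization is calibrated from the first update —
without the correction, short CPU-scale runs evaluate against the
near-initial statistics and validation metrics collapse. Initialization
is He-uniform from the configuration seed; BN ε = 1e-3. Forward passes
are deterministic given weights and input.

## Loss

With soft cardinalities |P∩G| = Σ p·g, |P−G| = Σ p(1−g),
|G−P| = Σ (1−p)g:

```
L = 0.23·(1 − TI) + 0.65·(1 − Dice) + 0.12·(1 − TI)^γ
TI = (|P∩G| + ε) / (|P∩G| + α|P−G| + β|G−P| + ε)
```

The blend weights 0.23/0.65/0.12 are the published constants. α, β, γ
are not published; the defaults α = 0.7, β = 0.3 weight false negatives
more heavily (the usual choice for small lesions, and the direction the
loss's stated purpose — controlling the FP/FN trade-off — implies), and
γ = 0.75 is the standard focal-Tversky exponent. All three are explicit
configuration. ε = 1e-6 smooths every ratio; both-empty-mask Dice is
defined as 1. For the default weights and γ ≥ 1 the loss lies in [0,1],
vanishing iff P = G (up to ε); training uses the exact analytic
gradient, which the tests check against finite differences.

Reported metrics are pixelwise, from hard masks at threshold 0.5
("binary accuracy" is read as thresholded pixel accuracy). AUC is the
trapezoidal ROC area over all probability cut points and equals the
normalized Mann–Whitney statistic; "mAP" is read as pixelwise average
precision (PR-curve area), the only well-defined interpretation for a
binary task.

## Ensemble

How the fusion weights are trained is not published, nor the number of
extractors. Choice: N = 3 networks differing only by initialization
seed; weights are a softmax over per-extractor mean validation Dice with
temperature τ = 10. This is monotone in extractor quality, reduces to
uniform weights on ties, and degrades gracefully (τ→0 uniform, τ→∞
argmax). Masked/unmasked conflicts are resolved by thresholding the
convex combination at 0.5 — a weighted vote — since no per-region rule
is given.

## Synthetic phantoms

The generator emulates the statistics that drive the pipeline's design:
a smooth low-frequency background field around gray level 0.55, one to
three rotated elliptical hypoechoic nodules with mean contrast 0.35 and
Gaussian-feathered margins, unit-mean gamma multiplicative speckle
(shape 4, i.e. amplitude SD half the mean — heavy but realistic for
unfiltered B-mode), and a σ = 1.5 point-spread blur. Split sizes mirror
the emulated study: 450/95/92 train/val/test, and 15 folds with the
training count fixed at 450, test at 92, and validation resampled
uniformly from the observed 93–147 spread.

What the phantoms do *not* contain: acoustic shadowing and enhancement,
anatomy beyond ellipses, depth-dependent gain, scanner post-processing,
or inter-patient texture variation. Passing the desk-scale training
benchmark therefore shows the pipeline is implemented correctly and can
learn a speckled low-contrast segmentation task — it does not certify
clinical-grade performance on real ultrasound.

## Statistics

Fold columns are summarized by the arithmetic mean and *sample* SD
(n−1): reproducing the published summary table from the published fold
table requires the sample convention (population SD gives 0.0025 for
the accuracy column, not the printed 0.0026). The t-test is two-sided,
matching the stated hypotheses (H₁: value ≠ baseline), with the
published "p = 0.0001" entries treated as a reporting floor — the
harness reports full-precision p. Shapiro–Wilk uses Royston's AS R94 as
implemented in scipy; the tests cross-check W against an independent
classic (1965 coefficient-table) implementation to within 5e-4.

One published normality value does not reproduce from its own fold
table: the accuracy-column W computes to 0.9530 by both Royston's and
the classic algorithm (and 0.9652 by Shapiro–Francia), against a printed
0.9572. The Dice column *does* reproduce (0.9450 vs printed 0.9453), so
the harness is left asserting the printed accuracy value and failing it
visibly rather than papering over the discrepancy.

## Problem sizes and test design

The packaged benchmarks run at desk scale by design: training checks use
64×64 phantoms with a quarter-width encoder (filters 16…256, the same
architecture and both heads), 32 training images, and ≤ 12 epochs; the
ensemble check uses three eighth-width networks briefly trained. The
canonical 256×256, filters-64…1024 build is exercised for construction,
enumeration, and forward-pass contracts, not trained in the test suite.
Study-scale settings (256×256, batch 16–32, 20–100 epochs, early
stopping on validation loss) remain available through configuration.

The hysteresis-vs-flood-fill equivalence is checked exhaustively over
all 3⁹ ternary 3×3 magnitude patterns (below-low / weak / strong —
the complete case analysis for dual thresholds) plus a seeded random
sample of ternary 5×5 patterns; exhausting 5×5 outright (3²⁵ patterns)
is not informative per unit cost, since 8-connectivity decisions are
local and the 3×3 enumeration already covers every neighbourhood
configuration.

## Known limitations

- The NumPy engine targets clarity and testability; it is single-
  threaded beyond BLAS and not competitive with GPU frameworks for
  study-scale training.
- Nearest-neighbour upsampling in the full-resolution head (rather than
  a second pair of transposed convolutions) keeps the head cheap; the
  published enumeration is silent above 64×64.
- Sensitivity/specificity are pixelwise; lesion-wise detection rates are
  not computed.
- The phantom generator's realism limits are listed above; conclusions
  about real DDTI performance require real data and study-scale
  training.
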