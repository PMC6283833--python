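# Methods

## Problem and approach

`perlinaug` augments small datasets of labeled 2D texture patches — the
motivating case is 20 × 20-pixel HRCT regions of interest labeled with one of
six diffuse-lung-disease texture classes — by blending *pairs* of patches
through the sign mask of a smooth random field. Because the mask derives from
gradient noise rather than from axis-aligned cuts, the two classes meet along
an organic boundary, resembling real parenchyma where disease patterns mix.
Each augmented patch carries a per-pixel label grid, which turns a
patch-classification dataset into a per-pixel (segmentation-style) training
stream and lets a small number of source patches generate an effectively
unlimited supply of mixed examples.

The package implements the full loop: noise core, mask construction and
blending, a conventional flip + Gaussian baseline, a synthetic six-class
texture dataset, a scaled-down encoder–decoder CNN, and the pixel-by-pixel
accuracy statistic with paired t-tests.

## Simplex noise core

`perlinaug.noise` implements 2D simplex noise from scratch:

* the input point is skewed by `F2 = (√3 − 1)/2` onto a triangular lattice
  and the containing simplex's three corners identified;
* each corner contributes `(0.5 − d²)⁴ · (g · d)`, where `d` is the
  corner-to-point distance vector and `g` a pseudorandom gradient; corners
  with `d² ≥ 0.5` contribute nothing, so no explicit interpolation is needed;
* gradients come from the standard 12-direction set (the 2D projections of
  the cube-edge gradient triples), selected through a seeded permutation
  table;
* the sum is scaled by 70, the conventional normalization for this kernel;
  empirical extremes over large samples stay just inside [−1, 1] (≈ 0.996
  over 10⁴ points), which the tests assert as a hard bound.

The permutation table is `numpy.random.default_rng(seed).permutation(256)`,
doubled for wrap-free indexing. This shuffle is a documented part of the
contract so independent transcriptions (the test suite keeps one, written as
straight-line scalar code) can reproduce outputs bit-for-bit; agreement on
fixed probes is asserted to 1e-9.

`noise_field(h, w, scale, seed, octaves)` samples `values[i, j] =
simplex2d(j·scale, i·scale)`. **scale** (lattice units per pixel) defaults to
0.1, which puts roughly two feature periods across a 20-pixel patch and
yields coarse two-region masks; the source study does not report its noise
frequency, so the value is a package choice and is exposed as a parameter,
as is the octave count (default 1; multi-octave fractal summation is
renormalized by the total amplitude so the bound survives).

## Augmentation

`field_to_mask` thresholds a field at zero; exact zeros join the positive
region (a measure-zero tie, fixed for reproducibility). Over many seeds the
mean true-fraction of the mask sits near 0.5, consistent with the sign
symmetry of the noise.

`perlin_blend` takes pixels from patch A where the mask is true and from
patch B elsewhere, and records the same choice in the label grid — every
output pixel is bit-identical to the source patch its label names, which is
asserted as a property test. Flips are applied to the two sources *before*
masking, matching the stated order of the original procedure. Pair sampling
draws two patches uniformly; the classes may coincide (the study does not say
they must differ, and same-class blends are label-level identities). A
`distinct_classes` switch forces differing classes for exploration.

The conventional baseline flips up/down and left/right independently with
probability 0.5, then adds zero-mean Gaussian noise with σ equal to 1/10 of
the patch's own population standard deviation (population rather than sample:
at 400 pixels the difference is negligible, but one convention must be fixed
for bit-reproducibility).

Batch item *i* of a batch with seed *s* derives all its randomness from
`numpy.random.SeedSequence([s, i])`; one fresh mask seed per item comes from
that stream.

## Synthetic texture dataset

Real HRCT ROI sets are not publicly deposited, so `perlinaug.textures`
generates a six-class stand-in on an HU-like scale, clipped to [−1000, 400]:

| class         | mean (HU) | speckle sd | structure                      |
|---------------|-----------|------------|--------------------------------|
| normal        | −875      | 30         | none                           |
| GGO           | −550      | 60         | coarse smooth blobs (±80)      |
| consolidation | +50       | 40         | none                           |
| RO            | −650      | 50         | fine bright lines (+280)       |
| emphysema     | −700      | 40         | low-attenuation holes (−320)   |
| honeycombing  | −850      | 40         | ring walls (+700)              |

The parameterization echoes the radiological appearance of each pattern
(consolidation ≈ uniform soft-tissue density, emphysema ≈ air holes,
honeycombing ≈ cyst walls, RO ≈ reticulation, GGO ≈ hazy intermediate level)
but makes no claim of radiological realism: classes are separable by local
first- and second-order statistics *by construction* — a nearest-centroid
rule on (patch mean, patch sd) alone exceeds 80% — so a passing training
demonstration shows the pipeline learns separable textures end-to-end, not
that it would reach any particular accuracy on clinical HRCT. Real-data
features the generator does not emulate include vessels and airways,
patient-level correlation between patches, transitional zones between
patterns, and scanner/kernel-dependent noise texture.

The speckle component is re-centered to exact zero mean, so structureless
patches hit their nominal mean exactly. The default dataset is 100 patches
per class (600 total), mirroring the study design it stands in for.

## Dataset handling

The stratified splitter shuffles each class independently with a seeded
generator and moves `round(fraction · n_class)` patches to the test side;
with 100 per class and fraction 0.2 this gives 480/120 with exactly 20 test
patches per class. Archives are plain directories — 16-bit grayscale PNGs
(affine map [−1000, 400] HU ↔ [0, 65535], so quantization error is ≈ 0.02
HU), 8-bit indexed PNGs for label grids, and a CSV manifest that fixes order
and class names. Inputs to the network are normalized to [0, 1] with the same
window.

## Model

The classifier is a scaled-down FusionNet-style encoder–decoder: per level a
4 × 4 convolution followed by a two-convolution residual block, 2 × 2
max-pooling between levels, a bridge block, and a symmetric decoder using
nearest-neighbour upsampling with additive skip connections from the encoder;
a 1 × 1 head produces six per-pixel logits, softmaxed to probabilities.
Defaults: depth 2, 16 base filters (≈ 296k parameters). The original
network's exact depth and filter counts are not printed anywhere we could
verify, and full-scale training is GPU-class work; the scaled-down
configuration is explicitly a stand-in that preserves the architecture family
(residual blocks, skips, 4 × 4 kernels).

The backend is a minimal pure-numpy implementation: im2col convolutions with
stride 1 and "same" padding (asymmetric 1/2 for the even 4 × 4 kernel),
manual backpropagation (verified against central differences to ~1e-7
relative error), He-normal seeded initialization, and Adam. It is
single-threaded-deterministic: the same seeds reproduce histories
bit-for-bit on one machine. Different BLAS thread counts may reorder
reductions; the test thresholds carry enough margin that this does not
matter.

Training draws a fresh seeded augmented batch per step (batch size 16, the
study's value; step *s* uses batch seed `(seed·1000003 + s) mod 2³¹`),
minimizes per-pixel cross-entropy, and evaluates held-out pixel accuracy
every 25 steps on the untouched (never augmented) test set. Early stopping
keeps the best checkpoint and halts after 6 evaluations without improvement
or at `max_steps` (default 400; the demonstration reaches > 80% held-out
accuracy well inside that, and a full run takes a few minutes on one CPU).
Learning rate (2e-3), optimizer and loss are not specified by the source
study; they are package defaults chosen to converge reliably at this scale.
Sizes other than multiples of `2**depth` are reflect-padded in and cropped
out; note 20 × 20 passes depth 2 unpadded since 20 is divisible by 4.

## Evaluation

`pixel_accuracy` is the per-pixel aggregate: the percentage of pixels, over
all test patches, whose predicted class equals the reference class —
`100/(Nx·Ny·N_ROI) · ΣΣΣ [pred = truth]`. Per-class accuracies restrict to
pixels whose *reference* label is the class; a class absent from the
reference is reported as undefined (`None`), never as 0%. The pixel-weighted
average of the per-class values equals the overall mean, an identity the
tests assert to 1e-9.

`paired_t` compares two augmentation strategies on per-ROI accuracies paired
by identical test patch (the only pairing unit consistent with the accuracy
formula). Zero-variance differences are degenerate and flagged: identical
lists give t = 0, p = 1; a constant non-zero difference gives an infinite t
with p = 0.

`tile_quantify` labels a whole image by sliding a tile window (default
stride = tile/2, with extra windows flush against the far edges so every
pixel is covered), summing softmax probabilities across overlapping tiles,
and taking the argmax; pixels outside the foreground mask get the ignore
label −1 and are excluded from accuracy. Whether the original quantification
used overlapping tiles is unstated; both dense and non-overlapping inference
are supported via `stride`.

## Problem sizes and numerical choices

The shipped demonstration trains depth-2/16-filter models for up to 400
steps of batch 16 on the 600-patch synthetic dataset — a deliberate desk
scale; the figures it produces characterize this pipeline on these fixtures
only, not the original GPU-scale experiment, whose headline accuracies are
not reproducible without the undeposited clinical data. Argmax ties break
toward the lowest class index. Mask ties go positive. Probabilities are
clamped with an epsilon of 1e-12 inside the cross-entropy only.

## Known limitations

* The synthetic textures are statistically, not radiologically, realistic;
  no conclusion about clinical HRCT accuracy transfers.
* No directional claim is made (or tested) about mask-mixing vs conventional
  augmentation on the synthetic fixtures: both runs are emitted side by side,
  and the effect reported on real data need not transfer to textures this
  separable.
* The numpy backend is deliberately small; it is not a general-purpose deep
  learning library (no GPU, no 3D, stride-1 convolutions only).
* Whole-image quantification is exercised on synthetic composites; clinical
  lung masks and DICOM ingestion are out of scope.
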