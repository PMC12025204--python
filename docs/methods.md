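# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic data generator does and
does not emulate, and the design decisions taken where the design was
genuinely open.

## Image model and enhancement chain

All operators consume `(H, W, 3)` float images in `[0, 1]`. Histogram
operators quantize to `L` levels (default 256) with half-up rounding, for
cross-platform determinism.

**Multi-scale retinex.** Per channel,
`R = Σ_s w_s (log(I + ε) − log(G_σs ∗ I + ε))` with Gaussian surrounds
(`scipy.ndimage.gaussian_filter`, reflect boundary), followed by a min-max
rescale of the whole response to `[0, 1]`. Defaults: σ ∈ {15, 80, 250}
scaled by `image_size / 256`, equal weights, ε = 1/255 — the conventional
multi-scale-retinex setting; only the log-ratio form itself is prescribed.
A constant image has an identically zero response; the rescale of a zero
map returns zeros.

**Gamma correction.** `O = I^γ` on normalized intensities; default γ = 0.9
(a mild brightening; the exponent is a free parameter of the chain).

**Histogram equalization.** `T(v) = round((L−1)/(MN) · Σ_{i≤v} n_i)`.
On colour images the mapping is computed on the ITU-R 601 luminance
(0.299 R + 0.587 G + 0.114 B) and the luminance *delta* is added to all
three channels, which preserves the chrominance differences B−Y and R−Y and
avoids hue shifts. A constant image is returned unchanged: the raw formula
would map the single occupied level to L−1 and destroy the image, so the
degenerate histogram is treated as a no-op.

**Unsharp masking.** `O = clip(I + k (I − G_σ ∗ I))`; defaults k = 1,
σ = 1 px.

**CLAHE.** The classic tile scheme: the image is reflect-padded to a
multiple of the tile size; each tile's histogram is clipped at
`clip · tile_pixels / levels` counts (the usual multiple-of-the-uniform-bin
convention) with the excess redistributed by the standard integer scheme
(uniform increment, then one count at a time over bins still below the
limit); per-tile equalization maps are kept in float and each pixel is
mapped by bilinear interpolation between the four nearest tile maps — tile
centers at pixel index `i·k + k/2`, clamped at the borders — with a single
half-up quantization at the end. One tile with `clip ≥ levels` reduces
exactly to global histogram equalization. Agreement with
`skimage.exposure.equalize_adapthist` is within ±1 gray level at every pixel
once the two implementations are given the same histogram granularity
(skimage's 16384-gray binning yields 253 effective bins) and skimage's final
min-max stretch is applied to both outputs.

**Stage order.** crop → retinex → gamma → histogram equalization → unsharp →
CLAHE, fully configurable; any subset may be run. Horizontal/vertical flips
and integer shifts with reflect padding are available as seeded train-time
augmentation.

Illumination-normalizing enhancement deliberately flattens absolute
brightness and contrast. Consequently anything downstream must separate
classes on *morphology* (size, border, texture) — this shaped the fixture
design below.

## Synthetic lesion fixtures

Each image is a smooth skin-toned background (two low-frequency cosine
waves modulating a base colour, plus Gaussian pixel noise, default sd 0.02)
carrying one elliptical lesion with a sinusoidal border perturbation. The
pigment profile rises linearly across a narrow edge band and is exactly 1
in the lesion core, where the mean intensity drop equals the configured
`contrast` — this makes class-conditional statistics recoverable to within
sampling error, which the tests exploit. Pigment texture multiplies the
contrast (so a zero-contrast lesion is invisible), and the per-channel drop
weights (0.95, 1.00, 1.05) give lesions a slightly brownish cast while
keeping the channel-mean drop equal to `contrast`.

The default class grid spreads lesion radii over 0.08–0.44 of the image
side, alternates low/high contrast (0.30/0.55), border-wobble amplitude
(0.03/0.18) and relative texture sd (0.05/0.20) between neighbouring
classes, and fixes the border lobe count at `3 + class_id`. No two classes
share both size and appearance, and size — which enhancement preserves —
carries most of the signal. Defaults were chosen so that the seven classes
are separable by morphology; with a monotone one-dimensional grid adjacent
classes overlap heavily and no classifier can untangle them.

Anomaly images are uniform white-noise fields: maximally far, in mean
absolute distance, from any smooth lesion image.

What the generator does **not** emulate: hair and ruler artifacts, specular
highlights, vignetting, camera colour profiles, multiple or non-elliptical
lesions, and the long-tailed heterogeneity of real dermoscopy archives.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that its stages compose as designed — not that the reported
fixture accuracies transfer to clinical images.

## GAN balancing

A small DCGAN-style pair per minority class: the generator maps latent
normal noise through a dense layer to a 4×4 grid and doubles the resolution
with nearest-neighbour upsampling + 3×3 convolutions to the target size
(sigmoid output); the discriminator mirrors it with leaky-ReLU convolutions
and max pooling down to 4×4. Training alternates exactly one ascent step of
`log D(x) + log(1 − D(G(z)))` for D with one descent step of
`log(1 − D(G(z)))` for G (the saturating minimax form is the default; a
non-saturating `−log D(G(z))` variant sits behind a flag). Adam with
β₁ = 0.5, learning rate 10⁻³ for both players; log arguments are clamped at
ε = 10⁻⁷ when the value function is *reported* (gradients use the stable
sigmoid form). Balancing tops every class up to the majority count and tags
generated items `synthetic` in the metadata; originals are never touched.
At fixture scale (8×8 blobs, latent 16, batch 16) 500 steps put the
generator's mean image within 0.05 L1/pixel of the data mean across seeds.

## Convolutional autoencoder

Encoder: stacked `3×3 conv → ReLU → 2×2/stride-2 max pool`; default widths
(32, 64), the end-to-end pipeline configuration uses (16, 32, 64). The
decoder always contains exactly two upsampling stages — its output grid is
4× the bottleneck grid (the super-resolution reading of the design) — and
ends in a sigmoid, so reconstructions live in (0, 1). When the decoder grid
differs from the input grid the reconstruction target is the input resized
bilinearly. Classifier head: flatten → dense ReLU (dropout 0.5) → softmax.

Training minimizes `BCE(x, x̂) + CE(y, p)` (unit weights, both
configurable) plus L2 (0.01) on weight matrices, with Adam at learning rate
0.001, batch 32 — the package defaults. Everything is
deterministic given the seed.

**Reconstruction-error convention.** The BCE objective has an irreducible
pointwise floor: even a perfect reconstruction of a mid-gray pixel `x`
costs `H(x) = −x log x − (1−x) log(1−x)` ≈ 0.5 nats. Statements about
"halving reconstruction error" are therefore made on the *mean absolute
pixel distance* between image and reconstruction — the same quantity used
for anomaly scoring, which has no such floor — while the BCE curve itself
is required to decrease. Ten epochs on 200 fixture images cut the mean
absolute error to ≈ 0.3× the untrained model's.

**Anomaly detection.** Score = mean |x − x̂|; threshold = `mean + k·sd`
(default k = 2) of reference errors. The reference errors should come from
held-out in-distribution images: training-set errors are biased low by
fitting and would inflate false flags on fresh normals.

## Kernel SVM with quantum feature map

Features = flattened bottleneck activations, projected onto the
leading-variance directions (PCA fitted on training data only) and each
coordinate affinely rescaled to `[0, π]` by its training min/max; the
projection is stored and reused verbatim for test data.

Kernels: polynomial `(scale·⟨x,z⟩ + offset)^degree` (defaults 1.0 / 0.0 /
3); and the second-order-expansion fidelity kernel, simulated exactly as a
statevector for up to 12 qubits. The circuit applies `repetitions` (default
2) rounds of a Hadamard layer followed by a diagonal phase layer with
first-order angles `θᵢ = xᵢ` on Z of qubit i and second-order angles
`θᵢⱼ = (π − xᵢ)(π − xⱼ)` on Z⊗Z of every entangled pair (full pairwise by
default). The Hadamard layer is a normalized Walsh–Hadamard transform; the
phase layer is a precomputed table of basis-state signs, so a kernel entry
costs O(2ⁿ).

**Bandwidth.** With features spanning `[0, π]` and unit scale the phase
differences between nearby points swing through several multiples of 2π,
the fidelity kernel oscillates at a much finer scale than the data, and the
SVM memorizes (training accuracy can be forced to 1 with large C while
held-out accuracy sits near chance) — the known quantum-kernel bandwidth
pathology. `KernelSpec.scale` multiplies the feature angles and acts as the
bandwidth; 0.25 makes the kernel smooth at blob scale and is what the
quantum-family tests use. The default stays 1.0.

The dual problems are solved by `sklearn.svm.SVC(kernel='precomputed')`,
one binary machine per class (one-vs-rest). Support vectors, signed dual
coefficients `αᵢyᵢ` and the bias `d` are extracted, and all predictions are
computed from the stored expansion `f(x) = Σ αᵢyᵢ K(sᵢ, x) + d`; the
multi-class label is the argmax of the one-vs-rest scores with ties broken
toward the lowest class index. KKT conditions (`0 ≤ α ≤ C`, `Σ αy = 0`) are
asserted in tests, and the XOR solve is verified against an exhaustive
small-grid maximization of the dual. On XOR the degree-3 polynomial kernel
needs `C ≥ 5` for a hard margin — at `C = 1` the optimal soft-margin
solution (confirmed by the grid solve) trades one margin error for slack,
so correctness checks use `C = 10`. The Gram matrix is checked for symmetry
and positive semi-definiteness (minimum eigenvalue ≥ −10⁻⁸ relative) before
fitting.

## Grad-CAM

Gradients of the target class's pre-softmax logit are backpropagated from
the classifier head to a chosen encoder convolution (default: the last).
Channel weights are the spatial means of those gradients; the heatmap is
`ReLU(Σ_k w_k A_k)`, bilinearly upsampled to the input grid and divided by
its maximum (an all-zero map is returned as-is). Localization is only
meaningful where the classifier has seen lesions at comparable positions:
models trained with lesion centers spanning the frame put ≳ 90% of heatmap
mass in the correct quadrant for correctly classified images, whereas a
model trained only on centered lesions attends elsewhere for corner lesions.

## Evaluation metrics

Confusion matrix with rows = true class. Per class: precision, recall
(sensitivity), specificity `TN/(TN+FP)`, F1; summaries as macro (unweighted
mean, the default report), micro and support-weighted F1. A zero denominator
yields 0 and raises a `zero_division` flag rather than NaN. Accuracy equals
micro-recall for single-label problems, which the tests assert.

## Pipeline and reproducibility

Stage order: load/generate → enhance → stratified 80/20 split (seeded,
per-class counts within one item of the realized global fraction) →
optional GAN balancing of the **training partition only** (keeping
synthetic images out of validation) → autoencoder training → latent
extraction → feature reduction → SVM fit → validation metrics, with the
softmax head's accuracy reported as a baseline. One global seed derives all
stage seeds through `numpy.random.SeedSequence`, so a rerun with the same
configuration reproduces the report bit for bit. A `permute_labels` flag
destroys the image-label link as a negative control; accuracy then drops to
chance (≈ 1/K), which bounds any leakage through the pipeline.

Problem sizes in the shipped checks — 490 images at 64×64 for the
end-to-end run, 200 images for autoencoder training, 8×8 blobs for the GAN
loop, ≤ 4 qubits for kernel-oracle comparisons — are desk-scale choices
that keep the whole suite to a few CPU-minutes while leaving each
behaviour measurable.

## Known limitations

* The NumPy networks are exact but not fast; they are sized for method
  study, not for full dermoscopy archives.
* Fixture accuracies say nothing about clinical performance (see the
  fixture section for what is not modelled).
* The GAN is evaluated by mean-image proximity and output validity, not by
  distributional metrics (FID/IS hooks are out of scope).
* Quantum kernels are simulated noiselessly; shot noise and hardware error
  models are out of scope.
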