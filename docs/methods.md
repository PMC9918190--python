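# Methods

This note documents the models, the synthetic data they are exercised on,
and the numerical and design choices behind both. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Infrared meibography shows the everted eyelid's tarsal plate as a bright
elliptical band and the meibomian glands as brighter, roughly vertical,
slightly tortuous stripes within it. The quantity of clinical interest is
the gland-to-tarsus area ratio (its complement is the gland loss
proportion). The pipeline therefore (1) classifies the lid side, since
upper and lower lids have distinct tarsal morphology, (2) segments the
tarsus, (3) segments the glands, clips them to the tarsus, and (4) reports
the area ratio. Evaluation is pixel-wise: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy, Dice 2TP/(2TP+FP+FN), and ROC/AUC over
the binarisation threshold.

## Preprocessing and augmentation

Frames are cropped to a 420 × 890 region of interest (offsets are
configuration; only the target size is fixed), smoothed with a 3 × 3
bilateral filter and max-min normalised to [0, 1]. The bilateral filter is
a convex combination of neighbourhood intensities weighted by a spatial
Gaussian (`sigma_space`, pixels) and a range Gaussian (`sigma_color`,
intensity units), with replicated borders; constants are preserved exactly
and the output stays in [0, 1]. Constant images normalise to all zeros — a
declared convention that avoids division by zero while keeping the range
contract.

Augmentation expands each sample exactly 16-fold: the full on/off product
of four operations, so the factor is structural rather than incidental.

* *horizontal flip* — applied to image and masks alike;
* *color jitter* — brightness/contrast jitter, the grayscale-compatible
  reading of color jittering;
* *random lighting* — a low-frequency multiplicative illumination gradient;
* *Gaussian noise* — additive zero-mean noise (σ = 0.02 by default). The
  augmentation vocabulary for this imaging domain is not standardised; an
  additive Gaussian perturbation is the conventional per-image stochastic
  operation and is what this package implements.

All stochastic draws are made once per sample from the seed, so the variant
set is deterministic and the all-off variant is bit-identical to the input.

Patients are assigned to train/validation/test (default 70/20/10) as whole
units: patients are shuffled, then each goes to the set with the largest
remaining image deficit (greedy largest-remainder). No patient straddles
sets, and realised image fractions stay within one patient's worth of the
targets.

Polygon annotations (COCO-style JSON) are rasterised by even-odd fill
sampled at integer pixel centers, with boundary pixels included: an
axis-aligned rectangle with corners (2,2)–(5,4) covers the full 4 × 3
pixel block. Vertices outside the physical image extent
[−0.5, size−0.5] are clipped with a logged warning.

## Synthetic meibograph

The generator renders a scene from explicit parameters and returns the
exact masks, so segmentation quality can be measured without clinical data.

* **Geometry is relative.** All positions and sizes are fractions of the
  image, so a 64 × 128 test-scale scene and a 420 × 890 full-scale scene
  depict the same anatomy.
* **Tarsus** — an ellipse; the vertical semi-axis is drawn from
  (0.32, 0.40) of image height for upper lids and (0.18, 0.25) for lower
  lids. The ranges are disjoint, so a band-height threshold at 0.57 of
  image height recovers the lid side with certainty on easy scenes —
  the classifier's task is well-posed by construction.
* **Glands** — 10–16 constant-width vertical stripes (width ≈ 2% of image
  width), sinusoidally perturbed in proportion to a tortuosity parameter,
  clipped to the tarsus. Atrophy removes the given fraction of each
  stripe's length from the lid-margin end, emulating gland shortening; the
  area ratio then tracks (1 − atrophy) analytically, which the tests
  exploit as a parameter-recovery check.
* **Artifacts** — "hard" scenes add 2–4 specular tear-film highlights
  (bright Gaussian blobs), 3–6 dark eyelash streaks (thin near-vertical
  parabolas) and σ = 0.04 sensor noise; "easy" scenes have no artifacts and
  σ = 0.01. Artifacts are composited *after* the masks are fixed: they
  occlude the image, never the truth, making the hard set a controlled
  robustness probe.
* Intensity ordering is enforced by construction (glands ≈ 0.80 > tarsus
  ≈ 0.45 > surround ≈ 0.15 before texture and noise).

What the generator does **not** model: Placido-ring optics, perspective
and lid curvature, intensity inhomogeneity across patients, gland
distortion/dilatation, and annotation noise (its masks are exact). Passing
tests therefore demonstrate that the pipeline's machinery learns and is
measured correctly at desk scale, not that clinical-grade accuracy would be
reached on real data.

## Networks and training

All models run on `meibseg.nn`, a small reverse-mode autodiff stack over
float64 numpy arrays (conv2d via im2col with matmul kernels, scatter-add
backward via bincount). Gradients of every op are verified against finite
differences in the test suite. Channel counts scale with a single
`base_width`, giving width-reduced variants of the standard residual
topologies for CPU-scale runs; architectures are resolution-agnostic
(inputs not divisible by the downsampling factor are edge-padded internally
and cropped on output).

* **Classifier** — stem convolution (stride 2) plus four residual blocks,
  global average pooling, binary head; inputs are centered (−0.5) for
  conditioning. Trained with cross-entropy; the best-validation-accuracy
  checkpoint is returned.
* **Shape prior (VAE-GAN)** — encoder: three stride-2 convolutions and a
  dense layer to a Gaussian code (mean, logvar); decoder/generator: dense
  layer plus three upsample-conv stages to a sigmoid mask; discriminator:
  three stride-2 convolutions, global average pooling, sigmoid score.
  Training alternates (a) a VAE step minimising per-pixel binary
  cross-entropy plus KL divergence to N(0, I) with weight β = 1, (b) a
  discriminator step on real vs decoded masks, (c) a non-saturating
  generator step −log D(G(z)) on the decoder. Latent dimension defaults to
  16 at toy scale (64 at full scale); logvar is clamped to [−10, 10] for
  stability. One prior is trained per lid side, selected by the classifier,
  since the two lids' tarsal shapes differ.
* **Segmenter (U-Net)** — residual encoder with three resolution levels, a
  segmentation decoder with skip connections, and a cascaded reconstruction
  decoder without skips (so reconstruction cannot bypass the bottleneck and
  the reconstruction error regularises the shared encoder). Both heads are
  sigmoids. The composite loss is λ₁·RL + λ₂·DcL + λ₃·DL with defaults
  (0.1, 1.0, 0.05): Dice dominates, reconstruction and shape terms
  regularise. RL is a smoothed mean absolute error (√(d² + 1e-12), making
  it differentiable at zero error); DcL uses smoothing ε = 1e-6; DL clamps
  the discriminator score to [1e-7, 1−1e-7] before the log. The
  discriminator is frozen: its parameters accumulate no gradients and are
  byte-identical before and after segmenter training (asserted in tests).
  Separate segmenters per (lid side × target) are trained and selected at
  inference by the classifier. The shape term is used for the tarsus by
  default and is off for glands (gland shapes are not band-like, and the
  prior is a tarsus-shape model).

Every loop uses an exponentially decayed learning rate
lr(epoch) = 0.001 · γ^epoch with γ = 0.98 by default, Adam, batch size 4,
and full determinism given the seed. Adam was chosen over momentum-free
adaptive methods after RMSprop proved unreliable at the 5-epoch toy budget
(reaching perfect held-out accuracy in only two-thirds of trial runs);
RMSprop remains available via `TrainConfig(optimizer="rmsprop")`.
Binarisation threshold is 0.5, configurable for ROC sweeps.

## Evaluation choices

* ROC curves pool pixels across the evaluated images (one curve per task);
  a per-image macro-averaged AUC is provided as a secondary reduction.
  101 evenly spaced thresholds by default; `n_thresholds=None` places a
  threshold at every distinct score, where the trapezoidal AUC equals the
  Mann–Whitney pair-counting statistic exactly.
* The positive predicate is score > threshold, with threshold 0 declaring
  every pixel positive, so the curve's endpoints are exactly (0,0) and
  (1,1) with all thresholds inside [0, 1].
* Metrics with empty denominators are reported as NaN (an explicit
  "undefined" marker), never as silent zeros.

## Scaled-down study conditions

CPU-scale experiment sizes, chosen once as this package's study conditions:
64 × 128 images; the classifier experiment uses 40 easy images
(20 patients × 2, alternating sides), 5 epochs, width 16; the tarsus
experiment uses 48 easy upper-lid images (one per patient), a 150-step
shape-prior run, and 20 U-Net epochs (≈180 optimisation steps); the
occlusion-robustness comparison uses hard scenes, a 120-step prior and
10-epoch runs paired over three seeds. `scripts/acceptance.py` re-runs the
first two end to end.

## Known limitations

* Generative samples from the N(0, I) prior are coarse at these step
  budgets: decoded latents of *encoded* masks stay inside the learned shape
  territory (tested), but unconditional samples are blurrier and can bleed
  beyond it. The discriminator, not the generator, is the exported
  artifact, so this does not affect the segmentation pipeline.
* The shape-constraint term's benefit on occluded scenes is small at desk
  scale — the paired comparison in the test suite shows the prior does not
  hurt and helps marginally; stronger effects would need harder occlusions
  or longer training than the CPU budget allows.
* The numpy autodiff stack is single-threaded apart from BLAS matmuls and
  is sized for toy experiments; full-scale 420 × 890 training is supported
  by the architecture but not by the compute envelope the package targets.
* λ weights, optimizer hyperparameters, latent dimensionality and crop
  offsets are configuration with sensible defaults, not clinically
  validated settings.
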