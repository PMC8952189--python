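# Methods

`octadr` implements a multi-scale screening pipeline for diabetic
retinopathy (DR) on en-face OCTA angiograms: unsupervised vessel
segmentation, morphology encoding through a signed distance map, a
three-channel composite image, one shallow CNN per analysis scale, and
soft-voting fusion of the per-scale class probabilities. Because
clinical OCTA cohorts are rarely shareable, the package ships a
synthetic phantom generator that reproduces the class markers the
method relies on, so every stage is exercised end to end by code alone.

## Synthetic phantoms

A phantom is a pure function of its `PhantomSpec` (seed included).
Vessel trees grow from random border points toward the image centre by
a meandering random walk with stochastic branching; daughter branches
thin by a factor 0.75. Centerlines are splatted at sub-pixel spacing,
inflated to their caliber with a Euclidean distance transform, and
given a linear one-pixel anti-aliasing falloff; the binary truth is
that profile thresholded at 0.5, with pixels inside the foveal
avascular zone (FAZ) disc cleared before thresholding, so a re-render
from the stored centerlines reproduces the mask exactly (Dice 1).
The background is Gaussian speckle (sigma 0.08 in intensity units)
around level 0.18 under a low-frequency multiplicative shading field
(amplitude 0.3), which is what the local-equalization stage is there
to undo. Vessels are bright (level 0.85) as in superficial-plexus
angiograms; polarity is a flag.

Class signatures follow the clinical markers: the DR spec deletes 40%
of grown segments (capillary dropout), thins the mean caliber from
3.0 to 2.2 px, and doubles the FAZ radius (20 -> 40 px at the
256-px reference size, scaled proportionally at other sizes). The NDR
spec uses dropout 0, caliber 3.0, FAZ 20 px. These defaults are
deliberately unsubtle — the generator's job is to guarantee a class
signal the pipeline must recover, not to calibrate human-grade
difficulty. What passing tests show is that the pipeline's machinery
(segmentation quality, channel encoding, multi-scale training, fusion)
works; they do not certify performance on real scans, whose speckle
statistics, plexus-specific anatomy and grader noise the phantoms do
not emulate.

## Enhancement

`equalize_local` is contrast-limited adaptive histogram equalization:
per-tile rank equalization with clipped histograms and bilinear
blending between tile mappings (delegated to
`skimage.exposure.equalize_adapthist`). Window default: roughly a
quarter of the image side, forced odd; clip limit 0.02. A constant
image is mapped to mid-range 0.5 by convention.

`ggmrf_smooth` minimizes the generalized Gauss-Markov random-field
energy

    E(x) = sum_s |x_s - y_s|^alpha + lambda * sum_{s~r} |x_s - x_r|^beta

by coordinate descent: pixels are scheduled in four colour classes
(2x2 block parity) so no two simultaneously updated pixels are
neighbours even under 8-connectivity; each pixel's convex 1-D problem
is solved by 30 golden-section iterations over the bracket spanned by
its data value and neighbours (interval below the 1e-4 tolerance), and
an update is accepted only if it strictly lowers the local energy, so
the total energy is non-increasing per sweep by construction. Border
pixels simply omit missing neighbours. Defaults: alpha = 2,
beta = 1.01 (edge-preserving, near-L1), 8-neighbourhood, 3 sweeps,
lambda = 0.1. The prior weight deserves a note: with beta ~ 1 the
prior's gradient is ~lambda per neighbour almost independently of the
local contrast, while the quadratic fidelity gradient is at most
~2 * 0.2 for typical noise amplitudes on a [0, 1] scale. A weight of 1
therefore lets eight neighbours overwhelm fidelity and flattens thin
(2-3 px) capillaries like a median filter, *increasing* the error to
the clean image; lambda = 0.1 keeps the prior subordinate and measured
denoising MSE roughly halves. Values in [0.05, 0.2] behave similarly.

## Vessel segmentation

The intensity likelihood is a two-component 1-D Gaussian mixture fitted
by EM on all pixels, initialized deterministically from the Otsu split
(ties toward background); components are ordered so the vessel class
has the higher mean, and the mean log-likelihood trace is monotone
non-decreasing (asserted in tests). The full prior-appearance
machinery of earlier stochastic OCTA models is deliberately reduced to
this two-class mixture: vessel/background is all the downstream
composite needs.

Labels then descend the Potts-MGRF energy

    E(l) = sum_s -log p(y_s | l_s) + gamma * sum_{s~r} [l_s != l_r]

by iterated conditional modes (ICM) in fixed raster order (a numba
kernel), starting from the pixelwise maximum-likelihood labeling;
gamma = 0 reduces exactly to the ML labeling. Iteration stops when the
changed-label fraction drops below 1e-4 or after 30 sweeps. ICM is a
local minimizer; on 4x4 images the test suite compares its energy
against exhaustive enumeration of all 65,536 labelings (never below
the global optimum; a fixed point when started there). Defaults
gamma = 1.5, 8-neighbourhood. A 2-D connectivity filter removes
8-connected components under 20 px. On seeded 128-px phantom cohorts
the full stage (equalize -> GGMRF -> MGRF -> filter) reaches mean Dice
~0.95 against the generator's truth.

## Distance map and composite

`signed_distance` assigns each vessel pixel the exact Euclidean
distance to the nearest background pixel and each background pixel the
negative distance to the nearest vessel pixel
(`scipy.ndimage.distance_transform_edt`; verified against a
brute-force all-pairs oracle). The discrete grid has no zero-level
pixel class: a foreground pixel touching background carries +1, not 0.
Degenerate all-one/all-zero masks saturate at +/- the image diagonal
with a warning. The composite stacks (enhanced gray, binary mask,
interior distance) — interior only, because vessel caliber is the
morphology marker of interest; the negative half remains exportable.
Channel 3 is normalized by the per-image interior maximum by default;
a fixed constant is available when cross-image comparability matters.

## Multi-scale decomposition

From each composite: the full frame, four non-overlapping quarters
(side/2), sixteen tiles (side/4), and a centered fovea crop (side/2) —
the 1024 -> 512/256/512 ratios of full-resolution scans, applied to
any divisible side. Windows are half-open, 0-based, row-major; odd
crop remainders floor the top-left offset. Tiles inherit the parent's
subject id and label as weak labels; stitching uses stored origins and
is bit-exact.

## Phase classifiers

Each level trains the same shallow plan: four valid-3x3 convolution
blocks (16/32/64/128 filters, stride 1, ReLU) each followed by 2x2
stride-2 max-pooling, two 128-wide fully connected layers, and a
2-class soft-max. One convolution per block is the checkable layout
(the per-layer weight census for a 1024-px input — 432 / 4,608 /
18,432 / 73,728 conv weights, 492,032 flattened features, 62,980,096
first-FC weights — is asserted exactly); a `convs_per_block=2` flag
exposes the doubled variant. Biases exist in the model but are
tallied separately from the weight census, which is the conventional
bias-free kernel product. Valid convolutions need a >= 46-px input to
survive four blocks; smaller tiles (the sixteenths of a 128-px
desk-scale frame) drop trailing blocks until the plan fits.

Training minimizes soft-max cross-entropy (log clamped at 1e-12) with
Adam (lr 0.001, batch 32), dropout 0.2 after every pooling stage and
hidden FC layer, and label-preserving augmentation drawn uniformly
from the square's 8-element dihedral group (flips and 90/180/270
rotations) re-sampled each epoch. A stratified 10% validation split
tracks per-epoch loss/accuracy. The engine is a compact NumPy
implementation (im2col convolutions, max-pool argmax routing,
analytic softmax/CE gradient) validated by numeric gradient checks;
everything draws from one seeded generator, so runs are
bit-reproducible. Epoch defaults are scaled to problem size: 50 for
full-scale work, 8 in the desk-scale experiment below.

## Fusion and evaluation

Tile probabilities are averaged per subject within a level; the
ensemble score is the unweighted mean of the per-level DR
probabilities (soft voting — tile-first or pooled averaging are
identical for unweighted means, asserted in tests). Decision
threshold 0.5, ties to DR: a screening tool prefers false referrals
to missed disease. Metrics (DR positive) are accuracy, sensitivity,
specificity, precision, F1, reported in percent; zero-denominator
metrics are flagged undefined rather than reported as 0. Balanced
accuracy and Cohen's kappa are reported separately (the two are
sometimes conflated; we compute both). The ROC sweeps unique scores
with ties grouped; AUC is the trapezoidal area and equals the
pairwise-concordance estimator (asserted against it and
`sklearn.metrics.roc_auc_score`).

`crossvalidate` owns subject-level stratified 5-fold partitioning:
all tiles of a subject share its fold, every phase sees the identical
held-out 20%, and pooled predictions give the summary metrics. A
class with fewer than k subjects raises an error proposing a smaller
k. Leakage detection is by subject id only — a duplicated image under
a new id is not caught.

## The scaled experiment

`run_experiment` generates a seeded 50 + 50 cohort at 128 px,
preprocesses and decomposes every frame, holds out one stratified fold
(20%) shared by all four levels, trains each level for 8 epochs, and
fuses. These sizes are the package's desk-scale reference
configuration: large enough that the fused classifier separates the
phantom classes essentially perfectly (fused accuracy is typically
100% with decreasing training losses; the acceptance bound is >= 85%),
small enough to run on a single CPU in about a minute and a half.
`scripts/acceptance.py` re-runs this experiment plus the exact
structural checks and writes the measured numbers to JSON.

## Known limitations

- Phantoms are 2-D single-plexus caricatures: no depth-resolved
  capillary layers, no physically modelled OCT speckle, no projection
  artefacts, no grader disagreement.
- ICM finds local minima only; a graph-cut would be exact for this
  binary Potts model but is unnecessary for the stated contracts.
- The fovea window is the geometric centre (with a manual offset
  override), not an anatomical detection.
- Training at full 1024-px scale with the 63M-parameter first FC layer
  is feasible in this engine but slow on one CPU; the architecture
  census covers that configuration exactly, while training defaults
  target the smaller scales.
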