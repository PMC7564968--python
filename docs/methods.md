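# Methods

This note documents the models, parameter choices and numerical details
behind the package, and what the synthetic study can and cannot show.

## Synthetic stimuli

Each stimulus is a square grayscale image in [0, 1]: a low-amplitude
smoothed-noise background (mid-gray ± 0.06 · Gaussian-filtered noise,
σ = 2 px) with a textured "object" — 2–4 oriented Gabor patches plus one
geometric shape (disk or rectangle), softly windowed — confined to a square
*main-body box* whose side is 40–60% of the image, placed strictly inside
the bounds. The box operationalizes the object's main body, the region
augmentation crops must preserve. Per-image RNG streams are derived from
(seed, image id), so image k's content is independent of how many images are
generated. Default library sizes are 1750 training and 120 test images,
matching the emulated recording protocol; the analysis scripts run at
400/60 and 32×32, sizes chosen so all six stages complete in minutes on one
CPU core.

These stimuli are not natural images: they lack scene clutter, broadband
1/f statistics and semantic content. Nothing downstream depends on natural
statistics — only on features being a fixed deterministic function of
pixels — so passing tests validate the *machinery* (augmentation geometry,
similarity accounting, model fitting, attribution bookkeeping), not claims
about natural-image representations.

## Augmentation

Per variant: crop side drawn uniformly (integers) from [main-body side,
image side]; crop origin uniform among placements containing the main-body
box; bilinear rescale to the original size (no antialiasing filter; an
identity crop is returned bit-identically); flip drawn uniformly from
{none, horizontal, vertical, both}, applied after rescaling (crop → scale →
flip). Crops are square, so rescaling is isotropic and no aspect-ratio
distortion is introduced. The crop law is the simplest distribution
satisfying "random sizes preserving the main body"; the interpolation order
and the flip timing are configurable only by editing one function each, as
they are conventions rather than scientific claims. Default n_aug = 10.

## The frozen feature hierarchy

The built-in extractor is a pure-NumPy CNN: five 3×3 same-padded
convolutions with ReLU (2×2 max-pool after stages 1, 2 and 5) followed by
three fully connected ReLU stages, exposed as layers 1–8. Weights are
He-scaled Gaussians drawn deterministically from a seed; conv biases are
+0.05 so rectified maps are not identically zero; fc biases are zero. The
network is frozen — never trained. "The feature" of a layer is the
post-activation, post-pool map flattened in channel-row-column order; this
convention is fixed because the similarity analysis is only well-defined
once the snapshot point is.

An untrained extractor preserves the *hierarchical, conv-then-fc* structure
but not the representational geometry a trained network develops. On the
frozen net the layer-similarity profile is compressed (all layers score
0.94–0.98) and the deepest fc layers map all images near a dominant
direction, so matched vs. mismatched pairings nearly tie there. The
conv-similarity decline and fc rise reported for trained networks are
therefore *not* asserted for the toy extractor; the tests pin the metric
and statistic mechanics instead. An externally trained network can be
plugged in through `load_external_extractor` (.npz weight layout documented
there) and profiled identically.

Analysis-scale extractor: 32×32 input, conv widths (4, 6, 8, 8, 8), fc
widths (64, 48, 32), keeping every layer's dimension ≤ 1024 so the
penalized fits stay in the seconds range. The 64×64 default with widths
(8, 12, 16, 16, 16)/(256, 128, 32) remains available.

## Synthetic voxels

A voxel is a sparse linear readout of one layer: 10 nonzero Gaussian
weights on randomly chosen feature dimensions (the same functional form the
linear encoder assumes, making recovery well-posed). ROI → layer
assignment follows a ventral-stream gradient (V1 ~ layers 1–2, V2 ~ 2–3,
V3 ~ 3–4, V4 ~ 4–6, LO ~ 5–8, categorical and configurable). *Equivariant*
voxels read the exact features F_l(i); *invariant* voxels read the mean of
F_l over ensemble_k = 10 fresh augmentations of i (a distinct RNG stream
from the training library), so their noiseless response is identical for
every augmented variant of an image by construction. The ensemble is shared
across the invariant voxels of a run; voxels still differ through their
weights and layers.

Noise is Gaussian with standard deviation expressed relative to the
unit-variance noiseless signal (the signal is standardized over the
training split before noise is added, and the response re-standardized
after). The default noise_sd = 0.2 is a configuration choice — real-voxel
SNR is not specified by the emulated protocol — picked as a
moderate-reliability regime in which ground truth remains recoverable.
Within each ROI the first ⌈fraction · n⌉ drawn voxels are invariant, a
deterministic rounding rule that makes class counts exactly testable.

## Encoding models

**Linear.** Per voxel, L1-penalized least squares on per-dimension
standardized features (standardization statistics always from the original
training features, also for augmented fits, so model variants share a
scale). The penalty is chosen per voxel from the descending grid
(0.3, 0.1, 0.03, 0.01) by Pearson r on an inner validation split — the last
⌊0.2 n⌋ training rows in a fixed seed-derived shuffled order — then the
model is refit on the full training set at the chosen penalty. All voxels
sharing a penalty are fit in one call over a precomputed Gram matrix, which
keeps an 8-layer, 200-voxel fit under 10 s. Coordinate descent runs with
tol = 1e-3, max_iter = 2000; exactly constant training responses are
flagged degenerate and get zero weights.

**TL.** Per ROI, a two-hidden-layer ReLU network (scikit-learn
MLPRegressor; Adam, mini-batches, MSE) mapping features to all of the ROI's
voxels jointly, with early stopping on a held-out fraction of the training
rows (R² criterion, scikit-learn's convention). Defaults: hidden widths
(64, 32), learning rate 1e-3, batch 32, ≤ 400 epochs, patience 25; training
is deterministic given the config seed. On purely linear voxels the TL
model approaches the linear fit when given enough capacity and epochs
(gap < 0.05 at widths (192, 96), 1000 epochs); the smaller defaults trade a
few hundredths of r for speed.

**Layer selection.** Per voxel, the layer with the highest test-set Pearson
r; exact ties resolve to the shallower layer. Selecting on the test set
replicates the published procedure despite its circularity;
`selection="validation"` selects on the inner validation split instead.
Constant predictions score r = 0 (degenerate) rather than NaN.

**Augmented fits.** The training table contains the 10 variants per
original, each labeled with the original's response; the originals
themselves are excluded (matching the 17,500-image augmented library; a
variant including them would dilute the probe and is left to callers who
pass a custom library).

## Evaluation

*Permutation threshold*: the (1 − α) quantile of Pearson r between one
fixed standard-normal prediction and 100,000 independently permuted
standard-normal responses; one-sided, since encoding accuracy is a
one-sided claim. At n = 120, α = 0.001 this is ≈ 0.28 (Monte-Carlo spread
± 0.02 across seeds). *Layer preferences*: among voxels above threshold,
the percentage whose selected layer falls in the strong-invariance group
{1, 2, 7, 8}; an ROI with no accurate voxels reports missing, never 0.
*Top-K comparison*: per ROI, the K best voxels ranked by original-model
accuracy (a fixed voxel set, making before/after well-defined), mean and
variance of both models' accuracies, the mean drop, and a paired two-sided
t-test; zero-variance differences are flagged degenerate. *Attribution*:
per family, a voxel is accurate when max(original r, augmented r) exceeds
the threshold and attributed to whichever is larger (ties to original); the
four-way view attributes each accurate voxel to its argmax among (linear,
aug-linear, tl, aug-tl), ties broken in that order. Integer counts are
reported alongside fractions so the partition identities can be checked
exactly.

*Trend reporting.* `mann_kendall_trend` uses the tie-corrected variance,
continuity-corrected z and two-sided normal p, with direction gated at
p < 0.05. The conv/fc trend report instead reports a *descriptive*
direction (the sign of S) with the p-value alongside: windows of 3–5 layers
can never clear p < 0.05 under the normal approximation even when strictly
monotone (|z| ≤ 2.20 at n = 5, ≤ 1.70 at n = 4), so a p-gated direction
over the fc suffix would be uninformative by construction. The fc window
defaults to layers 5–8 so the turn out of the conv stack is part of the
tested rise; (6, 7, 8) restricts it to fc layers proper.

## Pipeline and reproducibility

Every stochastic stage derives its generator from the global seed plus a
stage token (CRC-32 of a label fed into a SeedSequence), so no two stages
share a stream and any stage is bit-reproducible in isolation. The pipeline
driver writes each stage's outputs with SHA-256 digests into a manifest;
on rerun a stage is skipped when its recorded outputs are intact and
nothing upstream was recomputed, and any damaged or missing intermediate
triggers recomputation of exactly that stage and its descendants. Images
interchange as 8-bit grayscale PNG (lossless at that quantization) with
JSON sidecars; matrices as HDF5 (bit-exact) with CSV mirrors. A best-effort
reader for the public vim-1 MATLAB v7.3 response layout is included but not
exercised by the tests (it requires the downloaded deposit).

## Problem sizes

Chosen so the full test suite and the analysis scripts run in minutes on
one CPU core: encoding experiments at 400 train / 60 test images, 5 ROIs ×
40 voxels (200 voxels), 10 augmentations; layer-recovery checks at 100
voxels, noise 0.1; the augmentation-count check at the full 1750-image /
64×64 scale (counting only); permutation nulls at 100,000 draws.

## Known limitations

- The frozen random extractor exhibits hierarchical *structure* but not
  trained representational geometry; conclusions about trained networks
  require plugging in external weights.
- The synthetic voxel model is exactly the linear encoder's functional
  form; TL's advantage on real nonlinear responses is not probed here.
- The TL early-stopping criterion is R² on a random validation split
  (library convention), not Pearson r on the fixed shuffled split the
  linear path uses.
- ROI-level comparisons are reported without multiple-comparison
  correction, mirroring the emulated analysis; the raw p-values are in the
  output tables.
- Test-set layer selection is statistically circular; the honest
  alternative is one flag away and lowers accuracies slightly.
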