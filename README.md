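# invarscope

Representation-invariance analysis of hierarchical convolutional features
and voxel-wise visual encoding models, probed with data augmentation.

## The scientific problem

Both deep convolutional networks and the ventral visual stream (V1 → V2 →
V3 → V4 → LO) are thought to build increasingly *invariant* representations:
codes that change little when an image is cropped, rescaled or flipped. This
package implements an augmentation-based probe of that idea, exercisable
end-to-end on synthetic data with known ground truth:

1. **Augmentation.** Each training image yields 10 variants: a random square
   crop that preserves the object's main body, rescaled to the original size
   (bilinear), then flipped one of four ways (none / horizontal / vertical /
   both).
2. **Network invariance.** For an 8-layer feature hierarchy (5 conv + 3 fc),
   the similarity between an original's layer-*l* features and its variants'
   is the cosine similarity

   D_cos = ⟨F_l(I_o), F_l(I_A)⟩ / (‖F_l(I_o)‖ ‖F_l(I_A)‖),

   averaged per image; layer-wise trends are tested with the Mann–Kendall
   statistic S = Σ_{i<j} sign(x_j − x_i).
3. **Voxel-wise encoding models.** Two families map layer features to voxel
   responses — an L1-penalized ("sparse") linear readout per voxel, and a
   two-hidden-layer ReLU network per ROI ("TL"). One model is fit per layer;
   per voxel, the layer with the best test-set Pearson r is selected. A voxel
   counts as *accurately predicted* when r exceeds the permutation-null
   threshold (p < 0.001; ≈ 0.28 at 120 test images, matching the 0.27
   working threshold used with real recordings).
4. **The augmentation probe of voxels.** Augmented images inherit their
   original's response ("label copying"). Retraining on the augmented
   library helps voxels that respond invariantly and hurts voxels that track
   the transformation — so the sign of the accuracy change classifies
   voxels, and the fraction better predicted by the augmented model should
   rise from V1 to LO if invariance grows along the ventral stream.

Because real recordings (the public vim-1 dataset) and a pre-trained
AlexNet are deliberately out of scope, the `stimuli`/`voxels` modules
generate a synthetic study: textured-object images with main-body boxes, a
frozen random 8-layer extractor, and voxel populations that are sparse
linear readouts of a planted layer — *equivariant* voxels read the exact
features, *invariant* voxels read features averaged over an augmentation
ensemble, with the invariant fraction rising from 0.2 (V1) to 0.8 (LO).

## Worked example

The numbered scripts under `analysis/` run the full study at desk scale
(400 train / 60 test images at 32×32, 5 ROIs × 40 voxels):

```bash
python analysis/01_simulate.py
python analysis/02_augment.py
python analysis/03_extract_features.py
python analysis/04_invariance_profile.py
python analysis/05_fit_encoders.py
python analysis/06_evaluate.py
```

The final script prints (abridged):

```
top-voxel accuracy drop after augmented training (linear):
  V1: mean drop +0.417 (t=10.49, p=6.5e-13)
  V2: mean drop +0.350 (t=6.25, p=2.3e-07)
  V3: mean drop +0.262 (t=4.84, p=2.1e-05)
  V4: mean drop +0.161 (t=3.53, p=1.1e-03)
  LO: mean drop +0.072 (t=1.85, p=7.2e-02)

fraction of voxels better predicted by the augmented linear model
(vs planted invariant fraction):
  V1: 0.125 (planted 0.20)
  V2: 0.275 (planted 0.35)
  V3: 0.450 (planted 0.50)
  V4: 0.500 (planted 0.65)
  LO: 0.575 (planted 0.80)
V1->LO trend: Mann-Kendall S=+10 (rising)
```

Reading the numbers: augmented training costs the most accuracy in the
ROI dominated by equivariant voxels (V1) and almost nothing in the
invariance-dominated ROI (LO), and the share of voxels that the augmented
model predicts *better* rises strictly monotonically along the ROI order,
tracking the planted invariant fractions — the augmentation probe recovers
the gradient it was designed to detect. Small summary tables land under
`results/`; bulky intermediates (image libraries, feature matrices) under
`scratch/`.

The same pipeline is available programmatically:

```python
from invarscope import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(seed=7, out_dir="scratch/run"))
```

## Layout

- `src/invarscope/` — the library: stimulus/voxel generators, augmentation,
  the frozen NumPy CNN, similarity/trend analysis, encoding models,
  evaluation statistics, file I/O and the resumable pipeline driver.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  details and known limitations.
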