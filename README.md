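# octadr

Multi-scale screening of diabetic retinopathy (DR) from en-face OCTA
angiograms. The pipeline captures both the *appearance* and the
*morphology* of the retinal vasculature:

1. **Enhancement** — local (contrast-limited adaptive) histogram
   equalization, then edge-preserving denoising under a generalized
   Gauss-Markov random field, minimizing
   `E(x) = Σ_s |x_s − y_s|^α + λ Σ_{s∼r} |x_s − x_r|^β`.
2. **Vessel segmentation** — an unsupervised Markov-Gibbs random
   field: a two-component Gaussian intensity mixture (EM, Otsu init)
   plus a Potts smoothness prior, descended by iterated conditional
   modes on `E(ℓ) = Σ_s −log p(y_s|ℓ_s) + γ Σ_{s∼r} [ℓ_s ≠ ℓ_r]`,
   followed by a 2-D connectivity filter.
3. **Morphology channel** — the signed Euclidean distance map Φ of the
   vessel mask (positive inside vessels, negative outside); the
   interior part encodes vessel caliber, which DR reduces.
4. **Composite** — an H×W×3 stack (enhanced gray, binary mask,
   normalized interior distance) fed to the classifiers.
5. **Multi-scale CNNs** — the frame is analyzed at four levels (full,
   4 quarters, 16 tiles, a centered fovea crop); each level trains a
   shallow CNN (four valid-3×3 conv blocks 16/32/64/128 + 2×2
   max-pool, two 128-wide FC layers, 2-class soft-max; Adam, lr 0.001,
   batch 32, dropout 0.2, dihedral flip/rotation augmentation).
6. **Soft-voting fusion** — the unweighted mean of per-level DR
   probabilities, thresholded at 0.5 (ties → DR).

Clinical OCTA cohorts are rarely shareable, so the package includes a
seeded phantom generator producing bright branching vasculature on a
speckled, shaded background with a foveal avascular zone (FAZ), plus a
DR class with capillary dropout, thinner vessels and an enlarged FAZ —
the markers the method keys on — with exact ground-truth masks. It is
aimed at readers who want to study or extend the method's mechanics
with fully reproducible, self-contained experiments.

## Worked example

```python
import numpy as np
from octadr import (ndr_spec, generate_phantom, preprocess_image,
                    ExperimentConfig, run_experiment)

# one phantom through the imaging stages
sample = generate_phantom(ndr_spec(128, seed=7))
comp = preprocess_image(sample.image)          # equalize → GGMRF → MGRF → Φ
mask = comp.channels[..., 1]
dice = 2 * np.sum(mask * sample.truth_mask) / (mask.sum() + sample.truth_mask.sum())
print(f"segmentation Dice vs truth: {dice:.3f}")

# the full screening experiment on a seeded 50+50 cohort at 128 px
res = run_experiment(ExperimentConfig(n_per_class=50, image_size=128,
                                      epochs=8, seed=0))
print({k: v for k, v in res["fused_metrics"].as_dict().items() if v is not None})
```

prints (seed 0; ~90 s on one CPU):

```
segmentation Dice vs truth: 0.885
{'accuracy': 100.0, 'sensitivity': 100.0, 'specificity': 100.0,
 'precision': 100.0, 'f1': 100.0, 'auc': 100.0,
 'balanced_accuracy': 100.0, 'kappa': 1.0}
```

The Dice score says the unsupervised MGRF segmentation recovers ~89%
of this phantom's true vessel mask (cohort mean ~0.95); the fused metrics say the four-level
ensemble separates the held-out 20% of DR from NDR phantoms perfectly —
the phantom class contrast is deliberately strong, so this demonstrates
the machinery, not clinical-grade difficulty (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```bash
octadr simulate --n-per-class 10 --size 128 --seed 1 --out cohort/
octadr enhance cohort/dr_000_image.png --out enh.png --window 33
octadr segment enh.png --out mask.png --gamma 1.5 --min-cc 20
octadr channels enh.png mask.png --out comp.tiff
octadr tile comp.tiff --out tiles/
octadr pipeline --n-per-class 50 --size 128 --epochs 8 --seed 0 --out runs/demo
```

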