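# phylloseg

Quantitative, label-free differentiation of the two major breast
fibroepithelial tumors — **fibroadenoma (FA)** and **phyllodes tumor (PT)**
— from two-channel multiphoton microscopy (MPM) images: second harmonic
generation (SHG, fibrillar collagen) plus autofluorescence (AF, cellular
signal). The two lesions are managed very differently (PT requires wide
excision) yet are hard to tell apart on core-needle biopsy; this package
implements a computer-aided analysis that turns their histological
hallmarks — balanced round ducts in FA versus exaggerated stromal growth
with leaf-like epithelial clefts in PT — into reproducible numbers.

The pipeline:

1. **Semantic segmentation.** A SegNet-style encoder–decoder (max-pool
   stages record argmax indices; the decoder upsamples by index unpooling)
   assigns every pixel to *Epithelial*, *Stroma*, or *Outer*. Training uses
   SGD with momentum 0.9, learning rate 0.01, L2 regularization 5·10⁻⁴,
   mini-batches of 4, and paired random flip/translation (≤ 20 px)
   augmentation. Implemented from scratch in numpy; no GPU needed.
2. **Morphometric scores.** Per image (or per 128-px block):
   the epithelial-to-stromal area ratio
   `r = #Epithelial px / #Stroma px` (higher in PT) and the mean SHG
   intensity within stroma, `s = mean(SHG | Stroma)` on the 8-bit converted
   image (higher in FA). Segmentation quality is reported as per-image
   total accuracy and ground-truth-area-weighted IoU.
3. **Statistics and discrimination.** Two-sample Kolmogorov–Smirnov tests
   on the per-image scores, and a closed-form two-class Fisher LDA in the
   (r, s) plane: `w = S⁻¹(μ_PT − μ_FA)` with the boundary through the
   midpoint of the class means. On z-standardized features the angle of
   the boundary to the SHG axis measures which score drives the separation
   (90° = SHG alone).

Since no patient images are publicly available, the package ships a
first-class **synthetic cohort generator** that emulates the acquisition
design — 5 FA + 5 PT patients, 6–12 imaged regions each, 33 FA + 43 PT
frames of 512×512 px (1 µm/px, 12-bit) — with per-patient random effects,
Poisson shot noise and Gaussian read noise. Its defaults realize the
qualitative class contrasts (larger epithelial fraction and elongated
clefts in PT, stronger stromal SHG in FA) and are documented as free
parameters in `docs/methods.md`, not as measured values.

## Worked example

```python
from phylloseg import (CohortSpec, generate_cohort, split_dataset,
                       score_dataset)
from phylloseg.segmentation import NetworkConfig, TrainingConfig, train
from phylloseg.evaluation import evaluate_split

cohort = generate_cohort(CohortSpec(seed=1), frame_size=128)   # 33 FA + 43 PT
cohort = split_dataset(cohort, train_fraction=0.5, rng_seed=7) # 38 / 38
model = train(cohort, NetworkConfig(encoder_depth=2, base_filters=8),
              TrainingConfig(epochs=120, seed=3))
report = evaluate_split(model, cohort, "test")
print(f"test accuracy {report.summary['accuracy_mean']:.3f}, "
      f"weighted IoU {report.summary['weighted_iou_mean']:.3f}")

_, stats = score_dataset(cohort, "ground_truth")
print(f"area ratio FA {stats.area_ratio_mean['FA']:.2f} vs "
      f"PT {stats.area_ratio_mean['PT']:.2f}  (KS p {stats.ks_area_ratio[1]:.1e})")
print(f"stromal SHG FA {stats.shg_mean['FA']:.1f} vs "
      f"PT {stats.shg_mean['PT']:.1f}  (KS p {stats.ks_shg[1]:.1e})")
```

Output from this exact snippet:

```
test accuracy 0.984, weighted IoU 0.968
area ratio FA 0.40 vs PT 1.20  (KS p 1.3e-21)
stromal SHG FA 114.0 vs PT 73.4  (KS p 2.2e-308)
```

The segmenter recovers ~98% of pixels on held-out images; the two scores
separate the lesion groups in the expected directions (PT has the larger
epithelial-to-stromal ratio, FA the stronger stromal SHG), both highly
significant under the KS test.

The same workflow is available from the shell:

```bash
phylloseg run-all --out runs/demo --seed 1     # simulate … classify
phylloseg report runs/demo                     # human-readable summary
```

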