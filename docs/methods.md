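# Methods

This note documents the models, parameters, numerical choices, and known
limitations of the package. It is the design record: every default named
here is the package's own choice unless it is a standard, widely reported
setting of the underlying method.

## Problem setting

Fibroadenoma (FA) and phyllodes tumor (PT) are fibroepithelial breast
tumors built from the same two compartments — duct epithelium and
collagenous stroma — but with different architecture: FA shows balanced
epithelial/stromal proliferation with rounded ducts, PT shows stromal
overgrowth that folds the epithelium into elongated leaf-like clefts.
Label-free MPM imaging sees both compartments without staining: fibrillar
collagen produces SHG, and cellular epithelium is bright in
autofluorescence while slightly dark in SHG. The analysis converts those
contrasts into two per-image scores and a linear discriminant.

## Synthetic cohort generator

**What it emulates.** The acquisition design: 5 patients per lesion class,
6–12 regions imaged per patient, class totals of 33 (FA) and 43 (PT)
frames; 512×512 px frames at 1 µm/px recorded at 12 bits and converted to
8 bits for analysis. Per-patient region counts are drawn uniformly subject
to the range and total constraints.

**Tissue morphology.** Each frame holds one smooth tissue blob (star-convex
boundary with a 3-term Fourier radius perturbation; base radius solved by
bisection so the blob covers `tissue_coverage` = 0.88 of the frame); the
complement is the Outer class. Epithelial structures are stamped strictly
inside the tissue until a per-image target epithelial fraction (of tissue
area) is reached: rotated ellipses for FA (eccentricity 0.3), curved
constant-width ribbons — random walks with angular diffusion 0.35 rad/step
— for PT (eccentricity 0.95), the simplest shape family with controllable
elongation. The per-image fraction is drawn from Normal(mean, 0.05) with
class means 0.30 (FA) and 0.55 (PT). Stopping at target-crossing overshoots
by about half a structure, i.e. ≈ `mean/(2·duct_count_mean)` ≈ 1–3% of the
target; the Monte-Carlo calibration test bounds the net bias at ±0.03.

**Optics.** Constant per-class 12-bit means — SHG: stroma 1800 (FA) or
1200 (PT), epithelium 250, outer 0; AF: epithelium 2200, stroma 900,
outer 0 — then Poisson shot noise on the signal, additive Gaussian read
noise (SD 30), clipping to [0, 4095] and rounding. This is the standard
photon-counting model; it deliberately omits fibrillar texture, so class
contrast is clean and the segmentation task is nearly thresholdable.

**Patient effects and relative discriminability.** Between-patient
heterogeneity is additive Gaussian on transformed scales, which keeps
parameters valid: SD 0.4 on logit(epithelial fraction) and SD 0.06 on
log(stromal SHG mean). These two scales are deliberately asymmetric: they
make the area-ratio distributions of the two classes partially overlap
across patients while stromal SHG separates them cleanly, so the two-score
scatter reproduces the qualitative structure the discrimination analysis
is designed to expose (an LDA boundary nearly perpendicular to the SHG
axis). Effect sizes are free parameters of the generator — configuration,
not measurements.

**Reproducibility.** One cohort seed fans out to per-class, per-patient,
and per-image seeds through `numpy.random.SeedSequence(entropy, spawn_key)`
so generation is bit-reproducible and order-independent.

**What passing tests do not show.** Real MPM tissue has fibrillar texture,
uneven illumination, stitching seams, out-of-focus regions, and annotation
noise; none are modeled. Performance numbers on this generator are
analogues demonstrating that the pipeline recovers known structure, not
estimates of clinical performance.

## Segmentation

A reduced SegNet-style encoder–decoder over the 2 input channels
(SHG, AF): each encoder stage is conv3×3 → ReLU → 2×2 max-pool storing
argmax indices; each decoder stage unpools into the recorded indices and
convolves; the final conv maps to 3 class logits. Index unpooling
guarantees output resolution equals input resolution. The canonical
architecture is VGG16-scale; the package default is 3 stages of 16 base
filters, and the desk-scale preset used in the experiments is 2 stages of
8 filters — sufficient because the synthetic task is contrast-dominated.

Training: pixel-wise softmax cross-entropy (unweighted; the class balance
is mild) plus L2 penalty, SGD with momentum 0.9, learning rate 0.01, L2
5·10⁻⁴, mini-batch 4 — the reported recipe — with identical random
flips and integer translations up to 20 px applied to image and mask
(vacated pixels: intensity 0, label Outer). The recorded epoch default is
5000; the desk-scale experiments use 120 epochs at 128-px resolution,
which converges on this task (the smoothed loss curve is monotone and the
last-50-epoch mean is far below the first-50 mean). Per-channel
normalization constants are computed on the training split only and stored
with the checkpoint. Everything is float32 numpy; single-threaded
execution is deterministic for a fixed seed.

Numerical notes: He-normal initialization scaled by fan-in; softmax is
max-shifted; cross-entropy clamps probabilities at 1e-12 and raises a
structured error on non-finite loss.

## Evaluation

Confusion matrices use rows = ground truth, columns = prediction.
Total accuracy is trace/total. IoU per class is
`cm[k,k] / (row_k + col_k − cm[k,k])`; a class absent from both rasters
has undefined IoU (NaN) and is excluded from aggregates. Weighted IoU is
the ground-truth-area-weighted sum of defined per-class IoUs (absent
classes carry zero weight, so the weights of defined classes sum to 1).
Metrics are computed per image and aggregated as mean and sample SD
(ddof = 1; SD reported as 0 for n = 1); pooled-pixel variants are also
emitted. Difference images color false negatives magenta and false
positives green relative to a reference class (default Stroma — the
reference class for a 3-class FN/FP rendering is a convention of this
package).

## Scores and statistics

The area ratio is the literal quotient Epithelial/Stroma (the fraction
variant Epithelial/(Epithelial+Stroma) is available via the generator's
fraction parameterization but the quotient is what the scoring reports);
Outer never enters either score. Stromal SHG is averaged on the 8-bit
converted image (floor(v/16), the stated analysis convention; whether the
original conversion rescaled per image is unknown — a global fixed divisor
is used). Zero-stroma inputs yield NaN scores that are flagged and
excluded, mirroring the zero-stroma block exclusion.

KS test: D is the supremum ECDF gap evaluated on the pooled sample (exact
under ties). The p-value uses the asymptotic two-sample Kolmogorov
distribution with effective size n_x n_y/(n_x+n_y); for
n_x + n_y ≤ 20 the exact permutation distribution is enumerated instead.
The test is applied to per-image scores pooled across patients (per-image
values from one patient are correlated, so p-values are anti-conservative
in the strict hierarchical sense; a per-patient aggregation is available
by grouping the score table before testing).

## Discrimination

Block features: 512-px images tile into 4×4 = 16 blocks of 128 px; blocks
with zero stromal pixels are excluded; 500 blocks per class are sampled
uniformly without replacement (all are taken, with a warning, if fewer are
eligible). Fisher LDA is closed-form with pooled within-class covariance
(pooled ddof n−2); a relative ridge `1e-6·trace(S)/p·I` is added when the
covariance is near-singular (condition number > 1e10). The intercept
places the boundary at the midpoint of class means (equal priors — no
prior information is assumed). Features are z-standardized with training
statistics by default so the boundary-angle diagnostic
`arccos(|w_ratio|/‖w‖)` is scale-free; raw-feature mode exists for
plotting. Reported accuracy is resubstitution accuracy on the fitted
points; no held-out classification split is defined for this analysis.

## Pipeline

`run_full` derives every stage seed as
`sha256(global_seed:stage:index) mod 2³¹`, caches stages behind
config-hash markers (`<stage>.done`), and writes `run_manifest.json` with
SHA-256 checksums of all artifacts. The report renders exclusively from
serialized artifacts.

## Problem sizes used in the shipped experiments

Cohorts for segmentation experiments are rendered at 128×128 px (the
geometry scales down cleanly because the intensity model is
resolution-free); training uses the 2-stage/8-filter preset for 120
epochs. The block analysis uses the full 512-px frames. Monte-Carlo
checks use 300 mask draws (fraction calibration), 100 renders (noise
means), 30 reduced cohorts (intraclass correlation), 10 cohorts (boundary
orientation), and 2000 null simulations at n = 30 per group (KS
calibration).

## Known limitations

* The generator's effect sizes are free parameters; no patient-image gap
  is published to calibrate them against, so group-difference magnitudes
  are illustrative.
* Constant-per-class intensities make segmentation easier than on real
  tissue; accuracy analogues are upper-bound demonstrations.
* PT clefts are non-branching ribbons; true leaf-like architecture
  branches.
* The KS test ignores within-patient correlation (see above).
* The numpy network is CPU-bound and desk-scale; it is not intended for
  512-px, 5000-epoch training runs.
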