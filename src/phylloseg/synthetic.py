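"""Synthetic two-channel MPM image generator with ground-truth masks.

No public image data exist for the FA-vs-PT problem, so the pipeline is
exercised end-to-end on simulated cohorts that reproduce the acquisition
design (5 patients per lesion class, 6--12 imaged regions each, 33 FA and
43 PT frames in total) and the two qualitative contrasts the analysis rests
on:

* **morphology** — FA-like frames contain balanced, roughly round epithelial
  ducts occupying a smaller fraction of the tissue; PT-like frames contain
  elongated, curved, leaf-like epithelial clefts occupying a larger fraction,
* **optics** — stromal collagen emits stronger SHG in FA than in PT, while
  the epithelium is dark in SHG and bright in autofluorescence in both.

The generative model is deliberately simple: a smooth tissue blob on an
empty (Outer) background, epithelial structures stamped strictly inside the
tissue until a target epithelial fraction is met, and a constant-per-class
intensity model with Poisson shot noise and Gaussian read noise, clipped and
quantized to the 12-bit range. Between-patient heterogeneity enters as
additive Gaussian random effects on logit(epithelial fraction) and
log(stromal SHG mean), which keeps both parameters in their valid ranges.
All default effect sizes are free parameters of this package chosen to give
a realistic-looking but learnable task; they are not measured values.

Reproducibility: one global seed fans out to per-patient and per-image
seeds through ``numpy.random.SeedSequence`` spawn keys, so cohorts are
bit-reproducible regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import disk as draw_disk

from .errors import GeometryError, InvalidParameterError
from .io import (
    OUTER,
    STROMA,
    EPITHELIAL,
    MPMImage,
    DatasetManifest,
    write_image,
    write_mask,
)

__all__ = [
    "CohortSpec",
    "MorphologyParams",
    "OpticsParams",
    "fa_morphology",
    "pt_morphology",
    "default_optics",
    "generate_tissue_mask",
    "render_mpm_image",
    "generate_cohort",
]


@dataclass
class CohortSpec:
    """Cohort design: patients per class and imaged regions per patient.

    Defaults emulate the acquisition design of the study setting: 5 + 5
    patients, 6--12 regions each, and fixed class totals of 33 FA and 43 PT
    images.
    """

    n_patients_per_class: int = 5
    regions_per_patient_range: tuple[int, int] = (6, 12)
    target_totals: dict[str, int] | None = None  # None -> {"FA": 33, "PT": 43}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_totals is None:
            self.target_totals = {"FA": 33, "PT": 43}
        lo, hi = self.regions_per_patient_range
        if lo < 1 or hi < lo:
            raise InvalidParameterError(
                f"regions_per_patient_range {self.regions_per_patient_range} invalid"
            )
        if self.n_patients_per_class < 1:
            raise InvalidParameterError("need at least one patient per class")
        n = self.n_patients_per_class
        for lesion, total in self.target_totals.items():
            if not n * lo <= total <= n * hi:
                raise InvalidParameterError(
                    f"{lesion}: total {total} unreachable with {n} patients "
                    f"and {lo}-{hi} regions each"
                )


@dataclass
class MorphologyParams:
    """Shape model for one lesion class.

    ``duct_eccentricity`` controls elongation of epithelial structures
    (FA low: near-round ducts; PT high: leaf-like clefts) and
    ``cleft_like`` switches the shape family from ellipses to curved
    ribbons. ``epithelial_fraction_mean`` is the target value of
    epithelial / (epithelial + stromal) area. ``patient_effect_sd`` is the
    scale of the between-patient Gaussian effect applied on the logit of the
    epithelial fraction; the analogous effect on log stromal SHG lives in
    :class:`OpticsParams` (``shg_patient_effect_sd``). Defaults make the
    area ratio partially overlap between lesion classes while stromal SHG
    separates them cleanly, mirroring the relative discriminability the
    two-score scatter analysis is designed to expose.
    """

    duct_count_mean: float = 12.0
    duct_eccentricity: float = 0.3
    cleft_like: bool = False
    epithelial_fraction_mean: float = 0.30
    epithelial_fraction_sd: float = 0.05
    tissue_coverage: float = 0.88
    patient_effect_sd: float = 0.4

    def __post_init__(self) -> None:
        for name in ("epithelial_fraction_mean", "epithelial_fraction_sd", "tissue_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.duct_eccentricity < 1.0:
            raise InvalidParameterError("duct_eccentricity must lie in [0, 1)")
        if self.duct_count_mean <= 0:
            raise InvalidParameterError("duct_count_mean must be positive")


@dataclass
class OpticsParams:
    """Acquisition model: frame geometry, per-class 12-bit intensity means,
    and the photon-counting noise model (Poisson shot noise plus Gaussian
    read noise, clipped to the 12-bit range and quantized)."""

    frame_size: int = 512
    pixel_size: float = 1.0
    bit_depth_raw: int = 12
    shg_stroma_mean: float = 1800.0
    shg_epithelial_mean: float = 250.0
    af_epithelial_mean: float = 2200.0
    af_stroma_mean: float = 900.0
    read_noise_sd: float = 30.0
    shot_noise: bool = True
    shg_patient_effect_sd: float = 0.06

    def __post_init__(self) -> None:
        top = 2 ** self.bit_depth_raw - 1
        for name in ("shg_stroma_mean", "shg_epithelial_mean", "af_epithelial_mean", "af_stroma_mean"):
            v = getattr(self, name)
            if not 0 <= v <= top:
                raise InvalidParameterError(f"{name}={v} outside [0, {top}]")
        if self.frame_size < 8:
            raise InvalidParameterError("frame_size too small")
        if self.read_noise_sd < 0:
            raise InvalidParameterError("read_noise_sd must be non-negative")


def fa_morphology() -> MorphologyParams:
    """FA-like defaults: balanced round ducts, moderate epithelial fraction."""
    return MorphologyParams(
        duct_count_mean=12.0,
        duct_eccentricity=0.3,
        cleft_like=False,
        epithelial_fraction_mean=0.30,
        epithelial_fraction_sd=0.05,
    )


def pt_morphology() -> MorphologyParams:
    """PT-like defaults: elongated leaf-like clefts, larger epithelial fraction."""
    return MorphologyParams(
        duct_count_mean=8.0,
        duct_eccentricity=0.95,
        cleft_like=True,
        epithelial_fraction_mean=0.55,
        epithelial_fraction_sd=0.05,
    )


def default_optics(frame_size: int = 512, lesion: str = "FA") -> OpticsParams:
    """Class-dependent optics: stromal SHG is stronger for FA than PT."""
    shg_stroma = 1800.0 if lesion == "FA" else 1200.0
    return OpticsParams(frame_size=frame_size, shg_stroma_mean=shg_stroma)


# ---------------------------------------------------------------------------
# tissue mask generation

def _tissue_blob(n: int, coverage: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth star-convex blob with area ~= coverage * n**2, centered with a
    small jitter; the boundary radius is a low-order Fourier perturbation."""
    if coverage >= 1.0:
        return np.ones((n, n), dtype=bool)
    if coverage <= 0.0:
        return np.zeros((n, n), dtype=bool)
    cy, cx = (n - 1) / 2 + rng.normal(0, 0.02 * n, size=2)
    yy, xx = np.mgrid[0:n, 0:n]
    theta = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    amp = rng.uniform(0.03, 0.08, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    perturb = sum(a * np.cos(k * theta + p) for k, (a, p) in enumerate(zip(amp, phase), start=2))
    shape = 1.0 + perturb
    # binary search the base radius so the clipped blob hits the coverage target
    target = coverage * n * n
    lo, hi = 0.1 * n, 1.2 * n
    for _ in range(20):
        r0 = 0.5 * (lo + hi)
        area = (rad <= r0 * shape).sum()
        if area < target:
            lo = r0
        else:
            hi = r0
    return rad <= 0.5 * (lo + hi) * shape


def _stamp_ellipse(allowed: np.ndarray, area: float, ecc: float,
                   rng: np.random.Generator) -> np.ndarray | None:
    """One rotated ellipse of roughly the given pixel area, clipped to the
    allowed region. Returns None if no anchor pixel is available."""
    n = allowed.shape[0]
    anchors = np.flatnonzero(allowed)
    if anchors.size == 0:
        return None
    r0, c0 = np.unravel_index(rng.choice(anchors), allowed.shape)
    q = np.sqrt(1.0 - ecc ** 2)  # minor/major axis ratio
    a = np.sqrt(area / (np.pi * q))
    rr, cc = draw_ellipse(
        r0, c0, a * q, a, shape=(n, n), rotation=rng.uniform(0, np.pi)
    )
    out = np.zeros_like(allowed)
    out[rr, cc] = True
    return out & allowed


def _stamp_ribbon(allowed: np.ndarray, area: float, ecc: float,
                  rng: np.random.Generator) -> np.ndarray | None:
    """One curved ribbon (random walk with width) of roughly the given area;
    the leaf-like cleft shape family. Elongation grows with eccentricity."""
    n = allowed.shape[0]
    anchors = np.flatnonzero(allowed)
    if anchors.size == 0:
        return None
    r, c = np.unravel_index(rng.choice(anchors), allowed.shape)
    q = np.sqrt(1.0 - ecc ** 2)
    elong = 1.0 / max(q, 0.05)              # length / width
    length = np.sqrt(area * elong)
    width = max(area / length, 2.0)
    half = max(width / 2.0, 1.0)
    step = max(half, 1.5)
    n_steps = max(int(np.ceil(length / step)), 2)
    theta = rng.uniform(0, 2 * np.pi)
    out = np.zeros_like(allowed)
    rf, cf = float(r), float(c)
    for _ in range(n_steps):
        rr, cc = draw_disk((rf, cf), half + 0.5, shape=(n, n))
        out[rr, cc] = True
        theta += rng.normal(0.0, 0.35)
        rf += step * np.sin(theta)
        cf += step * np.cos(theta)
        rf = float(np.clip(rf, 0, n - 1))
        cf = float(np.clip(cf, 0, n - 1))
    return out & allowed


def generate_tissue_mask(
    morph: MorphologyParams,
    frame_size: int = 512,
    rng_seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Draw one ground-truth label mask over {Outer, Stroma, Epithelial}.

    The Outer class is the complement of a smooth tissue blob covering
    ``tissue_coverage`` of the frame. Epithelial structures (ellipses, or
    curved ribbons when ``cleft_like``) are stamped strictly inside the
    tissue until the realized epithelial fraction of the tissue area reaches
    a per-image target drawn from
    ``Normal(epithelial_fraction_mean, epithelial_fraction_sd)``.
    """
    rng = np.random.default_rng(rng_seed)
    n = frame_size
    tissue = _tissue_blob(n, morph.tissue_coverage, rng)
    mask = np.where(tissue, STROMA, OUTER).astype(np.uint8)
    tissue_area = int(tissue.sum())
    if tissue_area == 0:
        return mask

    frac = float(np.clip(
        rng.normal(morph.epithelial_fraction_mean, morph.epithelial_fraction_sd),
        0.0, 0.95,
    ))
    target = frac * tissue_area
    if target < 1.0:
        return mask

    # keep epithelium strictly interior to tissue
    margin = max(2, n // 256)
    allowed = ndimage.binary_erosion(tissue, iterations=margin)
    if not allowed.any():
        raise GeometryError(
            f"frame of {n} px too small to place epithelial structures inside tissue"
        )
    mean_area = max(target / morph.duct_count_mean, 12.0)
    stamp = _stamp_ribbon if morph.cleft_like else _stamp_ellipse
    epithelium = np.zeros_like(tissue)
    max_attempts = int(8 * morph.duct_count_mean) + 40
    for _ in range(max_attempts):
        if epithelium.sum() >= target:
            break
        area = mean_area * rng.lognormal(0.0, 0.3)
        piece = stamp(allowed, area, morph.duct_eccentricity, rng)
        if piece is None:
            raise GeometryError("no interior tissue available for epithelial structures")
        epithelium |= piece
    mask[epithelium] = EPITHELIAL
    return mask


# ---------------------------------------------------------------------------
# rendering

def render_mpm_image(
    mask: np.ndarray,
    optics: OpticsParams,
    rng_seed: int | np.random.SeedSequence = 0,
) -> MPMImage:
    """Render the two-channel 12-bit image for a label mask.

    Per-class constant means (SHG: stroma bright, epithelium dim, outer
    dark; AF: epithelium bright, stroma dim, outer dark), then Poisson shot
    noise on the signal, additive Gaussian read noise, clipping to
    ``[0, 2**bit_depth_raw - 1]`` and quantization. Deterministic given the
    seed.
    """
    mask = np.asarray(mask)
    if mask.shape != (optics.frame_size, optics.frame_size):
        raise InvalidParameterError(
            f"mask shape {mask.shape} does not match optics frame_size {optics.frame_size}"
        )
    rng = np.random.default_rng(rng_seed)
    top = 2 ** optics.bit_depth_raw - 1

    def channel(outer_mean: float, stroma_mean: float, epi_mean: float) -> np.ndarray:
        base = np.choose(mask, [outer_mean, stroma_mean, epi_mean])
        signal = rng.poisson(base).astype(np.float64) if optics.shot_noise else base.astype(np.float64)
        if optics.read_noise_sd > 0:
            signal = signal + rng.normal(0.0, optics.read_noise_sd, size=mask.shape)
        return np.clip(np.rint(signal), 0, top).astype(np.uint16)

    shg = channel(0.0, optics.shg_stroma_mean, optics.shg_epithelial_mean)
    af = channel(0.0, optics.af_stroma_mean, optics.af_epithelial_mean)
    return MPMImage(shg=shg, af=af, bit_depth=optics.bit_depth_raw,
                    pixel_size=optics.pixel_size)


# ---------------------------------------------------------------------------
# cohort assembly

def _allocate_regions(total: int, n_patients: int, lo: int, hi: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Random per-patient region counts in [lo, hi] summing exactly to total."""
    counts = np.full(n_patients, lo, dtype=int)
    remainder = total - counts.sum()
    while remainder > 0:
        open_slots = np.flatnonzero(counts < hi)
        counts[rng.choice(open_slots)] += 1
        remainder -= 1
    return counts


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def generate_cohort(
    spec: CohortSpec,
    morph_fa: MorphologyParams | None = None,
    morph_pt: MorphologyParams | None = None,
    optics_fa: OpticsParams | None = None,
    optics_pt: OpticsParams | None = None,
    out_dir: str | Path | None = None,
    frame_size: int | None = None,
) -> DatasetManifest:
    """Simulate a full two-class cohort and return its manifest.

    Per-patient Gaussian random effects (scale ``patient_effect_sd``) shift
    logit(epithelial fraction) and log(stromal SHG mean), so images from one
    patient are correlated. When ``out_dir`` is given, images (16-bit TIFF)
    and masks (8-bit PNG) are written there and the manifest references the
    files; otherwise everything stays in memory.

    With the default spec this produces exactly 33 FA + 43 PT = 76 images
    from 5 + 5 patients, reproducibly for a fixed ``spec.seed``.
    """
    morphs = {"FA": morph_fa or fa_morphology(), "PT": morph_pt or pt_morphology()}
    optics = {
        "FA": optics_fa or default_optics(lesion="FA"),
        "PT": optics_pt or default_optics(lesion="PT"),
    }
    if frame_size is not None:
        optics = {k: replace(v, frame_size=frame_size) for k, v in optics.items()}

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)

    rows = []
    images: dict[str, MPMImage] = {}
    masks: dict[str, np.ndarray] = {}
    lo, hi = spec.regions_per_patient_range
    for class_idx, lesion in enumerate(("FA", "PT")):
        morph, opt = morphs[lesion], optics[lesion]
        class_ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(class_idx,))
        alloc_rng = np.random.default_rng(class_ss)
        counts = _allocate_regions(
            spec.target_totals[lesion], spec.n_patients_per_class, lo, hi, alloc_rng
        )
        for p_idx, n_regions in enumerate(counts):
            patient_id = f"{lesion}{p_idx + 1:02d}"
            patient_ss = np.random.SeedSequence(
                entropy=spec.seed, spawn_key=(class_idx, p_idx)
            )
            prng = np.random.default_rng(patient_ss)
            eff_frac = prng.normal(0.0, morph.patient_effect_sd)
            eff_shg = prng.normal(0.0, opt.shg_patient_effect_sd)
            p_morph = replace(
                morph,
                epithelial_fraction_mean=_expit(
                    _logit(morph.epithelial_fraction_mean) + eff_frac
                ),
            )
            p_opt = replace(
                opt,
                shg_stroma_mean=float(np.clip(
                    np.exp(np.log(opt.shg_stroma_mean) + eff_shg),
                    1.0, 2 ** opt.bit_depth_raw - 1,
                )),
            )
            for r_idx in range(n_regions):
                image_id = f"{patient_id}_r{r_idx + 1:02d}"
                img_ss = np.random.SeedSequence(
                    entropy=spec.seed, spawn_key=(class_idx, p_idx, r_idx)
                )
                mask_ss, render_ss = img_ss.spawn(2)
                mask = generate_tissue_mask(p_morph, p_opt.frame_size, mask_ss)
                image = render_mpm_image(mask, p_opt, render_ss)
                img_path, mask_path = (
                    f"images/{image_id}.tif",
                    f"masks/{image_id}.png",
                )
                if out is not None:
                    write_image(out / img_path, image)
                    write_mask(out / mask_path, mask)
                else:
                    images[image_id] = image
                    masks[image_id] = mask
                rows.append(
                    dict(
                        image_id=image_id,
                        patient_id=patient_id,
                        lesion=lesion,
                        image_path=img_path,
                        mask_path=mask_path,
                        seed=int(img_ss.entropy),
                    )
                )

    frame = pd.DataFrame(rows)
    manifest = DatasetManifest(frame=frame, root=out, images=images, masks=masks)
    if out is not None:
        manifest.save_csv(out / "manifest.csv")
    return manifest
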