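"""Per-image quantitative signatures and FA-vs-PT group statistics.

Two scores are computed per image (or per 128-px block):

* **epithelial-to-stromal area ratio** — epithelial pixel count divided by
  stromal pixel count; the Outer region is excluded entirely. Elevated in
  PT, whose leaf-like clefts (epithelium plus lumen) occupy more area.
* **mean stromal SHG intensity** — arithmetic mean of the SHG channel over
  Stroma-labeled pixels, measured on the 8-bit converted image; higher in
  FA, reflecting denser/more organized collagen.

Scores with zero stromal area are undefined and returned as NaN (flagged,
never silently zero); callers drop them, mirroring the zero-stroma block
exclusion used in the block analysis. Group differences are tested with the
two-sample Kolmogorov--Smirnov test (asymptotic by default, exact
permutation enumeration for small samples).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyInputError, ShapeMismatchError, InvalidParameterError
from .io import (
    DatasetManifest,
    MPMImage,
    STROMA,
    EPITHELIAL,
    convert_to_8bit,
)

logger = logging.getLogger(__name__)


@dataclass
class ScoreRecord:
    """Both signatures for one image (or block), with provenance."""

    image_id: str
    patient_id: str
    lesion: str
    area_ratio: float
    shg_stroma_mean: float
    source: str  # ground_truth | predicted

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.area_ratio) or math.isnan(self.shg_stroma_mean))


@dataclass
class GroupStats:
    """Per-lesion mean/SD of each score plus the KS comparison."""

    n: dict
    area_ratio_mean: dict
    area_ratio_sd: dict
    shg_mean: dict
    shg_sd: dict
    ks_area_ratio: tuple[float, float]  # (D, p)
    ks_shg: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "area_ratio": {"mean": self.area_ratio_mean, "sd": self.area_ratio_sd},
            "shg_stroma_mean": {"mean": self.shg_mean, "sd": self.shg_sd},
            "ks": {
                "area_ratio": {"D": self.ks_area_ratio[0], "p": self.ks_area_ratio[1]},
                "shg_stroma_mean": {"D": self.ks_shg[0], "p": self.ks_shg[1]},
            },
        }


def area_ratio(mask: np.ndarray) -> float:
    """Epithelial px / stromal px; NaN when the mask has no stroma."""
    mask = np.asarray(mask)
    n_stroma = int((mask == STROMA).sum())
    if n_stroma == 0:
        return float("nan")
    return float((mask == EPITHELIAL).sum() / n_stroma)


def mean_shg_in_stroma(image: MPMImage, mask: np.ndarray) -> float:
    """Mean SHG intensity over Stroma pixels on the 8-bit image; NaN when
    the mask has no stroma."""
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ShapeMismatchError(f"image {image.shape} vs mask {mask.shape}")
    img8 = convert_to_8bit(image)
    sel = mask == STROMA
    if not sel.any():
        return float("nan")
    return float(np.asarray(img8.shg, dtype=np.float64)[sel].mean())


def ks_two_sample(
    x, y, method: str = "auto"
) -> tuple[float, float]:
    """Two-sample Kolmogorov--Smirnov test.

    D is the supremum ECDF gap (evaluated over the pooled sample, so ties
    are handled exactly). The p-value comes from the asymptotic two-sample
    Kolmogorov distribution with effective size n_x n_y / (n_x + n_y), or
    from exact enumeration of all label assignments when
    ``n_x + n_y <= 20`` (method="auto") or on request (method="exact").
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("KS test needs two non-empty samples")
    if method not in ("auto", "exact", "asymp"):
        raise InvalidParameterError(f"unknown KS method '{method}'")

    d = _ks_statistic(x, y)
    exact = method == "exact" or (method == "auto" and x.size + y.size <= 20)
    if exact:
        p = _ks_exact_p(x, y, d)
    else:
        p = float(stats.ks_2samp(x, y, method="asymp").pvalue)
    return d, min(max(p, np.finfo(float).tiny), 1.0)


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def _ks_exact_p(x: np.ndarray, y: np.ndarray, d_obs: float) -> float:
    """Exact permutation p: fraction of all C(n_x+n_y, n_x) label
    assignments of the pooled values whose D is >= the observed one."""
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    count = total = 0
    idx_all = frozenset(range(n))
    for comb in combinations(range(n), nx):
        xs = np.sort(pooled[list(comb)])
        ys = np.sort(pooled[list(idx_all - set(comb))])
        if _ks_statistic(xs, ys) >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def score_dataset(
    manifest: DatasetManifest,
    masks_source: str = "ground_truth",
    predicted_masks: dict[str, np.ndarray] | None = None,
) -> tuple[list[ScoreRecord], GroupStats]:
    """Score every image of a cohort and compute FA/PT group statistics.

    ``masks_source`` is "ground_truth" (manifest masks) or "predicted"
    (masks supplied via ``predicted_masks``, keyed by image_id). Images with
    a missing mask are skipped with a warning; undefined scores are kept as
    NaN in the records but excluded from group statistics.
    """
    if masks_source not in ("ground_truth", "predicted"):
        raise InvalidParameterError(f"unknown masks_source '{masks_source}'")
    if masks_source == "predicted" and predicted_masks is None:
        raise InvalidParameterError("masks_source='predicted' requires predicted_masks")
    records: list[ScoreRecord] = []
    for _, row in manifest.frame.iterrows():
        image_id = row["image_id"]
        if masks_source == "predicted":
            if image_id not in predicted_masks:
                logger.warning("no predicted mask for %s; record skipped", image_id)
                continue
            mask = predicted_masks[image_id]
        else:
            mask = manifest.load_mask(image_id)
        image = manifest.load_image(image_id)
        records.append(
            ScoreRecord(
                image_id=image_id,
                patient_id=row["patient_id"],
                lesion=row["lesion"],
                area_ratio=area_ratio(mask),
                shg_stroma_mean=mean_shg_in_stroma(image, mask),
                source=masks_source,
            )
        )
    return records, group_stats(records)


def records_frame(records: list[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "patient_id": r.patient_id,
                "lesion": r.lesion,
                "area_ratio": r.area_ratio,
                "shg_stroma_mean": r.shg_stroma_mean,
                "source": r.source,
            }
            for r in records
        ]
    )


def group_stats(records: list[ScoreRecord]) -> GroupStats:
    """Per-lesion mean/SD (sample SD, undefined scores dropped) and KS tests
    on per-image values pooled across patients."""
    frame = records_frame([r for r in records if r.defined])
    if frame.empty:
        raise EmptyInputError("no defined score records")
    out = {"n": {}, "rm": {}, "rs": {}, "sm": {}, "ss": {}}
    samples = {}
    for lesion, grp in frame.groupby("lesion"):
        out["n"][lesion] = int(len(grp))
        out["rm"][lesion] = float(grp["area_ratio"].mean())
        out["rs"][lesion] = float(grp["area_ratio"].std(ddof=1)) if len(grp) > 1 else 0.0
        out["sm"][lesion] = float(grp["shg_stroma_mean"].mean())
        out["ss"][lesion] = float(grp["shg_stroma_mean"].std(ddof=1)) if len(grp) > 1 else 0.0
        samples[lesion] = grp
    if set(samples) == {"FA", "PT"}:
        ks_ratio = ks_two_sample(
            samples["FA"]["area_ratio"], samples["PT"]["area_ratio"]
        )
        ks_shg = ks_two_sample(
            samples["FA"]["shg_stroma_mean"], samples["PT"]["shg_stroma_mean"]
        )
    else:
        ks_ratio = ks_shg = (float("nan"), float("nan"))
    return GroupStats(
        n=out["n"],
        area_ratio_mean=out["rm"],
        area_ratio_sd=out["rs"],
        shg_mean=out["sm"],
        shg_sd=out["ss"],
        ks_area_ratio=ks_ratio,
        ks_shg=ks_shg,
    )
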