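"""Two-score discrimination of FA vs PT with Fisher linear discriminant
analysis, at whole-image or 128-px block granularity.

The feature space is (epithelial-to-stromal area ratio, mean stromal SHG
intensity). For the block analysis, every image is tiled into 128-px
blocks, blocks with zero stromal area are excluded, and a fixed number of
blocks (default 500) is sampled per lesion class without replacement.

The classifier is closed-form two-class Fisher LDA: with pooled
within-class covariance S and class means m_FA, m_PT,

    w = S^{-1} (m_PT - m_FA),    b = -w . (m_FA + m_PT) / 2,

so the decision rule is sign(w . x + b) with the boundary through the
midpoint of the class means (equal priors). Features are z-standardized by
default so that the orientation of the boundary relative to the SHG axis is
scale-free: an angle near 90 degrees means the SHG intensity alone drives
the separation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import EmptyInputError, InvalidParameterError, SingularCovarianceError
from .io import DatasetManifest, tile_image, convert_to_8bit
from .scoring import area_ratio, mean_shg_in_stroma

logger = logging.getLogger(__name__)

FEATURES = ["area_ratio", "shg_stroma_mean"]


class FisherLDA(BaseEstimator, ClassifierMixin):
    """Closed-form two-class Fisher linear discriminant.

    Parameters
    ----------
    standardize : bool
        z-score features with training statistics before fitting (the
        boundary-angle diagnostic is only meaningful on comparable scales).
    ridge : float
        Relative ridge added to the pooled covariance when it is
        near-singular: ``ridge * trace(S) / n_features * I``. Set to 0 to
        disable (singular covariance then raises).

    Fitted attributes: ``w_`` (weights in the, possibly standardized,
    feature space), ``b_`` (intercept), ``means_`` (per-class), ``cov_``
    (pooled within-class covariance), ``classes_``, ``scale_mean_`` /
    ``scale_std_`` when standardizing.
    """

    def __init__(self, standardize: bool = True, ridge: float = 1e-6):
        self.standardize = standardize
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise InvalidParameterError("X must be 2-D (n_samples, n_features)")
        if not np.isfinite(X).all():
            raise InvalidParameterError("features contain NaN/inf (undefined scores?)")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise InvalidParameterError(f"need exactly 2 classes, got {self.classes_}")
        if self.standardize:
            self.scale_mean_ = X.mean(axis=0)
            self.scale_std_ = np.maximum(X.std(axis=0, ddof=0), 1e-12)
            X = (X - self.scale_mean_) / self.scale_std_
        x0, x1 = X[y == self.classes_[0]], X[y == self.classes_[1]]
        if len(x0) < 2 or len(x1) < 2:
            raise InvalidParameterError("each class needs at least 2 samples")
        m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
        n0, n1 = len(x0), len(x1)
        s = ((n0 - 1) * np.cov(x0, rowvar=False) + (n1 - 1) * np.cov(x1, rowvar=False)) / (
            n0 + n1 - 2
        )
        s = np.atleast_2d(s)
        p = X.shape[1]
        if np.linalg.cond(s) > 1e10 or not np.isfinite(np.linalg.cond(s)):
            if self.ridge <= 0:
                raise SingularCovarianceError("pooled covariance is singular; enable ridge")
            s = s + self.ridge * (np.trace(s) / p if np.trace(s) > 0 else 1.0) * np.eye(p)
        self.cov_ = s
        self.means_ = np.stack([m0, m1])
        self.w_ = np.linalg.solve(s, m1 - m0)
        if np.allclose(self.w_, 0.0):
            warnings.warn("identical class means: degenerate LDA with zero weight vector")
        self.b_ = -float(self.w_ @ (m0 + m1) / 2.0)
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.standardize:
            X = (X - self.scale_mean_) / self.scale_std_
        return X @ self.w_ + self.b_

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


def fit_lda(points: pd.DataFrame, standardize: bool = True, ridge: float = 1e-6) -> FisherLDA:
    """Fit :class:`FisherLDA` on a feature-point table (columns
    ``area_ratio``, ``shg_stroma_mean``, ``lesion``)."""
    return FisherLDA(standardize=standardize, ridge=ridge).fit(
        points[FEATURES].to_numpy(), points["lesion"].to_numpy()
    )


def classify(model: FisherLDA, points: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Predict lesion labels for feature points; returns the annotated table
    and accuracies (overall, per class, per granularity when present)."""
    out = points.copy()
    out["predicted"] = model.predict(points[FEATURES].to_numpy())
    correct = out["predicted"] == out["lesion"]
    acc = {"overall": float(correct.mean())}
    for lesion, grp in out.groupby("lesion"):
        acc[f"class_{lesion}"] = float((grp["predicted"] == lesion).mean())
    if "granularity" in out.columns:
        for gran, grp in out.groupby("granularity"):
            acc[f"granularity_{gran}"] = float((grp["predicted"] == grp["lesion"]).mean())
    return out, acc


def boundary_angle_to_shg_axis(model: FisherLDA) -> float:
    """Angle, in degrees in [0, 90], between the separating line and the SHG
    intensity axis (feature order: area ratio first, SHG second).

    A pure-SHG weight vector gives 90 degrees (boundary perpendicular to the
    SHG axis, i.e. SHG alone separates the classes); a pure-ratio weight
    gives 0.
    """
    w = np.asarray(model.w_, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise InvalidParameterError("zero weight vector has no boundary orientation")
    # boundary direction is perpendicular to w; its angle to the SHG axis
    # (unit vector along feature 2) has cosine |w[0]| / ||w||
    return float(np.degrees(np.arccos(np.clip(abs(w[0]) / norm, 0.0, 1.0))))


def build_block_features(
    manifest: DatasetManifest,
    masks_source: str = "ground_truth",
    predicted_masks: dict[str, np.ndarray] | None = None,
    block_px: int = 128,
    n_per_class: int = 500,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Tile every cohort image into ``block_px`` blocks, drop blocks with
    zero stromal area, sample ``n_per_class`` blocks per lesion class
    uniformly without replacement, and score each sampled block.

    Returns a feature-point table with columns image_id, block_index,
    patient_id, lesion, area_ratio, shg_stroma_mean, granularity.
    If a class has fewer eligible blocks than requested, all of them are
    used and a warning is issued.
    """
    if masks_source == "predicted" and predicted_masks is None:
        raise InvalidParameterError("masks_source='predicted' requires predicted_masks")
    eligible: dict[str, list[dict]] = {}
    for _, row in manifest.frame.iterrows():
        image_id = row["image_id"]
        image = convert_to_8bit(manifest.load_image(image_id))
        if masks_source == "predicted":
            if image_id not in predicted_masks:
                logger.warning("no predicted mask for %s; image skipped", image_id)
                continue
            mask = predicted_masks[image_id]
        else:
            mask = manifest.load_mask(image_id)
        blocks = tile_image(image, mask, block_px)
        for b_idx, (b_img, b_mask) in enumerate(blocks):
            r = area_ratio(b_mask)
            if np.isnan(r):  # zero-stroma block: excluded
                continue
            eligible.setdefault(row["lesion"], []).append(
                dict(
                    image_id=image_id,
                    block_index=b_idx,
                    patient_id=row["patient_id"],
                    lesion=row["lesion"],
                    area_ratio=r,
                    shg_stroma_mean=mean_shg_in_stroma(b_img, b_mask),
                    granularity=f"block_{block_px}",
                )
            )
    if not eligible:
        raise EmptyInputError("no eligible blocks in the cohort")
    rng = np.random.default_rng(rng_seed)
    rows: list[dict] = []
    for lesion in sorted(eligible):
        pool = eligible[lesion]
        if len(pool) == 0:
            raise EmptyInputError(f"class {lesion} has zero eligible blocks")
        if len(pool) < n_per_class:
            warnings.warn(
                f"class {lesion}: only {len(pool)} eligible blocks "
                f"(< requested {n_per_class}); using all"
            )
            chosen = range(len(pool))
        else:
            chosen = rng.choice(len(pool), size=n_per_class, replace=False)
        rows.extend(pool[i] for i in chosen)
    return pd.DataFrame(rows)


def image_features(records) -> pd.DataFrame:
    """Feature-point table at whole-image granularity from score records
    (undefined scores dropped)."""
    rows = [
        dict(
            image_id=r.image_id,
            patient_id=r.patient_id,
            lesion=r.lesion,
            area_ratio=r.area_ratio,
            shg_stroma_mean=r.shg_stroma_mean,
            granularity="full_image",
        )
        for r in records
        if r.defined
    ]
    if not rows:
        raise EmptyInputError("no defined score records")
    return pd.DataFrame(rows)
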