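"""Image, mask, and manifest I/O plus the raster utilities shared by every
pipeline stage: 12-to-8-bit conversion, block tiling, and train/test splits.

Conventions
-----------
* Label masks are ``uint8`` rasters over ``{0: Outer, 1: Stroma,
  2: Epithelial}`` (bit-exact file contract, PNG or TIFF).
* Images are two-channel (SHG, AF) rasters stored as multi-page 16-bit TIFF
  holding 12-bit data; the 8-bit analysis copies are derived with
  ``floor(v / 16)``.
* Manifests are CSV with one row per image:
  ``image_id, patient_id, lesion, image_path, mask_path, seed[, split]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import EmptyInputError, ShapeMismatchError, InvalidParameterError

# label codes (bit-exact file contract)
OUTER = 0
STROMA = 1
EPITHELIAL = 2
LABELS = (OUTER, STROMA, EPITHELIAL)
LABEL_NAMES = {OUTER: "Outer", STROMA: "Stroma", EPITHELIAL: "Epithelial"}


@dataclass
class MPMImage:
    """Two-channel multiphoton raster.

    Attributes
    ----------
    shg : ndarray
        Second-harmonic-generation channel (collagen), 2-D.
    af : ndarray
        Autofluorescence channel (cellular signal), 2-D, same shape.
    bit_depth : int
        8 or 12; intensities must lie in ``[0, 2**bit_depth - 1]``.
    pixel_size : float
        Lateral pixel size in micrometers.
    """

    shg: np.ndarray
    af: np.ndarray
    bit_depth: int = 12
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.shg = np.asarray(self.shg)
        self.af = np.asarray(self.af)
        if self.shg.shape != self.af.shape:
            raise ShapeMismatchError(
                f"SHG {self.shg.shape} and AF {self.af.shape} shapes differ"
            )
        if self.bit_depth not in (8, 12):
            raise InvalidParameterError(f"bit_depth must be 8 or 12, got {self.bit_depth}")
        top = 2 ** self.bit_depth - 1
        for name, ch in (("shg", self.shg), ("af", self.af)):
            if ch.size and (ch.min() < 0 or ch.max() > top):
                raise InvalidParameterError(
                    f"{name} intensities outside [0, {top}] for bit_depth {self.bit_depth}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.shg.shape

    def channels(self) -> np.ndarray:
        """Stack as (H, W, 2) with channel order (SHG, AF)."""
        return np.stack([self.shg, self.af], axis=-1)


def validate_mask(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size and not np.isin(labels, LABELS).all():
        bad = np.setdiff1d(np.unique(labels), LABELS)
        raise InvalidParameterError(f"mask contains non-label values {bad.tolist()}")
    return labels.astype(np.uint8, copy=False)


def convert_to_8bit(image: MPMImage) -> MPMImage:
    """Map a 12-bit image to 8 bit by ``floor(v / 16)``; identity on 8-bit input."""
    if image.bit_depth == 8:
        return image
    return MPMImage(
        shg=(np.asarray(image.shg, dtype=np.uint16) // 16).astype(np.uint8),
        af=(np.asarray(image.af, dtype=np.uint16) // 16).astype(np.uint8),
        bit_depth=8,
        pixel_size=image.pixel_size,
    )


def tile_image(
    image: MPMImage, mask: np.ndarray, block_px: int = 128
) -> list[tuple[MPMImage, np.ndarray]]:
    """Split an image/mask pair into non-overlapping ``block_px`` square blocks.

    Blocks are returned in row-major order; concatenating them reconstructs
    the original rasters bit-exactly.
    """
    h, w = image.shape
    if mask.shape != (h, w):
        raise ShapeMismatchError(f"mask {mask.shape} does not match image {(h, w)}")
    if h % block_px or w % block_px:
        raise InvalidParameterError(
            f"frame {h}x{w} not divisible by block size {block_px}"
        )
    blocks = []
    for r0 in range(0, h, block_px):
        for c0 in range(0, w, block_px):
            sl = (slice(r0, r0 + block_px), slice(c0, c0 + block_px))
            blocks.append(
                (
                    MPMImage(
                        shg=image.shg[sl],
                        af=image.af[sl],
                        bit_depth=image.bit_depth,
                        pixel_size=image.pixel_size,
                    ),
                    mask[sl],
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# manifests

MANIFEST_COLUMNS = ["image_id", "patient_id", "lesion", "image_path", "mask_path", "seed"]


@dataclass
class DatasetManifest:
    """Bookkeeping for a cohort of images: one row per image, optional
    in-memory store for datasets that were never written to disk.

    ``frame`` columns: image_id, patient_id, lesion (FA|PT), image_path,
    mask_path, seed, and — once :func:`split_dataset` has run — split
    (train|test).
    """

    frame: pd.DataFrame
    root: Path | None = None
    images: dict[str, MPMImage] = field(default_factory=dict, repr=False)
    masks: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise InvalidParameterError(f"manifest missing columns {missing}")
        ids = self.frame["image_id"]
        if ids.duplicated().any():
            raise InvalidParameterError("image_ids are not unique")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_split(self) -> bool:
        return "split" in self.frame.columns and self.frame["split"].notna().all()

    def subset(self, split: str) -> pd.DataFrame:
        if not self.has_split:
            raise InvalidParameterError("manifest has no train/test split yet")
        return self.frame[self.frame["split"] == split]

    def _resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p

    def load_image(self, image_id: str) -> MPMImage:
        if image_id in self.images:
            return self.images[image_id]
        row = self.frame.set_index("image_id").loc[image_id]
        return read_image(self._resolve(row["image_path"]))

    def load_mask(self, image_id: str) -> np.ndarray:
        if image_id in self.masks:
            return self.masks[image_id]
        row = self.frame.set_index("image_id").loc[image_id]
        return read_mask(self._resolve(row["mask_path"]))

    def save_csv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path: str | os.PathLike) -> "DatasetManifest":
        frame = pd.read_csv(path, dtype={"image_id": str, "patient_id": str})
        return cls(frame=frame, root=Path(path).parent)

    def with_frame(self, frame: pd.DataFrame) -> "DatasetManifest":
        return replace(self, frame=frame)


def split_dataset(
    manifest: DatasetManifest, train_fraction: float, rng_seed: int
) -> DatasetManifest:
    """Assign ``floor(train_fraction * N)`` images to the train split uniformly
    at random without replacement; the remainder become the test split.

    Deterministic for a given seed. With the cohort of 76 images this yields
    38 train images at fraction 0.5 and 15 at fraction 0.2.
    """
    n = len(manifest)
    if n == 0:
        raise EmptyInputError("cannot split an empty manifest")
    if not 0.0 < train_fraction < 1.0:
        raise InvalidParameterError("train_fraction must lie strictly in (0, 1)")
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(rng_seed)
    train_idx = rng.choice(n, size=n_train, replace=False)
    split = np.full(n, "test", dtype=object)
    split[train_idx] = "train"
    frame = manifest.frame.copy()
    frame["split"] = split
    return manifest.with_frame(frame)


# ---------------------------------------------------------------------------
# raster file I/O

def write_image(path: str | os.PathLike, image: MPMImage) -> None:
    """Write a two-channel image as a 2-page 16-bit TIFF (SHG first, AF second).

    Bit depth and pixel size travel in the TIFF description tag.
    """
    stack = np.stack(
        [np.asarray(image.shg, dtype=np.uint16), np.asarray(image.af, dtype=np.uint16)]
    )
    tifffile.imwrite(
        path,
        stack,
        description=f"channels=SHG,AF bit_depth={image.bit_depth} pixel_size_um={image.pixel_size}",
    )


def read_image(path: str | os.PathLike) -> MPMImage:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description or ""
    bit_depth, pixel_size = 12, 1.0
    for token in desc.split():
        if token.startswith("bit_depth="):
            bit_depth = int(token.split("=", 1)[1])
        elif token.startswith("pixel_size_um="):
            pixel_size = float(token.split("=", 1)[1])
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise InvalidParameterError(f"expected a 2-page TIFF at {path}, got {stack.shape}")
    return MPMImage(shg=stack[0], af=stack[1], bit_depth=bit_depth, pixel_size=pixel_size)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    iio.imwrite(path, validate_mask(mask))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    return validate_mask(iio.imread(path))
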