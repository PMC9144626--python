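"""SegNet-style encoder--decoder for 3-class pixel-wise segmentation.

The segmenter assigns every pixel of a two-channel (SHG + AF) image to
Epithelial, Stroma, or Outer. The architecture is a reduced SegNet: a
convolutional encoder whose 2x2 max-pool stages record their argmax
indices, and a mirrored decoder that upsamples by *index unpooling* —
scattering values back into the exact positions the encoder pooled from —
so the output resolution equals the input resolution by construction.
Canonical SegNet is VGG16-sized; the default here is a 3-stage reduction
suitable for desk-scale training, with depth and width exposed in
:class:`NetworkConfig`.

Training follows the reported recipe: stochastic gradient descent with
momentum 0.9, initial learning rate 0.01, L2 regularization 5e-4,
mini-batches of 4, and paired random flip/translation augmentation (up to
20 px). The epoch count defaults to the recorded 5000 but is expected to be
overridden for small synthetic tasks.

The public surface is a scikit-learn style estimator
(:class:`SegNetSegmenter`) plus thin :func:`train` / :func:`predict`
wrappers operating on manifests and :class:`~phylloseg.io.MPMImage`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .errors import (
    EmptyInputError,
    InvalidParameterError,
    ShapeMismatchError,
)
from .io import MPMImage, DatasetManifest, OUTER, convert_to_8bit


@dataclass
class NetworkConfig:
    """Architecture knobs. ``encoder_depth`` is the number of pool stages
    (input side must be divisible by ``2**encoder_depth``);
    ``use_pooling_indices`` switches decoder upsampling between SegNet index
    unpooling (True) and nearest-neighbour upsampling (False)."""

    input_channels: int = 2
    n_classes: int = 3
    encoder_depth: int = 3
    base_filters: int = 16
    use_pooling_indices: bool = True


@dataclass
class TrainingConfig:
    """Optimizer and augmentation settings (defaults follow the recorded
    training recipe; override ``epochs`` for desk-scale runs)."""

    momentum: float = 0.9
    learning_rate: float = 0.01
    l2_regularization: float = 0.0005
    epochs: int = 5000
    mini_batch: int = 4
    max_translation_px: int = 20
    flip_augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "epochs", "mini_batch"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.momentum < 0 or self.l2_regularization < 0 or self.max_translation_px < 0:
            raise InvalidParameterError("negative optimizer/augmentation setting")


# ---------------------------------------------------------------------------
# augmentation

def _translate(arr: np.ndarray, dx: int, dy: int, fill) -> np.ndarray:
    """out[r, c] = arr[r - dy, c - dx]; vacated pixels get ``fill``."""
    out = np.full_like(arr, fill)
    h, w = arr.shape[:2]
    height = max(0, h - abs(dy))
    width = max(0, w - abs(dx))
    if height and width:
        sr, sc = max(0, -dy), max(0, -dx)
        dr, dc = max(0, dy), max(0, dx)
        out[dr : dr + height, dc : dc + width] = arr[sr : sr + height, sc : sc + width]
    return out


def _augment_arrays(
    img: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    max_translation: int,
    flip: bool,
) -> tuple[np.ndarray, np.ndarray]:
    if flip:
        if rng.random() < 0.5:
            img, mask = img[:, ::-1], mask[:, ::-1]
        if rng.random() < 0.5:
            img, mask = img[::-1], mask[::-1]
    if max_translation > 0:
        dx, dy = rng.integers(-max_translation, max_translation + 1, size=2)
        if dx or dy:
            img = _translate(img, int(dx), int(dy), 0)
            mask = _translate(mask, int(dx), int(dy), OUTER)
    return np.ascontiguousarray(img), np.ascontiguousarray(mask)


def augment_pair(
    image: MPMImage,
    mask: np.ndarray,
    cfg: TrainingConfig,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[MPMImage, np.ndarray]:
    """Apply one identical random flip + translation (<= ``max_translation_px``)
    to an image/mask pair. Vacated pixels are filled with intensity 0 and the
    Outer label."""
    if image.shape != mask.shape:
        raise ShapeMismatchError(f"image {image.shape} vs mask {mask.shape}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    stacked = image.channels()
    out_img, out_mask = _augment_arrays(
        stacked, mask, rng, cfg.max_translation_px, cfg.flip_augment
    )
    return (
        MPMImage(
            shg=out_img[..., 0],
            af=out_img[..., 1],
            bit_depth=image.bit_depth,
            pixel_size=image.pixel_size,
        ),
        out_mask,
    )


# ---------------------------------------------------------------------------
# network

class _EncoderDecoder:
    """Encoder--decoder graph with optional index unpooling."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        f = [cfg.base_filters * 2 ** i for i in range(cfg.encoder_depth)]
        self.enc_convs, self.enc_relus = [], []
        c_prev = cfg.input_channels
        for fi in f:
            self.enc_convs.append(_nn.Conv3x3(c_prev, fi, rng))
            self.enc_relus.append(_nn.ReLU())
            c_prev = fi
        self.dec_convs, self.dec_relus = [], []
        for i in reversed(range(cfg.encoder_depth)):
            c_out = cfg.n_classes if i == 0 else f[i - 1]
            self.dec_convs.append(_nn.Conv3x3(f[i], c_out, rng))
            self.dec_relus.append(_nn.ReLU() if i != 0 else None)

    @property
    def convs(self):
        return self.enc_convs + self.dec_convs

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._pool_idx, self._pool_shapes = [], []
        for conv, relu in zip(self.enc_convs, self.enc_relus):
            x = relu.forward(conv.forward(x, train), train)
            self._pool_shapes.append(x.shape)
            x, idx = _nn.maxpool2(x)
            self._pool_idx.append(idx)
        for stage, (conv, relu) in enumerate(zip(self.dec_convs, self.dec_relus)):
            level = self.cfg.encoder_depth - 1 - stage
            if self.cfg.use_pooling_indices:
                x = _nn.unpool2(x, self._pool_idx[level], self._pool_shapes[level])
            else:
                x = x.repeat(2, axis=1).repeat(2, axis=2)
            x = conv.forward(x, train)
            if relu is not None:
                x = relu.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for stage in reversed(range(len(self.dec_convs))):
            conv, relu = self.dec_convs[stage], self.dec_relus[stage]
            level = self.cfg.encoder_depth - 1 - stage
            if relu is not None:
                dout = relu.backward(dout)
            dout = conv.backward(dout)
            if self.cfg.use_pooling_indices:
                dout = _nn.unpool2_grad(dout, self._pool_idx[level])
            else:
                n, h, w, c = dout.shape
                dout = dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))
        for conv, relu, idx, shape in zip(
            reversed(self.enc_convs),
            reversed(self.enc_relus),
            reversed(self._pool_idx),
            reversed(self._pool_shapes),
        ):
            dout = _nn.unpool2(dout, idx, shape)
            dout = relu.backward(dout)
            dout = conv.backward(dout)


class SegNetSegmenter(BaseEstimator):
    """Pixel-wise 3-class segmenter with a scikit-learn estimator interface.

    ``fit`` expects ``X`` of shape (n_images, H, W, 2) — 8-bit (SHG, AF)
    intensities — and ``y`` of shape (n_images, H, W) with labels
    {0, 1, 2}. Channel normalization constants are computed from the
    training data and stored on the fitted estimator.

    Fitted attributes: ``net_`` (weights), ``history_`` (per-epoch loss and
    batch accuracy), ``norm_mean_`` / ``norm_std_`` (per-channel), and
    ``classes_``.
    """

    def __init__(
        self,
        encoder_depth: int = 3,
        base_filters: int = 16,
        use_pooling_indices: bool = True,
        input_channels: int = 2,
        n_classes: int = 3,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        l2_regularization: float = 0.0005,
        epochs: int = 5000,
        mini_batch: int = 4,
        max_translation_px: int = 20,
        flip_augment: bool = True,
        seed: int = 0,
    ):
        self.encoder_depth = encoder_depth
        self.base_filters = base_filters
        self.use_pooling_indices = use_pooling_indices
        self.input_channels = input_channels
        self.n_classes = n_classes
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.l2_regularization = l2_regularization
        self.epochs = epochs
        self.mini_batch = mini_batch
        self.max_translation_px = max_translation_px
        self.flip_augment = flip_augment
        self.seed = seed

    # -- helpers ----------------------------------------------------------
    def _check_geometry(self, h: int, w: int) -> None:
        d = 2 ** self.encoder_depth
        if h % d or w % d:
            raise InvalidParameterError(
                f"frame {h}x{w} not divisible by 2**encoder_depth = {d}"
            )

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.norm_mean_) / self.norm_std_).astype(np.float32)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[-1] != self.input_channels:
            raise InvalidParameterError(
                f"X must be (n, H, W, {self.input_channels}), got {X.shape}"
            )
        if y.shape != X.shape[:3]:
            raise ShapeMismatchError(f"y {y.shape} does not match X {X.shape[:3]}")
        n = X.shape[0]
        if n == 0:
            raise EmptyInputError("empty training set")
        if self.mini_batch > n:
            raise InvalidParameterError(
                f"mini_batch {self.mini_batch} exceeds training-set size {n}"
            )
        self._check_geometry(X.shape[1], X.shape[2])

        self.norm_mean_ = X.mean(axis=(0, 1, 2), dtype=np.float64).astype(np.float32)
        self.norm_std_ = np.maximum(
            X.std(axis=(0, 1, 2), dtype=np.float64), 1e-6
        ).astype(np.float32)
        Xn = self._normalize(X)
        y = y.astype(np.uint8)

        rng = np.random.default_rng(self.seed)
        self.net_ = _EncoderDecoder(
            NetworkConfig(
                input_channels=self.input_channels,
                n_classes=self.n_classes,
                encoder_depth=self.encoder_depth,
                base_filters=self.base_filters,
                use_pooling_indices=self.use_pooling_indices,
            ),
            rng,
        )
        opt = _nn.SGDMomentum(
            self.net_.convs, self.learning_rate, self.momentum, self.l2_regularization
        )
        history = {"epoch": [], "loss": [], "batch_accuracy": []}
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            ep_loss, ep_acc, n_batches = 0.0, 0.0, 0
            for b0 in range(0, n - self.mini_batch + 1, self.mini_batch):
                idx = order[b0 : b0 + self.mini_batch]
                imgs, labs = [], []
                for i in idx:
                    im, lab = _augment_arrays(
                        Xn[i], y[i], rng, self.max_translation_px, self.flip_augment
                    )
                    imgs.append(im)
                    labs.append(lab)
                xb = np.stack(imgs)
                yb = np.stack(labs)
                logits = self.net_.forward(xb, train=True)
                loss, dlogits = _nn.softmax_cross_entropy(logits, yb)
                self.net_.backward(dlogits)
                opt.step()
                ep_loss += loss
                ep_acc += float((logits.argmax(-1) == yb).mean())
                n_batches += 1
            history["epoch"].append(epoch)
            history["loss"].append(ep_loss / max(n_batches, 1))
            history["batch_accuracy"].append(ep_acc / max(n_batches, 1))
        self.history_ = history
        self.classes_ = np.arange(self.n_classes)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class probabilities, shape (n, H, W, n_classes)."""
        if not hasattr(self, "net_"):
            raise InvalidParameterError("estimator is not fitted")
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 3
        if single:
            X = X[None]
        if X.shape[-1] != self.input_channels:
            raise ShapeMismatchError(f"expected {self.input_channels} channels, got {X.shape[-1]}")
        self._check_geometry(X.shape[1], X.shape[2])
        Xn = self._normalize(X)
        out = []
        for b0 in range(0, X.shape[0], 4):
            logits = self.net_.forward(Xn[b0 : b0 + 4], train=False)
            out.append(_nn.softmax(logits))
        proba = np.concatenate(out)
        return proba[0] if single else proba

    def predict(self, X) -> np.ndarray:
        """Argmax label mask(s), shape (n, H, W) (or (H, W) for one image)."""
        return self.predict_proba(X).argmax(axis=-1).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean pixel accuracy."""
        return float((self.predict(X) == np.asarray(y)).mean())

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        if not hasattr(self, "net_"):
            raise InvalidParameterError("cannot save an unfitted estimator")
        arrays = {"norm_mean": self.norm_mean_, "norm_std": self.norm_std_}
        for i, conv in enumerate(self.net_.convs):
            arrays[f"w{i}"] = conv.w
            arrays[f"b{i}"] = conv.b
        meta = {
            "params": self.get_params(),
            "history": self.history_,
            "n_convs": len(self.net_.convs),
        }
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegNetSegmenter":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            est = cls(**meta["params"])
            est.norm_mean_ = f["norm_mean"]
            est.norm_std_ = f["norm_std"]
            est.net_ = _EncoderDecoder(
                NetworkConfig(
                    input_channels=est.input_channels,
                    n_classes=est.n_classes,
                    encoder_depth=est.encoder_depth,
                    base_filters=est.base_filters,
                    use_pooling_indices=est.use_pooling_indices,
                ),
                np.random.default_rng(0),
            )
            for i, conv in enumerate(est.net_.convs):
                conv.w = f[f"w{i}"]
                conv.b = f[f"b{i}"]
            est.history_ = meta["history"]
            est.classes_ = np.arange(est.n_classes)
        return est


# ---------------------------------------------------------------------------
# manifest-level wrappers

def _load_split_arrays(
    manifest: DatasetManifest, split: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    rows = manifest.subset(split)
    if rows.empty:
        raise EmptyInputError(f"no images in split '{split}'")
    X, y, ids = [], [], []
    for _, row in rows.iterrows():
        img = convert_to_8bit(manifest.load_image(row["image_id"]))
        X.append(img.channels().astype(np.float32))
        y.append(manifest.load_mask(row["image_id"]))
        ids.append(row["image_id"])
    return np.stack(X), np.stack(y), ids


def train(
    manifest: DatasetManifest,
    net: NetworkConfig | None = None,
    cfg: TrainingConfig | None = None,
) -> SegNetSegmenter:
    """Train the segmenter on the manifest's train split (images are
    converted to 8 bit first). Returns the fitted estimator; its
    ``history_`` carries per-epoch loss."""
    net = net or NetworkConfig()
    cfg = cfg or TrainingConfig()
    X, y, _ = _load_split_arrays(manifest, "train")
    est = SegNetSegmenter(
        encoder_depth=net.encoder_depth,
        base_filters=net.base_filters,
        use_pooling_indices=net.use_pooling_indices,
        input_channels=net.input_channels,
        n_classes=net.n_classes,
        learning_rate=cfg.learning_rate,
        momentum=cfg.momentum,
        l2_regularization=cfg.l2_regularization,
        epochs=cfg.epochs,
        mini_batch=min(cfg.mini_batch, X.shape[0]),
        max_translation_px=cfg.max_translation_px,
        flip_augment=cfg.flip_augment,
        seed=cfg.seed,
    )
    return est.fit(X, y)


def predict(model: SegNetSegmenter, image: MPMImage) -> np.ndarray:
    """Segment one image (any bit depth; converted to 8 bit internally)."""
    img8 = convert_to_8bit(image)
    return model.predict(img8.channels().astype(np.float32))
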