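"""Binary kernel-crop classification: damaged vs undamaged, paddy vs milled.

Damaged kernels are partially or fully darkened (insect, mold, water or
heat damage); paddy kernels are still enclosed in their hull. Each trait is
a separately trained binary classifier over fixed-size RGB crops of single
kernels.

Three interchangeable backbones sit behind one train/evaluate/predict
contract:

``vgg19_transfer``
    The VGG19 convolutional architecture (sixteen 3x3 stride-1 conv layers
    in five blocks, 2x2 stride-2 max-pools, channel widths
    64-64-128-128-256x4-512x8), run as a FROZEN feature extractor with
    seeded He-initialised random filters, global-average-pooled into a
    feature vector feeding a trainable logistic head. This exercises the
    transfer-learning structure (frozen stack + trained binary head, fixed
    input size) at desk scale; no pretrained weights are shipped.
``small_cnn``
    Three frozen random conv blocks (3x3 conv, ReLU, 2x2 max-pool; 8-16-32
    channels) + global average/std pooling + logistic head. The default.
``hsv_texture_features``
    Per-channel HSV mean/std plus an edge-energy texture statistic, with a
    logistic separator. Dependency-light fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize as sk_resize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .colorimetry import rgb_to_hsv179
from .errors import InvalidInputError, NotFittedError
from .segmentation import GrainScene, KernelContour

DEFAULT_CROP_SIZE = 224
BACKBONES = ("vgg19_transfer", "small_cnn", "hsv_texture_features")

# VGG19 convolutional plan: channel width per conv layer, "M" = 2x2 max-pool
VGG19_PLAN = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M",
              512, 512, 512, 512, "M", 512, 512, 512, 512, "M"]
N_VGG19_CONV_LAYERS = sum(1 for v in VGG19_PLAN if v != "M")


@dataclass
class KernelCrop:
    """A square RGB crop of one kernel, optionally labelled.

    ``label`` is 1 for the positive class of the task (damaged / paddy),
    0 for the negative class, or None for unlabelled crops.
    """

    image: np.ndarray  # (size, size, 3) uint8
    label: Optional[int] = None
    origin: str = ""

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] != img.shape[1]:
            raise InvalidInputError(
                f"crop must be square with 3 channels, got shape {img.shape}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise InvalidInputError(f"label must be 0, 1 or None, got {self.label}")
        self.image = img


@dataclass(frozen=True)
class ClassifierSpec:
    """Backbone choice and training hyperparameters."""

    backbone: str = "small_cnn"
    frozen_layers: int = N_VGG19_CONV_LAYERS  # vgg19_transfer only
    epochs: int = 100  # iteration budget of the head optimiser
    batch_size: int = 32
    seed: int = 0
    input_size: int = DEFAULT_CROP_SIZE

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise InvalidInputError(
                f"backbone must be one of {BACKBONES}, got {self.backbone!r}"
            )
        if self.backbone == "vgg19_transfer" and not (
            1 <= self.frozen_layers <= N_VGG19_CONV_LAYERS
        ):
            raise InvalidInputError(
                f"frozen_layers must be in [1, {N_VGG19_CONV_LAYERS}]"
            )
        if self.epochs < 1 or self.batch_size < 1 or self.input_size < 8:
            raise InvalidInputError("epochs, batch_size >= 1 and input_size >= 8 required")


@dataclass(frozen=True)
class EvalResult:
    """2x2 confusion counts (positive class = damaged / paddy) + accuracy %."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def confusion(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


def prepare_crop(
    scene: GrainScene,
    contour: KernelContour,
    size: int = DEFAULT_CROP_SIZE,
    pad_fraction: float = 0.10,
) -> KernelCrop:
    """Crop one kernel's padded bounding box and resize to size x size.

    The box is padded by ``pad_fraction`` per side, padded to square with
    the scene's median background color (out-of-image regions likewise), and
    resized. Kernels at the image border are handled by background fill.
    """
    img = np.asarray(scene.image)[..., :3]
    h, w = img.shape[:2]
    pts = np.asarray(contour.points)
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if x1 < 0 or y1 < 0 or x0 > w - 1 or y0 > h - 1:
        raise InvalidInputError("contour lies outside the image bounds")
    pad_x = (x1 - x0) * pad_fraction
    pad_y = (y1 - y0) * pad_fraction
    x0, x1 = x0 - pad_x, x1 + pad_x
    y0, y1 = y0 - pad_y, y1 + pad_y
    # square box around the padded rectangle
    side = max(x1 - x0, y1 - y0)
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    x0, x1 = int(np.floor(cx - side / 2)), int(np.ceil(cx + side / 2))
    y0, y1 = int(np.floor(cy - side / 2)), int(np.ceil(cy + side / 2))
    background = np.median(img.reshape(-1, 3), axis=0).astype(np.uint8)
    out = np.tile(background, ((y1 - y0), (x1 - x0), 1))
    sx0, sx1 = max(x0, 0), min(x1, w)
    sy0, sy1 = max(y0, 0), min(y1, h)
    out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
    resized = sk_resize(out, (size, size), order=1, anti_aliasing=True, preserve_range=True)
    return KernelCrop(
        image=np.clip(resized, 0, 255).astype(np.uint8),
        origin=f"{scene.source_path}#({cx:.0f},{cy:.0f})",
    )


# ---------------------------------------------------------------------------
# feature extraction backbones
# ---------------------------------------------------------------------------

def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution; x (H,W,Cin), w (3,3,Cin,Cout)."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(0, 1))
    # win: (H, W, Cin, 3, 3)
    return np.einsum("hwcij,ijco->hwo", win, w, optimize=True) + b


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return x.reshape(h // 2, 2, w // 2, 2, -1).max(axis=(1, 3))


def _he_filters(rng: np.random.Generator, c_in: int, c_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (9 * c_in))
    return rng.normal(0.0, std, size=(3, 3, c_in, c_out))


class _ConvStack:
    """Frozen random-filter conv stack shared by small_cnn / vgg19_transfer."""

    def __init__(self, plan: Sequence, seed: int, n_layers: Optional[int] = None):
        rng = np.random.default_rng(seed)
        self.ops: List[Tuple[str, Optional[np.ndarray]]] = []
        c_in = 3
        conv_count = 0
        for item in plan:
            if item == "M":
                self.ops.append(("pool", None))
                continue
            if n_layers is not None and conv_count >= n_layers:
                break
            w = _he_filters(rng, c_in, int(item))
            self.ops.append(("conv", w))
            c_in = int(item)
            conv_count += 1

    def features(self, image: np.ndarray) -> np.ndarray:
        x = image.astype(np.float64) / 255.0
        for kind, w in self.ops:
            if kind == "pool":
                if min(x.shape[:2]) >= 2:
                    x = _maxpool2(x)
            else:
                x = np.maximum(_conv3x3(x, w, np.zeros(w.shape[-1])), 0.0)
        # global average + std pooling over the spatial grid
        return np.concatenate([x.mean(axis=(0, 1)), x.std(axis=(0, 1))])


SMALL_CNN_PLAN = [8, "M", 16, "M", 32, "M"]


def _hsv_texture_features(image: np.ndarray) -> np.ndarray:
    hsv = rgb_to_hsv179(image)
    gray = np.asarray(image)[..., :3].astype(float).mean(axis=2)
    grad = ndi.sobel(gray, axis=0) ** 2 + ndi.sobel(gray, axis=1) ** 2
    feats = [hsv[..., i].mean() for i in range(3)]
    feats += [hsv[..., i].std() for i in range(3)]
    feats.append(np.sqrt(grad).mean())  # edge energy: hull texture marker
    return np.asarray(feats)


class KernelClassifier:
    """One binary trait classifier: frozen featuriser + trained logistic head."""

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self._head: Optional[LogisticRegression] = None
        if spec.backbone == "vgg19_transfer":
            self._stack = _ConvStack(VGG19_PLAN, spec.seed, n_layers=spec.frozen_layers)
        elif spec.backbone == "small_cnn":
            self._stack = _ConvStack(SMALL_CNN_PLAN, spec.seed)
        else:
            self._stack = None

    @property
    def fitted(self) -> bool:
        return self._head is not None

    def featurize(self, crops: Sequence[KernelCrop]) -> np.ndarray:
        if self._stack is not None:
            return np.stack([self._stack.features(c.image) for c in crops])
        return np.stack([_hsv_texture_features(c.image) for c in crops])

    def fit_head(self, X: np.ndarray, y: np.ndarray) -> None:
        # pooled features span orders of magnitude; standardise before the
        # logistic separator so regularisation treats channels evenly
        head = make_pipeline(
            StandardScaler(),
            LogisticRegression(
                max_iter=max(1000, self.spec.epochs * 10), random_state=self.spec.seed
            ),
        )
        head.fit(X, y)
        self._head = head

    def predict(self, crops: Sequence[KernelCrop]) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("classifier head is not trained")
        return self._head.predict(self.featurize(crops)).astype(int)

    def save(self, path: Union[str, Path]) -> None:
        joblib.dump({"spec": self.spec, "head": self._head}, path)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "KernelClassifier":
        d = joblib.load(path)
        clf = cls(d["spec"])
        clf._head = d["head"]
        return clf


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> EvalResult:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn)


def train_classifier(
    crops: Sequence[KernelCrop],
    spec: ClassifierSpec,
    train_fraction: float = 0.8,
    seed: Optional[int] = None,
) -> Tuple[KernelClassifier, EvalResult]:
    """Train a binary trait classifier with a shuffled holdout evaluation.

    Requires >= 20 labelled crops with both classes present. Returns the
    fitted classifier and the held-out ``EvalResult``.
    """
    seed = spec.seed if seed is None else seed
    labelled = [c for c in crops if c.label is not None]
    if len(labelled) < 20:
        raise InvalidInputError(f"need >= 20 labelled crops, got {len(labelled)}")
    y = np.array([c.label for c in labelled])
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present in the training crops")
    if not (0.0 < train_fraction < 1.0):
        raise InvalidInputError(f"train_fraction must be in (0, 1), got {train_fraction}")
    clf = KernelClassifier(spec)
    X = clf.featurize(labelled)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed, shuffle=True, stratify=y
    )
    clf.fit_head(X_tr, y_tr)
    y_pred = clf._head.predict(X_te).astype(int)
    return clf, _confusion(y_te, y_pred)


def evaluate(classifier: KernelClassifier, crops: Sequence[KernelCrop]) -> EvalResult:
    """Confusion counts and accuracy of a fitted classifier on labelled crops."""
    if not classifier.fitted:
        raise NotFittedError("classifier head is not trained")
    labelled = [c for c in crops if c.label is not None]
    if not labelled:
        raise InvalidInputError("no labelled crops to evaluate")
    y_true = np.array([c.label for c in labelled])
    y_pred = classifier.predict(labelled)
    return _confusion(y_true, y_pred)
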