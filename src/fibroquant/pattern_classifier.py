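"""Trainable per-pixel tissue classifier (pattern-recognition route).

The proprietary pattern-recognition engine used on the original slides is
treated as a black box defined by its training I/O: the user marks regions of
myocardium, fibrosis and glass, the engine learns a per-pixel rule, and the
fibrosis percentage is taken over tissue, ignoring glass.  This module keeps
that contract with a standard supervised learner: each pixel is described by
nine features — its three optical densities plus the local mean and local
standard deviation of each OD channel over a square window ("spatial
recognition" only; no object-level morphology) — and classified by a
multinomial logistic model fitted with SGD.  The ``iteration_budget`` maps to
the learner's epoch count.

Class imbalance in the marked regions is handled by inverse-frequency class
weights (switchable off), so a small fibrosis region is not swamped by a large
myocardium one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from sklearn.linear_model import SGDClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .stain_deconvolution import NoTissueError, rgb_to_od
from .synthetic_histology import ParameterError, RgbTile, TissueClass

MODEL_FORMAT_VERSION = 1

#: The three classes this route distinguishes, in canonical order.
CLASSIFIER_CLASSES = (TissueClass.MYOCARDIUM, TissueClass.FIBROSIS, TissueClass.GLASS)


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingRegion:
    """One user-marked region: a tile, a boolean mask within it, a class."""

    tile: RgbTile
    mask: np.ndarray  # boolean, same H x W as tile
    tissue_class: TissueClass

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != self.tile.shape:
            raise ValidationError("region mask must match its tile's shape")
        if not m.any():
            raise ValidationError("region mask is empty")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class TrainingReport:
    training_accuracy: float
    n_iterations: int
    confusion: np.ndarray  # rows: true class (canonical order), cols: predicted
    class_order: tuple[TissueClass, ...] = CLASSIFIER_CLASSES


@dataclass
class PixelClassifierModel:
    pipeline: Pipeline
    window: int
    background_intensity: np.ndarray
    class_order: tuple[TissueClass, ...]
    format_version: int = MODEL_FORMAT_VERSION


@dataclass(frozen=True)
class ClassMap:
    labels: np.ndarray  # uint8 TissueClass codes over the tile

    @property
    def fibrosis_pct_of_tissue(self) -> float:
        return tissue_fibrosis_pct(self)


def extract_features(tile: RgbTile, window: int = 7, background_intensity=(252.0, 252.0, 252.0)) -> np.ndarray:
    """Per-pixel feature stack: OD triple + local mean and SD per OD channel.

    The window is a square of odd side ``window``; edges are reflect-padded;
    ``window=1`` degenerates to mean = raw OD and SD = 0.  Local SD is the
    population SD of the window (computed as sqrt(E[x^2] - E[x]^2), clipped at
    zero against rounding).
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be an odd positive integer")
    od = rgb_to_od(tile, background_intensity)
    feats = np.empty(od.shape[:2] + (9,), dtype=float)
    feats[..., 0:3] = od
    for c in range(3):
        ch = od[..., c]
        mu = float(ch.mean())  # center first: keeps the variance numerically clean
        d = ch - mu
        mean_d = ndimage.uniform_filter(d, size=window, mode="reflect")
        mean_d2 = ndimage.uniform_filter(d * d, size=window, mode="reflect")
        feats[..., 3 + c] = mean_d + mu
        feats[..., 6 + c] = np.sqrt(np.clip(mean_d2 - mean_d * mean_d, 0.0, None))
    return feats


def _gather_training_pixels(
    regions: list[TrainingRegion], window: int, background_intensity
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for region in regions:
        feats = extract_features(region.tile, window, background_intensity)
        xs.append(feats[region.mask])
        ys.append(np.full(int(region.mask.sum()), int(region.tissue_class), dtype=np.uint8))
    return np.concatenate(xs), np.concatenate(ys)


def train_classifier(
    regions: list[TrainingRegion],
    iteration_budget: int = 1000,
    seed: int = 0,
    window: int = 7,
    background_intensity=(252.0, 252.0, 252.0),
    balance_classes: bool = True,
) -> tuple[PixelClassifierModel, TrainingReport]:
    """Fit the per-pixel classifier on marked regions and report accuracy.

    Requires at least two classes with >= 50 labeled pixels each.  The
    training accuracy is measured the way the original workflow reported it:
    by reclassifying the training pixels with the fitted model.  Deterministic
    for a fixed seed and region order.
    """
    if not regions:
        raise ValidationError("training set is empty")
    x, y = _gather_training_pixels(regions, window, background_intensity)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("training set must cover at least two classes")
    small = counts < 50
    if small.any():
        name = TissueClass(int(classes[small][0])).name
        raise ValidationError(f"class {name} has fewer than 50 labeled pixels")
    clf = SGDClassifier(
        loss="log_loss",
        max_iter=iteration_budget,
        tol=1e-4,
        random_state=seed,
        class_weight="balanced" if balance_classes else None,
    )
    pipeline = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    pipeline.fit(x, y)
    pred = pipeline.predict(x)
    order = [int(c) for c in CLASSIFIER_CLASSES if int(c) in classes]
    k = len(order)
    confusion = np.zeros((k, k), dtype=int)
    index = {c: i for i, c in enumerate(order)}
    for t, p in zip(y, pred):
        confusion[index[int(t)], index[int(p)]] += 1
    model = PixelClassifierModel(
        pipeline=pipeline,
        window=window,
        background_intensity=np.asarray(background_intensity, dtype=float),
        class_order=tuple(TissueClass(c) for c in order),
    )
    report = TrainingReport(
        training_accuracy=float(np.mean(pred == y)),
        n_iterations=iteration_budget,
        confusion=confusion,
        class_order=model.class_order,
    )
    return model, report


def classify_tile(tile: RgbTile, model: PixelClassifierModel, window: int | None = None) -> ClassMap:
    """Classify every pixel of a tile with a trained model."""
    w = model.window if window is None else window
    if w != model.window:
        raise ParameterError(
            f"model was trained with window={model.window}, got window={w}"
        )
    feats = extract_features(tile, w, model.background_intensity)
    pred = model.pipeline.predict(feats.reshape(-1, 9))
    return ClassMap(pred.reshape(tile.shape).astype(np.uint8))


def tissue_fibrosis_pct(class_map: ClassMap) -> float:
    """Fibrosis percent of tissue: 100 * fibrosis / (fibrosis + myocardium)."""
    labels = class_map.labels
    n_fib = int(np.count_nonzero(labels == TissueClass.FIBROSIS))
    n_myo = int(np.count_nonzero(labels == TissueClass.MYOCARDIUM))
    if n_fib + n_myo == 0:
        raise NoTissueError("classified tile contains no tissue pixels")
    return 100.0 * n_fib / (n_fib + n_myo)


#: Class colors for the classifier markup image.
CLASS_PALETTE = {
    TissueClass.GLASS: (255, 255, 255),
    TissueClass.MYOCARDIUM: (205, 92, 92),
    TissueClass.FIBROSIS: (65, 105, 225),
    TissueClass.OTHER: (190, 190, 120),
}


def render_class_markup(class_map: ClassMap) -> RgbTile:
    lut = np.zeros((4, 3), dtype=np.uint8)
    for c, color in CLASS_PALETTE.items():
        lut[c] = color
    return RgbTile(lut[class_map.labels], provenance="class-markup")


def save_model(model: PixelClassifierModel, path: str | Path) -> None:
    """Persist the model as a single portable file with a version header."""
    payload = {
        "format_version": model.format_version,
        "window": model.window,
        "background_intensity": model.background_intensity.tolist(),
        "class_order": [int(c) for c in model.class_order],
        "pipeline": model.pipeline,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> PixelClassifierModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported model format version: {version!r}")
    return PixelClassifierModel(
        pipeline=payload["pipeline"],
        window=int(payload["window"]),
        background_intensity=np.asarray(payload["background_intensity"], dtype=float),
        class_order=tuple(TissueClass(c) for c in payload["class_order"]),
        format_version=version,
    )


def regions_from_phantom(
    phantom, tile: RgbTile, max_pixels_per_class: int = 4000, seed: int = 0
) -> list[TrainingRegion]:
    """Build training regions by subsampling a phantom's label map.

    Stand-in for hand-marked regions on desk-scale synthetic slides: up to
    ``max_pixels_per_class`` pixels per class (seeded subsample) for
    myocardium, fibrosis and glass; OTHER pixels are never marked, mirroring
    a trainer who only outlines unambiguous examples of the three classes.
    """
    rng = np.random.default_rng(seed)
    regions = []
    for c in CLASSIFIER_CLASSES:
        idx = np.flatnonzero(phantom.label_map == c)
        if idx.size == 0:
            continue
        if idx.size > max_pixels_per_class:
            idx = rng.choice(idx, size=max_pixels_per_class, replace=False)
        mask = np.zeros(phantom.label_map.shape, dtype=bool)
        mask.ravel()[idx] = True
        regions.append(TrainingRegion(tile, mask, c))
    return regions
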