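"""Root segmentation: background subtraction, thresholding, and a
trainable random-forest pixel classifier.

Two routes from a raw image to a binary :class:`RootMask`:

* **Otsu route** — grayscale morphological opening estimates the smooth
  background; subtracting it leaves the thin bright root strokes, which a
  global Otsu threshold then binarizes. No training required.
* **Model route** — a :class:`RootPixelClassifier` (a scikit-learn style
  estimator wrapping a random forest) is trained on a library of
  image/mask pairs — in practice the synthetic root library — using a
  small per-pixel feature stack (intensity, Gaussian smoothing, gradient
  magnitude, Hessian ridge response, local variance at several scales).

Root polarity (bright roots on dark background or the reverse) is
auto-detected and normalized so the rest of the pipeline can assume
bright-on-dark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from rootscape.errors import ParameterError, TrainingError, ValidationError
from rootscape.image_io import RasterImage

logger = logging.getLogger(__name__)

#: Format tag embedded in serialized models; predict refuses a mismatch.
MODEL_FORMAT_VERSION = "rootscape-segmenter-1"

DEFAULT_SCALES = (1.0, 2.0, 4.0)


@dataclass(frozen=True)
class RootMask:
    """Binary foreground map; the substrate for all descriptors."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValidationError("mask must be 2D")
        object.__setattr__(self, "values", vals.astype(bool))

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def area(self) -> int:
        """Foreground pixel count (the `area` macrophenotype)."""
        return int(self.values.sum())

    def is_empty(self) -> bool:
        return not self.values.any()


def as_mask_array(mask) -> np.ndarray:
    """Coerce a RootMask or array-like to a 2D boolean array."""
    if isinstance(mask, RootMask):
        return mask.values
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError("mask must be 2D")
    return arr.astype(bool)


def _as_image_array(img) -> np.ndarray:
    if isinstance(img, RasterImage):
        return img.values
    return np.asarray(img, dtype=float)


def normalize_polarity(img) -> np.ndarray:
    """Return intensities flipped, if needed, so roots are the bright minority.

    Roots occupy a small fraction of the frame, so the Otsu majority class
    is background: if the majority lies above the threshold the background
    is bright and the image is inverted.
    """
    vals = _as_image_array(img)
    if np.ptp(vals) < 1e-9:
        return vals
    t = threshold_otsu(vals)
    if np.mean(vals > t) > 0.5:
        return 1.0 - vals
    return vals


def subtract_background(img, radius: int = 15) -> RasterImage:
    """Remove smooth background by grayscale opening with a disc.

    Polarity is normalized first (roots bright), the background is the
    morphological opening with a disc of ``radius`` pixels, and the result
    is ``clip(img - background, 0, 1)``. Structures wider than the disc
    survive in the background and are suppressed; thin root strokes remain.
    """
    if radius < 1:
        raise ParameterError(f"radius must be >= 1, got {radius}")
    vals = normalize_polarity(img)
    background = morphology.opening(vals, morphology.disk(int(radius)))
    return RasterImage(values=np.clip(vals - background, 0.0, 1.0))


@dataclass(frozen=True)
class PixelFeatureStack:
    """Per-pixel feature planes for the pixel classifier.

    ``planes`` has shape (n_features, H, W): the raw intensity plane plus,
    per scale σ, Gaussian-smoothed intensity, gradient magnitude, the
    smaller Hessian eigenvalue (a ridge detector — strongly negative on
    thin bright curvilinear structures), and local variance.
    """

    planes: np.ndarray
    scales: tuple[float, ...]
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.planes.shape[0] != 1 + 4 * len(self.scales):
            raise ValidationError("plane count must be 1 + 4 x number_of_scales")

    def as_samples(self) -> np.ndarray:
        """Flatten to an (n_pixels, n_features) design matrix."""
        n = self.planes.shape[0]
        return self.planes.reshape(n, -1).T


def compute_pixel_features(img, scales: Sequence[float] = DEFAULT_SCALES) -> PixelFeatureStack:
    """Compute the per-pixel feature stack at the given Gaussian scales."""
    scales = tuple(float(s) for s in scales)
    if len(scales) == 0:
        raise ParameterError("at least one scale is required")
    if any(s <= 0 for s in scales):
        raise ParameterError(f"scales must be positive, got {scales}")
    vals = _as_image_array(img)
    planes = [vals]
    names = ["intensity"]
    for s in scales:
        smooth = ndi.gaussian_filter(vals, sigma=s)
        grad = ndi.gaussian_gradient_magnitude(vals, sigma=s)
        H = hessian_matrix(vals, sigma=s, order="rc", mode="reflect",
                           use_gaussian_derivatives=True)
        ridge = hessian_matrix_eigvals(H)[-1]  # smaller eigenvalue
        var = np.clip(ndi.gaussian_filter(vals**2, sigma=s) - smooth**2, 0.0, None)
        planes += [smooth, grad, ridge, var]
        names += [f"gauss_s{s:g}", f"grad_s{s:g}", f"ridge_s{s:g}", f"var_s{s:g}"]
    return PixelFeatureStack(
        planes=np.stack(planes), scales=scales, names=tuple(names)
    )


class RootPixelClassifier(BaseEstimator):
    """Random-forest pixel classifier for root segmentation.

    A scikit-learn style estimator: ``fit`` consumes a library of
    (image, mask) pairs, subsampling a balanced set of foreground and
    background pixels per image; ``predict_mask`` returns a RootMask for
    a new image. Deterministic given ``random_state``.

    Parameters
    ----------
    scales : sequence of float
        Gaussian scales (px) of the feature stack; stored with the model
        and re-validated at predict time.
    n_estimators : int
        Trees in the forest.
    max_samples_per_image : int
        Pixel budget per class per training image.
    random_state : int
        Seed for subsampling and forest construction.
    """

    def __init__(
        self,
        scales: Sequence[float] = DEFAULT_SCALES,
        n_estimators: int = 100,
        max_samples_per_image: int = 5000,
        random_state: int = 0,
    ):
        self.scales = tuple(float(s) for s in scales)
        self.n_estimators = n_estimators
        self.max_samples_per_image = max_samples_per_image
        self.random_state = random_state

    @property
    def n_feature_planes(self) -> int:
        return 1 + 4 * len(self.scales)

    def fit(self, images: Sequence, masks: Sequence) -> "RootPixelClassifier":
        """Fit on a library of dimension-matched (image, mask) pairs."""
        images = list(images)
        masks = list(masks)
        if len(images) == 0:
            raise TrainingError("training library is empty")
        if len(images) != len(masks):
            raise TrainingError("images and masks differ in count")
        rng = np.random.default_rng(self.random_state)
        xs, ys = [], []
        for img, mask in zip(images, masks):
            ivals = _as_image_array(img)
            mvals = as_mask_array(mask)
            if ivals.shape != mvals.shape:
                raise TrainingError(
                    f"image {ivals.shape} and mask {mvals.shape} dimensions differ"
                )
            feats = compute_pixel_features(ivals, self.scales).as_samples()
            flat = mvals.ravel()
            for label in (True, False):
                idx = np.flatnonzero(flat == label)
                if idx.size > self.max_samples_per_image:
                    idx = rng.choice(idx, size=self.max_samples_per_image, replace=False)
                xs.append(feats[idx])
                ys.append(np.full(idx.size, label, dtype=bool))
        X = np.vstack(xs)
        y = np.concatenate(ys)
        if len(np.unique(y)) < 2:
            raise TrainingError(
                "training library must contain both foreground and background pixels"
            )
        self.classifier_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        self.version_ = MODEL_FORMAT_VERSION
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "classifier_"):
            raise ValidationError("classifier is not fitted")
        if self.classifier_.n_features_in_ != self.n_feature_planes:
            raise ValidationError(
                "feature configuration mismatch: model was fitted with "
                f"{self.classifier_.n_features_in_} planes but the current "
                f"scales {self.scales} produce {self.n_feature_planes}"
            )

    def predict_proba_map(self, img) -> np.ndarray:
        """Per-pixel foreground probability map, same shape as the image."""
        self._check_fitted()
        vals = _as_image_array(img)
        feats = compute_pixel_features(vals, self.scales).as_samples()
        fg_col = int(np.flatnonzero(self.classifier_.classes_)[0])
        proba = self.classifier_.predict_proba(feats)[:, fg_col]
        return proba.reshape(vals.shape)

    def predict_mask(self, img, prob_cutoff: float = 0.5) -> RootMask:
        """Threshold the probability map at ``prob_cutoff``."""
        return RootMask(values=self.predict_proba_map(img) >= prob_cutoff)


def train_segmenter(
    library: Sequence[tuple],
    scales: Sequence[float] = DEFAULT_SCALES,
    trees: int = 100,
    max_samples_per_image: int = 5000,
    seed: int = 0,
) -> RootPixelClassifier:
    """Train a :class:`RootPixelClassifier` on (image, mask) pairs."""
    library = list(library)
    if len(library) == 0:
        raise TrainingError("training library is empty")
    images, masks = zip(*library)
    return RootPixelClassifier(
        scales=scales,
        n_estimators=trees,
        max_samples_per_image=max_samples_per_image,
        random_state=seed,
    ).fit(images, masks)


def segment(
    img,
    method: str | RootPixelClassifier = "otsu",
    prob_cutoff: float = 0.5,
    background_radius: int = 15,
) -> RootMask:
    """Segment a raw image into a RootMask.

    ``method="otsu"`` applies a global Otsu threshold to the
    background-subtracted image; passing a fitted
    :class:`RootPixelClassifier` thresholds its per-pixel foreground
    probability at ``prob_cutoff``. An all-background image yields an
    empty mask and a logged warning rather than an error.
    """
    vals = _as_image_array(img)
    if isinstance(method, RootPixelClassifier):
        mask = method.predict_mask(vals, prob_cutoff=prob_cutoff)
    elif method == "otsu":
        sub = subtract_background(vals, radius=background_radius).values
        if np.ptp(sub) < 1e-9:
            logger.warning("image appears to be all background; returning empty mask")
            return RootMask(values=np.zeros_like(vals, dtype=bool))
        mask = RootMask(values=sub > threshold_otsu(sub))
    else:
        raise ParameterError(f"unknown segmentation method: {method!r}")
    if mask.is_empty():
        logger.warning("segmentation produced an empty mask (all background?)")
    return mask


def clean_mask(
    mask,
    min_size: int = 0,
    fill_holes: bool = False,
    keep_largest: bool = False,
) -> RootMask:
    """Remove speckles, optionally fill holes and keep the largest component.

    8-connected components smaller than ``min_size`` pixels are dropped
    first, then interior holes are filled, then optionally only the
    largest remaining component is kept. Idempotent.
    """
    if min_size < 0:
        raise ParameterError(f"min_size must be >= 0, got {min_size}")
    vals = as_mask_array(mask).copy()
    if min_size > 1 and vals.any():
        labels, n = ndi.label(vals, structure=np.ones((3, 3), dtype=int))
        sizes = ndi.sum_labels(vals, labels, index=np.arange(1, n + 1))
        keep = np.concatenate([[False], sizes >= min_size])
        vals = keep[labels]
    if fill_holes:
        vals = ndi.binary_fill_holes(vals)
    if keep_largest and vals.any():
        labels, n = ndi.label(vals, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = ndi.sum_labels(vals, labels, index=np.arange(1, n + 1))
            vals = labels == (1 + int(np.argmax(sizes)))
    return RootMask(values=vals)


def save_model(model: RootPixelClassifier, path: str | Path) -> None:
    """Serialize a fitted model with its feature config and version tag."""
    model._check_fitted()
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.get_params(),
        "classifier": model.classifier_,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> RootPixelClassifier:
    """Load a serialized model, refusing a version-tag mismatch."""
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"model format {payload.get('format_version')!r} does not match "
            f"{MODEL_FORMAT_VERSION!r}"
        )
    model = RootPixelClassifier(**payload["params"])
    model.classifier_ = payload["classifier"]
    model.version_ = MODEL_FORMAT_VERSION
    model.n_features_in_ = model.classifier_.n_features_in_
    model._check_fitted()
    return model
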