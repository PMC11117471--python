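"""Lung-field extraction from CT slices.

The pipeline mirrors the standard HU-based preprocessing used in nodule
detection: calibrate raw scanner integers to Hounsfield units, binarize at an
air/tissue threshold so the lungs (near-air) and exterior air come out true,
drop everything connected to the image border (exterior air), split the
remaining air components into a left and a right lung group, expand each
group (morphological closing then convex hull) so that nodules attached to
the lung wall stay inside the mask, window the HU image to 8-bit, multiply by
the mask, and finally blank out bone and its edge neighbourhood.

All operations are pure functions of arrays; :class:`LungPreprocessor` wraps
them as a stateless sklearn-style transformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import sobel, threshold_otsu
from sklearn.base import BaseEstimator, TransformerMixin

from .synthdata import HUImage

__all__ = [
    "LungMask",
    "Uint8Image",
    "PreprocessConfig",
    "Calibration",
    "LungPreprocessor",
    "to_hu",
    "binarize_lungs",
    "extract_lung_mask",
    "hu_to_uint8",
    "apply_mask",
    "remove_bone",
    "preprocess_slice",
]


@dataclass(frozen=True)
class LungMask:
    """Binary lung mask; ``n_components`` is the connected-component count."""

    values: np.ndarray
    n_components: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.dtype != bool:
            uniq = np.unique(v)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be strictly binary")
            v = v.astype(bool)
        object.__setattr__(self, "values", v)

    @property
    def area(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class Uint8Image:
    """Grayscale image with integer values in [0, 255]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.min() < 0 or v.max() > 255:
            raise ValueError("uint8 image values must lie in [0, 255]")
        object.__setattr__(self, "values", v.astype(np.uint8))


@dataclass(frozen=True)
class Calibration:
    """Linear CT rescale: HU = raw * slope + intercept."""

    slope: float = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("rescale slope must be nonzero")


@dataclass(frozen=True)
class PreprocessConfig:
    binarize_threshold_hu: float = -400.0
    window_hu: tuple[float, float] = (-1200.0, 600.0)
    bone_threshold_hu: float = 300.0
    closing_radius_px: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.window_hu
        if not lo < hi:
            raise ValueError("window min must be below window max")
        if self.closing_radius_px < 0:
            raise ValueError("closing radius must be >= 0")


def to_hu(raw: np.ndarray, slope: float, intercept: float, spacing: float = 1.0) -> HUImage:
    """Calibrate raw scanner integers: HU = raw * slope + intercept."""
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    return HUImage(np.asarray(raw, dtype=float) * slope + intercept, spacing)


def binarize_lungs(img: HUImage, threshold: float = -400.0) -> np.ndarray:
    """True where the tissue is air-like (HU strictly below the threshold)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return img.values < threshold


def extract_lung_mask(binary: np.ndarray, closing_radius_px: int = 5) -> LungMask:
    """Turn the air-like binary image into an expanded lung mask.

    Steps: remove components touching the image border (exterior air); split
    the surviving components into a left and a right group by horizontal
    extent of their centroids; close each group with a disk and take its
    convex hull so wall-attached nodules — which punch soft-tissue holes into
    the air region — are covered.  Returns an empty mask (with a warning)
    when no interior air component exists.
    """
    binary = np.asarray(binary).astype(bool)
    labels = measure.label(binary, connectivity=2)
    border = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    interior = binary & ~np.isin(labels, border[border > 0])
    if not interior.any():
        warnings.warn("no interior air component found; returning an empty lung mask")
        return LungMask(np.zeros_like(binary), n_components=0)
    lab2 = measure.label(interior, connectivity=2)
    props = measure.regionprops(lab2)
    mid = binary.shape[1] / 2.0
    left_ids = [p.label for p in props if p.centroid[1] < mid]
    right_ids = [p.label for p in props if p.centroid[1] >= mid]
    footprint = morphology.disk(closing_radius_px) if closing_radius_px > 0 else None
    out = np.zeros_like(binary)
    for ids in (left_ids, right_ids):
        if not ids:
            continue
        group = np.isin(lab2, ids)
        if footprint is not None:
            group = morphology.closing(group, footprint)
        group = morphology.convex_hull_image(group)
        out |= group
    return LungMask(out, n_components=int(measure.label(out, connectivity=2).max()))


def hu_to_uint8(img: HUImage, window: tuple[float, float] = (-1200.0, 600.0)) -> Uint8Image:
    """Window the HU image linearly to [0, 255]; clip outside, round half-up."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("degenerate display window")
    scaled = (img.values - lo) / (hi - lo) * 255.0
    return Uint8Image(np.floor(np.clip(scaled, 0.0, 255.0) + 0.5).astype(np.uint8))


def apply_mask(img: Uint8Image, mask: LungMask) -> Uint8Image:
    """Zero the image outside the mask (pixel-wise product)."""
    if img.values.shape != mask.values.shape:
        raise ValueError("image and mask shapes differ")
    return Uint8Image(img.values * mask.values)


def remove_bone(
    img: Uint8Image, hu: HUImage, bone_threshold: float = 300.0
) -> Uint8Image:
    """Blank bone pixels and their detected edge neighbourhood.

    Bone = HU above the threshold.  Edges are found on the 8-bit image by a
    gradient-magnitude (Sobel) operator thresholded with Otsu's rule; only
    edge pixels adjacent to bone (within a 2-px dilation) are blanked, so
    structures far from any bone are untouched.
    """
    if img.values.shape != hu.values.shape:
        raise ValueError("image and HU shapes differ")
    bone = hu.values > bone_threshold
    if not bone.any():
        return Uint8Image(img.values.copy())
    grad = sobel(img.values.astype(float))
    if np.ptp(grad) > 0:
        edges = grad > threshold_otsu(grad)
    else:
        edges = np.zeros_like(bone)
    halo = morphology.dilation(bone, morphology.disk(2))
    kill = bone | (edges & halo)
    out = img.values.copy()
    out[kill] = 0
    return Uint8Image(out)


def preprocess_slice(
    raw: np.ndarray,
    calibration: Calibration = Calibration(),
    config: PreprocessConfig = PreprocessConfig(),
    spacing: float = 1.0,
) -> tuple[Uint8Image, LungMask]:
    """Full pipeline: calibrate, binarize, mask, window, multiply, de-bone."""
    hu = to_hu(raw, calibration.slope, calibration.intercept, spacing)
    binary = binarize_lungs(hu, config.binarize_threshold_hu)
    mask = extract_lung_mask(binary, config.closing_radius_px)
    u8 = hu_to_uint8(hu, config.window_hu)
    masked = apply_mask(u8, mask)
    return remove_bone(masked, hu, config.bone_threshold_hu), mask


class LungPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer over :func:`preprocess_slice`.

    ``transform`` maps a list of raw 2-D slices (or HUImages) to a list of
    ``(Uint8Image, LungMask)`` pairs.  ``fit`` only validates parameters.
    """

    def __init__(
        self,
        slope: float = 1.0,
        intercept: float = 0.0,
        binarize_threshold_hu: float = -400.0,
        window_hu: tuple[float, float] = (-1200.0, 600.0),
        bone_threshold_hu: float = 300.0,
        closing_radius_px: int = 5,
    ) -> None:
        self.slope = slope
        self.intercept = intercept
        self.binarize_threshold_hu = binarize_threshold_hu
        self.window_hu = window_hu
        self.bone_threshold_hu = bone_threshold_hu
        self.closing_radius_px = closing_radius_px

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            binarize_threshold_hu=self.binarize_threshold_hu,
            window_hu=tuple(self.window_hu),
            bone_threshold_hu=self.bone_threshold_hu,
            closing_radius_px=self.closing_radius_px,
        )

    def fit(self, X=None, y=None):
        self._config()
        Calibration(self.slope, self.intercept)
        self.n_features_in_ = 0
        return self

    def transform(self, X) -> list[tuple[Uint8Image, LungMask]]:
        cal = Calibration(self.slope, self.intercept)
        cfg = self._config()
        out = []
        for item in X:
            if isinstance(item, HUImage):
                raw, spacing = item.values, item.spacing
                # HUImage is already calibrated; use identity rescale
                item_cal = Calibration(1.0, 0.0)
            else:
                raw, spacing = np.asarray(item), 1.0
                item_cal = cal
            out.append(preprocess_slice(raw, item_cal, cfg, spacing))
        return out
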