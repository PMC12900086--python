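"""Red-green discriminant segmentation of nadir rice-canopy images.

A canopy photograph taken vertically from above is separated into
vegetation (leaf and stem) and background pixels using a per-pixel
discriminant index built from the red and green channels only:

    I = 128 + 128 * (G - R) / (G + R)

The index is the normalised green-red contrast rescaled so that gray
pixels (R = G) sit at the neutral value 128 and the extremes map to 0
(pure red) and 256 (pure green).  Pixels with ``I >= 134`` count as rice
leaf or stem; the canopy cover ratio is the percentage of such pixels in
the whole image.  The blue channel is decoded but deliberately ignored
by the classifier.

Images are plain ``numpy`` arrays of shape ``(height, width, 3)`` with
8-bit channels; masks are boolean arrays of shape ``(height, width)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np
from PIL import Image, UnidentifiedImageError
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ImageReadError, InputDomainError, UnsupportedImageError

__all__ = [
    "VEGETATION_THRESHOLD",
    "CoverResult",
    "CanopySegmenter",
    "discriminant_index",
    "segment",
    "cover_ratio",
    "load_image",
    "save_mask",
]

#: Inclusive classification threshold on the discriminant index.
VEGETATION_THRESHOLD = 134.0

# PIL modes that decode to 8 bits per channel and can be promoted to RGB.
_EIGHT_BIT_MODES = {"RGB", "RGBA", "L", "LA", "P", "PA", "1"}


def discriminant_index(r, g):
    """Red-green discriminant index ``I = 128 + 128*(g - r)/(g + r)``.

    Parameters
    ----------
    r, g : int, float or array-like
        Red and green channel intensities in ``[0, 255]``.  Scalars and
        arrays broadcast against each other.

    Returns
    -------
    float or ndarray
        The unclamped real-valued index in ``[0, 256]``.  Pixels with
        ``r + g == 0`` (pure black or pure blue) return the neutral
        value 128 so they never classify as vegetation.

    Raises
    ------
    InputDomainError
        If any channel value lies outside ``[0, 255]``.
    """
    r = np.asarray(r, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if np.any(r < 0) or np.any(r > 255) or np.any(g < 0) or np.any(g > 255):
        raise InputDomainError("channel intensities must lie in [0, 255]")
    total = r + g
    with np.errstate(divide="ignore", invalid="ignore"):
        index = 128.0 + 128.0 * (g - r) / total
    index = np.where(total == 0, 128.0, index)
    if index.ndim == 0:
        return float(index)
    return index


def _validate_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputDomainError(
            f"expected an (H, W, 3) RGB array, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InputDomainError("image must have at least one pixel")
    if not np.issubdtype(arr.dtype, np.integer):
        raise InputDomainError("channel values must be integers")
    if arr.min() < 0 or arr.max() > 255:
        raise InputDomainError("channel values must lie in [0, 255]")
    return arr


def segment(image, threshold: float = VEGETATION_THRESHOLD) -> np.ndarray:
    """Binarise an RGB canopy image into a vegetation mask.

    A pixel is vegetation iff its discriminant index is **at or above**
    ``threshold`` (inclusive comparison, default 134).  The blue channel
    plays no part in the decision.

    Returns a boolean array of shape ``(height, width)``.
    """
    arr = _validate_image(image)
    index = discriminant_index(arr[:, :, 0], arr[:, :, 1])
    return np.asarray(index) >= threshold


@dataclass(frozen=True)
class CoverResult:
    """Canopy cover derived from a vegetation mask.

    ``cover_percent`` is ``100 * vegetation_pixels / total_pixels``.
    """

    vegetation_pixels: int
    total_pixels: int
    cover_percent: float

    def __post_init__(self):
        if self.total_pixels < 1:
            raise InputDomainError("mask must contain at least one pixel")
        if not 0 <= self.vegetation_pixels <= self.total_pixels:
            raise InputDomainError("vegetation count outside [0, total]")

    @classmethod
    def from_counts(cls, vegetation_pixels: int, total_pixels: int) -> "CoverResult":
        if total_pixels < 1:
            raise InputDomainError("mask must contain at least one pixel")
        return cls(
            vegetation_pixels=int(vegetation_pixels),
            total_pixels=int(total_pixels),
            cover_percent=100.0 * vegetation_pixels / total_pixels,
        )

    def to_dict(self) -> dict:
        return {
            "vegetation_pixels": self.vegetation_pixels,
            "total_pixels": self.total_pixels,
            "cover_percent": self.cover_percent,
        }


def cover_ratio(mask) -> CoverResult:
    """Count vegetation flags in a boolean mask and derive cover percent."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        raise InputDomainError("mask must be a boolean array")
    if arr.size < 1:
        raise InputDomainError("mask must contain at least one pixel")
    return CoverResult.from_counts(int(arr.sum()), int(arr.size))


def load_image(path: str | PathLike) -> np.ndarray:
    """Load a PNG or JPEG file as an ``(H, W, 3)`` uint8 array.

    Alpha channels are dropped; grayscale is promoted to equal R = G = B.
    Files that are unreadable or truncated raise :class:`ImageReadError`;
    rasters deeper than 8 bits per channel raise
    :class:`UnsupportedImageError`.
    """
    try:
        with Image.open(path) as im:
            if im.mode not in _EIGHT_BIT_MODES:
                raise UnsupportedImageError(
                    f"unsupported image mode {im.mode!r}; "
                    "only 8-bit RGB/grayscale rasters are accepted"
                )
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.uint8)
    except UnsupportedImageError:
        raise
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    return arr


def save_mask(mask, path: str | PathLike) -> None:
    """Write a vegetation mask as an 8-bit PNG, vegetation white (255)."""
    arr = np.asarray(mask)
    if arr.dtype != bool or arr.ndim != 2:
        raise InputDomainError("mask must be a 2-D boolean array")
    Image.fromarray(arr.astype(np.uint8) * 255, mode="L").save(path)


class CanopySegmenter(TransformerMixin, BaseEstimator):
    """Stateless transformer wrapping :func:`segment`.

    Exposes the segmentation stage in scikit-learn estimator form so the
    threshold can travel through ``get_params``/``set_params`` and the
    stage can sit in a pipeline.  ``transform`` maps one ``(H, W, 3)``
    image to its ``(H, W)`` boolean mask.

    Parameters
    ----------
    threshold : float, default 134
        Inclusive discriminant-index threshold, in ``[0, 256]``.
    """

    def __init__(self, threshold: float = VEGETATION_THRESHOLD):
        self.threshold = threshold

    def fit(self, X=None, y=None):
        if not 0 <= self.threshold <= 256:
            raise InputDomainError("threshold must lie in [0, 256]")
        self.threshold_ = float(self.threshold)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            self.fit()
        return segment(X, threshold=self.threshold_)

    def cover(self, X) -> CoverResult:
        """Segment an image and return its :class:`CoverResult`."""
        return cover_ratio(self.transform(X))
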