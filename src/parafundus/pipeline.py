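"""Image-processing chain for hemorrhage-pattern scoring.

A fundus photograph region of interest (ROI) is reduced to two binary
skeleton images — one tracing the dark hemorrhage streaks, one tracing the
bright hemorrhage-sparse streaks between them — through the following
chain:

1. take the green channel of the RGB photograph (hemorrhages absorb green
   light most strongly, so this plane carries the contrast);
2. crop a 200 x 200 pixel ROI;
3. apply a 4-5 pixel band-pass filter, implemented as a difference of
   Gaussians whose full-widths-at-half-maximum equal the two scales;
4. binarize each polarity of the filter response with Otsu's threshold;
5. thin each binary image to unit-width curves (Zhang-Suen skeletonization
   as implemented by scikit-image).

All coordinates are 0-based, row-major, origin at the top-left; ROIs use
half-open index ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "RoiSpec",
    "BandpassParams",
    "SkeletonImage",
    "extract_green_channel",
    "crop_roi",
    "bandpass_filter",
    "binarize_otsu",
    "skeletonize",
    "extract_dual_skeletons",
]

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class DegenerateImageError(ValueError):
    """Raised when an image is constant and cannot be thresholded."""


@dataclass(frozen=True)
class RoiSpec:
    """Top-left corner and size of a rectangular region of interest.

    The default 200 x 200 pixel size is the working ROI for posterior-pole
    hemorrhage scoring; ``height``/``width`` may be overridden explicitly.
    """

    row: int
    col: int
    height: int = 200
    width: int = 200

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI dimensions must be positive")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI corner must be non-negative")


@dataclass(frozen=True)
class BandpassParams:
    """Pass band of the texture filter, in pixels.

    ``small_scale_px`` and ``large_scale_px`` are the FWHMs of the two
    Gaussians in the difference-of-Gaussians filter; structures between the
    two scales are passed, larger and smaller structures are suppressed.
    """

    small_scale_px: float = 4.0
    large_scale_px: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.small_scale_px < self.large_scale_px:
            raise ValueError(
                "band-pass scales must satisfy 0 < small < large, got "
                f"{self.small_scale_px} and {self.large_scale_px}"
            )

    @property
    def sigma_small(self) -> float:
        return self.small_scale_px / _FWHM_PER_SIGMA

    @property
    def sigma_large(self) -> float:
        return self.large_scale_px / _FWHM_PER_SIGMA


@dataclass(frozen=True)
class SkeletonImage:
    """A binary image of unit-width curves plus its polarity tag."""

    pixels: np.ndarray  # bool, height x width
    polarity: str  # "hemorrhage" or "hemorrhage_sparse"

    def __post_init__(self) -> None:
        if self.polarity not in ("hemorrhage", "hemorrhage_sparse"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))


def extract_green_channel(img: np.ndarray) -> np.ndarray:
    """Return the green plane of an 8-bit RGB image, values untouched."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    return np.ascontiguousarray(img[:, :, 1])


def crop_roi(img: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Copy the half-open window [row, row+h) x [col, col+w) out of ``img``.

    Raises IndexError if the ROI is not fully inside the image; nothing is
    silently clamped.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    if roi.row + roi.height > h or roi.col + roi.width > w:
        raise IndexError(
            f"ROI {roi} exceeds image bounds {h} x {w}"
        )
    return img[roi.row : roi.row + roi.height, roi.col : roi.col + roi.width].copy()


def bandpass_filter(img: np.ndarray, params: BandpassParams | None = None) -> np.ndarray:
    """Difference-of-Gaussians band-pass response (real-valued).

    Reflection padding at the borders; exactly zero response on constant
    input, and linear in the input.
    """
    if params is None:
        params = BandpassParams()
    x = np.asarray(img, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("band-pass filter expects a 2-D grayscale image")
    lo = gaussian_filter(x, params.sigma_small, mode="reflect")
    hi = gaussian_filter(x, params.sigma_large, mode="reflect")
    return lo - hi


def binarize_otsu(img: np.ndarray) -> np.ndarray:
    """Binarize a real-valued plane with Otsu's threshold.

    The plane is first rescaled linearly onto [0, 255] and binned into 256
    integer levels, because Otsu's criterion operates on a histogram.  The
    returned mask marks pixels strictly above the threshold that maximizes
    between-class variance.
    """
    x = np.asarray(img, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateImageError("constant image: Otsu threshold is undefined")
    q = np.rint((x - lo) * (255.0 / (hi - lo))).astype(np.uint8)
    t = threshold_otsu(q, nbins=256)
    return q > t


def skeletonize(binary: np.ndarray) -> np.ndarray:
    """Thin a binary image to unit-width curves (topology preserving)."""
    b = np.asarray(binary, dtype=bool)
    return _sk_skeletonize(b)


def extract_dual_skeletons(
    roi: np.ndarray, params: BandpassParams | None = None
) -> tuple[SkeletonImage, SkeletonImage]:
    """Skeletonize both texture polarities of an 8-bit grayscale ROI.

    The hemorrhage skeleton traces dark band-pass structures (negative
    filter response); the hemorrhage-sparse skeleton traces the bright
    inter-hemorrhage streaks (positive response).  Inverting the ROI
    intensities therefore swaps the two skeletons exactly.
    """
    resp = bandpass_filter(np.asarray(roi, dtype=np.float64), params)
    hem = SkeletonImage(skeletonize(binarize_otsu(-resp)), "hemorrhage")
    sparse = SkeletonImage(skeletonize(binarize_otsu(resp)), "hemorrhage_sparse")
    return hem, sparse
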