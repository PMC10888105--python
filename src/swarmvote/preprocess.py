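"""Brain-region extraction from MRI-like 2-D slices.

Pipeline: grayscale conversion, 9x9 Gaussian blur, Otsu binarization,
then the tight bounding box spanning the extreme points of the largest
8-connected foreground component.  The box is applied to the original
(unblurred) image, so off-brain noise specks are discarded and downstream
classifiers see only the brain region, still sharp.

Coordinates are row-major with origin at the top-left; boxes are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import RuntimeFailure, ValidationError

#: ITU-R BT.601 luma weights for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel rectangle [row_start, row_stop) x [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_stop and 0 <= self.col_start < self.col_stop):
            raise ValidationError(f"degenerate crop box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop))

    def expand(self, margin: int, image_shape: tuple[int, int]) -> "CropBox":
        """Grow each edge by ``margin`` pixels, clamped to the image bounds."""
        h, w = image_shape[:2]
        return CropBox(
            max(0, self.row_start - margin),
            min(h, self.row_stop + margin),
            max(0, self.col_start - margin),
            min(w, self.col_stop + margin),
        )

    def to_dict(self) -> dict:
        return {
            "row_start": self.row_start,
            "row_stop": self.row_stop,
            "col_start": self.col_start,
            "col_stop": self.col_stop,
        }


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit image to single-channel grayscale.

    Single-channel input is returned unchanged; 3-channel input is reduced
    with the BT.601 luma weights (0.299 R + 0.587 G + 0.114 B).
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        gray = image.astype(float) @ _LUMA
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValidationError(
        f"expected a 2-D or (H, W, 3) image, got shape {image.shape}"
    )


def gaussian_kernel_sigma(kernel_size: int) -> float:
    """Sigma implied by the kernel size: 0.3*((k-1)/2 - 1) + 0.8.

    The de-facto standard mapping in mainstream imaging toolchains; gives
    sigma = 1.7 for the 9x9 kernel.
    """
    return 0.3 * ((kernel_size - 1) / 2 - 1) + 0.8


def gaussian_blur(image: np.ndarray, kernel_size: int = 9) -> np.ndarray:
    """Separable Gaussian blur with a fixed square kernel and reflect padding.

    The 1-D kernel samples exp(-x^2 / (2 sigma^2)) at the integer offsets
    of a length-``kernel_size`` window and normalizes; sigma follows
    :func:`gaussian_kernel_sigma`.  Reflect padding avoids the artificial
    dark frame that zero padding would feed into Otsu's threshold.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValidationError(f"kernel size must be odd and >= 1, got {kernel_size}")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError(f"blur expects a single-channel image, got shape {image.shape}")
    if kernel_size == 1:
        return image.copy()
    sigma = gaussian_kernel_sigma(kernel_size)
    radius = (kernel_size - 1) // 2
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    out = image.astype(float)
    for axis in (0, 1):
        out = ndimage.correlate1d(out, kernel, axis=axis, mode="reflect")
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out


def otsu_threshold(image: np.ndarray) -> int:
    """Gray level maximizing between-class variance over the 256-bin histogram.

    Pixels strictly above the returned level are foreground.  Ties pick the
    lowest level.  A constant image has no between-class split and raises.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError(f"expected a single-channel image, got shape {image.shape}")
    hist = np.bincount(image.ravel().astype(np.int64), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise RuntimeFailure("degenerate histogram: image has fewer than 2 gray levels")
    total = hist.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)  # pixels at levels <= t
    mu_cum = np.cumsum(hist * levels)
    mu_total = mu_cum[-1]
    w1 = total - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(var_between))


def otsu_binarize(image: np.ndarray) -> np.ndarray:
    """Boolean foreground mask: pixels strictly above the Otsu threshold."""
    return np.asarray(image) > otsu_threshold(image)


def largest_component_box(mask: np.ndarray) -> CropBox:
    """Tight box over the extreme points of the largest 8-connected component.

    Area ties are broken toward the component whose first pixel in
    row-major scan order comes earliest.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RuntimeFailure("no foreground pixels in mask")
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    areas = np.bincount(labeled.ravel())[1:]
    candidates = np.flatnonzero(areas == areas.max()) + 1
    if len(candidates) > 1:
        flat = labeled.ravel()
        first_seen = {lab: np.argmax(flat == lab) for lab in candidates}
        winner = min(candidates, key=lambda lab: first_seen[lab])
    else:
        winner = candidates[0]
    rows, cols = np.nonzero(labeled == winner)
    return CropBox(int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1)


def crop_brain(
    image: np.ndarray,
    kernel_size: int = 9,
    margin: int = 0,
) -> tuple[np.ndarray, CropBox]:
    """Full brain-region crop: blur, binarize, box the largest component.

    The box found on the blurred binarized image is applied to the
    ORIGINAL image so the returned crop stays sharp.  ``margin`` grows the
    box by that many pixels per edge (clamped to the image).
    """
    image = np.asarray(image)
    gray = to_grayscale(image)
    blurred = gaussian_blur(gray, kernel_size)
    mask = otsu_binarize(blurred)
    box = largest_component_box(mask)
    if margin:
        box = box.expand(margin, gray.shape)
    return image[box.slices()], box
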