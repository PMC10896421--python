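"""Threshold-based tissue segmentation of calibrated slice stacks.

Each slice is segmented independently: pixels above a threshold (Otsu by
default, or a user-fixed value) are kept, speckle is removed with a
radius-1 morphological opening, and only the largest connected component
survives — the block face shows one organ cross-section per slice.  The
per-slice masks are stacked in z to form the 3D tissue mask that
restricts all downstream quantitation.  Slices whose mask comes out
empty (typical for end slices past the organ) are excluded with a
warning rather than failing the whole animal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk, opening

from .calibration import ImageStack

__all__ = ["TissueMask", "SegmentationError", "segment_slice", "segment_volume"]

logger = logging.getLogger(__name__)


class SegmentationError(ValueError):
    """Raised when no usable tissue mask can be produced."""


class EmptySliceError(SegmentationError):
    """A single slice produced an empty mask after cleanup."""


@dataclass
class TissueMask:
    """3D boolean tissue mask aligned to the calibrated stacks."""

    mask: np.ndarray
    method: str
    thresholds: list[float | None]  # per slice; None where the slice was excluded

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("tissue mask must be 3D")
        if self.n_voxels == 0:
            raise SegmentationError("tissue mask is empty: no tissue found")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


def segment_slice(
    slice_image: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Segment one calibrated slice into tissue vs background.

    Returns the boolean mask and the threshold that was applied.  Raises
    :class:`EmptySliceError` when nothing survives thresholding plus
    cleanup, so callers can exclude the slice.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    if img.ndim != 2:
        raise SegmentationError("slice must be 2D")
    if method == "otsu":
        if np.ptp(img) == 0:
            raise EmptySliceError("constant slice: Otsu threshold undefined")
        threshold = float(threshold_otsu(img))
    elif method == "fixed":
        if fixed_threshold is None:
            raise SegmentationError("method='fixed' requires fixed_threshold")
        threshold = float(fixed_threshold)
    else:
        raise SegmentationError(f"unknown segmentation method {method!r}")

    mask = img > threshold
    mask = opening(mask, disk(1)).astype(bool)
    if not mask.any():
        raise EmptySliceError(f"empty mask after cleanup (threshold {threshold:g})")
    labels = label(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    mask = labels == int(np.argmax(counts))
    return mask, threshold


def _segmentation_image(
    nadh_stack: ImageStack, fad_stack: ImageStack, combine_rule: str
) -> np.ndarray:
    if combine_rule == "nadh":
        return nadh_stack.data
    if combine_rule == "fad":
        return fad_stack.data
    if combine_rule == "mean":
        return 0.5 * (nadh_stack.data + fad_stack.data)
    raise SegmentationError(f"unknown combine_rule {combine_rule!r}")


def segment_volume(
    nadh_stack: ImageStack,
    fad_stack: ImageStack,
    method: str = "otsu",
    combine_rule: str = "nadh",
    fixed_threshold: float | None = None,
) -> TissueMask:
    """Segment every slice and stack the masks into a 3D tissue mask.

    ``combine_rule`` selects the image segmented: the NADH channel
    (default; brighter in liver), the FAD channel, or the per-pixel mean
    of both.  Empty slices are excluded (mask all-false, threshold
    recorded as None); a volume with no tissue anywhere is a hard error.
    """
    if nadh_stack.data.shape != fad_stack.data.shape:
        raise SegmentationError(
            f"channel shape mismatch: NADH {nadh_stack.data.shape} "
            f"vs FAD {fad_stack.data.shape}"
        )
    images = _segmentation_image(nadh_stack, fad_stack, combine_rule)

    masks = np.zeros(images.shape, dtype=bool)
    thresholds: list[float | None] = []
    n_empty = 0
    for s in range(images.shape[0]):
        try:
            masks[s], t = segment_slice(images[s], method, fixed_threshold)
            thresholds.append(t)
        except EmptySliceError:
            thresholds.append(None)
            n_empty += 1
    if n_empty:
        logger.warning(
            "%d of %d slices produced empty masks and were excluded",
            n_empty,
            images.shape[0],
        )
    if not masks.any():
        raise SegmentationError("no tissue found in any slice")
    return TissueMask(mask=masks, method=method, thresholds=thresholds)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom
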