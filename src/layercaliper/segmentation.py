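"""Stand-in layer segmenter: grayscale image → single-component binary mask.

This is a deliberately simple, documented pipeline (threshold → closing →
hole fill → small-object removal → keep largest component) so the CLI can
run end-to-end on raw images.  It is not a validated nuclear-layer
segmentation algorithm; for quantitative work users should supply masks
produced by their own validated segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .io import BinaryMask


class NoLayerFoundError(RuntimeError):
    """Segmentation produced an empty mask after filtering."""


@dataclass
class SegmentationParams:
    threshold_method: str = "otsu"      # 'otsu' or 'fixed'
    fixed_threshold: float | None = None
    min_object_area: int = 64
    closing_radius: int = 2
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required when threshold_method='fixed'")


def segment_layer(image: np.ndarray, params: SegmentationParams | None = None,
                  scale_um_per_px: float = 1.0) -> BinaryMask:
    """Segment the brightest layer of a single-channel image.

    Returns a single 8-connected component or raises
    :class:`NoLayerFoundError`.  Segmenting a clean binary rendering of a
    mask returns that mask (idempotence).
    """
    if params is None:
        params = SegmentationParams()
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected single-channel image, got shape {img.shape}")
    if img.dtype == bool:
        fg = img.copy()
    elif params.threshold_method == "otsu":
        if np.ptp(img) == 0:
            fg = np.ones(img.shape, bool)  # saturated input: everything is layer
        else:
            fg = img > threshold_otsu(img)
    else:
        fg = img > params.fixed_threshold
    if params.closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=disk(params.closing_radius))
    if params.fill_holes:
        fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), int))
    if n == 0:
        raise NoLayerFoundError("no foreground after thresholding")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.nonzero(areas >= params.min_object_area)[0]
    if len(keep) == 0:
        raise NoLayerFoundError(
            f"no component reaches min_object_area={params.min_object_area} "
            f"(largest was {int(areas.max())})")
    largest = keep[np.argmax(areas[keep])] + 1
    return BinaryMask(labels == largest, scale_um_per_px)
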