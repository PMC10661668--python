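"""Cell detection on the nuclear-channel time average.

The detection chain is a classical morphological background-subtraction
pipeline applied to the temporal mean of the nuclear channel: median blur
to suppress noise, a large grey-scale opening (default 32 px footprint)
whose result is taken as the background and subtracted, a small opening
(default 2 px) to sharpen contours, a fixed intensity threshold (default
100 counts on the 8-bit scale), connected-component labeling, and an area
filter that keeps only components strictly larger than 20 pixels.  A
max-projection ROI-intensity quantifier for z-stacks lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import DomainError

__all__ = [
    "DetectionParams",
    "ROIRegion",
    "temporal_mean",
    "detect_cells",
    "max_project_roi_mean",
]

_CONNECTIVITY_STRUCTURE = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the detection chain, defaulting to the 8-bit reference values."""

    median_blur_size: int = 3
    background_kernel: int = 32
    sharpen_kernel: int = 2
    threshold: float = 100.0
    min_area: int = 20  # exclusive: keep area > min_area
    connectivity: Literal[4, 8] = 8
    footprint_shape: Literal["square", "disk"] = "square"

    def __post_init__(self) -> None:
        if self.median_blur_size < 1 or self.median_blur_size % 2 == 0:
            raise DomainError("median_blur_size must be odd and >= 1")
        if min(self.background_kernel, self.sharpen_kernel) < 1:
            raise DomainError("morphological kernels must be >= 1")
        if not 0 <= self.threshold <= 255:
            raise DomainError("threshold must lie within the 8-bit range")
        if self.connectivity not in (4, 8):
            raise DomainError("connectivity must be 4 or 8")
        if self.footprint_shape not in ("square", "disk"):
            raise DomainError("footprint_shape must be 'square' or 'disk'")

    def footprint(self, size: int) -> np.ndarray:
        if self.footprint_shape == "square":
            return np.ones((size, size), dtype=bool)
        r = size / 2.0
        yy, xx = np.mgrid[:size, :size]
        c = (size - 1) / 2.0
        return (yy - c) ** 2 + (xx - c) ** 2 <= r**2


@dataclass(frozen=True)
class ROIRegion:
    """One detected cell footprint."""

    label: int
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    area: int
    centroid: tuple[float, float]  # (row, col)


def temporal_mean(movie_channel: np.ndarray) -> np.ndarray:
    """Per-pixel arithmetic mean over frames of a (T, H, W) stack."""
    stack = np.asarray(movie_channel)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise DomainError("expected a non-empty (T, H, W) stack")
    return stack.mean(axis=0)


def detect_cells(
    image: np.ndarray, params: DetectionParams | None = None
) -> tuple[np.ndarray, list[ROIRegion]]:
    """Run the detection chain on a single-channel image.

    Returns ``(label_mask, regions)`` where the mask holds labels 1..K in
    raster order of each component's first pixel, and every region's area is
    strictly greater than ``params.min_area``.
    """
    params = params or DetectionParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DomainError("expected a single-channel 2-D image")
    if params.background_kernel > min(img.shape):
        raise DomainError("background kernel exceeds image size")

    if params.median_blur_size > 1:
        img = ndimage.median_filter(img, size=params.median_blur_size)
    background = ndimage.grey_opening(
        img, footprint=params.footprint(params.background_kernel)
    )
    img = np.clip(img - background, 0.0, None)
    img = ndimage.grey_opening(img, footprint=params.footprint(params.sharpen_kernel))
    binary = img > params.threshold

    labels, _ = ndimage.label(binary, structure=_CONNECTIVITY_STRUCTURE[params.connectivity])
    return _filter_and_relabel(labels, params.min_area)


def _filter_and_relabel(labels: np.ndarray, min_area: int) -> tuple[np.ndarray, list[ROIRegion]]:
    """Drop components with area <= min_area; relabel 1..K by raster order of
    each component's first pixel."""
    n = labels.max()
    mask = np.zeros_like(labels, dtype=np.int32)
    regions: list[ROIRegion] = []
    if n == 0:
        return mask, regions

    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = [k for k in range(1, n + 1) if areas[k] > min_area]
    # scipy assigns labels in raster order of first encounter already, but we
    # re-derive the order explicitly so relabeling is contract, not accident.
    first_pixel = {}
    flat = labels.ravel()
    for k in keep:
        first_pixel[k] = int(np.argmax(flat == k))
    keep.sort(key=first_pixel.__getitem__)

    for new_label, old in enumerate(keep, start=1):
        rr, cc = np.nonzero(labels == old)
        mask[rr, cc] = new_label
        regions.append(
            ROIRegion(
                label=new_label,
                pixels=(rr, cc),
                area=int(rr.size),
                centroid=(float(rr.mean()), float(cc.mean())),
            )
        )
    return mask, regions


def max_project_roi_mean(
    zstack: np.ndarray, roi: ROIRegion | None = None
) -> float:
    """Max-project a (Z, H, W) stack, then average over the ROI pixels
    (whole frame when ``roi`` is None)."""
    stack = np.asarray(zstack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise DomainError("expected a non-empty (Z, H, W) stack")
    projection = stack.max(axis=0)
    if roi is None:
        return float(projection.mean())
    rr, cc = roi.pixels
    if rr.size == 0:
        raise DomainError("empty ROI")
    return float(projection[rr, cc].mean())
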