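"""Tissue masking: saturation channel -> median filter -> Otsu -> morphology.

Stained tissue is saturated against the near-white glass background, so
segmentation runs on the HSV saturation channel of the working-magnification
(x5) image: median smoothing (kernel 7), Otsu thresholding (foreground =
high-saturation side), morphological closing (4x4 square), removal of small
components (area < 100 px at the segmentation level), then per-component
hole handling: interior holes are filled except those larger than 16 px,
of which at most the 8 largest are preserved as tissue cavities.

Connectivity: 8-connected tissue components, 4-connected holes (the standard
duality that avoids checkerboard ambiguity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import closing

from .wsi import RasterImage

SEGMENTATION_MAGNIFICATION = 5.0


@dataclass
class MaskParams:
    median_kernel: int = 7       # px, odd
    close_kernel: int = 4        # px, square structuring element
    min_area_px: int = 100       # at the segmentation (x5) level
    min_hole_px: int = 16        # holes larger than this are preserved
    max_holes: int = 8           # cap on preserved holes per component
    reference_magnification: float = SEGMENTATION_MAGNIFICATION

    def __post_init__(self):
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        for name in ("close_kernel", "min_area_px", "min_hole_px", "max_holes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TissueMask:
    mask: np.ndarray           # H x W boolean
    magnification: float
    scale_to_level0: float     # linear factor from mask pixels to level-0 px

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


def saturation_channel(image: RasterImage) -> np.ndarray:
    """HSV saturation in [0, 1] of an RGB image."""
    return rgb2hsv(image.pixels)[:, :, 1]


def _hole_filter(component: np.ndarray, min_hole_px: int, max_holes: int) -> np.ndarray:
    """Fill interior holes except the <= max_holes largest ones above min_hole_px.

    Ties in hole size break toward the hole appearing first in scanline order
    (scipy labels in scanline order; we sort by (-area, label)).
    """
    filled = ndi.binary_fill_holes(component)
    holes = filled & ~component
    if not holes.any():
        return filled
    lbl, n = ndi.label(holes, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    areas = ndi.sum_labels(holes, lbl, index=np.arange(1, n + 1))
    candidates = [(int(-areas[i]), i + 1) for i in range(n) if areas[i] > min_hole_px]
    candidates.sort()
    keep = {label for _, label in candidates[:max_holes]}
    out = filled.copy()
    for label in keep:
        out[lbl == label] = False
    return out


def filter_components(mask: np.ndarray, params: MaskParams,
                      area_scale: float = 1.0) -> np.ndarray:
    """Small-component removal + per-component hole handling (idempotent)."""
    min_area = params.min_area_px * area_scale**2
    lbl, n = ndi.label(mask, structure=np.ones((3, 3)))  # 8-connectivity
    out = np.zeros_like(mask)
    for i in range(1, n + 1):
        comp = lbl == i
        if comp.sum() < min_area:
            continue
        out |= _hole_filter(comp, params.min_hole_px, params.max_holes)
    return out


def compute_tissue_mask(image: RasterImage, params: MaskParams = MaskParams(),
                        scale_to_level0: float = 1.0) -> TissueMask:
    """Run the full masking pipeline on a working-magnification RGB image.

    `scale_to_level0` records the linear factor from mask pixels back to
    level-0 slide pixels (base_magnification / image.magnification).
    """
    sat = saturation_channel(image)
    smoothed = ndi.median_filter(sat, size=params.median_kernel)
    if smoothed.max() == smoothed.min():
        fg = np.zeros(smoothed.shape, dtype=bool)
    else:
        fg = smoothed > threshold_otsu(smoothed)
    if params.close_kernel > 1:
        fg = closing(fg, footprint=np.ones((params.close_kernel, params.close_kernel)))
    # area threshold is defined at the reference segmentation level; scale if
    # the mask is computed at a different magnification
    area_scale = image.magnification / params.reference_magnification
    cleaned = filter_components(fg, params, area_scale=area_scale)
    if not cleaned.any():
        warnings.warn("tissue mask is empty after filtering", stacklevel=2)
    return TissueMask(
        mask=cleaned,
        magnification=image.magnification,
        scale_to_level0=scale_to_level0,
    )
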