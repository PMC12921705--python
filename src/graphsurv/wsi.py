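"""Slide reading at arbitrary magnification over pyramidal TIFF or flat rasters.

The public coordinate system is magnification, not pyramid level: reading a
x40 slide at x5 means a linear downsample factor of 8. All bounding boxes
are level-0, 0-based, half-open pixel coordinates. When no pyramid level
matches the requested magnification exactly, the nearest finer level is read
and resized by exact area averaging (PIL BOX filter), which is deterministic
and preserves constants.

Plain PNG/TIFF rasters are first-class single-level slides; because they
carry no magnification metadata, `open_slide` accepts a `base_magnification`
override and also honours a `<path>.meta.json` sidecar (written by the
synthetic slide generator) with keys `base_magnification` and optional `mpp`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import tifffile
from PIL import Image


class SlideFormatError(ValueError):
    """Unreadable or unsupported slide file."""


class SlideConfigurationError(ValueError):
    """Missing magnification metadata with no override."""


class BoundsError(ValueError):
    """Requested region falls outside the slide."""


@dataclass
class RasterImage:
    pixels: np.ndarray          # H x W x 3 uint8
    magnification: float
    origin: Tuple[int, int] = (0, 0)  # level-0 pixel coordinates

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RasterImage requires an HxWx3 RGB array")


@dataclass
class SlideHandle:
    path: Path
    base_magnification: float
    levels: List[Tuple[float, int, int]]  # (downsample, width, height)
    mpp: Optional[float] = None
    _arrays: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        factors = [f for f, _, _ in self.levels]
        if factors[0] != 1 or any(a >= b for a, b in zip(factors, factors[1:])):
            raise ValueError("level downsample factors must be strictly increasing from 1")

    @property
    def dimensions(self) -> Tuple[int, int]:
        """(width, height) at level 0."""
        _, w, h = self.levels[0]
        return w, h

    def level_array(self, level: int) -> np.ndarray:
        if level not in self._arrays:
            self._arrays[level] = _load_level(self.path, level)
        return self._arrays[level]


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr[:, :, :3].astype(np.uint8))


def _tiff_level_shapes(path: Path) -> List[Tuple[int, int]]:
    """(height, width) per pyramid level: sub-resolution levels if present,
    else decreasing-size pages."""
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        if len(series.levels) > 1:
            return [lvl.shape[:2] for lvl in series.levels]
        shapes = [p.shape[:2] for p in tf.pages if p.shape is not None]
    if len(shapes) > 1 and all(
        a[0] >= b[0] and a[1] >= b[1] for a, b in zip(shapes, shapes[1:])
    ):
        return shapes
    return shapes[:1]


def _load_level(path: Path, level: int) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff", ".svs"):
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            if len(series.levels) > 1:
                return _to_rgb(series.levels[level].asarray())
            return _to_rgb(tf.pages[level].asarray())
    if level != 0:
        raise SlideFormatError("flat raster has a single level")
    with Image.open(path) as im:
        return _to_rgb(np.asarray(im.convert("RGB")))


def open_slide(path, base_magnification: Optional[float] = None) -> SlideHandle:
    """Open a pyramidal TIFF/SVS or flat PNG/TIFF raster.

    Magnification comes from `base_magnification` if given, else from a
    `<path>.meta.json` sidecar; without either a SlideConfigurationError is
    raised (generic rasters carry no magnification metadata).
    """
    path = Path(path)
    if not path.exists():
        raise SlideFormatError(f"no such file: {path}")
    mpp = None
    if base_magnification is None:
        sidecar = path.with_name(path.name + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            base_magnification = meta.get("base_magnification")
            mpp = meta.get("mpp")
    if base_magnification is None:
        raise SlideConfigurationError(
            f"{path}: no magnification metadata; pass base_magnification"
        )

    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff", ".svs"):
            shapes = _tiff_level_shapes(path)
            h0, w0 = shapes[0]
            levels = [(round(w0 / w, 6), w, h) for h, w in shapes]
            levels[0] = (1.0, w0, h0)
        else:
            with Image.open(path) as im:
                w0, h0 = im.size
            levels = [(1.0, w0, h0)]
    except SlideConfigurationError:
        raise
    except Exception as exc:  # noqa: BLE001 - backend decode errors vary
        raise SlideFormatError(f"cannot read {path}: {exc}") from exc
    return SlideHandle(path=path, base_magnification=float(base_magnification),
                       levels=levels, mpp=mpp)


def _box_resize(arr: np.ndarray, out_w: int, out_h: int) -> np.ndarray:
    """Area-average resize; exact block mean (single rounding) when the
    source dimensions are integer multiples of the target."""
    h, w = arr.shape[:2]
    if out_h and out_w and h % out_h == 0 and w % out_w == 0:
        fy, fx = h // out_h, w // out_w
        blocks = arr.reshape(out_h, fy, out_w, fx, 3).astype(np.float64)
        mean = blocks.mean(axis=(1, 3))
        return np.floor(mean + 0.5).astype(np.uint8)
    im = Image.fromarray(arr)
    return np.asarray(im.resize((out_w, out_h), resample=Image.Resampling.BOX))


def read_region(handle: SlideHandle, magnification: float,
                bbox: Tuple[int, int, int, int]) -> RasterImage:
    """Read `bbox` = (x, y, w, h) in level-0 pixels at the given magnification.

    Output size is the bbox size divided by base/requested, rounded down.
    Reads from the nearest pyramid level at least as fine as required, then
    area-averages down to the target.
    """
    if magnification > handle.base_magnification:
        raise ValueError("requested magnification exceeds base magnification")
    x, y, w, h = bbox
    w0, h0 = handle.dimensions
    if x < 0 or y < 0 or w <= 0 or h <= 0 or x + w > w0 or y + h > h0:
        raise BoundsError(f"bbox {bbox} outside slide bounds {(w0, h0)}")

    factor = handle.base_magnification / magnification
    # nearest level no coarser than the requested factor
    level = 0
    for i, (ds, _, _) in enumerate(handle.levels):
        if ds <= factor + 1e-9:
            level = i
    ds = handle.levels[level][0]
    arr = handle.level_array(level)
    lx, ly = int(round(x / ds)), int(round(y / ds))
    lw, lh = int(round(w / ds)), int(round(h / ds))
    sub = arr[ly:ly + lh, lx:lx + lw]
    out_w, out_h = int(w // factor), int(h // factor)
    if (sub.shape[1], sub.shape[0]) != (out_w, out_h):
        sub = _box_resize(sub, out_w, out_h)
    return RasterImage(pixels=np.ascontiguousarray(sub), magnification=magnification,
                       origin=(x, y))
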