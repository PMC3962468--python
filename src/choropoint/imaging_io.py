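"""Raster and tabular I/O for the colocalization pipeline.

Coordinate convention, enforced at construction everywhere: 0-based
``(row, col)`` integer pixel coordinates with row 0 at the top of the image.
Binary masks are written as 8-bit rasters with foreground = 255 and
background = 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .errors import FormatError, ShapeMismatchError

DEFAULT_PIXEL_SIZE_UM = 10.0

MASK_SEMANTICS = ("vessel", "exclusion", "analysis_region")
POINT_LABELS = ("observed", "control")


@dataclass(frozen=True)
class GrayscaleImage:
    """A 2D 8-bit intensity raster with an isotropic physical pixel size.

    Parameters
    ----------
    pixels
        2D array of integers in [0, 255].
    pixel_size_um
        Physical size of one pixel in microns (default 10, the size of an
        exported 600 px C-scan pixel over a 6 mm field).
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"image must be 2D and non-empty, got shape {arr.shape}")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr, dtype=np.uint8))
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean per-pixel map with explicit foreground semantics.

    ``semantics`` is one of ``vessel`` (foreground = vessel lumen),
    ``exclusion`` (foreground = pixels removed from analysis) or
    ``analysis_region`` (foreground = pixels eligible for analysis).
    """

    foreground: np.ndarray
    semantics: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.foreground)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"mask must be 2D and non-empty, got shape {arr.shape}")
        if arr.dtype != bool:
            if not np.isin(arr, (0, 1, 255)).all():
                raise ValueError("mask values must be boolean-like (0/1/255)")
            arr = arr != 0
        object.__setattr__(self, "foreground", np.ascontiguousarray(arr, dtype=bool))
        if self.semantics not in MASK_SEMANTICS:
            raise ValueError(f"semantics must be one of {MASK_SEMANTICS}, got {self.semantics!r}")

    @property
    def height(self) -> int:
        return int(self.foreground.shape[0])

    @property
    def width(self) -> int:
        return int(self.foreground.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_foreground(self) -> int:
        return int(self.foreground.sum())

    def require_shape(self, shape: tuple[int, int], what: str = "mask") -> None:
        if self.shape != tuple(shape):
            raise ShapeMismatchError(f"{what} shape {self.shape} != expected {tuple(shape)}")


@dataclass(frozen=True)
class PointMap:
    """A set of single-pixel points tied to an image frame.

    Points are ``(row, col)`` integer pairs, unique, and strictly inside the
    frame. Each point stands for exactly one lesion (value-1 semantics).
    """

    points: np.ndarray
    frame_height: int
    frame_width: int
    label: str = "observed"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be an (n, 2) array, got shape {pts.shape}")
        if pts.size and not np.issubdtype(pts.dtype, np.integer):
            if not np.equal(np.mod(pts, 1), 0).all():
                raise ValueError("point coordinates must be integers")
        pts = np.ascontiguousarray(pts, dtype=np.int64)
        if self.frame_height < 1 or self.frame_width < 1:
            raise ValueError("frame dimensions must be positive")
        if pts.size:
            if pts[:, 0].min() < 0 or pts[:, 0].max() >= self.frame_height:
                raise ValueError("point row outside frame")
            if pts[:, 1].min() < 0 or pts[:, 1].max() >= self.frame_width:
                raise ValueError("point col outside frame")
            if len(np.unique(pts, axis=0)) != len(pts):
                raise ValueError("duplicate point coordinates")
        object.__setattr__(self, "points", pts)
        if self.label not in POINT_LABELS:
            raise ValueError(f"label must be one of {POINT_LABELS}, got {self.label!r}")

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.frame_height, self.frame_width)

    @property
    def rows(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def cols(self) -> np.ndarray:
        return self.points[:, 1]


def _collapse_channels(arr: np.ndarray, path: Path) -> np.ndarray:
    """Collapse an RGB(A) array whose color channels are all equal."""
    rgb = arr[..., :3]
    if not (rgb == rgb[..., :1]).all():
        raise FormatError(f"{path}: multi-channel image with unequal channels")
    return rgb[..., 0]


def read_grayscale(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> GrayscaleImage:
    """Read an 8-bit grayscale PNG/TIFF, preserving intensities bit-exactly.

    RGB(A) files are accepted only when every color channel is identical.
    ``pixel_size_um`` defaults to 10 μm/pixel, the exported C-scan geometry;
    callers with sidecar calibration pass their own value.
    """
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = _collapse_channels(arr, path)
    elif arr.ndim != 2:
        raise FormatError(f"{path}: unsupported image dimensionality {arr.ndim}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit data, got dtype {arr.dtype}")
    return GrayscaleImage(pixels=arr, pixel_size_um=pixel_size_um)


def write_grayscale(image: GrayscaleImage, path: str | Path) -> None:
    """Write an image as 8-bit grayscale (format inferred from the suffix)."""
    Image.fromarray(image.pixels, mode="L").save(Path(path))


def read_mask(path: str | Path, semantics: str) -> BinaryMask:
    """Read an 8-bit raster as a mask; values must be exactly 0 or 255."""
    path = Path(path)
    img = read_grayscale(path)
    arr = img.pixels
    if not np.isin(arr, (0, 255)).all():
        raise FormatError(f"{path}: mask raster must contain only 0 and 255")
    return BinaryMask(foreground=arr == 255, semantics=semantics)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit raster, foreground = 255 and background = 0."""
    raster = np.where(mask.foreground, 255, 0).astype(np.uint8)
    Image.fromarray(raster, mode="L").save(Path(path))


def write_points_csv(points: PointMap, path: str | Path) -> None:
    """Write a point set as CSV with header ``row,col,label``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "label"])
        for r, c in points.points:
            writer.writerow([int(r), int(c), points.label])


def read_points_csv(path: str | Path, frame_height: int, frame_width: int) -> PointMap:
    """Read a point CSV written by :func:`write_points_csv`."""
    rows: list[tuple[int, int]] = []
    labels: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != ["row", "col", "label"]:
            raise FormatError(f"{path}: expected header 'row,col,label'")
        for rec in reader:
            rows.append((int(rec["row"]), int(rec["col"])))
            labels.add(rec["label"])
    if len(labels) > 1:
        raise FormatError(f"{path}: mixed point labels {sorted(labels)}")
    label = labels.pop() if labels else "observed"
    pts = np.array(rows, dtype=np.int64).reshape(len(rows), 2)
    return PointMap(points=pts, frame_height=frame_height, frame_width=frame_width, label=label)
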