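"""Exact Euclidean distance to the nearest vessel pixel, and proximity binning.

Distances are exact center-to-center Euclidean (not chamfer-approximate),
in pixel units. A stroma point at distance d falls in the bin of its pixel
ceiling: ceil(d) in 1..3 -> NEAR_1_3, 4..6 -> MID_4_6, >= 7 -> FAR_GE7;
a point on a vessel pixel is OVER_VESSEL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .errors import NoVesselError
from .imaging_io import BinaryMask

# EDT distances are sqrt of integers; this guard keeps exact integer
# distances (e.g. 6.0) out of the next bin under floating-point jitter.
_CEIL_EPS = 1e-9


class ProximityClass(Enum):
    OVER_VESSEL = "over_vessel"
    NEAR_1_3 = "near_1_3"
    MID_4_6 = "mid_4_6"
    FAR_GE7 = "far_ge7"


@dataclass(frozen=True)
class DistanceField:
    """Per-pixel Euclidean distance (pixels) to the nearest vessel pixel."""

    distance: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.distance, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("distance field must be 2D")
        if arr.size and arr.min() < 0:
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "distance", np.ascontiguousarray(arr))

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.distance.shape)  # type: ignore[return-value]


def compute_distance_field(vessels: BinaryMask) -> DistanceField:
    """Exact EDT of the stroma with respect to the vessel foreground.

    distance[p] = min over vessel pixels q of ||p - q||; zero exactly on
    vessel pixels. Raises :class:`NoVesselError` on an all-stroma mask.
    """
    fg = vessels.foreground
    if not fg.any():
        raise NoVesselError("mask contains no vessel pixel; distance field undefined")
    return DistanceField(distance=ndimage.distance_transform_edt(~fg))


def bin_distance(d: float) -> ProximityClass:
    """Proximity class of a strictly positive distance via the ceiling rule."""
    if d <= 0:
        raise ValueError("bin_distance expects a strictly positive distance")
    b = math.ceil(d - _CEIL_EPS)
    if b <= 3:
        return ProximityClass.NEAR_1_3
    if b <= 6:
        return ProximityClass.MID_4_6
    return ProximityClass.FAR_GE7


def classify_proximity(point: tuple[int, int], field: DistanceField, vessels: BinaryMask) -> ProximityClass:
    """Proximity class of a single in-frame point."""
    r, c = int(point[0]), int(point[1])
    h, w = field.shape
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"point {point} outside frame {field.shape}")
    vessels.require_shape(field.shape, "vessel mask")
    if vessels.foreground[r, c]:
        return ProximityClass.OVER_VESSEL
    return bin_distance(float(field.distance[r, c]))


def classify_proximity_many(rows: np.ndarray, cols: np.ndarray, field: DistanceField,
                            vessels: BinaryMask) -> list[ProximityClass]:
    """Vectorized proximity classification of many points."""
    vessels.require_shape(field.shape, "vessel mask")
    on_vessel = vessels.foreground[rows, cols]
    d = field.distance[rows, cols]
    b = np.ceil(d - _CEIL_EPS).astype(np.int64)
    out: list[ProximityClass] = []
    for v, bi in zip(on_vessel, b):
        if v:
            out.append(ProximityClass.OVER_VESSEL)
        elif bi <= 3:
            out.append(ProximityClass.NEAR_1_3)
        elif bi <= 6:
            out.append(ProximityClass.MID_4_6)
        else:
            out.append(ProximityClass.FAR_GE7)
    return out
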