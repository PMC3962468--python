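"""Classify lesion points against the vessel mask and build per-eye results.

Percent denominators: ``pct_vessel``/``pct_stroma`` are percentages of the
included (post-exclusion) points; the stroma proximity-bin percentages are
percentages of the stroma points only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .distance_field import (DistanceField, ProximityClass, classify_proximity_many,
                             compute_distance_field)
from .errors import EyeAnalysisError, ShapeMismatchError
from .imaging_io import BinaryMask, GrayscaleImage, PointMap
from .null_model import NullSpec, generate_control_points
from .preprocess import (AnalysisConfig, binarize_vessels, build_analysis_region,
                         extract_lesion_points, filter_points_by_region)


@dataclass(frozen=True)
class PointClassification:
    """Counts and per-point classes for one point set against one vessel mask."""

    n: int
    n_vessel: int
    n_stroma: int
    n_near_1_3: int
    n_mid_4_6: int
    n_far_ge7: int
    per_point: tuple[ProximityClass, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if self.n_vessel + self.n_stroma != self.n:
            raise ValueError("vessel + stroma counts must equal total")
        if self.n_near_1_3 + self.n_mid_4_6 + self.n_far_ge7 != self.n_stroma:
            raise ValueError("stroma bin counts must sum to n_stroma")

    @property
    def pct_vessel(self) -> float:
        return 100.0 * self.n_vessel / self.n if self.n else float("nan")

    @property
    def pct_stroma(self) -> float:
        return 100.0 * self.n_stroma / self.n if self.n else float("nan")

    @property
    def pct_near_1_3(self) -> float:
        return 100.0 * self.n_near_1_3 / self.n_stroma if self.n_stroma else float("nan")

    @property
    def pct_mid_4_6(self) -> float:
        return 100.0 * self.n_mid_4_6 / self.n_stroma if self.n_stroma else float("nan")

    @property
    def pct_far_ge7(self) -> float:
        return 100.0 * self.n_far_ge7 / self.n_stroma if self.n_stroma else float("nan")

    def to_dict(self) -> dict[str, Any]:
        return {
            "n": self.n,
            "n_vessel": self.n_vessel,
            "n_stroma": self.n_stroma,
            "pct_vessel": self.pct_vessel,
            "pct_stroma": self.pct_stroma,
            "stroma_bins": {
                "near_1_3": {"count": self.n_near_1_3, "pct": self.pct_near_1_3},
                "mid_4_6": {"count": self.n_mid_4_6, "pct": self.pct_mid_4_6},
                "far_ge7": {"count": self.n_far_ge7, "pct": self.pct_far_ge7},
            },
        }


def classify_points(points: PointMap, vessels: BinaryMask,
                    fld: DistanceField | None = None) -> PointClassification:
    """Classify each point as on-vessel or into a stroma proximity bin.

    A point counts as vessel iff its pixel is vessel foreground — equivalent
    to multiplying the value-1 lesion raster by the 255/0 vessel map and
    counting 255s (see :func:`classify_points_multiply`). The distance field
    is computed on demand if not supplied.
    """
    vessels.require_shape(points.frame_shape, "vessel mask")
    if len(points) == 0:
        return PointClassification(0, 0, 0, 0, 0, 0, ())
    if fld is None:
        fld = compute_distance_field(vessels)
    classes = classify_proximity_many(points.rows, points.cols, fld, vessels)
    counts = {cls: 0 for cls in ProximityClass}
    for c in classes:
        counts[c] += 1
    n_vessel = counts[ProximityClass.OVER_VESSEL]
    return PointClassification(
        n=len(points),
        n_vessel=n_vessel,
        n_stroma=len(points) - n_vessel,
        n_near_1_3=counts[ProximityClass.NEAR_1_3],
        n_mid_4_6=counts[ProximityClass.MID_4_6],
        n_far_ge7=counts[ProximityClass.FAR_GE7],
        per_point=tuple(classes),
    )


def classify_points_multiply(points: PointMap, vessels: BinaryMask) -> tuple[int, int]:
    """On-vessel count via the raster route: rasterize points at value 1,
    multiply by the 255/0 vessel map, histogram the 255s.

    Independent of the coordinate-lookup route in :func:`classify_points`;
    both are kept so they can be cross-checked.
    """
    vessels.require_shape(points.frame_shape, "vessel mask")
    lesion_raster = np.zeros(points.frame_shape, dtype=np.int64)
    if len(points):
        lesion_raster[points.rows, points.cols] = 1
    vessel_raster = np.where(vessels.foreground, 255, 0).astype(np.int64)
    product = lesion_raster * vessel_raster
    n_vessel = int(np.count_nonzero(product == 255))
    return n_vessel, len(points) - n_vessel


@dataclass(frozen=True)
class EyeResult:
    """Everything measured on one eye: observed lesions plus matched control."""

    eye_id: str
    n_marked: int
    n_excluded: int
    n_included: int
    observed: PointClassification
    control: PointClassification
    vessel_area_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_included != self.n_marked - self.n_excluded:
            raise ValueError("n_included must equal n_marked - n_excluded")
        if self.observed.n != self.n_included:
            raise ValueError("observed classification count must equal n_included")
        if self.control.n != self.n_included:
            raise ValueError("control set must be count-matched to the observed set")
        if not 0.0 <= self.vessel_area_fraction <= 1.0:
            raise ValueError("vessel_area_fraction must be in [0, 1]")

    # Convenience passthroughs for the primary (observed) counts.
    @property
    def n_vessel(self) -> int:
        return self.observed.n_vessel

    @property
    def n_stroma(self) -> int:
        return self.observed.n_stroma

    @property
    def pct_vessel(self) -> float:
        return self.observed.pct_vessel

    @property
    def pct_stroma(self) -> float:
        return self.observed.pct_stroma

    def to_dict(self) -> dict[str, Any]:
        return {
            "eye_id": self.eye_id,
            "n_marked": self.n_marked,
            "n_excluded": self.n_excluded,
            "n_included": self.n_included,
            "vessel_area_fraction": self.vessel_area_fraction,
            "seed": self.seed,
            "observed": self.observed.to_dict(),
            "control": self.control.to_dict(),
        }


def analyze_eye(eye_id: str, marked: GrayscaleImage, cscan: GrayscaleImage,
                exclusion: BinaryMask | None, config: AnalysisConfig | None,
                seed: int) -> EyeResult:
    """Run the full per-eye chain, deterministically given ``seed``.

    extract marks -> build region -> filter points -> binarize vessels
    (restricted to the region) -> distance-bin -> generate and classify the
    count-matched uniform control. Raises :class:`EyeAnalysisError` on an
    empty region, an all-stroma mask, or zero included points.
    """
    config = config or AnalysisConfig()
    if marked.shape != cscan.shape:
        raise ShapeMismatchError(f"marked {marked.shape} vs cscan {cscan.shape}")

    points = extract_lesion_points(marked, config)
    region = build_analysis_region(cscan, exclusion)
    if region.n_foreground == 0:
        raise EyeAnalysisError(f"{eye_id}: analysis region is empty")
    kept, n_excluded = filter_points_by_region(points, region)
    if len(kept) == 0:
        raise EyeAnalysisError(f"{eye_id}: no lesion points inside the analysis region")

    vessels_raw = binarize_vessels(cscan, config)
    # Excluded areas are neither vessel nor stroma; drop them from the map.
    vessels = BinaryMask(foreground=vessels_raw.foreground & region.foreground,
                         semantics="vessel")
    if vessels.n_foreground == 0:
        raise EyeAnalysisError(f"{eye_id}: no vessel pixels inside the analysis region")

    fld = compute_distance_field(vessels)
    observed = classify_points(kept, vessels, fld)
    control_pts = generate_control_points(NullSpec(n_points=len(kept), region=region, seed=seed))
    control = classify_points(control_pts, vessels, fld)
    vessel_area_fraction = vessels.n_foreground / region.n_foreground

    return EyeResult(eye_id=eye_id, n_marked=len(points), n_excluded=n_excluded,
                     n_included=len(kept), observed=observed, control=control,
                     vessel_area_fraction=vessel_area_fraction, seed=seed)
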