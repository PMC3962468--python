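"""From raw rasters to analysis-ready objects.

Two jobs: turn a marked infrared image into one point per lesion mark, and
turn an en face C-scan into a binary vessel mask with artifact regions
(retinal-vessel shadows) excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ShapeMismatchError
from .imaging_io import BinaryMask, GrayscaleImage, PointMap

log = logging.getLogger(__name__)

#: Intensity threshold separating choroidal vessels from stroma on the C-scan.
DEFAULT_VESSEL_THRESHOLD = 60


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the per-eye analysis.

    vessel_threshold
        C-scan intensity cut; a pixel is vessel iff intensity <= threshold
        when ``vessel_is_dark`` (the en face convention: vessels are
        hyporeflective), else >= threshold. Default 60.
    mark_threshold
        Intensity cut isolating lesion paint marks on the marked IR image.
    min_mark_area
        Smallest connected mark (in pixels) that counts as a lesion.
    connectivity
        4 or 8; neighbor rule for grouping mark pixels into one lesion.
    """

    vessel_threshold: int = DEFAULT_VESSEL_THRESHOLD
    mark_threshold: int = 128
    min_mark_area: int = 1
    vessel_is_dark: bool = True
    marks_are_bright: bool = True
    connectivity: int = 8

    def __post_init__(self) -> None:
        for name in ("vessel_threshold", "mark_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if self.min_mark_area < 1:
            raise ValueError("min_mark_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def binarize_vessels(cscan: GrayscaleImage, config: AnalysisConfig | None = None) -> BinaryMask:
    """Threshold the C-scan into a vessel/stroma map.

    Vessel iff intensity <= ``vessel_threshold`` (inclusive) when vessels are
    dark, mirroring thresholding "at" a value that selects the dark lumen.
    """
    config = config or AnalysisConfig()
    if config.vessel_is_dark:
        fg = cscan.pixels <= config.vessel_threshold
    else:
        fg = cscan.pixels >= config.vessel_threshold
    n = int(fg.sum())
    if n == 0 or n == fg.size:
        log.warning("degenerate vessel mask: %s of %s pixels are vessel", n, fg.size)
    return BinaryMask(foreground=fg, semantics="vessel")


def build_analysis_region(image: GrayscaleImage, exclusion: BinaryMask | None = None) -> BinaryMask:
    """Full frame minus the exclusion foreground (whole frame if none given)."""
    region = np.ones(image.shape, dtype=bool)
    if exclusion is not None:
        exclusion.require_shape(image.shape, "exclusion mask")
        region &= ~exclusion.foreground
    if not region.any():
        log.error("analysis region is empty; downstream per-eye analysis will fail")
    return BinaryMask(foreground=region, semantics="analysis_region")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # Coordinates are nonnegative, so half-away-from-zero == floor(x + 0.5).
    return np.floor(x + 0.5).astype(np.int64)


def extract_lesion_points(marked: GrayscaleImage, config: AnalysisConfig | None = None) -> PointMap:
    """One point per connected paint mark: the component centroid, rounded.

    Marks are isolated by thresholding at ``mark_threshold`` (bright marks by
    default), grouped with 4- or 8-connectivity, filtered by
    ``min_mark_area``, and reduced to their centroid rounded
    half-away-from-zero to an integer pixel (clamped inside the frame).
    """
    config = config or AnalysisConfig()
    if config.marks_are_bright:
        binary = marked.pixels >= config.mark_threshold
    else:
        binary = marked.pixels <= config.mark_threshold
    structure = ndimage.generate_binary_structure(2, 2 if config.connectivity == 8 else 1)
    labels, n_comp = ndimage.label(binary, structure=structure)
    if n_comp == 0:
        log.warning("no lesion marks found on marked image")
        return PointMap(points=np.empty((0, 2), dtype=np.int64),
                        frame_height=marked.height, frame_width=marked.width, label="observed")
    ids = np.arange(1, n_comp + 1)
    areas = ndimage.sum_labels(binary, labels, ids)
    keep = ids[areas >= config.min_mark_area]
    if keep.size == 0:
        log.warning("all %d mark components below min_mark_area=%d", n_comp, config.min_mark_area)
        return PointMap(points=np.empty((0, 2), dtype=np.int64),
                        frame_height=marked.height, frame_width=marked.width, label="observed")
    centroids = np.array(ndimage.center_of_mass(binary, labels, keep), dtype=float)
    pts = _round_half_away(centroids)
    pts[:, 0] = np.clip(pts[:, 0], 0, marked.height - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, marked.width - 1)
    pts = np.unique(pts, axis=0)  # merged centroids after rounding collapse to one lesion
    return PointMap(points=pts, frame_height=marked.height, frame_width=marked.width, label="observed")


def filter_points_by_region(points: PointMap, region: BinaryMask) -> tuple[PointMap, int]:
    """Keep points whose pixel lies inside the analysis region.

    Returns the kept PointMap and the number excluded;
    ``len(kept) + n_excluded == len(points)`` always.
    """
    region.require_shape(points.frame_shape, "analysis region")
    if len(points) == 0:
        return points, 0
    inside = region.foreground[points.rows, points.cols]
    kept = PointMap(points=points.points[inside], frame_height=points.frame_height,
                    frame_width=points.frame_width, label=points.label)
    n_excluded = int((~inside).sum())
    log.info("region filter: %d kept, %d excluded of %d", len(kept), n_excluded, len(points))
    return kept, n_excluded
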