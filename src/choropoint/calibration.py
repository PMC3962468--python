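"""Scan-protocol geometry: native pixel spacings and exported-raster scale."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple


class PixelSpacing(NamedTuple):
    horizontal_um: float
    vertical_um: float
    axial_um: float


@dataclass(frozen=True)
class CubeGeometry:
    """Physical extent and sampling counts of an OCT macular cube, plus the
    pixel dimensions of its exported en face raster (default 600 x 600 over
    a 6 x 6 mm field)."""

    physical_width_um: float = 6000.0
    physical_height_um: float = 6000.0
    physical_depth_um: float = 2000.0
    a_scans_per_b: int = 512
    b_scans: int = 128
    samples_per_a_scan: int = 1024
    export_width_px: int = 600
    export_height_px: int = 600

    def __post_init__(self) -> None:
        for name in ("physical_width_um", "physical_height_um", "physical_depth_um",
                     "a_scans_per_b", "b_scans", "samples_per_a_scan",
                     "export_width_px", "export_height_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def native_pixel_spacing(geom: CubeGeometry) -> PixelSpacing:
    """Raw native spacings in microns: physical extent over sample count per axis.

    Returns unrounded floats; round at display time (the conventional report
    uses one decimal).
    """
    return PixelSpacing(
        horizontal_um=geom.physical_width_um / geom.a_scans_per_b,
        vertical_um=geom.physical_height_um / geom.b_scans,
        axial_um=geom.physical_depth_um / geom.samples_per_a_scan,
    )


def export_pixel_size(geom: CubeGeometry) -> float:
    """Microns per pixel of the exported en face raster (width / export width)."""
    return geom.physical_width_um / geom.export_width_px


def pixels_to_microns(d: float, scale: float) -> float:
    """Convert a pixel distance to microns at ``scale`` μm/pixel."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return d * scale


def microns_to_pixels(d_um: float, scale: float) -> float:
    """Inverse of :func:`pixels_to_microns`."""
    if d_um < 0:
        raise ValueError("distance must be nonnegative")
    return d_um / scale
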