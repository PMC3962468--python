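"""Count-matched random control point sets — the chance baseline.

Controls are sampled uniformly from the analysis region (retinal-vessel
artifact areas excluded), matching the exclusion applied to observed
lesions so the comparison is like-for-like. Default is sampling without
replacement: two lesions cannot share a pixel in single-point maps, so the
null honors the same constraint. ``allow_collisions=True`` mimics raw
noise-dot behavior for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapacityError
from .imaging_io import BinaryMask, PointMap


@dataclass(frozen=True)
class NullSpec:
    n_points: int
    region: BinaryMask
    seed: int
    allow_collisions: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")
        if self.region.semantics != "analysis_region":
            raise ValueError("region must carry analysis_region semantics")
        if not self.allow_collisions and self.n_points > self.region.n_foreground:
            raise CapacityError(
                f"cannot place {self.n_points} distinct points in a region of "
                f"{self.region.n_foreground} pixels")


def generate_control_points(spec: NullSpec) -> PointMap:
    """Draw ``n_points`` region pixels uniformly at random; seeded, reproducible."""
    rng = np.random.default_rng(spec.seed)
    flat = np.flatnonzero(spec.region.foreground)
    if spec.allow_collisions:
        # may produce duplicate sites; collapse them (PointMap requires unique points)
        chosen = np.unique(rng.choice(flat, size=spec.n_points, replace=True))
    else:
        chosen = rng.choice(flat, size=spec.n_points, replace=False, shuffle=False)
    h, w = spec.region.shape
    rows, cols = np.divmod(chosen, w)
    pts = np.column_stack([rows, cols])
    return PointMap(points=pts, frame_height=h, frame_width=w, label="control")
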