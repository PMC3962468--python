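"""Synthetic eyes: vessel-network C-scans, exclusion masks, lesion point sets
with tunable vessel affinity, and marked-IR rasters.

The lesion placement model is deliberately the simplest two-parameter family
whose null is exactly uniform: each analysis-region pixel p gets weight

    w(p) = 1 + affinity * exp(-d(p) / decay_lambda)

where d(p) is the Euclidean distance to the nearest vessel pixel (0 on
vessels). affinity = 0 is the uniform null; affinity -> inf concentrates all
lesions on vessels. The closed-form expected on-vessel fraction
(sum of w over vessel pixels / sum over region) is exposed for testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import CapacityError, GenerationError
from .imaging_io import (BinaryMask, GrayscaleImage, PointMap, write_grayscale,
                         write_mask, write_points_csv)

_MARK_BACKGROUND = 60
_MARK_VALUE = 255
#: minimum Chebyshev distance between lesion centers so 2x2 paint blobs
#: never touch under 8-connectivity
MARK_SEPARATION_PX = 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic eye. Defaults mirror the real-data scale:
    600 x 600 export, ~0.45 vessel area fraction, ~400 lesions per eye."""

    height: int = 600
    width: int = 600
    target_vessel_fraction: float = 0.45
    vessel_fraction_tol: float = 0.05
    vessel_width_px: tuple[int, int] = (5, 25)
    vessel_intensity: tuple[int, int] = (10, 50)
    stroma_intensity: tuple[int, int] = (120, 200)
    noise_sd: float = 8.0
    n_lesions: int = 400
    affinity: float = 0.0
    decay_lambda: float = 3.0
    min_separation_px: int = MARK_SEPARATION_PX
    exclusion_n_strips: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("frame must be at least 8x8")
        if not 0.0 < self.target_vessel_fraction < 1.0:
            raise ValueError("target_vessel_fraction must be in (0, 1)")
        for lo, hi in (self.vessel_intensity, self.stroma_intensity):
            if not (0 <= lo <= hi <= 255):
                raise ValueError("intensity ranges must be ordered within [0, 255]")
        # vessel range must sit clearly below stroma range so thresholding works
        if self.vessel_intensity[1] >= self.stroma_intensity[0]:
            raise ValueError("vessel intensities must lie entirely below stroma intensities")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.affinity < 0:
            raise ValueError("affinity must be >= 0")
        if self.decay_lambda <= 0:
            raise ValueError("decay_lambda must be > 0")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px must be >= 0")


@dataclass(frozen=True)
class SyntheticEye:
    cscan: GrayscaleImage
    truth_vessel_mask: BinaryMask
    exclusion: BinaryMask
    lesions: PointMap
    marked_ir: GrayscaleImage
    spec: SyntheticSpec


def _stroke_tube(canvas: np.ndarray, rng: np.random.Generator,
                 width_range: tuple[int, int]) -> None:
    """Stroke one random-walk centerline with a round brush onto ``canvas``."""
    h, w = canvas.shape
    width = int(rng.integers(width_range[0], width_range[1] + 1))
    radius = max(width / 2.0, 0.5)
    length = int(rng.integers((h + w) // 2, (h + w) * 2))
    r = float(rng.uniform(0, h))
    c = float(rng.uniform(0, w))
    theta = float(rng.uniform(0, 2 * math.pi))
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    step = max(radius / 2.0, 1.0)
    for _ in range(int(length / step)):
        r0, r1 = int(max(0, r - radius - 1)), int(min(h, r + radius + 2))
        c0, c1 = int(max(0, c - radius - 1)), int(min(w, c + radius + 2))
        if r0 < r1 and c0 < c1:
            dr = rr[r0:r1] - r
            dc = cc[:, c0:c1] - c
            canvas[r0:r1, c0:c1] |= (dr * dr + dc * dc) <= radius * radius
        theta += float(rng.normal(0, 0.25))  # bounded curvature
        r += step * math.sin(theta)
        c += step * math.cos(theta)
        if not (-radius < r < h + radius and -radius < c < w + radius):
            break


def generate_vessel_image(spec: SyntheticSpec,
                          max_attempts: int = 20) -> tuple[GrayscaleImage, BinaryMask]:
    """Render a dark tubular vessel network on a brighter stroma background.

    Tubes are added until the vessel area fraction reaches the target; the
    whole draw is retried (with a derived sub-seed) if it overshoots the
    tolerance. Returns the noisy image and the exact ground-truth mask.
    """
    base_rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    for attempt in range(max_attempts):
        rng = np.random.default_rng(base_rng.integers(2**63))
        truth = np.zeros((h, w), dtype=bool)
        for _ in range(10_000):
            if truth.mean() >= spec.target_vessel_fraction:
                break
            _stroke_tube(truth, rng, spec.vessel_width_px)
        frac = truth.mean()
        if abs(frac - spec.target_vessel_fraction) <= spec.vessel_fraction_tol:
            stroma_level = rng.integers(spec.stroma_intensity[0], spec.stroma_intensity[1] + 1)
            vessel_level = rng.integers(spec.vessel_intensity[0], spec.vessel_intensity[1] + 1)
            img = np.full((h, w), stroma_level, dtype=float)
            img[truth] = vessel_level
            if spec.noise_sd > 0:
                img += rng.normal(0, spec.noise_sd, size=img.shape)
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            return (GrayscaleImage(pixels=img),
                    BinaryMask(foreground=truth, semantics="vessel"))
    raise GenerationError(
        f"could not reach vessel fraction {spec.target_vessel_fraction} "
        f"± {spec.vessel_fraction_tol} in {max_attempts} attempts")


def generate_exclusion_mask(spec: SyntheticSpec) -> BinaryMask:
    """Wavy vertical strips mimicking retinal-vessel shadow artifacts (~5% area)."""
    rng = np.random.default_rng(spec.seed + 0x5EED)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.exclusion_n_strips):
        x = float(rng.uniform(0.1 * w, 0.9 * w))
        half = float(rng.uniform(0.006, 0.012)) * w + 1.5
        drift = rng.normal(0, 0.6, size=h).cumsum()
        centers = x + drift - drift.mean()
        lo = np.clip(np.floor(centers - half), 0, w).astype(int)
        hi = np.clip(np.ceil(centers + half), 0, w).astype(int)
        for r in range(h):
            mask[r, lo[r]:hi[r]] = True
    return BinaryMask(foreground=mask, semantics="exclusion")


def lesion_weight_field(truth: BinaryMask, affinity: float, decay_lambda: float) -> np.ndarray:
    """Per-pixel sampling weight w = 1 + affinity * exp(-d / lambda)."""
    if truth.foreground.any():
        d = ndimage.distance_transform_edt(~truth.foreground)
    else:
        d = np.full(truth.shape, np.inf)
    return 1.0 + affinity * np.exp(-d / decay_lambda)


def expected_on_vessel_fraction(truth: BinaryMask, region: BinaryMask,
                                affinity: float, decay_lambda: float) -> float:
    """Closed-form expected fraction of lesions on vessel pixels:
    sum of weights over vessel-and-region pixels over the region total."""
    region.require_shape(truth.shape, "analysis region")
    w = lesion_weight_field(truth, affinity, decay_lambda)
    reg = region.foreground
    total = w[reg].sum()
    if total == 0:
        raise ValueError("empty analysis region")
    return float(w[reg & truth.foreground].sum() / total)


def generate_lesions(truth: BinaryMask, region: BinaryMask, spec: SyntheticSpec) -> PointMap:
    """Sample ``n_lesions`` distinct region pixels with vessel-affine weights.

    Weighted sampling without replacement via Gumbel-perturbed log-weights;
    when ``min_separation_px`` > 0, candidates are accepted greedily in key
    order subject to a Chebyshev-distance separation so paint blobs cannot
    merge. Reproducible from ``spec.seed``.
    """
    region.require_shape(truth.shape, "analysis region")
    n = spec.n_lesions
    flat = np.flatnonzero(region.foreground)
    if n > flat.size:
        raise CapacityError(f"{n} lesions requested but region has {flat.size} pixels")
    rng = np.random.default_rng(spec.seed + 0x1E510)
    w = lesion_weight_field(truth, spec.affinity, spec.decay_lambda).ravel()[flat]
    keys = np.log(w) + rng.gumbel(size=flat.size)
    h, wid = truth.shape
    sep = spec.min_separation_px
    if sep <= 1:
        top = np.argpartition(keys, -n)[-n:]
        chosen = flat[top]
    else:
        order = np.argsort(keys)[::-1]
        taken = np.zeros((h, wid), dtype=bool)
        chosen_list: list[int] = []
        for idx in flat[order]:
            r, c = divmod(int(idx), wid)
            r0, r1 = max(0, r - sep + 1), min(h, r + sep)
            c0, c1 = max(0, c - sep + 1), min(wid, c + sep)
            if taken[r0:r1, c0:c1].any():
                continue
            taken[r, c] = True
            chosen_list.append(idx)
            if len(chosen_list) == n:
                break
        if len(chosen_list) < n:
            raise GenerationError(
                f"separation {sep} px admits only {len(chosen_list)} of {n} lesions")
        chosen = np.asarray(chosen_list)
    rows, cols = np.divmod(chosen, wid)
    return PointMap(points=np.column_stack([rows, cols]), frame_height=h,
                    frame_width=wid, label="observed")


def generate_marked_ir(lesions: PointMap, spec: SyntheticSpec) -> GrayscaleImage:
    """Render the grader's marks: a bright 2x2 blob per lesion on mid-gray.

    The blob covers rows [r-1, r] and cols [c-1, c] (clipped at the frame),
    so its centroid rounds back to (r, c) exactly. Raises
    :class:`GenerationError` if two lesion centers are closer than the
    3-pixel Chebyshev separation that keeps blobs disjoint.
    """
    h, w = lesions.frame_height, lesions.frame_width
    img = np.full((h, w), _MARK_BACKGROUND, dtype=np.uint8)
    occupied = np.zeros((h, w), dtype=bool)
    for r, c in lesions.points:
        r, c = int(r), int(c)
        r0, r1 = max(0, r - MARK_SEPARATION_PX + 1), min(h, r + MARK_SEPARATION_PX)
        c0, c1 = max(0, c - MARK_SEPARATION_PX + 1), min(w, c + MARK_SEPARATION_PX)
        if occupied[r0:r1, c0:c1].any():
            raise GenerationError(
                f"lesion at ({r}, {c}) is within {MARK_SEPARATION_PX} px of another; "
                "2x2 marks would merge")
        occupied[r, c] = True
        img[max(0, r - 1):r + 1, max(0, c - 1):c + 1] = _MARK_VALUE
    return GrayscaleImage(pixels=img)


def generate_eye(spec: SyntheticSpec) -> SyntheticEye:
    """Generate one complete synthetic eye from one spec."""
    cscan, truth = generate_vessel_image(spec)
    exclusion = generate_exclusion_mask(spec)
    region = BinaryMask(foreground=~exclusion.foreground, semantics="analysis_region")
    lesions = generate_lesions(truth, region, spec)
    marked_ir = generate_marked_ir(lesions, spec)
    return SyntheticEye(cscan=cscan, truth_vessel_mask=truth, exclusion=exclusion,
                        lesions=lesions, marked_ir=marked_ir, spec=spec)


# Cohort scale constants emulating the study population: ~414 lesions per
# eye with a reported spread of 71.5 (SEM over 17 eyes -> SD ~ 71.5 * sqrt(17)).
COHORT_MEAN_LESIONS = 414
COHORT_LESION_SD = 71.5 * math.sqrt(17)


def generate_cohort(n_eyes: int, spec_template: SyntheticSpec, seed: int) -> list[SyntheticEye]:
    """Generate a cohort of eyes with jittered per-eye specs.

    Per-eye lesion counts are drawn around the template's ``n_lesions``
    (scaled spread, floored at 60 so eyes pass the >= 50 inclusion rule) and
    vessel fractions jittered by ±0.03; every eye gets its own seed derived
    from the master seed, so cohorts are byte-reproducible.
    """
    if n_eyes < 2:
        raise ValueError("a cohort needs at least 2 eyes")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_eyes)]
    sd = COHORT_LESION_SD * spec_template.n_lesions / COHORT_MEAN_LESIONS
    eyes = []
    for eye_seed in child_seeds:
        n = int(np.clip(round(rng.normal(spec_template.n_lesions, sd)), 60,
                        spec_template.height * spec_template.width // 20))
        frac = float(np.clip(spec_template.target_vessel_fraction + rng.uniform(-0.03, 0.03),
                             0.05, 0.9))
        eyes.append(generate_eye(replace(spec_template, n_lesions=n,
                                         target_vessel_fraction=frac, seed=eye_seed)))
    return eyes


def write_eye(eye: SyntheticEye, out_dir: str | Path) -> None:
    """Write one eye's artifacts (PNG rasters, lesion CSV, spec JSON) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_grayscale(eye.cscan, out / "cscan.png")
    write_mask(eye.truth_vessel_mask, out / "truth.png")
    write_mask(eye.exclusion, out / "exclusion.png")
    write_grayscale(eye.marked_ir, out / "marked_ir.png")
    write_points_csv(eye.lesions, out / "lesions.csv")
    with open(out / "spec.json", "w") as fh:
        json.dump(asdict(eye.spec), fh, indent=2)
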