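import numpy as np
import pytest

from choropoint.distance_field import compute_distance_field
from choropoint.imaging_io import BinaryMask
from choropoint.synthetic_data import SyntheticSpec, generate_eye


@pytest.fixture(scope="session")
def small_eye():
    """One deterministic 200x200 synthetic eye used by several suites."""
    spec = SyntheticSpec(height=200, width=200, n_lesions=150, seed=11, noise_sd=0.0)
    return generate_eye(spec)


@pytest.fixture(scope="session")
def sim_eyes():
    """17 small precomputed (region, vessels, field) triples for cohort simulations."""
    eyes = []
    for i in range(17):
        spec = SyntheticSpec(height=120, width=120, n_lesions=60, seed=500 + i,
                             target_vessel_fraction=0.38 + 0.015 * (i % 5), noise_sd=0.0)
        eye = generate_eye(spec)
        region = BinaryMask(foreground=~eye.exclusion.foreground, semantics="analysis_region")
        vessels = BinaryMask(foreground=eye.truth_vessel_mask.foreground & region.foreground,
                             semantics="vessel")
        eyes.append((region, vessels, compute_distance_field(vessels)))
    return eyes


def simulate_cohort(sim_eyes, rng, n_lesions=400, affinity=0.0, decay_lambda=3.0):
    """One simulated cohort over precomputed eyes: per-eye observed (lesion
    generator at the given affinity) and count-matched uniform control
    classifications, via the package's own sampling and classification."""
    from choropoint.colocalization import classify_points
    from choropoint.null_model import NullSpec, generate_control_points
    from choropoint.synthetic_data import SyntheticSpec, generate_lesions

    obs, ctl = [], []
    for region, vessels, fld in sim_eyes:
        s1, s2 = (int(s) for s in rng.integers(2**31, size=2))
        h, w = region.shape
        spec = SyntheticSpec(height=h, width=w, n_lesions=n_lesions, affinity=affinity,
                             decay_lambda=decay_lambda, min_separation_px=0, seed=s1)
        lesions = generate_lesions(vessels, region, spec)
        controls = generate_control_points(NullSpec(n_points=n_lesions, region=region, seed=s2))
        obs.append(classify_points(lesions, vessels, fld))
        ctl.append(classify_points(controls, vessels, fld))
    return obs, ctl


def brute_force_distance(foreground: np.ndarray) -> np.ndarray:
    """O(N*M) exhaustive nearest-vessel-pixel Euclidean distance oracle."""
    h, w = foreground.shape
    vr, vc = np.nonzero(foreground)
    assert vr.size > 0
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d2 = ((rr[..., None] - vr) ** 2 + (cc[..., None] - vc) ** 2).min(axis=-1)
    return np.sqrt(d2.astype(float))
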