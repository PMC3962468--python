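import numpy as np
import pytest
from scipy import stats

from choropoint.cohort_stats import paired_one_tailed_t
from choropoint.errors import CapacityError, GenerationError
from choropoint.imaging_io import BinaryMask, PointMap
from choropoint.preprocess import AnalysisConfig, binarize_vessels, extract_lesion_points
from choropoint.synthetic_data import (SyntheticSpec, expected_on_vessel_fraction,
                                       generate_cohort, generate_exclusion_mask,
                                       generate_eye, generate_lesions, generate_marked_ir,
                                       generate_vessel_image, lesion_weight_field)

from .conftest import simulate_cohort


def full_region(h, w):
    return BinaryMask(foreground=np.ones((h, w), bool), semantics="analysis_region")


class TestGenerateVesselImage:
    def test_fraction_within_tolerance(self):
        spec = SyntheticSpec(height=300, width=300, seed=1)
        _, truth = generate_vessel_image(spec)
        assert abs(truth.foreground.mean() - 0.45) <= 0.05

    def test_noiseless_threshold_recovers_truth_exactly(self):
        spec = SyntheticSpec(height=300, width=300, noise_sd=0.0, seed=2)
        cscan, truth = generate_vessel_image(spec)
        mask = binarize_vessels(cscan, AnalysisConfig(vessel_threshold=60))
        np.testing.assert_array_equal(mask.foreground, truth.foreground)

    def test_determinism(self):
        spec = SyntheticSpec(height=200, width=200, seed=3)
        a_img, a_truth = generate_vessel_image(spec)
        b_img, b_truth = generate_vessel_image(spec)
        np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
        np.testing.assert_array_equal(a_truth.foreground, b_truth.foreground)

    def test_invalid_intensity_ranges_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(vessel_intensity=(10, 150), stroma_intensity=(120, 200))


class TestExclusionMask:
    def test_area_fraction_modest(self):
        excl = generate_exclusion_mask(SyntheticSpec(height=300, width=300, seed=4))
        assert 0.0 < excl.foreground.mean() < 0.15

    def test_determinism(self):
        spec = SyntheticSpec(height=200, width=200, seed=5)
        np.testing.assert_array_equal(generate_exclusion_mask(spec).foreground,
                                      generate_exclusion_mask(spec).foreground)


@pytest.fixture(scope="module")
def truth300():
    spec = SyntheticSpec(height=300, width=300, noise_sd=0.0, seed=6)
    _, truth = generate_vessel_image(spec)
    return truth


class TestGenerateLesions:
    def test_lesions_inside_region(self, truth300):
        excl = generate_exclusion_mask(SyntheticSpec(height=300, width=300, seed=6))
        region = BinaryMask(foreground=~excl.foreground, semantics="analysis_region")
        spec = SyntheticSpec(height=300, width=300, n_lesions=500, seed=7)
        pts = generate_lesions(truth300, region, spec)
        assert region.foreground[pts.rows, pts.cols].all()

    def test_affinity_zero_is_uniform(self, truth300):
        region = full_region(300, 300)
        spec = SyntheticSpec(height=300, width=300, n_lesions=5000, affinity=0.0,
                             min_separation_px=0, seed=8)
        pts = generate_lesions(truth300, region, spec)
        f = truth300.foreground.mean()
        got = truth300.foreground[pts.rows, pts.cols].mean()
        se = np.sqrt(f * (1 - f) / 5000)
        assert abs(got - f) < 3 * se

    def test_extreme_affinity_limit_all_on_vessels(self, truth300):
        region = full_region(300, 300)
        # the weight ratio between on-vessel and 1-px-away pixels must dwarf
        # the Gumbel perturbation, hence the tiny decay length
        spec = SyntheticSpec(height=300, width=300, n_lesions=2000, affinity=1e12,
                             decay_lambda=0.05, min_separation_px=0, seed=9)
        pts = generate_lesions(truth300, region, spec)
        assert truth300.foreground[pts.rows, pts.cols].all()

    def test_closed_form_expectation(self, truth300):
        region = full_region(300, 300)
        spec = SyntheticSpec(height=300, width=300, n_lesions=5000, affinity=5.0,
                             decay_lambda=3.0, min_separation_px=0, seed=10)
        pts = generate_lesions(truth300, region, spec)
        expected = expected_on_vessel_fraction(truth300, region, 5.0, 3.0)
        got = truth300.foreground[pts.rows, pts.cols].mean()
        se = np.sqrt(expected * (1 - expected) / 5000)
        assert abs(got - expected) < 3 * se

    def test_weight_field_unit_on_vessels(self, truth300):
        w = lesion_weight_field(truth300, affinity=4.0, decay_lambda=3.0)
        assert w[truth300.foreground] == pytest.approx(5.0)
        assert (w >= 1.0).all()

    def test_capacity_error(self, truth300):
        region = full_region(300, 300)
        with pytest.raises(CapacityError):
            generate_lesions(truth300, region,
                             SyntheticSpec(height=300, width=300, n_lesions=90001, seed=1))

    def test_separation_enforced(self, truth300):
        spec = SyntheticSpec(height=300, width=300, n_lesions=800, seed=11)
        pts = generate_lesions(truth300, full_region(300, 300), spec)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pts.points).query(pts.points, k=2, p=np.inf)
        assert d[:, 1].min() >= 3

    def test_determinism(self, truth300):
        spec = SyntheticSpec(height=300, width=300, n_lesions=400, seed=12)
        a = generate_lesions(truth300, full_region(300, 300), spec)
        b = generate_lesions(truth300, full_region(300, 300), spec)
        np.testing.assert_array_equal(a.points, b.points)


class TestGenerateMarkedIr:
    def test_zero_lesions_background_only(self):
        pm = PointMap(points=np.empty((0, 2)), frame_height=50, frame_width=50)
        img = generate_marked_ir(pm, SyntheticSpec(height=50, width=50))
        assert len(np.unique(img.pixels)) == 1

    @pytest.mark.parametrize("k", [1, 25])
    def test_round_trip_recovers_exact_centers(self, k):
        rng = np.random.default_rng(k)
        spec = SyntheticSpec(height=200, width=200, n_lesions=k, seed=int(rng.integers(1e6)))
        truth = BinaryMask(foreground=np.eye(200, dtype=bool), semantics="vessel")
        pts = generate_lesions(truth, full_region(200, 200), spec)
        img = generate_marked_ir(pts, spec)
        recovered = extract_lesion_points(img)
        assert sorted(map(tuple, recovered.points)) == sorted(map(tuple, pts.points))

    def test_edge_lesions_recovered(self):
        pm = PointMap(points=np.array([[0, 0], [0, 49], [49, 0], [49, 49], [25, 25]]),
                      frame_height=50, frame_width=50)
        img = generate_marked_ir(pm, SyntheticSpec(height=50, width=50))
        recovered = extract_lesion_points(img)
        assert sorted(map(tuple, recovered.points)) == sorted(map(tuple, pm.points))

    def test_close_lesions_rejected(self):
        pm = PointMap(points=np.array([[10, 10], [10, 12]]), frame_height=50, frame_width=50)
        with pytest.raises(GenerationError):
            generate_marked_ir(pm, SyntheticSpec(height=50, width=50))

    def test_determinism(self):
        pm = PointMap(points=np.array([[10, 10], [20, 20]]), frame_height=50, frame_width=50)
        spec = SyntheticSpec(height=50, width=50)
        np.testing.assert_array_equal(generate_marked_ir(pm, spec).pixels,
                                      generate_marked_ir(pm, spec).pixels)


class TestGenerateCohort:
    def test_minimal_cohort(self):
        template = SyntheticSpec(height=120, width=120, n_lesions=80, seed=0)
        eyes = generate_cohort(2, template, seed=1)
        assert len(eyes) == 2

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, SyntheticSpec(), seed=1)

    def test_master_seed_reproducibility(self):
        template = SyntheticSpec(height=120, width=120, n_lesions=80, seed=0)
        a = generate_cohort(3, template, seed=9)
        b = generate_cohort(3, template, seed=9)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.cscan.pixels, eb.cscan.pixels)
            np.testing.assert_array_equal(ea.lesions.points, eb.lesions.points)
        assert a[0].spec.seed != a[1].spec.seed

    def test_lesion_counts_jittered(self):
        template = SyntheticSpec(height=200, width=200, n_lesions=120, seed=0)
        eyes = generate_cohort(5, template, seed=2)
        counts = [len(e.lesions) for e in eyes]
        assert len(set(counts)) > 1
        assert all(c >= 60 for c in counts)


class TestStatisticalSignatures:
    def test_null_p_values_uniform(self, sim_eyes):
        """affinity 0 cohorts: the paired test's p-values look uniform (KS)."""
        rng = np.random.default_rng(314)
        pvals = []
        for _ in range(150):
            obs, ctl = simulate_cohort(sim_eyes[:6], rng, n_lesions=150, affinity=0.0)
            res = paired_one_tailed_t([o.pct_vessel for o in obs],
                                      [c.pct_vessel for c in ctl], "greater")
            pvals.append(res.p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_positive_affinity_signature(self, sim_eyes):
        """Observed near-bin percentage above control, far bin below."""
        rng = np.random.default_rng(42)
        obs, ctl = simulate_cohort(sim_eyes, rng, n_lesions=300, affinity=10.0)
        near_obs = np.mean([o.pct_near_1_3 for o in obs])
        near_ctl = np.mean([c.pct_near_1_3 for c in ctl])
        far_obs = np.mean([o.pct_far_ge7 for o in obs])
        far_ctl = np.mean([c.pct_far_ge7 for c in ctl])
        assert near_obs > near_ctl
        assert far_obs < far_ctl
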