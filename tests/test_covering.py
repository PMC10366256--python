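"""The covering heuristic: penalty weighting, edge selection, axis search,
and the two-phase cover with its envelope guarantees."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from majorload import (Cone, CoverConfig, assign_magnitudes,
                       compute_major_directions, cover, covers,
                       local_candidates, mean_direction, penalty,
                       search_best_axis, select_edge_vector, unit)
from majorload.exceptions import (CoverageViolationError,
                                  DegenerateVectorError, EmptyDatasetError)
from conftest import make_dataset, random_rotation

EZ = np.array([0.0, 0.0, 1.0])


def tilted(angle_deg, azim_deg=0.0):
    """Unit vector tilted from e_z by angle, azimuth in the x-y plane."""
    t, a = np.radians(angle_deg), np.radians(azim_deg)
    return np.array([np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), np.cos(t)])


class TestPenalty:
    def test_edge_itself_has_full_weight(self):
        assert penalty(0.0, 0.1, 6.0) == 1.0

    def test_farthest_point_collapses_to_floor(self):
        assert penalty(1.0, 0.1, 6.0) == 0.1

    def test_midpoint_value(self):
        # 0.1 + 0.9 * 0.5**6 by hand
        assert penalty(0.5, 0.1, 6.0) == pytest.approx(0.1140625, abs=1e-15)

    @pytest.mark.parametrize("d", [-0.1, 1.1])
    def test_domain_error_outside_unit_interval(self, d):
        with pytest.raises(ValueError):
            penalty(d, 0.1, 6.0)

    @settings(deadline=None, max_examples=100)
    @given(d=st.floats(0, 1), v_min=st.floats(0.01, 1), p=st.floats(0, 20))
    def test_bounded_between_floor_and_one(self, d, v_min, p):
        v = penalty(d, v_min, p)
        assert v_min - 1e-12 <= v <= 1.0 + 1e-12

    @settings(deadline=None, max_examples=100)
    @given(v_min=st.floats(0.01, 0.99), p=st.floats(0.1, 20),
           d1=st.floats(0, 1), d2=st.floats(0, 1))
    def test_non_increasing_in_distance(self, v_min, p, d1, d2):
        lo, hi = sorted((d1, d2))
        assert penalty(lo, v_min, p) >= penalty(hi, v_min, p) - 1e-12


class TestMeanDirection:
    def test_symmetric_pair_averages_to_bisector(self):
        u = np.array([tilted(5.0, 90.0), tilted(5.0, 270.0)])
        np.testing.assert_allclose(mean_direction(u), EZ, atol=1e-12)

    def test_identical_vectors_reproduce_themselves(self):
        u = np.tile(tilted(30.0), (3, 1))
        np.testing.assert_allclose(mean_direction(u), tilted(30.0), atol=1e-12)

    def test_antipodal_cancellation_is_degenerate(self):
        assert mean_direction(np.array([EZ, -EZ])) is None

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyDatasetError):
            mean_direction(np.empty((0, 3)))


class TestEdgeSelection:
    def test_outlier_is_farthest_from_mean(self, rng):
        cluster = np.array([tilted(rng.uniform(0, 3), rng.uniform(0, 360))
                            for _ in range(10)])
        outlier = tilted(40.0)
        units = np.vstack([cluster, outlier])
        mean = mean_direction(units)
        # brute-force: chord distance to the mean
        expected = int(np.argmax(np.linalg.norm(units - mean, axis=1)))
        assert expected == len(units) - 1
        assert select_edge_vector(units, mean) == expected

    def test_single_vector_is_its_own_edge(self):
        assert select_edge_vector(EZ[None, :], EZ) == 0

    def test_tie_broken_by_lowest_index(self):
        units = np.array([tilted(20.0, 0.0), tilted(20.0, 180.0)])
        assert select_edge_vector(units, EZ) == 0

    def test_degenerate_mean_falls_back_to_largest_magnitude(self):
        units = np.array([EZ, -EZ])
        assert select_edge_vector(units, None, magnitudes=np.array([1.0, 5.0])) == 1
        with pytest.raises(DegenerateVectorError):
            select_edge_vector(units, None)


class TestLocalCandidates:
    def test_two_theta_boundary(self):
        units = np.array([tilted(19.9), tilted(20.1), EZ])
        idx = local_candidates(units, EZ, 10.0)
        assert 0 in idx and 2 in idx and 1 not in idx


class TestSearchBestAxis:
    config = CoverConfig(half_apex_deg=10.0, penalty_exponent=6.0)

    def test_single_local_vector_keeps_edge_as_axis(self):
        cone = search_best_axis(EZ, EZ[None, :], np.zeros(1), self.config,
                                frame_ref=tilted(30.0))
        np.testing.assert_allclose(cone.axis, EZ, atol=1e-12)

    def test_pair_fifteen_degrees_apart_covered_by_one_cone(self):
        a, b = tilted(0.0), tilted(15.0)
        units = np.vstack([a, b])
        d = np.linalg.norm(units - a, axis=1)
        cone = search_best_axis(a, units, d / d.max(), self.config,
                                frame_ref=mean_direction(units))
        assert covers(cone, a) and covers(cone, b)
        # the midpoint axis beats any single-vector cone: its score is the
        # total weight, which is strictly more than either vector alone
        assert cone.axis @ unit(a + b) > np.cos(np.radians(3.0))

    def test_vector_beyond_reach_never_covered(self):
        a, far = tilted(0.0), tilted(25.0)
        units = np.vstack([a, far])
        d = np.linalg.norm(units - a, axis=1)
        cone = search_best_axis(a, units, d / d.max(), self.config,
                                frame_ref=mean_direction(units))
        assert covers(cone, a)
        assert not covers(cone, far)  # tilt + half-apex reach at most 20 deg


class TestComputeMajorDirections:
    def test_identical_vectors_need_one_cone(self):
        ds = make_dataset(np.tile([1.0, 2.0, 2.0], (5, 1)))
        cones = compute_major_directions(ds)
        assert len(cones) == 1
        np.testing.assert_allclose(cones[0].axis, unit(np.array([1.0, 2.0, 2.0])),
                                   atol=1e-12)

    def test_separated_clusters_need_one_cone_each(self, three_cluster_dataset):
        cones = compute_major_directions(three_cluster_dataset)
        assert len(cones) == 3

    def test_all_zero_dataset_rejected(self):
        ds = make_dataset(np.zeros((3, 3)))
        with pytest.raises(EmptyDatasetError):
            compute_major_directions(ds)

    def test_termination_within_sample_count(self, rng):
        ds = make_dataset(rng.normal(size=(40, 3)))
        cones = compute_major_directions(ds, CoverConfig(half_apex_deg=5.0))
        assert len(cones) <= 40


class TestAssignMagnitudes:
    def test_magnitude_is_max_of_covered(self):
        vecs = np.array([tilted(1.0), tilted(3.0), tilted(5.0)])
        vecs = vecs * np.array([500.0, 1200.0, 800.0])[:, None]
        ds = make_dataset(vecs)
        loads = assign_magnitudes([Cone(EZ, 10.0)], ds)
        assert loads[0].magnitude == pytest.approx(1200.0)
        assert loads[0].covered_indices == (0, 1, 2)

    def test_single_covered_sample(self):
        ds = make_dataset([[0.0, 0.0, 321.0]])
        loads = assign_magnitudes([Cone(EZ, 10.0)], ds)
        assert loads[0].magnitude == pytest.approx(321.0)

    def test_uncovered_sample_is_an_error(self):
        ds = make_dataset([[0, 0, 1.0], [1.0, 0, 0]])
        with pytest.raises(CoverageViolationError):
            assign_magnitudes([Cone(EZ, 10.0)], ds)

    def test_cone_covering_nothing_is_an_error(self):
        ds = make_dataset([[0, 0, 1.0]])
        with pytest.raises(CoverageViolationError):
            assign_magnitudes([Cone(EZ, 10.0), Cone(np.array([1.0, 0, 0]), 10.0)], ds)


class TestCoverEndToEnd:
    def test_identical_vector_dataset(self):
        ds = make_dataset(np.tile([0.0, 3.0, 4.0], (4, 1)))
        loads = cover(ds)
        assert len(loads) == 1
        np.testing.assert_allclose(loads[0].force_vector, [0.0, 3.0, 4.0],
                                   atol=1e-12)

    def test_cluster_magnitudes_are_per_cluster_maxima(self, three_cluster_dataset):
        ds = three_cluster_dataset
        loads = cover(ds)
        assert len(loads) == 3
        mags = ds.magnitudes()
        for load in loads:
            assert load.magnitude == pytest.approx(
                mags[list(load.covered_indices)].max())

    def test_deterministic(self):
        from majorload import generate_daily_activity_dataset

        ds = generate_daily_activity_dataset(seed=5, samples_per_activity=40)
        a, b = cover(ds), cover(ds)
        assert len(a) == len(b)
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la.cone.axis, lb.cone.axis)
            assert la.magnitude == lb.magnitude
            assert la.covered_indices == lb.covered_indices

    def test_scale_invariance(self, rng):
        vecs = rng.normal(size=(30, 3)) * rng.uniform(50, 250, (30, 1))
        loads1 = cover(make_dataset(vecs))
        loads2 = cover(make_dataset(vecs * 3.5))
        assert len(loads1) == len(loads2)
        for a, b in zip(loads1, loads2):
            np.testing.assert_allclose(a.cone.axis, b.cone.axis, atol=1e-12)
            assert b.magnitude == pytest.approx(3.5 * a.magnitude, rel=1e-12)

    def test_rotation_equivariance(self, rng):
        """The search grid is anchored to the data (edge and mean), so
        rotating every input rotates every output axis, to 1e-9."""
        from majorload import generate_daily_activity_dataset

        ds = generate_daily_activity_dataset(seed=9, samples_per_activity=60)
        rot = random_rotation(rng)
        ds_rot = make_dataset(ds.vectors() @ rot.T)
        loads, loads_rot = cover(ds), cover(ds_rot)
        assert len(loads) == len(loads_rot)
        for a, b in zip(loads, loads_rot):
            np.testing.assert_allclose(rot @ a.cone.axis, b.cone.axis, atol=1e-9)
            assert b.magnitude == pytest.approx(a.magnitude, rel=1e-9)

    def test_completeness_and_envelope(self, rng):
        from majorload import generate_daily_activity_dataset

        ds = generate_daily_activity_dataset(seed=2, samples_per_activity=50)
        loads = cover(ds)
        vectors, mags = ds.vectors(), ds.magnitudes()
        covered = np.zeros(len(ds), dtype=bool)
        for load in loads:
            inside = covers(load.cone, vectors)
            covered |= inside
            assert load.magnitude >= mags[inside].max() - 1e-9
        assert covered.all()
        assert max(l.magnitude for l in loads) == pytest.approx(mags.max())
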