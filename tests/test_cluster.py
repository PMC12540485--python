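"""Density-peak stay-area clustering: density profile, center selection,
label propagation and recovery of planted spatial structure."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from affectpath.cluster import (
    assign_points,
    cluster_stay_areas,
    compute_density,
    haversine_m,
    select_centers,
)
from affectpath.types import NOISE


def brute_force_assign(pts, rho, nearest_higher, centers):
    """Independent oracle: sort by density, propagate labels downhill."""
    labels = {}
    for area_id, c in enumerate(centers):
        labels[c] = area_id
    order = sorted(range(len(pts)), key=lambda i: (-rho[i], i))
    for i in order:
        if i in labels:
            continue
        labels[i] = labels[nearest_higher[i]]
    return np.array([labels[i] for i in range(len(pts))])


class TestComputeDensity:
    def test_single_point_degenerate(self):
        prof = compute_density(np.array([[121.3, 31.0]]), 500.0)
        assert prof.rho[0] == 0 and prof.delta[0] == 0 and prof.nearest_higher[0] == 0

    def test_two_points_kernel_value(self):
        # two points ~1 km apart, bandwidth 1000 m -> rho = exp(-1) each
        lat_off = 1000.0 / 111_194.93  # one km of latitude on the sphere used
        pts = np.array([[121.3, 31.0], [121.3, 31.0 + lat_off]])
        prof = compute_density(pts, 1000.0)
        d = haversine_m(pts[0, 0], pts[0, 1], pts[1, 0], pts[1, 1])
        assert d == pytest.approx(1000.0, rel=1e-3)
        np.testing.assert_allclose(prof.rho, math.exp(-1.0), rtol=1e-3)
        # tie in rho broken by index: point 0 is "denser"
        assert prof.nearest_higher[0] == 0
        assert prof.nearest_higher[1] == 0

    def test_densest_point_has_max_pairwise_delta(self, rng):
        pts = np.array([121.3, 31.0]) + rng.normal(0, 200, size=(100, 2)) / 111_320.0
        prof = compute_density(pts, 500.0)
        top = prof.density_order()[0]
        dmax = 0.0
        for i in range(len(pts)):
            d = haversine_m(pts[i, 0], pts[i, 1], pts[:, 0], pts[:, 1])
            dmax = max(dmax, d.max())
        assert prof.delta[top] == pytest.approx(dmax, rel=1e-9)

    def test_non_finite_coordinate_errors(self):
        with pytest.raises(ValueError):
            compute_density(np.array([[np.nan, 31.0]]), 500.0)


class TestSelectCenters:
    def test_all_points_when_n_equals_count(self, three_blobs):
        pts, _ = three_blobs
        prof = compute_density(pts[:10], 500.0)
        assert sorted(select_centers(prof, 10)) == list(range(10))

    def test_three_blobs_one_center_each(self, three_blobs):
        pts, truth = three_blobs
        prof = compute_density(pts, 500.0)
        centers = select_centers(prof, 3)
        assert sorted(truth[c] for c in centers) == [0, 1, 2]

    def test_too_many_centers_errors(self):
        prof = compute_density(np.array([[121.3, 31.0], [121.4, 31.0]]), 500.0)
        with pytest.raises(ValueError):
            select_centers(prof, 3)


class TestAssignPoints:
    def test_matches_brute_force_oracle(self, three_blobs):
        pts, _ = three_blobs
        pts = pts[:150]
        prof = compute_density(pts, 500.0)
        centers = select_centers(prof, 4)
        labels = assign_points(prof, centers, noise_quantile=0.0)
        oracle = brute_force_assign(pts, prof.rho, prof.nearest_higher, centers)
        np.testing.assert_array_equal(labels, oracle)

    def test_single_cluster_single_label(self, rng):
        pts = np.array([121.3, 31.0]) + rng.normal(0, 50, size=(40, 2)) / 111_320.0
        prof = compute_density(pts, 500.0)
        labels = assign_points(prof, select_centers(prof, 1))
        assert set(labels) == {0}

    def test_isolated_point_is_noise(self, three_blobs):
        pts, _ = three_blobs
        pts = np.vstack([pts, [[122.0, 31.5]]])  # ~70 km away
        _, labels = cluster_stay_areas(pts, 3, bandwidth=500.0)
        assert labels[-1] == NOISE


class TestClusterStayAreas:
    def test_three_blob_recovery(self, three_blobs):
        pts, truth = three_blobs
        areas, labels = cluster_stay_areas(pts, 3, bandwidth=500.0)
        assert adjusted_rand_score(truth, labels) >= 0.95
        assert sum(a.member_count for a in areas) + (labels == NOISE).sum() == len(pts)

    def test_permutation_invariance(self, three_blobs, rng):
        pts, _ = three_blobs
        _, labels = cluster_stay_areas(pts, 3, bandwidth=500.0)
        perm = rng.permutation(len(pts))
        _, labels_p = cluster_stay_areas(pts[perm], 3, bandwidth=500.0)
        assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)

    def test_operating_range_of_area_counts(self, rng):
        # 600 points spread widely support the 100..500 area range
        pts = np.column_stack([rng.uniform(121.0, 121.9, 600), rng.uniform(30.7, 31.5, 600)])
        for n_areas in (100, 500):
            areas, labels = cluster_stay_areas(pts, n_areas, bandwidth=500.0)
            assert len(areas) == n_areas
            assert labels.max() < n_areas

    def test_n_areas_one_collects_everything(self, rng):
        pts = np.array([121.3, 31.0]) + rng.normal(0, 100, size=(30, 2)) / 111_320.0
        areas, labels = cluster_stay_areas(pts, 1, bandwidth=500.0)
        assert areas[0].member_count == (labels == 0).sum()
        assert set(labels) <= {0, NOISE}

    def test_too_few_distinct_points_errors(self):
        pts = np.array([[121.3, 31.0]] * 5)
        with pytest.raises(ValueError):
            cluster_stay_areas(pts, 2, bandwidth=500.0)
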