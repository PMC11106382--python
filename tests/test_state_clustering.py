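"""L1-assignment k-means, k selection, occupancy, centroid reshaping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcdec.io_config import CohortManifest
from fcdec.state_clustering import (
    StateModel,
    kmeans_l1,
    manhattan_distance,
    occupancy,
    select_k,
    state_centroid_matrices,
    unvectorize_ec,
    vectorize_ec,
)


def blobs(k, n_per, d, sep, seed):
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((k, d)) * sep
    pts = np.vstack([centers[i] + rng.standard_normal((n_per, d)) for i in range(k)])
    labels = np.repeat(np.arange(k), n_per)
    return pts, labels


class TestManhattan:
    def test_coordinate_example(self):
        assert manhattan_distance(np.array([0, 0]), np.array([3, 4])) == 7.0

    def test_identical_vectors_zero(self):
        v = np.array([1.5, -2.0, 3.0])
        assert manhattan_distance(v, v) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            manhattan_distance(np.zeros(2), np.zeros(3))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        u, v, w = rng.standard_normal((3, 5))
        assert manhattan_distance(u, w) <= manhattan_distance(u, v) + manhattan_distance(v, w) + 1e-12


class TestKMeansL1:
    def test_k1_centroid_is_global_mean(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((40, 6))
        model = kmeans_l1(pts, k=1, seed=0, n_restarts=3)
        np.testing.assert_allclose(model.centroids[0], pts.mean(axis=0), atol=1e-12)

    def test_well_separated_blobs_perfectly_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        pts, labels = blobs(2, 50, 8, sep=10.0, seed=1)
        model = kmeans_l1(pts, k=2, seed=2, n_restarts=5)
        assert adjusted_rand_score(labels, model.assignments) == 1.0

    def test_duplicated_dataset_same_centroids(self):
        pts, _ = blobs(2, 30, 5, sep=8.0, seed=3)
        m1 = kmeans_l1(pts, k=2, seed=4, n_restarts=5)
        m2 = kmeans_l1(np.vstack([pts, pts]), k=2, seed=4, n_restarts=5)
        c1 = sorted(map(tuple, np.round(m1.centroids, 9)))
        c2 = sorted(map(tuple, np.round(m2.centroids, 9)))
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_objective_non_increasing_over_iterations(self):
        pts, _ = blobs(3, 40, 6, sep=3.0, seed=5)
        model = kmeans_l1(pts, k=3, seed=6, n_restarts=8)
        trace = model.objective_trace
        assert np.all(np.diff(trace) <= 1e-9)
        assert model.objective == trace[-1]

    def test_determinism(self):
        pts, _ = blobs(2, 40, 6, sep=2.0, seed=7)
        m1 = kmeans_l1(pts, k=3, seed=8, n_restarts=10)
        m2 = kmeans_l1(pts, k=3, seed=8, n_restarts=10)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(ValueError):
            kmeans_l1(np.zeros((2, 3)), k=5, seed=0)


class TestSelectK:
    def test_three_separated_blobs_select_three(self):
        pts, _ = blobs(3, 60, 6, sep=12.0, seed=9)
        k_best, curves = select_k(pts, range(2, 7), seed=10, n_restarts=5)
        assert k_best == 3
        assert curves[3]["silhouette"] > 0.9  # perfectly separated equal blobs

    def test_all_identical_points_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            select_k(np.ones((20, 4)), range(2, 5), seed=0)

    def test_curves_returned_for_every_candidate(self):
        pts, _ = blobs(2, 30, 4, sep=6.0, seed=11)
        _, curves = select_k(pts, range(2, 6), seed=12, n_restarts=3)
        assert set(curves) == {2, 3, 4, 5}
        for v in curves.values():
            assert {"silhouette", "calinski_harabasz"} <= set(v)


def _model(assignments, point_ids, k):
    return StateModel(
        k=k,
        centroids=np.zeros((k, 2)),
        assignments=np.asarray(assignments),
        point_ids=point_ids,
        objective=0.0,
        objective_trace=np.zeros(1),
    )


class TestOccupancy:
    def test_all_windows_one_state(self):
        model = _model([1] * 10, [("a", i) for i in range(10)], k=2)
        occ = occupancy(model)
        assert occ["overall"][1]["fraction"] == 1.0
        assert occ["overall"][2]["fraction"] == 0.0

    def test_three_of_eleven_is_2727_percent(self):
        model = _model([1] * 3 + [2] * 8, [("a", i) for i in range(11)], k=2)
        occ = occupancy(model)
        assert round(100 * occ["overall"][1]["fraction"], 2) == 27.27
        assert occ["overall"][1]["count"] == 3

    def test_group_fractions_sum_to_one(self):
        import pandas as pd

        rng = np.random.default_rng(13)
        ids = [("p1", i) for i in range(7)] + [("c1", i) for i in range(5)]
        model = _model(rng.integers(1, 4, size=12), ids, k=3)
        manifest = CohortManifest(
            pd.DataFrame(
                {"subject_id": ["p1", "c1"], "group": ["patient", "control"],
                 "age": [20, 21], "sex": ["M", "F"]}
            )
        )
        occ = occupancy(model, manifest)
        for g in ("patient", "control"):
            total = sum(v["fraction"] for v in occ["by_group"][g].values())
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_label_permutation_leaves_occupancy_multiset(self):
        model = _model([1, 1, 2, 2, 2], [("a", i) for i in range(5)], k=2)
        swapped = _model([2, 2, 1, 1, 1], [("a", i) for i in range(5)], k=2)
        f1 = sorted(v["fraction"] for v in occupancy(model)["overall"].values())
        f2 = sorted(v["fraction"] for v in occupancy(swapped)["overall"].values())
        assert f1 == f2


class TestCentroidMatrices:
    def test_vectorize_roundtrip(self):
        rng = np.random.default_rng(14)
        m = rng.standard_normal((5, 5))
        np.fill_diagonal(m, 0.0)
        np.testing.assert_array_equal(unvectorize_ec(vectorize_ec(m), 5), m)

    def test_centroid_of_identical_matrices_is_that_matrix(self):
        rng = np.random.default_rng(15)
        m = rng.standard_normal((4, 4))
        np.fill_diagonal(m, 0.0)
        pts = np.tile(vectorize_ec(m), (10, 1))
        model = kmeans_l1(pts, k=1, seed=0, n_restarts=1)
        np.testing.assert_allclose(state_centroid_matrices(model, 4)[0], m, atol=1e-12)

    def test_zero_diagonal_preserved(self):
        rng = np.random.default_rng(16)
        pts = rng.standard_normal((20, 12))  # vectorized 4x4 off-diagonal
        model = kmeans_l1(pts, k=2, seed=1, n_restarts=3)
        for c in state_centroid_matrices(model, 4):
            np.testing.assert_array_equal(np.diag(c), 0.0)

    def test_centroids_match_planted_regimes_on_simulated_cohort(self, config):
        # windows deep inside each regime produce centroids closest (L1) to
        # the matching planted coupling matrix
        from fcdec.granger_dec import WindowSpec, dec_series
        from fcdec.state_clustering import fit_states
        from fcdec.synthetic_cohort import SimParams, simulate_cohort

        sp = SimParams(n_patients=3, n_controls=3)
        subs, truth, _, _ = simulate_cohort(config, sp, seed=30)
        ec = {ts.subject_id: dec_series(ts, WindowSpec(22, 1), truth.coupled_roi_indices)
              for ts in subs}
        model = fit_states(ec, k=2, seed=31, n_restarts=10)
        cents = state_centroid_matrices(model, 6)
        planted = truth.coupling_matrices
        d = np.array([[np.abs(c - p).sum() for p in planted] for c in cents])
        # each centroid matches a distinct planted regime
        assert set(np.argmin(d, axis=1)) == {0, 1}
        for row in d:
            assert row.min() < row.max()
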