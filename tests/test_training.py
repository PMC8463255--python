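"""k-means center selection and the two training modes."""

import itertools

import numpy as np
import pytest

import rbfseg as rs
from rbfseg.exceptions import DegenerateCentersError
from rbfseg.training import _sse


def brute_force_nearest(samples, centers):
    out = []
    for x in samples:
        d = [np.linalg.norm(x - c) for c in centers]
        out.append(int(np.argmin(d)))
    return np.asarray(out)


def best_two_partition_sse(values):
    """Exhaustive optimal 2-partition SSE for a 1-D sample set."""
    values = np.asarray(values, dtype=float)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=len(values)):
        bits = np.asarray(bits)
        if bits.sum() in (0, len(values)):
            continue
        sse = sum(
            ((values[bits == b] - values[bits == b].mean()) ** 2).sum()
            for b in (0, 1)
        )
        best = min(best, sse)
    return best


class TestInitCenters:
    def test_centers_are_distinct_sample_rows(self, rng):
        X = rng.uniform(size=(30, 3))
        C = rs.init_centers(X, 6, seed=0)
        assert len(np.unique(C, axis=0)) == 6
        for c in C:
            assert any(np.array_equal(c, x) for x in X)

    def test_k_equals_e_is_a_permutation(self, rng):
        X = rng.uniform(size=(5, 2))
        C = rs.init_centers(X, 5, seed=3)
        assert np.array_equal(
            np.sort(C, axis=0), np.sort(X, axis=0)
        )

    def test_determinism_and_degeneracy(self, rng):
        X = rng.uniform(size=(10, 2))
        assert np.array_equal(rs.init_centers(X, 4, 7), rs.init_centers(X, 4, 7))
        with pytest.raises(DegenerateCentersError):
            rs.init_centers(np.zeros((10, 2)), 2, 0)


class TestAssignClusters:
    def test_samples_at_centers_map_to_themselves(self, rng):
        C = rng.uniform(size=(4, 2))
        assert np.array_equal(rs.assign_clusters(C, C), np.arange(4))

    def test_tie_breaks_toward_lowest_index(self):
        assert rs.assign_clusters([[5.0]], [[0.0], [10.0]])[0] == 0

    def test_matches_brute_force(self, rng):
        X = rng.uniform(size=(50, 3))
        C = rng.uniform(size=(6, 3))
        assert np.array_equal(
            rs.assign_clusters(X, C), brute_force_nearest(X, C)
        )


class TestUpdateCenters:
    def test_member_mean(self):
        X = np.array([[1.0], [3.0], [10.0]])
        new = rs.update_centers(X, [0, 0, 1], [[0.0], [9.0]])
        assert new == pytest.approx(np.array([[2.0], [10.0]]))

    def test_mass_conservation(self, rng):
        X = rng.uniform(size=(40, 2))
        C = rs.init_centers(X, 5, 0)
        a = rs.assign_clusters(X, C)
        new = rs.update_centers(X, a, C)
        counts = np.bincount(a, minlength=5)
        assert (counts[:, None] * new).sum(axis=0) == pytest.approx(X.sum(axis=0))

    def test_empty_cluster_reseeds_to_farthest_sample(self):
        X = np.array([[0.0], [0.1], [50.0]])
        # cluster 1 empty; farthest point from the surviving centers is 50
        new = rs.update_centers(X, [0, 0, 0], [[0.05], [1000.0]])
        assert new[1] == pytest.approx([50.0])


class TestKmeans:
    def test_converges_immediately_on_repeated_points(self):
        X = np.repeat(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]]), 4, axis=0)
        C, n_iter = rs.kmeans(X, 3, seed=0)
        assert sorted(map(tuple, C)) == [(0.0, 0.0), (1.0, 1.0), (2.0, 0.0)]

    def test_two_well_separated_1d_groups(self):
        X = np.array([[0.0], [1.0], [9.0], [10.0]])
        C, _ = rs.kmeans(X, 2, seed=0, n_init=4)
        assert sorted(c[0] for c in C) == pytest.approx([0.5, 9.5])

    def test_objective_monotone_nonincreasing(self, rng):
        for _ in range(20):
            X = rng.uniform(size=(rng.integers(10, 40), 2))
            C = rs.init_centers(X, 3, rng)
            prev = np.inf
            for _ in range(25):
                a = rs.assign_clusters(X, C)
                sse = _sse(X, C, a)
                assert sse <= prev + 1e-12
                prev = sse
                C = rs.update_centers(X, a, C)

    def test_matches_exhaustive_best_two_partition(self, rng):
        for E in range(3, 9):
            for _ in range(5):
                vals = rng.uniform(size=E)
                X = vals[:, None]
                C, _ = rs.kmeans(X, 2, seed=int(rng.integers(2**31)), n_init=8)
                a = rs.assign_clusters(X, C)
                C = rs.update_centers(X, a, C)
                sse = _sse(X, C, rs.assign_clusters(X, C))
                assert sse == pytest.approx(best_two_partition_sse(vals), abs=1e-9)


class TestTrain:
    def _separable_set(self):
        # two intensity bands, zero noise: trivially separable
        spec = rs.PhantomSpec(
            shape=(32, 32), n_classes=2, class_means=(0.2, 0.8),
            noise_sd=0.0, geometry="bands", seed=0,
        )
        image, labels = rs.generate_phantom(spec)
        train_set = rs.sample_pixels(labels, 40, seed=1, image=image)
        test_set = rs.sample_pixels(
            labels, 40, seed=2, exclude=train_set.coord_set,
            image=image, scaling=train_set.scaling,
        )
        return train_set, test_set

    def test_noiseless_separable_phantom_is_classified_perfectly(self):
        train_set, test_set = self._separable_set()
        network, _ = rs.train(train_set, g=8, seed=0)
        raw = network.activations(test_set.features) @ network.weights
        assert (raw.argmax(1) == test_set.targets.argmax(1)).all()

    def test_interpolation_when_g_equals_e(self, benchmark_phantom):
        _, image, labels = benchmark_phantom
        train_set = rs.sample_pixels(labels, 10, seed=9, image=image)
        network, log = rs.train(train_set, g=len(train_set), seed=0)
        assert log.final_error < 1e-8

    def test_iterative_zero_lr_limit_leaves_error_unchanged(self):
        train_set, _ = self._separable_set()
        _, log = rs.train(
            train_set, g=6, seed=0, mode="iterative", epochs=20, lr=1e-12,
        )
        first = log.errors[0]
        assert log.errors[-1] == pytest.approx(first, rel=1e-6)

    def test_closed_form_error_bounds_iterative(self):
        train_set, _ = self._separable_set()
        _, closed = rs.train(train_set, g=6, seed=4)
        _, iterative = rs.train(
            train_set, g=6, seed=4, mode="iterative", epochs=500,
        )
        assert closed.final_error <= iterative.final_error + 1e-12

    def test_iterative_curve_is_nonincreasing(self):
        train_set, _ = self._separable_set()
        _, log = rs.train(train_set, g=6, seed=4, mode="iterative", epochs=400)
        errors = log.errors
        assert (np.diff(errors) <= 1e-12).all()

    def test_degenerate_training_set_raises(self):
        constant = rs.PixelSample(
            coords=np.array([[0, 0], [0, 1], [1, 0], [1, 1]]),
            features=np.zeros((4, 4)),
            targets=np.eye(2)[[0, 0, 1, 1]],
        )
        with pytest.raises(rs.exceptions.TrainingError):
            rs.train(constant, g=2, seed=0)

    def test_default_hidden_count(self):
        assert rs.default_hidden_count(600) == 25
        assert rs.default_hidden_count(3) == 2
        assert rs.default_hidden_count(2) == 2

    def test_log_csv_round_trip(self, tmp_path):
        train_set, _ = self._separable_set()
        _, log = rs.train(train_set, g=6, seed=0, mode="iterative", epochs=100)
        path = tmp_path / "log.csv"
        log.to_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert list(frame.columns) == ["iteration", "error"]
        assert len(frame) == len(log.records)


def test_kmeans_against_sklearn_reference(rng):
    """Cross-check the hand-rolled clustering against scikit-learn's on the
    same initial centers: identical fixed points."""
    from sklearn.cluster import KMeans

    X = rng.uniform(size=(60, 3))
    init = rs.init_centers(X, 4, seed=11)
    ours, _ = rs.kmeans(X, 4, seed=11)
    ref = KMeans(n_clusters=4, init=init, n_init=1, tol=1e-12, max_iter=300).fit(X)
    ours_sse = _sse(X, ours, rs.assign_clusters(X, ours))
    assert ours_sse == pytest.approx(ref.inertia_, rel=1e-6)
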