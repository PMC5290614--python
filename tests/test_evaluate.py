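import numpy as np
import pytest

from treelandscape.evaluate import (
    continuity,
    equivalence_classes,
    fit_report,
    one_nn,
    procrustes,
    trustworthiness,
)
from treelandscape.stress import embedded_distances


@pytest.fixture
def toy_n4():
    """4 points: input from 1D coords [0,1,2,4], embedding from [0,1,4,2].

    With k=1 the embedding gives point 2 a spurious neighbor (3, input
    rank 3) and point 3 one (1, input rank 2): trustworthiness penalty 3.
    Symmetrically the lost input neighbors cost continuity penalty 3, so
    both equal 1 - 2*3/(4*1*(8-3-1)) = 0.625 by hand.
    """
    delta = embedded_distances(np.array([[0.0], [1.0], [2.0], [4.0]]))
    X = np.array([[0.0], [1.0], [4.0], [2.0]])
    return delta, X


class TestTrustworthinessContinuity:
    def test_rank_preserving_embedding_scores_one(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(size=(30, 2))
        delta = embedded_distances(pts)
        for k in (1, 5, 10):
            assert trustworthiness(delta, pts, k) == 1.0
            assert continuity(delta, pts, k) == 1.0

    def test_toy_matches_hand_computation(self, toy_n4):
        delta, X = toy_n4
        assert trustworthiness(delta, X, 1) == pytest.approx(0.625, abs=1e-12)
        assert continuity(delta, X, 1) == pytest.approx(0.625, abs=1e-12)

    def test_duality_under_space_swap(self):
        rng = np.random.default_rng(1)
        A = embedded_distances(rng.uniform(size=(15, 2)))
        B = rng.uniform(size=(15, 2))
        Bd = embedded_distances(B)
        assert trustworthiness(A, B, 4) == pytest.approx(
            continuity(Bd, A, 4), abs=1e-12)

    def test_degrades_under_progressive_corruption(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(size=(40, 2))
        delta = embedded_distances(pts)
        scores_t, scores_c = [], []
        for noise in (0.0, 0.05, 0.5, 5.0):
            X = pts + noise * rng.standard_normal(pts.shape)
            scores_t.append(trustworthiness(delta, X, 5))
            scores_c.append(continuity(delta, X, 5))
        for s in (scores_t, scores_c):
            assert all(b <= a + 0.02 for a, b in zip(s, s[1:]))
            assert s[-1] < s[0]

    def test_k_out_of_range_rejected(self, toy_n4):
        delta, X = toy_n4
        with pytest.raises(ValueError):
            trustworthiness(delta, X, 2)  # k must be < N/2
        with pytest.raises(ValueError):
            continuity(delta, X, 0)

    def test_tearing_hurts_continuity_more_than_trustworthiness(self):
        """Splitting one tight cluster in half across the embedding loses
        input neighbors (continuity) without inventing many new ones."""
        rng = np.random.default_rng(3)
        cluster = rng.normal(scale=0.05, size=(20, 2))
        far = rng.normal(loc=5.0, scale=0.05, size=(10, 2))
        pts = np.vstack([cluster, far])
        delta = embedded_distances(pts)
        X = pts.copy()
        X[10:20] += 40.0  # tear the first cluster apart
        assert continuity(delta, X, 5) < trustworthiness(delta, X, 5)


class TestOneNN:
    def test_separated_clusters_score_one(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.1, (15, 2)), rng.normal(10, 0.1, (15, 2))])
        labels = ["a"] * 15 + ["b"] * 15
        assert one_nn(pts, labels) == 1.0

    def test_random_labels_score_near_chance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(400, 2))
        labels = rng.permutation(np.repeat(np.arange(4), 100))
        assert one_nn(pts, labels) == pytest.approx(0.25, abs=0.08)

    def test_accepts_distance_matrix_or_coordinates(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(size=(20, 2))
        labels = ["a"] * 10 + ["b"] * 10
        assert one_nn(pts, labels) == one_nn(embedded_distances(pts), labels)

    def test_single_label_degenerate(self):
        with pytest.raises(ValueError, match="single partition"):
            one_nn(np.random.default_rng(7).uniform(size=(5, 2)), ["x"] * 5)


class TestProcrustes:
    def _rand_config(self, seed, n=12, p=3):
        return np.random.default_rng(seed).uniform(size=(n, p))

    def test_similarity_copy_has_zero_residual(self):
        A = self._rand_config(0)
        Q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(3, 3)))
        B = 2.7 * A @ Q + np.array([5.0, -3.0, 1.0])
        assert procrustes(A, B).residual < 1e-10

    def test_mirrored_copy_allowed(self):
        A = self._rand_config(2, p=2)
        B = A * np.array([-1.0, 1.0])
        assert procrustes(A, B).residual < 1e-10

    def test_transform_components_reconstruct_alignment(self):
        A = self._rand_config(3, p=2)
        B = 0.5 * A + 1.0
        r = procrustes(A, B)
        aligned = r.scale * (B @ r.rotation) + r.translation
        np.testing.assert_allclose(aligned, A, atol=1e-10)

    def test_displaced_point_matches_grid_search_oracle(self):
        A = self._rand_config(4, n=8, p=2)
        B = A.copy()
        B[0] += np.array([0.4, -0.2])
        r = procrustes(A, B).residual
        A0 = A - A.mean(0)
        B0 = B - B.mean(0)
        ssa = np.sum(A0**2)
        best = np.inf
        for refl in (1.0, -1.0):
            for th in np.linspace(0, 2 * np.pi, 7200, endpoint=False):
                R = np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]]) @ np.diag([1.0, refl])
                BR = B0 @ R
                s = np.sum(A0 * BR) / np.sum(BR**2)  # optimal scale given R
                best = min(best, np.sum((A0 - s * BR) ** 2) / ssa)
        assert r == pytest.approx(best, abs=1e-4)

    def test_matches_scipy_disparity(self):
        from scipy.spatial import procrustes as scipy_procrustes

        A = self._rand_config(5)
        B = self._rand_config(6)
        _, _, disparity = scipy_procrustes(A, B)
        assert procrustes(A, B).residual == pytest.approx(disparity, rel=1e-9)

    def test_symmetric_residual(self):
        A = self._rand_config(7)
        B = self._rand_config(8)
        assert procrustes(A, B).residual == pytest.approx(
            procrustes(B, A).residual, abs=1e-10)

    def test_degenerate_configuration_rejected(self):
        A = np.ones((5, 2))
        with pytest.raises(ValueError, match="coincident"):
            procrustes(A, A)


class TestEquivalenceClasses:
    def test_identical_runs_form_one_class(self):
        X = np.random.default_rng(0).uniform(size=(10, 2))
        classes, R = equivalence_classes([X.copy() for _ in range(10)])
        assert classes == [list(range(10))]
        assert np.allclose(R, 0)

    def test_nine_similar_one_random_split_nine_one(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(size=(30, 3))
        runs = []
        for i in range(9):
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            runs.append((1 + 0.1 * i) * base @ Q + rng.normal(scale=1e-3,
                                                              size=base.shape))
        runs.append(rng.uniform(size=(30, 3)))  # independent stray run
        classes, _ = equivalence_classes(runs)
        assert sorted(classes[0]) == list(range(9))
        assert classes[1:] == [[9]]

    def test_two_runs_single_class_with_warning(self):
        rng = np.random.default_rng(2)
        runs = [rng.uniform(size=(8, 2)) for _ in range(2)]
        with pytest.warns(UserWarning, match="undefined"):
            classes, _ = equivalence_classes(runs)
        assert classes == [[0, 1]]


def test_fit_report_bundles_measures():
    rng = np.random.default_rng(3)
    pts = np.vstack([rng.normal(0, 0.2, (20, 2)), rng.normal(6, 0.2, (20, 2))])
    delta = embedded_distances(pts)
    labels = ["a"] * 20 + ["b"] * 20
    rep = fit_report(delta, pts, labels, ks=(1, 5, 10))
    assert rep.one_nn == 1.0 and rep.one_nn_ceiling == 1.0
    assert set(rep.trustworthiness_k) == {1, 5, 10}
    assert all(0 <= v <= 1 for v in rep.continuity_k.values())
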