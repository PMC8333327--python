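import itertools

import numpy as np
import pandas as pd
import pytest

from zoomacro.clustering import CurveSeries, assemble_series, classical_mds, \
    choose_k, dtw_distance, dtw_matrix, pam_cluster, validity_indices
from zoomacro.gam import SmoothCurveSet


def dtw_bruteforce(A, B):
    """Exhaustive enumeration of all monotone warping paths (tiny series)."""
    A = np.atleast_2d(np.asarray(A, float).T).T
    if A.ndim == 1:
        A = A[:, None]
    B = np.atleast_2d(np.asarray(B, float).T).T
    if B.ndim == 1:
        B = B[:, None]
    n, m = len(A), len(B)

    def cost(i, j):
        return float(np.linalg.norm(A[i] - B[j]))

    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], acc)
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                walk(ni, nj, acc + cost(ni, nj))

    walk(0, 0, cost(0, 0))
    return best[0]


def _curveset(model_id, pct_dev, curves):
    return SmoothCurveSet(model_id=model_id, pct_dev=pct_dev, curves={
        c: pd.DataFrame({"grid_index": np.arange(1, 101),
                         "x": np.linspace(0, 1, 100),
                         "value": v, "se": np.zeros(100)})
        for c, v in curves.items()})


class TestAssembleSeries:
    def test_threshold_is_strict(self):
        grid = np.linspace(-1, 1, 100)
        sets = [_curveset(f"m{i}", dev, {"a": grid})
                for i, dev in enumerate([0.39, 0.41, 0.5, 0.7])]
        out = assemble_series(sets, dev_threshold=0.40)
        assert [s.model_id for s in out] == ["m1", "m2", "m3"]

    def test_all_zero_curves_stay_zero(self):
        sets = [_curveset(f"m{i}", 0.9, {"a": np.zeros(100)})
                for i in range(3)]
        out = assemble_series(sets)
        for s in out:
            assert np.all(s.values == 0)

    def test_missing_covariate_zero_filled(self):
        grid = np.linspace(-1, 1, 100)
        sets = [_curveset("m0", 0.9, {"a": grid, "b": grid}),
                _curveset("m1", 0.9, {"a": grid}),
                _curveset("m2", 0.9, {"a": -grid, "b": grid})]
        out = assemble_series(sets)
        m1 = next(s for s in out if s.model_id == "m1")
        assert np.all(m1.values[:, m1.dimensions.index("b")] == 0)

    def test_weighted_mode_downweights_minor_curves(self):
        grid = np.linspace(-1, 1, 100)
        sets = [_curveset(f"m{i}", 0.9, {"a": grid, "b": 0.1 * grid})
                for i in range(3)]
        out = assemble_series(sets, standardize="weighted")
        s = out[0]
        sd = s.values.std(axis=0)
        assert sd[s.dimensions.index("b")] == pytest.approx(
            0.1 * sd[s.dimensions.index("a")], rel=1e-6)

    def test_too_few_models_rejected(self):
        sets = [_curveset("m0", 0.9, {"a": np.zeros(100)})]
        with pytest.raises(ValueError):
            assemble_series(sets)


class TestDTW:
    def test_identical_series_zero(self, rng):
        a = rng.normal(0, 1, (20, 3))
        assert dtw_distance(a, a) == 0.0

    def test_stated_small_examples(self):
        assert dtw_distance(np.array([0.0, 0.0]),
                            np.array([1.0, 1.0])) == pytest.approx(2.0)
        assert dtw_distance(np.array([0.0]),
                            np.array([1.0, 1.0, 1.0])) == pytest.approx(3.0)

    def test_symmetry(self, rng):
        a = rng.normal(0, 1, (15, 2))
        b = rng.normal(0, 1, (12, 2))
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_matches_exhaustive_path_enumeration(self, rng):
        for _ in range(50):
            n, m = rng.integers(1, 6, size=2)
            d = rng.integers(1, 4)
            a = rng.normal(0, 1, (n, d))
            b = rng.normal(0, 1, (m, d))
            assert dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            dtw_distance(rng.normal(0, 1, (5, 2)), rng.normal(0, 1, (5, 3)))

    def test_matrix_symmetric_zero_diagonal(self, rng):
        series = [CurveSeries(f"s{i}", rng.normal(0, 1, (10, 2)), ["a", "b"])
                  for i in range(4)]
        D = dtw_matrix(series)
        M = D.to_numpy()
        assert np.allclose(M, M.T, atol=1e-12)
        assert np.all(np.diag(M) == 0)

    def test_identical_series_give_zero_matrix(self):
        v = np.linspace(0, 1, 10)[:, None]
        series = [CurveSeries(f"s{i}", v, ["a"]) for i in range(3)]
        assert np.all(dtw_matrix(series).to_numpy() == 0)


def pam_bruteforce_cost(M, k):
    n = M.shape[0]
    best = np.inf
    for med in itertools.combinations(range(n), k):
        best = min(best, M[:, med].min(axis=1).sum())
    return best


class TestPAM:
    def test_cost_equals_bruteforce_on_small_instances(self, rng):
        for trial in range(30):
            n = int(rng.integers(5, 9))
            k = int(rng.integers(2, 4))
            X = rng.normal(0, 1, (n, 2))
            M = np.linalg.norm(X[:, None] - X[None, :], axis=2)
            D = pd.DataFrame(M, index=[f"p{i}" for i in range(n)],
                             columns=[f"p{i}" for i in range(n)])
            cl = pam_cluster(D, k, seed=trial)
            assert cl.cost == pytest.approx(pam_bruteforce_cost(M, k))

    def test_two_blobs_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (4, 2)),
                       rng.normal(10, 0.1, (4, 2))])
        M = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        ids = [f"p{i}" for i in range(8)]
        cl = pam_cluster(pd.DataFrame(M, index=ids, columns=ids), 2, seed=0)
        labels = [cl.assignment[i] for i in ids]
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_medoids_assigned_to_own_cluster(self, rng):
        X = rng.normal(0, 1, (12, 2))
        M = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        ids = [f"p{i}" for i in range(12)]
        cl = pam_cluster(pd.DataFrame(M, index=ids, columns=ids), 3, seed=1)
        med_labels = [cl.assignment[m] for m in cl.medoids]
        assert len(set(med_labels)) == 3

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(0, 1, (15, 2))
        M = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        ids = [f"p{i}" for i in range(15)]
        D = pd.DataFrame(M, index=ids, columns=ids)
        a = pam_cluster(D, 4, seed=9)
        b = pam_cluster(D, 4, seed=9)
        assert a.assignment == b.assignment and a.cost == b.cost

    def test_invalid_k_rejected(self, rng):
        M = np.abs(rng.normal(0, 1, (5, 5)))
        np.fill_diagonal(M, 0)
        D = pd.DataFrame((M + M.T) / 2)
        with pytest.raises(ValueError):
            pam_cluster(D, 5, seed=0)


class TestValidityIndices:
    def _dist(self, X):
        M = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        ids = [f"p{i}" for i in range(len(X))]
        return pd.DataFrame(M, index=ids, columns=ids), ids

    def test_tight_distant_clusters_beat_random_split(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (5, 2)),
                       rng.normal(20, 0.05, (5, 2))])
        D, ids = self._dist(X)
        good = pam_cluster(D, 2, seed=0)
        mds = classical_mds(D)
        vi_good = validity_indices(D, good, mds.coords)
        # random split of one blob in two
        from zoomacro.clustering import Clustering
        bad = Clustering(k=2, medoids=[ids[0], ids[2]],
                         assignment={i: (1 if j % 2 else 2)
                                     for j, i in enumerate(ids)},
                         cost=0.0)
        vi_bad = validity_indices(D, bad, mds.coords)
        assert vi_good.dunn >= 10 * vi_bad.dunn

    def test_perfectly_separated_point_clusters(self):
        X = np.array([[0.0, 0], [0, 0], [9, 9], [9, 9]])
        D, ids = self._dist(X)
        cl = pam_cluster(D, 2, seed=0)
        vi = validity_indices(D, cl, classical_mds(D).coords)
        assert vi.mean_silhouette == pytest.approx(1.0)
        assert vi.davies_bouldin == pytest.approx(0.0, abs=1e-8)
        assert vi.davies_bouldin_modified == pytest.approx(0.0, abs=1e-8)


class TestChooseK:
    def _family_distances(self, rng, n_fam=4, per_fam=6, spread=0.5):
        centers = rng.normal(0, 10, (n_fam, 4))
        X = np.vstack([c + rng.normal(0, spread, (per_fam, 4))
                       for c in centers])
        ids = [f"f{i // per_fam}m{i % per_fam}" for i in range(len(X))]
        M = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        return pd.DataFrame(M, index=ids, columns=ids)

    def test_four_planted_families_recovered(self, rng):
        D = self._family_distances(rng)
        sel = choose_k(D, seed=0)
        assert sel.chosen_k == 4

    def test_unanimity_is_respected(self, rng):
        D = self._family_distances(rng, n_fam=3)
        sel = choose_k(D, seed=0)
        if len(set(sel.votes.values())) == 1:
            assert sel.chosen_k == next(iter(sel.votes.values()))

    def test_plurality_tie_goes_to_smallest(self):
        import zoomacro.clustering as cl

        votes = {"calinski_harabasz": 3, "dunn": 3, "mean_silhouette": 4,
                 "davies_bouldin": 4, "davies_bouldin_modified": 5}
        counts = pd.Series(list(votes.values())).value_counts()
        top = counts[counts == counts.max()].index.min()
        assert top == 3


class TestClassicalMDS:
    def test_collinear_points_recovered_exactly(self):
        pos = np.array([0.0, 1.0, 3.0])
        M = np.abs(pos[:, None] - pos[None, :])
        D = pd.DataFrame(M, index=list("abc"), columns=list("abc"))
        res = classical_mds(D, dim=2)
        X = res.coords.to_numpy()
        rec = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        assert np.allclose(rec, M, atol=1e-9)
        assert res.n_clipped == 0

    def test_euclidean_input_zero_stress(self, rng):
        X = rng.normal(0, 2, (10, 2))
        M = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        D = pd.DataFrame(M)
        rec_X = classical_mds(D, dim=2).coords.to_numpy()
        rec = np.linalg.norm(rec_X[:, None] - rec_X[None, :], axis=2)
        assert np.sqrt(np.sum((rec - M) ** 2)) <= 1e-8

    def test_matches_pcoa_reference(self, rng):
        """Cross-check against the scikit-bio principal-coordinates oracle."""
        from skbio.stats.ordination import pcoa
        X = rng.normal(0, 1, (8, 3))
        M = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        ours = classical_mds(pd.DataFrame(M), dim=2)
        ref = pcoa(M, number_of_dimensions=2)
        ours_d = np.abs(ours.coords.to_numpy())
        ref_d = np.abs(ref.samples.to_numpy())
        assert np.allclose(np.sort(ours_d, axis=0), np.sort(ref_d, axis=0),
                           atol=1e-6)

    def test_degenerate_all_zero_distances(self):
        D = pd.DataFrame(np.zeros((4, 4)))
        res = classical_mds(D, dim=2)
        assert np.allclose(res.coords.to_numpy(), 0.0)
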