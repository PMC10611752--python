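import numpy as np
import pytest
from scipy import stats as sps

import trajalign as ta
from trajalign.align import _cost_matrix

from oracles import brute_force_min_cost


def _random_pair(rng, max_len=5, max_dim=3):
    m, n = rng.integers(1, max_len + 1, size=2)
    S = rng.integers(1, max_dim + 1)
    return rng.normal(size=(m, S)), rng.normal(size=(n, S))


class TestPairwiseAlign:
    def test_self_alignment_is_zero_cost_diagonal(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 3))
        path = ta.pairwise_align(A, A)
        assert path.total_cost == 0.0
        assert path.pairs == [(i, i) for i in range(6)]

    def test_known_three_vs_two_optimum(self):
        A = np.array([[0.0], [1.0], [2.0]])
        B = np.array([[0.0], [2.0]])
        path = ta.pairwise_align(A, B)
        assert path.total_cost == pytest.approx(1.0)
        assert path.total_cost == pytest.approx(brute_force_min_cost(A, B))
        assert path.pairs[0] == (0, 0) and path.pairs[-1] == (2, 1)

    def test_single_point_sequence_path(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(1, 2))
        B = rng.normal(size=(4, 2))
        path = ta.pairwise_align(A, B)
        assert path.pairs == [(0, j) for j in range(4)]
        d = _cost_matrix(A, B, "euclidean")
        assert path.total_cost == pytest.approx(d.sum())

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            A, B = _random_pair(rng)
            got = ta.pairwise_align(A, B).total_cost
            assert got == pytest.approx(brute_force_min_cost(A, B), rel=1e-12)

    def test_cost_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            A, B = _random_pair(rng)
            assert ta.pairwise_align(A, B).total_cost == pytest.approx(
                ta.pairwise_align(B, A).total_cost
            )

    def test_path_is_monotone_without_skips(self):
        rng = np.random.default_rng(3)
        A, B = rng.normal(size=(8, 2)), rng.normal(size=(5, 2))
        path = ta.pairwise_align(A, B)
        steps = np.diff(np.array(path.pairs), axis=0)
        assert set(map(tuple, steps)) <= {(1, 0), (0, 1), (1, 1)}
        assert path.pairs[0] == (0, 0) and path.pairs[-1] == (7, 4)

    def test_dimension_mismatch_and_empty_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            ta.pairwise_align(np.zeros((2, 2)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="empty"):
            ta.pairwise_align(np.zeros((0, 2)), np.zeros((2, 2)))

    def test_pearson_metric(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(4, 6))
        path = ta.pairwise_align(A, A, cost_metric="pearson")
        assert path.total_cost == pytest.approx(0.0, abs=1e-12)


class TestMerge:
    def test_merge_known_path(self):
        A = np.array([[0.0], [1.0], [2.0]])
        B = np.array([[0.0], [2.0]])
        path = ta.AlignmentPath(pairs=[(0, 0), (1, 1), (2, 1)], total_cost=1.0)
        c = ta.merge_along_path(A, B, path)
        np.testing.assert_allclose(c.points, [[0.0], [1.5], [2.0]])
        np.testing.assert_allclose(c.weights, [2.0, 2.0, 2.0])

    def test_merge_identical_along_diagonal(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(5, 3))
        path = ta.pairwise_align(A, A)
        c = ta.merge_along_path(A, A, path)
        np.testing.assert_allclose(c.points, A)
        np.testing.assert_allclose(c.weights, 2.0)

    def test_weighted_mean(self):
        A = np.array([[0.0]])
        B = np.array([[4.0]])
        path = ta.AlignmentPath(pairs=[(0, 0)], total_cost=4.0)
        c = ta.merge_along_path(A, B, path, weights_A=np.array([3.0]),
                                weights_B=np.array([1.0]))
        assert c.points[0, 0] == pytest.approx(1.0)
        assert c.weights[0] == pytest.approx(4.0)

    def test_convex_hull_and_weight_accounting(self):
        rng = np.random.default_rng(11)
        A, B = rng.normal(size=(6, 3)), rng.normal(size=(4, 3))
        wA = rng.uniform(1, 5, size=6)
        wB = rng.uniform(1, 5, size=4)
        path = ta.pairwise_align(A, B)
        c = ta.merge_along_path(A, B, path, wA, wB)
        ii = [p[0] for p in path.pairs]
        jj = [p[1] for p in path.pairs]
        np.testing.assert_allclose(c.weights, wA[ii] + wB[jj])
        lo = np.minimum(A[ii], B[jj])
        hi = np.maximum(A[ii], B[jj])
        assert np.all(c.points >= lo - 1e-12) and np.all(c.points <= hi + 1e-12)


class TestResample:
    def test_identity_at_current_length(self):
        c = ta.ConsensusTrajectory(points=np.arange(8.0).reshape(4, 2),
                                   weights=np.arange(1.0, 5.0))
        r = ta.resample_consensus(c, 4)
        np.testing.assert_array_equal(r.points, c.points)
        np.testing.assert_array_equal(r.weights, c.weights)

    def test_linear_midpoint(self):
        c = ta.ConsensusTrajectory(points=np.array([[0.0], [2.0]]),
                                   weights=np.array([1.0, 1.0]))
        r = ta.resample_consensus(c, 3)
        np.testing.assert_allclose(r.points, [[0.0], [1.0], [2.0]])

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(4)
        c = ta.ConsensusTrajectory(points=rng.normal(size=(7, 3)),
                                   weights=rng.uniform(1, 3, 7))
        for L in (3, 5, 20):
            r = ta.resample_consensus(c, L)
            np.testing.assert_array_equal(r.points[0], c.points[0])
            np.testing.assert_array_equal(r.points[-1], c.points[-1])

    def test_too_short_target_errors(self):
        c = ta.ConsensusTrajectory(points=np.zeros((4, 1)), weights=np.ones(4))
        with pytest.raises(ValueError):
            ta.resample_consensus(c, 2)


def _monotone_trajectories(rng, n=3, G=8, S=2):
    """Monotone single-warp trajectories sharing increasing profiles."""
    out = []
    for i in range(n):
        a = rng.uniform(0.5, 2.0)
        t = np.linspace(0, 1, G) ** a
        grid = np.vstack([t * (s + 1) for s in range(S)])
        out.append(ta.IndividualTrajectory(f"p{i}", [], np.linspace(0, 1, G), grid))
    return out


class TestBuildConsensus:
    def test_identical_trajectories_any_order(self):
        # consensus length matching the grid keeps the reduction exact
        rng = np.random.default_rng(6)
        grid = np.sort(rng.normal(size=(2, 6)), axis=1)
        trajs = [ta.IndividualTrajectory(f"p{i}", [], np.linspace(0, 1, 6), grid)
                 for i in range(3)]
        for order in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
            c = ta.build_consensus(trajs, order, consensus_length=6)
            np.testing.assert_allclose(c.points, grid.T, atol=1e-12)
            np.testing.assert_allclose(c.weights, 3.0)

    def test_two_trajectories_reduce_to_pairwise_merge(self):
        rng = np.random.default_rng(8)
        trajs = _monotone_trajectories(rng, n=2)
        c = ta.build_consensus(trajs, [0, 1], consensus_length=10)
        path = ta.pairwise_align(trajs[0].points, trajs[1].points)
        merged = ta.merge_along_path(trajs[0].points, trajs[1].points, path)
        expected = ta.resample_consensus(merged, 10)
        np.testing.assert_allclose(c.points, expected.points)
        np.testing.assert_allclose(c.weights, expected.weights)

    def test_monotone_inputs_yield_monotone_consensus(self):
        rng = np.random.default_rng(9)
        trajs = _monotone_trajectories(rng, n=3)
        c = ta.build_consensus(trajs, [0, 1, 2], consensus_length=20)
        assert np.all(np.diff(c.points, axis=0) >= -1e-9)

    def test_invalid_order_rejected(self):
        rng = np.random.default_rng(1)
        trajs = _monotone_trajectories(rng, n=3)
        with pytest.raises(ValueError, match="permutation"):
            ta.build_consensus(trajs, [0, 1], consensus_length=10)


class TestFit:
    def test_determinism(self, small_cohort):
        kwargs = dict(K=8, n_members=4, rng_seed=77)
        m1 = ta.fit(small_cohort.dataset, **kwargs)
        m2 = ta.fit(small_cohort.dataset, **kwargs)
        assert m1.seed.feature_names == m2.seed.feature_names
        for c1, c2 in zip(m1.ensemble, m2.ensemble):
            np.testing.assert_array_equal(c1.points, c2.points)
            np.testing.assert_array_equal(c1.weights, c2.weights)

    def test_single_member_two_individuals_reduction(self, small_cohort):
        ds = small_cohort.dataset.subset_individuals(
            small_cohort.dataset.individual_ids[:2]
        )
        model = ta.fit(ds, K=6, n_members=1, rng_seed=0)
        assert model.n_members == 1
        assert model.ensemble[0].length == model.hyperparams["consensus_length"]
        assert model.ensemble[0].n_features == model.seed.size

    def test_rejects_underobserved_individuals(self):
        cohort = ta.simulate_cohort(n_individuals=4, timepoints_range=(4, 5),
                                    n_seed_features=4, n_noise_features=4,
                                    rng_seed=0)
        ds = cohort.dataset
        first = ds.individual_ids[0]
        first_cols = list(ds.columns_for(first))
        keep = first_cols[:2] + [
            i for i, s in enumerate(ds.samples) if s.individual_id != first
        ]
        short = ta.LongitudinalDataset(
            feature_names=ds.feature_names,
            samples=[ds.samples[i] for i in keep],
            values=ds.values[:, keep],
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            ta.fit(short, K=4, n_members=1)

    def test_subsample_fraction(self, small_cohort):
        model = ta.fit(small_cohort.dataset, K=6, n_members=3, rng_seed=1,
                       subsample_frac=0.5)
        assert model.n_members == 3

    def test_ensemble_members_agree_on_ordering(self, default_cohort, default_model):
        """Pseudotime orderings from different members correlate strongly."""
        estimates = ta.predict(default_model, default_cohort.dataset)
        positions = np.array([e.member_positions for e in estimates])  # N x B
        B = positions.shape[1]
        rhos = [
            sps.spearmanr(positions[:, i], positions[:, j]).statistic
            for i in range(B) for j in range(i + 1, B)
        ]
        assert np.mean(rhos) >= 0.9
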