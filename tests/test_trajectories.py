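import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonymorph.io_formats import ColonyKey
from colonymorph.trajectories import (
    EnsembleGrid,
    FeatureTrajectory,
    bin_series,
    build_common_grid,
    fill_trajectory,
    pairwise_distances,
    trajectory_distance,
)


def make_traj(coords, grid, observed=None, key=None):
    coords = np.asarray(coords, dtype=float)
    obs = np.ones(len(coords), dtype=bool) if observed is None else observed
    return FeatureTrajectory(
        key=key or ColonyKey(1, 1), grid=grid, coords=coords, observed=obs
    )


class TestBinning:
    def test_two_points_one_bin_averaged(self):
        out = bin_series([10, 50], [[0, 0, 0], [2, 2, 2]], bin_hours=1.0)
        assert len(out) == 1
        b, v = out[0]
        assert b == 0
        np.testing.assert_array_equal(v, [1, 1, 1])

    def test_single_point(self):
        out = bin_series([90], [[5, 6, 7]])
        assert out[0][0] == 1
        np.testing.assert_array_equal(out[0][1], [5, 6, 7])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bin_series([], np.empty((0, 3)))

    @given(seed=st.integers(0, 500), n=st.integers(1, 40))
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_grouping(self, seed, n):
        r = np.random.default_rng(seed)
        times = np.sort(r.integers(0, 600, size=n))
        pts = r.normal(size=(n, 3))
        got = dict(bin_series(times, pts, bin_hours=1.0))
        expected: dict[int, list] = {}
        for t, p in zip(times, pts):
            expected.setdefault(int(t // 60), []).append(p)
        assert set(got) == set(expected)
        for b in expected:
            np.testing.assert_allclose(got[b], np.mean(expected[b], axis=0))


class TestCommonGrid:
    def test_odd_median(self):
        grid = build_common_grid([24.0, 58.0, 70.0])
        assert grid.t_final_hours == 58.0

    def test_identical_last_times(self):
        assert build_common_grid([36.0, 36.0]).t_final_hours == 36.0

    def test_even_count_lower_median(self):
        assert build_common_grid([10.0, 20.0, 30.0, 40.0]).t_final_hours == 20.0

    def test_rounds_down_to_bin_boundary(self):
        assert build_common_grid([10.7]).t_final_hours == 10.0


class TestFilling:
    def test_linear_midpoint(self):
        grid = EnsembleGrid(t_final_hours=2.0)
        traj = fill_trajectory([(0, np.zeros(3)), (2, np.full(3, 2.0))], grid)
        np.testing.assert_allclose(traj.coords[1], [1, 1, 1])
        assert traj.observed.tolist() == [True, False, True]

    def test_saturation_extrapolation_to_grid_end(self):
        # colony observed through 24 h on a 58 h ensemble grid: every later
        # bin holds the 24 h value
        grid = EnsembleGrid(t_final_hours=58.0)
        binned = [(b, np.array([b / 10, 0.0, 0.0])) for b in range(25)]
        traj = fill_trajectory(binned, grid)
        for b in range(25, 59):
            np.testing.assert_array_equal(traj.coords[b], [2.4, 0.0, 0.0])
        assert not traj.observed[25:].any()

    def test_leading_gap_holds_first_value(self):
        grid = EnsembleGrid(t_final_hours=5.0)
        traj = fill_trajectory([(3, np.array([7.0, 0, 0]))], grid)
        np.testing.assert_array_equal(traj.coords[:3, 0], 7.0)

    def test_fully_observed_is_identity(self, rng):
        grid = EnsembleGrid(t_final_hours=9.0)
        vals = rng.normal(size=(10, 3))
        traj = fill_trajectory(list(enumerate(vals)), grid)
        np.testing.assert_array_equal(traj.coords, vals)
        assert traj.observed.all()

    def test_filling_never_alters_observed_bins(self, rng):
        grid = EnsembleGrid(t_final_hours=20.0)
        obs_bins = sorted(rng.choice(21, size=7, replace=False))
        binned = [(int(b), rng.normal(size=3)) for b in obs_bins]
        traj = fill_trajectory(binned, grid)
        for b, v in binned:
            np.testing.assert_array_equal(traj.coords[b], v)


class TestDistance:
    def test_identical_is_zero(self, rng):
        grid = EnsembleGrid(t_final_hours=5.0)
        c = rng.normal(size=(6, 3))
        assert trajectory_distance(make_traj(c, grid), make_traj(c.copy(), grid)) == 0.0

    def test_constant_trajectories(self):
        grid = EnsembleGrid(t_final_hours=9.0)
        p, q = np.array([1.0, 2.0, 2.0]), np.array([4.0, 6.0, 2.0])
        a = make_traj(np.tile(p, (10, 1)), grid)
        b = make_traj(np.tile(q, (10, 1)), grid)
        assert trajectory_distance(a, b) == pytest.approx(5.0)
        assert trajectory_distance(a, b, mode="sum") == pytest.approx(50.0)

    def test_mismatched_grids_raise(self):
        a = make_traj(np.zeros((3, 3)), EnsembleGrid(t_final_hours=2.0))
        b = make_traj(np.zeros((4, 3)), EnsembleGrid(t_final_hours=3.0))
        with pytest.raises(ValueError, match="grid"):
            trajectory_distance(a, b)

    def test_metric_axioms_on_random_triples(self):
        r = np.random.default_rng(1234)
        grid = EnsembleGrid(t_final_hours=7.0)
        for _ in range(300):
            a, b, c = (make_traj(r.normal(size=(8, 3)), grid) for _ in range(3))
            dab = trajectory_distance(a, b)
            dba = trajectory_distance(b, a)
            assert dab == dba >= 0
            assert dab <= trajectory_distance(a, c) + trajectory_distance(c, b) + 1e-12


class TestPairwise:
    def test_two_trajectories_single_entry(self, rng):
        grid = EnsembleGrid(t_final_hours=4.0)
        trajs = [
            make_traj(rng.normal(size=(5, 3)), grid, key=ColonyKey(1, i + 1))
            for i in range(2)
        ]
        cd = pairwise_distances(trajs)
        assert len(cd.values) == 1
        assert cd.values[0] == pytest.approx(trajectory_distance(*trajs))

    def test_matches_bruteforce_double_loop(self, rng):
        grid = EnsembleGrid(t_final_hours=11.0)
        trajs = [
            make_traj(rng.normal(size=(12, 3)), grid, key=ColonyKey(1, i + 1))
            for i in range(10)
        ]
        cd = pairwise_distances(trajs)
        for i, j, d in cd.iter_pairs():
            assert d == pytest.approx(trajectory_distance(trajs[i], trajs[j]))

    def test_order_invariance(self, rng):
        grid = EnsembleGrid(t_final_hours=6.0)
        trajs = [
            make_traj(rng.normal(size=(7, 3)), grid, key=ColonyKey(1, i + 1))
            for i in range(5)
        ]
        cd = pairwise_distances(trajs)
        perm = [3, 0, 4, 1, 2]
        cd2 = pairwise_distances([trajs[i] for i in perm])
        for i in range(5):
            for j in range(5):
                if i != j:
                    a, b = perm[i], perm[j]
                    assert cd2.distance(i, j) == pytest.approx(cd.distance(a, b))
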