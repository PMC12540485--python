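"""Trajectory construction and time-decayed interaction-graph weights."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectpath.graph import (
    EdgeWeightParams,
    build_graph,
    build_trajectory,
    edge_weight,
    user_t_max,
)
from affectpath.types import (
    NOISE,
    CheckIn,
    EmotionPoint,
    GraphVertex,
    Quadrant,
    UserTrajectory,
)


def _checkin(user, t):
    return CheckIn(user_id=user, t=t, lon=121.3, lat=31.0,
                   readings=(EmotionPoint(0.5, 0.5),))


def sigma(z):
    return 1.0 / (1.0 + math.exp(-z))


class TestEdgeWeight:
    def test_closed_form_values(self):
        p = EdgeWeightParams(alpha=10.0, t_max=1000.0)
        assert edge_weight(1000.0, p) == pytest.approx(sigma(0.1), abs=1e-9)
        assert edge_weight(1000.0, p) == pytest.approx(0.52498, abs=1e-5)
        assert edge_weight(100.0, p) == pytest.approx(sigma(1.0), abs=1e-9)
        assert edge_weight(100.0, p) == pytest.approx(0.73106, abs=1e-5)

    def test_short_gap_limit_is_one(self):
        p = EdgeWeightParams(alpha=10.0, t_max=1000.0)
        assert edge_weight(1e-9, p) == pytest.approx(1.0, abs=1e-6)

    @given(st.floats(min_value=1.0, max_value=1e8),
           st.floats(min_value=1.0, max_value=1e8))
    @settings(max_examples=200, deadline=None)
    def test_decreasing_and_bounded(self, dt1, dt2):
        p = EdgeWeightParams(alpha=10.0, t_max=1e6)
        w1, w2 = edge_weight(dt1, p), edge_weight(dt2, p)
        # the open upper bound saturates to 1.0 in floating point
        assert 0.5 < w1 <= 1.0
        if dt1 < dt2:
            assert w1 >= w2

    def test_nonpositive_gap_errors(self):
        with pytest.raises(ValueError):
            edge_weight(0.0, EdgeWeightParams())


class TestBuildTrajectory:
    def test_three_steps(self):
        cs = [_checkin("u", t) for t in (10.0, 20.0, 30.0)]
        traj = build_trajectory(cs, [0, 1, 0], [Quadrant.I, Quadrant.II, Quadrant.I])
        assert len(traj) == 3 and traj.usable
        assert traj.steps[1][0] == GraphVertex(1, Quadrant.II)

    def test_noise_checkins_dropped(self):
        cs = [_checkin("u", t) for t in (10.0, 20.0, 30.0)]
        traj = build_trajectory(cs, [0, NOISE, 1], [Quadrant.I] * 3)
        assert len(traj) == 2
        assert [v.area_id for v, _ in traj.steps] == [0, 1]

    def test_equal_timestamps_shifted_one_second(self):
        cs = [_checkin("u", 100.0), _checkin("u", 100.0)]
        traj = build_trajectory(cs, [0, 1], [Quadrant.I, Quadrant.II])
        assert [t for _, t in traj.steps] == [100.0, 101.0]

    def test_short_trajectory_flagged_unusable(self):
        traj = build_trajectory([_checkin("u", 1.0)], [0], [Quadrant.I])
        assert not traj.usable


class TestBuildGraph:
    def _traj(self, user, areas, times, quadrant=Quadrant.I):
        steps = [(GraphVertex(a, quadrant), t) for a, t in zip(areas, times)]
        return UserTrajectory(user_id=user, steps=steps)

    def test_single_pair(self):
        g = build_graph([self._traj("u", [0, 1], [0.0, 50.0])])
        assert g.n_vertices == 2 and g.n_edges == 1
        v0 = GraphVertex(0, Quadrant.I)
        # single gap: T_max equals the gap, so the weight is sigma(1/alpha)
        assert g.out_degree[v0] == pytest.approx(sigma(0.1), abs=1e-9)

    def test_weights_accumulate_across_users(self):
        t1 = self._traj("u1", [0, 1], [0.0, 100.0])
        t2 = self._traj("u2", [0, 1], [0.0, 9999.0])
        g = build_graph([t1, t2])
        key = (GraphVertex(0, Quadrant.I), GraphVertex(1, Quadrant.I))
        assert g.edges[key] == pytest.approx(2 * sigma(0.1), abs=1e-9)

    def test_direction_follows_time_order(self):
        g = build_graph([self._traj("u", [0, 1, 0], [0.0, 10.0, 20.0])])
        a, b = GraphVertex(0, Quadrant.I), GraphVertex(1, Quadrant.I)
        assert (a, b) in g.edges and (b, a) in g.edges

    def test_total_weight_matches_brute_force(self, rng):
        trajs = []
        for u in range(5):
            m = int(rng.integers(2, 8))
            times = np.cumsum(rng.uniform(10, 1e5, size=m))
            areas = rng.integers(0, 4, size=m)
            trajs.append(self._traj(f"u{u}", areas, times))
        g = build_graph(trajs)
        expected = 0.0
        for tr in trajs:
            tmax = user_t_max(tr)
            for (_, ta), (_, tb) in zip(tr.steps, tr.steps[1:]):
                expected += sigma(tmax / (10.0 * (tb - ta)))
        assert g.total_weight() == pytest.approx(expected, abs=1e-9)
        assert g.n_edges <= sum(len(t) - 1 for t in trajs)

    def test_user_order_invariance(self, rng):
        trajs = [self._traj(f"u{u}", rng.integers(0, 3, size=5),
                            np.cumsum(rng.uniform(10, 1e4, size=5))) for u in range(6)]
        g1 = build_graph(trajs)
        g2 = build_graph(trajs[::-1])
        assert set(g1.edges) == set(g2.edges)
        for key, w in g1.edges.items():
            assert g2.edges[key] == pytest.approx(w, abs=1e-12)

    def test_all_unusable_errors(self):
        with pytest.raises(ValueError):
            build_graph([UserTrajectory("u", [(GraphVertex(0, Quadrant.I), 1.0)])])
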