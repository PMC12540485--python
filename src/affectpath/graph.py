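"""Emotional interaction graph with time-decayed edge weights.

Each user's labelled check-ins form a chronological walk over
(stay area, quadrant) vertices.  Every consecutive pair contributes a
directed edge whose strength decays with the time gap between the two
posts: g(dt) = sigma(T_max / (alpha * dt)), where T_max is that user's
largest inter-post gap and alpha regulates how sharply short gaps bind
vertices together.  Weights from all users accumulate on shared edges.

g is strictly decreasing in dt and bounded in (0.5, 1): even the slowest
transition of a user retains half strength relative to an instantaneous
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .types import NOISE, CheckIn, EmotionGraph, GraphVertex, Quadrant, UserTrajectory

DEFAULT_ALPHA = 10.0


@dataclass(frozen=True)
class EdgeWeightParams:
    """Decay regulator alpha and the user's maximum inter-post gap."""

    alpha: float = DEFAULT_ALPHA
    t_max: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")


def edge_weight(dt: float, params: EdgeWeightParams) -> float:
    """Logistic time-decay weight sigma(T_max / (alpha * dt)) in (0.5, 1)."""
    if dt <= 0:
        raise ValueError(f"time gap must be > 0, got {dt}")
    z = params.t_max / (params.alpha * dt)
    return 1.0 / (1.0 + math.exp(-z))


def build_trajectory(
    user_checkins: Sequence[CheckIn],
    assignments: Sequence[int],
    quadrants: Sequence[Quadrant],
) -> UserTrajectory:
    """Turn one user's labelled check-ins into a vertex trajectory.

    Inputs are parallel sequences in chronological file order; noise
    check-ins are dropped.  Posts sharing a timestamp are shifted forward
    one second each in file order, so the trajectory's timestamps are
    strictly increasing (the decay weight needs dt > 0).
    """
    if not user_checkins:
        raise ValueError("no check-ins for user")
    if not len(user_checkins) == len(assignments) == len(quadrants):
        raise ValueError("checkins, assignments and quadrants must be parallel")
    user_id = user_checkins[0].user_id
    steps: List[Tuple[GraphVertex, float]] = []
    for c, area, q in zip(user_checkins, assignments, quadrants):
        if c.user_id != user_id:
            raise ValueError("check-ins from multiple users passed to build_trajectory")
        if area == NOISE:
            continue
        t = float(c.t)
        if steps and t <= steps[-1][1]:
            t = steps[-1][1] + 1.0
        steps.append((GraphVertex(int(area), q), t))
    return UserTrajectory(user_id=user_id, steps=steps)


def user_t_max(traj: UserTrajectory) -> float:
    """The user's maximum gap between consecutive posts, in seconds."""
    gaps = [t2 - t1 for (_, t1), (_, t2) in zip(traj.steps, traj.steps[1:])]
    if not gaps:
        raise ValueError(f"trajectory of {traj.user_id} has no transitions")
    return max(gaps)


def build_graph(
    trajectories: Sequence[UserTrajectory],
    alpha: float = DEFAULT_ALPHA,
) -> EmotionGraph:
    """Accumulate every user's consecutive transitions into one graph.

    Edge weight = sum over users, over that user's traversals of the
    ordered pair, of the per-transition decay weight.  T_max is computed
    per user.  Unusable trajectories (fewer than two surviving steps) are
    skipped; if all are unusable this raises.
    """
    graph = EmotionGraph()
    usable = 0
    for traj in trajectories:
        if not traj.usable:
            continue
        usable += 1
        params = EdgeWeightParams(alpha=alpha, t_max=user_t_max(traj))
        for (v1, t1), (v2, t2) in zip(traj.steps, traj.steps[1:]):
            graph.add_edge(v1, v2, edge_weight(t2 - t1, params))
    if usable == 0:
        raise ValueError("no usable trajectory (all have < 2 labelled steps)")
    return graph
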