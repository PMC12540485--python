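"""Domain types shared by every pipeline stage.

The pipeline moves geotagged social-media posts ("check-ins") through
four representations: raw :class:`CheckIn` records, discrete
:class:`StayArea` locations, vertices ``(stay area, emotional quadrant)``
of a directed :class:`EmotionGraph`, and finally per-user
:class:`TrajectoryMatrix` inputs for the sequence predictor.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

#: Label used for check-ins rejected as spatial noise by the clusterer.
NOISE = -1


class Quadrant(enum.Enum):
    """One of the four emotional states of the valence/arousal circumplex.

    Quadrant I is high valence & high intensity (e.g. excitement), II low
    valence & high intensity (distress), III low valence & low intensity
    (depression), IV high valence & low intensity (contentment).
    """

    I = 1
    II = 2
    III = 3
    IV = 4

    @property
    def positive(self) -> bool:
        """Whether the quadrant lies on the pleasant (high-valence) side."""
        return self in (Quadrant.I, Quadrant.IV)


@dataclass(frozen=True)
class EmotionPoint:
    """A single image's emotion reading: valence ``x`` and intensity ``y``.

    Both coordinates are dimensionless and bounded in [-1, 1]; the origin
    is the neutral state of the circumplex.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite emotion reading ({self.x}, {self.y})")
        if not -1.0 <= self.x <= 1.0:
            raise ValueError(f"valence {self.x} outside [-1, 1]")
        if not -1.0 <= self.y <= 1.0:
            raise ValueError(f"intensity {self.y} outside [-1, 1]")


@dataclass(frozen=True)
class CheckIn:
    """One geotagged post: user, UTC epoch second, WGS84 position, readings.

    ``readings`` holds one (valence, intensity) pair per image attached to
    the post and must be non-empty.
    """

    user_id: str
    t: float
    lon: float
    lat: float
    readings: Tuple[EmotionPoint, ...]

    def __post_init__(self) -> None:
        if not self.readings:
            raise ValueError("check-in has no emotion readings")
        if not math.isfinite(self.t):
            raise ValueError("non-finite timestamp")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class StayArea:
    """A spatial cluster of check-ins treated as one discrete location."""

    area_id: int
    center: Tuple[float, float]  # (lon, lat)
    member_count: int

    def __post_init__(self) -> None:
        if self.member_count < 0:
            raise ValueError("member_count must be >= 0")


@dataclass(frozen=True)
class GraphVertex:
    """A vertex of the emotional interaction graph: (stay area, quadrant)."""

    area_id: int
    quadrant: Quadrant


@dataclass
class UserTrajectory:
    """A user's chronologically ordered walk over graph vertices.

    Timestamps must be strictly increasing; trajectories with fewer than
    two steps carry no transition and are flagged unusable for edges.
    """

    user_id: str
    steps: List[Tuple[GraphVertex, float]]

    def __post_init__(self) -> None:
        ts = [t for _, t in self.steps]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"trajectory of {self.user_id}: timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def usable(self) -> bool:
        return len(self.steps) >= 2


@dataclass
class EmotionGraph:
    """Directed weighted graph over (stay area, quadrant) vertices.

    Edge weights accumulate time-decayed transition strengths across all
    users.  ``out_degree`` caches the weighted out-degree of each vertex,
    its importance weight in the embedding objective.
    """

    vertices: List[GraphVertex] = field(default_factory=list)
    edges: Dict[Tuple[GraphVertex, GraphVertex], float] = field(default_factory=dict)

    def add_edge(self, src: GraphVertex, dst: GraphVertex, weight: float) -> None:
        if weight <= 0:
            raise ValueError(f"edge weight must be > 0, got {weight}")
        if src not in self._index:
            self.vertices.append(src)
            self._index[src] = len(self.vertices) - 1
        if dst not in self._index:
            self.vertices.append(dst)
            self._index[dst] = len(self.vertices) - 1
        self.edges[(src, dst)] = self.edges.get((src, dst), 0.0) + weight

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.vertices)}
        for (s, d), w in self.edges.items():
            if w <= 0:
                raise ValueError(f"edge ({s}, {d}) has non-positive weight {w}")
            for v in (s, d):
                if v not in self._index:
                    raise ValueError(f"edge endpoint {v} is not a known vertex")

    def index_of(self, v: GraphVertex) -> int:
        return self._index[v]

    @property
    def out_degree(self) -> Dict[GraphVertex, float]:
        deg: Dict[GraphVertex, float] = {v: 0.0 for v in self.vertices}
        for (src, _), w in self.edges.items():
            deg[src] += w
        return deg

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_weight(self) -> float:
        return float(sum(self.edges.values()))


@dataclass
class EmbeddingTable:
    """Per-vertex real vectors of common length ``dim``."""

    dim: int
    vectors: Dict[GraphVertex, np.ndarray]

    def __post_init__(self) -> None:
        for v, u in self.vectors.items():
            if u.shape != (self.dim,):
                raise ValueError(f"vector for {v} has shape {u.shape}, expected ({self.dim},)")
            if not np.all(np.isfinite(u)):
                raise ValueError(f"non-finite embedding for {v}")

    def __getitem__(self, v: GraphVertex) -> np.ndarray:
        return self.vectors[v]

    def __contains__(self, v: GraphVertex) -> bool:
        return v in self.vectors


@dataclass
class TrajectoryMatrix:
    """Predictor input: chronological stack of step embeddings plus target.

    ``rows[i]`` is the embedding of the trajectory's (i+1)-th step; the
    target is the (area, quadrant) of the step after the last row.
    """

    user_id: str
    rows: np.ndarray  # (m-1, d)
    target: GraphVertex

    def __post_init__(self) -> None:
        if self.rows.ndim != 2 or self.rows.shape[0] < 1:
            raise ValueError("trajectory matrix needs at least one row")

    @property
    def n_steps(self) -> int:
        return int(self.rows.shape[0])
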