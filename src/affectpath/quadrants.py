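"""Post-level emotion aggregation and circumplex quadrant classification.

Each image in a post carries a (valence, intensity) reading.  A post's
composite emotion is the raw componentwise sum of its readings; the sum's
signs place it in one of the four circumplex quadrants.  The sum is kept
un-normalised deliberately: many-image posts express a stronger signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from .types import CheckIn, EmotionPoint, Quadrant


@dataclass(frozen=True)
class AggregatedEmotion:
    """Componentwise sum of a post's readings, with the image count ``n``."""

    x: float
    y: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("aggregate over zero readings")
        # each reading is bounded by 1 in absolute value
        if abs(self.x) > self.n + 1e-12 or abs(self.y) > self.n + 1e-12:
            raise ValueError("aggregate magnitude exceeds reading count")


def validate_reading(x: float, y: float) -> EmotionPoint:
    """Check a (valence, intensity) pair and return it as an EmotionPoint.

    Raises ValueError naming the offending coordinate when either value
    falls outside [-1, 1].
    """
    if not math.isfinite(x) or not -1.0 <= x <= 1.0:
        raise ValueError(f"valence {x} outside [-1, 1]")
    if not math.isfinite(y) or not -1.0 <= y <= 1.0:
        raise ValueError(f"intensity {y} outside [-1, 1]")
    return EmotionPoint(x, y)


def aggregate_post(readings: Sequence[EmotionPoint]) -> AggregatedEmotion:
    """Sum the readings of one post componentwise (no averaging)."""
    if not readings:
        raise ValueError("cannot aggregate an empty list of readings")
    return AggregatedEmotion(
        x=float(sum(p.x for p in readings)),
        y=float(sum(p.y for p in readings)),
        n=len(readings),
    )


def quadrant_of(agg: "AggregatedEmotion | EmotionPoint") -> Quadrant:
    """Map an aggregated emotion to its circumplex quadrant.

    High/low is judged against the neutral origin; values exactly on an
    axis count as "low", so (0, 0) classifies as quadrant III.  The
    conservative break avoids inflating the positive classes, which
    already dominate online data.
    """
    x, y = agg.x, agg.y
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite emotion ({x}, {y})")
    if x > 0 and y > 0:
        return Quadrant.I
    if x <= 0 and y > 0:
        return Quadrant.II
    if x <= 0 and y <= 0:
        return Quadrant.III
    return Quadrant.IV


def mean_mode(agg: AggregatedEmotion) -> EmotionPoint:
    """Optional averaged view of an aggregate (off the default path)."""
    return EmotionPoint(agg.x / agg.n, agg.y / agg.n)


def label_checkins(checkins: Sequence[CheckIn]) -> List[Tuple[AggregatedEmotion, Quadrant]]:
    """Aggregate and classify every check-in, preserving order."""
    out = []
    for c in checkins:
        agg = aggregate_post(c.readings)
        out.append((agg, quadrant_of(agg)))
    return out
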