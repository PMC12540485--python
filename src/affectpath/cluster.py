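"""Stay-area identification by density-peak clustering.

Check-in points are unevenly dense: city centers concentrate most posts
while suburbs are sparse.  The classic density-peak scheme handles this
without fixing a cluster radius: each point gets a Gaussian-kernel local
density ``rho`` and a separation ``delta`` (distance to the nearest point
of strictly higher density); cluster centers are the points with the
largest ``gamma = rho * delta``, and every other point inherits the label
of its nearest higher-density neighbour in a single pass of decreasing
density.  Low-density points far from any denser neighbour are noise.

All distances are haversine meters on WGS84 coordinates; the all-pairs
computation is O(n^2), acceptable at desk scale (a spatial index could
replace it for larger inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .types import NOISE, CheckIn, StayArea

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in meters between WGS84 points (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass
class DensityProfile:
    """Per-point density statistics driving center selection and labelling.

    ``nearest_higher[i]`` is the index of the closest point of strictly
    higher density (ties in rho broken toward lower index); the globally
    densest point is its own sentinel and carries the maximum pairwise
    distance as delta.
    """

    rho: np.ndarray
    delta: np.ndarray
    nearest_higher: np.ndarray
    bandwidth: float

    @property
    def n_points(self) -> int:
        return len(self.rho)

    def density_order(self) -> np.ndarray:
        """Indices sorted by strictly decreasing density (index tie-break)."""
        return np.lexsort((np.arange(self.n_points), -self.rho))


def compute_density(points: np.ndarray, bandwidth: float) -> DensityProfile:
    """Gaussian-kernel density and nearest-higher separation per point.

    ``points`` is an (n, 2) array of (lon, lat); ``bandwidth`` is the
    kernel scale in meters.  rho_i = sum_{j != i} exp(-(d_ij/bw)^2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (lon, lat)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinate in points")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    n = len(pts)
    if n == 1:
        return DensityProfile(np.zeros(1), np.zeros(1), np.zeros(1, dtype=int), bandwidth)

    lon, lat = pts[:, 0], pts[:, 1]
    rho = np.zeros(n)
    block = max(1, int(2e7) // n)
    for s in range(0, n, block):
        e = min(n, s + block)
        d = haversine_m(lon[s:e, None], lat[s:e, None], lon[None, :], lat[None, :])
        k = np.exp(-((d / bandwidth) ** 2))
        rho[s:e] = k.sum(axis=1) - 1.0  # drop the self term

    order = np.lexsort((np.arange(n), -rho))
    delta = np.zeros(n)
    nearest = np.zeros(n, dtype=int)
    max_pair = 0.0
    for k_pos in range(n):
        i = order[k_pos]
        if k_pos == 0:
            nearest[i] = i  # densest point: self sentinel
            continue
        higher = order[:k_pos]
        d = haversine_m(lon[i], lat[i], lon[higher], lat[higher])
        j = int(np.argmin(d))
        delta[i] = d[j]
        nearest[i] = higher[j]
        max_pair = max(max_pair, float(d.max()))
    top = order[0]
    delta[top] = max_pair
    return DensityProfile(rho, delta, nearest, bandwidth)


def select_centers(profile: DensityProfile, n_centers: int) -> List[int]:
    """Indices of the n_centers points with the largest gamma = rho * delta.

    Returned in decreasing-gamma order (ties toward lower index), which
    fixes the area-id numbering.
    """
    n = profile.n_points
    if not 1 <= n_centers <= n:
        raise ValueError(f"n_centers={n_centers} outside [1, {n}]")
    gamma = profile.rho * profile.delta
    order = np.lexsort((np.arange(n), -gamma))
    return [int(i) for i in order[:n_centers]]


def assign_points(
    profile: DensityProfile,
    centers: Sequence[int],
    noise_quantile: float = 0.01,
) -> np.ndarray:
    """Label every point with its center's area id or NOISE.

    A single pass in decreasing-density order lets each point inherit the
    label of its nearest higher-density neighbour, so labels flow downhill
    from the centers.  Points in the bottom ``noise_quantile`` of density
    that sit farther than 3 bandwidths from their nearest denser neighbour
    are noise, as is anything downstream of a noise point.
    """
    n = profile.n_points
    labels = np.full(n, -2, dtype=int)  # -2 = not yet assigned
    center_ids = {int(c): area_id for area_id, c in enumerate(centers)}
    rho_cut = np.quantile(profile.rho, noise_quantile) if n > 1 else -np.inf
    for i in profile.density_order():
        i = int(i)
        if i in center_ids:
            labels[i] = center_ids[i]
            continue
        if profile.rho[i] < rho_cut and profile.delta[i] > 3.0 * profile.bandwidth:
            labels[i] = NOISE
            continue
        up = int(profile.nearest_higher[i])
        if up == i:
            # densest point not selected as a center: no uphill neighbour
            labels[i] = NOISE
        else:
            labels[i] = labels[up]
    return labels


def cluster_stay_areas(
    checkins: "Sequence[CheckIn] | np.ndarray",
    n_areas: int,
    bandwidth: float = 500.0,
    noise_quantile: float = 0.01,
) -> Tuple[List[StayArea], np.ndarray]:
    """Cluster check-ins into ``n_areas`` stay areas.

    Returns the areas (centers are density-weighted means of member
    coordinates) and the per-check-in assignment array (area id or NOISE).
    """
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    if isinstance(checkins, np.ndarray):
        pts = np.asarray(checkins, dtype=float)
    else:
        pts = np.array([[c.lon, c.lat] for c in checkins], dtype=float)
    n_distinct = len(np.unique(pts, axis=0))
    if n_distinct < n_areas:
        raise ValueError(f"only {n_distinct} distinct points for n_areas={n_areas}")
    profile = compute_density(pts, bandwidth)
    centers = select_centers(profile, n_areas)
    labels = assign_points(profile, centers, noise_quantile)
    areas = []
    for area_id in range(n_areas):
        mask = labels == area_id
        count = int(mask.sum())
        if count:
            w = profile.rho[mask] + 1e-12  # weight members by local density
            center = (
                float(np.average(pts[mask, 0], weights=w)),
                float(np.average(pts[mask, 1], weights=w)),
            )
        else:
            center = (float(pts[centers[area_id], 0]), float(pts[centers[area_id], 1]))
        areas.append(StayArea(area_id=area_id, center=center, member_count=count))
    return areas, labels
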