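"""Clustering of pooled water observations into hydration sites.

A hydration site is a small spherical region of a binding pocket that is
occupied by a water molecule in a large fraction of trajectory frames.  The
algorithm is greedy density clustering on the pooled oxygen positions:

1. count, for every observation, its neighbors within ``site_radius``;
2. take the observation with the most neighbors as seed (ties broken by
   lower ``(frame, water_id)``) and set the site center to the centroid of
   its in-radius neighborhood;
3. claim every unassigned observation within ``site_radius`` of the center,
   keeping only the nearest one per frame;
4. suppress future seeds within ``min_center_separation`` of accepted
   centers;
5. repeat on the remaining observations until the best candidate's occupancy
   falls below ``min_occupancy_fraction``.

The procedure is deterministic and, for the first seed, coincides with an
exhaustive maximum-neighbor-count search, which the tests exploit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import Trajectory, WaterObservation

logger = logging.getLogger("solvsite")


@dataclass(frozen=True)
class RegionSpec:
    """Analysis region: a sphere (center, radius) or an axis-aligned box."""

    kind: str  # "sphere" | "box"
    center: tuple[float, float, float] | None = None
    radius: float | None = None
    box_min: tuple[float, float, float] | None = None
    box_max: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.kind == "sphere":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise ValueError("sphere region needs center and radius > 0")
        elif self.kind == "box":
            if self.box_min is None or self.box_max is None:
                raise ValueError("box region needs box_min and box_max")
            if not np.all(np.asarray(self.box_max) > np.asarray(self.box_min)):
                raise ValueError("box region must have positive volume")
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")

    def contains(self, pos: np.ndarray) -> bool:
        if self.kind == "sphere":
            return bool(np.linalg.norm(pos - np.asarray(self.center))
                        <= self.radius)
        return bool(np.all(pos >= np.asarray(self.box_min))
                    and np.all(pos <= np.asarray(self.box_max)))


@dataclass(frozen=True)
class ClusterParams:
    """Greedy-clustering parameters (angstrom / fraction of frames)."""

    site_radius: float = 1.0
    min_center_separation: float = 2.0
    min_occupancy_fraction: float = 0.5

    def __post_init__(self):
        if self.site_radius <= 0:
            raise ValueError("site_radius must be positive")
        if self.min_center_separation < self.site_radius:
            raise ValueError("min_center_separation must be >= site_radius")
        if not 0.0 < self.min_occupancy_fraction <= 1.0:
            raise ValueError("min_occupancy_fraction must be in (0, 1]")


@dataclass
class HydrationSite:
    """A clustered hydration site with its member observations.

    ``thermo`` is populated by :mod:`solvsite.site_thermo`; sites read back
    from a site map carry member keys but not full observations.
    """

    center: np.ndarray
    members: list[WaterObservation]
    occupancy_fraction: float
    n_frames: int
    thermo: object | None = None
    member_keys_cache: list[tuple[int, int]] | None = field(
        default=None, repr=False)

    def member_keys(self) -> list[tuple[int, int]]:
        if self.members:
            return [obs.key for obs in self.members]
        return list(self.member_keys_cache or [])

    @property
    def n_members(self) -> int:
        return len(self.member_keys())


def pool_observations(traj: Trajectory, region: RegionSpec
                      ) -> list[WaterObservation]:
    """All observations (every frame pooled) whose oxygen lies in the region."""
    pooled = [obs for obs in traj.observations() if region.contains(obs.pos)]
    logger.info("pool_observations: %d of %d observations inside region",
                len(pooled), sum(len(f) for f in traj.frames))
    return pooled


def max_neighbor_seed(observations: Sequence[WaterObservation],
                      site_radius: float) -> int:
    """Exhaustive search for the observation with the most in-radius neighbors.

    Ties are broken by lower (frame, water_id).  This is the brute-force
    oracle for the greedy algorithm's first seed.
    """
    pos = np.array([o.position for o in observations]).reshape(-1, 3)
    best = None
    for i in range(len(observations)):
        count = int(np.sum(np.linalg.norm(pos - pos[i], axis=1) <= site_radius))
        key = (-count, observations[i].frame, observations[i].water_id)
        if best is None or key < best[0]:
            best = (key, i)
    return best[1]


def cluster_sites(observations: Sequence[WaterObservation],
                  params: ClusterParams,
                  n_frames: int) -> list[HydrationSite]:
    """Greedy maximal-occupancy clustering of pooled observations."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    obs = sorted(observations, key=lambda o: o.key)
    if not obs:
        return []
    pos = np.array([o.position for o in obs])
    available = np.ones(len(obs), dtype=bool)
    suppressed = np.zeros(len(obs), dtype=bool)
    centers: list[np.ndarray] = []
    sites: list[HydrationSite] = []

    while True:
        active = available & ~suppressed
        if not active.any():
            break
        tree = cKDTree(pos[available])
        avail_idx = np.flatnonzero(available)
        # neighbor counts among unclaimed observations (self included)
        counts_avail = np.asarray(tree.query_ball_point(
            pos[avail_idx], params.site_radius, return_length=True))
        counts = np.zeros(len(obs), dtype=int)
        counts[avail_idx] = counts_avail
        counts[~active] = -1
        # seed: max count, ties by lower (frame, water_id) == lower index
        seed = int(np.argmax(counts))
        neighborhood = avail_idx[tree.query_ball_point(pos[seed],
                                                       params.site_radius)]
        center = pos[neighborhood].mean(axis=0)
        claimed_idx = avail_idx[tree.query_ball_point(center,
                                                      params.site_radius)]
        # one member per frame: keep the nearest to the center
        best_per_frame: dict[int, int] = {}
        for i in claimed_idx:
            d = float(np.linalg.norm(pos[i] - center))
            prev = best_per_frame.get(obs[i].frame)
            if prev is None or d < float(np.linalg.norm(pos[prev] - center)):
                best_per_frame[obs[i].frame] = int(i)
        member_idx = sorted(best_per_frame.values())
        occupancy = len(member_idx) / n_frames
        if occupancy < params.min_occupancy_fraction:
            break
        available[claimed_idx] = False
        centers.append(center)
        too_close = (np.linalg.norm(pos - center, axis=1)
                     < params.min_center_separation)
        suppressed |= too_close
        sites.append(HydrationSite(
            center=center,
            members=[obs[i] for i in member_idx],
            occupancy_fraction=occupancy,
            n_frames=n_frames))

    logger.info("cluster_sites: %d sites from %d observations (%d frames)",
                len(sites), len(obs), n_frames)
    return sites
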