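"""Time-scaled distance (linear form) and k-nearest-neighbor retrieval.

The linear time-scaled distance between two fixes is

    sqrt(dx^2 + dy^2 + (s * vmax * dt)^2)

i.e. elapsed time enters as the maximum distance travelable in dt, scaled by
the dimensionless factor s. With s = 0 (or dt = 0) it reduces to the plain
Euclidean distance, so s = 0 recovers purely spatial hulls.

Neighbor retrieval is brute-force O(n) per parent (vectorised over numpy);
the fully sorted per-parent orderings are exposed so hull construction over
many k values can reuse one sort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .trajectory import Fix, Trajectory, Vmax

__all__ = ["TSDParams", "NeighborSet", "tsd", "nearest_neighbors", "neighbor_ordering"]


@dataclass(frozen=True)
class TSDParams:
    """Time-scaling factor s (dimensionless, >= 0) and the vmax that anchors it."""

    s: float
    vmax: Vmax

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s) and self.s >= 0):
            raise ParameterError(f"s must be finite and >= 0, got {self.s}")

    @property
    def time_scale(self) -> float:
        """Meters per second of elapsed time on the TSD time axis (s * vmax)."""
        return self.s * self.vmax.value


@dataclass(frozen=True)
class NeighborSet:
    """The k fixes (parent included) nearest to a parent under the TSD."""

    parent_index: int
    member_indices: tuple[int, ...]
    k: int

    def __post_init__(self) -> None:
        if len(self.member_indices) != self.k:
            raise ParameterError("member count does not match k")
        if len(set(self.member_indices)) != self.k:
            raise ParameterError("duplicate members")
        if self.parent_index not in self.member_indices:
            raise ParameterError("parent missing from its neighbor set")


def tsd(a: Fix, b: Fix, params: TSDParams) -> float:
    """Linear time-scaled distance between two fixes. Symmetric, >= Euclidean."""
    dx = a.x - b.x
    dy = a.y - b.y
    dtau = params.time_scale * (a.t - b.t)
    return math.sqrt(dx * dx + dy * dy + dtau * dtau)


def _tsd_sq_to_parent(coords: np.ndarray, times: np.ndarray, parent: int, time_scale: float) -> np.ndarray:
    d = coords - coords[parent]
    dtau = time_scale * (times - times[parent])
    return d[:, 0] ** 2 + d[:, 1] ** 2 + dtau**2


def neighbor_ordering(coords: np.ndarray, times: np.ndarray, s: float, vmax: float) -> np.ndarray:
    """(n, n) matrix whose row p lists all fix indices by increasing TSD to p.

    Ties are broken by smaller fix index (stable sort), except that the
    parent itself is always first — it is at distance zero and must belong
    to every neighbor set, even when other fixes coincide with it spatially.
    """
    n = len(times)
    scale = s * vmax
    order = np.empty((n, n), dtype=np.intp)
    for p in range(n):
        row = np.argsort(_tsd_sq_to_parent(coords, times, p, scale), kind="stable")
        pos = int(np.nonzero(row == p)[0][0])
        if pos != 0:
            row[1 : pos + 1] = row[:pos].copy()
            row[0] = p
        order[p] = row
    return order


def nearest_neighbors(traj: Trajectory, parent_index: int, k: int, params: TSDParams) -> NeighborSet:
    """k-nearest fixes to ``parent_index`` under the TSD, parent included.

    Ties broken by smaller fix index for cross-platform determinism.
    """
    n = len(traj)
    if not 3 <= k <= n:
        raise ParameterError(f"k={k} out of range [3, {n}]")
    if not 0 <= parent_index < n:
        raise ParameterError(f"parent_index={parent_index} out of range")
    order = neighbor_ordering(traj.coords, traj.times, params.s, params.vmax.value)
    members = tuple(int(i) for i in order[parent_index, :k])
    return NeighborSet(parent_index=parent_index, member_indices=members, k=k)
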