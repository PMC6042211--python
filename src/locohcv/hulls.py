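"""Local convex hulls, their areas, enclosed points and visit statistics.

A hullset holds one hull per fix; its ``total_area`` is the SUM of the hull
areas (overlaps double-counted on purpose) — that sum is the normaliser of
the hull-coverage density used for cross-validation scoring.

Visit statistics follow the T-LoCoH convention: the fixes enclosed by a hull
are sorted by time and cut into bouts wherever consecutive enclosed fixes
are separated by more than the inter-visit gap (ivg); NSV is the bout count
and MNLV the mean bout size, so nsv * mnlv equals the enclosed count exactly.
The ivg has no canonical value; the default is 86400 s (at most one visit
per day) and every output records the value used.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
import shapely
from shapely.geometry import mapping
from shapely.strtree import STRtree

from .errors import ParameterError
from .trajectory import Trajectory, Vmax
from .tsd_neighbors import NeighborSet, neighbor_ordering

__all__ = [
    "Hull",
    "Hullset",
    "build_hull",
    "build_hullset",
    "visit_stats",
    "hullset_to_geojson",
    "DEFAULT_IVG",
]

DEFAULT_IVG = 86400.0


@dataclass(frozen=True)
class Hull:
    """One parent fix's local convex hull.

    ``geometry`` is the convex hull of the member coordinates: a Polygon in
    the regular case, a Point/LineString (area 0, ``degenerate=True``) when
    the members are coincident or collinear. ``enclosed_indices`` are the
    fixes of the generating point set inside or on the hull boundary.
    """

    parent_index: int
    geometry: shapely.Geometry
    area: float
    enclosed_indices: tuple[int, ...]
    degenerate: bool
    nsv: int | None = None
    mnlv: float | None = None

    @property
    def n_enclosed(self) -> int:
        return len(self.enclosed_indices)


def _convex_geometry(points: np.ndarray) -> tuple[shapely.Geometry, float, bool]:
    """Convex hull of a coordinate multiset; duplicates removed first."""
    unique = np.unique(points, axis=0)
    geom = shapely.convex_hull(shapely.multipoints(unique))
    area = float(geom.area)
    return geom, area, area <= 0.0


def build_hull(traj: Trajectory, members: NeighborSet) -> Hull:
    """Convex hull of a neighbor set, with boundary-inclusive enclosed fixes.

    Degenerate (collinear/coincident) member sets yield a valid zero-area
    geometry flagged degenerate rather than an error.
    """
    if members.k < 3:
        raise ParameterError("a hull needs at least 3 members")
    coords = traj.coords
    geom, area, degenerate = _convex_geometry(coords[list(members.member_indices)])
    pts = shapely.points(coords)
    enclosed = tuple(int(i) for i in np.nonzero(shapely.covers(geom, pts))[0])
    return Hull(
        parent_index=members.parent_index,
        geometry=geom,
        area=area,
        enclosed_indices=enclosed,
        degenerate=degenerate,
    )


@dataclass
class Hullset:
    """All local hulls of one (k, s) pair over one generating point set."""

    traj: Trajectory
    hulls: list[Hull]
    total_area: float
    k: int
    s: float

    def __post_init__(self) -> None:
        if len(self.hulls) != len(self.traj):
            raise ParameterError("hullset must hold one hull per generating fix")

    @property
    def n(self) -> int:
        return len(self.hulls)

    @property
    def degenerate(self) -> bool:
        """True when the summed area cannot support the density interpretation."""
        return self.total_area <= 0.0

    @cached_property
    def tree(self) -> STRtree:
        """Spatial index over hull geometries (built lazily)."""
        return STRtree([h.geometry for h in self.hulls])

    def count_covering_hulls(self, xs, ys) -> np.ndarray:
        """For each query point, the number of hulls containing it (boundary inclusive)."""
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        pts = shapely.points(np.column_stack([xs, ys]))
        pt_idx, _ = self.tree.query(pts, predicate="covered_by")
        return np.bincount(pt_idx, minlength=len(pts))

    def with_visit_stats(self, ivg: float = DEFAULT_IVG) -> "Hullset":
        hulls = [visit_stats(h, self.traj, ivg) for h in self.hulls]
        return Hullset(self.traj, hulls, self.total_area, self.k, self.s)


def build_hullset(traj: Trajectory, k: int, s: float, vmax: Vmax) -> Hullset:
    """One local hull per fix, using TSD k-nearest neighbors; Aᵢ = Σ areas.

    With k = len(traj) every hull is the global convex hull, so the total
    area is n times the global hull area.
    """
    n = len(traj)
    if not 3 <= k <= n:
        raise ParameterError(f"k={k} out of range [3, {n}]")
    coords = traj.coords
    order = neighbor_ordering(coords, traj.times, s, vmax.value)

    geoms = []
    areas = np.empty(n)
    degen = np.empty(n, dtype=bool)
    for p in range(n):
        geom, area, is_degen = _convex_geometry(coords[order[p, :k]])
        geoms.append(geom)
        areas[p] = area
        degen[p] = is_degen

    # one bulk containment query: (hull idx, fix idx) pairs, boundary inclusive
    pts = shapely.points(coords)
    point_tree = STRtree(pts)
    hull_idx, fix_idx = point_tree.query(np.array(geoms, dtype=object), predicate="covers")
    enclosed: list[list[int]] = [[] for _ in range(n)]
    for h, f in zip(hull_idx.tolist(), fix_idx.tolist()):
        enclosed[h].append(f)

    hulls = [
        Hull(
            parent_index=p,
            geometry=geoms[p],
            area=float(areas[p]),
            enclosed_indices=tuple(sorted(enclosed[p])),
            degenerate=bool(degen[p]),
        )
        for p in range(n)
    ]
    return Hullset(traj=traj, hulls=hulls, total_area=float(areas.sum()), k=k, s=s)


def visit_stats(hull: Hull, traj: Trajectory, ivg: float) -> Hull:
    """Fill nsv/mnlv by segmenting the enclosed fixes into temporal bouts.

    A gap of strictly more than ``ivg`` seconds between consecutive enclosed
    fixes starts a new visit.
    """
    if not ivg > 0:
        raise ParameterError(f"ivg must be > 0, got {ivg}")
    if not hull.enclosed_indices:
        raise ParameterError(f"hull {hull.parent_index} encloses no fixes")
    times = np.sort(traj.times[list(hull.enclosed_indices)])
    nsv = 1 + int(np.count_nonzero(np.diff(times) > ivg))
    mnlv = len(times) / nsv
    return replace(hull, nsv=nsv, mnlv=mnlv)


def hullset_to_geojson(hullset: Hullset) -> dict:
    """GeoJSON FeatureCollection, one Feature per hull."""
    features = []
    for h in hullset.hulls:
        props = {
            "parent_index": h.parent_index,
            "area_m2": h.area,
            "n_enclosed": h.n_enclosed,
            "nsv": h.nsv,
            "mnlv": h.mnlv,
            "degenerate": h.degenerate,
        }
        features.append({"type": "Feature", "geometry": mapping(h.geometry), "properties": props})
    return {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"k": hullset.k, "s": hullset.s, "total_area_m2": hullset.total_area},
    }
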