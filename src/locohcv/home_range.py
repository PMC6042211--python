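"""Isopleth home-range polygons and summary metrics from a hullset.

Hulls are ranked by enclosed-point count (descending — the usual
point-density ordering) and unioned in that order until the union encloses
the requested fraction of fixes; the union's area is the reported home
range. Internal math stays in m²; reported areas are km².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import shapely
from shapely.ops import unary_union

from .errors import DegenerateHullsetError, ParameterError
from .hulls import DEFAULT_IVG, Hullset

__all__ = ["Isopleth", "HomeRangeSummary", "build_isopleth", "summarize"]

DEFAULT_LEVEL = 0.95


@dataclass(frozen=True)
class Isopleth:
    """Union of the densest hulls enclosing at least ``level`` of the fixes."""

    level: float
    geometry: shapely.Geometry
    area_km2: float
    n_enclosed: int
    n_hulls: int


@dataclass(frozen=True)
class HomeRangeSummary:
    hr_area_km2: float
    mean_nsv: float
    mean_mnlv: float
    k: int
    s: float
    ivg: float
    level: float


def build_isopleth(hullset: Hullset, level: float) -> Isopleth:
    """Union hulls in decreasing point-density order up to the coverage target.

    Sort key: enclosed-point count descending, ties by smaller area then
    smaller parent index. Hulls are added until the accumulated union
    encloses at least ceil(level * n) distinct fixes.
    """
    if not 0.0 < level <= 1.0:
        raise ParameterError(f"isopleth level must be in (0, 1], got {level}")
    if hullset.degenerate:
        raise DegenerateHullsetError("cannot build an isopleth from a zero-area hullset")

    n = hullset.n
    target = math.ceil(level * n)
    ranked = sorted(hullset.hulls, key=lambda h: (-h.n_enclosed, h.area, h.parent_index))

    selected = []
    enclosed: set[int] = set()
    for hull in ranked:
        selected.append(hull.geometry)
        enclosed.update(hull.enclosed_indices)
        if len(enclosed) >= target:
            break
    geometry = unary_union(selected)
    return Isopleth(
        level=level,
        geometry=geometry,
        area_km2=float(geometry.area) / 1e6,
        n_enclosed=len(enclosed),
        n_hulls=len(selected),
    )


def summarize(hullset: Hullset, level: float = DEFAULT_LEVEL, ivg: float = DEFAULT_IVG) -> HomeRangeSummary:
    """Home-range area at ``level`` plus unweighted hull means of NSV and MNLV."""
    stats = hullset.with_visit_stats(ivg)
    iso = build_isopleth(stats, level)
    nsvs = [h.nsv for h in stats.hulls]
    mnlvs = [h.mnlv for h in stats.hulls]
    return HomeRangeSummary(
        hr_area_km2=iso.area_km2,
        mean_nsv=sum(nsvs) / len(nsvs),
        mean_mnlv=sum(mnlvs) / len(mnlvs),
        k=hullset.k,
        s=hullset.s,
        ivg=ivg,
        level=level,
    )
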