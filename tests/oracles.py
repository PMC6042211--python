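"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive and shares no geometry code with the
package: full-sort nearest neighbors, Andrew monotone-chain hulls, shoelace
areas and sign-based point-in-convex-polygon tests.
"""

from __future__ import annotations

import math

from locohcv import SplitScheme, Trajectory, split_train_test


def naive_tsd(a, b, s: float, vmax: float) -> float:
    dx = a.x - b.x
    dy = a.y - b.y
    dtau = s * vmax * (a.t - b.t)
    return math.sqrt(dx * dx + dy * dy + dtau * dtau)


def naive_neighbors(traj: Trajectory, parent: int, k: int, s: float, vmax: float) -> list[int]:
    """Full sort of all TSDs; ties by index; parent forced first."""
    ranked = sorted((naive_tsd(traj.fixes[parent], f, s, vmax), f.index) for f in traj.fixes)
    idx = [i for _, i in ranked]
    idx.remove(parent)
    return ([parent] + idx)[:k]


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points) -> list[tuple[float, float]]:
    """Andrew monotone chain; returns CCW vertices, collinear points dropped.

    Degenerate inputs give 1 (point) or 2 (segment) vertices.
    """
    pts = sorted(set((float(x), float(y)) for x, y in points))
    if len(pts) <= 2:
        return pts
    lower: list = []
    for p in pts:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in reversed(pts):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:  # fully collinear
        return [pts[0], pts[-1]]
    return hull


def shoelace(vertices) -> float:
    if len(vertices) < 3:
        return 0.0
    area = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def _on_segment(p, a, b, eps: float) -> bool:
    if abs(_cross(a, b, p)) > eps:
        return False
    return (
        min(a[0], b[0]) - eps <= p[0] <= max(a[0], b[0]) + eps
        and min(a[1], b[1]) - eps <= p[1] <= max(a[1], b[1]) + eps
    )


def point_in_hull(p, hull, eps: float = 1e-9) -> bool:
    """Boundary-inclusive containment in a CCW convex polygon (or segment/point)."""
    p = (float(p[0]), float(p[1]))
    if len(hull) == 1:
        return abs(p[0] - hull[0][0]) <= eps and abs(p[1] - hull[0][1]) <= eps
    if len(hull) == 2:
        scale = max(abs(v) for pt in hull for v in pt) + 1.0
        return _on_segment(p, hull[0], hull[1], eps * scale)
    scale = max(abs(v) for pt in hull for v in pt) + 1.0
    n = len(hull)
    for i in range(n):
        if _cross(hull[i], hull[(i + 1) % n], p) < -eps * scale * scale:
            return False
    return True


def naive_hullset(traj: Trajectory, k: int, s: float, vmax: float):
    """[(hull vertices, area)] per parent, plus the summed area."""
    hulls = []
    total = 0.0
    coords = traj.coords
    for parent in range(len(traj)):
        members = naive_neighbors(traj, parent, k, s, vmax)
        verts = convex_hull(coords[members])
        area = shoelace(verts)
        hulls.append((verts, area))
        total += area
    return hulls, total


def naive_cv_score(traj: Trajectory, k: int, s: float, scheme: SplitScheme, vmax: float) -> float:
    """End-to-end brute-force recomputation of the cross-validation score."""
    total = 0.0
    for train, test in split_train_test(traj, scheme):
        hulls, area = naive_hullset(train, k, s, vmax)
        assert area > 1.0
        for fix in test:
            g = sum(point_in_hull((fix.x, fix.y), verts) for verts, _ in hulls)
            total += math.log(g / area) if g >= 1 else -2.0 * math.log(area)
    return total


def naive_visit_counts(times, ivg: float) -> tuple[int, float]:
    ts = sorted(times)
    nsv = 1
    for a, b in zip(ts, ts[1:]):
        if b - a > ivg:
            nsv += 1
    return nsv, len(ts) / nsv
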