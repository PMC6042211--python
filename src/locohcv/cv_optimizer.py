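"""Cross-validated selection of (k, s) for local convex hull home ranges.

The hullset built from a training split is read as a probability density:
at a location covered by g of the training hulls the density is g divided
by the summed hull area A of the hullset (overlaps double-counted, which is
exactly what makes the coverage function integrate to A). A held-out point
covered by no hull is assigned probability 1/A^2 instead of 0, so its log
score is finite but substantially below that of any covered point. The
score of a parameter pair is the total natural-log probability of all
held-out points across all splits:

    P(k, s) = sum_i sum_j log(g_ij / A_i)        (fallback log(1 / A_i^2))

Larger training hullsets cover more but are normalised by a larger A, so
k = k_max (all hulls identical to the global hull) is penalised naturally.

The search over (k, s) runs in three stages: a coarse grid (default
k = 4..800 step 20, s = 0..0.05 step 0.01), a mid refinement of 40 k values
around the coarse peak in steps of 5, and a fine scan of 10 k values in
steps of 1 with s resolved at 0.001 around the mid peak. All evaluated
cells are merged into one surface and the best cell is reported under the
tie rule (highest score, then smaller k, then smaller s).

Scoring areas are in m²; because the 1/A² fallback is not scale invariant,
a training hullset with A <= 1 m² is rejected as degenerate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.strtree import STRtree

from .errors import DegenerateHullsetError, ParameterError
from .hulls import Hullset
from .trajectory import Fix, Trajectory, Vmax, compute_vmax
from .tsd_neighbors import neighbor_ordering

__all__ = [
    "SplitScheme",
    "ScoreSurface",
    "SearchConfig",
    "split_train_test",
    "log_density",
    "cv_score",
    "coarse_grid_search",
    "refine_search",
    "optimize",
]

logger = logging.getLogger(__name__)

#: Fraction of fallback-scored test points above which a warning is logged.
FALLBACK_WARN_FRACTION = 0.5

_S_DECIMALS = 9  # grid s values snapped to 1e-9 so float keys compare exactly


def _snap(s: float) -> float:
    return round(float(s), _S_DECIMALS)


@dataclass(frozen=True)
class SplitScheme:
    """How the track is partitioned into training and testing sets.

    ``random`` draws each test set uniformly without replacement;
    ``temporal-blocks`` holds out one contiguous time block per split, the
    blocks tiling the track. Both modes are deterministic given ``seed``.
    """

    n_splits: int = 5
    test_fraction: float = 0.25
    mode: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ParameterError(f"n_splits must be >= 1, got {self.n_splits}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ParameterError(f"test_fraction must be in (0, 1), got {self.test_fraction}")
        if self.mode not in ("random", "temporal-blocks"):
            raise ParameterError(f"unknown split mode {self.mode!r}")


def split_train_test(traj: Trajectory, scheme: SplitScheme) -> list[tuple[Trajectory, list[Fix]]]:
    """Deterministic train/test partitions; train and test are disjoint and tile the track."""
    n = len(traj)
    if n < 8:
        raise ParameterError(f"need at least 8 fixes to split, got {n}")

    pairs: list[tuple[Trajectory, list[Fix]]] = []
    if scheme.mode == "random":
        m = int(round(scheme.test_fraction * n))
        if m < 1 or n - m < 4:
            raise ParameterError(
                f"test_fraction={scheme.test_fraction} on n={n} leaves m={m} test / "
                f"{n - m} train points (need m >= 1 and train >= 4)"
            )
        rng = np.random.default_rng(scheme.seed)
        for _ in range(scheme.n_splits):
            perm = rng.permutation(n)
            test_idx = np.sort(perm[:m])
            train_idx = np.sort(perm[m:])
            pairs.append((traj.subset(train_idx), [traj.fixes[i] for i in test_idx]))
    else:  # temporal-blocks
        if scheme.n_splits > n:
            raise ParameterError("more temporal blocks than fixes")
        blocks = np.array_split(np.arange(n), scheme.n_splits)
        for block in blocks:
            if len(block) < 1 or n - len(block) < 4:
                raise ParameterError("temporal block leaves too few training points")
            train_idx = np.setdiff1d(np.arange(n), block)
            pairs.append((traj.subset(train_idx), [traj.fixes[i] for i in block]))
    return pairs


def log_density(hullset: Hullset, p) -> float:
    """Natural-log density of the hull-coverage distribution at a point.

    ``p`` is a Fix or an (x, y) pair. Returns log(g / A) where g is the
    number of hulls covering p (boundary inclusive) and A the summed hull
    area; uncovered points fall back to log(1 / A^2).
    """
    x, y = (p.x, p.y) if isinstance(p, Fix) else (float(p[0]), float(p[1]))
    total_area = hullset.total_area
    if total_area <= 1.0:
        raise DegenerateHullsetError(
            f"hullset total area {total_area} m² <= 1 m²: density scoring undefined "
            "(are coordinates really in meters?)"
        )
    g = int(hullset.count_covering_hulls([x], [y])[0])
    if g >= 1:
        return math.log(g / total_area)
    return -2.0 * math.log(total_area)


class _Evaluator:
    """Shared state for scoring many (k, s) cells on one track.

    Caches the splits, the per-(split, s) neighbor orderings and the
    per-cell scores, so the three search stages never recompute a cell.
    """

    def __init__(self, traj: Trajectory, scheme: SplitScheme, vmax: Vmax):
        self.vmax = vmax.value
        self.splits = split_train_test(traj, scheme)
        self._train_coords = [tr.coords for tr, _ in self.splits]
        self._train_times = [tr.times for tr, _ in self.splits]
        self._test_points = [
            shapely.points(np.array([(f.x, f.y) for f in te])) for _, te in self.splits
        ]
        self.max_k = min(len(tr) for tr, _ in self.splits)
        self.n_test = sum(len(te) for _, te in self.splits)
        self._orders: dict[tuple[int, float], np.ndarray] = {}
        self._cells: dict[tuple[int, float], float] = {}

    def _ordering(self, split: int, s: float) -> np.ndarray:
        key = (split, _snap(s))
        if key not in self._orders:
            self._orders[key] = neighbor_ordering(
                self._train_coords[split], self._train_times[split], s, self.vmax
            )
        return self._orders[key]

    def _split_score(self, split: int, k: int, s: float) -> tuple[float, int]:
        coords = self._train_coords[split]
        order = self._ordering(split, s)
        geoms = np.array(
            [shapely.convex_hull(shapely.multipoints(coords[order[p, :k]])) for p in range(len(coords))],
            dtype=object,
        )
        total_area = float(shapely.area(geoms).sum())
        if total_area <= 1.0:
            raise DegenerateHullsetError(
                f"split {split}: training hullset area {total_area} m² <= 1 m² "
                f"at k={k}, s={s} (degenerate geometry)"
            )
        tree = STRtree(geoms)
        pts = self._test_points[split]
        pt_idx, _ = tree.query(pts, predicate="covered_by")
        g = np.bincount(pt_idx, minlength=len(pts))
        logs = np.full(len(pts), -2.0 * math.log(total_area))
        covered = g > 0
        logs[covered] = np.log(g[covered] / total_area)
        return float(logs.sum()), int(np.count_nonzero(~covered))

    def score(self, k: int, s: float) -> float:
        key = (int(k), _snap(s))
        if key in self._cells:
            return self._cells[key]
        if not 3 <= k <= self.max_k:
            raise ParameterError(f"k={k} invalid for training subsets (3..{self.max_k})")
        total = 0.0
        fallbacks = 0
        for split in range(len(self.splits)):
            part, nf = self._split_score(split, k, s)
            total += part
            fallbacks += nf
        if self.n_test and fallbacks / self.n_test > FALLBACK_WARN_FRACTION:
            logger.warning(
                "k=%d s=%g: %d/%d test points outside all hulls (fallback-scored)",
                k, s, fallbacks, self.n_test,
            )
        self._cells[key] = total
        return total


def cv_score(traj: Trajectory, k: int, s: float, scheme: SplitScheme, vmax: Vmax | None = None) -> float:
    """Total held-out log probability P(k, s) summed over all splits.

    vmax defaults to the value computed once on the full trajectory (kept
    fixed across splits so s means the same thing in every split).
    """
    if vmax is None:
        vmax = compute_vmax(traj)
    return _Evaluator(traj, scheme, vmax).score(k, s)


@dataclass(frozen=True)
class SearchConfig:
    """Grid extents and step sizes of the three-stage search.

    Refine windows are half-widths: the mid stage spans 40 k values around
    the coarse peak (±20, step 5) and the fine stage 10 k values (±5,
    step 1) with s refined at ``s_step_fine`` within ± one coarse s step.
    """

    s_min: float = 0.0
    s_max: float = 0.05
    s_step_coarse: float = 0.01
    s_step_fine: float = 0.001
    k_min: int = 4
    k_max_grid: int = 800
    k_step_coarse: int = 20
    k_step_mid: int = 5
    k_step_fine: int = 1
    refine_window_mid: int = 20
    refine_window_fine: int = 5

    def __post_init__(self) -> None:
        if self.k_min < 3:
            raise ParameterError("k_min must be >= 3")
        if self.k_max_grid < self.k_min:
            raise ParameterError("k_max_grid < k_min")
        if not 0 <= self.s_min <= self.s_max:
            raise ParameterError("need 0 <= s_min <= s_max")
        for name in ("s_step_coarse", "s_step_fine"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("k_step_coarse", "k_step_mid", "k_step_fine"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")


@dataclass
class ScoreSurface:
    """P(k, s) over a set of evaluated grid cells, with the argmax.

    ``scores[i, j]`` is the score at ``k_values[i]``, ``s_values[j]``; NaN
    marks cells never evaluated (merged stages are not rectangular).
    ``best`` is (k, s, score) under the tie rule: highest score, ties going
    to smaller k then smaller s.
    """

    k_values: tuple[int, ...]
    s_values: tuple[float, ...]
    scores: np.ndarray
    best: tuple[int, float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.k_values), len(self.s_values)):
            raise ParameterError("score matrix shape does not match axes")
        self.best = self._argmax()

    def _argmax(self) -> tuple[int, float, float]:
        best = None
        for i, k in enumerate(self.k_values):
            for j, s in enumerate(self.s_values):
                v = self.scores[i, j]
                if np.isnan(v):
                    continue
                cand = (v, -k, -s)
                if best is None or cand > best[0]:
                    best = (cand, (k, s, float(v)))
        if best is None:
            raise ParameterError("empty score surface")
        return best[1]

    def cells(self) -> dict[tuple[int, float], float]:
        out = {}
        for i, k in enumerate(self.k_values):
            for j, s in enumerate(self.s_values):
                if not np.isnan(self.scores[i, j]):
                    out[(k, _snap(s))] = float(self.scores[i, j])
        return out

    @classmethod
    def from_cells(cls, cells: dict[tuple[int, float], float]) -> "ScoreSurface":
        ks = tuple(sorted({k for k, _ in cells}))
        ss = tuple(sorted({s for _, s in cells}))
        mat = np.full((len(ks), len(ss)), np.nan)
        ki = {k: i for i, k in enumerate(ks)}
        si = {s: j for j, s in enumerate(ss)}
        for (k, s), v in cells.items():
            mat[ki[k], si[s]] = v
        return cls(k_values=ks, s_values=ss, scores=mat)

    def to_dict(self) -> dict:
        return {
            "k_values": list(self.k_values),
            "s_values": list(self.s_values),
            "scores": [
                [None if np.isnan(v) else v for v in row] for row in self.scores
            ],
            "best": {"k": self.best[0], "s": self.best[1], "score": self.best[2]},
        }


def _s_grid(lo: float, hi: float, step: float) -> list[float]:
    n_steps = int(math.floor((hi - lo) / step + 1e-9))
    return [_snap(lo + i * step) for i in range(n_steps + 1)]


def _k_grid(lo: int, hi: int, step: int) -> list[int]:
    return list(range(lo, hi + 1, step))


def _evaluate_grid(ev: _Evaluator, ks, ss, stage: str) -> ScoreSurface:
    mat = np.full((len(ks), len(ss)), np.nan)
    total = len(ks) * len(ss)
    done = 0
    best = -math.inf
    for i, k in enumerate(ks):
        for j, s in enumerate(ss):
            mat[i, j] = ev.score(k, s)
            best = max(best, mat[i, j])
            done += 1
        logger.info("%s stage: %d/%d cells, running best P=%.4f", stage, done, total, best)
    return ScoreSurface(k_values=tuple(ks), s_values=tuple(ss), scores=mat)


def _feasible_kmax(config: SearchConfig, ev: _Evaluator) -> int:
    cap = min(config.k_max_grid, ev.max_k)
    if cap < config.k_min:
        raise ParameterError(
            f"k_min={config.k_min} exceeds the largest usable k ({cap}) "
            "for these training splits"
        )
    return cap


def coarse_grid_search(
    traj: Trajectory,
    scheme: SplitScheme,
    vmax: Vmax | None = None,
    config: SearchConfig = SearchConfig(),
    _evaluator: _Evaluator | None = None,
) -> ScoreSurface:
    """Stage 1: full matrix over the coarse (k, s) grid."""
    if vmax is None:
        vmax = compute_vmax(traj)
    ev = _evaluator or _Evaluator(traj, scheme, vmax)
    cap = _feasible_kmax(config, ev)
    ks = _k_grid(config.k_min, cap, config.k_step_coarse)
    ss = _s_grid(config.s_min, config.s_max, config.s_step_coarse)
    return _evaluate_grid(ev, ks, ss, "coarse")


def refine_search(
    traj: Trajectory,
    scheme: SplitScheme,
    vmax: Vmax | None = None,
    config: SearchConfig = SearchConfig(),
    coarse: ScoreSurface | None = None,
    _evaluator: _Evaluator | None = None,
) -> ScoreSurface:
    """Stages 2 and 3 around the coarse peak; returns the merged surface.

    Stage 2 rescans k in ±refine_window_mid around the coarse best (step
    k_step_mid) at the coarse s values; stage 3 scans k in
    ±refine_window_fine (step k_step_fine) and s at s_step_fine within
    ± one coarse s step of the stage-2 best. Windows are clipped to the
    legal ranges, so a peak at the grid edge never evaluates out-of-range
    cells.
    """
    if vmax is None:
        vmax = compute_vmax(traj)
    ev = _evaluator or _Evaluator(traj, scheme, vmax)
    if coarse is None:
        coarse = coarse_grid_search(traj, scheme, vmax, config, _evaluator=ev)
    cap = _feasible_kmax(config, ev)

    cells = dict(coarse.cells())
    ev._cells.update(cells)  # reuse coarse cells when an external surface was passed

    bk, _, _ = coarse.best
    ks2 = _k_grid(max(config.k_min, bk - config.refine_window_mid),
                  min(cap, bk + config.refine_window_mid), config.k_step_mid)
    ss2 = _s_grid(config.s_min, config.s_max, config.s_step_coarse)
    mid = _evaluate_grid(ev, ks2, ss2, "mid")
    cells.update(mid.cells())
    bk2, bs2, _ = ScoreSurface.from_cells(cells).best

    ks3 = _k_grid(max(config.k_min, bk2 - config.refine_window_fine),
                  min(cap, bk2 + config.refine_window_fine), config.k_step_fine)
    ss3 = _s_grid(max(config.s_min, _snap(bs2 - config.s_step_coarse)),
                  min(config.s_max, _snap(bs2 + config.s_step_coarse)), config.s_step_fine)
    fine = _evaluate_grid(ev, ks3, ss3, "fine")
    cells.update(fine.cells())

    return ScoreSurface.from_cells(cells)


def optimize(
    traj: Trajectory,
    scheme: SplitScheme,
    vmax: Vmax | None = None,
    config: SearchConfig = SearchConfig(),
) -> tuple[ScoreSurface, ScoreSurface]:
    """Full three-stage search; returns (coarse surface, merged final surface)."""
    if vmax is None:
        vmax = compute_vmax(traj)
    ev = _Evaluator(traj, scheme, vmax)
    coarse = coarse_grid_search(traj, scheme, vmax, config, _evaluator=ev)
    final = refine_search(traj, scheme, vmax, config, coarse=coarse, _evaluator=ev)
    return coarse, final
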