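"""Track data model, delimited-text I/O and basic kinematics.

Coordinates must already be projected planar meters: the loader never
reprojects, and geographic Movebank columns (``location-long`` /
``location-lat``) are rejected with a hint to project the data first.
Timestamps are accepted as ISO-8601 strings or epoch seconds and stored
internally as epoch seconds (float).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "Fix",
    "Trajectory",
    "Vmax",
    "LoadReport",
    "load_trajectory",
    "write_trajectory",
    "compute_vmax",
]

DEFAULT_COLUMNS = {
    "individual_id": "individual_id",
    "timestamp": "timestamp",
    "x": "x",
    "y": "y",
}

#: Movebank export columns that indicate unprojected geographic coordinates.
_GEOGRAPHIC_ALIASES = ("location-long", "location-lat", "location_long", "location_lat")


@dataclass(frozen=True)
class Fix:
    """One GPS fix: position in a projected metric plane at an instant.

    ``index`` is the 0-based position in time order within its trajectory;
    ``t`` is epoch seconds.
    """

    index: int
    t: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.t)):
            raise InputError(f"fix {self.index}: non-finite coordinate or timestamp")


@dataclass(frozen=True)
class Vmax:
    """Maximum observed speed (m/s) over consecutive fixes; scales the time axis."""

    value: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value >= 0):
            raise InputError(f"vmax must be finite and >= 0, got {self.value}")


@dataclass(frozen=True)
class LoadReport:
    n_rows: int
    n_kept: int
    n_dropped: int
    dropped_reasons: tuple[str, ...] = ()


@dataclass
class Trajectory:
    """Time-ordered fixes for one individual.

    Fixes are strictly increasing in time; exact duplicate timestamps are an
    error (the time-scaled distance is undefined in spirit for simultaneous
    fixes of one animal).
    """

    individual_id: str
    fixes: list[Fix]
    crs_note: str = "projected planar meters (unspecified)"
    load_report: LoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ts = [f.t for f in self.fixes]
        for a, b in zip(ts, ts[1:]):
            if b == a:
                raise InputError(f"duplicate timestamp {a!r} in trajectory {self.individual_id!r}")
            if b < a:
                raise InputError("fixes are not sorted by time")
        for i, f in enumerate(self.fixes):
            if f.index != i:
                raise InputError(f"fix at position {i} carries index {f.index}")

    def __len__(self) -> int:
        return len(self.fixes)

    def __iter__(self):
        return iter(self.fixes)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of x/y in meters."""
        return np.array([(f.x, f.y) for f in self.fixes], dtype=float).reshape(-1, 2)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.fixes], dtype=float)

    def subset(self, indices) -> "Trajectory":
        """New (reindexed) trajectory from a sorted selection of fix positions."""
        idx = sorted(int(i) for i in indices)
        fixes = [replace(self.fixes[j], index=i) for i, j in enumerate(idx)]
        return Trajectory(self.individual_id, fixes, self.crs_note)

    @staticmethod
    def from_arrays(x, y, t, individual_id: str = "track", crs_note: str | None = None) -> "Trajectory":
        order = np.argsort(np.asarray(t, dtype=float), kind="stable")
        fixes = [
            Fix(index=i, t=float(t[j]), x=float(x[j]), y=float(y[j]))
            for i, j in enumerate(order)
        ]
        kw = {} if crs_note is None else {"crs_note": crs_note}
        return Trajectory(individual_id, fixes, **kw)


def _parse_timestamp(raw) -> float:
    """ISO-8601 or epoch seconds -> epoch seconds (float). Raises ValueError."""
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        if math.isfinite(float(raw)):
            return float(raw)
        raise ValueError(f"non-finite timestamp {raw!r}")
    text = str(raw).strip()
    if not text:
        raise ValueError("empty timestamp")
    try:
        return float(text)
    except ValueError:
        pass
    stamp = pd.Timestamp(text)
    if stamp.tzinfo is None:
        stamp = stamp.tz_localize("UTC")
    return stamp.timestamp()


def load_trajectory(path, column_map: dict[str, str] | None = None) -> Trajectory:
    """Read a delimited-text track file (comma or tab autodetected).

    Parameters
    ----------
    path : path-like
        File with at least timestamp/x/y columns; ``individual_id`` optional.
    column_map : dict, optional
        Maps logical names (``individual_id``, ``timestamp``, ``x``, ``y``)
        to the file's column names. Defaults to the logical names themselves.

    Returns
    -------
    Trajectory sorted by time, with a :class:`LoadReport` attached recording
    dropped unparseable rows.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ConfigurationError(f"unknown column_map keys: {sorted(unknown)}")
        cols.update(column_map)

    try:
        frame = pd.read_csv(path, sep=None, engine="python", dtype=str, comment=None)
    except FileNotFoundError:
        raise InputError(f"track file not found: {path}")
    except Exception as exc:  # malformed file
        raise InputError(f"cannot parse track file {path}: {exc}")

    have = set(frame.columns)
    missing = [name for name in ("timestamp", "x", "y") if cols[name] not in have]
    if missing:
        geo = [c for c in _GEOGRAPHIC_ALIASES if c in have]
        if geo and (cols["x"] not in have or cols["y"] not in have):
            raise ConfigurationError(
                f"{path}: found geographic columns {geo} but no projected x/y; "
                "project your data to planar meters before loading "
                "(this tool never reprojects)"
            )
        raise ConfigurationError(
            f"{path}: missing required column(s) {[cols[m] for m in missing]}; "
            "use --column-map/column_map to name your columns"
        )

    individual_id = "unknown"
    if cols["individual_id"] in have:
        ids = frame[cols["individual_id"]].dropna().unique()
        if len(ids) > 1:
            raise InputError(
                f"{path}: multiple individuals {list(ids)[:5]}; load one individual at a time"
            )
        if len(ids) == 1:
            individual_id = str(ids[0])

    rows: list[tuple[float, float, float]] = []
    reasons: list[str] = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        record = dict(zip(frame.columns, row))
        try:
            t = _parse_timestamp(record[cols["timestamp"]])
            x = float(record[cols["x"]])
            y = float(record[cols["y"]])
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError("non-finite coordinate")
        except (ValueError, TypeError) as exc:
            reasons.append(f"row {pos}: {exc}")
            continue
        rows.append((t, x, y))

    if len(rows) < 4:
        raise InputError(
            f"{path}: only {len(rows)} valid fixes (need >= 4 for hull-based analysis)"
        )

    rows.sort(key=lambda r: r[0])
    dup = [rows[i][0] for i in range(1, len(rows)) if rows[i][0] == rows[i - 1][0]]
    if dup:
        shown = ", ".join(repr(t) for t in sorted(set(dup))[:10])
        raise InputError(f"{path}: duplicate timestamp(s): {shown}")

    fixes = [Fix(index=i, t=t, x=x, y=y) for i, (t, x, y) in enumerate(rows)]
    traj = Trajectory(individual_id, fixes)
    traj.load_report = LoadReport(
        n_rows=len(frame),
        n_kept=len(fixes),
        n_dropped=len(frame) - len(fixes),
        dropped_reasons=tuple(reasons),
    )
    return traj


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a loader-compatible CSV; round-trips at full float precision."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["individual_id", "timestamp", "x", "y"])
        for f in traj.fixes:
            writer.writerow([traj.individual_id, repr(f.t), repr(f.x), repr(f.y)])


def compute_vmax(traj: Trajectory) -> Vmax:
    """Maximum speed over consecutive fix pairs (displacement / time gap)."""
    if len(traj) < 2:
        raise InputError("vmax needs at least 2 fixes")
    coords = traj.coords
    dt = np.diff(traj.times)
    if np.any(dt <= 0):
        raise InputError("non-increasing timestamps")  # precluded by Trajectory invariant
    step = np.hypot(*np.diff(coords, axis=0).T)
    return Vmax(float(np.max(step / dt)))
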