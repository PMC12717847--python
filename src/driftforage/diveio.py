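"""Summarised-dive tables: schema, SRDL-style CSV dialects, exclusion rules.

A summarised dive is the satellite-relayed abstraction of one dive:
four interior inflection points (time s from dive start, depth m)
between surface endpoints, plus maximum depth, duration and the
post-dive surface interval.  This module reads and writes such tables,
validates their structural invariants, and applies the outlier
exclusion rules used before any metric is computed.

Exclusion rules, applied in a fixed order with each dive counted once
under the first rule it fails:

1. ``shallow``               maximum depth not exceeding 15 m
2. ``short``                 duration not exceeding 5 min
3. ``missing_or_duplicate``  missing values, or duplicate/non-increasing
                             point times within the dive
4. ``fast_segment``          any segment vertical rate above 4 m/s
5. ``too_long``              total duration above 90 min
6. ``too_deep``              maximum depth above 2,000 m
7. ``long_surface``          post-dive surface interval above 10 min

Boundary behaviour is strict as printed: a dive of exactly 15 m or
exactly 5 min is removed; exactly 90 min, 2,000 m or 10 min surface is
retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POINT_COLS = ["t1", "d1", "t2", "d2", "t3", "d3", "t4", "d4"]
REQUIRED_COLS = ["seal_id", "start_time", *POINT_COLS,
                 "max_depth", "duration", "surface_interval"]

RULE_ORDER = ["shallow", "short", "missing_or_duplicate", "fast_segment",
              "too_long", "too_deep", "long_surface"]

#: retention thresholds (strict inequalities in the stated direction)
MIN_DEPTH_M = 15.0
MIN_DURATION_S = 300.0
MAX_SEGMENT_RATE_MS = 4.0
MAX_DURATION_S = 5400.0
MAX_DEPTH_M = 2000.0
MAX_SURFACE_S = 600.0


@dataclass
class FilterReport:
    """Auditable account of the exclusion pass."""

    removed: dict = field(default_factory=dict)  # rule -> count
    retained: int = 0
    total: int = 0

    def __post_init__(self):
        for rule in RULE_ORDER:
            self.removed.setdefault(rule, 0)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def to_json(self, path=None) -> str:
        payload = json.dumps({"removed": self.removed, "retained": self.retained,
                              "total": self.total}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def segment_rates(dives: pd.DataFrame) -> np.ndarray:
    """Vertical rate (m/s, signed depth rate) of the 5 segments per dive."""
    t = np.column_stack([np.zeros(len(dives)),
                         dives[["t1", "t2", "t3", "t4"]].to_numpy(float),
                         dives["duration"].to_numpy(float)])
    d = np.column_stack([np.zeros(len(dives)),
                         dives[["d1", "d2", "d3", "d4"]].to_numpy(float),
                         np.zeros(len(dives))])
    dt = np.diff(t, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.diff(d, axis=1) / dt


def filter_dives(dives: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the exclusion rules; return (retained dives, report)."""
    n = len(dives)
    report = FilterReport(total=n)
    if n == 0:
        return dives.copy(), report

    num = dives[[c for c in REQUIRED_COLS if c != "seal_id"]].apply(
        pd.to_numeric, errors="coerce")
    depth = num["max_depth"].to_numpy()
    dur = num["duration"].to_numpy()
    surf = num["surface_interval"].to_numpy()

    t = np.column_stack([np.zeros(n), num[["t1", "t2", "t3", "t4"]].to_numpy(),
                         dur])
    structural = num.isna().any(axis=1).to_numpy()
    with np.errstate(invalid="ignore"):
        structural |= np.any(np.diff(t, axis=1) <= 0, axis=1)

    rates = segment_rates(dives.assign(**{c: num[c] for c in num.columns}))
    with np.errstate(invalid="ignore"):
        fast = np.nanmax(np.abs(rates), axis=1) > MAX_SEGMENT_RATE_MS

    with np.errstate(invalid="ignore"):
        checks = [
            ("shallow", ~(depth > MIN_DEPTH_M)),
            ("short", ~(dur > MIN_DURATION_S)),
            ("missing_or_duplicate", structural),
            ("fast_segment", fast),
            ("too_long", dur > MAX_DURATION_S),
            ("too_deep", depth > MAX_DEPTH_M),
            ("long_surface", surf > MAX_SURFACE_S),
        ]
    assigned = np.zeros(n, bool)
    for rule, bad in checks:
        bad = np.asarray(bad) & ~assigned
        report.removed[rule] = int(bad.sum())
        assigned |= bad
    retained = dives.loc[~assigned].copy()
    report.retained = len(retained)
    return retained, report


# ---------------------------------------------------------------------------
# CSV dialects

#: column maps: native header -> file header
DIALECTS = {
    "native": {c: c for c in REQUIRED_COLS},
    "srdl": {
        "seal_id": "REF", "start_time": "DE_DATE",
        "t1": "T1", "d1": "D1", "t2": "T2", "d2": "D2",
        "t3": "T3", "d3": "D3", "t4": "T4", "d4": "D4",
        "max_depth": "MAX_DEP", "duration": "DIVE_DUR",
        "surface_interval": "SURF_DUR",
    },
}


def _parse_times(series: pd.Series) -> pd.Series:
    """Parse a time column to float seconds (UTC epoch for timestamps)."""
    as_num = pd.to_numeric(series, errors="coerce")
    if as_num.notna().all():
        return as_num.astype(float)
    parsed = pd.to_datetime(series, errors="coerce", utc=True, format="mixed")
    bad = parsed.isna() & as_num.isna()
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"unparseable time {series.iloc[idx]!r} at row {idx}")
    out = as_num.astype(float)
    mask = out.isna()
    out[mask] = parsed[mask].astype("int64") / 1e9
    return out


def read_dive_table(path, dialect: str = "native") -> pd.DataFrame:
    """Read a summarised-dive CSV in the named dialect.

    SRDL-style files encode inflection times as percentages of dive
    duration; these are converted to seconds from dive start.  Returns
    the native schema.  Empty files yield an empty table with a logged
    warning.
    """
    colmap = DIALECTS[dialect]
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("empty dive table: %s", path)
        return pd.DataFrame(columns=REQUIRED_COLS)
    if raw.empty:
        logger.warning("dive table has headers but no rows: %s", path)
        return pd.DataFrame(columns=REQUIRED_COLS)
    missing = [file_col for file_col in colmap.values()
               if file_col not in raw.columns]
    if missing:
        raise KeyError(f"{path}: missing expected columns {missing} "
                       f"for dialect {dialect!r}")
    df = pd.DataFrame({native: raw[file_col]
                       for native, file_col in colmap.items()})
    df["start_time"] = _parse_times(df["start_time"])
    for c in REQUIRED_COLS[2:]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if dialect == "srdl":
        for c in ("t1", "t2", "t3", "t4"):
            df[c] = df[c] / 100.0 * df["duration"]
    return df


def write_dive_table(dives: pd.DataFrame, path, dialect: str = "native") -> None:
    colmap = DIALECTS[dialect]
    out = dives.copy()
    if dialect == "srdl":
        for c in ("t1", "t2", "t3", "t4"):
            out[c] = out[c] / out["duration"] * 100.0
    out = out[list(colmap)].rename(columns=colmap)
    out.to_csv(path, index=False)


def flag_invalid(dives: pd.DataFrame) -> np.ndarray:
    """Boolean mask of dives violating structural invariants.

    A dive is flagged when any required field is missing or its point
    times are not strictly increasing within (0, duration).
    """
    n = len(dives)
    num = dives[[c for c in REQUIRED_COLS if c != "seal_id"]].apply(
        pd.to_numeric, errors="coerce")
    t = np.column_stack([np.zeros(n), num[["t1", "t2", "t3", "t4"]].to_numpy(),
                         num["duration"].to_numpy()])
    bad = num.isna().any(axis=1).to_numpy()
    with np.errstate(invalid="ignore"):
        bad |= np.any(np.diff(t, axis=1) <= 0, axis=1)
    return bad


# ---------------------------------------------------------------------------
# Geographic adapter (I/O boundary only)

EARTH_RADIUS_M = 6_371_000.0


def lonlat_to_planar(lon, lat, lon0: float, lat0: float):
    """Local-tangent-plane (equirectangular) projection, metres east/north.

    Adequate for regional tracks; the analysis itself is planar.
    """
    lon, lat = np.asarray(lon, float), np.asarray(lat, float)
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y


def planar_to_lonlat(x, y, lon0: float, lat0: float):
    x, y = np.asarray(x, float), np.asarray(y, float)
    lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * np.cos(np.radians(lat0))))
    lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
    return lon, lat
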