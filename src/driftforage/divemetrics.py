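"""Dive-effort metrics, temporal-window aggregation, habitat classification.

Four metrics summarise the three stages of a dive cycle:

* descent / ascent rate (m/s): absolute vertical rate between the
  surface and the first inflection point, and between the last
  inflection point and the surface — the transit stage.
* dive residual (s): residual of an ordinary least-squares regression
  of dive duration on maximum depth — relative dive duration for a
  given depth (positive = long for its depth).
* surface residual (s): observed post-dive surface interval minus the
  predicted *minimum* interval for a dive of that duration, where the
  minimum envelope is a linear quantile regression at a small quantile
  (tau = 0.05 by default).

Metrics are averaged over the same non-overlapping temporal windows as
the drift-rate change, and each window's mean location is classified
shelf/oceanic against the 1,500 m isobath.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .bathymetry import SHELF_BREAK_M, BathymetryGrid
from .driftrate import SECONDS_PER_DAY, assign_blocks

logger = logging.getLogger(__name__)

METRIC_COLS = ["descent_rate", "ascent_rate", "dive_residual",
               "surface_residual"]


def transit_rates(dives: pd.DataFrame) -> pd.DataFrame:
    """Absolute descent and ascent rates from the outer inflection points.

    Dives with a zero-length transit interval are dropped with a log
    entry (they cannot carry a rate).
    """
    t1 = dives["t1"].to_numpy(float)
    t4 = dives["t4"].to_numpy(float)
    dur = dives["duration"].to_numpy(float)
    ok = (t1 > 0) & (dur - t4 > 0)
    if not ok.all():
        logger.warning("dropping %d dives with zero-length transit intervals",
                       int((~ok).sum()))
    sub = dives.loc[ok]
    out = sub.copy()
    out["descent_rate"] = np.abs(sub["d1"].to_numpy(float) / t1[ok])
    out["ascent_rate"] = np.abs(sub["d4"].to_numpy(float)
                                / (dur[ok] - t4[ok]))
    return out


def dive_residual(dives: pd.DataFrame, scope: str = "pooled") -> pd.Series:
    """OLS residual of duration ~ max depth (s); fitting scope pooled or per-seal."""
    def _fit(df):
        if len(df) < 30:
            raise ValueError("dive-residual regression needs >= 30 dives")
        depth = df["max_depth"].to_numpy(float)
        if np.std(depth) < 1e-9:
            raise ValueError("degenerate depth variance in dive-residual fit")
        X = sm.add_constant(depth)
        fit = sm.OLS(df["duration"].to_numpy(float), X).fit()
        return pd.Series(fit.resid, index=df.index)

    if scope == "pooled":
        return _fit(dives).rename("dive_residual")
    if scope == "per-seal":
        return (dives.groupby("seal_id", group_keys=False)
                .apply(_fit, include_groups=False).rename("dive_residual"))
    raise ValueError(f"unknown scope {scope!r}")


def surface_residual(dives: pd.DataFrame, tau: float = 0.05,
                     scope: str = "pooled", max_fit_n: int = 30000,
                     seed: int = 0) -> pd.Series:
    """Surface interval minus the tau-quantile minimum-recovery envelope.

    The envelope is a linear quantile regression of surface interval on
    duration; ~(1 - tau) of residuals are positive by construction.
    Very large tables are fitted on a seeded subsample and predicted in
    full.
    """
    def _fit(df):
        if len(df) < 100:
            raise ValueError("surface-residual envelope needs >= 100 dives")
        sub = df
        if len(df) > max_fit_n:
            sub = df.sample(max_fit_n, random_state=seed)
        model = smf.quantreg("surface_interval ~ duration", sub)
        with warnings.catch_warnings():
            # IRLS for the quantile fit converges in estimate long before
            # its iteration cap on near-degenerate exponential tails
            warnings.simplefilter("ignore")
            fit = model.fit(q=tau, max_iter=2000)
        pred = (fit.params["Intercept"]
                + fit.params["duration"] * df["duration"].to_numpy(float))
        return pd.Series(df["surface_interval"].to_numpy(float) - pred,
                         index=df.index)

    if scope == "pooled":
        return _fit(dives).rename("surface_residual")
    if scope == "per-seal":
        return (dives.groupby("seal_id", group_keys=False)
                .apply(_fit, include_groups=False).rename("surface_residual"))
    raise ValueError(f"unknown scope {scope!r}")


def compute_metrics(dives: pd.DataFrame, scope: str = "pooled",
                    tau: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """All four per-dive metrics on a filtered summarised-dive table."""
    out = transit_rates(dives)
    out["dive_residual"] = dive_residual(out, scope=scope)
    out["surface_residual"] = surface_residual(out, tau=tau, scope=scope,
                                               seed=seed)
    out["day"] = np.floor(out["start_time"].to_numpy(float)
                          / SECONDS_PER_DAY).astype(int)
    return out


def window_aggregate(metrics: pd.DataFrame, drift_windows: pd.DataFrame,
                     window_days: int, mode: str = "block",
                     min_dives: int = 5,
                     anchors: dict | None = None) -> pd.DataFrame:
    """Per-window unweighted means of each metric, joined with DR and dDR.

    The window grid must match the one used for the drift series: same
    length and anchors (the contract is checked against the drift
    table's recorded window length).  Windows with fewer than
    ``min_dives`` dives are dropped and counted in ``attrs``.
    """
    w = int(window_days)
    if drift_windows.attrs.get("window_days", w) != w:
        raise ValueError(
            f"window misalignment: drift series was built at "
            f"{drift_windows.attrs['window_days']} days, metrics at {w}")
    has_pos = {"x", "y"}.issubset(metrics.columns)
    rows = []
    dropped = 0
    for seal, grp in metrics.groupby("seal_id", sort=True):
        anchor = (anchors or {}).get(seal, int(grp["day"].min()))
        day = grp["day"].to_numpy(int)
        if mode == "block":
            block = assign_blocks(day, w, anchor)
            sub = grp.assign(_block=block)
        elif mode == "running":
            # centred running mean of width w sampled at block mid-times
            parts = []
            for b in np.unique(assign_blocks(day, w, anchor)):
                mid = anchor + b * w + w / 2.0
                inwin = (day >= mid - w / 2.0) & (day < mid + w / 2.0)
                parts.append(grp.loc[inwin].assign(_block=b))
            sub = pd.concat(parts) if parts else grp.iloc[:0].assign(_block=0)
        else:
            raise ValueError(f"unknown window mode {mode!r}")
        cols = METRIC_COLS + (["x", "y"] if has_pos else [])
        agg = sub.groupby("_block")[cols].mean()
        agg["n_dives"] = sub.groupby("_block").size()
        small = agg["n_dives"] < min_dives
        dropped += int(small.sum())
        agg = agg[~small].reset_index().rename(columns={"_block": "block"})
        agg.insert(0, "seal_id", seal)
        agg["mid_day"] = anchor + agg["block"] * w + w / 2.0
        rows.append(agg)
    recs = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    merged = recs.merge(
        drift_windows[["seal_id", "block", "dr_window", "ddr"]],
        on=["seal_id", "block"], how="inner")
    merged.attrs["window_days"] = w
    merged.attrs["dropped_small_windows"] = dropped
    return merged


def classify_habitat(records: pd.DataFrame, bathy: BathymetryGrid,
                     isobath: float = SHELF_BREAK_M) -> pd.DataFrame:
    """Label each window record shelf/oceanic from its mean position.

    Shelf iff the interpolated seafloor is strictly shallower than the
    isobath (exactly on the isobath counts as oceanic).  Records whose
    mean position falls outside the grid are dropped with a log entry.
    """
    if not {"x", "y"}.issubset(records.columns):
        raise ValueError("records lack mean positions (x, y)")
    inside = bathy.contains(records["x"].to_numpy(float),
                            records["y"].to_numpy(float))
    if not inside.all():
        logger.warning("dropping %d window records outside the bathymetry grid",
                       int((~inside).sum()))
    out = records.loc[inside].copy()
    depth = bathy.depth_at(out["x"].to_numpy(float), out["y"].to_numpy(float))
    out["seafloor"] = depth
    out["habitat"] = np.where(depth < isobath, "shelf", "oceanic")
    return out
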