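"""Drift-rate estimation: candidate segments, Kalman screening, windowed dDR.

Passive drift segments — minutes-long stretches where a seal stops
swimming and sinks or rises at a buoyancy-determined rate — are the
in-situ window onto body condition.  The chain here is:

1. ``candidate_segments``: slow, long interior segments of summarised
   dives deeper than 100 m (shallower dives are excluded because
   residual lung air distorts buoyancy).
2. ``kalman_screen``: a robust random-walk Kalman filter treats each
   candidate's vertical speed as either an observation of the slowly
   varying drift-rate trajectory (Gaussian around the state) or a
   contaminant (uniform over the plausible speed range).  The posterior
   responsibility Z of the inlier component is the screen; candidates
   with Z > 0.5 are retained.  (q, r, w) are estimated by bounded-
   iteration EM with a Rauch-Tung-Striebel pass for the M-step moments.
3. ``daily_drift_rate`` / ``delta_dr``: unweighted per-day means, then
   non-overlapping blocks of 1, 2, 3, 7 or 10 days anchored at each
   seal's first at-sea day; foraging success is the between-block
   difference dDR_n = DR_n - DR_{n-1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0
WINDOW_LENGTHS = (1, 2, 3, 7, 10)


@dataclass
class CandidateCriteria:
    min_dive_depth: float = 100.0   # m; dives at most this deep are ignored
    min_duration: float = 400.0     # s; drift segments are many minutes long
    max_abs_speed: float = 0.6      # m/s; beyond this is active swimming
    #: drift begins when the seal stops swimming after its descent, so the
    #: segment before a candidate must be transit-like (fast); slow bottom
    #: segments following other slow segments are foraging, not drift
    require_transit_before: bool = True


@dataclass
class ScreenParams:
    speed_range: tuple[float, float] = (-1.5, 1.5)  # contaminant support
    z_threshold: float = 0.5
    max_iter: int = 30
    tol: float = 1e-5
    min_candidates: int = 5
    init_r: float = 2.25e-4         # (0.015 m/s)^2 observation variance
    init_q: float = 4e-4            # state RW variance per day
    init_w: float = 0.5
    max_r: float = 2.5e-3           # (0.05 m/s)^2; segment speeds from long
                                    # summarised segments cannot be noisier


def candidate_segments(dives: pd.DataFrame,
                       criteria: CandidateCriteria | None = None
                       ) -> pd.DataFrame:
    """Extract drift-segment candidates from filtered summarised dives.

    Interior segments (2-4 of 5) meeting the duration and speed bounds,
    from dives with ``max_depth`` above the 100 m cut.  Speed is the
    segment's vertical rate, positive upward (-d depth/dt).
    """
    crit = criteria or CandidateCriteria()
    deep = dives[dives["max_depth"] > crit.min_dive_depth]
    out = []
    pt = [(None, None), ("t1", "d1"), ("t2", "d2"), ("t3", "d3"), ("t4", "d4")]
    for seg in range(3):  # interior segments: p1->p2, p2->p3, p3->p4
        (ta, da), (tb, db) = pt[seg + 1], pt[seg + 2]
        dur = deep[tb].to_numpy(float) - deep[ta].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            speed = -(deep[db].to_numpy(float) - deep[da].to_numpy(float)) / dur
        ok = (dur >= crit.min_duration) & (np.abs(speed) <= crit.max_abs_speed)
        if crit.require_transit_before:
            if seg == 0:
                prev_rate = (deep["d1"].to_numpy(float)
                             / deep["t1"].to_numpy(float))
            else:
                (tp, dp), (tc, dc) = pt[seg], pt[seg + 1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    prev_rate = ((deep[dc].to_numpy(float)
                                  - deep[dp].to_numpy(float))
                                 / (deep[tc].to_numpy(float)
                                    - deep[tp].to_numpy(float)))
            ok &= np.abs(prev_rate) > crit.max_abs_speed
        sub = deep.loc[ok]
        mid = sub["start_time"].to_numpy(float) + 0.5 * (
            sub[ta].to_numpy(float) + sub[tb].to_numpy(float))
        cand = pd.DataFrame({
            "seal_id": sub["seal_id"].to_numpy(),
            "time": mid,
            "speed": speed[ok],
            "seg_duration": dur[ok],
            "dive_max_depth": sub["max_depth"].to_numpy(float),
            "segment": seg + 2,
            "dive_index": sub.index.to_numpy(),
        })
        if "is_drift" in sub.columns:
            cand["true_drift"] = sub["is_drift"].to_numpy() & (seg + 2 == 2)
        out.append(cand)
    if not out:
        return pd.DataFrame(columns=["seal_id", "time", "speed", "seg_duration",
                                     "dive_max_depth", "segment", "dive_index"])
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["seal_id", "time"]).reset_index(drop=True)


def _screen_one(y: np.ndarray, t_days: np.ndarray, par: ScreenParams):
    """Robust Kalman EM on one seal's candidate series; returns Z.

    E-step: forward pass with responsibility-deflated observation
    variance, then an RTS smoother; responsibilities Z come from the
    smoothed posterior predictive against a uniform contaminant.
    M-step: w is the mean responsibility; r a median-based (hence
    outlier-resistant) weighted residual variance; q a responsibility-
    weighted increment variance per day.  Iterated to ``max_iter`` or
    parameter convergence.
    """
    n = y.size
    dt = np.maximum(np.diff(t_days), 1e-4)
    lo, hi = par.speed_range
    u_dens = 1.0 / (hi - lo)
    q, r, w = par.init_q, par.init_r, par.init_w
    W = np.full(n, par.init_w)  # per-observation working weights
    Z = np.full(n, par.init_w)

    for _ in range(par.max_iter):
        m = np.zeros(n)
        P = np.zeros(n)
        mp = np.zeros(n)
        Pp = np.zeros(n)
        m_prev, P_prev = np.median(y[:min(7, n)]), 1e-2
        for i in range(n):
            if i > 0:
                m_prev, P_prev = m[i - 1], P[i - 1] + q * dt[i - 1]
            mp[i], Pp[i] = m_prev, P_prev
            r_eff = r / max(W[i], 1e-6)
            K = P_prev / (P_prev + r_eff)
            m[i] = m_prev + K * (y[i] - m_prev)
            P[i] = (1.0 - K) * P_prev
        # RTS smoother with lag-one covariances
        ms, Ps = m.copy(), P.copy()
        C = np.zeros(n - 1) if n > 1 else np.zeros(0)
        for i in range(n - 2, -1, -1):
            G = P[i] / Pp[i + 1]
            ms[i] = m[i] + G * (ms[i + 1] - mp[i + 1])
            Ps[i] = P[i] + G * G * (Ps[i + 1] - Pp[i + 1])
            C[i] = G * Ps[i + 1]
        S = Ps + r
        dens_in = np.exp(-0.5 * (y - ms) ** 2 / S) / np.sqrt(2.0 * np.pi * S)
        Z = w * dens_in / (w * dens_in + (1.0 - w) * u_dens + 1e-300)
        W = Z
        w_new = float(np.clip(Z.mean(), 0.02, 0.995))
        high = Z > 0.8
        r_new = r
        if high.sum() > 10:
            # median of chi^2_1 is 0.455: median-unbiased variance estimate
            r_new = float(np.median((y - ms)[high] ** 2) / 0.455
                          + Ps[high].mean())
        r_new = float(np.clip(r_new, 1e-8, par.max_r))
        if n > 1:
            inc = (np.diff(ms) ** 2 + Ps[1:] + Ps[:-1] - 2.0 * C) / dt
            wq = Z[1:] * Z[:-1]
            q_new = float(np.clip(np.sum(wq * inc) / max(np.sum(wq), 1e-9),
                                  1e-10, 1.0))
        else:
            q_new = q
        done = (abs(w_new - w) < par.tol
                and abs(r_new - r) < par.tol * max(r, 1e-6)
                and abs(q_new - q) < par.tol * max(q, 1e-8))
        q, r, w = q_new, r_new, w_new
        if done:
            break
    return Z, {"q": q, "r": r, "w": w}


def kalman_screen(candidates: pd.DataFrame,
                  params: ScreenParams | None = None) -> pd.DataFrame:
    """Screen candidates per seal; adds inlier probability Z and retained flag.

    Seals with fewer than ``min_candidates`` candidates cannot support
    the trajectory model: their candidates are flagged unscreened
    (Z = NaN, retained False) and a warning is logged.
    """
    par = params or ScreenParams()
    out = candidates.sort_values(["seal_id", "time"]).reset_index(drop=True)
    out["Z"] = np.nan
    out["retained"] = False
    for seal, grp in out.groupby("seal_id", sort=False):
        if len(grp) < par.min_candidates:
            logger.warning("seal %s: only %d drift candidates; left unscreened",
                           seal, len(grp))
            continue
        y = grp["speed"].to_numpy(float)
        t_days = grp["time"].to_numpy(float) / SECONDS_PER_DAY
        Z, fitted = _screen_one(y, t_days, par)
        out.loc[grp.index, "Z"] = Z
        out.loc[grp.index, "retained"] = Z > par.z_threshold
    return out


def daily_drift_rate(estimates: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per seal-day mean of retained drift speeds.

    Days without retained segments are absent from the output (missing,
    never zero).
    """
    kept = estimates[estimates["retained"]].copy()
    kept["day"] = np.floor(kept["time"].to_numpy(float) / SECONDS_PER_DAY
                           ).astype(int)
    g = kept.groupby(["seal_id", "day"])["speed"]
    out = g.mean().rename("dr").reset_index()
    out["n_segments"] = g.size().to_numpy()
    return out


def assign_blocks(days: np.ndarray, window_days: int, anchor: int) -> np.ndarray:
    """Non-overlapping consecutive block index for integer days."""
    return (np.asarray(days, int) - int(anchor)) // int(window_days)


def delta_dr(daily: pd.DataFrame, window_days: int, mode: str = "block",
             min_segments: int = 1,
             anchors: dict | None = None) -> pd.DataFrame:
    """Windowed drift rate and its between-window change dDR.

    Blocks are consecutive, non-overlapping spans of ``window_days``
    anchored at each seal's first at-sea day (pass ``anchors`` to share
    an anchor with the dive-metric aggregation).  A block's DR is the
    unweighted mean of the daily DR values present in it; dDR at block n
    is DR_n - DR_{n-1} and is missing unless both blocks are valid and
    consecutive.  ``mode="running"`` instead samples a centred running
    mean of width ``window_days`` at each block's mid-time.
    """
    if mode not in ("block", "running"):
        raise ValueError(f"unknown window mode {mode!r}")
    w = int(window_days)
    rows = []
    for seal, grp in daily.groupby("seal_id", sort=True):
        anchor = (anchors or {}).get(seal, int(grp["day"].min()))
        day = grp["day"].to_numpy(int)
        if mode == "block":
            block = assign_blocks(day, w, anchor)
            agg = (grp.assign(block=block)
                   .groupby("block")
                   .agg(dr_window=("dr", "mean"),
                        n_segments=("n_segments", "sum"),
                        n_days=("day", "size")))
        else:
            blocks = np.unique(assign_blocks(day, w, anchor))
            vals = {}
            for b in blocks:
                mid = anchor + b * w + w / 2.0
                inwin = (day >= mid - w / 2.0) & (day < mid + w / 2.0)
                if inwin.any():
                    vals[b] = (grp["dr"].to_numpy()[inwin].mean(),
                               int(grp["n_segments"].to_numpy()[inwin].sum()),
                               int(inwin.sum()))
            agg = pd.DataFrame.from_dict(
                vals, orient="index",
                columns=["dr_window", "n_segments", "n_days"])
            agg.index.name = "block"
        agg = agg[agg["n_segments"] >= min_segments]
        agg = agg.reset_index()
        agg["ddr"] = np.where(
            np.diff(agg["block"], prepend=agg["block"].iloc[0] - 2) == 1,
            agg["dr_window"].diff(), np.nan) if len(agg) else np.nan
        agg.insert(0, "seal_id", seal)
        agg["mid_day"] = anchor + agg["block"] * w + w / 2.0
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["seal_id", "block", "dr_window", "n_segments", "n_days",
                 "ddr", "mid_day"])
    out.attrs["window_days"] = w
    out.attrs["mode"] = mode
    return out
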