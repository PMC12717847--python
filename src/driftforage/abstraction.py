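"""Broken-stick abstraction of high-resolution dive profiles.

Mimics the onboard summarisation of satellite-relay data loggers:
starting from the two surface endpoints, iteratively add the sample
with the greatest absolute vertical deviation from the current
piecewise-linear reconstruction, until k (= 4, the tag firmware's
choice) interior inflection points are selected.  Deviation is measured
vertically at equal time, and ties break to the earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AbstractionResult:
    times: np.ndarray         # k+2 selected times incl. endpoints, sorted
    depths: np.ndarray        # matching depths
    indices: np.ndarray       # selected sample indices, sorted by time
    max_error: float          # final max |reconstruction - observed| (m)
    iterations: list          # per-iteration (chosen index, deviation)


def broken_stick(times, depths, k: int = 4, dive_name: str = "") -> AbstractionResult:
    """Select the k interior inflection points of one dive profile."""
    t = np.asarray(times, float)
    d = np.asarray(depths, float)
    if t.size != d.size:
        raise ValueError("times and depths differ in length")
    if t.size < k + 2:
        raise ValueError(
            f"profile {dive_name or '<unnamed>'} has {t.size} samples; "
            f"broken-stick with k={k} needs at least {k + 2}")
    sel = [0, t.size - 1]
    iterations = []
    for _ in range(k):
        sel_sorted = sorted(sel)
        recon = np.interp(t, t[sel_sorted], d[sel_sorted])
        dev = np.abs(recon - d)
        dev[sel_sorted] = -1.0  # never reselect
        idx = int(np.argmax(dev))  # argmax takes the earliest tie
        iterations.append((idx, float(dev[idx])))
        sel.append(idx)
    order = np.argsort(sel)
    sel = np.asarray(sel)[order]
    recon = np.interp(t, t[sel], d[sel])
    return AbstractionResult(
        times=t[sel], depths=d[sel], indices=sel,
        max_error=float(np.max(np.abs(recon - d))), iterations=iterations)


def reconstruct(result: AbstractionResult, query_times) -> np.ndarray:
    """Piecewise-linear depth at query times; exact at selected points."""
    q = np.asarray(query_times, float)
    lo, hi = result.times[0], result.times[-1]
    if np.any(q < lo) or np.any(q > hi):
        raise ValueError(f"query time outside dive span [{lo}, {hi}]")
    return np.interp(q, result.times, result.depths)


def summarise_profiles(profiles, k: int = 4) -> pd.DataFrame:
    """Broken-stick summarisation of DiveProfiles to a summarised-dive table."""
    rows = []
    for p in profiles:
        res = broken_stick(p.times, p.depths, k=k,
                           dive_name=f"{p.seal_id}@{p.start_time:.0f}")
        interior_t = res.times[1:-1]
        interior_d = res.depths[1:-1]
        row = {"seal_id": p.seal_id, "start_time": p.start_time}
        for j in range(k):
            row[f"t{j + 1}"] = interior_t[j]
            row[f"d{j + 1}"] = interior_d[j]
        row.update({
            "max_depth": float(np.max(p.depths)),
            "duration": float(p.duration),
            "surface_interval": float(p.surface_interval),
        })
        rows.append(row)
    return pd.DataFrame(rows)
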