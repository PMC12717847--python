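"""Synthetic southern-elephant-seal world generator.

Generates, with known ("truth") parameters, everything the downstream
analysis consumes: per-seal daily body-condition trajectories expressed
as drift rate (DR, m/s, positive upward), dive records summarised to
four inflection points in the style of a CTD-SRDL tag, noisy ARGOS
position fixes, and a planar bathymetry grid.

The generative model, briefly:

* A seal's condition proxy is its drift rate.  Seals depart negatively
  buoyant (DR ~ -0.3 m/s) and drift toward neutral over months as net
  energy gain accumulates.  Daily net gain is a baseline trend plus a
  spatially autocorrelated prey-field anomaly sampled along the track,
  so day-to-day foraging success (dDR = DR_d - DR_{d-1}) fluctuates.
* Each dive-effort metric m on day d is generated as
  base_m(depth) + gamma_m * dDR_d + A_m * h_m(DR_d) + ar1_m(d) + noise,
  where gamma_m is the linear foraging-success effect the response
  model later tries to recover, h_m is a smooth monotone buoyancy
  effect, and ar1_m is a within-seal AR(1) daily latent.
* A small fraction of dives (~3.5%) contain a passive drift segment
  whose vertical depth rate equals -(DR + noise); these occur only in
  dives deeper than 100 m.
* Dives are summarised to 4 interior inflection points on a 4-s grid;
  only a random daily subsample is "transmitted" (observed), and 2-15
  ARGOS fixes/day are emitted with class-dependent isotropic noise.

All randomness flows through integer-indexed per-seal generators, so a
fixed seed yields bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .bathymetry import BathymetryGrid, BathymetrySpec, make_bathymetry

METRICS = ("descent", "ascent", "dive_res", "surf_res")

#: direction of the buoyancy effect on each metric: transit rates fall as
#: seals approach neutral buoyancy, dive and surface residuals rise.
BUOY_DIRECTION = {"descent": -1.0, "ascent": -1.0, "dive_res": 1.0, "surf_res": 1.0}

#: conventional ARGOS location-class isotropic error SDs (m per axis)
DEFAULT_ARGOS_SDS = {"3": 250.0, "2": 500.0, "1": 1000.0,
                     "0": 2000.0, "A": 4000.0, "B": 8000.0}
DEFAULT_ARGOS_PROBS = {"3": 0.03, "2": 0.06, "1": 0.16,
                       "0": 0.25, "A": 0.25, "B": 0.25}

SECONDS_PER_DAY = 86400.0


def buoyancy_shape(dr: np.ndarray) -> np.ndarray:
    """Smooth monotone buoyancy curve, ~(-0.5, 0.5) over the DR range.

    A saturating nonlinearity centred mid-range so the spline smooth in
    the response model has genuine curvature to absorb.
    """
    return 0.5 * np.tanh((np.asarray(dr, float) + 0.125) / 0.1)


@dataclass
class SimConfig:
    """Generative conditions for one synthetic deployment cohort."""

    n_seals: int = 30
    days_per_seal: int = 180
    dives_per_day_mean: float = 60.0
    transmitted_dives_range: tuple[int, int] = (30, 110)
    argos_fixes_per_day_range: tuple[int, int] = (2, 15)
    drift_dive_prob: float = 0.035
    sampling_interval: float = 4.0
    # linear foraging-success effects (per m/s of dDR)
    gamma_descent: float = 2.0
    gamma_ascent: float = 2.0
    gamma_diveres: float = -3000.0
    gamma_surfres: float = 0.0
    # peak-to-peak scale of the smooth buoyancy effect per metric
    buoyancy_effect_amplitudes: dict = field(default_factory=lambda: {
        "descent": 0.40, "ascent": 0.40, "dive_res": 300.0, "surf_res": 15.0})
    # per-dive observation noise SDs (m/s, m/s, s, s) + drift-segment speed SD
    noise_sds: dict = field(default_factory=lambda: {
        "descent": 0.12, "ascent": 0.12, "dive_res": 80.0, "surf_res": 5.0,
        "drift": 0.01})
    # within-seal AR(1) daily latent per metric: stationary SDs and phi/day
    ar1_sds: dict = field(default_factory=lambda: {
        "descent": 0.04, "ascent": 0.04, "dive_res": 40.0, "surf_res": 8.0})
    ar1_phi: float = 0.6
    # seal-to-seal heterogeneity: per-seal dDR slope multiplier sd (fraction
    # of gamma) and per-seal intercept shifts (metric units)
    seal_slope_sd_frac: float = 0.2
    seal_intercept_sds: dict = field(default_factory=lambda: {
        "descent": 0.05, "ascent": 0.05, "dive_res": 60.0, "surf_res": 8.0})
    # condition dynamics (drift-rate units per day)
    dr_start_mean: float = -0.28
    dr_start_sd: float = 0.03
    dr_equilibrium: float = -0.05   # gain decelerates approaching this DR
    dr_recovery_rate: float = 0.025  # per day, toward the equilibrium
    dr_fluct_sd: float = 0.025
    dr_bounds: tuple[float, float] = (-0.35, 0.10)
    lipid_neutral: float = 0.35
    condition_slope: float = 1.0  # DR per unit lipid proxy above neutral
    # movement (m/day)
    step_mean: float = 45_000.0
    step_sd: float = 12_000.0
    heading_sd: float = 0.5
    eastward_bias: float = 12_000.0
    eastward_bias_days: int = 45
    argos_class_sds: dict = field(default_factory=lambda: dict(DEFAULT_ARGOS_SDS))
    argos_class_probs: dict = field(default_factory=lambda: dict(DEFAULT_ARGOS_PROBS))
    prey_smooth_cells: float = 3.0
    bathymetry_spec: BathymetrySpec = field(default_factory=BathymetrySpec)
    emit_profiles: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.drift_dive_prob <= 1.0:
            raise ValueError("drift_dive_prob must lie in [0, 1]")
        for name in ("n_seals", "days_per_seal"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.dives_per_day_mean <= 0 or self.sampling_interval <= 0:
            raise ValueError("rates and intervals must be positive")
        lo, hi = self.transmitted_dives_range
        if not (1 <= lo <= hi <= 186):
            raise ValueError("transmitted_dives_range must lie within [1, 186]")
        alo, ahi = self.argos_fixes_per_day_range
        if not (1 <= alo <= ahi):
            raise ValueError("argos_fixes_per_day_range must be ordered and >= 1")
        for key, val in [*self.noise_sds.items(), *self.ar1_sds.items(),
                         *self.buoyancy_effect_amplitudes.items()]:
            if not np.isfinite(val) or val < 0:
                raise ValueError(f"non-finite or negative config value for {key}")
        scalars = [self.gamma_descent, self.gamma_ascent, self.gamma_diveres,
                   self.gamma_surfres, self.dr_recovery_rate,
                   self.dr_equilibrium, self.dr_fluct_sd, self.step_mean,
                   self.ar1_phi]
        if not all(np.isfinite(v) for v in scalars):
            raise ValueError("non-finite config value")


@dataclass
class DiveProfile:
    """High-resolution (regularly sampled) depth record for one dive."""

    seal_id: str
    start_time: float  # seconds since seal departure
    depths: np.ndarray  # metres positive down; endpoints at the surface
    sampling_interval: float
    surface_interval: float
    drift_segment: tuple | None = None  # (start_idx, end_idx, speed m/s up)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.depths.size) * self.sampling_interval

    @property
    def duration(self) -> float:
        return (self.depths.size - 1) * self.sampling_interval


@dataclass
class SimulationBundle:
    config: SimConfig
    truth: pd.DataFrame       # one row per seal-day
    dives: pd.DataFrame       # one row per generated dive (all, with flags)
    profiles: list            # DiveProfile for transmitted dives (optional)
    fixes: pd.DataFrame       # ARGOS fixes with class labels and noise SDs
    bathy: BathymetryGrid
    truth_params: dict        # generative coefficients, for recovery tests

    @property
    def transmitted(self) -> pd.DataFrame:
        return self.dives[self.dives["transmitted"]].reset_index(drop=True)


def _seal_rng(seed: int, seal_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, 7919, seal_index])


def _prey_anomaly_field(bathy: BathymetryGrid, rng: np.random.Generator,
                        smooth_cells: float) -> np.ndarray:
    """Standardised lognormal patch-quality anomaly on the bathy grid."""
    raw = rng.standard_normal((bathy.y.size, bathy.x.size))
    z = gaussian_filter(raw, sigma=smooth_cells, mode="reflect")
    z = (z - z.mean()) / z.std()
    q = np.exp(0.6 * z)
    return (q - q.mean()) / q.std()


def _simulate_path(cfg: SimConfig, bathy: BathymetryGrid,
                   rng: np.random.Generator) -> np.ndarray:
    """Daily waypoints (days+1, 2): correlated walk with early seaward bias."""
    n = cfg.days_per_seal + 1
    steps = np.clip(rng.normal(cfg.step_mean, cfg.step_sd, n - 1),
                    5_000.0, 2.5 * cfg.step_mean)
    heading = np.cumsum(rng.normal(0.0, cfg.heading_sd, n - 1))
    dx = steps * np.cos(heading)
    dy = steps * np.sin(heading)
    days = np.arange(n - 1)
    dx = dx + cfg.eastward_bias * (days < cfg.eastward_bias_days)
    start = np.array([cfg.bathymetry_spec.break_x - 50_000.0,
                      0.5 * (bathy.y[0] + bathy.y[-1])])
    start = start + rng.normal(0.0, 20_000.0, 2)
    pos = np.vstack([start, start + np.cumsum(np.column_stack([dx, dy]), axis=0)])
    # reflect (triangle-fold) at the domain walls so long trips keep moving
    # through fresh prey cells instead of sticking to a boundary
    margin = 5_000.0
    for ax, axis_vals in ((0, bathy.x), (1, bathy.y)):
        lo, hi = axis_vals[0] + margin, axis_vals[-1] - margin
        span = hi - lo
        b = np.mod(pos[:, ax] - lo, 2.0 * span)
        pos[:, ax] = lo + np.where(b > span, 2.0 * span - b, b)
    return pos


def _simulate_condition(cfg: SimConfig, anomaly: np.ndarray, pos: np.ndarray,
                        bathy: BathymetryGrid, rng: np.random.Generator):
    """Daily DR trajectory (with one burn-in day) and net daily gain."""
    n = cfg.days_per_seal
    ix = np.clip(np.searchsorted(bathy.x, pos[:n, 0]) - 1, 0, bathy.x.size - 1)
    iy = np.clip(np.searchsorted(bathy.y, pos[:n, 1]) - 1, 0, bathy.y.size - 1)
    local = anomaly[iy, ix]
    fluct = cfg.dr_fluct_sd * local + rng.normal(0.0, 0.2 * cfg.dr_fluct_sd, n)
    dr = np.empty(n + 1)
    dr[0] = rng.normal(cfg.dr_start_mean, cfg.dr_start_sd)
    lo, hi = cfg.dr_bounds
    dr[0] = np.clip(dr[0], lo, hi)
    net = np.empty(n)
    for d in range(n):
        # recovery decelerates as condition approaches its equilibrium
        net[d] = (cfg.dr_recovery_rate * (cfg.dr_equilibrium - dr[d])
                  + fluct[d])
        dr[d + 1] = np.clip(dr[d] + net[d], lo, hi)
    return dr, net  # dr[0] is the burn-in (pre-departure) value


def _ar1_series(n: int, phi: float, sd: float, rng: np.random.Generator):
    if sd == 0 or n == 0:
        return np.zeros(n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(max(1.0 - phi ** 2, 1e-12))
    eps = rng.normal(0.0, innov_sd, n - 1) if n > 1 else np.empty(0)
    for d in range(1, n):
        out[d] = phi * out[d - 1] + eps[d - 1]
    return out


def _snap(t: np.ndarray, dt: float) -> np.ndarray:
    return np.round(np.asarray(t, float) / dt) * dt


def _enforce_increasing(cols: list[np.ndarray], dt: float) -> None:
    """In-place: make each successive time column at least dt later."""
    for a, b in zip(cols[:-1], cols[1:]):
        np.maximum(b, a + dt, out=b)


def _simulate_seal_dives(cfg: SimConfig, seal_id: str, dr: np.ndarray,
                         net: np.ndarray, pos: np.ndarray,
                         bathy: BathymetryGrid, rng: np.random.Generator
                         ) -> pd.DataFrame:
    """All dives for one seal as a summarised-dive table with truth columns."""
    n_days = cfg.days_per_seal
    dt = cfg.sampling_interval
    dr_day = dr[1:]               # DR on days 0..n-1
    ddr_day = np.diff(dr)         # dDR on days 0..n-1 (uses burn-in day)

    amps = cfg.buoyancy_effect_amplitudes
    shape = {m: BUOY_DIRECTION[m] * amps[m] * buoyancy_shape(dr_day)
             for m in METRICS}
    ar1 = {m: _ar1_series(n_days, cfg.ar1_phi, cfg.ar1_sds[m], rng)
           for m in METRICS}
    gammas = {"descent": cfg.gamma_descent, "ascent": cfg.gamma_ascent,
              "dive_res": cfg.gamma_diveres, "surf_res": cfg.gamma_surfres}
    # seal-level random slope (multiplicative on gamma) and intercept
    slope_mult = {m: 1.0 + rng.normal(0.0, cfg.seal_slope_sd_frac)
                  for m in METRICS}
    icpt = {m: rng.normal(0.0, cfg.seal_intercept_sds[m]) for m in METRICS}
    effect = {m: gammas[m] * slope_mult[m] * ddr_day + shape[m] + ar1[m] + icpt[m]
              for m in METRICS}

    n_dives = rng.poisson(cfg.dives_per_day_mean, n_days)
    n_dives = np.maximum(n_dives, 1)
    day = np.repeat(np.arange(n_days), n_dives)
    tot = day.size
    start = day * SECONDS_PER_DAY + rng.uniform(0.0, SECONDS_PER_DAY - 7200.0, tot)

    sf = np.asarray(bathy.depth_at(pos[day, 0], pos[day, 1]))
    is_drift = rng.random(tot) < cfg.drift_dive_prob
    is_drift &= 0.88 * sf > 120.0  # drift segments need room below 100 m

    noise = cfg.noise_sds
    rd = np.clip(1.10 + effect["descent"][day] + rng.normal(0, noise["descent"], tot),
                 0.35, 3.2)
    ra = np.clip(1.00 + effect["ascent"][day] + rng.normal(0, noise["ascent"], tot),
                 0.35, 3.2)

    # --- geometry: non-drift dives -------------------------------------
    depth = np.exp(rng.normal(np.log(420.0), 0.45, tot))
    depth = np.clip(depth, 12.0, np.minimum(1100.0, 0.92 * sf))
    # outer inflection depths vary widely: bottom-phase vertical excursions
    # during active hunting span tens to hundreds of metres, and the maximum
    # depth falls either at the end of the descent or mid-bottom
    f1 = rng.uniform(0.70, 0.97, tot)
    f4 = rng.uniform(0.70, 0.97, tot)
    max_at_descent = rng.random(tot) < 0.5
    d1 = np.where(max_at_descent, depth, f1 * depth)
    d2 = np.where(max_at_descent, depth * rng.uniform(0.55, 0.95, tot), depth)
    d3 = depth * rng.uniform(0.55, 0.95, tot)
    d3 = np.where(max_at_descent & (rng.random(tot) < 0.5),
                  depth * rng.uniform(0.80, 1.0, tot), d3)
    d4 = f4 * depth
    transit = d1 / rd + d4 / ra
    dur_offset = effect["dive_res"][day] + rng.normal(0, noise["dive_res"], tot)
    T = np.maximum(380.0 + 2.0 * depth + dur_offset, transit + 240.0)
    bottom = T - transit
    t1 = d1 / rd
    t2 = t1 + bottom * rng.uniform(0.28, 0.40, tot)
    t3 = t1 + bottom * rng.uniform(0.60, 0.72, tot)
    t4 = t1 + bottom
    drift_speed = np.full(tot, np.nan)

    # --- geometry: drift dives (overwrite the flagged subset) ----------
    k = int(is_drift.sum())
    if k:
        i = np.flatnonzero(is_drift)
        sfi = sf[i]
        d1i = np.clip(rng.uniform(200.0, 600.0, k), 120.0, 0.88 * sfi)
        duri = rng.uniform(420.0, 680.0, k)
        rate = -(dr_day[day[i]] + rng.normal(0.0, noise["drift"], k))  # depth rate
        # keep the whole drift run between 35 m and the seafloor: shoal the
        # start depth, then shorten the segment, before ever distorting speed
        sink = rate > 0
        d1i = np.where(sink, np.minimum(d1i, 0.93 * sfi - rate * duri),
                       np.maximum(d1i, 35.0 - rate * duri))
        d1i = np.clip(d1i, 120.0, 0.88 * sfi)
        with np.errstate(divide="ignore", invalid="ignore"):
            dur_max = np.where(sink, (0.93 * sfi - d1i) / np.maximum(rate, 1e-9),
                               (d1i - 35.0) / np.maximum(-rate, 1e-9))
        # a drift that would hit the seafloor (or surface layer) ends early:
        # the segment stays truthful in speed but may be short
        duri = np.clip(np.minimum(duri, dur_max), 60.0, None)
        d2i = np.clip(d1i + rate * duri, 35.0, 0.93 * sfi)
        t1i = d1i / rd[i]
        t2i = t1i + duri
        t3i = t2i + rng.uniform(70.0, 150.0, k)
        d3i = np.minimum(np.maximum(d1i, d2i) * 1.06, 0.92 * sfi)
        t4i = t3i + rng.uniform(70.0, 150.0, k)
        d4i = 0.90 * d3i
        Ti = t4i + d4i / ra[i]
        for arr, val in [(t1, t1i), (t2, t2i), (t3, t3i), (t4, t4i), (T, Ti),
                         (d1, d1i), (d2, d2i), (d3, d3i), (d4, d4i)]:
            arr[i] = val
        depth[i] = np.max(np.column_stack([d1i, d2i, d3i, d4i]), axis=1)
        dur_offset[i] = np.nan

    # snap to the tag's sampling grid and keep times strictly increasing
    t1, t2, t3, t4, T = (_snap(a, dt) for a in (t1, t2, t3, t4, T))
    np.maximum(t1, dt, out=t1)
    _enforce_increasing([t1, t2, t3, t4, T], dt)
    if k:
        i = np.flatnonzero(is_drift)
        drift_speed[i] = -(d2[i] - d1[i]) / (t2[i] - t1[i])

    surf = (45.0 + 0.035 * T + rng.exponential(55.0, tot)
            + effect["surf_res"][day] + rng.normal(0.0, noise["surf_res"], tot))
    surf = np.maximum(surf, 10.0)

    n_tx = rng.integers(cfg.transmitted_dives_range[0],
                        cfg.transmitted_dives_range[1] + 1, n_days)
    transmitted = np.zeros(tot, bool)
    offsets = np.concatenate([[0], np.cumsum(n_dives)])
    for d in range(n_days):
        lo, hi = offsets[d], offsets[d + 1]
        take = min(n_tx[d], hi - lo)
        transmitted[lo + rng.choice(hi - lo, take, replace=False)] = True

    max_depth = np.max(np.column_stack([d1, d2, d3, d4]), axis=1)
    return pd.DataFrame({
        "seal_id": seal_id, "start_time": start,
        "t1": t1, "d1": d1, "t2": t2, "d2": d2,
        "t3": t3, "d3": d3, "t4": t4, "d4": d4,
        "max_depth": max_depth, "duration": T, "surface_interval": surf,
        "day": day, "transmitted": transmitted, "is_drift": is_drift,
        "drift_speed_true": drift_speed, "dr_true": dr_day[day],
        "ddr_true": ddr_day[day], "duration_offset_true": dur_offset,
        "seafloor": sf,
    })


def profile_from_points(point_times, point_depths, sampling_interval: float
                        ) -> np.ndarray:
    """Sample a piecewise-linear dive polyline on the regular tag grid."""
    t = np.asarray(point_times, float)
    d = np.asarray(point_depths, float)
    grid = np.arange(0.0, t[-1] + sampling_interval / 2, sampling_interval)
    return np.interp(grid, t, d)


def simulate_dive(day_state: dict, rng: np.random.Generator) -> DiveProfile:
    """Generate one high-resolution dive profile from a daily state.

    ``day_state`` carries ``dr_true``, ``ddr_true``, ``seafloor`` and
    optionally ``drift_segment`` = (start_depth m, duration s, speed m/s,
    positive upward) requesting a planted passive segment.  A seafloor
    shallower than 15 m yields a surface-bound shallow dive that the
    exclusion filter is meant to remove later.
    """
    dt = float(day_state.get("sampling_interval", 4.0))
    sf = float(day_state["seafloor"])
    seal_id = str(day_state.get("seal_id", "seal"))
    start = float(day_state.get("start_time", 0.0))
    if sf < 15.0:
        dur = _snap(240.0, dt)
        depths = profile_from_points([0, dur / 2, dur], [0, max(sf - 1, 1), 0], dt)
        return DiveProfile(seal_id, start, depths, dt,
                           float(rng.exponential(60.0) + 40.0))

    dr = float(day_state.get("dr_true", -0.2))
    ddr = float(day_state.get("ddr_true", 0.0))
    rd = float(np.clip(1.10 + 2.0 * ddr + rng.normal(0, 0.1), 0.35, 3.2))
    ra = float(np.clip(1.00 + 2.0 * ddr + rng.normal(0, 0.1), 0.35, 3.2))
    seg = day_state.get("drift_segment")
    if seg is not None:
        d_from, dur, speed = map(float, seg)
        d1 = min(d_from, 0.88 * sf)
        t1 = d1 / rd
        t2 = t1 + dur
        d2 = float(np.clip(d1 - speed * dur, 1.0, 0.95 * sf))
        t3 = t2 + 100.0
        d3 = min(max(d1, d2) * 1.05, 0.95 * sf)
        t4 = t3 + 100.0
        d4 = 0.9 * d3
        T = t4 + d4 / ra
    else:
        depth = float(np.clip(np.exp(rng.normal(np.log(420.0), 0.45)),
                              12.0, min(1100.0, 0.92 * sf)))
        d1, d4 = 0.90 * depth, 0.90 * depth
        t1 = d1 / rd
        T = max(380.0 + 2.0 * depth + rng.normal(0, 60.0), t1 + d4 / ra + 240.0)
        t4 = T - d4 / ra
        bottom = t4 - t1
        t2, t3 = t1 + 0.33 * bottom, t1 + 0.66 * bottom
        d2, d3 = depth, 0.86 * depth

    t1, t2, t3, t4, T = (float(_snap(v, dt)) for v in (t1, t2, t3, t4, T))
    times = [0.0, max(t1, dt)]
    for v in (t2, t3, t4, T):
        times.append(max(v, times[-1] + dt))
    depths_pts = [0.0, d1, d2, d3, d4, 0.0]
    depths = profile_from_points(times, depths_pts, dt)
    drift_idx = None
    if seg is not None:
        i0, i1 = int(round(times[1] / dt)), int(round(times[2] / dt))
        drift_idx = (i0, i1, -(d2 - d1) / (times[2] - times[1]))
    return DiveProfile(seal_id, start, depths, dt,
                       float(rng.exponential(55.0) + 45.0 + 0.035 * T), drift_idx)


def add_argos_noise(true_positions: pd.DataFrame, schedule: pd.DataFrame,
                    rng: np.random.Generator,
                    class_sds: dict | None = None) -> pd.DataFrame:
    """Noisy ARGOS fixes from true waypoints and a (time, class) schedule.

    True positions are linearly interpolated to the scheduled fix times;
    isotropic Gaussian noise with the class SD is added per axis.
    """
    class_sds = class_sds or DEFAULT_ARGOS_SDS
    if len(schedule) == 0:
        return pd.DataFrame(columns=["time", "x", "y", "klass", "sd"])
    tp = true_positions.sort_values("time")
    t = schedule["time"].to_numpy(float)
    x = np.interp(t, tp["time"].to_numpy(float), tp["x"].to_numpy(float))
    y = np.interp(t, tp["time"].to_numpy(float), tp["y"].to_numpy(float))
    sd = schedule["klass"].map(class_sds).to_numpy(float)
    if np.any(~np.isfinite(sd)):
        raise ValueError("schedule contains a class with no configured SD")
    out = pd.DataFrame({
        "time": t,
        "x": x + rng.normal(0.0, 1.0, t.size) * sd,
        "y": y + rng.normal(0.0, 1.0, t.size) * sd,
        "klass": schedule["klass"].to_numpy(),
        "sd": sd,
    })
    return out


def _seal_fixes(cfg: SimConfig, seal_id: str, pos: np.ndarray,
                rng: np.random.Generator) -> pd.DataFrame:
    days = cfg.days_per_seal
    lo, hi = cfg.argos_fixes_per_day_range
    n_fix = rng.integers(lo, hi + 1, days)
    t = np.concatenate([
        d * SECONDS_PER_DAY + np.sort(rng.uniform(0, SECONDS_PER_DAY, n))
        for d, n in enumerate(n_fix)])
    classes = np.array(list(cfg.argos_class_probs))
    probs = np.array(list(cfg.argos_class_probs.values()), float)
    probs = probs / probs.sum()
    klass = rng.choice(classes, t.size, p=probs)
    truth = pd.DataFrame({
        "time": np.arange(days + 1) * SECONDS_PER_DAY,
        "x": pos[:, 0], "y": pos[:, 1]})
    fixes = add_argos_noise(truth, pd.DataFrame({"time": t, "klass": klass}),
                            rng, cfg.argos_class_sds)
    fixes.insert(0, "seal_id", seal_id)
    return fixes


def simulate_world(config: SimConfig) -> SimulationBundle:
    """Generate a full synthetic deployment under *config*."""
    config.validate()
    world_rng = np.random.default_rng([config.seed, 104729])
    bathy = make_bathymetry(config.bathymetry_spec)
    anomaly = _prey_anomaly_field(bathy, world_rng, config.prey_smooth_cells)

    truth_rows, dive_tables, fix_tables, profiles = [], [], [], []
    sexes = ["F", "M"]
    for s in range(config.n_seals):
        rng = _seal_rng(config.seed, s)
        seal_id = f"seal{s:03d}"
        sex = sexes[s % 2]
        pos = _simulate_path(config, bathy, rng)
        dr, net = _simulate_condition(config, anomaly, pos, bathy, rng)
        dives = _simulate_seal_dives(config, seal_id, dr, net, pos, bathy, rng)
        fixes = _seal_fixes(config, seal_id, pos, rng)
        days = np.arange(config.days_per_seal)
        truth_rows.append(pd.DataFrame({
            "seal_id": seal_id, "sex": sex, "day": days,
            "x": pos[days, 0], "y": pos[days, 1],
            "lipid": config.lipid_neutral + dr[1:] / config.condition_slope,
            "dr_true": dr[1:], "ddr_true": np.diff(dr),
            "energy_gain": net,
        }))
        dives.insert(1, "sex", sex)
        dive_tables.append(dives)
        fix_tables.append(fixes)
        if config.emit_profiles:
            tx = dives[dives["transmitted"]]
            for row in tx.itertuples(index=False):
                pts_t = [0.0, row.t1, row.t2, row.t3, row.t4, row.duration]
                pts_d = [0.0, row.d1, row.d2, row.d3, row.d4, 0.0]
                depths = profile_from_points(pts_t, pts_d,
                                             config.sampling_interval)
                profiles.append(DiveProfile(
                    seal_id, row.start_time, depths, config.sampling_interval,
                    row.surface_interval))

    truth_params = {
        "gamma_descent": config.gamma_descent,
        "gamma_ascent": config.gamma_ascent,
        "gamma_diveres": config.gamma_diveres,
        "gamma_surfres": config.gamma_surfres,
        "buoyancy_effect_amplitudes": dict(config.buoyancy_effect_amplitudes),
        "ar1_phi": config.ar1_phi,
        "drift_dive_prob": config.drift_dive_prob,
    }
    return SimulationBundle(
        config=config,
        truth=pd.concat(truth_rows, ignore_index=True),
        dives=pd.concat(dive_tables, ignore_index=True),
        profiles=profiles,
        fixes=pd.concat(fix_tables, ignore_index=True),
        bathy=bathy,
        truth_params=truth_params,
    )
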