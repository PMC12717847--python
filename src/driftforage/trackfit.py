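"""Speed filtering and continuous-time correlated-random-walk track fitting.

ARGOS fixes are first screened with an iterative maximum-speed filter
(default 4 m/s).  The retained fixes are then fitted with a
continuous-time correlated random walk: per axis, position integrates an
Ornstein-Uhlenbeck velocity with reversion rate beta (1/s) and diffusion
sigma (m s^-3/2... formally the Brownian forcing scale).  The model is
linear-Gaussian, so exact inter-fix transition matrices follow from the
irregular time gaps, (beta, sigma) are estimated by maximising the
Kalman-filter likelihood (shared across the two independent axes), and
positions at arbitrary times come from the Rauch-Tung-Striebel smoother.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)


class AllFixesRemovedError(RuntimeError):
    pass


class CTCRWFitError(RuntimeError):
    def __init__(self, msg, best_params=None, grad_norm=None):
        super().__init__(msg)
        self.best_params = best_params
        self.grad_norm = grad_norm


def speed_filter(fixes: pd.DataFrame, vmax: float = 4.0) -> pd.DataFrame:
    """Iteratively drop fixes implying speeds above vmax to both neighbours.

    Interior fixes are removed when the implied speed to both the
    previous and next retained fix exceeds vmax; an endpoint is removed
    when the speeds to its two nearest retained fixes both exceed vmax.
    Iterates to a fixed point.
    """
    if len(fixes) < 2:
        raise ValueError("speed filter needs at least 2 fixes")
    fixes = fixes.sort_values("time").reset_index(drop=True)
    t = fixes["time"].to_numpy(float)
    x = fixes["x"].to_numpy(float)
    y = fixes["y"].to_numpy(float)
    keep = np.ones(t.size, bool)
    while True:
        idx = np.flatnonzero(keep)
        if idx.size < 2:
            raise AllFixesRemovedError("speed filter removed all fixes")
        tt, xx, yy = t[idx], x[idx], y[idx]
        dt = np.maximum(np.diff(tt), 1e-6)
        sp = np.hypot(np.diff(xx), np.diff(yy)) / dt  # speed on each gap
        bad = np.zeros(idx.size, bool)
        if idx.size >= 3:
            bad[1:-1] = (sp[:-1] > vmax) & (sp[1:] > vmax)
            # endpoints: test against the two nearest retained fixes
            sp02 = np.hypot(xx[2] - xx[0], yy[2] - yy[0]) / max(tt[2] - tt[0], 1e-6)
            bad[0] = (sp[0] > vmax) & (sp02 > vmax)
            spn = np.hypot(xx[-1] - xx[-3], yy[-1] - yy[-3]) / max(tt[-1] - tt[-3], 1e-6)
            bad[-1] = (sp[-1] > vmax) & (spn > vmax)
        if not bad.any():
            break
        keep[idx[bad]] = False
    return fixes.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# CTCRW state-space machinery (one axis; state = [position, velocity])

def _transition(beta: float, sigma: float, dt: np.ndarray):
    """Exact discrete transition (Phi) and innovation covariance (Q)."""
    e1 = np.exp(-beta * dt)
    e2 = np.exp(-2.0 * beta * dt)
    phi01 = (1.0 - e1) / beta
    q_vv = sigma ** 2 * (1.0 - e2) / (2.0 * beta)
    q_xv = sigma ** 2 * (1.0 - 2.0 * e1 + e2) / (2.0 * beta ** 2)
    q_xx = sigma ** 2 / beta ** 2 * (dt - 2.0 * (1.0 - e1) / beta
                                     + (1.0 - e2) / (2.0 * beta))
    return e1, phi01, q_xx, q_xv, q_vv


def _kalman(times, obs, obs_var, beta, sigma, return_moments=False):
    """Kalman filter for one axis; NaN observations are pure predictions.

    Returns the log-likelihood and, optionally, the per-time predicted
    and filtered moments needed by the smoother.
    """
    t = np.asarray(times, float)
    n = t.size
    dt = np.diff(t)
    e1, phi01, q_xx, q_xv, q_vv = _transition(beta, sigma, np.maximum(dt, 1e-9))

    m = np.zeros((n, 2))
    P = np.zeros((n, 2, 2))
    mp = np.zeros((n, 2))
    Pp = np.zeros((n, 2, 2))

    first = int(np.flatnonzero(~np.isnan(obs))[0])
    mp[0] = [obs[first], 0.0]
    Pp[0] = np.diag([max(obs_var[first], 1.0) * 100.0,
                     sigma ** 2 / (2.0 * beta)])
    ll = 0.0
    for i in range(n):
        if i > 0:
            F = np.array([[1.0, phi01[i - 1]], [0.0, e1[i - 1]]])
            Q = np.array([[q_xx[i - 1], q_xv[i - 1]],
                          [q_xv[i - 1], q_vv[i - 1]]])
            mp[i] = F @ m[i - 1]
            Pp[i] = F @ P[i - 1] @ F.T + Q
        if np.isnan(obs[i]):
            m[i], P[i] = mp[i], Pp[i]
            continue
        S = Pp[i, 0, 0] + max(obs_var[i], 1e-12)
        v = obs[i] - mp[i, 0]
        K = Pp[i, :, 0] / S
        m[i] = mp[i] + K * v
        P[i] = Pp[i] - np.outer(K, Pp[i, 0, :])
        ll += -0.5 * (np.log(2.0 * np.pi * S) + v * v / S)
    if not return_moments:
        return ll
    return ll, m, P, mp, Pp


def _rts(times, m, P, mp, Pp, beta):
    """Rauch-Tung-Striebel smoother; returns smoothed means and covariances."""
    t = np.asarray(times, float)
    n = t.size
    ms = m.copy()
    Ps = P.copy()
    dt = np.maximum(np.diff(t), 1e-9)
    for i in range(n - 2, -1, -1):
        e1 = np.exp(-beta * dt[i])
        F = np.array([[1.0, (1.0 - e1) / beta], [0.0, e1]])
        G = P[i] @ F.T @ np.linalg.inv(Pp[i + 1])
        ms[i] = m[i] + G @ (ms[i + 1] - mp[i + 1])
        Ps[i] = P[i] + G @ (Ps[i + 1] - Pp[i + 1]) @ G.T
    return ms, Ps


@dataclass
class TrackEstimate:
    """Fitted CTCRW track for one seal."""

    times: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray
    var_x: np.ndarray
    var_y: np.ndarray
    beta: float
    sigma: float
    loglik: float
    fixes: pd.DataFrame  # retained fixes the model was fitted to

    def positions(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "x": self.mean_x,
                             "y": self.mean_y, "var_x": self.var_x,
                             "var_y": self.var_y})


def _nll(theta, t, ox, oy, ovar):
    beta, sigma = np.exp(theta)
    if not (1e-8 < beta < 1.0 and 1e-6 < sigma < 1e3):
        return 1e12
    return -(_kalman(t, ox, ovar, beta, sigma)
             + _kalman(t, oy, ovar, beta, sigma))


def fit_ctcrw(fixes: pd.DataFrame, n_restarts: int = 3,
              tol: float = 1e-8) -> TrackEstimate:
    """Fit the CTCRW by maximum likelihood and smooth at observation times.

    Quasi-Newton (L-BFGS-B) on log-parameters with multiple restarts;
    convergence when the relative log-likelihood change falls below tol.
    """
    if len(fixes) < 10:
        raise ValueError("CTCRW fit needs at least 10 fixes")
    fixes = fixes.sort_values("time").reset_index(drop=True)
    t = fixes["time"].to_numpy(float)
    # collapse exactly coincident times (keep the better fix)
    keep = np.concatenate([[True], np.diff(t) > 0])
    fixes = fixes.loc[keep].reset_index(drop=True)
    t = fixes["time"].to_numpy(float)
    ox = fixes["x"].to_numpy(float)
    oy = fixes["y"].to_numpy(float)
    ovar = fixes["sd"].to_numpy(float) ** 2

    span = t[-1] - t[0]
    disp = np.hypot(np.diff(ox), np.diff(oy))
    mean_speed = max(np.median(disp / np.maximum(np.diff(t), 1.0)), 1e-3)
    betas0 = [1.0 / (6 * 3600.0), 1.0 / 86400.0, 1.0 / (3 * 86400.0)]
    best = None
    for b0 in betas0[:max(n_restarts, 1)]:
        s0 = mean_speed * np.sqrt(2.0 * b0)
        res = minimize(_nll, np.log([b0, s0]), args=(t, ox, oy, ovar),
                       method="L-BFGS-B", options={"ftol": tol, "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise CTCRWFitError("CTCRW likelihood optimisation failed",
                            best_params=None if best is None else np.exp(best.x),
                            grad_norm=None if best is None
                            else float(np.linalg.norm(best.jac)))
    beta, sigma = np.exp(best.x)
    est_x = _kalman(t, ox, ovar, beta, sigma, return_moments=True)
    est_y = _kalman(t, oy, ovar, beta, sigma, return_moments=True)
    msx, Psx = _rts(t, *est_x[1:], beta)
    msy, Psy = _rts(t, *est_y[1:], beta)
    return TrackEstimate(
        times=t, mean_x=msx[:, 0], mean_y=msy[:, 0],
        var_x=Psx[:, 0, 0], var_y=Psy[:, 0, 0],
        beta=float(beta), sigma=float(sigma), loglik=float(-best.fun),
        fixes=fixes)


def predict_positions(estimate: TrackEstimate, times,
                      allow_extrapolate: bool = False) -> pd.DataFrame:
    """Smoother-based positions (with variance) at arbitrary query times."""
    q = np.unique(np.asarray(times, float))
    t0, t1 = estimate.times[0], estimate.times[-1]
    if not allow_extrapolate and (q.min() < t0 or q.max() > t1):
        raise ValueError("query time outside track span "
                         f"[{t0}, {t1}]; pass allow_extrapolate=True to override")
    fx = estimate.fixes
    t = fx["time"].to_numpy(float)
    grid = np.union1d(t, q)
    obs_x = np.full(grid.size, np.nan)
    obs_y = np.full(grid.size, np.nan)
    ovar = np.full(grid.size, np.nan)
    pos = np.searchsorted(grid, t)
    obs_x[pos] = fx["x"].to_numpy(float)
    obs_y[pos] = fx["y"].to_numpy(float)
    ovar[pos] = fx["sd"].to_numpy(float) ** 2
    beta, sigma = estimate.beta, estimate.sigma
    _, mx, Px, mpx, Ppx = _kalman(grid, obs_x, ovar, beta, sigma, True)
    _, my, Py, mpy, Ppy = _kalman(grid, obs_y, ovar, beta, sigma, True)
    msx, Psx = _rts(grid, mx, Px, mpx, Ppx, beta)
    msy, Psy = _rts(grid, my, Py, mpy, Ppy, beta)
    sel = np.searchsorted(grid, q)
    return pd.DataFrame({
        "time": q, "x": msx[sel, 0], "y": msy[sel, 0],
        "var_x": Psx[sel, 0, 0], "var_y": Psy[sel, 0, 0]})


def innovation_diagnostics(estimate: TrackEstimate) -> dict:
    """One-step-ahead residual report (model checking, not selection).

    Standardised innovations per axis and their lag-1 autocorrelation;
    near-white innovations support the correlated-random-walk process.
    """
    fx = estimate.fixes
    t = fx["time"].to_numpy(float)
    ovar = fx["sd"].to_numpy(float) ** 2
    out = {}
    for axis in ("x", "y"):
        obs = fx[axis].to_numpy(float)
        _, m, P, mp, Pp = _kalman(t, obs, ovar, estimate.beta, estimate.sigma,
                                  True)
        S = Pp[:, 0, 0] + ovar
        z = (obs - mp[:, 0]) / np.sqrt(S)
        z = z[1:]  # first innovation dominated by the diffuse prior
        r1 = float(np.corrcoef(z[:-1], z[1:])[0, 1]) if z.size > 3 else np.nan
        out[axis] = {"std_innovations_mean": float(z.mean()),
                     "std_innovations_sd": float(z.std()),
                     "lag1_autocorr": r1}
    return out


def simulate_ctcrw_track(beta: float, sigma: float, times,
                         rng: np.random.Generator,
                         start=(0.0, 0.0)) -> pd.DataFrame:
    """Exact simulation of the CTCRW at given times (testing oracle)."""
    t = np.asarray(times, float)
    dt = np.diff(t)
    e1, phi01, q_xx, q_xv, q_vv = _transition(beta, sigma, dt)
    out = np.zeros((t.size, 2, 2))  # (time, axis, [pos, vel])
    out[0, 0, 0], out[0, 1, 0] = start
    sd_v = sigma / np.sqrt(2.0 * beta)
    out[0, :, 1] = rng.normal(0.0, sd_v, 2)
    for i in range(1, t.size):
        Q = np.array([[q_xx[i - 1], q_xv[i - 1]], [q_xv[i - 1], q_vv[i - 1]]])
        L = np.linalg.cholesky(Q + 1e-12 * np.eye(2))
        F = np.array([[1.0, phi01[i - 1]], [0.0, e1[i - 1]]])
        for ax in range(2):
            out[i, ax] = F @ out[i - 1, ax] + L @ rng.standard_normal(2)
    return pd.DataFrame({"time": t, "x": out[:, 0, 0], "y": out[:, 1, 0],
                         "vx": out[:, 0, 1], "vy": out[:, 1, 1]})
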