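"""Penalized additive mixed models for dive metrics vs foraging success.

Each dive-effort metric y, windowed per seal, is modelled as

    y_it = b0 + beta1 * dDR_it + f(DR_it) + a_i + c_i * dDR_it + e_it

where beta1 is the linear foraging-success effect of interest, f is a
penalized spline smooth absorbing the buoyancy control of dive
behaviour, (a_i, c_i) are a correlated per-seal random intercept and
dDR slope, and within-seal errors follow a continuous-time AR(1):
corr(e_it, e_is) = phi^|t - s| with t in days since departure.

Estimation uses the mixed-model representation of penalized splines:
the smooth's wiggly basis enters as an iid random-effect block with
variance tau^2, so a single REML criterion governs the smoothing
parameter, the variance components and phi.  The residual variance is
profiled out analytically and the remaining variance ratios are
optimised numerically; fixed effects, BLUPs and standard errors come
from Henderson's mixed-model equations on CAR1-whitened data.

In the degenerate limit (no smooth, no random effects, phi = 0) the
machinery reduces exactly to ordinary least squares, which anchors the
implementation against a closed-form oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

METRIC_RESPONSES = {
    "descent": "descent_rate",
    "ascent": "ascent_rate",
    "dive_res": "dive_residual",
    "surf_res": "surface_residual",
}


@dataclass
class ModelSpec:
    """One stratified model: metric x sex x habitat x window length."""

    metric: str
    sex: str = "all"
    habitat: str = "all"
    window_days: int = 1
    n_basis: int = 10
    penalty_order: int = 2
    include_smooth: bool = True
    include_random: bool = True
    include_ar1: bool = True


@dataclass
class ModelDesign:
    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray               # fixed effects: intercept, dDR, smooth null space
    X_names: list
    Z_spline: np.ndarray        # penalized (wiggly) smooth basis, scaled
    Z_spline_scale: np.ndarray
    seal_codes: np.ndarray      # 0..n_seals-1, rows sorted by (seal, time)
    n_seals: int
    ddr: np.ndarray
    ddr_scale: float
    times: np.ndarray           # days since departure (window mid-times)
    dr: np.ndarray
    spline_knots: np.ndarray | None
    spline_constraint: np.ndarray | None  # maps 9 constrained -> basis coefs
    spline_split: tuple | None  # (U_pen, scale, u_null)


def _bspline_basis(x: np.ndarray, n_basis: int, degree: int = 3):
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-10:
        raise ValueError("degenerate DR column: smooth basis cannot be built")
    n_interior = n_basis - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()
    return B, knots


def _difference_penalty(n_basis: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def build_design(records: pd.DataFrame, spec: ModelSpec) -> ModelDesign:
    """Assemble fixed, smooth and random design pieces for one stratum."""
    df = records
    if spec.sex != "all":
        df = df[df["sex"] == spec.sex]
    if spec.habitat != "all":
        df = df[df["habitat"] == spec.habitat]
    df = df.dropna(subset=[METRIC_RESPONSES[spec.metric], "ddr", "dr_window"])
    df = df.sort_values(["seal_id", "mid_day"]).reset_index(drop=True)
    n_seals = df["seal_id"].nunique()
    if n_seals < 2:
        raise ValueError(f"stratum {spec} has {n_seals} seals; need >= 2")
    if n_seals < 10:
        logger.warning("stratum %s has only %d seals; inference may be fragile",
                       spec.metric, n_seals)

    y = df[METRIC_RESPONSES[spec.metric]].to_numpy(float)
    ddr = df["ddr"].to_numpy(float)
    dr = df["dr_window"].to_numpy(float)
    times = df["mid_day"].to_numpy(float)
    codes = pd.Categorical(df["seal_id"]).codes.astype(int)

    X_cols = [np.ones(y.size), ddr]
    X_names = ["intercept", "ddr"]
    Zs = np.zeros((y.size, 0))
    Zs_scale = np.zeros(0)
    knots = Q = split = None
    if spec.include_smooth:
        B, knots = _bspline_basis(dr, spec.n_basis)
        c = B.sum(axis=0, keepdims=True)
        Q = null_space(c)                      # (n_basis, n_basis-1)
        Bc = B @ Q
        Sc = Q.T @ _difference_penalty(spec.n_basis, spec.penalty_order) @ Q
        vals, vecs = np.linalg.eigh(Sc)
        tol = vals[-1] * 1e-8
        pen = vals > tol
        if not pen.any() or pen.all():
            raise ValueError("unexpected penalty null-space dimension")
        U_pen = vecs[:, pen] / np.sqrt(vals[pen])
        U_null = vecs[:, ~pen]
        Zs = Bc @ U_pen
        Zs_scale = Zs.std(axis=0)
        Zs_scale[Zs_scale < 1e-12] = 1.0
        Zs = Zs / Zs_scale
        for j in range(U_null.shape[1]):
            X_cols.append(Bc @ U_null[:, j])
            X_names.append(f"smooth_null{j}")
        split = (U_pen, Zs_scale, U_null)
    ddr_scale = float(np.std(ddr))
    if ddr_scale < 1e-12:
        raise ValueError("degenerate dDR column")
    return ModelDesign(
        spec=spec, y=y, X=np.column_stack(X_cols), X_names=X_names,
        Z_spline=Zs, Z_spline_scale=Zs_scale, seal_codes=codes,
        n_seals=n_seals, ddr=ddr, ddr_scale=ddr_scale, times=times, dr=dr,
        spline_knots=knots, spline_constraint=Q, spline_split=split)


# ---------------------------------------------------------------------------
# REML machinery

def _car1_rho(design: ModelDesign, phi: float) -> np.ndarray:
    """Per-row correlation with the previous row; 0 at each seal's first row."""
    t = design.times
    rho = np.zeros(t.size)
    if t.size > 1:
        same = design.seal_codes[1:] == design.seal_codes[:-1]
        gaps = np.maximum(t[1:] - t[:-1], 1e-6)
        rho[1:] = np.where(same, phi ** gaps, 0.0)
    return np.clip(rho, 0.0, 1.0 - 1e-10)


def _whiten(M: np.ndarray, rho: np.ndarray) -> np.ndarray:
    M = np.atleast_2d(M.T).T
    scale = np.sqrt(1.0 - rho ** 2)
    out = M.copy()
    out[1:] -= rho[1:, None] * M[:-1]
    out /= scale[:, None]
    return out


def _assemble_Z(design: ModelDesign, include_random: bool) -> np.ndarray:
    parts = [design.Z_spline] if design.Z_spline.shape[1] else []
    if include_random:
        n = design.y.size
        Zr = np.zeros((n, 2 * design.n_seals))
        rows = np.arange(n)
        Zr[rows, 2 * design.seal_codes] = 1.0
        Zr[rows, 2 * design.seal_codes + 1] = design.ddr / design.ddr_scale
        parts.append(Zr)
    if not parts:
        return np.zeros((design.y.size, 0))
    return np.column_stack(parts)


def _g_inverse(theta_g: dict, design: ModelDesign, q_spline: int,
               include_random: bool):
    """Inverse and log-determinant of the relative random-effect covariance."""
    diag_inv = []
    logdet = 0.0
    if q_spline:
        lam = theta_g["lam_spline"]
        diag_inv.extend([1.0 / lam] * q_spline)
        logdet += q_spline * np.log(lam)
    blocks = None
    if include_random:
        g11, g22, rho_b = theta_g["g_int"], theta_g["g_slope"], theta_g["rho_b"]
        c = rho_b * np.sqrt(g11 * g22)
        det = g11 * g22 - c * c  # positive: |rho_b| < 1 and variances > 0
        Ginv = np.array([[g22, -c], [-c, g11]]) / det
        blocks = Ginv
        logdet += design.n_seals * np.log(det)
    return diag_inv, blocks, logdet


def _reml_neg2(theta_g: dict, design: ModelDesign, phi: float,
               include_random: bool, want_fit: bool = False):
    y, X = design.y, design.X
    n, p = y.size, X.shape[1]
    q_s = design.Z_spline.shape[1]
    Z = _assemble_Z(design, include_random)
    q = Z.shape[1]

    rho = _car1_rho(design, phi)
    logdet_C = float(np.sum(np.log(1.0 - rho ** 2)))
    yt = _whiten(y[:, None], rho)[:, 0]
    Xt = _whiten(X, rho)
    A = [Xt]
    if q:
        A.append(_whiten(Z, rho))
    A = np.column_stack(A)

    M = A.T @ A
    diag_inv, blocks, logdet_G = _g_inverse(theta_g, design, q_s,
                                            include_random)
    if q:
        gi = np.zeros(q)
        gi[:len(diag_inv)] = diag_inv
        idx = p + np.arange(q)
        M[idx, idx] += gi
        if blocks is not None:
            base = p + q_s
            for s in range(design.n_seals):
                sl = slice(base + 2 * s, base + 2 * s + 2)
                M[sl, sl] += blocks
    rhs = A.T @ yt
    try:
        cf = cho_factor(M, lower=True)
    except np.linalg.LinAlgError:
        return (np.inf, None) if want_fit else np.inf
    sol = cho_solve(cf, rhs)
    ypy = float(yt @ yt - rhs @ sol)
    if ypy <= 0:
        return (np.inf, None) if want_fit else np.inf
    logdet_M = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    neg2 = (n - p) * np.log(ypy / (n - p)) + logdet_C + logdet_G + logdet_M
    if not want_fit:
        return neg2
    sigma2 = ypy / (n - p)
    cov_all = cho_solve(cf, np.eye(M.shape[0])) * sigma2
    return neg2, {"beta": sol[:p], "u": sol[p:], "sigma2": sigma2,
                  "cov": cov_all, "A_cols": p + q, "neg2reml": neg2}


@dataclass
class FitResult:
    """Fitted response model for one stratum."""

    spec: ModelSpec
    beta: np.ndarray
    beta_names: list
    beta1: float
    beta1_se: float
    p_value: float
    significant: bool
    var_intercept: float
    var_slope: float
    corr_int_slope: float
    var_spline: float
    phi: float
    sigma2: float
    r2_fitted_obs: float
    neg2reml: float
    converged: bool
    n_records: int
    n_seals: int
    reml_path: list = field(default_factory=list, repr=False)
    _smooth: dict | None = field(default=None, repr=False)

    def smooth_eval(self, dr_values) -> pd.DataFrame:
        """Evaluate the fitted DR smooth with approximate pointwise CIs."""
        if self._smooth is None:
            raise ValueError("model was fitted without a smooth")
        s = self._smooth
        x = np.clip(np.asarray(dr_values, float), *s["range"])
        B = BSpline.design_matrix(x, s["knots"], 3).toarray()
        Bc = B @ s["Q"]
        F = np.column_stack([Bc @ s["U_null"],
                             (Bc @ s["U_pen"]) / s["scale"]])
        est = F @ s["coefs"]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", F, s["cov"], F), 0.0))
        return pd.DataFrame({"dr": x, "smooth": est,
                             "lo": est - 1.96 * se, "hi": est + 1.96 * se})


def fit_pamm(design: ModelDesign, maxfev: int = 220) -> FitResult:
    """Fit the penalized additive mixed model by profiled REML."""
    spec = design.spec
    q_s = design.Z_spline.shape[1]
    use_smooth = spec.include_smooth and q_s > 0
    use_rand = spec.include_random
    use_ar1 = spec.include_ar1

    names = []
    if use_smooth:
        names.append("log_lam")
    if use_rand:
        names += ["log_g_int", "log_g_slope", "z_rho_b"]
    if use_ar1:
        names.append("z_phi")

    def unpack(vec):
        d = dict(zip(names, vec))
        theta_g = {
            "lam_spline": float(np.exp(np.clip(d.get("log_lam", 0.0), -25, 25))),
            "g_int": float(np.exp(np.clip(d.get("log_g_int", 0.0), -25, 25))),
            "g_slope": float(np.exp(np.clip(d.get("log_g_slope", 0.0), -25, 25))),
            "rho_b": float(np.tanh(d.get("z_rho_b", 0.0))) * 0.99,
        }
        phi = float(1.0 / (1.0 + np.exp(-d.get("z_phi", 0.0)))) * 0.999 \
            if use_ar1 else 0.0
        return theta_g, phi

    path = []
    best_so_far = [np.inf]

    def objective(vec):
        theta_g, phi = unpack(vec)
        val = _reml_neg2(theta_g, design, phi, use_rand)
        if val < best_so_far[0]:
            best_so_far[0] = val
            path.append(float(val))
        return val

    converged = True
    if names:
        x0 = []
        for nm in names:
            x0.append({"log_lam": 0.0, "log_g_int": -2.0, "log_g_slope": -2.0,
                       "z_rho_b": 0.0, "z_phi": -0.5}[nm])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(objective, np.asarray(x0), method="Nelder-Mead",
                           options={"maxfev": maxfev, "xatol": 2e-3,
                                    "fatol": 1e-4, "adaptive": True})
        if not np.isfinite(res.fun):
            raise RuntimeError(
                f"REML optimisation failed for {spec.metric}: trace={path[-5:]}")
        converged = bool(res.success or len(path) > 3)
        theta_g, phi = unpack(res.x)
    else:
        theta_g, phi = unpack([])

    neg2, fit = _reml_neg2(theta_g, design, phi, use_rand, want_fit=True)
    if fit is None:
        raise RuntimeError(f"REML evaluation degenerate for {spec.metric}")
    if use_ar1 and phi > 0.985:
        logger.warning("%s: AR1 parameter at boundary (phi=%.3f)",
                       spec.metric, phi)

    p = design.X.shape[1]
    beta = fit["beta"]
    se1 = float(np.sqrt(fit["cov"][1, 1]))
    beta1 = float(beta[1])
    zval = beta1 / se1 if se1 > 0 else np.inf
    pval = float(2.0 * stats.norm.sf(abs(zval)))
    sigma2 = fit["sigma2"]

    Z = _assemble_Z(design, use_rand)
    fitted = design.X @ beta + (Z @ fit["u"] if Z.shape[1] else 0.0)
    r2 = float(np.corrcoef(fitted, design.y)[0, 1] ** 2) \
        if np.std(fitted) > 0 else 0.0

    var_int = theta_g["g_int"] * sigma2 if use_rand else 0.0
    var_slope = (theta_g["g_slope"] * sigma2 / design.ddr_scale ** 2
                 if use_rand else 0.0)
    smooth = None
    if use_smooth:
        U_pen, scale, U_null = design.spline_split
        k_null = U_null.shape[1]
        coefs = np.concatenate([beta[2:2 + k_null], fit["u"][:q_s]])
        idx = np.concatenate([np.arange(2, 2 + k_null),
                              p + np.arange(q_s)])
        smooth = {"knots": design.spline_knots, "Q": design.spline_constraint,
                  "U_pen": U_pen, "U_null": U_null, "scale": scale,
                  "coefs": coefs, "cov": fit["cov"][np.ix_(idx, idx)],
                  "range": (design.dr.min(), design.dr.max())}

    return FitResult(
        spec=spec, beta=beta, beta_names=design.X_names, beta1=beta1,
        beta1_se=se1, p_value=pval, significant=pval < 0.05,
        var_intercept=float(var_int), var_slope=float(var_slope),
        corr_int_slope=float(theta_g["rho_b"]) if use_rand else 0.0,
        var_spline=float(theta_g["lam_spline"] * sigma2) if use_smooth else 0.0,
        phi=float(phi), sigma2=float(sigma2), r2_fitted_obs=r2,
        neg2reml=float(neg2), converged=converged, n_records=design.y.size,
        n_seals=design.n_seals, reml_path=path, _smooth=smooth)


def significance_flag(p: float) -> str:
    if p < 0.05:
        return "sig"
    if p < 0.10:
        return "~"  # marginally significant
    return "ns"


def coefficient_table(fits: list[FitResult]) -> pd.DataFrame:
    """Tidy table of linear dDR coefficients across strata and windows."""
    if not fits:
        raise ValueError("no fits supplied")
    rows = [{
        "metric": f.spec.metric, "sex": f.spec.sex, "habitat": f.spec.habitat,
        "window_days": f.spec.window_days, "beta1": f.beta1, "se": f.beta1_se,
        "p": f.p_value, "flag": significance_flag(f.p_value),
        "r2": f.r2_fitted_obs, "phi": f.phi, "n": f.n_records,
    } for f in fits]
    return pd.DataFrame(rows)


def attenuation_report(table: pd.DataFrame,
                       expected_windows=(1, 2, 3, 7, 10)) -> pd.DataFrame:
    """Per stratum: |beta1| by window and its Kendall trend with window length.

    A negative Kendall tau means the foraging-success effect weakens as
    the temporal window lengthens.  Strata with missing windows are
    flagged (partial report), single-window strata carry tau = NaN.
    """
    rows = []
    for (metric, sex, habitat), grp in table.groupby(
            ["metric", "sex", "habitat"], sort=True):
        grp = grp.sort_values("window_days")
        wins = grp["window_days"].to_numpy()
        absb = np.abs(grp["beta1"].to_numpy())
        if wins.size < 2:
            tau = np.nan
        elif np.ptp(absb) == 0:
            tau = 0.0  # constant sequence: no trend
        else:
            tau = float(stats.kendalltau(wins, absb).statistic)
        rows.append({
            "metric": metric, "sex": sex, "habitat": habitat,
            "n_windows": int(wins.size),
            "complete": set(wins) >= set(expected_windows),
            "kendall_tau": tau,
            **{f"abs_beta1_w{w}": (float(absb[wins == w][0])
                                   if (wins == w).any() else np.nan)
               for w in expected_windows},
        })
    return pd.DataFrame(rows)
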