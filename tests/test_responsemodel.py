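"""Penalized additive mixed model: design, REML limits, reporting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from driftforage import (FitResult, ModelSpec, attenuation_report,
                         build_design, coefficient_table, fit_pamm)
from driftforage.responsemodel import _bspline_basis, significance_flag


def synth_records(n_seals=12, n_per=60, gamma=2.0, slope_sd=0.0,
                  icpt_sd=0.0, phi=0.0, noise=0.5, seed=0, smooth_amp=0.0):
    """Window-record table with known linear effect and optional extras."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_seals):
        slope = gamma * (1 + rng.normal(0, slope_sd))
        icpt = rng.normal(0, icpt_sd)
        ddr = rng.normal(0, 0.03, n_per)
        dr = np.clip(-0.3 + 0.0025 * np.arange(n_per)
                     + rng.normal(0, 0.02, n_per), -0.35, 0.1)
        e = np.zeros(n_per)
        e[0] = rng.normal(0, noise)
        for i in range(1, n_per):
            e[i] = phi * e[i - 1] + rng.normal(0, noise * np.sqrt(1 - phi**2))
        y = 1.0 + icpt + slope * ddr + smooth_amp * np.tanh(
            (dr + 0.125) / 0.1) + e
        rows.append(pd.DataFrame({
            "seal_id": f"s{s:02d}", "mid_day": np.arange(n_per) + 0.5,
            "ddr": ddr, "dr_window": dr, "descent_rate": y,
            "sex": "F" if s % 2 else "M", "habitat": "oceanic"}))
    return pd.concat(rows, ignore_index=True)


def test_design_dimensions_bookkeeping():
    recs = synth_records()
    d = build_design(recs, ModelSpec(metric="descent"))
    # one smooth: 2 parametric columns + 9 constrained basis functions,
    # split into 1 unpenalized (fixed) + 8 penalized (random) directions
    assert d.X.shape[1] + d.Z_spline.shape[1] == 2 + 9
    assert d.X.shape[1] == 3
    assert d.Z_spline.shape[1] == 8


def test_bspline_partition_of_unity_before_constraint():
    x = np.linspace(-0.3, 0.1, 200)
    B, _ = _bspline_basis(x, 10)
    np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)


def test_constant_dr_column_rejected():
    recs = synth_records()
    recs["dr_window"] = -0.2
    with pytest.raises(ValueError, match="degenerate DR"):
        build_design(recs, ModelSpec(metric="descent"))


def test_ols_limit_exact():
    recs = synth_records(noise=1.0)
    spec = ModelSpec(metric="descent", include_smooth=False,
                     include_random=False, include_ar1=False)
    fit = fit_pamm(build_design(recs, spec))
    ols = sm.OLS(recs["descent_rate"],
                 sm.add_constant(recs["ddr"])).fit()
    assert fit.beta1 == pytest.approx(ols.params.iloc[1], rel=1e-9)
    assert fit.beta1_se == pytest.approx(ols.bse.iloc[1], rel=1e-9)


def test_independent_errors_give_small_phi():
    recs = synth_records(phi=0.0, slope_sd=0.1, icpt_sd=0.2, seed=3)
    fit = fit_pamm(build_design(recs, ModelSpec(metric="descent")))
    assert fit.phi < 0.2


def test_ar1_errors_recovered():
    recs = synth_records(phi=0.6, slope_sd=0.1, icpt_sd=0.2, seed=4,
                         n_seals=15, n_per=80)
    fit = fit_pamm(build_design(recs, ModelSpec(metric="descent")))
    assert 0.4 < fit.phi < 0.8


def test_zero_random_slope_limit_matches_fixed_fit():
    recs = synth_records(slope_sd=0.0, icpt_sd=0.0, noise=0.4, seed=5)
    full = fit_pamm(build_design(recs, ModelSpec(
        metric="descent", include_ar1=False)))
    fixed = fit_pamm(build_design(recs, ModelSpec(
        metric="descent", include_random=False, include_ar1=False)))
    assert full.var_slope < 0.05 * full.beta1 ** 2
    assert full.beta1_se == pytest.approx(fixed.beta1_se, rel=0.10)
    assert full.beta1 == pytest.approx(fixed.beta1, rel=0.02)


def test_smooth_recovers_buoyancy_shape():
    recs = synth_records(smooth_amp=0.5, noise=0.1, seed=6)
    fit = fit_pamm(build_design(recs, ModelSpec(metric="descent",
                                                include_ar1=False)))
    grid = np.linspace(-0.3, 0.05, 25)
    sm_df = fit.smooth_eval(grid)
    target = 0.5 * np.tanh((grid + 0.125) / 0.1)
    target = target - target.mean()
    est = (sm_df["smooth"] - sm_df["smooth"].mean()).to_numpy()
    # penalization flattens the fit near the data-sparse boundaries, so
    # demand faithful shape rather than pointwise identity
    assert np.corrcoef(est, target)[0, 1] > 0.9
    assert (np.diff(est) > -1e-3).all()  # monotone rise like the target
    assert est[-1] - est[0] > 0.4       # most of the 0.5-amplitude swing


def test_reml_path_monotone_non_increasing():
    recs = synth_records(phi=0.3, slope_sd=0.1, seed=7)
    fit = fit_pamm(build_design(recs, ModelSpec(metric="descent")))
    path = np.asarray(fit.reml_path)
    assert (np.diff(path) <= 1e-10).all()


def test_wald_inference_and_flags():
    assert significance_flag(0.03) == "sig"
    assert significance_flag(0.07) == "~"
    assert significance_flag(0.5) == "ns"
    recs = synth_records(gamma=2.0, noise=0.3, seed=8)
    fit = fit_pamm(build_design(recs, ModelSpec(metric="descent",
                                                include_ar1=False)))
    assert fit.significant
    table = coefficient_table([fit])
    assert table.loc[0, "flag"] == "sig"
    assert set(table.columns) >= {"metric", "sex", "habitat", "window_days",
                                  "beta1", "se", "p", "flag"}


def test_stratified_design_subsets_records():
    recs = synth_records()
    d_all = build_design(recs, ModelSpec(metric="descent"))
    d_f = build_design(recs, ModelSpec(metric="descent", sex="F"))
    assert d_f.y.size < d_all.y.size
    assert d_f.n_seals == 6


def test_attenuation_report_trivial_cases():
    rows = []
    for metric, betas in [("descent", [1.0, 0.8, 0.6, 0.3, 0.2]),
                          ("ascent", [0.5] * 5)]:
        for w, b in zip((1, 2, 3, 7, 10), betas):
            rows.append({"metric": metric, "sex": "all", "habitat": "all",
                         "window_days": w, "beta1": b, "se": 0.1, "p": 0.01})
    rep = attenuation_report(pd.DataFrame(rows))
    dec = rep[rep["metric"] == "descent"].iloc[0]
    const = rep[rep["metric"] == "ascent"].iloc[0]
    assert dec["kendall_tau"] == pytest.approx(-1.0)
    assert const["kendall_tau"] == 0.0
    assert dec["complete"]


def test_attenuation_report_flags_partial_windows():
    rows = [{"metric": "descent", "sex": "all", "habitat": "all",
             "window_days": 1, "beta1": 1.0, "se": 0.1, "p": 0.01}]
    rep = attenuation_report(pd.DataFrame(rows))
    assert not rep["complete"].iloc[0]
    assert np.isnan(rep["kendall_tau"].iloc[0])


def test_coefficient_table_requires_fits():
    with pytest.raises(ValueError, match="no fits"):
        coefficient_table([])
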