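"""Drift candidates, Kalman screening, daily DR and windowed dDR."""

import numpy as np
import pandas as pd
import pytest

from driftforage import (CandidateCriteria, ScreenParams, candidate_segments,
                         daily_drift_rate, delta_dr, kalman_screen)


def summarised_dive(seal="s", start=0.0, t=(400, 900, 1000, 1100),
                    d=(400, 525, 540, 480), max_depth=560.0, duration=1500.0):
    return {"seal_id": seal, "start_time": start,
            "t1": t[0], "d1": d[0], "t2": t[1], "d2": d[1],
            "t3": t[2], "d3": d[2], "t4": t[3], "d4": d[3],
            "max_depth": max_depth, "duration": duration,
            "surface_interval": 120.0}


def test_shallow_dives_yield_no_candidates():
    dive = summarised_dive(max_depth=90.0, d=(60, 85, 88, 70))
    out = candidate_segments(pd.DataFrame([dive]))
    assert len(out) == 0


def test_planted_slow_segment_becomes_candidate():
    # segment p1->p2: 500 s at depth rate +0.25 m/s -> speed -0.25 (sinking)
    dive = summarised_dive(t=(400, 900, 1000, 1100), d=(400, 525, 540, 480))
    out = candidate_segments(pd.DataFrame([dive]))
    assert len(out) == 1
    assert out["speed"].iloc[0] == pytest.approx(-0.25)
    assert out["segment"].iloc[0] == 2


def test_fast_v_dive_yields_no_candidates():
    dive = summarised_dive(t=(300, 320, 340, 360),
                           d=(450, 455, 460, 450), duration=700.0)
    out = candidate_segments(pd.DataFrame([dive]))
    assert len(out) == 0


def test_candidate_speed_matches_planted_drift(chain_data):
    est = chain_data["estimates"]
    true = est[est["true_drift"]]
    dives = chain_data["bundle"].transmitted  # dive_index refers here
    speeds_true = dives.loc[true["dive_index"], "drift_speed_true"].to_numpy()
    np.testing.assert_allclose(true["speed"], speeds_true, atol=1e-9)


def _series(speeds, days=None):
    speeds = np.asarray(speeds, float)
    days = np.arange(speeds.size) * 0.5 if days is None else np.asarray(days)
    return pd.DataFrame({"seal_id": "s", "time": days * 86400.0,
                         "speed": speeds, "seg_duration": 500.0,
                         "dive_max_depth": 500.0, "segment": 2,
                         "dive_index": np.arange(speeds.size)})


def test_pure_inlier_series_fully_retained():
    rng = np.random.default_rng(0)
    traj = -0.3 + 0.002 * np.arange(60) + rng.normal(0, 0.008, 60)
    out = kalman_screen(_series(traj))
    assert (out["Z"] > 0.5).all()


def test_single_far_outlier_rejected():
    rng = np.random.default_rng(1)
    speeds = rng.normal(0.0, 0.01, 40)
    speeds[20] = 1.0
    out = kalman_screen(_series(speeds)).sort_values("dive_index")
    assert out["Z"].iloc[20] < 0.5
    assert not out["retained"].iloc[20]


def test_screen_invariant_to_location_shift():
    rng = np.random.default_rng(2)
    speeds = -0.25 + rng.normal(0, 0.01, 50)
    speeds[10] = 0.4
    z0 = kalman_screen(_series(speeds))["Z"].to_numpy()
    z1 = kalman_screen(_series(speeds + 0.15))["Z"].to_numpy()
    np.testing.assert_allclose(z0, z1, atol=0.05)


def test_outlier_z_monotone_in_distance():
    rng = np.random.default_rng(3)
    base = rng.normal(-0.2, 0.01, 50)
    zs = []
    for dist in (0.05, 0.1, 0.2, 0.4):
        speeds = base.copy()
        speeds[25] = -0.2 + dist
        out = kalman_screen(_series(speeds)).sort_values("dive_index")
        zs.append(out["Z"].iloc[25])
    assert all(a >= b - 0.02 for a, b in zip(zs[:-1], zs[1:]))


def test_sparse_seals_left_unscreened(caplog):
    with caplog.at_level("WARNING"):
        out = kalman_screen(_series([-0.2, -0.21, -0.2]))
    assert out["Z"].isna().all()
    assert not out["retained"].any()
    assert "unscreened" in caplog.text


def test_contaminated_series_screened(chain_data):
    """Labelled simulation: contaminants rare in the retained set, true
    segments nearly always kept."""
    est = chain_data["estimates"]
    kept = est[est["retained"]]
    assert (~kept["true_drift"]).mean() < 0.05
    assert est.loc[est["true_drift"], "retained"].mean() > 0.8


def test_daily_mean_and_missing_day_convention():
    est = pd.DataFrame({
        "seal_id": "s",
        "time": [0.25 * 86400, 0.5 * 86400, 2.25 * 86400],
        "speed": [-0.20, -0.22, -0.30],
        "retained": [True, True, False],
    })
    daily = daily_drift_rate(est)
    assert len(daily) == 1  # day 2 has no retained segments: missing, not 0
    assert daily["dr"].iloc[0] == pytest.approx(-0.21)
    assert daily["n_segments"].iloc[0] == 2


def test_daily_dr_tracks_truth(chain_data):
    daily = chain_data["daily"]
    truth = chain_data["bundle"].truth
    m = daily.merge(truth, on=["seal_id", "day"])
    rmse = np.sqrt(((m["dr"] - m["dr_true"]) ** 2).mean())
    assert rmse < 0.02


def _daily(vals, days=None):
    days = np.arange(len(vals)) if days is None else days
    return pd.DataFrame({"seal_id": "s", "day": days, "dr": vals,
                         "n_segments": 2})


def test_two_day_blocks_arithmetic():
    dd = delta_dr(_daily([-0.3, -0.28, -0.25, -0.24]), window_days=2)
    assert dd["dr_window"].tolist() == pytest.approx([-0.29, -0.245])
    assert dd["ddr"].iloc[1] == pytest.approx(0.045)
    assert np.isnan(dd["ddr"].iloc[0])


def test_constant_series_gives_zero_ddr():
    dd = delta_dr(_daily([-0.2] * 10), window_days=3)
    assert np.allclose(dd["ddr"].dropna(), 0.0)


def test_w1_equals_day_to_day_differences():
    rng = np.random.default_rng(4)
    vals = rng.normal(-0.2, 0.02, 15)
    days = np.delete(np.arange(17), [5, 11])  # two missing days
    dd = delta_dr(_daily(vals, days), window_days=1)
    direct = np.diff(vals)
    adjacent = np.diff(days) == 1
    np.testing.assert_allclose(dd["ddr"].to_numpy()[1:][adjacent],
                               direct[adjacent])
    assert np.isnan(dd["ddr"].to_numpy()[1:][~adjacent]).all()


def test_ddr_missing_when_block_lacks_segments():
    daily = _daily([-0.3, -0.28, -0.26, -0.25], days=[0, 1, 2, 3])
    daily.loc[1, "n_segments"] = 0
    dd = delta_dr(daily, window_days=1, min_segments=1)
    assert 1 not in dd["block"].tolist()
    # block 2 follows a dropped block: no consecutive predecessor
    assert np.isnan(dd.loc[dd["block"] == 2, "ddr"]).all()


def test_windowed_ddr_correlates_with_truth(chain_data):
    dd = delta_dr(chain_data["daily"], window_days=1)
    dd["day"] = (dd["mid_day"] - 0.5).astype(int)
    truth = chain_data["bundle"].truth[["seal_id", "day", "ddr_true"]]
    m = dd.dropna(subset=["ddr"]).merge(truth, on=["seal_id", "day"])
    assert np.corrcoef(m["ddr"], m["ddr_true"])[0, 1] > 0.8


def test_unknown_window_mode_rejected():
    with pytest.raises(ValueError, match="window mode"):
        delta_dr(_daily([-0.2]), window_days=1, mode="diagonal")
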