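"""Changepoint detection and pregnancy dating, with an exhaustive dynamic
program as the segmentation oracle."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from gulotherm import (ReproductionSettings, SimConfig, classify_female_year,
                       denning_localization, detect_implantation,
                       detect_parturition, pelt_changepoints,
                       reference_gestation_window, simulate_cohort)
from gulotherm.reproduction import ReproductiveAssignment

from conftest import cohort_daily


# --- independent oracle: exhaustive O(n^2) optimal partitioning ------------

def exhaustive_segmentation(x: np.ndarray, beta: float) -> list[int]:
    """Optimal penalized partitioning by full dynamic programming, written
    directly from the cost definition (no pruning, no shared code)."""
    n = len(x)
    F = [-beta] + [np.inf] * n
    prev = [0] * (n + 1)
    for t in range(1, n + 1):
        for s in range(t):
            seg = x[s:t]
            cost = float(np.sum((seg - seg.mean()) ** 2))
            val = F[s] + cost + beta
            if val < F[t]:
                F[t] = val
                prev[t] = s
    cps = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def test_pelt_matches_exhaustive_dp_on_random_series():
    rng = np.random.default_rng(123)
    for _ in range(60):
        n = int(rng.integers(10, 61))
        x = rng.normal(38.5, 0.1, n)
        for cp in rng.choice(np.arange(3, n - 3), size=rng.integers(0, 3),
                             replace=False):
            x[cp:] += rng.normal(0, 0.4)
        beta = float(rng.uniform(0.05, 2.0))
        model = pelt_changepoints(x, beta)
        assert list(model.changepoints) == exhaustive_segmentation(x, beta)


def test_constant_series_has_no_changepoints():
    model = pelt_changepoints(np.full(50, 38.5), penalty="auto")
    assert model.changepoints == ()
    assert model.segment_means == (38.5,)


def test_single_mean_shift_located():
    rng = np.random.default_rng(5)
    x = np.concatenate([np.full(50, 38.5), np.full(50, 38.0)])
    x += rng.normal(0, 0.05, 100)
    model = pelt_changepoints(x, penalty="auto")
    assert any(abs(cp - 50) <= 1 for cp in model.changepoints)


def test_short_series_rejected():
    with pytest.raises(ValueError, match="short"):
        pelt_changepoints(np.arange(5.0))


# --- implantation / parturition -------------------------------------------

def _daily_frame(doys, means, year=2013):
    dates = [dt.date(year, 1, 1) + dt.timedelta(days=int(d) - 1)
             for d in doys]
    return pd.DataFrame({"animal_id": "F1", "date": dates, "doy": doys,
                         "mean_tb": means, "min_tb": means, "max_tb": means,
                         "daily_variation": 0.0, "mean_activity": np.nan,
                         "n_obs": 288, "has_imputed": False,
                         "excluded": False, "exclude_reason": ""})


def _pregnant_trace(impl=14, part=60, depth=0.5, noise=0.02, seed=0,
                    n_days=150):
    rng = np.random.default_rng(seed)
    doys = np.arange(1, n_days + 1)
    y = np.full(n_days, 38.5)
    ges = (doys >= impl) & (doys < part)
    y[ges] -= depth * (doys[ges] - impl) / (part - impl)
    rec = (doys >= part) & (doys < part + 3)
    y[rec] -= depth * (1 - (doys[rec] - part + 1) / 3)
    return _daily_frame(doys, y + rng.normal(0, noise, n_days))


def test_implantation_recovered_on_synthetic_trace():
    daily = _pregnant_trace(impl=14, depth=0.5)
    assert abs(detect_implantation(daily) - 14) <= 3


def test_flat_trace_has_no_implantation():
    rng = np.random.default_rng(1)
    daily = _daily_frame(np.arange(1, 151),
                         38.5 + rng.normal(0, 0.02, 150))
    assert detect_implantation(daily) is None


def test_transient_dip_fails_length_rule():
    rng = np.random.default_rng(2)
    y = 38.5 + rng.normal(0, 0.02, 150)
    y[20:22] -= 0.4
    assert detect_implantation(_daily_frame(np.arange(1, 151), y)) is None


def test_parturition_day_and_activity_drop():
    daily = _pregnant_trace(impl=14, part=60)
    act = pd.Series(200.0, index=np.arange(1, 151))
    act.loc[60:70] = 60.0  # post-partum quiescence
    part, drop = detect_parturition(daily, 14, act)
    assert abs(part - 60) <= 2
    assert drop


def test_monotone_decline_without_rebound_is_undetermined():
    doys = np.arange(1, 61)
    y = 38.5 - 0.5 * np.clip(doys - 10, 0, None) / 50
    a = classify_female_year(_daily_frame(doys, y), "F1", 2013)
    assert a.state == "undetermined"
    assert a.evidence == {"tb_decline": True, "tb_rebound": False}


def test_slow_rebound_detected_when_cumulative_rise_met():
    """A +0.1 deg C/day rebound triggers at the day the cumulative rise
    reaches the threshold, not at the first uptick."""
    doys = np.arange(1, 121)
    y = np.full(120, 38.5)
    y[14:60] = 38.5 - 0.5 * (doys[14:60] - 14) / 46
    y[59:] = np.minimum(38.5, y[59] + 0.1 * (doys[59:] - 60))
    part, _ = detect_parturition(_daily_frame(doys, y), 14)
    # cumulative rise from the trough reaches 0.25 on day 63
    assert part == 63


def test_reference_gestation_window_arithmetic():
    def preg(i, impl, part):
        return ReproductiveAssignment(f"F{i}", 2013, "pregnant",
                                      implantation_doy=impl,
                                      parturition_doy=part)
    assert reference_gestation_window(
        [preg(1, 10, 60), preg(2, 20, 70)]) == (15, 65)
    assert reference_gestation_window([preg(1, 14, 60)]) == (14, 60)
    with pytest.raises(ValueError):
        reference_gestation_window(
            [ReproductiveAssignment("F1", 2013, "non_pregnant")])


# --- cohort-level recovery -------------------------------------------------

def test_state_and_date_recovery_on_cohort(small_cohort, small_daily):
    truth = {r.animal_id: r for r in small_cohort.truth.records}
    for aid, d in small_daily.groupby("animal_id"):
        a = classify_female_year(d, aid, 2012)
        rec = truth[aid]
        assert (a.state == "pregnant") == (rec.state == "pregnant")
        if a.state == "pregnant":
            assert abs(a.implantation_doy - rec.implantation_doy) <= 3
            assert abs(a.parturition_doy - rec.parturition_doy) <= 2


def test_decline_depth_on_low_noise_run():
    cfg = SimConfig(n_animals=2, years=1, seed=21, pregnancy_fraction=1.0,
                    noise_sd=0.01, fever_rate=0.0, artifact_rate=0.0)
    cohort = simulate_cohort(cfg)
    daily = cohort_daily(cohort)
    for aid, d in daily.groupby("animal_id"):
        a = classify_female_year(d, aid, 2012)
        assert a.state == "pregnant"
        assert a.decline_depth == pytest.approx(0.5, abs=0.15)


# --- denning ---------------------------------------------------------------

def _gps(points, start="2013-02-01"):
    ts = pd.date_range(start, periods=len(points), freq="3h", tz="UTC")
    lat, lon = zip(*points)
    return pd.DataFrame({"animal_id": "F1", "timestamp": ts,
                         "lat": lat, "lon": lon})


def test_denning_identical_fixes():
    gps = _gps([(67.0, 17.67)] * 40)
    assert denning_localization(gps).all()


def test_denning_transect_rejected():
    # ~10 km of northward movement
    gps = _gps([(67.0 + i * 0.002, 17.67) for i in range(40)])
    assert not denning_localization(gps).iloc[-1]


def test_denning_scatter_within_radius():
    rng = np.random.default_rng(3)
    pts = [(67.0 + rng.normal(0, 100) / 111_320.0,
            17.67 + rng.normal(0, 100) / 43_500.0) for _ in range(160)]
    res = denning_localization(_gps(pts))
    assert res.mean() >= 0.9
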