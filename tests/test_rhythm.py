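"""Lomb-Scargle periodogram, significance, and the rolling rhythm scan."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import lombscargle as scipy_lombscargle

from gulotherm import (RawSeries, lomb_scargle_power, periodogram,
                       rhythm_prevalence, rhythm_probability_inputs,
                       rolling_rhythm_scan, significance_threshold)
from gulotherm.rhythm import (DEFAULT_PERIODS_H, RhythmRecord, classify_period,
                              peak_p_value)

from conftest import tb_series


def test_power_matches_scipy_reference_on_irregular_series():
    """Independent oracle: scipy's tau-form periodogram rescaled to the
    variance normalization."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(40, 400))
        t = np.sort(rng.uniform(0.0, 360.0, n))
        y = (rng.uniform(0.2, 2.0) * np.sin(2 * np.pi * t / rng.uniform(5, 28))
             + rng.normal(0, 1, n))
        mine = lomb_scargle_power(t, y, DEFAULT_PERIODS_H)
        yc = y - y.mean()
        ref = scipy_lombscargle(t, yc, 2 * np.pi / DEFAULT_PERIODS_H) \
            / (yc @ yc / (n - 1))
        assert np.max(np.abs(mine - ref)) <= 1e-8 * max(ref.max(), 1.0)


def test_pure_sine_peaks_at_its_period():
    t = np.arange(0.0, 15 * 24, 5 / 60)
    y = np.sin(2 * np.pi * t / 24.0)
    pg = periodogram(t, y)
    assert pg.peak_period_h == pytest.approx(24.0, abs=0.1)


def test_peak_survives_random_deletion():
    rng = np.random.default_rng(1)
    t = np.arange(0.0, 15 * 24, 5 / 60)
    keep = rng.random(len(t)) > 0.3
    y = np.sin(2 * np.pi * t / 24.0) + rng.normal(0, 0.3, len(t))
    pg = periodogram(t[keep], y[keep])
    assert pg.peak_period_h == pytest.approx(24.0, abs=0.1)


@pytest.mark.parametrize("period", [3.0, 8.0, 12.0, 19.5, 24.0, 28.0])
def test_noiseless_peak_exact_to_grid(period):
    t = np.arange(0.0, 15 * 24, 0.25)
    pg = periodogram(t, np.cos(2 * np.pi * t / period))
    assert abs(pg.peak_period_h - period) <= 0.1 + 1e-9


def test_power_invariances():
    rng = np.random.default_rng(2)
    t = np.sort(rng.uniform(0, 200, 150))
    y = np.sin(2 * np.pi * t / 24) + rng.normal(0, 0.5, 150)
    base = lomb_scargle_power(t, y)
    assert np.allclose(lomb_scargle_power(t, y + 5.0), base, atol=1e-8)
    assert np.allclose(lomb_scargle_power(t + 1000.0, y), base, atol=1e-6)


def test_constant_series_has_zero_power():
    t = np.arange(0.0, 100.0, 0.25)
    assert np.all(lomb_scargle_power(t, np.full(len(t), 38.5)) == 0.0)


def test_threshold_closed_forms():
    # M = 1: p(z) = e^-z
    assert peak_p_value(2.0, 1) == pytest.approx(np.exp(-2.0))
    # a span giving exactly M = 100 independent frequencies in [2, 30] h
    span = 100.0 / (1.0 / 2.0 - 1.0 / 30.0)
    thr, m = significance_threshold(span, np.array([2.0, 30.0]),
                                    n_samples=10_000, alpha=0.05)
    assert m == 100
    # algebraic inversion: z = -ln(1 - 0.95**(1/100)) = 7.576
    assert thr == pytest.approx(-np.log(1 - 0.95 ** 0.01), rel=1e-9)
    assert thr == pytest.approx(7.576, abs=0.01)
    assert peak_p_value(thr, m) == pytest.approx(0.05, rel=1e-9)


def test_white_noise_rarely_significant():
    rng = np.random.default_rng(3)
    t = np.arange(0.0, 15 * 24, 0.25)
    hits = 0
    n_runs = 100
    for _ in range(n_runs):
        pg = periodogram(t, rng.normal(0, 1, len(t)))
        hits += pg.p_value(pg.peak_power) < 0.05
    assert 0.0 <= hits / n_runs <= 0.12


def test_ar1_noise_spurious_peaks_rarely_classify_as_rhythms():
    """Serial correlation makes the analytic white-noise null strongly
    anti-conservative: on rhythm-free AR1 noise most windows show some
    significant peak. Those peaks scatter over the period band, so the
    quantity the analysis actually consumes — the 24 h / 12 h
    classification — stays controlled."""
    from gulotherm import SimConfig, simulate_cohort
    zero_amp = {s: 0.0 for s in ("winter", "spring", "summer", "autumn")}
    cfg = SimConfig(n_animals=1, years=1, seed=17, pregnancy_fraction=0.0,
                    fever_rate=0.0, artifact_rate=0.0,
                    circadian_amplitude_by_season=zero_amp)
    cohort = simulate_cohort(cfg)
    records = rolling_rhythm_scan(tb_series(cohort, "W01"))
    scanned = [r for r in records if r.rhythm_class != "skipped"]
    sig = np.mean([r.rhythm_class != "none" for r in scanned])
    assert sig > 0.5  # documented anti-conservatism under AR1 noise
    false_rhythms = np.mean([r.rhythm_class in ("h24", "h12")
                             for r in scanned])
    assert false_rhythms <= 0.10


@pytest.mark.parametrize("period, cls", [
    (23.6, "h24"), (12.4, "h12"), (18.2, "other"), (24.4, "h24"),
    (11.5, "h12"), (24.5, "other"),
])
def test_rounding_and_classification(period, cls):
    assert classify_period(period) == cls


def test_rolling_scan_classifies_synthetic_rhythm(clean_animal):
    s = tb_series(clean_animal, "W01")
    records = rolling_rhythm_scan(s)
    scanned = [r for r in records if r.rhythm_class != "skipped"]
    frac_h24 = np.mean([r.rhythm_class == "h24" for r in scanned])
    assert frac_h24 >= 0.95


def test_rolling_scan_fast_path_equals_direct_periodogram(clean_animal):
    """The day-partial decomposition must reproduce the straightforward
    periodogram exactly."""
    s = tb_series(clean_animal, "W01")
    records = rolling_rhythm_scan(s)
    t_hours = s.timestamps.asi8 / 3.6e12
    t_hours = t_hours - t_hours[0]
    dates = np.array([d.toordinal() for d in s.timestamps.date])
    day = dates.min() + 150
    mask = (dates >= day - 7) & (dates <= day + 7)
    pg = periodogram(t_hours[mask], s.values[mask])
    rec = next(r for r in records
               if pd.Timestamp(r.date).toordinal() == day)
    assert rec.peak_period_h == pytest.approx(pg.peak_period_h, abs=1e-9)
    assert rec.peak_p == pytest.approx(pg.p_value(pg.peak_power), rel=1e-6,
                                       abs=1e-12)


def test_low_coverage_days_are_skipped():
    ts = pd.date_range("2013-01-01", periods=288 * 4, freq="5min", tz="UTC")
    vals = 38.5 + 0.5 * np.sin(np.arange(len(ts)) * 2 * np.pi / 288)
    s = RawSeries("A", "tb", ts, vals)
    records = rolling_rhythm_scan(s)  # 4 days of data in 15-day windows
    assert all(r.rhythm_class == "skipped" for r in records)


def _rec(cls, doy=100):
    return RhythmRecord("A", None, doy, "tb", 1.0,
                        24.0 if cls != "skipped" else None,
                        0.01 if cls in ("h24", "h12", "other") else None,
                        None, cls)


def test_prevalence_arithmetic():
    records = [_rec("h24")] * 50 + [_rec("h12")] * 25 + [_rec("none")] * 25
    prev = rhythm_prevalence(records)
    assert prev["h24"] == 0.5
    assert prev["h12"] == 0.25
    assert prev["combined_24_12_share"] == 1.0
    assert rhythm_prevalence([_rec("h24")])["h24"] == 1.0


def test_probability_inputs_mapping():
    records = [_rec("h24", 10), _rec("none", 11), _rec("skipped", 12),
               _rec("h12", 13)]
    df = rhythm_probability_inputs(records)
    assert len(df) == 3  # skipped day omitted entirely
    assert df.loc[df["doy"] == 10, ["h24", "h12"]].values.tolist() == [[1, 0]]
    assert df.loc[df["doy"] == 11, ["h24", "h12"]].values.tolist() == [[0, 0]]
    assert df.loc[df["doy"] == 13, ["h24", "h12"]].values.tolist() == [[0, 1]]


def test_seasonal_amplitude_modulates_detection():
    """Windows centred in the high-amplitude season are classified h24 at
    least as often as in the low-amplitude season when noise is strong."""
    from gulotherm import SimConfig, simulate_cohort
    cfg = SimConfig(n_animals=1, years=1, seed=33, pregnancy_fraction=0.0,
                    fever_rate=0.0, artifact_rate=0.0, noise_sd=1.2,
                    ar1_rho=0.2,
                    circadian_amplitude_by_season={"winter": 0.05,
                                                   "spring": 0.4,
                                                   "summer": 0.8,
                                                   "autumn": 0.4})
    cohort = simulate_cohort(cfg)
    records = rolling_rhythm_scan(tb_series(cohort, "W01"))
    by_month = {}
    for r in records:
        if r.rhythm_class == "skipped":
            continue
        m = pd.Timestamp(r.date).month
        by_month.setdefault(m, []).append(r.rhythm_class == "h24")
    summer = np.mean(sum((by_month.get(m, []) for m in (6, 7, 8)), []))
    winter = np.mean(sum((by_month.get(m, []) for m in (1, 12)), []))
    assert summer > winter
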