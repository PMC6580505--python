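"""Synthetic wolverine biologging cohort with known ground truth.

The generator produces multi-animal, multi-year core body temperature (T_b),
collar activity and GPS series with the statistical structure the analysis
assumes:

* baseline T_b ~38.5 deg C with a small annual sinusoid peaking in July;
* a circadian rhythm (24-h fundamental plus a 12-h harmonic) whose amplitude
  depends on meteorological season and whose phase is anchored to local
  solar noon;
* gestational hypothermia in pregnant females: a linear decline of
  configurable depth from implantation to parturition, a step recovery over
  3 days, and a damped within-day rhythm during gestation;
* fever days (a constant offset added to every sample of the day), sub-34
  deg C single-sample logger artifacts, AR1 noise and random missingness;
* an activity series (integer counts 0-510) driven by the same circadian
  phase with Poisson sampling noise, so T_b and activity are coupled;
* GPS fixes from a home-range random walk, collapsing onto a den site for
  pregnant females after parturition.

Every draw comes from one seeded generator, so a config determines the
output byte-for-byte.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .solar import season_of

_ARTIFACT_LOW, _ARTIFACT_HIGH = 30.0, 33.5
_RECOVERY_DAYS = 3
_DENNING_SD_M = 100.0
_DENNING_DAYS = 30
_GPS_INTERVAL_H = 3
_ACT_NOISE_FLOOR = 5.0  # Poisson mean floor so quiet hours still vary

_SEASON_BY_MONTH = np.array(
    [0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 0], dtype=int)  # Jan..Dec -> index
_SEASON_NAMES = ("winter", "spring", "summer", "autumn")


@dataclass(frozen=True)
class AnimalYearTruth:
    animal_id: str
    year: int
    state: str  # pregnant / non_pregnant
    implantation_doy: int | None
    parturition_doy: int | None
    fever_dates: tuple[dt.date, ...]
    rhythm_period_h: float


@dataclass
class GroundTruth:
    """True generating parameters per animal-year plus artifact bookkeeping.

    ``artifact_indices`` maps animal_id to 0-based row positions within that
    animal's T_b series (after missingness was applied), and
    ``artifact_true_values`` to the pre-corruption T_b at those rows.
    """

    records: list[AnimalYearTruth] = field(default_factory=list)
    artifact_indices: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_true_values: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "animal_id": r.animal_id,
                "year": r.year,
                "state": r.state,
                "implantation_doy": "" if r.implantation_doy is None else r.implantation_doy,
                "parturition_doy": "" if r.parturition_doy is None else r.parturition_doy,
                "fever_dates": ";".join(d.isoformat() for d in r.fever_dates),
                "artifact_row_indices": ";".join(
                    str(i) for i in self.artifact_indices.get(r.animal_id, [])),
            })
        return pd.DataFrame.from_records(rows)


@dataclass
class Cohort:
    """Simulated series in the on-disk schemas plus the generating truth."""

    tb: pd.DataFrame        # animal_id, timestamp, tb_c
    activity: pd.DataFrame  # animal_id, timestamp, act_x, act_y, act_total
    gps: pd.DataFrame       # animal_id, timestamp, lat, lon
    truth: GroundTruth
    config: SimConfig


def ambient_temperature(doy: np.ndarray | float, *, mean: float = 0.0,
                        amplitude: float = 12.0, peak_doy: int = 196) -> np.ndarray:
    """Helper sinusoid for ambient temperature, -12 deg C in January to
    +12 deg C in July at the defaults."""
    doy = np.asarray(doy, dtype=float)
    return mean + amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _timestamp_grid(cfg: SimConfig) -> pd.DatetimeIndex:
    start = dt.datetime(cfg.start_year, 1, 1, tzinfo=dt.timezone.utc)
    end = dt.datetime(cfg.start_year + cfg.years, 1, 1, tzinfo=dt.timezone.utc)
    return pd.date_range(start, end, freq=f"{cfg.sampling_interval}min",
                         inclusive="left")


def _circadian_shape(phase: np.ndarray, f12: float) -> np.ndarray:
    """Unit-amplitude daily waveform: cosine fundamental + 12-h harmonic."""
    return (1.0 - f12) * np.cos(phase) + f12 * np.cos(2.0 * phase)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR1 noise with marginal standard deviation ``sd``."""
    eps = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = eps[0]
    c = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + c * eps[i]
    return sd * out


def _season_amplitudes(cfg: SimConfig, months: np.ndarray) -> np.ndarray:
    table = np.array([cfg.circadian_amplitude_by_season[s] for s in _SEASON_NAMES])
    return table[_SEASON_BY_MONTH[months - 1]]


def _gestation_profile(dates: np.ndarray, year: int, impl_doy: int,
                       part_doy: int, depth: float) -> np.ndarray:
    """Daily T_b offset: linear ramp 0 -> -depth over gestation, linear
    recovery back to 0 over 3 days after parturition. ``dates`` are
    per-sample ordinal day numbers."""
    impl = dt.date(year, 1, 1).toordinal() + impl_doy - 1
    part = dt.date(year, 1, 1).toordinal() + part_doy - 1
    off = np.zeros(dates.shape)
    ges = (dates >= impl) & (dates < part)
    off[ges] = -depth * (dates[ges] - impl) / max(part - impl, 1)
    rec = (dates >= part) & (dates < part + _RECOVERY_DAYS)
    off[rec] = -depth * (1.0 - (dates[rec] - part + 1) / _RECOVERY_DAYS)
    return off


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full cohort. See the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    animal_rngs = rng.spawn(config.n_animals)

    ts = _timestamp_grid(config)
    n = len(ts)
    hours_utc = ts.hour.values + ts.minute.values / 60.0
    doy = ts.dayofyear.values.astype(float)
    years_arr = ts.year.values
    months = ts.month.values
    ordinals = np.array([t.toordinal() for t in ts.date])
    year_len = np.where([calendar.isleap(y) for y in years_arr], 366.0, 365.0)

    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.seasonal_peak_doy) / year_len)
    solar_hour = hours_utc + config.site_lon / 15.0
    phase = 2 * np.pi * (solar_hour - 12.0) / config.rhythm_period_h
    shape = _circadian_shape(phase, config.harmonic12_fraction)
    amp = _season_amplitudes(config, months)

    tb_frames, act_frames, gps_frames = [], [], []
    truth = GroundTruth()

    for a in range(config.n_animals):
        arng = animal_rngs[a]
        animal_id = f"W{a + 1:02d}"

        gest_off = np.zeros(n)
        amp_scale = np.ones(n)
        fever_add = np.zeros(n)
        pregnant_years: dict[int, tuple[int, int]] = {}

        for yi in range(config.years):
            year = config.start_year + yi
            in_year = years_arr == year
            pregnant = arng.random() < config.pregnancy_fraction
            impl = part = None
            if pregnant:
                lo, hi = config.implantation_doy_range
                impl = int(arng.integers(lo, hi + 1))
                part = impl + config.gestation_length_days
                prof_daily = _gestation_profile(ordinals, year, impl, part,
                                                config.hypothermia_depth)
                gest_off += np.where(in_year, prof_daily, 0.0)
                ges_mask = in_year & (gest_off < 0)
                amp_scale[ges_mask] = 1.0 - config.gestation_amplitude_shrink
                pregnant_years[year] = (impl, part)

            n_fever = int(arng.poisson(config.fever_rate))
            ylen = 366 if calendar.isleap(year) else 365
            fever_doys = sorted(set(
                int(d) for d in arng.integers(1, ylen + 1, size=n_fever)))
            fever_dates = tuple(dt.date(year, 1, 1) + dt.timedelta(days=d - 1)
                                for d in fever_doys)
            for d in fever_doys:
                mask = in_year & (doy == d)
                fever_add[mask] += config.fever_magnitude

            truth.records.append(AnimalYearTruth(
                animal_id=animal_id, year=year,
                state="pregnant" if pregnant else "non_pregnant",
                implantation_doy=impl, parturition_doy=part,
                fever_dates=fever_dates,
                rhythm_period_h=config.rhythm_period_h))

        noise = _ar1(arng, n, config.ar1_rho, config.noise_sd)
        tb = (config.baseline_tb + seasonal + amp * amp_scale * shape
              + gest_off + fever_add + noise)

        keep = arng.random(n) >= config.missing_fraction
        tb_kept = tb[keep]
        ts_kept = ts[keep]
        n_kept = len(tb_kept)

        n_art = int(arng.poisson(config.artifact_rate * config.years))
        art_idx = _pick_spaced_indices(arng, n_kept, n_art, min_gap=3)
        true_vals = tb_kept[art_idx].copy()
        tb_kept = tb_kept.copy()
        tb_kept[art_idx] = arng.uniform(_ARTIFACT_LOW, _ARTIFACT_HIGH,
                                        size=len(art_idx))
        truth.artifact_indices[animal_id] = art_idx
        truth.artifact_true_values[animal_id] = true_vals

        tb_frames.append(pd.DataFrame({
            "animal_id": animal_id, "timestamp": ts_kept,
            "tb_c": np.round(tb_kept, 3)}))

        peak_amp = amp.max()
        season_scale = amp / peak_amp if peak_amp > 0 else np.zeros_like(amp)
        act_frames.append(_simulate_activity(
            arng, animal_id, config, ts, shape, season_scale))

        gps_frames.append(_simulate_gps(arng, animal_id, config, pregnant_years))

    return Cohort(
        tb=pd.concat(tb_frames, ignore_index=True),
        activity=pd.concat(act_frames, ignore_index=True),
        gps=pd.concat(gps_frames, ignore_index=True),
        truth=truth, config=config)


def _pick_spaced_indices(rng: np.random.Generator, n: int, k: int,
                         min_gap: int) -> np.ndarray:
    """k interior indices pairwise at least min_gap apart (artifacts must be
    isolated single-sample dips)."""
    chosen: list[int] = []
    attempts = 0
    while len(chosen) < k and attempts < 100 * max(k, 1):
        cand = int(rng.integers(min_gap, max(n - min_gap, min_gap + 1)))
        if all(abs(cand - c) >= min_gap for c in chosen):
            chosen.append(cand)
        attempts += 1
    return np.array(sorted(chosen), dtype=int)


def _simulate_activity(rng: np.random.Generator, animal_id: str,
                       cfg: SimConfig, ts: pd.DatetimeIndex,
                       shape: np.ndarray, season_scale: np.ndarray
                       ) -> pd.DataFrame:
    """Counts 0-510 from the circadian phase: Poisson draws around
    255*(1+shape)*season_scale/2 per axis, summed."""
    mean_total = np.clip(255.0 * (1.0 + shape) * season_scale, 0.0, 510.0)
    lam = np.maximum(mean_total / 2.0, _ACT_NOISE_FLOOR)
    act_x = np.minimum(rng.poisson(lam), 255)
    act_y = np.minimum(rng.poisson(lam), 255)
    keep = rng.random(len(ts)) >= cfg.missing_fraction
    return pd.DataFrame({
        "animal_id": animal_id, "timestamp": ts[keep],
        "act_x": act_x[keep], "act_y": act_y[keep],
        "act_total": (act_x + act_y)[keep]})


def _simulate_gps(rng: np.random.Generator, animal_id: str, cfg: SimConfig,
                  pregnant_years: dict[int, tuple[int, int]]) -> pd.DataFrame:
    """3-hourly fixes: home-range random walk; after parturition the female
    stays within ~100 m of a den for a month."""
    start = dt.datetime(cfg.start_year, 1, 1, tzinfo=dt.timezone.utc)
    end = dt.datetime(cfg.start_year + cfg.years, 1, 1, tzinfo=dt.timezone.utc)
    ts = pd.date_range(start, end, freq=f"{_GPS_INTERVAL_H}h", inclusive="left")
    n = len(ts)
    deg_per_m_lat = 1.0 / 111_320.0
    deg_per_m_lon = deg_per_m_lat / np.cos(np.radians(cfg.site_lat))
    center = (cfg.site_lat + rng.normal(0, 0.05),
              cfg.site_lon + rng.normal(0, 0.1))
    step_m = rng.normal(0.0, 800.0, size=(n, 2)).cumsum(axis=0)
    step_m -= step_m.mean(axis=0)  # keep the walk anchored to the home range
    lat = center[0] + step_m[:, 0] * deg_per_m_lat
    lon = center[1] + step_m[:, 1] * deg_per_m_lon

    for year, (_, part) in pregnant_years.items():
        den = (center[0] + rng.normal(0, 0.01), center[1] + rng.normal(0, 0.02))
        part_date = dt.date(year, 1, 1) + dt.timedelta(days=part - 1)
        d0 = dt.datetime.combine(part_date, dt.time(), tzinfo=dt.timezone.utc)
        d1 = d0 + dt.timedelta(days=_DENNING_DAYS)
        mask = (ts >= d0) & (ts < d1)
        m = int(mask.sum())
        lat[mask] = den[0] + rng.normal(0, _DENNING_SD_M, m) * deg_per_m_lat
        lon[mask] = den[1] + rng.normal(0, _DENNING_SD_M, m) * deg_per_m_lon

    return pd.DataFrame({"animal_id": animal_id, "timestamp": ts,
                         "lat": np.round(lat, 6), "lon": np.round(lon, 6)})


def cohort_daily_summaries(cohort: Cohort, qc: bool = True) -> pd.DataFrame:
    """Daily summaries for every animal of a simulated cohort with the
    standard QC chain applied, plus a 0/1 ``pregnant`` truth column.

    Convenience for tests and examples; the pipeline applies the same chain
    to data read from disk.
    """
    from .io_qc import (RawSeries, detect_artifacts, flag_fever_days,
                        impute_artifacts, summarize_daily)

    truth = {r.animal_id: r for r in cohort.truth.records}
    frames = []
    for aid, grp in cohort.tb.groupby("animal_id"):
        s = RawSeries(str(aid), "tb", pd.DatetimeIndex(grp["timestamp"]),
                      grp["tb_c"].to_numpy())
        if qc:
            scan = detect_artifacts(s)
            if len(scan.indices):
                s = impute_artifacts(s, scan.indices)
        d = summarize_daily(s)
        if qc:
            d = flag_fever_days(d)
        d["pregnant"] = int(truth[str(aid)].state == "pregnant")
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write tb.csv, activity.csv, gps.csv and truth.csv for ``config``.

    Deterministic: the same config (including seed) yields byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    paths = {}

    tb = cohort.tb.copy()
    tb["timestamp"] = tb["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    paths["tb"] = out / "tb.csv"
    tb.to_csv(paths["tb"], index=False)

    act = cohort.activity.copy()
    act["timestamp"] = act["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    paths["activity"] = out / "activity.csv"
    act.to_csv(paths["activity"], index=False)

    gps = cohort.gps.copy()
    gps["timestamp"] = gps["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    paths["gps"] = out / "gps.csv"
    gps.to_csv(paths["gps"], index=False)

    paths["truth"] = out / "truth.csv"
    cohort.truth.to_frame().to_csv(paths["truth"], index=False)
    return paths
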