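"""Reading, quality control and aggregation of biologging series.

Cleaning rules follow the field protocol for implanted-logger data:

* the week of capture and the day of death are excluded;
* fever days (daily mean T_b >= 40 deg C, boundary inclusive) are excluded;
* isolated sub-34 deg C dips with immediate return to baseline are logger
  artifacts, replaced by the mean of the 3 previous and 3 following clean
  observations; days containing replaced values stay in daily-mean analyses
  but are excluded from daily-variation analyses;
* longer sub-threshold excursions are *not* treated as artifacts (they could
  be genuine hypothermia) and are reported separately.

Timestamps are stored UTC; day boundaries and hour-of-day are taken in a
configurable local timezone (default Europe/Stockholm) because daily
patterns are referenced to local light conditions.
"""

from __future__ import annotations

import datetime as dt
import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_TIMEZONE = "Europe/Stockholm"

TB_COLUMNS = ("animal_id", "timestamp", "tb_c")
ACTIVITY_COLUMNS = ("animal_id", "timestamp", "act_x", "act_y", "act_total")
GPS_COLUMNS = ("animal_id", "timestamp", "lat", "lon")


class Flag(str, enum.Enum):
    OK = "ok"
    ARTIFACT = "artifact"
    IMPUTED = "imputed"
    FEVER_DAY = "fever_day"
    CAPTURE_WEEK = "capture_week"
    DEATH_DAY = "death_day"


class SchemaError(ValueError):
    """Input file does not match the expected column schema."""


@dataclass
class RawSeries:
    """One animal's timestamped measurement stream with per-sample QC flags.

    ``values`` are deg C for kind="tb" and summed counts 0-510 for
    kind="activity". Flags start as "ok"; QC operations rewrite them.
    """

    animal_id: str
    kind: str  # "tb" | "activity"
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("tb", "activity"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.flags is None:
            self.flags = np.full(len(self.values), Flag.OK.value, dtype=object)
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values differ in length")
        diffs = np.diff(self.timestamps.asi8)
        if np.any(diffs <= 0):
            bad = self.timestamps[1:][diffs <= 0]
            raise ValueError(
                f"timestamps not strictly increasing for {self.animal_id}; "
                f"first offender {bad[0]}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def included(self) -> np.ndarray:
        """Samples that enter downstream aggregation (ok or imputed)."""
        return np.isin(self.flags, (Flag.OK.value, Flag.IMPUTED.value))

    def sampling_interval_minutes(self) -> float:
        if len(self) < 2:
            raise ValueError("need >= 2 samples to infer the interval")
        return float(np.median(np.diff(self.timestamps.asi8)) / 60e9)

    def copy(self) -> "RawSeries":
        return RawSeries(self.animal_id, self.kind, self.timestamps.copy(),
                         self.values.copy(), self.flags.copy())


def read_series(path: str | Path, kind: str) -> dict[str, RawSeries]:
    """Read tb.csv or activity.csv into one RawSeries per animal.

    Rows with unparseable timestamps are dropped and reported via a warning;
    duplicate timestamps within an animal raise.
    """
    required = TB_COLUMNS if kind == "tb" else ACTIVITY_COLUMNS
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    parsed = pd.to_datetime(df["timestamp"], errors="coerce", utc=True,
                            format="ISO8601")
    bad = parsed.isna()
    if bad.any():
        warnings.warn(f"{path}: dropped {int(bad.sum())} row(s) with "
                      f"unparseable timestamps (first at input row "
                      f"{int(np.flatnonzero(bad)[0])})")
        df, parsed = df[~bad], parsed[~bad]
    df = df.assign(timestamp=parsed)

    out: dict[str, RawSeries] = {}
    value_col = "tb_c" if kind == "tb" else "act_total"
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp")
        dup = grp["timestamp"].duplicated()
        if dup.any():
            raise ValueError(
                f"{path}: duplicated timestamp(s) for {animal_id}: "
                f"{list(grp.loc[dup, 'timestamp'].head(3))}")
        values = grp[value_col].to_numpy(dtype=float)
        if kind == "activity":
            if np.any((values < 0) | (values > 510)):
                raise ValueError(f"{path}: activity outside [0, 510] "
                                 f"for {animal_id}")
        out[str(animal_id)] = RawSeries(
            str(animal_id), kind, pd.DatetimeIndex(grp["timestamp"]), values)
    return out


def read_gps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GPS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df


def exclude_window(series: RawSeries, event_date: dt.date, mode: str) -> RawSeries:
    """Flag the capture week ([capture, capture+7d)) or the day of death.

    Returns a flagged copy; samples outside the series span are a no-op.
    """
    if mode not in ("capture_week", "death_day"):
        raise ValueError(f"unknown exclusion mode {mode!r}")
    out = series.copy()
    days = 7 if mode == "capture_week" else 1
    start = pd.Timestamp(event_date, tz="UTC")
    end = start + pd.Timedelta(days=days)
    mask = (out.timestamps >= start) & (out.timestamps < end)
    flag = Flag.CAPTURE_WEEK.value if mode == "capture_week" else Flag.DEATH_DAY.value
    out.flags[np.asarray(mask)] = flag
    return out


@dataclass(frozen=True)
class ArtifactScan:
    """Isolated low dips (artifacts) vs longer low excursions."""

    indices: np.ndarray  # sample indices of artifact runs
    excursions: list[tuple[int, int]]  # [start, end) of runs longer than max_run


def detect_artifacts(series: RawSeries, low_threshold: float = 34.0,
                     max_run: int = 2) -> ArtifactScan:
    """Find runs of <= max_run consecutive samples below ``low_threshold``
    whose flanking samples are at or above it (the "immediate return to
    baseline" signature of logger failure). Longer excursions are possible
    true hypothermia and are reported, not flagged.
    """
    if series.kind != "tb":
        raise ValueError("artifact detection applies to tb series only")
    low = series.values < low_threshold
    idx: list[int] = []
    excursions: list[tuple[int, int]] = []
    n = len(low)
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < n and low[j]:
            j += 1
        run = j - i
        flanked = i > 0 and j < n  # runs touching the ends lack a flank
        if run <= max_run and flanked:
            idx.extend(range(i, j))
        else:
            excursions.append((i, j))
        i = j
    return ArtifactScan(np.array(idx, dtype=int), excursions)


def impute_artifacts(series: RawSeries, indices: np.ndarray,
                     k: int = 3) -> RawSeries:
    """Replace each flagged sample by the mean of the k nearest clean
    preceding and k nearest clean following samples.

    With fewer than k clean neighbours on a side the available ones are used
    and a warning is emitted. Only flagged indices change; everything else
    is bit-identical.
    """
    out = series.copy()
    flagged = set(int(i) for i in indices)
    for i in sorted(flagged):
        out.flags[i] = Flag.ARTIFACT.value
    for i in sorted(flagged):
        before = [series.values[j] for j in range(i - 1, -1, -1)
                  if j not in flagged][:k]
        after = [series.values[j] for j in range(i + 1, len(series))
                 if j not in flagged][:k]
        if len(before) < k or len(after) < k:
            warnings.warn(f"{series.animal_id}: only {len(before)} preceding "
                          f"and {len(after)} following clean neighbours for "
                          f"artifact at index {i}")
        neighbours = before + after
        if not neighbours:
            raise ValueError(f"no clean neighbours around index {i}")
        out.values[i] = float(np.mean(neighbours))
        out.flags[i] = Flag.IMPUTED.value
    return out


def summarize_daily(tb: RawSeries, activity: RawSeries | None = None,
                    sparse_floor: float = 0.5,
                    timezone: str = DEFAULT_TIMEZONE) -> pd.DataFrame:
    """Per-day aggregates over non-excluded samples.

    Columns: animal_id, date, doy, mean_tb, min_tb, max_tb, daily_variation,
    mean_activity, n_obs, has_imputed, excluded, exclude_reason.
    daily_variation = max - min of the day's T_b. Days whose sample count
    falls below ``sparse_floor`` of the expected count are excluded
    (reason "sparse"). Day boundaries follow the local timezone.
    """
    local = tb.timestamps.tz_convert(timezone)
    dates = pd.Series(local.date, name="date")
    inc = tb.included
    df = pd.DataFrame({"date": dates, "value": tb.values,
                       "imputed": tb.flags == Flag.IMPUTED.value,
                       "included": inc})
    df = df[df["included"]]
    expected = 1440.0 / tb.sampling_interval_minutes()

    agg = df.groupby("date").agg(
        mean_tb=("value", "mean"), min_tb=("value", "min"),
        max_tb=("value", "max"), n_obs=("value", "size"),
        has_imputed=("imputed", "any"))
    agg["daily_variation"] = agg["max_tb"] - agg["min_tb"]

    if activity is not None:
        act_local = activity.timestamps.tz_convert(timezone)
        act_df = pd.DataFrame({"date": pd.Series(act_local.date),
                               "act": activity.values,
                               "included": activity.included})
        act_df = act_df[act_df["included"]]
        act_mean = act_df.groupby("date")["act"].mean().rename("mean_activity")
        agg = agg.join(act_mean, how="left")
    else:
        agg["mean_activity"] = np.nan

    agg = agg.reset_index()
    agg["animal_id"] = tb.animal_id
    agg["doy"] = pd.to_datetime(agg["date"]).dt.dayofyear
    agg["excluded"] = agg["n_obs"] < sparse_floor * expected
    agg["exclude_reason"] = np.where(agg["excluded"], "sparse", "")
    cols = ["animal_id", "date", "doy", "mean_tb", "min_tb", "max_tb",
            "daily_variation", "mean_activity", "n_obs", "has_imputed",
            "excluded", "exclude_reason"]
    return agg[cols]


def flag_fever_days(daily: pd.DataFrame, threshold: float = 40.0) -> pd.DataFrame:
    """Exclude days with mean T_b >= threshold (boundary inclusive)."""
    out = daily.copy()
    fever = out["mean_tb"] >= threshold
    out.loc[fever, "excluded"] = True
    out.loc[fever, "exclude_reason"] = np.where(
        out.loc[fever, "exclude_reason"] == "", "fever",
        out.loc[fever, "exclude_reason"] + ";fever")
    return out


def summarize_hourly(series: RawSeries,
                     gestation_windows: list[tuple[dt.date, dt.date]] | None = None,
                     timezone: str = DEFAULT_TIMEZONE) -> pd.DataFrame:
    """Mean value per (season, hour-of-day) for one animal, excluding
    flagged samples and, for pregnant females, the gestation window.

    Returns a DataFrame with columns animal_id, season, hour, mean_value.
    """
    from .solar import season_of

    local = series.timestamps.tz_convert(timezone)
    keep = series.included.copy()
    if gestation_windows:
        for start, end in gestation_windows:
            s = pd.Timestamp(start, tz="UTC")
            e = pd.Timestamp(end, tz="UTC") + pd.Timedelta(days=1)
            keep &= ~((series.timestamps >= s) & (series.timestamps < e))
    df = pd.DataFrame({
        "season": [season_of(d) for d in local.date],
        "hour": local.hour,
        "value": series.values})[keep]
    out = (df.groupby(["season", "hour"], sort=True)["value"].mean()
             .rename("mean_value").reset_index())
    out.insert(0, "animal_id", series.animal_id)
    return out
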