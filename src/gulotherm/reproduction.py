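"""Pregnancy classification from daily mean body temperature.

Wolverines implant in December-February after embryonic diapause; gestation
(~30-50 days) shows as a continuous decline of daily mean T_b of a few
tenths of a degree, ending in an abrupt rebound to baseline at parturition.
This module dates implantation with an exact PELT changepoint segmentation
of the daily-mean series, dates parturition from the rebound (optionally
corroborated by a collar-activity drop and GPS denning localization), and
classifies each female-year as pregnant / non-pregnant / undetermined.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ReproductionSettings

EARTH_RADIUS_M = 6_371_000.0


# ---------------------------------------------------------------------------
# PELT changepoint detection (Gaussian change-in-mean cost)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChangepointModel:
    """Optimal segmentation of a series under a penalized Gaussian
    change-in-mean cost: sum of segment residual sums of squares plus
    penalty * (number of changepoints)."""

    values: np.ndarray
    changepoints: tuple[int, ...]  # first index of each new segment
    segment_means: tuple[float, ...]
    penalty: float

    @property
    def segments(self) -> list[tuple[int, int]]:
        bounds = (0,) + self.changepoints + (len(self.values),)
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def robust_noise_variance(values: np.ndarray) -> float:
    """Noise variance from the median absolute first difference; robust to
    the mean shifts being detected. sd = 1.4826 * MAD(diff) / sqrt(2)."""
    d = np.diff(np.asarray(values, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    sd = 1.4826 * mad / np.sqrt(2.0)
    if sd <= 0:
        sd = float(np.std(d) / np.sqrt(2.0)) or 1e-8
    return sd * sd


def pelt_changepoints(values: np.ndarray,
                      penalty: float | str = "auto") -> ChangepointModel:
    """Exact penalized optimal partitioning via PELT.

    Cost of a segment is its residual sum of squares around the segment
    mean; penalty "auto" is an MBIC-like 3 * log(n) * sigma^2 with sigma^2
    the robust first-difference noise variance. The pruning is exact for
    this cost (K = 0), so the result equals the exhaustive dynamic program.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"series too short for changepoint analysis (n={n})")
    if np.any(~np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if penalty == "auto":
        beta = 3.0 * np.log(n) * robust_noise_variance(x)
    else:
        beta = float(penalty)

    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def seg_cost(s: int, t: int) -> float:
        # RSS of x[s:t] around its mean
        m = t - s
        su = cs[t] - cs[s]
        return (cs2[t] - cs2[s]) - su * su / m

    F = np.empty(n + 1)
    F[0] = -beta
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(1, n + 1):
        costs = [F[s] + seg_cost(s, t) + beta for s in candidates]
        best = int(np.argmin(costs))
        F[t] = costs[best]
        last[t] = candidates[best]
        # exact pruning: drop s that can never be optimal again
        candidates = [s for s, c in zip(candidates, costs)
                      if c - beta <= F[t]]
        candidates.append(t)

    cps: list[int] = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    cps.sort()
    bounds = [0] + cps + [n]
    means = tuple(float(np.mean(x[bounds[i]:bounds[i + 1]]))
                  for i in range(len(bounds) - 1))
    return ChangepointModel(x, tuple(cps), means, beta)


# ---------------------------------------------------------------------------
# Implantation / parturition dating
# ---------------------------------------------------------------------------

@dataclass
class ReproductiveAssignment:
    animal_id: str
    year: int
    state: str  # pregnant / non_pregnant / undetermined
    implantation_doy: int | None = None
    parturition_doy: int | None = None
    decline_depth: float = 0.0
    evidence: dict[str, bool] = field(default_factory=dict)


def _year_series(daily: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(doy, mean_tb) of non-excluded days sorted by DOY."""
    d = daily.loc[~daily["excluded"]].sort_values("doy")
    return d["doy"].to_numpy(dtype=int), d["mean_tb"].to_numpy(dtype=float)


def detect_implantation(daily: pd.DataFrame,
                        settings: ReproductionSettings | None = None
                        ) -> int | None:
    """Day of year when the gestational decline begins, or None.

    A changepoint inside the search window qualifies if it starts a run of
    successively lower segment means with cumulative decline >= depth_min
    lasting >= len_min days.
    """
    st = settings or ReproductionSettings()
    doys, y = _year_series(daily)
    if len(y) < 10:
        return None
    model = pelt_changepoints(y, st.penalty)
    segs = model.segments
    means = model.segment_means
    lo, hi = st.search_window
    for k in range(1, len(segs)):
        start_doy = int(doys[segs[k][0]])
        if not (lo <= start_doy <= hi):
            continue
        if means[k] >= means[k - 1]:
            continue
        # extend through successively lower segments
        j = k
        while j + 1 < len(segs) and means[j + 1] < means[j]:
            j += 1
        depth = means[k - 1] - min(means[k:j + 1])
        end_doy = int(doys[segs[j][1] - 1])
        if depth >= st.depth_min and end_doy - start_doy >= st.len_min:
            return _refine_onset(doys, y, start_doy, lo, hi)
    return None


def _refine_onset(doys: np.ndarray, y: np.ndarray, cp_doy: int,
                  win_lo: int, win_hi: int, halfwidth: int = 20) -> int:
    """Sharpen the decline onset with a broken-stick least-squares fit.

    The segment means of a shallow linear decline place the first
    changepoint a few days into the ramp; fitting flat-then-linear around
    it and taking the break recovers the actual onset day.
    """
    sel = (doys >= cp_doy - halfwidth) & (doys <= cp_doy + halfwidth)
    d, v = doys[sel].astype(float), y[sel]
    best = (np.inf, cp_doy)
    for b in range(max(win_lo, cp_doy - 12), min(win_hi, cp_doy + 12) + 1):
        ramp = np.maximum(d - b, 0.0)
        X = np.column_stack([np.ones_like(d), ramp])
        coef, res, *_ = np.linalg.lstsq(X, v, rcond=None)
        if coef[1] >= 0:  # must break downward
            continue
        rss = float(res[0]) if len(res) else float(
            np.sum((v - X @ coef) ** 2))
        if rss < best[0]:
            best = (rss, b)
    return int(best[1])


def _baseline_before(doys: np.ndarray, y: np.ndarray, impl_doy: int,
                     lookback: int = 14) -> float:
    mask = (doys < impl_doy) & (doys >= impl_doy - lookback)
    if not mask.any():
        mask = doys < impl_doy
    if not mask.any():
        return float(y[0])
    return float(np.mean(y[mask]))


def detect_parturition(daily: pd.DataFrame, implantation_doy: int,
                       activity_daily: pd.Series | None = None,
                       settings: ReproductionSettings | None = None
                       ) -> tuple[int | None, bool]:
    """First day after implantation where the cumulative rebound from the
    gestation trough reaches rise_min *and* the daily mean returns to
    within recovery_tol of the pre-implantation baseline within
    recovery_days. Returns (doy or None, activity_drop_flag).
    """
    st = settings or ReproductionSettings()
    doys, y = _year_series(daily)
    base = _baseline_before(doys, y, implantation_doy)
    after = doys > implantation_doy
    d_a, y_a = doys[after], y[after]
    part: int | None = None
    trough = np.inf
    for i in range(1, len(d_a)):
        trough = min(trough, y_a[i - 1])
        rise = y_a[i] - trough
        if rise < st.rise_min:
            continue
        horizon = (d_a >= d_a[i]) & (d_a <= d_a[i] + st.recovery_days)
        # the rebound must be sustained: a single elevated day (e.g. a mild
        # fever inside gestation) must not pass, so the typical post-rise
        # level, not the maximum, has to reach baseline
        if horizon.any() and np.median(y_a[horizon]) >= base - st.recovery_tol:
            part = int(d_a[i])
            break

    activity_drop = False
    if part is not None and activity_daily is not None and len(activity_daily):
        act = activity_daily.dropna()
        idx = act.index.to_numpy()
        vals = act.to_numpy(dtype=float)
        for d in range(part - 2, part + 3):
            trail = (idx >= d - 14) & (idx < d)
            here = idx == d
            if trail.sum() >= 5 and here.any():
                if vals[here][0] <= (1.0 - st.activity_drop_fraction) * np.mean(vals[trail]):
                    activity_drop = True
                    break
    return part, activity_drop


def estimate_decline_depth(daily: pd.DataFrame, implantation_doy: int,
                           parturition_doy: int) -> float:
    """Depth of gestational hypothermia: reference mean minus the daily mean
    on the day before parturition. The reference is the December mean when
    at least 15 December days exist in the record, otherwise the two weeks
    preceding implantation."""
    doys, y = _year_series(daily)
    dates = pd.to_datetime(daily.loc[~daily["excluded"], "date"])
    dec = dates.dt.month == 12
    if int(dec.sum()) >= 15:
        ref = float(daily.loc[~daily["excluded"]].loc[dec.values, "mean_tb"].mean())
    else:
        ref = _baseline_before(doys, y, implantation_doy)
    # gestation trough: lowest daily mean in the 3 days before parturition
    # (robust to the rebound being dated a day late)
    pre = (doys >= parturition_doy - 3) & (doys < parturition_doy)
    if not pre.any():
        return 0.0
    return ref - float(np.min(y[pre]))


def classify_female_year(daily: pd.DataFrame, animal_id: str, year: int,
                         activity_daily: pd.Series | None = None,
                         settings: ReproductionSettings | None = None
                         ) -> ReproductiveAssignment:
    """Full per-female-year call: pregnant when both the decline and the
    rebound are found; a decline without rebound (e.g. logger retrieved
    mid-gestation) is undetermined."""
    st = settings or ReproductionSettings()
    impl = detect_implantation(daily, st)
    if impl is None:
        return ReproductiveAssignment(animal_id, year, "non_pregnant")
    part, act_drop = detect_parturition(daily, impl, activity_daily, st)
    if part is None:
        return ReproductiveAssignment(
            animal_id, year, "undetermined", implantation_doy=impl,
            evidence={"tb_decline": True, "tb_rebound": False})
    depth = estimate_decline_depth(daily, impl, part)
    return ReproductiveAssignment(
        animal_id, year, "pregnant", implantation_doy=impl,
        parturition_doy=part, decline_depth=depth,
        evidence={"tb_decline": True, "tb_rebound": True,
                  "activity_drop": act_drop})


def reference_gestation_window(assignments: list[ReproductiveAssignment]
                               ) -> tuple[int, int]:
    """[mean implantation DOY, mean parturition DOY] over pregnant females,
    rounded to whole days; applied to non-pregnant females in group
    comparisons."""
    preg = [a for a in assignments if a.state == "pregnant"]
    if not preg:
        raise ValueError("no pregnant assignments to average")
    impl = float(np.mean([a.implantation_doy for a in preg]))
    part = float(np.mean([a.parturition_doy for a in preg]))
    return int(round(impl)), int(round(part))


def denning_localization(gps: pd.DataFrame, window_days: int = 5,
                         radius_m: float = 500.0) -> pd.Series:
    """Per-day boolean: all fixes of the trailing ``window_days`` lie within
    ``radius_m`` of their centroid (great-circle). Index: date."""
    df = gps.sort_values("timestamp")
    dates = df["timestamp"].dt.date
    uniq = sorted(dates.unique())
    lat = np.radians(df["lat"].to_numpy())
    lon = np.radians(df["lon"].to_numpy())
    out = {}
    date_arr = dates.to_numpy()
    for day in uniq:
        start = day - dt.timedelta(days=window_days - 1)
        mask = (date_arr >= start) & (date_arr <= day)
        if not mask.any():
            out[day] = False
            continue
        la, lo_ = lat[mask], lon[mask]
        clat, clon = la.mean(), lo_.mean()
        d = _haversine_m(la, lo_, clat, clon)
        out[day] = bool(np.all(d <= radius_m))
    return pd.Series(out, name="denning")


def _haversine_m(lat1: np.ndarray, lon1: np.ndarray,
                 lat2: float, lon2: float) -> np.ndarray:
    dlat = lat1 - lat2
    dlon = lon1 - lon2
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def assignments_frame(assignments: list[ReproductiveAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append({
            "animal_id": a.animal_id, "year": a.year, "state": a.state,
            "implantation_doy": a.implantation_doy if a.implantation_doy else "",
            "parturition_doy": a.parturition_doy if a.parturition_doy else "",
            "decline_depth": round(a.decline_depth, 3),
            "tb_decline": a.evidence.get("tb_decline", False),
            "tb_rebound": a.evidence.get("tb_rebound", False),
            "activity_drop": a.evidence.get("activity_drop", False),
            "gps_localized": a.evidence.get("gps_localized", False),
        })
    return pd.DataFrame.from_records(rows)
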