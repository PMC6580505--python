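"""Configuration objects for the synthetic cohort and the analysis pipeline.

Both are plain dataclasses with eager validation; ``PipelineConfig``
round-trips through YAML so a run is fully described by one file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

SEASONS = ("winter", "spring", "summer", "autumn")


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {field_name}: {msg}")


@dataclass
class SimConfig:
    """Parameters of the synthetic wolverine cohort.

    Defaults emulate the study system: a ~38.5 deg C core temperature with a
    small annual cycle peaking in July, a season-dependent circadian rhythm
    with a 12-h harmonic, gestational hypothermia of ~0.5 deg C in pregnant
    females implanting in January, occasional fever days, rare sub-34 deg C
    logger artifacts, AR1 sensor/physiology noise, and random missingness.
    """

    n_animals: int = 10
    years: int = 1
    start_year: int = 2012
    sampling_interval: int = 5  # minutes; one of 5 / 10 / 15
    baseline_tb: float = 38.5  # deg C
    seasonal_amplitude: float = 0.15  # deg C
    seasonal_peak_doy: int = 196
    circadian_amplitude_by_season: dict[str, float] = field(
        default_factory=lambda: {"winter": 1.2, "spring": 0.9,
                                 "summer": 0.8, "autumn": 1.0})
    rhythm_period_h: float = 24.0
    harmonic12_fraction: float = 0.3
    ar1_rho: float = 0.6
    noise_sd: float = 0.15  # deg C
    pregnancy_fraction: float = 0.77
    implantation_doy_range: tuple[int, int] = (5, 25)
    gestation_length_days: int = 45
    hypothermia_depth: float = 0.5  # deg C
    gestation_amplitude_shrink: float = 0.4  # fractional rhythm damping
    fever_rate: float = 0.5  # events / animal-year
    fever_magnitude: float = 2.0  # deg C added on fever days
    artifact_rate: float = 2.0  # events / animal-year
    missing_fraction: float = 0.02
    site_lat: float = 67.0
    site_lon: float = 17.67
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_animals >= 1, "n_animals", "must be >= 1")
        _check(self.years >= 1, "years", "must be >= 1")
        _check(self.sampling_interval in (5, 10, 15), "sampling_interval",
               "must be one of 5, 10, 15 minutes")
        for name in ("pregnancy_fraction", "missing_fraction",
                     "harmonic12_fraction", "gestation_amplitude_shrink"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, "must be a fraction in [0, 1]")
        for name in ("fever_rate", "artifact_rate", "noise_sd",
                     "seasonal_amplitude", "hypothermia_depth"):
            _check(getattr(self, name) >= 0.0, name, "must be >= 0")
        _check(abs(self.ar1_rho) < 1.0, "ar1_rho", "must satisfy |rho| < 1")
        _check(set(self.circadian_amplitude_by_season) == set(SEASONS),
               "circadian_amplitude_by_season",
               f"must provide all of {SEASONS}")
        _check(all(a >= 0 for a in self.circadian_amplitude_by_season.values()),
               "circadian_amplitude_by_season", "amplitudes must be >= 0")
        lo, hi = self.implantation_doy_range
        _check(1 <= lo <= hi <= 366, "implantation_doy_range",
               "must be an increasing DOY pair in [1, 366]")
        _check(self.gestation_length_days >= 1, "gestation_length_days",
               "must be >= 1")
        _check(abs(self.site_lat) <= 90, "site_lat", "must be in [-90, 90]")


@dataclass
class QCSettings:
    fever_c: float = 40.0
    artifact_c: float = 34.0
    artifact_max_run: int = 2
    impute_k: int = 3
    capture_week_days: int = 7
    sparse_floor: float = 0.5
    timezone: str = "Europe/Stockholm"


@dataclass
class ReproductionSettings:
    depth_min: float = 0.3  # deg C cumulative decline
    len_min: int = 20  # days of decline
    rise_min: float = 0.25  # deg C day-over-day rebound
    recovery_days: int = 5
    recovery_tol: float = 0.2  # deg C band around baseline
    search_window: tuple[int, int] = (1, 60)
    penalty: float | str = "auto"
    activity_drop_fraction: float = 0.4
    denning_window_days: int = 5
    denning_radius_m: float = 500.0


@dataclass
class ModelSettings:
    k_doy: int = 40
    k_hour: int = 10
    cyclic: bool = True
    alpha: float = 0.05


@dataclass
class RhythmSettings:
    window_days: int = 15
    period_range: tuple[float, float] = (2.0, 30.0)
    grid_step: float = 0.1  # hours
    min_coverage: float = 0.5
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs besides the input directory."""

    site_lat: float = 67.0
    site_lon: float = 17.67
    timezone: str = "Europe/Stockholm"
    qc: QCSettings = field(default_factory=QCSettings)
    reproduction: ReproductionSettings = field(default_factory=ReproductionSettings)
    model: ModelSettings = field(default_factory=ModelSettings)
    rhythm: RhythmSettings = field(default_factory=RhythmSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.qc.fever_c > 0 and self.qc.artifact_c > 0, "qc",
               "thresholds must be positive")
        _check(0 < self.qc.sparse_floor <= 1, "qc.sparse_floor",
               "must be in (0, 1]")
        _check(0 < self.model.alpha < 1, "model.alpha", "must be in (0, 1)")
        lo, hi = self.rhythm.period_range
        _check(0 < lo < hi, "rhythm.period_range", "must be increasing and positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sub = {"qc": QCSettings, "reproduction": ReproductionSettings,
               "model": ModelSettings, "rhythm": RhythmSettings}
        kwargs: dict[str, Any] = {}
        for key, val in raw.items():
            if key in sub:
                fields_ok = {f.name for f in dataclasses.fields(sub[key])}
                bad = set(val) - fields_ok
                if bad:
                    raise ValueError(f"unknown config keys under {key}: {sorted(bad)}")
                val = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in val.items()}
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)
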