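"""Pipeline and simulation configuration.

All analysis thresholds default to the values used operationally for the
southeastern-US right whale survey program: on-effort filters (Beaufort sea
state <= 3, altitude <= 365 m, visibility >= 3.7 km), the effort-outlier cutoff
(> 340 km2 per sampling unit), the depth exclusion rule (above sea level or
> 70 m), composite grid cell sizes (5.56 km east-west rows in the south,
7.52 km northwest-southeast rows in the north), the 22 degC isotherm, a
constant-effort prediction reference of 250 km2, spline basis dimension 3, and
five 80/20 cross-validation repeats.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml


def _finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name}: non-finite value {v!r}")


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class TrueEffects:
    """Amplitudes and shapes of the latent occurrence response.

    The latent occurrence logit is

        eta = intercept + season_effect
              + sst_amp * exp(-(SST - sst_peak)^2 / (2 sst_sd^2))        (unimodal)
              + shore_amp * exp(-dist_to_shore / shore_scale)            (decreasing)
              + depth_amp * exp(-(depth - depth_peak)^2 / (2 depth_sd^2))(unimodal)
              + iso_amp * tanh(dist_to_22iso / iso_scale)                (plateau)
              + mig_amp * exp(-(northing - mu(sm))^2 / (2 mig_sd^2))     (migration)

    where mu(sm) = mig_center + mig_osc * cos(2 pi (sm - 1) / 7) puts whales
    farther north at the start (December A) and end (March B) of the season and
    farther south mid-season. Setting every ``*_amp`` to zero yields a
    constant-probability null model.
    """

    intercept: float = -6.0
    season_effects: tuple[float, ...] = (0.4, -0.4)
    sst_amp: float = 2.5
    sst_peak: float = 14.0
    sst_sd: float = 3.0
    shore_amp: float = 2.0
    shore_scale: float = 25.0
    depth_amp: float = 0.7
    depth_peak: float = 17.0
    depth_sd: float = 10.0
    iso_amp: float = 1.0
    iso_scale: float = 40.0
    mig_amp: float = 1.2
    mig_center: float = 150.0
    mig_osc: float = 60.0
    mig_sd: float = 80.0


@dataclass
class DetectionTruth:
    """Half-normal detection scale model sigma = exp(b0 + b1 * seastate).

    Defaults give effective search widths of roughly 1.2-2.2 km across the
    platform x sea-state strata, the range reported for these surveys.
    """

    beta0: dict[str, float] = field(
        default_factory=lambda: {"Skymaster": 0.35, "TwinOtter": 0.55}
    )
    beta1: float = -0.12
    truncation_km: float = 3.0


@dataclass
class SimConfig:
    """Configuration of the synthetic survey world.

    The defaults describe the study conditions every downstream test runs
    under: a 2-season x 8-semimonth coastal study area of ~320 composite grid
    cells (~5000 sampling units), a cold (-1.5 degC) and a warm (+1.5 degC)
    season, a Gulf Stream proxy warm band offshore, spatially coherent cloud
    interference over 30% of pixels, and detection-thinned surveys from two
    platforms.
    """

    seed: int = 20031201
    n_seasons: int = 2
    first_season_year: int = 2009
    # domain (projected km; coast is the x = 0 line, ocean at x > 0)
    x_min: float = -6.0
    x_max: float = 60.0
    y_min: float = 0.0
    y_max: float = 310.0
    pixel_km: float = 1.5
    # bathymetry and coastline
    shelf_max_depth_m: float = 75.0
    shelf_width_km: float = 60.0
    shelf_profile_power: float = 0.9
    shelf_width_mod: float = 0.5       # alongshore shelf-width modulation
    coast_wiggle_km: float = 4.0       # shoreline meander amplitude
    # SST dynamics (degC)
    sst_winter_mean: float = 16.0
    sst_seasonal_dip: float = 5.0
    sst_anomaly_per_season: tuple[float, ...] = (-1.5, 1.5)
    sst_lat_gradient: float = 2.0  # degC warmer at y_min, cooler at y_max
    gulf_stream_offset_km: float = 45.0
    gulf_stream_width_km: float = 12.0
    # the warm band blends the background toward an advected core temperature
    # (> 22 degC year-round), rather than adding heat locally
    gulf_stream_core_c: float = 24.5
    gulf_stream_meander_km: float = 12.0  # onshore-offshore meander amplitude
    sst_noise_sd: float = 0.9
    sst_noise_corr_km: float = 9.0
    sst_noise_ar1: float = 0.6
    cloud_fraction: float = 0.3
    cloud_corr_km: float = 20.0
    # latent whale distribution
    true_effects: TrueEffects = field(default_factory=TrueEffects)
    positive_count_mean: float = 3.0
    group_size_mean: float = 2.2
    calf_fraction: float = 0.4
    calf_depth_bias: float = 0.15
    # surveys
    detection: DetectionTruth = field(default_factory=DetectionTruth)
    flights_per_semimonth: int = 8
    platform_probs: dict[str, float] = field(
        default_factory=lambda: {"Skymaster": 0.75, "TwinOtter": 0.25}
    )
    seastate_probs: tuple[float, ...] = (0.15, 0.30, 0.30, 0.20, 0.05)
    offeffort_altitude_rate: float = 0.04
    offeffort_visibility_rate: float = 0.04
    duplicate_rate: float = 0.05
    verification_rate: float = 0.03

    def __post_init__(self) -> None:
        _finite(
            "SimConfig",
            self.x_min, self.x_max, self.y_min, self.y_max, self.pixel_km,
            self.shelf_max_depth_m, self.shelf_width_km,
            self.sst_winter_mean, self.sst_seasonal_dip,
            self.gulf_stream_offset_km, self.gulf_stream_width_km,
            self.gulf_stream_core_c, self.sst_noise_sd, self.cloud_fraction,
        )
        _finite("SimConfig.sst_anomaly_per_season", *self.sst_anomaly_per_season)
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ValueError("cloud_fraction must lie in [0, 1]")
        if self.gulf_stream_width_km < 0:
            raise ValueError("gulf_stream_width_km must be >= 0")
        if self.pixel_km <= 0:
            raise ValueError("pixel_km must be > 0")
        if len(self.sst_anomaly_per_season) < self.n_seasons:
            raise ValueError("need one SST anomaly per season")
        if len(self.true_effects.season_effects) < self.n_seasons:
            raise ValueError("need one season effect per season")

    @property
    def season_labels(self) -> list[str]:
        y0 = self.first_season_year
        return [f"{y0 + i}/{y0 + i + 1}" for i in range(self.n_seasons)]


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Analysis thresholds and model settings (defaults = published values)."""

    max_seastate: int = 3
    max_altitude_m: float = 365.0
    min_visibility_km: float = 3.7
    max_effort_km2: float = 340.0
    max_depth_m: float = 70.0
    south_cell_km: float = 5.56
    north_cell_km: float = 7.52
    isotherm_c: float = 22.0
    effort_ref_km2: float = 250.0
    basis_dim: int = 3
    cv_repeats: int = 5
    cv_train_fraction: float = 0.8
    skymaster_blind_spot_km: float = 0.186
    min_raster_coverage: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "max_altitude_m", "min_visibility_km", "max_effort_km2",
            "max_depth_m", "south_cell_km", "north_cell_km", "effort_ref_km2",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(cfg: SimConfig | PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def load_sim_config(path: str) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["true_effects"] = TrueEffects(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.get("true_effects", {}).items()
        }
    )
    raw["detection"] = DetectionTruth(**raw.get("detection", {}))
    for key in ("sst_anomaly_per_season", "seastate_probs"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)


def load_pipeline_config(path: str) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def config_diff(cfg: PipelineConfig) -> dict[str, tuple[Any, Any]]:
    """Fields differing from the defaults, as {name: (value, default)}."""
    default = PipelineConfig()
    out: dict[str, tuple[Any, Any]] = {}
    for f in dataclasses.fields(cfg):
        v, d = getattr(cfg, f.name), getattr(default, f.name)
        if v != d:
            out[f.name] = (v, d)
    return out
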