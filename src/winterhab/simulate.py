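"""Synthetic survey world with known ground truth.

Emulates the data-generating context of the southeastern-US right whale
aerial surveys on a flat projected plane: a north-south coastline at x = 0, a
monotonically deepening shelf, daily SST fields with a seasonal cycle,
per-season anomalies, a warm offshore band (Gulf Stream proxy, > 22 degC in
its core), spatially coherent cloud interference, a latent whale occurrence
surface responding smoothly to SST / depth / distance to shore / signed
isotherm distance plus a semimonth x northing migration signal, zero-inflated
group counts, and detection-thinned line-transect surveys from two aircraft
platforms whose half-normal detection scale depends on sea state.

Everything is driven by a single seeded generator: identical
:class:`~winterhab.config.SimConfig` (including seed) gives byte-identical
outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString

from winterhab import enviro
from winterhab.config import PipelineConfig, SimConfig, TrueEffects
from winterhab.enviro import Raster, SSTComposite
from winterhab.surveys import Grid, build_grid, season_days, semimonth_key


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

@dataclass
class Environment:
    """Generated bathymetry, shoreline and daily SST stacks per season."""

    config: SimConfig
    bathymetry: Raster
    shoreline: LineString
    template: Raster                      # raster geometry carrier
    days: dict[str, list[dt.date]]        # season label -> daily dates
    sst: dict[str, np.ndarray]            # season -> (n_days, ny, nx)
    clouds: dict[str, np.ndarray]         # season -> bool, True = cloudy

    def semimonth_day_index(self, season: str) -> dict[int, np.ndarray]:
        """Day indices of each semimonthly period (ordinals 1-8)."""
        _, ordinal = semimonth_key(
            pd.Series([d.isoformat() for d in self.days[season]])
        )
        return {
            sm: np.nonzero((ordinal == sm).to_numpy())[0]
            for sm in range(1, 9)
        }

    def composite(self, season: str, semimonth: int,
                  use_clouds: bool = True) -> SSTComposite:
        idx = self.semimonth_day_index(season)[semimonth]
        stack = self.sst[season][idx]
        mask = self.clouds[season][idx] if use_clouds else \
            np.zeros_like(stack, dtype=bool)
        return enviro.composite_sst(stack, mask, self.template, season,
                                    semimonth)

    def composites(self, use_clouds: bool = True) -> list[SSTComposite]:
        return [
            self.composite(season, sm, use_clouds)
            for season in self.config.season_labels
            for sm in range(1, 9)
        ]


def _smooth_field(rng: np.random.Generator, shape, corr_pixels: float
                  ) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian random field."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, corr_pixels, mode="nearest")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_environment(config: SimConfig) -> Environment:
    """Generate bathymetry, shoreline and daily SST rasters with cloud masks."""
    rng = np.random.default_rng(config.seed)
    nx = int(round((config.x_max - config.x_min) / config.pixel_km))
    ny = int(round((config.y_max - config.y_min) / config.pixel_km))
    template = Raster(config.x_min, config.y_min, config.pixel_km,
                      np.zeros((ny, nx)))
    gx, gy = template.centers()

    # gently meandering coastline and alongshore shelf-width modulation keep
    # depth, distance to shore and SST correlated but not collinear, as on
    # the real shelf; depth still deepens monotonically offshore at fixed y
    def coast_x(yy):
        a = config.coast_wiggle_km
        return a * (np.sin(yy / 55.0) + 0.6 * np.sin(yy / 23.0 + 2.0))

    width = config.shelf_width_km * (
        1.0 + config.shelf_width_mod * (
            np.sin(gy / 47.0 + 1.0) + 0.5 * np.sin(gy / 13.0 + 0.7)
        )
    )
    off = gx - coast_x(gy)
    depth = config.shelf_max_depth_m * (
        np.minimum(np.maximum(off, 0.0) / width, 1.0)
        ** config.shelf_profile_power
    )
    depth = np.where(off <= 0.0, 4.0 * off, depth)
    bathy = Raster(config.x_min, config.y_min, config.pixel_km, depth)

    ys_dense = np.linspace(config.y_min, config.y_max, 400)
    shoreline = LineString(np.column_stack([coast_x(ys_dense), ys_dense]))

    # warm-band blending weight: 1 in the band core, 0 far away
    band_w = np.zeros_like(gx)
    if config.gulf_stream_width_km > 0:
        x_band = config.gulf_stream_offset_km + \
            config.gulf_stream_meander_km * np.sin(2 * np.pi * gy / 190.0)
        band_w = np.exp(
            -((gx - x_band) ** 2) / (2.0 * config.gulf_stream_width_km ** 2)
        )
    lat = config.sst_lat_gradient * (
        1.0 - 2.0 * (gy - config.y_min) / (config.y_max - config.y_min)
    )

    corr_px = config.sst_noise_corr_km / config.pixel_km
    cloud_px = config.cloud_corr_km / config.pixel_km

    days: dict[str, list[dt.date]] = {}
    sst: dict[str, np.ndarray] = {}
    clouds: dict[str, np.ndarray] = {}
    for s_idx, season in enumerate(config.season_labels):
        dlist = season_days(season)
        nd = len(dlist)
        anom = config.sst_anomaly_per_season[s_idx]
        t = np.arange(nd) / (nd - 1)
        base = config.sst_winter_mean - config.sst_seasonal_dip * np.sin(
            np.pi * t
        )
        stack = np.empty((nd, ny, nx))
        cmask = np.zeros((nd, ny, nx), dtype=bool)
        eps = _smooth_field(rng, (ny, nx), corr_px)
        rho = config.sst_noise_ar1
        for i in range(nd):
            if i > 0:
                eps = rho * eps + np.sqrt(1 - rho * rho) * _smooth_field(
                    rng, (ny, nx), corr_px
                )
            bg = base[i] + anom + lat
            core = config.gulf_stream_core_c + anom
            stack[i] = bg + (core - bg) * band_w \
                + config.sst_noise_sd * eps
            if config.cloud_fraction > 0:
                cf = _smooth_field(rng, (ny, nx), cloud_px)
                thresh = np.quantile(cf, 1.0 - config.cloud_fraction)
                cmask[i] = cf >= thresh
        days[season] = dlist
        sst[season] = stack
        clouds[season] = cmask

    return Environment(config, bathy, shoreline, template, days, sst, clouds)


# ---------------------------------------------------------------------------
# Latent whale distribution
# ---------------------------------------------------------------------------

def effect_curves(eff: TrueEffects) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """True covariate response curves on dense grids (logit scale)."""
    out = {}
    sst = np.linspace(5.0, 30.0, 251)
    out["sst_c"] = (sst, eff.sst_amp * np.exp(
        -((sst - eff.sst_peak) ** 2) / (2 * eff.sst_sd ** 2)))
    ds = np.linspace(0.0, 60.0, 241)
    out["dist_to_shore_km"] = (ds, eff.shore_amp * np.exp(-ds / eff.shore_scale))
    dep = np.linspace(0.0, 75.0, 301)
    out["depth_m"] = (dep, eff.depth_amp * np.exp(
        -((dep - eff.depth_peak) ** 2) / (2 * eff.depth_sd ** 2)))
    iso = np.linspace(-60.0, 200.0, 261)
    out["dist_to_22iso_km"] = (iso, eff.iso_amp * np.tanh(iso / eff.iso_scale))
    return out


def latent_logit(units: pd.DataFrame, eff: TrueEffects,
                 season_index: np.ndarray) -> np.ndarray:
    """Latent occurrence logit for rows of a unit covariate table."""
    sst = units["sst_c"].to_numpy(float)
    ds = units["dist_to_shore_km"].to_numpy(float)
    dep = units["depth_m"].to_numpy(float)
    iso = units["dist_to_22iso_km"].to_numpy(float)
    nor = units["northing"].to_numpy(float)
    sm = units["semimonth"].to_numpy(float)

    mu_sm = eff.mig_center + eff.mig_osc * np.cos(2 * np.pi * (sm - 1) / 7.0)
    eta = (
        eff.intercept
        + np.asarray(eff.season_effects)[season_index]
        + eff.sst_amp * np.exp(-((sst - eff.sst_peak) ** 2)
                               / (2 * eff.sst_sd ** 2))
        + eff.shore_amp * np.exp(-ds / eff.shore_scale)
        + eff.depth_amp * np.exp(-((dep - eff.depth_peak) ** 2)
                                 / (2 * eff.depth_sd ** 2))
        + eff.iso_amp * np.tanh(np.nan_to_num(iso) / eff.iso_scale)
        + eff.mig_amp * np.exp(-((nor - mu_sm) ** 2) / (2 * eff.mig_sd ** 2))
    )
    return eta


@dataclass
class TruthRecord:
    """Latent and realized whale distribution per sampling unit."""

    units: pd.DataFrame    # cell_id, season, semimonth, covariates, eta,
                           # p_occ, mu_pos, presence, n_whales
    groups: pd.DataFrame   # group_id, cell_id, season, semimonth, x, y,
                           # size, calf
    effects: TrueEffects
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        p = self.units["p_occ"].to_numpy(float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("occurrence probabilities outside [0, 1]")
        if np.any(self.units["mu_pos"].to_numpy(float) < 0):
            raise ValueError("negative expected counts")
        n = self.units["n_whales"].to_numpy()
        if np.any(n < 0) or not np.issubdtype(n.dtype, np.integer):
            raise ValueError("realized counts must be integers >= 0")


def generate_whales(
    env: Environment,
    config: SimConfig | None = None,
    grid: Grid | None = None,
    pipeline_cfg: PipelineConfig | None = None,
) -> TruthRecord:
    """Realize the latent whale distribution over cells x semimonths.

    Occurrence follows a Bernoulli draw of the latent logit surface; positive
    whale counts are 1 + Poisson(mean - 1); counts are split into groups
    placed uniformly within their cell, with cow-calf-pair probability
    increasing in shallower cells.
    """
    config = config or env.config
    grid = grid or build_grid()
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    rng = np.random.default_rng(config.seed + 1)

    cov = enviro.covariate_table(
        env.bathymetry, env.shoreline, env.composites(use_clouds=False),
        grid, pipeline_cfg,
    )
    season_index = (
        cov["season"].map(
            {s: i for i, s in enumerate(config.season_labels)}
        ).to_numpy()
    )
    eff = config.true_effects
    eta = latent_logit(cov, eff, season_index)
    p = 1.0 / (1.0 + np.exp(-eta))
    m = config.positive_count_mean
    if m < 1:
        raise ValueError("positive_count_mean must be >= 1")

    presence = rng.random(len(p)) < p
    n_whales = np.zeros(len(p), dtype=int)
    n_whales[presence] = 1 + rng.poisson(m - 1.0, int(presence.sum()))

    units = cov.copy()
    units["eta"] = eta
    units["p_occ"] = p
    units["mu_pos"] = m
    units["presence"] = presence
    units["n_whales"] = n_whales

    # split realized counts into groups and place them in their cells
    zones = {z.name: z for z in grid.zones}
    rows = []
    gid = 0
    for row in units.loc[presence].itertuples():
        cell = grid.cell(row.cell_id)
        z = zones[cell.zone]
        remaining = row.n_whales
        p_calf = float(np.clip(
            config.calf_fraction
            + config.calf_depth_bias * (eff.depth_peak - row.depth_m) / 30.0,
            0.0, 1.0,
        ))
        while remaining > 0:
            size = min(remaining, 1 + rng.poisson(
                max(config.group_size_mean - 1.0, 0.0)))
            du = rng.uniform(0.0, cell.size_km)
            dv = rng.uniform(-cell.size_km / 2.0, cell.size_km / 2.0)
            u0 = z.row_u_start(cell.row) + cell.col * cell.size_km
            x, y = z.from_frame(u0 + du, cell.row * cell.size_km + dv)
            rows.append(
                (f"G{gid:06d}", row.cell_id, row.season, row.semimonth,
                 float(x), float(y), int(size), bool(rng.random() < p_calf))
            )
            gid += 1
            remaining -= size
    groups = pd.DataFrame(
        rows,
        columns=["group_id", "cell_id", "season", "semimonth", "x", "y",
                 "size", "calf"],
    )
    return TruthRecord(units, groups, eff, effect_curves(eff))


# ---------------------------------------------------------------------------
# Surveys
# ---------------------------------------------------------------------------

def _zone_segments(z):
    """Per-flight segment template: one on-transect segment per cell plus
    transit hops between consecutive transects."""
    xs0, ys0, xs1, ys1, status = [], [], [], [], []
    for i in range(z.n_transects):
        v = i * z.cell_km
        us = z.row_u_start(i)
        for j in range(z.n_cells_along):
            u0, u1 = us + j * z.cell_km, us + (j + 1) * z.cell_km
            x0, y0 = z.from_frame(u0, v)
            x1, y1 = z.from_frame(u1, v)
            xs0.append(x0); ys0.append(y0); xs1.append(x1); ys1.append(y1)
            status.append("on_transect")
        if i + 1 < z.n_transects:
            x0, y0 = z.from_frame(us + z.length, v)
            x1, y1 = z.from_frame(z.row_u_start(i + 1) + z.length,
                                  v + z.cell_km)
            xs0.append(x0); ys0.append(y0); xs1.append(x1); ys1.append(y1)
            status.append("transit")
    return (np.array(xs0), np.array(ys0), np.array(xs1), np.array(ys1),
            np.array(status, dtype=object))


def generate_surveys(
    truth: TruthRecord,
    env: Environment,
    config: SimConfig | None = None,
    grid: Grid | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fly synthetic surveys over the realized whale field.

    Each semimonth every zone is flown ``flights_per_semimonth`` times on
    random days with per-flight platform, sea state, altitude and visibility.
    Whale groups within the truncation distance of a flown transect are
    detected with probability exp(-d^2 / 2 sigma^2) of their perpendicular
    distance d, sigma = exp(beta0_platform + beta1 * seastate). Fixed
    proportions of flights are made off-effort through altitude/visibility
    violations, and fixed proportions of sightings are duplicated or flagged
    as verification records, so downstream filter accounting is predictable.
    """
    config = config or env.config
    grid = grid or build_grid()
    if config.detection.truncation_km <= 0:
        raise ValueError("truncation distance must be positive")
    rng = np.random.default_rng(config.seed + 2)
    platforms = sorted(config.platform_probs)
    pprobs = np.array([config.platform_probs[p] for p in platforms])
    pprobs = pprobs / pprobs.sum()
    ss_vals = np.arange(len(config.seastate_probs))
    templates = {z.name: _zone_segments(z) for z in grid.zones}

    flight_meta = []
    for season in config.season_labels:
        day_idx = {
            sm: [env.days[season][i] for i in idx]
            for sm, idx in env.semimonth_day_index(season).items()
        }
        for sm in range(1, 9):
            for z in grid.zones:
                for k in range(config.flights_per_semimonth):
                    date = day_idx[sm][int(rng.integers(len(day_idx[sm])))]
                    platform = platforms[int(rng.choice(len(platforms),
                                                        p=pprobs))]
                    seastate = int(rng.choice(ss_vals,
                                              p=config.seastate_probs))
                    altitude = float(rng.normal(305.0, 20.0))
                    visibility = float(rng.uniform(5.0, 15.0))
                    flight_meta.append(
                        [season, sm, z.name, k, date, platform, seastate,
                         altitude, visibility]
                    )
    # exact off-effort injection: altitude and visibility violations
    n_flights = len(flight_meta)
    n_alt = round(config.offeffort_altitude_rate * n_flights)
    n_vis = round(config.offeffort_visibility_rate * n_flights)
    bad = rng.choice(n_flights, size=min(n_alt + n_vis, n_flights),
                     replace=False)
    for i in bad[:n_alt]:
        flight_meta[i][7] = float(rng.uniform(370.0, 420.0))
    for i in bad[n_alt:]:
        flight_meta[i][8] = float(rng.uniform(1.0, 3.5))

    zones = {z.name: z for z in grid.zones}
    det = config.detection
    groups = truth.groups
    g_by_key: dict[tuple, pd.DataFrame] = {}
    if len(groups):
        zone_of_cell = groups["cell_id"].str.split("-").str[0]
        for key, sub in groups.groupby(
            [groups["season"], groups["semimonth"], zone_of_cell]
        ):
            g_by_key[key] = sub

    seg_frames = []
    sight_rows = []
    sight_id = 0
    for season, sm, zname, k, date, platform, seastate, altitude, visibility \
            in flight_meta:
        z = zones[zname]
        xs0, ys0, xs1, ys1, status = templates[zname]
        survey_id = f"{season.replace('/', '-')}_{sm}_{zname}_{k}"
        seg_frames.append(pd.DataFrame({
            "survey_id": survey_id,
            "date": date.isoformat(),
            "platform": platform,
            "x0": xs0, "y0": ys0, "x1": xs1, "y1": ys1,
            "seastate": seastate,
            "altitude_m": altitude,
            "visibility_km": visibility,
            "status": status,
            "is_verification": False,
        }))
        on_effort = (
            seastate <= 3 and altitude <= 365.0 and visibility >= 3.7
        )
        sub = g_by_key.get((season, sm, zname))
        if sub is None or not len(sub):
            continue
        u, v = z.to_frame(sub["x"].to_numpy(), sub["y"].to_numpy())
        row = np.round(v / z.cell_km).astype(int)
        d = np.abs(v - row * z.cell_km)
        us = z.row_u_start(0) + row * z.stagger * z.cell_km
        in_swath = (d <= det.truncation_km) & (u >= us) & (u <= us + z.length)
        sigma = np.exp(det.beta0[platform] + det.beta1 * seastate)
        pdet = np.exp(-d * d / (2.0 * sigma * sigma))
        detected = in_swath & (rng.random(len(sub)) < pdet)
        for gi, dist in zip(np.nonzero(detected)[0], d[detected]):
            g = sub.iloc[gi]
            sight_rows.append({
                "sighting_id": f"S{sight_id:06d}",
                "survey_id": survey_id,
                "date": date.isoformat(),
                "x": g["x"], "y": g["y"],
                "group_size": int(g["size"]),
                "calf_present": bool(g["calf"]),
                "perp_distance_km": float(dist),
                "platform": platform,
                "seastate": seastate,
                "is_duplicate": False,
                "is_verification": False,
                "initial_status_on_effort": on_effort,
                "group_id": g["group_id"],
            })
            sight_id += 1

    segments = pd.concat(seg_frames, ignore_index=True)
    sightings = pd.DataFrame(sight_rows)
    if len(sightings):
        # inject duplicate and verification records at fixed proportions
        n_dup = round(config.duplicate_rate * len(sightings))
        n_ver = round(config.verification_rate * len(sightings))
        extra = []
        if n_dup:
            picks = rng.choice(len(sightings), n_dup, replace=False)
            dup = sightings.iloc[picks].copy()
            dup["is_duplicate"] = True
            extra.append(dup)
        if n_ver:
            picks = rng.choice(len(sightings), n_ver, replace=False)
            ver = sightings.iloc[picks].copy()
            ver["is_verification"] = True
            extra.append(ver)
        if extra:
            sightings = pd.concat([sightings] + extra, ignore_index=True)
        sightings["sighting_id"] = [
            f"S{i:06d}" for i in range(len(sightings))
        ]
    return segments, sightings


def simulate_all(
    config: SimConfig | None = None,
    grid: Grid | None = None,
    pipeline_cfg: PipelineConfig | None = None,
):
    """Environment, truth and surveys in one call."""
    config = config or SimConfig()
    grid = grid or build_grid()
    env = generate_environment(config)
    truth = generate_whales(env, config, grid, pipeline_cfg)
    segments, sightings = generate_surveys(truth, env, config, grid)
    return env, truth, segments, sightings
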