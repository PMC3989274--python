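"""Synthetic-data generator: environment, latent whales, surveys."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from winterhab import simulate, surveys
from winterhab.config import PipelineConfig, SimConfig, TrueEffects
from winterhab.simulate import (
    generate_environment,
    generate_surveys,
    generate_whales,
    latent_logit,
)

SMALL = dict(x_max=40.0, y_max=80.0, n_seasons=1,
             sst_anomaly_per_season=(0.0,))


def small_cfg(**kw):
    base = {**SMALL, **kw}
    eff = base.pop("true_effects", TrueEffects(season_effects=(0.0,)))
    return SimConfig(true_effects=eff, **base)


def small_grid():
    return surveys.build_grid(south_transects=12, south_cells_along=6,
                              north_transects=0, north_cells_along=0,
                              split_northing=1e9)


@pytest.fixture(scope="module")
def small_env():
    return generate_environment(small_cfg())


class TestEnvironment:
    def test_deterministic_given_seed(self):
        cfg = small_cfg()
        e1 = generate_environment(cfg)
        e2 = generate_environment(cfg)
        s = cfg.season_labels[0]
        assert np.array_equal(e1.sst[s], e2.sst[s])
        assert np.array_equal(e1.clouds[s], e2.clouds[s])
        assert np.array_equal(e1.bathymetry.data, e2.bathymetry.data)

    def test_zero_cloud_fraction_fully_observed(self):
        env = generate_environment(small_cfg(cloud_fraction=0.0))
        s = env.config.season_labels[0]
        assert not env.clouds[s].any()

    def test_cloud_fraction_approximate(self, small_env):
        s = small_env.config.season_labels[0]
        frac = small_env.clouds[s].mean()
        assert frac == pytest.approx(0.3, abs=0.02)

    def test_season_anomaly_shifts_domain_mean(self):
        """A +2 degC season anomaly raises the season's domain-mean SST by
        2 +- 0.1 relative to a zero-anomaly season."""
        cfg = small_cfg(n_seasons=2, sst_anomaly_per_season=(0.0, 2.0),
                        true_effects=TrueEffects(season_effects=(0.0, 0.0)))
        env = generate_environment(cfg)
        s0, s1 = cfg.season_labels
        diff = env.sst[s1].mean() - env.sst[s0].mean()
        assert diff == pytest.approx(2.0, abs=0.1)

    def test_depth_monotone_offshore_up_to_shelf_max(self, small_env):
        d = small_env.bathymetry.data
        ocean = d > 0
        # along each west-east row, ocean depth never decreases
        for row, orow in zip(d, ocean):
            vals = row[orow]
            assert np.all(np.diff(vals) >= -1e-9)
        assert d.max() <= small_env.config.shelf_max_depth_m + 1e-9

    def test_warm_band_core_exceeds_22(self):
        cfg = small_cfg(gulf_stream_offset_km=25.0,
                        gulf_stream_meander_km=0.0)
        env = generate_environment(cfg)
        s = cfg.season_labels[0]
        xs = env.template.xs()
        core = np.argmin(np.abs(xs - 25.0))
        # band-core composite SST stays above 22 degC in every semimonth
        for sm in range(1, 9):
            comp = env.composite(s, sm, use_clouds=False)
            assert np.nanmin(comp.raster.data[:, core]) > 22.0

    def test_zero_band_width_removes_isotherm(self):
        cfg = small_cfg(gulf_stream_width_km=0.0, sst_anomaly_per_season=(-1.0,))
        env = generate_environment(cfg)
        s = cfg.season_labels[0]
        # mid-winter (February) field stays below 22 degC everywhere
        feb = env.composite(s, 5, use_clouds=False)
        bound = (cfg.sst_winter_mean + cfg.sst_lat_gradient
                 + 5 * cfg.sst_noise_sd)
        assert np.nanmax(feb.raster.data) < min(22.0, bound + 1e-9)

    def test_nonfinite_config_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            small_cfg(sst_winter_mean=float("nan"))
        with pytest.raises(ValueError, match="cloud_fraction"):
            small_cfg(cloud_fraction=1.4)


class TestWhales:
    def test_zero_amplitudes_constant_probability(self, small_env):
        eff = TrueEffects(intercept=-2.0, season_effects=(0.0,),
                          sst_amp=0, shore_amp=0, depth_amp=0, iso_amp=0,
                          mig_amp=0)
        cfg = dataclasses.replace(small_env.config, true_effects=eff)
        truth = generate_whales(small_env, cfg, small_grid())
        p = truth.units["p_occ"]
        expect = 1 / (1 + np.exp(2.0))
        assert np.allclose(p, expect)

    def test_occurrence_peaks_near_configured_sst(self, processed):
        """Binned empirical occurrence frequency attains its maximum in the
        13-15 degC bin for the default peak of 14 degC (>= 5000 periods)."""
        u = processed["truth"].units.dropna(subset=["sst_c"])
        assert len(u) >= 5000
        bins = np.arange(7, 25, 2.0)
        freq = u.groupby(pd.cut(u["sst_c"], bins), observed=True)[
            "presence"].mean()
        best = freq.idxmax()
        assert best.left >= 11 and best.right <= 17
        # finer check on the long default run: max in the 13-15 bin
        fine = u.groupby(pd.cut(u["sst_c"], np.arange(9, 21, 2.0)),
                         observed=True)["presence"].mean()
        assert fine.idxmax() == pd.Interval(13.0, 15.0)

    def test_season_intercept_orders_totals(self, small_env):
        """A +1 season intercept yields more whales than a 0 season in
        >= 95% of 100 replicate pairs of Bernoulli realizations."""
        grid = small_grid()
        eff0 = TrueEffects(season_effects=(0.0,))
        cfg = dataclasses.replace(small_env.config, true_effects=eff0)
        truth = generate_whales(small_env, cfg, grid)
        eta = truth.units["eta"].to_numpy()
        eta = eta[np.isfinite(eta)]
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(100):
            n0 = (rng.random(len(eta)) < 1 / (1 + np.exp(-eta))).sum()
            n1 = (rng.random(len(eta)) < 1 / (1 + np.exp(-(eta + 1)))).sum()
            wins += n1 > n0
        assert wins >= 95

    def test_positive_count_mean_matches_config(self, small_env):
        eff = TrueEffects(intercept=1.0, season_effects=(0.0,))  # dense
        cfg = dataclasses.replace(small_env.config, true_effects=eff)
        truth = generate_whales(small_env, cfg, small_grid())
        pos = truth.units.loc[truth.units["presence"], "n_whales"]
        assert len(pos) >= 400
        assert pos.mean() == pytest.approx(cfg.positive_count_mean,
                                           rel=0.05)

    def test_truth_invariants(self, processed):
        u = processed["truth"].units
        assert ((u["p_occ"] >= 0) & (u["p_occ"] <= 1)).all()
        assert (u["n_whales"] >= 0).all()
        assert (u.loc[~u["presence"], "n_whales"] == 0).all()
        g = processed["truth"].groups
        merged = g.groupby(["cell_id", "season", "semimonth"])["size"].sum()
        realized = u.set_index(["cell_id", "season", "semimonth"])["n_whales"]
        assert (merged == realized.loc[merged.index]).all()


class TestSurveys:
    def test_deterministic(self, small_env):
        cfg = small_env.config
        grid = small_grid()
        t1 = generate_whales(small_env, cfg, grid)
        s1, g1 = generate_surveys(t1, small_env, cfg, grid)
        t2 = generate_whales(small_env, cfg, grid)
        s2, g2 = generate_surveys(t2, small_env, cfg, grid)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_zero_whales_zero_sightings_segments_emitted(self, small_env):
        eff = TrueEffects(intercept=-40.0, season_effects=(0.0,))
        cfg = dataclasses.replace(small_env.config, true_effects=eff)
        grid = small_grid()
        truth = generate_whales(small_env, cfg, grid)
        segs, sights = generate_surveys(truth, small_env, cfg, grid)
        assert len(sights) == 0
        assert len(segs) > 0

    def test_huge_sigma_detects_every_inswath_group(self, small_env):
        """With beta0 huge, every group is sighted on every on-effort flight
        over its semimonth (perfect detection)."""
        cfg = dataclasses.replace(
            small_env.config,
            detection=simulate.SimConfig().detection.__class__(
                beta0={"Skymaster": 8.0, "TwinOtter": 8.0}, beta1=0.0,
                truncation_km=3.0),
            flights_per_semimonth=2,
            duplicate_rate=0.0, verification_rate=0.0,
            offeffort_altitude_rate=0.0, offeffort_visibility_rate=0.0,
        )
        grid = small_grid()
        truth = generate_whales(small_env, cfg, grid)
        segs, sights = generate_surveys(truth, small_env, cfg, grid)
        n_groups = len(truth.groups)
        # every group seen exactly flights_per_semimonth times
        assert len(sights) == 2 * n_groups

    def test_negative_beta1_lowers_high_seastate_detection(self, small_env):
        """Empirical detection frequency at sea state 3 is lower than at sea
        state 0 (>= 2000 exposures each)."""
        eff = TrueEffects(intercept=0.5, season_effects=(0.0,))  # dense truth
        cfg = dataclasses.replace(small_env.config, true_effects=eff,
                                  duplicate_rate=0.0, verification_rate=0.0)
        grid = small_grid()
        truth = generate_whales(small_env, cfg, grid)
        segs, sights = generate_surveys(truth, small_env, cfg, grid)
        flights = segs.groupby("survey_id").agg(
            seastate=("seastate", "first"), date=("date", "first"))
        _, f_ord = surveys.semimonth_key(flights["date"])
        exposures = truth.groups.groupby("semimonth").size()
        rates = {}
        for ss in (0, 3):
            fl = flights[flights["seastate"] == ss]
            expo = sum(exposures.get(sm, 0) for sm in f_ord[fl.index])
            dets = (sights["seastate"] == ss).sum()
            rates[ss] = dets / max(expo, 1)
        assert rates[3] < rates[0]
        assert len(sights) >= 2000

    def test_detected_distances_follow_halfnormal(self, processed):
        """KS test of pooled perpendicular distances within one platform x
        sea state stratum against the generating truncated half-normal."""
        cfg = processed["cfg"]
        sig = processed["sightings"]
        south = sig[sig["survey_id"].str.contains("_S_")
                    & ~sig["is_duplicate"] & ~sig["is_verification"]]
        sub = south[(south["platform"] == "Skymaster")
                    & (south["seastate"] == 1)]
        x = sub["perp_distance_km"].to_numpy()
        assert len(x) >= 300
        sigma = np.exp(cfg.detection.beta0["Skymaster"]
                       + cfg.detection.beta1 * 1)
        w = 5.56 / 2  # swath half-width for southern rows

        def cdf(t):
            num = stats.norm.cdf(t / sigma) - 0.5
            den = stats.norm.cdf(w / sigma) - 0.5
            return np.clip(num / den, 0, 1)

        p = stats.kstest(x, cdf).pvalue
        assert p > 0.01

    def test_injected_record_proportions_exact(self, sim_world):
        sig = sim_world["sightings"]
        n_base = (~sig["is_duplicate"] & ~sig["is_verification"]).sum()
        assert sig["is_duplicate"].sum() == round(0.05 * n_base)
        assert sig["is_verification"].sum() == round(0.03 * n_base)

    def test_invalid_truncation_rejected(self, small_env):
        cfg = dataclasses.replace(
            small_env.config,
            detection=dataclasses.replace(small_env.config.detection,
                                          truncation_km=-1.0))
        truth = generate_whales(small_env, cfg, small_grid())
        with pytest.raises(ValueError, match="truncation"):
            generate_surveys(truth, small_env, cfg, small_grid())
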