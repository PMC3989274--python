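"""Shared fixtures: one default synthetic-survey run and its processed stages.

The default SimConfig is the study condition every end-to-end check runs
under; building it once per session keeps the suite fast.
"""

import numpy as np
import pandas as pd
import pytest

from winterhab import detection, enviro, hurdle, simulate, surveys
from winterhab.config import PipelineConfig, SimConfig
from winterhab.gam import TermSpec

PRESENCE_TERMS = [
    TermSpec.tensor("semimonth", "northing"),
    TermSpec.smooth("dist_to_shore_km"),
    TermSpec.factor("year"),
    TermSpec.smooth("effort_km2"),
    TermSpec.smooth("sst_c"),
    TermSpec.smooth("depth_m"),
    TermSpec.smooth("dist_to_22iso_km"),
]
ABUNDANCE_TERMS = [
    TermSpec.tensor("semimonth", "northing"),
    TermSpec.factor("year"),
    TermSpec.smooth("sst_c"),
    TermSpec.smooth("dist_to_22iso_km"),
    TermSpec.smooth("dist_to_shore_km"),
    TermSpec.smooth("depth_m"),
]


@pytest.fixture(scope="session")
def sim_world():
    """Default simulated world: environment, truth, raw surveys."""
    cfg = SimConfig()
    grid = surveys.build_grid()
    env, truth, segments, sightings = simulate.simulate_all(cfg, grid)
    return {
        "cfg": cfg, "pcfg": PipelineConfig(), "grid": grid, "env": env,
        "truth": truth, "segments": segments, "sightings": sightings,
    }


@pytest.fixture(scope="session")
def processed(sim_world):
    """Filtered surveys, detection models, sampling units and covariates."""
    w = sim_world
    fseg, fsig, filt_report = surveys.filter_on_effort(
        w["segments"], w["sightings"], w["pcfg"]
    )
    models = {
        p: detection.fit_detection(fsig, platform=p)
        for p in ("Skymaster", "TwinOtter")
    }
    units, agg_report = surveys.aggregate(fseg, fsig, models, w["grid"],
                                          w["pcfg"])
    cov = enviro.covariate_table(
        w["env"].bathymetry, w["env"].shoreline,
        w["env"].composites(use_clouds=True), w["grid"], w["pcfg"],
    )
    table = hurdle.build_model_table(units, cov)
    return {
        **w, "fseg": fseg, "fsig": fsig, "filt_report": filt_report,
        "models": models, "units": units, "agg_report": agg_report,
        "cov": cov, "table": table, "usable": table[table["usable"]],
    }


@pytest.fixture(scope="session")
def fitted_hurdle(processed):
    """Hurdle model fit with the full candidate term set on the default run."""
    hm = hurdle.fit_hurdle(processed["usable"], PRESENCE_TERMS,
                           ABUNDANCE_TERMS)
    eref = float(processed["usable"]["effort_km2"].quantile(0.9))
    pred = hurdle.predict_map(hm, processed["table"], effort_ref=eref,
                              cfg=processed["pcfg"])
    return {"model": hm, "pred": pred, "effort_ref": eref}


@pytest.fixture()
def rng():
    return np.random.default_rng(20031201)


def make_segments(rows):
    """Small segment-table helper for constructed fixtures."""
    base = {
        "survey_id": "T", "date": "2009-12-10", "platform": "Skymaster",
        "x0": 0.0, "y0": 2.78, "x1": 5.0, "y1": 2.78, "seastate": 1,
        "altitude_m": 300.0, "visibility_km": 10.0, "status": "on_transect",
        "is_verification": False,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def make_sightings(rows):
    base = {
        "sighting_id": "S0", "survey_id": "T", "date": "2009-12-10",
        "x": 2.0, "y": 2.0, "group_size": 1, "calf_present": False,
        "perp_distance_km": 0.5, "platform": "Skymaster", "seastate": 1,
        "is_duplicate": False, "is_verification": False,
        "initial_status_on_effort": True,
    }
    return pd.DataFrame([{**base, **r} for r in rows])
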