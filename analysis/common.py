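"""Shared plumbing for the numbered analysis drivers.

Each driver regenerates the deterministic synthetic world from the run
configuration (cheap), reads any upstream tables it needs from the results
directory, and writes its own outputs there. Run the drivers in order:

    python analysis/01_simulate.py
    python analysis/02_fit_detection.py
    ...
"""

from __future__ import annotations

import argparse
import dataclasses
from pathlib import Path

from winterhab import simulate, surveys
from winterhab.config import PipelineConfig, SimConfig, load_sim_config
from winterhab.gam import TermSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"

PRESENCE_CANDIDATES = [
    TermSpec.tensor("semimonth", "northing"),
    TermSpec.smooth("dist_to_shore_km"),
    TermSpec.factor("year"),
    TermSpec.smooth("effort_km2"),
    TermSpec.smooth("sst_c"),
    TermSpec.smooth("depth_m"),
    TermSpec.smooth("dist_to_22iso_km"),
]
ABUNDANCE_CANDIDATES = [
    TermSpec.tensor("semimonth", "northing"),
    TermSpec.factor("year"),
    TermSpec.smooth("sst_c"),
    TermSpec.smooth("dist_to_22iso_km"),
    TermSpec.smooth("dist_to_shore_km"),
    TermSpec.smooth("depth_m"),
]


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=None,
                    help="override the simulation seed")
    ap.add_argument("--results", type=str, default=str(RESULTS))
    return ap.parse_args()


def load_world(args):
    """Rebuild the deterministic simulated world for this run."""
    results = Path(args.results)
    cfg_path = results / "data" / "sim_config.yaml"
    if cfg_path.exists():
        cfg = load_sim_config(str(cfg_path))
    else:
        cfg = SimConfig()
    if args.seed is not None:
        cfg = dataclasses.replace(cfg, seed=args.seed)
    pcfg = PipelineConfig()
    grid = surveys.build_grid()
    env, truth, segments, sightings = simulate.simulate_all(cfg, grid)
    return {
        "results": results, "cfg": cfg, "pcfg": pcfg, "grid": grid,
        "env": env, "truth": truth, "segments": segments,
        "sightings": sightings,
    }
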