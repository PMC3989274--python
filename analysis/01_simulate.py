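#!/usr/bin/env python
"""Generate the synthetic survey world and write its raw artifacts.

Writes the flight-segment and sighting tables, the bathymetry grid, the
shoreline, the latent truth per sampling unit, and the configurations used,
under results/data/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_world, parse_args

import dataclasses

from winterhab import io_utils
from winterhab.config import save_config


def main() -> None:
    args = parse_args(__doc__)
    w = load_world(args)
    out = w["results"] / "data"
    out.mkdir(parents=True, exist_ok=True)

    save_config(w["cfg"], str(out / "sim_config.yaml"))
    save_config(w["pcfg"], str(out / "pipeline_config.yaml"))
    io_utils.write_survey_tables(
        w["segments"], w["sightings"],
        str(out / "segments.csv"), str(out / "sightings.csv"),
    )
    io_utils.write_ascii_grid(w["env"].bathymetry, str(out / "bathymetry.asc"))
    io_utils.write_geojson(io_utils.shoreline_to_geojson(w["env"].shoreline),
                           str(out / "shoreline.geojson"))
    io_utils.write_geojson(w["grid"].to_geojson(), str(out / "grid.geojson"))
    w["truth"].units.to_csv(out / "truth_units.csv", index=False)
    (out / "truth_params.json").write_text(
        json.dumps(dataclasses.asdict(w["cfg"].true_effects), indent=2)
    )

    u = w["truth"].units
    print(f"Simulated {w['cfg'].n_seasons} seasons over {len(w['grid'])} "
          f"grid cells: {len(u)} cell-periods, latent occupancy "
          f"{u['p_occ'].mean():.3f}, {int(u['n_whales'].sum())} whales "
          f"realized, {len(w['segments'])} flight segments, "
          f"{len(w['sightings'])} sightings recorded.")
    print(f"Artifacts written to {out}")


if __name__ == "__main__":
    main()
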