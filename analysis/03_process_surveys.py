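#!/usr/bin/env python
"""Aggregate effort-corrected searched area and whale counts per unit.

Clips each on-effort segment to the composite grid, converts track length to
searched swath area with the platform/sea-state effective search widths
(minus the Skymaster blind spot), sums per cell x semimonth, counts whales
per unit, and flags effort outliers (> 340 km2).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import parse_args

from winterhab import detection, io_utils, surveys
from winterhab.config import PipelineConfig


def main() -> None:
    args = parse_args(__doc__)
    results = Path(args.results)
    data = results / "data"
    pcfg = PipelineConfig()
    grid = surveys.build_grid()
    segments, sightings, _ = io_utils.read_survey_tables(
        str(data / "segments.csv"), str(data / "sightings.csv"))
    fseg, fsig, _ = surveys.filter_on_effort(segments, sightings, pcfg)
    models = {
        p: detection.DetectionModel.from_json(
            (results / f"detection_{p}.json").read_text())
        for p in ("Skymaster", "TwinOtter")
    }
    units, report = surveys.aggregate(fseg, fsig, models, grid, pcfg)
    units.to_csv(results / "sampling_units.csv", index=False)
    surveyed = units[units["effort_km2"] > 0]
    print(f"{len(units)} sampling units ({len(surveyed)} surveyed); total "
          f"effort {report['total_effort_km2']:.0f} km2, "
          f"{report['total_whales']} whales in "
          f"{int(units['sightings'].sum())} sightings; "
          f"{report['units_excluded_effort']} effort outliers flagged.")


if __name__ == "__main__":
    main()
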