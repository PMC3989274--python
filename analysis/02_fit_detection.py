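#!/usr/bin/env python
"""Filter surveys to on-effort records and fit the detection functions.

Reads the raw segment/sighting tables, applies the on-effort rules
(sea state <= 3, altitude <= 365 m, visibility >= 3.7 km, on a track line;
no verification or duplicate records), fits the covariate half-normal
detection function per platform, and writes the fitted models with their
effective-search-width tables.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import parse_args

from winterhab import detection, io_utils, surveys
from winterhab.config import PipelineConfig


def main() -> None:
    args = parse_args(__doc__)
    data = Path(args.results) / "data"
    pcfg = PipelineConfig()
    segments, sightings, read_report = io_utils.read_survey_tables(
        str(data / "segments.csv"), str(data / "sightings.csv"))
    fseg, fsig, filt = surveys.filter_on_effort(segments, sightings, pcfg)

    models = {}
    for platform in ("Skymaster", "TwinOtter"):
        m = detection.fit_detection(fsig, platform=platform)
        models[platform] = m
        (data.parent / f"detection_{platform}.json").write_text(m.to_json())
        esw = ", ".join(f"ss{s}={v:.2f}" for s, v in m.esw_table.items())
        print(f"{platform}: beta0={m.beta0:.3f} beta1={m.beta1:.3f} "
              f"W={m.truncation_km:.2f} km, n={m.n_obs}; ESW km: {esw}")

    io_utils.write_report(
        {"read": read_report, "filter": filt},
        str(data.parent / "filter_report.json"),
        str(data.parent / "filter_report.txt"),
    )
    print(f"Kept {filt['segments_kept']}/{filt['segments_in']} segments and "
          f"{filt['sightings_kept']}/{filt['sightings_in']} sightings "
          f"on-effort; reports written.")


if __name__ == "__main__":
    main()
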