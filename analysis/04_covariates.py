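#!/usr/bin/env python
"""Derive environmental covariates for every cell x semimonth.

Computes mean depth and slope, distance to shore, cloud-masked semimonthly
SST composites, and signed distance to the 22 degC isotherm; flags units
with invalid depth or missing SST.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_world, parse_args

from winterhab import enviro


def main() -> None:
    args = parse_args(__doc__)
    w = load_world(args)
    cov = enviro.covariate_table(
        w["env"].bathymetry, w["env"].shoreline,
        w["env"].composites(use_clouds=True), w["grid"], w["pcfg"],
    )
    out = w["results"] / "covariates.csv"
    cov.to_csv(out, index=False)
    reasons = cov.loc[~cov["covariates_ok"], "exclude_reason"].value_counts()
    print(f"Covariates for {len(cov)} cell-periods; "
          f"{int(cov['covariates_ok'].sum())} complete. Exclusions: "
          f"{reasons.to_dict() or 'none'}.")
    print(f"Written to {out}")


if __name__ == "__main__":
    main()
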