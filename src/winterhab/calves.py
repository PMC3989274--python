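"""Demographic segregation of cow-calf pairs.

Compares environmental conditions at exact sighting locations (sampled from
the native-resolution layers, not the sampling grid) between sightings with
and without a calf: Mann-Whitney tests per variable, and per-semimonth
comparisons of UTM northing with Holm's sequential Bonferroni correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from winterhab import enviro
from winterhab.config import PipelineConfig
from winterhab.surveys import semimonth_key

_EXACT_MAX_N = 12


# ---------------------------------------------------------------------------
# Environment at sighting locations
# ---------------------------------------------------------------------------

def extract_sighting_env(
    sightings: pd.DataFrame,
    env,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Point-sample environmental layers at each sighting location.

    Depth comes from the native bathymetry pixel; SST from the daily image of
    the sighting date, only where that day's pixel is cloud-free (records
    with clouded SST keep their other variables); isotherm distance from the
    sighting's semimonthly composite. Records with depth above sea level are
    excluded, as are sightings outside all layers.

    ``env`` is a :class:`winterhab.simulate.Environment` (or any object with
    the same bathymetry/shoreline/daily-SST attributes).
    """
    cfg = cfg or PipelineConfig()
    season, ordinal = semimonth_key(sightings["date"])
    iso_contours: dict[tuple, object] = {}
    rows = []
    dropped_outside = 0
    dropped_land = 0
    for i, s in sightings.reset_index(drop=True).iterrows():
        x, y = float(s["x"]), float(s["y"])
        depth = env.bathymetry.sample(x, y)
        if not np.isfinite(depth):
            dropped_outside += 1
            continue
        if depth <= 0:
            dropped_land += 1
            continue
        seas, sm = season.iloc[i], int(ordinal.iloc[i])
        date = pd.Timestamp(s["date"]).date()
        day_idx = env.days[seas].index(date)
        r = env.template
        jx = int(np.floor((x - r.x0) / r.pixel_km))
        iy = int(np.floor((y - r.y0) / r.pixel_km))
        sst = np.nan
        if 0 <= iy < r.ny and 0 <= jx < r.nx:
            if not env.clouds[seas][day_idx, iy, jx]:
                sst = float(env.sst[seas][day_idx, iy, jx])
        key = (seas, sm)
        if key not in iso_contours:
            comp = env.composite(seas, sm, use_clouds=True)
            iso_contours[key] = (comp, enviro.isotherm_contours(
                comp, cfg.isotherm_c))
        comp, contours = iso_contours[key]
        if contours is None:
            diso = np.nan
        else:
            from shapely.geometry import Point
            dist = float(Point(x, y).distance(contours))
            pix = comp.raster.sample(x, y)
            if not np.isfinite(pix):
                diso = np.nan
            else:
                diso = -dist if pix > cfg.isotherm_c else dist
        rows.append({
            "sighting_id": s["sighting_id"],
            "calf_present": bool(s["calf_present"]),
            "depth_m": depth,
            "dist_to_shore_km": enviro.distance_to_shore(x, y, env.shoreline),
            "sst_c": sst,
            "dist_to_22iso_km": diso,
            "northing": y,
            "season": seas,
            "semimonth": sm,
        })
    report = {
        "n_in": int(len(sightings)),
        "n_out": len(rows),
        "dropped_outside_layers": dropped_outside,
        "dropped_above_sea_level": dropped_land,
    }
    return pd.DataFrame(rows), report


# ---------------------------------------------------------------------------
# Mann-Whitney test
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    variable: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    range1: tuple[float, float]
    range2: tuple[float, float]
    U: float
    z_score: float
    p_value: float
    method: str  # "exact" | "normal"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[: len(a)].sum())
    return r1 - len(a) * (len(a) + 1) / 2.0


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by enumerating all group assignments of the pooled
    values; as extreme = |U - n1 n2 / 2| at least as large as observed."""
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(pooled)
    ranks = rankdata(pooled)
    mid = n1 * (n - n1) / 2.0
    obs_dev = abs(u_obs - mid) - 1e-12
    count = 0
    total = 0
    base = n1 * (n1 + 1) / 2.0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - base
        total += 1
        if abs(u - mid) >= obs_dev:
            count += 1
    return count / total


def mann_whitney(
    a,
    b,
    variable: str = "",
    continuity: bool = True,
    tie_correction: bool = True,
    force_normal: bool = False,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses midranks for ties; for n1 + n2 <= 12 the p-value is computed by
    exact enumeration over all group assignments, otherwise by the normal
    approximation with tie-corrected variance and (by default) continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    u = _u_statistic(a, b)
    mean_u = n1 * n2 / 2.0

    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    if tie_correction:
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    else:
        var_u = n1 * n2 * (n + 1) / 12.0

    if var_u <= 0:  # all pooled values identical
        return TestResult(variable, n1, n2, float(a.mean()), float(b.mean()),
                          (a.min(), a.max()), (b.min(), b.max()),
                          u, 0.0, 1.0, "degenerate")

    dev = u - mean_u
    cc = 0.5 if continuity and dev != 0 else 0.0
    z = (dev - np.sign(dev) * cc) / np.sqrt(var_u)
    from scipy.stats import norm
    p_norm = float(2.0 * norm.sf(abs(z)))
    p_norm = min(p_norm, 1.0)

    if n <= _EXACT_MAX_N and not force_normal:
        p = _exact_two_sided_p(a, b, u)
        method = "exact"
    else:
        p = p_norm
        method = "normal"
    return TestResult(
        variable, n1, n2, float(a.mean()), float(b.mean()),
        (float(a.min()), float(a.max())), (float(b.min()), float(b.max())),
        float(u), float(z), float(max(p, np.finfo(float).tiny)), method,
    )


def environment_comparison(records: pd.DataFrame) -> pd.DataFrame:
    """Calf-present vs calf-absent comparison for each environmental variable
    (the summary-table shape: means, ranges, z, p)."""
    rows = []
    for var in ("depth_m", "dist_to_shore_km", "sst_c", "dist_to_22iso_km"):
        sub = records[np.isfinite(records[var])]
        a = sub.loc[sub["calf_present"], var].to_numpy()
        b = sub.loc[~sub["calf_present"], var].to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        res = mann_whitney(a, b, variable=var)
        rows.append({
            "variable": var,
            "n_calf": res.n1, "n_nocalf": res.n2,
            "mean_calf": res.mean1, "mean_nocalf": res.mean2,
            "min_calf": res.range1[0], "max_calf": res.range1[1],
            "min_nocalf": res.range2[0], "max_nocalf": res.range2[1],
            "z_score": res.z_score, "p_value": res.p_value,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequential Bonferroni (Holm) over semimonthly northing comparisons
# ---------------------------------------------------------------------------

def holm_decisions(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down: order p ascending, compare p_(i) to alpha/(m-i+1),
    stop at the first failure; everything before it is rejected."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


def semimonth_northing_comparisons(
    records: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Calf vs no-calf northing comparison in each semimonthly period.

    One Mann-Whitney per semimonth (periods lacking either group are skipped
    and reported), with Holm's sequential Bonferroni over the tested family.
    """
    rows = []
    for sm in range(1, 9):
        sub = records[records["semimonth"] == sm]
        a = sub.loc[sub["calf_present"], "northing"].to_numpy()
        b = sub.loc[~sub["calf_present"], "northing"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            rows.append({"semimonth": sm, "tested": False, "n_calf": len(a),
                         "n_nocalf": len(b), "U": np.nan, "z_score": np.nan,
                         "p_value": np.nan})
            continue
        res = mann_whitney(a, b, variable="northing")
        rows.append({
            "semimonth": sm, "tested": True, "n_calf": res.n1,
            "n_nocalf": res.n2, "mean_calf": res.mean1,
            "mean_nocalf": res.mean2, "U": res.U, "z_score": res.z_score,
            "p_value": res.p_value,
        })
    out = pd.DataFrame(rows)
    tested = out["tested"].to_numpy(dtype=bool)
    decisions = np.zeros(len(out), dtype=bool)
    if tested.any():
        decisions[tested] = holm_decisions(
            out.loc[tested, "p_value"].to_numpy(), alpha
        )
    out["holm_reject"] = decisions
    return out
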