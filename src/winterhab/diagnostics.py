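"""Residual diagnostics for the hurdle habitat model.

Deviance residuals compare observed whale counts with predicted relative
abundance; global Moran's I with inverse-distance weights over all grid cells
screens each semimonthly period's residuals for spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Composite hurdle deviance residuals
# ---------------------------------------------------------------------------

def hurdle_deviance_residuals(pred: pd.DataFrame, observed: pd.DataFrame
                              ) -> tuple[pd.DataFrame, dict]:
    """Signed square-root deviance of observed counts vs predicted relative
    abundance.

    Composite definition: positive counts y use the gamma deviance form
    d = 2[-log(y/r) + (y - r)/r] against the relative-abundance prediction r;
    zero counts use the presence component's binomial contribution
    d = -2 log(1 - p). The sign is that of (y - r), so units with predicted
    abundance but no whales get negative residuals. Masked units are skipped.

    ``observed`` needs cell_id, season, semimonth, whales; ``pred`` is a
    :func:`winterhab.hurdle.predict_map` table.
    """
    df = pred.merge(
        observed[["cell_id", "season", "semimonth", "whales"]],
        on=["cell_id", "season", "semimonth"], how="inner",
    )
    skipped = int(df["masked"].sum())
    df = df[~df["masked"]].copy()
    y = df["whales"].to_numpy(float)
    r = df["rel_abundance"].to_numpy(float)
    p = np.clip(df["p_presence"].to_numpy(float), 1e-12, 1 - 1e-12)
    r = np.clip(r, 1e-12, None)
    d = np.empty(len(df))
    pos = y > 0
    d[pos] = 2.0 * (-np.log(y[pos] / r[pos]) + (y[pos] - r[pos]) / r[pos])
    d[~pos] = -2.0 * np.log(1.0 - p[~pos])
    resid = np.sign(y - r) * np.sqrt(np.maximum(d, 0.0))
    df["dev_residual"] = resid

    zero = df[~pos]
    nonzero = df[pos]
    summary = {
        "n": int(len(df)),
        "n_skipped_masked": skipped,
        "mean_residual": float(resid.mean()) if len(df) else float("nan"),
        "se_residual": float(resid.std(ddof=1) / np.sqrt(len(df)))
        if len(df) > 1 else float("nan"),
        "mean_obs_minus_pred_absent": float(
            (zero["whales"] - zero["rel_abundance"]).mean()
        ) if len(zero) else float("nan"),
        "mean_obs_minus_pred_present": float(
            (nonzero["whales"] - nonzero["rel_abundance"]).mean()
        ) if len(nonzero) else float("nan"),
    }
    return df, summary


# ---------------------------------------------------------------------------
# Global Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    I: float
    n: int
    expected: float
    z_score: float
    weight_scheme: str
    degenerate: bool = False
    semimonth: int | None = None
    season: str | None = None


def morans_i(
    values: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    row_standardize: bool = False,
) -> MoranResult:
    """Global Moran's I with inverse-distance weights over all cell pairs.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with w_ij = 1/d_ij
    (w_ii = 0), z the centred values. The z-score uses the expectation
    -1/(n-1) and variance under the normality assumption. With
    ``row_standardize`` each row of the weight matrix is scaled to sum to 1
    (the variant whose I is confined to roughly [-1, 1]; the unstandardized
    statistic may exceed those bounds slightly).
    """
    v = np.asarray(values, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 cells")
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    d = np.hypot(dx, dy)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident cell centers (zero distance)")
    w = np.zeros((n, n))
    w[off] = 1.0 / d[off]
    scheme = "inverse_distance"
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
        scheme = "inverse_distance_row_std"

    z = v - v.mean()
    denom = float(np.sum(z * z))
    expected = -1.0 / (n - 1)
    if denom == 0.0:
        return MoranResult(float("nan"), n, expected, float("nan"), scheme,
                           degenerate=True)
    s0 = float(w.sum())
    I = float(n / s0 * (z @ w @ z) / denom)

    s1 = 0.5 * float(np.sum((w + w.T) ** 2))
    s2 = float(np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2))
    var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / (
        s0 * s0 * (n * n - 1.0)
    ) - expected ** 2
    z_score = (I - expected) / np.sqrt(var) if var > 0 else float("nan")
    return MoranResult(I, n, expected, float(z_score), scheme)


def moran_by_semimonth(
    residuals: pd.DataFrame,
    value_col: str = "dev_residual",
    row_standardize: bool = False,
) -> pd.DataFrame:
    """Moran's I of residuals for each season x semimonth separately.

    Periods with fewer than 3 cells or zero residual variance are reported as
    degenerate.
    """
    rows = []
    for (season, sm), g in residuals.groupby(["season", "semimonth"]):
        if len(g) < 3:
            rows.append({"season": season, "semimonth": sm, "I": np.nan,
                         "n": len(g), "z_score": np.nan, "degenerate": True})
            continue
        res = morans_i(
            g[value_col].to_numpy(), g["easting"].to_numpy(),
            g["northing"].to_numpy(), row_standardize,
        )
        rows.append({
            "season": season, "semimonth": sm, "I": res.I, "n": res.n,
            "expected": res.expected, "z_score": res.z_score,
            "degenerate": res.degenerate,
        })
    return pd.DataFrame(rows)
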