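"""Hurdle habitat model: stepwise term selection and relative-abundance maps.

The hurdle model pairs a quasibinomial-logit GAM for whale presence-absence
(fit to all sampling units) with a gamma-log GAM for the number of whales in
units where whales were sighted. Predicted relative abundance is the product
of the occurrence probability and the conditional expected count, mapped at a
constant reference survey effort so that variable effort does not confound
the spatial pattern.

Terms are chosen by forward stepwise selection: starting from the null model,
each remaining candidate is added singly and the addition with the lowest GCV
advances, accepted only if an analysis-of-deviance F-test against the
previous step improves the model, the GCV decreases, and the fitted partial
effect's +-2 SE band is not zero everywhere. Candidate models are compared
out-of-sample by the mean average squared prediction error (ASPE) over five
random 80/20 train/validation splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from winterhab import gam
from winterhab.config import PipelineConfig
from winterhab.gam import GAMFit, TermSpec


def build_model_table(units: pd.DataFrame, covariates: pd.DataFrame
                      ) -> pd.DataFrame:
    """Join sampling units with covariates and mark usable training rows.

    A row is usable when it was surveyed (effort > 0), not an effort outlier,
    and has complete covariates (valid depth, non-missing SST/isotherm).
    """
    df = units.rename(columns={"exclude_reason": "unit_exclude_reason"}).merge(
        covariates.drop(columns=["easting", "northing"], errors="ignore"),
        on=["cell_id", "season", "semimonth"], how="left",
    )
    df["presence"] = (df["whales"] > 0).astype(float)
    df["year"] = df["season"]
    cov_reason = df["exclude_reason"].fillna("no_covariates")
    df["exclude_reason"] = np.where(
        df["unit_exclude_reason"].fillna("") != "",
        df["unit_exclude_reason"], cov_reason,
    )
    df = df.drop(columns=["unit_exclude_reason"])
    df["usable"] = (
        (df["effort_km2"] > 0)
        & ~df["excluded"].astype(bool)
        & df["covariates_ok"].fillna(False).astype(bool)
    )
    return df


# ---------------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    step: int
    term: str
    percent_deviance: float
    gcv: float
    mean_aspe: float
    f_stat: float
    p_value: float
    accepted: bool
    edf: float = float("nan")


def _zero_band_everywhere(fit_: GAMFit, term: TermSpec, df: pd.DataFrame
                          ) -> bool:
    """True when the +-2 SE band of the fitted partial effect contains zero
    at every observed covariate value (the term shows no effect anywhere)."""
    if term.kind == "factor":
        return False
    effect, se = gam.partial_effect(fit_, term.name, df)
    return bool(np.all(np.abs(effect) <= 2.0 * se))


def anova_f(prev: GAMFit, new: GAMFit) -> tuple[float, float]:
    """Analysis-of-deviance F-test between nested fits (scale from the
    larger model)."""
    d_edf = new.edf_total - prev.edf_total
    d_dev = prev.deviance - new.deviance
    if d_edf <= 1e-8 or new.scale <= 0:
        return float("nan"), 1.0
    f = (d_dev / d_edf) / new.scale
    df2 = max(new.n - new.edf_total, 1.0)
    p = float(stats.f.sf(max(f, 0.0), d_edf, df2))
    return float(f), p


def stepwise_select(
    df: pd.DataFrame,
    candidates: list[TermSpec],
    family: str,
    response: str,
    alpha: float = 0.05,
    compute_aspe: bool = True,
    cv_seed: int = 0,
    cfg: PipelineConfig | None = None,
    n_restarts: int = 2,
) -> tuple[list[StepRecord], list[TermSpec]]:
    """Forward stepwise term selection by GCV / analysis of deviance.

    Ties in GCV are broken by fewer effective degrees of freedom, then by
    candidate order.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate terms")
    cfg = cfg or PipelineConfig()
    current: list[TermSpec] = []
    remaining = list(candidates)
    prev_fit = gam.fit(df, response, [], family=family)
    records: list[StepRecord] = []
    step = 0
    while remaining:
        step += 1
        trials = []
        for spec in remaining:
            try:
                f = gam.fit(df, response, current + [spec], family=family,
                            n_restarts=n_restarts)
            except gam.GAMError:
                continue
            trials.append((spec, f))
        if not trials:
            break
        trials.sort(
            key=lambda t: (round(t[1].gcv, 12), round(t[1].edf_total, 6),
                           candidates.index(t[0]))
        )
        spec, best = trials[0]
        f_stat, p_val = anova_f(prev_fit, best)
        accepted = (
            best.gcv < prev_fit.gcv
            and p_val < alpha
            and not _zero_band_everywhere(best, spec, df)
        )
        aspe = float("nan")
        if compute_aspe and accepted:
            aspe, _ = cross_validate_aspe(
                df, current + [spec], family, response,
                repeats=cfg.cv_repeats, train_fraction=cfg.cv_train_fraction,
                seed=cv_seed, n_restarts=n_restarts,
            )
        records.append(StepRecord(
            step=step, term=spec.name,
            percent_deviance=best.percent_deviance, gcv=best.gcv,
            mean_aspe=aspe, f_stat=f_stat, p_value=p_val, accepted=accepted,
            edf=best.edf_total,
        ))
        if not accepted:
            break
        current.append(spec)
        remaining.remove(spec)
        prev_fit = best
    return records, current


def cross_validate_aspe(
    df: pd.DataFrame,
    terms: list[TermSpec],
    family: str,
    response: str,
    repeats: int = 5,
    train_fraction: float = 0.8,
    seed: int = 0,
    n_restarts: int = 2,
) -> tuple[float, int]:
    """Mean average squared prediction error over random train/test splits.

    Each repeat refits on a random 80% of rows and scores the held-out 20% on
    the response scale (probability vs 0/1 for the presence component, counts
    for the abundance component). Validation rows with a factor level unseen
    in training are dropped; their total count is returned alongside.
    """
    rng = np.random.default_rng(seed)
    n = len(df)
    aspes = []
    dropped = 0
    for _ in range(repeats):
        idx = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        tr = df.iloc[idx[:n_train]]
        va = df.iloc[idx[n_train:]]
        fit_ = gam.fit(tr, response, terms, family=family,
                       n_restarts=n_restarts)
        pred = gam.predict(fit_, va, exclude_out_of_range=False)
        # drop unseen factor levels (out-of-range numeric rows are kept:
        # spline evaluation extrapolates linearly for scoring purposes)
        keep = np.ones(len(va), dtype=bool)
        for t in fit_.terms:
            if t.levels is not None:
                keep &= va[t.spec.covariates[0]].isin(t.levels).to_numpy()
        dropped += int((~keep).sum())
        y = va[response].to_numpy(float)[keep]
        aspes.append(float(np.mean((y - pred.response[keep]) ** 2)))
    return float(np.mean(aspes)), dropped


# ---------------------------------------------------------------------------
# Hurdle fit and prediction
# ---------------------------------------------------------------------------

@dataclass
class HurdleModel:
    """Paired occurrence and positive-abundance fits."""

    presence: GAMFit
    abundance: GAMFit
    presence_terms: list[TermSpec]
    abundance_terms: list[TermSpec]
    n_positive: int
    effort_covariate: str = "effort_km2"

    def presence_uses_effort(self) -> bool:
        return any(
            self.effort_covariate in t.spec.covariates
            for t in self.presence.terms
        )


def fit_hurdle(
    df: pd.DataFrame,
    presence_terms: list[TermSpec],
    abundance_terms: list[TermSpec],
    min_positive: int = 30,
    n_restarts: int = 3,
) -> HurdleModel:
    """Fit the two hurdle components.

    The presence component models 1{whales > 0} over all usable units with a
    quasibinomial-logit GAM; the abundance component models the whale count
    over units with whales present with a gamma-log GAM.
    """
    pres = df
    pos = df[df["whales"] > 0]
    if len(pos) < min_positive:
        raise ValueError(f"only {len(pos)} positive units (need >= {min_positive})")
    if pres["presence"].nunique() < 2:
        raise ValueError("degenerate presence response (all equal)")
    if pos["whales"].nunique() < 2:
        raise ValueError("degenerate abundance response: all positive counts equal")
    presence_fit = gam.fit(pres, "presence", presence_terms,
                           family="quasibinomial", n_restarts=n_restarts)
    pos = pos.assign(whales_f=pos["whales"].astype(float))
    abundance_fit = gam.fit(pos, "whales_f", abundance_terms, family="gamma",
                            n_restarts=n_restarts)
    return HurdleModel(presence_fit, abundance_fit, presence_terms,
                       abundance_terms, n_positive=len(pos))


def predict_map(
    hurdle: HurdleModel,
    newdata: pd.DataFrame,
    effort_ref: float | None = None,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Constant-effort relative-abundance hindcast for cells x semimonths.

    Survey effort is overridden to ``effort_ref`` everywhere (it must lie
    within the presence model's training range). Relative abundance is
    p * E[N | presence]; its standard error uses the delta method under
    component independence: Var ~= p^2 Var(E) + E^2 Var(p). Rows with
    out-of-training-range covariates, unseen years or missing covariates are
    masked with a reason.
    """
    cfg = cfg or PipelineConfig()
    effort_ref = cfg.effort_ref_km2 if effort_ref is None else effort_ref
    df = newdata.copy()
    if hurdle.presence_uses_effort():
        rng_ = hurdle.presence.covariate_ranges().get(hurdle.effort_covariate)
        if rng_ is not None and not (rng_[0] <= effort_ref <= rng_[1]):
            raise ValueError(
                f"effort_ref {effort_ref} outside presence training range {rng_}"
            )
        df[hurdle.effort_covariate] = effort_ref

    pred_p = gam.predict(hurdle.presence, df, exclude_out_of_range=True)
    pred_e = gam.predict(hurdle.abundance, df, exclude_out_of_range=True)

    mask = pred_p.mask & pred_e.mask
    reasons = [
        pr if pr else er
        for pr, er in zip(pred_p.mask_reason, pred_e.mask_reason)
    ]
    if "covariates_ok" in df.columns:
        bad = ~df["covariates_ok"].fillna(False).astype(bool).to_numpy()
        for i in np.nonzero(bad)[0]:
            if mask[i]:
                reasons[i] = str(df["exclude_reason"].iloc[i]) or "missing_covariate"
            mask[i] = False
    if "excluded" in df.columns:
        bad = df["excluded"].astype(bool).to_numpy()
        for i in np.nonzero(bad)[0]:
            if mask[i]:
                reasons[i] = str(df["exclude_reason"].iloc[i]) or "excluded_unit"
            mask[i] = False

    p = pred_p.response
    e = pred_e.response
    ra = p * e
    var_ra = (p * pred_e.se_response) ** 2 + (e * pred_p.se_response) ** 2
    out = df[[c for c in ("cell_id", "season", "semimonth", "easting",
                          "northing") if c in df.columns]].copy()
    out["p_presence"] = np.where(mask, p, np.nan)
    out["se_p"] = np.where(mask, pred_p.se_response, np.nan)
    out["expected_n"] = np.where(mask, e, np.nan)
    out["se_n"] = np.where(mask, pred_e.se_response, np.nan)
    out["rel_abundance"] = np.where(mask, ra, np.nan)
    out["se_rel_abundance"] = np.where(mask, np.sqrt(var_ra), np.nan)
    out["masked"] = ~mask
    out["mask_reason"] = reasons
    return out


def abundance_centroid(pred: pd.DataFrame, by: str = "season") -> pd.Series:
    """Relative-abundance-weighted mean northing per group (km)."""
    ok = pred[~pred["masked"]]
    def _cent(g: pd.DataFrame) -> float:
        w = g["rel_abundance"].to_numpy()
        if w.sum() <= 0:
            return float("nan")
        return float(np.average(g["northing"].to_numpy(), weights=w))
    return ok.groupby(by).apply(_cent, include_groups=False)


def vif_report(df: pd.DataFrame, covariates: list[str]) -> pd.Series:
    """Variance inflation factors of the candidate predictors (screening
    report only; exclusion is a configuration choice, not automatic)."""
    sub = df[covariates].dropna()
    X = (sub - sub.mean()) / sub.std(ddof=0)
    out = {}
    for i, c in enumerate(covariates):
        others = [cc for cc in covariates if cc != c]
        A = np.column_stack([np.ones(len(X))] + [X[o].to_numpy() for o in others])
        yv = X[c].to_numpy()
        beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
        resid = yv - A @ beta
        r2 = 1.0 - resid.var() / yv.var()
        out[c] = float(1.0 / max(1.0 - r2, 1e-12))
    return pd.Series(out, name="VIF")
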