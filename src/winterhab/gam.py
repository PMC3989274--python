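"""Penalized regression-spline GAM engine.

Fits generalized additive models by penalized IRLS with smoothing parameters
chosen to minimize the GCV score n * D / (n - edf)^2, the criterion used to
select the habitat models. Smooth terms are natural cubic regression splines
with knots at covariate quantiles and basis dimension k = 3 (so each smooth
contributes at most 2 effective degrees of freedom), optionally with
*shrinkage*: the penalty's null-space eigenvalue is replaced by a small
positive value so that lambda -> infinity shrinks the whole term to zero and
its edf to 0, letting the smoothing selection remove uninformative terms.
The semimonth x northing interaction is a tensor product of two marginal k = 3
bases with one penalty per margin. Factor terms (survey year) enter
unpenalized.

Supported families: gaussian (identity), quasibinomial (logit) and gamma
(log); the quasi families estimate the scale phi from Pearson residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

_SHRINK_EPS = 1e-2   # null-space eigenvalue, relative to the largest
_RANK_TOL = 1e-10


# ---------------------------------------------------------------------------
# Cubic regression spline basis
# ---------------------------------------------------------------------------

class CubicSplineBasis:
    """Natural cubic regression spline parameterized by its values at knots.

    The spline interpolates coefficient values beta_j at knots xi_j with
    natural (zero second derivative) end conditions; the penalty
    beta' S beta equals the integrated squared second derivative, whose null
    space is the straight lines. Evaluation outside the knot range is linear
    extrapolation.
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if len(knots) < 3 or np.any(np.diff(knots) <= 0):
            raise ValueError("need >= 3 strictly increasing knots")
        self.knots = knots
        k = len(knots)
        h = np.diff(knots)
        D = np.zeros((k - 2, k))
        for i in range(k - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
        B = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        Binv_D = np.linalg.solve(B, D)
        self.F = np.vstack([np.zeros(k), Binv_D, np.zeros(k)])  # values -> f''
        self.S = D.T @ Binv_D
        self._h = h

    @property
    def k(self) -> int:
        return len(self.knots)

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        kn, F, h = self.knots, self.F, self._h
        k = self.k
        X = np.zeros((len(x), k))
        j = np.clip(np.searchsorted(kn, x, side="right") - 1, 0, k - 2)
        lo, hi = x < kn[0], x > kn[-1]
        mid = ~(lo | hi)
        if mid.any():
            jm = j[mid]
            xm = x[mid]
            hj = h[jm]
            am = (kn[jm + 1] - xm) / hj
            ap = (xm - kn[jm]) / hj
            cm = ((kn[jm + 1] - xm) ** 3 / hj - hj * (kn[jm + 1] - xm)) / 6.0
            cp = ((xm - kn[jm]) ** 3 / hj - hj * (xm - kn[jm])) / 6.0
            rows = np.zeros((mid.sum(), k))
            rows[np.arange(len(jm)), jm] += am
            rows[np.arange(len(jm)), jm + 1] += ap
            rows += cm[:, None] * F[jm] + cp[:, None] * F[jm + 1]
            X[mid] = rows
        if lo.any():
            e0 = np.zeros(k); e0[0] = 1.0
            e1 = np.zeros(k); e1[1] = 1.0
            slope = (e1 - e0) / h[0] - (h[0] / 6.0) * F[1]
            X[lo] = e0 + (x[lo] - kn[0])[:, None] * slope
        if hi.any():
            em1 = np.zeros(k); em1[-1] = 1.0
            em2 = np.zeros(k); em2[-2] = 1.0
            slope = (em1 - em2) / h[-1] + (h[-1] / 6.0) * F[-2]
            X[hi] = em1 + (x[hi] - kn[-1])[:, None] * slope
        return X


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    ux = np.unique(x[np.isfinite(x)])
    if len(ux) < k:
        raise ValueError(
            f"degenerate covariate: {len(ux)} distinct values for k={k} knots"
        )
    kn = np.quantile(ux, np.linspace(0.0, 1.0, k))
    if np.any(np.diff(kn) <= 0):  # heavy ties; fall back to spread values
        kn = ux[np.linspace(0, len(ux) - 1, k).round().astype(int)].astype(float)
    return kn


def _shrinkage_penalty(S: np.ndarray) -> np.ndarray:
    """Replace null-space eigenvalues by a small positive fraction of the
    largest, so infinite smoothing drives the whole term to zero."""
    w, U = np.linalg.eigh(S)
    wmax = float(w.max())
    if wmax <= 0:
        return np.eye(S.shape[0]) * _SHRINK_EPS
    w = np.where(w < _RANK_TOL * wmax, _SHRINK_EPS * wmax, w)
    return (U * w) @ U.T


# ---------------------------------------------------------------------------
# Model terms
# ---------------------------------------------------------------------------

@dataclass
class TermSpec:
    """Declarative model term: a 1-D smooth, a tensor smooth or a factor."""

    name: str
    covariates: tuple[str, ...]
    kind: str = "smooth"          # smooth | tensor | factor
    k: int = 3
    shrinkage: bool = True

    @staticmethod
    def smooth(cov: str, k: int = 3, shrinkage: bool = True) -> "TermSpec":
        return TermSpec(f"s({cov})", (cov,), "smooth", k, shrinkage)

    @staticmethod
    def tensor(cov1: str, cov2: str, k: int = 3, shrinkage: bool = True
               ) -> "TermSpec":
        return TermSpec(f"te({cov1},{cov2})", (cov1, cov2), "tensor", k,
                        shrinkage)

    @staticmethod
    def factor(cov: str) -> "TermSpec":
        return TermSpec(f"factor({cov})", (cov,), "factor")


class _BuiltTerm:
    """A term with its trained basis, constraint transform and penalties."""

    def __init__(self, spec: TermSpec, df: pd.DataFrame):
        self.spec = spec
        self.name = spec.name
        self.levels: list | None = None
        self.ranges: dict[str, tuple[float, float]] = {}
        if spec.kind == "factor":
            vals = df[spec.covariates[0]]
            self.levels = sorted(pd.unique(vals))
            # a single observed level is absorbed by the intercept
            self.n_cols = max(len(self.levels) - 1, 0)
            self.penalties: list[np.ndarray] = []
            return
        for cov in spec.covariates:
            x = df[cov].to_numpy(dtype=float)
            self.ranges[cov] = (float(np.nanmin(x)), float(np.nanmax(x)))
        if spec.kind == "smooth":
            x = df[spec.covariates[0]].to_numpy(dtype=float)
            self.basis = CubicSplineBasis(_quantile_knots(x, spec.k))
            Xraw = self.basis.design(x)
            S = [self.basis.S]
        elif spec.kind == "tensor":
            x1 = df[spec.covariates[0]].to_numpy(dtype=float)
            x2 = df[spec.covariates[1]].to_numpy(dtype=float)
            self.basis1 = CubicSplineBasis(_quantile_knots(x1, spec.k))
            self.basis2 = CubicSplineBasis(_quantile_knots(x2, spec.k))
            X1, X2 = self.basis1.design(x1), self.basis2.design(x2)
            Xraw = _row_kron(X1, X2)
            k1, k2 = self.basis1.k, self.basis2.k
            S = [
                np.kron(self.basis1.S, np.eye(k2)),
                np.kron(np.eye(k1), self.basis2.S),
            ]
        else:
            raise ValueError(f"unknown term kind {spec.kind}")
        # sum-to-zero constraint over the training rows
        cmean = Xraw.mean(axis=0, keepdims=True)
        self.Z = linalg.null_space(cmean)
        self.n_cols = self.Z.shape[1]
        pen = [self.Z.T @ s @ self.Z for s in S]
        if spec.shrinkage:
            pen = [_shrinkage_penalty(s) for s in pen]
        self.penalties = pen

    def design(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list]:
        """Design columns, row mask of evaluable rows, and mask reasons."""
        n = len(df)
        ok = np.ones(n, dtype=bool)
        reasons: list[str] = [""] * n
        if self.spec.kind == "factor":
            vals = df[self.spec.covariates[0]].to_numpy()
            X = np.zeros((n, self.n_cols))
            known = np.isin(vals, self.levels)
            for j, lev in enumerate(self.levels[1:]):
                X[:, j] = vals == lev
            for i in np.nonzero(~known)[0]:
                ok[i] = False
                reasons[i] = f"unseen_level:{self.spec.covariates[0]}"
            return X, ok, reasons
        for cov in self.spec.covariates:
            x = df[cov].to_numpy(dtype=float)
            lo, hi = self.ranges[cov]
            bad = (x < lo) | (x > hi) | ~np.isfinite(x)
            for i in np.nonzero(bad)[0]:
                if ok[i]:
                    reasons[i] = f"out_of_range:{cov}"
                ok[i] = False
        if self.spec.kind == "smooth":
            x = np.nan_to_num(df[self.spec.covariates[0]].to_numpy(dtype=float))
            Xraw = self.basis.design(x)
        else:
            x1 = np.nan_to_num(df[self.spec.covariates[0]].to_numpy(dtype=float))
            x2 = np.nan_to_num(df[self.spec.covariates[1]].to_numpy(dtype=float))
            Xraw = _row_kron(self.basis1.design(x1), self.basis2.design(x2))
        return Xraw @ self.Z, ok, reasons


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


def build_basis(x: np.ndarray, k: int = 3, shrinkage: bool = True
                ) -> tuple[np.ndarray, np.ndarray]:
    """Centred cubic-spline design columns and penalty for one covariate."""
    df = pd.DataFrame({"x": np.asarray(x, dtype=float)})
    term = _BuiltTerm(TermSpec.smooth("x", k=k, shrinkage=shrinkage), df)
    X, _, _ = term.design(df)
    return X, term.penalties[0]


def build_interaction(x1: np.ndarray, x2: np.ndarray, k: int = 3,
                      shrinkage: bool = True
                      ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Tensor-product surface design columns and per-margin penalties."""
    df = pd.DataFrame({"a": np.asarray(x1, float), "b": np.asarray(x2, float)})
    term = _BuiltTerm(TermSpec.tensor("a", "b", k=k, shrinkage=shrinkage), df)
    X, _, _ = term.design(df)
    return X, term.penalties


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

class Family:
    name: str

    @staticmethod
    def by_name(name: str) -> "Family":
        fam = {
            "gaussian": Gaussian,
            "binomial": QuasiBinomial,
            "quasibinomial": QuasiBinomial,
            "gamma": GammaLog,
        }.get(name)
        if fam is None:
            raise ValueError(f"unknown family {name!r}")
        return fam()


class Gaussian(Family):
    name = "gaussian"
    link = "identity"

    def check_response(self, y):
        pass

    def initialize(self, y):
        return y.astype(float)

    def linkfun(self, mu):
        return mu

    def linkinv(self, eta):
        return eta

    def mu_eta(self, eta):
        return np.ones_like(eta)

    def variance(self, mu):
        return np.ones_like(mu)

    def deviance(self, y, mu, weights=None):
        w = np.ones_like(y) if weights is None else weights
        return float(np.sum(w * (y - mu) ** 2))


class QuasiBinomial(Family):
    name = "quasibinomial"
    link = "logit"
    _CAP = 30.0

    def check_response(self, y):
        if np.any((y < 0) | (y > 1)):
            raise ValueError("binomial response must lie in [0, 1]")

    def initialize(self, y):
        return (y + 0.5) / 2.0

    def linkfun(self, mu):
        return np.log(mu / (1.0 - mu))

    def linkinv(self, eta):
        eta = np.clip(eta, -self._CAP, self._CAP)
        return 1.0 / (1.0 + np.exp(-eta))

    def mu_eta(self, eta):
        mu = self.linkinv(eta)
        return mu * (1.0 - mu)

    def variance(self, mu):
        return mu * (1.0 - mu)

    def deviance(self, y, mu, weights=None):
        w = np.ones_like(y) if weights is None else weights
        eps = 1e-12
        mu = np.clip(mu, eps, 1.0 - eps)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
            t2 = np.where(y < 1, (1.0 - y) * np.log((1.0 - y) / (1.0 - mu)), 0.0)
        return float(2.0 * np.sum(w * (t1 + t2)))


class GammaLog(Family):
    name = "gamma"
    link = "log"
    _CAP = 30.0

    def check_response(self, y):
        if np.any(y <= 0):
            raise ValueError("gamma response must be strictly positive")

    def initialize(self, y):
        return y.astype(float)

    def linkfun(self, mu):
        return np.log(mu)

    def linkinv(self, eta):
        return np.exp(np.clip(eta, -self._CAP, self._CAP))

    def mu_eta(self, eta):
        return self.linkinv(eta)

    def variance(self, mu):
        return mu ** 2

    def deviance(self, y, mu, weights=None):
        w = np.ones_like(y) if weights is None else weights
        return float(2.0 * np.sum(w * (-np.log(y / mu) + (y - mu) / mu)))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class GAMError(RuntimeError):
    pass


class GAMNonConvergence(GAMError):
    pass


class GAMSeparation(GAMError):
    pass


@dataclass
class GAMFit:
    """A fitted penalized GAM."""

    family: str
    terms: list[_BuiltTerm]
    beta: np.ndarray
    lam: np.ndarray                      # one per penalty matrix
    edf_total: float
    edf_by_term: dict[str, float]
    deviance: float
    null_deviance: float
    gcv: float
    scale: float
    Vb: np.ndarray                       # Bayesian coefficient covariance
    n: int
    term_slices: dict[str, slice]
    converged: bool = True
    response_name: str = "y"

    @property
    def percent_deviance(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def covariate_ranges(self) -> dict[str, tuple[float, float]]:
        out: dict[str, tuple[float, float]] = {}
        for t in self.terms:
            out.update(t.ranges)
        return out


@dataclass
class Prediction:
    eta: np.ndarray
    se_eta: np.ndarray
    response: np.ndarray
    se_response: np.ndarray
    mask: np.ndarray           # True = prediction valid
    mask_reason: list[str]


def _assemble(terms: list[_BuiltTerm], df: pd.DataFrame):
    """Full design matrix (intercept first), row mask, penalty embeddings."""
    n = len(df)
    cols = [np.ones((n, 1))]
    ok = np.ones(n, dtype=bool)
    reasons = [""] * n
    slices: dict[str, slice] = {}
    pen: list[tuple[slice, np.ndarray]] = []
    start = 1
    for t in terms:
        X, t_ok, t_reasons = t.design(df)
        sl = slice(start, start + t.n_cols)
        slices[t.name] = sl
        cols.append(X)
        for s in t.penalties:
            pen.append((sl, s))
        for i in np.nonzero(~t_ok)[0]:
            if ok[i]:
                reasons[i] = t_reasons[i]
            ok[i] = False
        start += t.n_cols
    return np.hstack(cols), ok, reasons, slices, pen


def _pirls(X, y, family: Family, pen, lam, weights, beta0=None,
           max_iter=200, tol=1e-8):
    """Penalized IRLS for fixed smoothing parameters."""
    n, p = X.shape
    S = np.zeros((p, p))
    for (sl, Sj), lj in zip(pen, lam):
        S[sl, sl] += lj * Sj
    w_prior = np.ones(n) if weights is None else np.asarray(weights, float)

    if beta0 is not None:
        beta = beta0.copy()
        eta = X @ beta
        mu = family.linkinv(eta)
    else:
        mu = family.initialize(y)
        mu = np.clip(mu, 1e-8, None)
        if family.name == "quasibinomial":
            mu = np.clip(mu, 1e-4, 1 - 1e-4)
        eta = family.linkfun(mu)
        beta = np.zeros(p)

    dev = family.deviance(y, mu, w_prior)
    converged = False
    for _ in range(max_iter):
        dmu = family.mu_eta(eta)
        var = family.variance(mu)
        w = w_prior * dmu * dmu / np.maximum(var, 1e-12)
        z = eta + (y - mu) / np.maximum(dmu, 1e-12)
        WX = X * w[:, None]
        XtWX = X.T @ WX
        H = XtWX + S
        jitter = 1e-10 * (np.trace(H) / p + 1.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", linalg.LinAlgWarning)
                beta_new = linalg.solve(H + jitter * np.eye(p),
                                        X.T @ (w * z), assume_a="pos")
        except linalg.LinAlgError as exc:
            raise GAMNonConvergence(f"singular penalized system: {exc}") from exc
        eta = X @ beta_new
        if family.name == "quasibinomial" and np.max(np.abs(eta)) > 100:
            raise GAMSeparation("divergent linear predictor (separation)")
        mu = family.linkinv(eta)
        dev_new = family.deviance(y, mu, w_prior)
        beta = beta_new
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    if not converged:
        raise GAMNonConvergence(f"IRLS iteration cap reached (deviance {dev:.4g})")

    dmu = family.mu_eta(eta)
    var = family.variance(mu)
    w = w_prior * dmu * dmu / np.maximum(var, 1e-12)
    WX = X * w[:, None]
    XtWX = X.T @ WX
    H = XtWX + S
    jitter = 1e-10 * (np.trace(H) / p + 1.0)
    Hinv = np.linalg.inv(H + jitter * np.eye(p))
    A = Hinv @ XtWX
    edf_vec = np.diag(A).copy()
    pearson = float(np.sum(w_prior * (y - mu) ** 2 / np.maximum(var, 1e-12)))
    return {
        "beta": beta, "eta": eta, "mu": mu, "deviance": dev,
        "edf_vec": edf_vec, "Hinv": Hinv, "pearson": pearson, "w": w,
    }


def fit(
    df: pd.DataFrame,
    response: str,
    term_specs: Sequence[TermSpec],
    family: str = "gaussian",
    weights: np.ndarray | None = None,
    lam: Sequence[float] | None = None,
    select: bool = True,
    n_restarts: int = 3,
) -> GAMFit:
    """Fit a penalized GAM, optionally selecting lambda by GCV.

    With ``lam`` given (one value per penalty; a smooth has one, a tensor
    two) no selection is done; ``lam=None, select=False`` fits unpenalized
    (all lambda 0), reproducing the ordinary GLM.
    """
    fam = Family.by_name(family)
    y = df[response].to_numpy(dtype=float)
    fam.check_response(y)
    terms = [_BuiltTerm(spec, df) for spec in term_specs]
    X, ok, _, slices, pen = _assemble(terms, df)
    if not ok.all():
        raise ValueError("training rows outside their own covariate range")
    n = len(y)
    n_pen = len(pen)

    warm: dict[str, np.ndarray | None] = {"beta": None}

    def fit_at(loglam: np.ndarray) -> tuple[float, dict]:
        lam_vec = np.exp(np.clip(loglam, -20.0, 30.0))
        try:
            res = _pirls(X, y, fam, pen, lam_vec, weights, beta0=warm["beta"])
        except GAMError:
            try:
                res = _pirls(X, y, fam, pen, lam_vec, weights, beta0=None)
            except GAMError:
                return 1e12, {}
        warm["beta"] = res["beta"]
        edf = float(np.sum(res["edf_vec"]))
        gcv = n * res["deviance"] / (n - edf) ** 2
        return gcv, res

    if n_pen == 0 or (lam is None and not select):
        lam_vec = np.zeros(max(n_pen, 0))
        res = _pirls(X, y, fam, pen, lam_vec, weights)
    elif lam is not None:
        lam_vec = np.asarray(lam, dtype=float)
        if len(lam_vec) != n_pen:
            raise ValueError(f"need {n_pen} lambda values, got {len(lam_vec)}")
        res = _pirls(X, y, fam, pen, lam_vec, weights)
    else:
        starts = [np.zeros(n_pen), np.full(n_pen, 3.0), np.full(n_pen, -3.0)]
        best = None
        for s in starts[:max(1, n_restarts)]:
            warm["beta"] = None
            opt = optimize.minimize(
                lambda ll: fit_at(ll)[0], s, method="Nelder-Mead",
                options={"xatol": 0.05, "fatol": 1e-9, "maxfev": 120 * n_pen + 80},
            )
            if best is None or opt.fun < best.fun:
                best = opt
        warm["beta"] = None
        lam_vec = np.exp(np.clip(best.x, -20.0, 30.0))
        _, res = fit_at(best.x)
        if not res:
            raise GAMNonConvergence("smoothing selection failed to converge")

    edf_total = float(np.sum(res["edf_vec"]))
    edf_by_term = {
        name: float(np.sum(res["edf_vec"][sl])) for name, sl in slices.items()
    }
    scale = res["pearson"] / max(n - edf_total, 1.0)
    gcv_score = n * res["deviance"] / (n - edf_total) ** 2

    # null deviance: intercept-only fit of the same family
    if len(term_specs) == 0:
        null_dev = res["deviance"]
    else:
        null_res = _pirls(np.ones((n, 1)), y, fam, [], np.zeros(0), weights)
        null_dev = null_res["deviance"]

    return GAMFit(
        family=fam.name,
        terms=terms,
        beta=res["beta"],
        lam=lam_vec,
        edf_total=edf_total,
        edf_by_term=edf_by_term,
        deviance=res["deviance"],
        null_deviance=null_dev,
        gcv=gcv_score,
        scale=scale,
        Vb=res["Hinv"] * scale,
        n=n,
        term_slices=slices,
        response_name=response,
    )


def gcv(fit_: GAMFit) -> float:
    return fit_.gcv


def deviance(fit_: GAMFit) -> float:
    return fit_.deviance


def percent_deviance(fit_: GAMFit) -> float:
    return fit_.percent_deviance


def predict(
    fit_: GAMFit,
    df: pd.DataFrame,
    exclude_out_of_range: bool = True,
) -> Prediction:
    """Linear predictor, response and standard errors for new rows.

    Rows with a covariate outside the training range, or an unseen factor
    level, are masked (with a reason) when ``exclude_out_of_range`` is set.
    """
    for t in fit_.terms:
        for cov in t.spec.covariates:
            if cov not in df.columns:
                raise KeyError(f"missing covariate column {cov!r}")
    X, ok, reasons, _, _ = _assemble(fit_.terms, df)
    eta = X @ fit_.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit_.Vb, X), 0.0))
    fam = Family.by_name(fit_.family)
    resp = fam.linkinv(eta)
    se_resp = np.abs(fam.mu_eta(eta)) * se
    if exclude_out_of_range:
        mask = ok
    else:
        mask = np.ones(len(df), dtype=bool)
        reasons = [""] * len(df)
    return Prediction(eta, se, resp, se_resp, mask, reasons)


def partial_effect(
    fit_: GAMFit, term_name: str, df: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """A term's contribution to the linear predictor, with standard errors."""
    if term_name not in fit_.term_slices:
        raise KeyError(f"no term {term_name!r} in model")
    term = next(t for t in fit_.terms if t.name == term_name)
    Xt, _, _ = term.design(df)
    sl = fit_.term_slices[term_name]
    effect = Xt @ fit_.beta[sl]
    V = fit_.Vb[sl, sl]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xt, V, Xt), 0.0))
    return effect, se
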