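"""Cox proportional-hazards models for the LE8 analyses.

Three exposure forms are supported, mirroring the study's analysis plan:

* quartile indicators (Q1, the least healthy quartile, as reference),
* the continuous composite score entered linearly,
* the continuous composite modelled with a penalised cubic B-spline whose
  complexity is pinned a priori at a target effective degrees of freedom
  (default 4) via a monotone smoothing-parameter search.

Adjustment sets follow the study's Models 1-3: Model 1 unadjusted,
Model 2 age + sex + Townsend deprivation, Model 3 additionally six
baseline comorbidities.  Diagnostics (Schoenfeld residual tests),
spline-by-moderator likelihood-ratio interaction tests, and a Fine-Gray
subdistribution-hazard fit for competing risks are provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from ._coxcore import PartialLikelihood, check_design, newton_maximize
from .errors import (
    DesignMatrixError,
    EstimationError,
    ParameterError,
    ValidationError,
)

MODEL2_COVARIATES = ("age_years", "female", "townsend")
COMORBIDITY_COLUMNS = (
    "comorb_stroke",
    "comorb_mi",
    "comorb_chronic_coronary",
    "comorb_heart_failure",
    "comorb_type2_diabetes",
    "comorb_depression",
)


@dataclass(frozen=True)
class ModelSpec:
    """Adjustment set and exposure form for a Cox fit.

    ``adjustment``: "model1" (none), "model2" (age, sex, Townsend), or
    "model3" (model2 + six comorbidity flags).
    """

    adjustment: str = "model1"
    exposure_form: str = "quartile"  # quartile | linear | pspline
    ties: str = "efron"

    def covariates(self) -> tuple[str, ...]:
        if self.adjustment == "model1":
            return ()
        if self.adjustment == "model2":
            return MODEL2_COVARIATES
        if self.adjustment == "model3":
            return MODEL2_COVARIATES + COMORBIDITY_COLUMNS
        raise ParameterError(f"unknown adjustment set {self.adjustment!r}")


@dataclass
class CoxFit:
    """Fitted Cox model: log-hazard coefficients with inference."""

    coefficients: pd.Series
    standard_errors: pd.Series
    covariance: pd.DataFrame
    log_partial_likelihood: float
    n_events: int
    converged: bool
    ties: str = "efron"
    ll_path: list = field(default_factory=list)

    def hazard_ratios(self) -> pd.DataFrame:
        hr = np.exp(self.coefficients)
        lo = np.exp(self.coefficients - 1.96 * self.standard_errors)
        hi = np.exp(self.coefficients + 1.96 * self.standard_errors)
        z = self.coefficients / self.standard_errors
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "hr": hr,
                "ci_low": lo,
                "ci_high": hi,
                "p": p,
            }
        )

    def summary(self) -> pd.DataFrame:
        return self.hazard_ratios()


def _build_design(
    data: pd.DataFrame, spec: ModelSpec, exposure: str = "composite"
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    if spec.exposure_form == "quartile":
        q = pd.Categorical(data["quartile"], categories=["Q1", "Q2", "Q3", "Q4"])
        for lab in ("Q2", "Q3", "Q4"):
            cols.append((q == lab).astype(float))
            names.append(lab)
    elif spec.exposure_form == "linear":
        cols.append(data[exposure].to_numpy(dtype=float))
        names.append(exposure)
    elif spec.exposure_form is not None and spec.exposure_form != "none":
        raise ParameterError(
            f"exposure_form {spec.exposure_form!r} not handled by fit_cox"
        )
    for c in spec.covariates():
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    if not cols:
        raise ParameterError("empty design: no exposure and no covariates")
    X = np.column_stack(cols)
    return X, names


def _event_mask(data: pd.DataFrame) -> np.ndarray:
    s = data["status"].astype(str).to_numpy()
    return s == "event"


def fit_cox(data: pd.DataFrame, spec: ModelSpec) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``data`` is a survival table with columns ``time_years``, ``status``
    ("event"/"censored"/"competing_death" -- anything other than "event"
    is treated as censoring for a cause-specific fit), the exposure
    (``quartile`` or ``composite``), and the adjustment covariates.
    """
    time = data["time_years"].to_numpy(dtype=float)
    event = _event_mask(data)
    if event.sum() < 1:
        raise EstimationError("no events in dataset")
    X, names = _build_design(data, spec)
    check_design(X, names)
    entry = (
        data["entry_years"].to_numpy(dtype=float)
        if "entry_years" in data.columns
        else None
    )

    pl = PartialLikelihood(X, time, event, entry=entry, ties=spec.ties)
    beta, ll, g, H, path, conv = newton_maximize(pl, np.zeros(X.shape[1]))
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        log_partial_likelihood=ll,
        n_events=int(event.sum()),
        converged=conv,
        ties=spec.ties,
        ll_path=path,
    )


# ---------------------------------------------------------------------------
# penalised spline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineSpec:
    """Cubic B-spline basis with a second-difference coefficient penalty.

    ``n_basis`` basis functions (degree 3; interior knots at exposure
    quantiles); the smoothing parameter is searched so the spline block's
    effective degrees of freedom hits ``target_df`` within ``df_tol``.
    """

    n_basis: int = 8
    degree: int = 3
    penalty_order: int = 2
    target_df: float = 4.0
    df_tol: float = 0.01


@dataclass
class SplineFit:
    """Fitted penalised-spline Cox model for a continuous exposure."""

    knots: np.ndarray
    degree: int
    constraint: np.ndarray  # basis-coefficient map theta = Z @ gamma
    gamma: np.ndarray  # spline coefficients (constrained space)
    beta_cov: pd.Series  # adjustment-covariate coefficients
    covariance: np.ndarray  # (A + lam P)^{-1} over [gamma, beta_cov]
    smoothing: float
    effective_df: float
    linear_coef: float
    se_linear: float
    x_min: float
    x_max: float
    x_ref: float
    log_partial_likelihood: float  # unpenalised, at the penalised estimate
    n_events: int
    converged: bool

    @property
    def k_spline(self) -> int:
        return self.constraint.shape[1]

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        B = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        return B @ self.constraint

    def curve(self, x) -> np.ndarray:
        """Fitted log-hazard function f(x) (arbitrary additive level)."""
        scalar = np.ndim(x) == 0
        out = self.basis(np.atleast_1d(x)) @ self.gamma
        return float(out[0]) if scalar else out


def _bspline_knots(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    n_interior = spec.n_basis - spec.degree - 1
    if n_interior < 0:
        raise ParameterError("n_basis too small for cubic degree")
    lo, hi = float(np.min(x)), float(np.max(x))
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    return np.concatenate(
        [[lo] * (spec.degree + 1), interior, [hi] * (spec.degree + 1)]
    )


def _difference_penalty(k: int, order: int) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _ones_complement(k: int) -> np.ndarray:
    """Orthonormal basis of the complement of the constant coefficient
    direction (which the partial likelihood cannot identify)."""
    ones = np.ones((k, 1)) / np.sqrt(k)
    Q, _ = np.linalg.qr(np.hstack([ones, np.eye(k)[:, : k - 1]]))
    return Q[:, 1:]


def _pspline_fit_at_lambda(lam, pl, P_full, k_con, beta0):
    beta, llp, g, H, path, conv = newton_maximize(
        lambda b: pl(b, penalty=(lam, P_full)), beta0
    )
    # unpenalised information at the penalised estimate
    ll_u, g_u, H_u = pl(beta)
    A = -H_u
    M = A + lam * P_full
    T = np.linalg.solve(M, A)
    df_spline = float(np.trace(T[:k_con, :k_con]))
    return beta, ll_u, A, M, df_spline, conv


def fit_cox_pspline(
    data: pd.DataFrame,
    spec: SplineSpec | None = None,
    adjustment: ModelSpec | None = None,
    exposure: str = "composite",
    smoothing: float | None = None,
    x_ref: float | None = None,
) -> SplineFit:
    """Fit a penalised cubic-spline Cox model for a continuous exposure.

    The second-difference penalty leaves linear trends unpenalised, so as
    ``smoothing -> inf`` the fit collapses onto the linear Cox model.  By
    default the smoothing parameter is chosen by bisection so the spline
    block's effective df (trace of the ridge-adjusted information
    smoother) hits ``spec.target_df``; pass ``smoothing`` to fix it.

    ``linear_coef``/``se_linear`` summarise the least-squares linear trend
    of the fitted curve over the sample exposures (delta-method SE).
    """
    spec = spec or SplineSpec()
    adjustment = adjustment or ModelSpec(adjustment="model1", exposure_form="none")
    x = data[exposure].to_numpy(dtype=float)
    if np.unique(x).size < 10:
        raise ValidationError("exposure needs >= 10 distinct values")
    time = data["time_years"].to_numpy(dtype=float)
    event = _event_mask(data)
    if event.sum() < 1:
        raise EstimationError("no events in dataset")

    knots = _bspline_knots(x, spec)
    B = BSpline.design_matrix(x, knots, spec.degree).toarray()
    k = B.shape[1]
    Z = _ones_complement(k)
    Bc = B @ Z
    k_con = Z.shape[1]
    cov_names = list(adjustment.covariates())
    A_cov = (
        data[cov_names].to_numpy(dtype=float)
        if cov_names
        else np.empty((len(data), 0))
    )
    X = np.hstack([Bc, A_cov])
    check_design(X, [f"s{j}" for j in range(k_con)] + cov_names)
    P = Z.T @ _difference_penalty(k, spec.penalty_order) @ Z
    P_full = np.zeros((X.shape[1], X.shape[1]))
    P_full[:k_con, :k_con] = P

    max_df = k_con  # unpenalised spline block dimension
    if not (1.0 < spec.target_df < max_df) and smoothing is None:
        raise ParameterError(
            f"target_df {spec.target_df} unreachable with {k} basis functions"
        )

    pl = PartialLikelihood(X, time, event, ties=adjustment.ties)
    beta0 = np.zeros(X.shape[1])
    if smoothing is not None:
        lam = float(smoothing)
        beta, ll_u, A, M, df, conv = _pspline_fit_at_lambda(
            lam, pl, P_full, k_con, beta0
        )
    else:
        lo, hi = 1e-6, 1e6
        beta, ll_u, A, M, df_lo, conv = _pspline_fit_at_lambda(
            lo, pl, P_full, k_con, beta0
        )
        while df_lo < spec.target_df and lo > 1e-12:
            lo /= 100.0
            beta, ll_u, A, M, df_lo, conv = _pspline_fit_at_lambda(
                lo, pl, P_full, k_con, beta
            )
        _, _, _, _, df_hi, _ = _pspline_fit_at_lambda(hi, pl, P_full, k_con, beta)
        while df_hi > spec.target_df and hi < 1e12:
            hi *= 100.0
            _, _, _, _, df_hi, _ = _pspline_fit_at_lambda(hi, pl, P_full, k_con, beta)
        if not (df_hi <= spec.target_df <= df_lo):
            raise ParameterError(
                f"target_df {spec.target_df} outside reachable range "
                f"[{df_hi:.2f}, {df_lo:.2f}]"
            )
        for _ in range(60):
            lam = np.exp(0.5 * (np.log(lo) + np.log(hi)))
            beta, ll_u, A, M, df, conv = _pspline_fit_at_lambda(
                lam, pl, P_full, k_con, beta
            )
            if abs(df - spec.target_df) <= spec.df_tol:
                break
            if df > spec.target_df:
                lo = lam
            else:
                hi = lam

    V = np.linalg.inv(M)
    gamma = beta[:k_con]
    beta_cov = pd.Series(beta[k_con:], index=cov_names)

    # linear-trend summary of the fitted curve over the sample exposures
    xc = x - x.mean()
    sxx = float(xc @ xc)
    c_lin = np.zeros(X.shape[1])
    c_lin[:k_con] = (xc @ Bc) / sxx
    linear_coef = float(c_lin @ beta)
    se_linear = float(np.sqrt(c_lin @ V @ c_lin))

    fit = SplineFit(
        knots=knots,
        degree=spec.degree,
        constraint=Z,
        gamma=gamma,
        beta_cov=beta_cov,
        covariance=V,
        smoothing=float(lam),
        effective_df=float(df),
        linear_coef=linear_coef,
        se_linear=se_linear,
        x_min=float(np.min(x)),
        x_max=float(np.max(x)),
        x_ref=float(np.median(x)) if x_ref is None else float(x_ref),
        log_partial_likelihood=float(ll_u),
        n_events=int(event.sum()),
        converged=conv,
    )
    return fit


def hr_curve(
    fit: SplineFit, reference: float | None = None, grid=None
) -> pd.DataFrame:
    """Hazard-ratio curve HR(x) = exp(f(x) - f(ref)) with pointwise
    delta-method 95% CIs.  Grid points beyond the observed exposure range
    are clipped with a warning."""
    ref = fit.x_ref if reference is None else float(reference)
    if grid is None:
        grid = np.linspace(fit.x_min, fit.x_max, 200)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < fit.x_min) | (grid > fit.x_max)):
        warnings.warn(
            "grid extends beyond the observed exposure range; clipping",
            stacklevel=2,
        )
        grid = np.clip(grid, fit.x_min, fit.x_max)
    Bg = fit.basis(grid)
    Br = fit.basis(np.array([ref]))
    C = Bg - Br  # contrast rows
    loghr = C @ fit.gamma
    Vs = fit.covariance[: fit.k_spline, : fit.k_spline]
    var = np.einsum("ij,jk,ik->i", C, Vs, C)
    se = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {
            "exposure": grid,
            "hr": np.exp(loghr),
            "ci_low": np.exp(loghr - 1.96 * se),
            "ci_high": np.exp(loghr + 1.96 * se),
        }
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def schoenfeld_residuals(data: pd.DataFrame, fit: CoxFit) -> pd.DataFrame:
    """Schoenfeld residuals, one row per event.

    Uses the tie convention of the fit: under Efron, each of the d tied
    events is compared with the average of the d down-weighted risk-set
    means, so the residuals sum to the (vanishing) score at the MLE."""
    time = data["time_years"].to_numpy(dtype=float)
    event = _event_mask(data)
    names = list(fit.coefficients.index)
    X = _design_from_names(data, names)
    beta = fit.coefficients.to_numpy()
    order = np.argsort(time, kind="stable")
    t, d, Xs = time[order], event[order], X[order]
    r = np.exp(np.clip(Xs @ beta, -200, 200))
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum((r[:, None] * Xs)[::-1], axis=0)[::-1]
    ev_idx = np.flatnonzero(d)
    first = np.searchsorted(t, t[ev_idx], side="left")
    means = S1[first] / S0[first, None]
    if fit.ties == "efron":
        te = t[ev_idx]
        ut, gstart, counts = np.unique(te, return_index=True, return_counts=True)
        for g in np.flatnonzero(counts >= 2):
            sl = slice(gstart[g], gstart[g] + counts[g])
            rows = ev_idx[sl]
            m = counts[g]
            s0D = r[rows].sum()
            s1D = (r[rows, None] * Xs[rows]).sum(axis=0)
            i0 = first[gstart[g]]
            avg = np.zeros(len(names))
            for L_ in range(m):
                f = L_ / m
                avg += (S1[i0] - f * s1D) / (S0[i0] - f * s0D)
            means[sl] = avg / m
    resid = Xs[ev_idx] - means
    return pd.DataFrame(resid, columns=names, index=t[ev_idx]).rename_axis("time")


def _design_from_names(data: pd.DataFrame, names) -> np.ndarray:
    cols = []
    q = pd.Categorical(
        data.get("quartile", pd.Series(index=data.index, dtype=object)),
        categories=["Q1", "Q2", "Q3", "Q4"],
    )
    for name in names:
        if name in ("Q2", "Q3", "Q4"):
            cols.append((q == name).astype(float))
        else:
            cols.append(data[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def schoenfeld_test(data: pd.DataFrame, fit: CoxFit) -> pd.DataFrame:
    """Proportional-hazards score test per covariate (Grambsch-Therneau),
    correlating Schoenfeld residuals with event rank."""
    resid = schoenfeld_residuals(data, fit)
    m = len(resid)
    if m < 2:
        raise EstimationError("need >= 2 events for the Schoenfeld test")
    g = stats.rankdata(resid.index.to_numpy(), method="average")
    gc = g - g.mean()
    R = resid.to_numpy()
    names = list(resid.columns)
    Vinv = fit.covariance.to_numpy()  # = I^{-1}
    rows = []
    denom_g = float(gc @ gc)
    # Grambsch-Therneau with scaled residuals r* = m * s V: the score
    # statistic for a time-varying coefficient on covariate j is
    # [sum (g-gbar) r*_j]^2 / (m * V_jj * sum (g-gbar)^2)
    u_star = m * (gc @ R @ Vinv)
    for j, name in enumerate(names):
        chi2 = u_star[j] ** 2 / (m * Vinv[j, j] * denom_g)
        corr = float(np.corrcoef(gc, R[:, j])[0, 1]) if R[:, j].std() > 0 else 0.0
        rows.append(
            {
                "covariate": name,
                "corr_with_time": corr,
                "chi2": chi2,
                "p": float(stats.chi2.sf(chi2, 1)),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# moderation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRTResult:
    chi_square: float
    df: int
    p_value: float


def lrt_interaction(
    data: pd.DataFrame,
    moderator: str,
    spec: SplineSpec | None = None,
    adjustment: ModelSpec | None = None,
    exposure: str = "composite",
) -> LRTResult:
    """Likelihood-ratio test for spline-by-moderator effect modification.

    The main-effects model holds a penalised spline of the exposure plus
    the (binary) moderator and adjustment covariates; the interaction
    model adds spline-basis x moderator columns sharing the main fit's
    smoothing parameter.  The chi-square compares unpenalised log partial
    likelihoods at the penalised estimates, on the interaction block's
    effective df (rounded, >= 1) -- an approximate, honest accounting for
    penalised fits.
    """
    spec = spec or SplineSpec()
    adjustment = adjustment or ModelSpec(adjustment="model1", exposure_form="none")
    mod = data[moderator].to_numpy(dtype=float)
    levels = np.unique(mod)
    if levels.size != 2:
        raise ParameterError("moderator must be binary (two observed levels)")
    event = _event_mask(data)
    for lev in levels:
        if event[mod == lev].sum() == 0:
            raise EstimationError(
                f"moderator level {lev} has no events (stratum error)"
            )
    mod01 = (mod == levels[1]).astype(float)

    x = data[exposure].to_numpy(dtype=float)
    time = data["time_years"].to_numpy(dtype=float)
    knots = _bspline_knots(x, spec)
    B = BSpline.design_matrix(x, knots, spec.degree).toarray()
    Z = _ones_complement(B.shape[1])
    Bc = B @ Z
    k_con = Bc.shape[1]
    P = Z.T @ _difference_penalty(B.shape[1], spec.penalty_order) @ Z
    cov_names = list(adjustment.covariates())
    A_cov = (
        data[cov_names].to_numpy(dtype=float)
        if cov_names
        else np.empty((len(data), 0))
    )

    # main fit: search lambda for the target df
    main = fit_cox_pspline(
        data.assign(_mod=mod01),
        spec=spec,
        adjustment=adjustment,
        exposure=exposure,
    )
    lam = main.smoothing

    def fit_design(X, P_full, beta0):
        pl = PartialLikelihood(X, time, event, ties=adjustment.ties)
        beta, llp, g, H, path, conv = newton_maximize(
            lambda b: pl(b, penalty=(lam, P_full)), beta0
        )
        ll_u, _, H_u = pl(beta)
        return beta, ll_u, -H_u

    X_main = np.hstack([Bc, mod01[:, None], A_cov])
    Pm = np.zeros((X_main.shape[1],) * 2)
    Pm[:k_con, :k_con] = P
    beta_m, ll_main, A_m = fit_design(X_main, Pm, np.zeros(X_main.shape[1]))

    X_int = np.hstack([Bc, mod01[:, None], Bc * mod01[:, None], A_cov])
    Pi = np.zeros((X_int.shape[1],) * 2)
    Pi[:k_con, :k_con] = P
    sl = slice(k_con + 1, 2 * k_con + 1)
    Pi[sl, sl] = P
    b0 = np.zeros(X_int.shape[1])
    b0[: k_con + 1] = beta_m[: k_con + 1]
    if A_cov.shape[1]:
        b0[-A_cov.shape[1] :] = beta_m[-A_cov.shape[1] :]
    beta_i, ll_int, A_i = fit_design(X_int, Pi, b0)

    M_i = A_i + lam * Pi
    T = np.linalg.solve(M_i, A_i)
    df_added = float(np.trace(T[sl, sl]))
    chi2 = max(0.0, 2.0 * (ll_int - ll_main))
    df = max(1, int(round(df_added)))
    return LRTResult(
        chi_square=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df))
    )


# ---------------------------------------------------------------------------
# competing risks
# ---------------------------------------------------------------------------

def _censoring_survival(time: np.ndarray, censored: np.ndarray):
    """Kaplan-Meier estimate of the censoring distribution G(t) with a
    left-continuous evaluator G(t-)."""
    order = np.argsort(time, kind="stable")
    t, c = time[order], censored[order]
    ut = np.unique(t)
    n_at_risk = len(t) - np.searchsorted(t, ut, side="left")
    d_cens = np.array([c[t == u].sum() for u in ut], dtype=float)
    factors = 1.0 - d_cens / n_at_risk
    surv = np.cumprod(factors)

    def G_minus(s: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(ut, np.asarray(s, dtype=float), side="left") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, len(surv) - 1)], 1.0)
        return out

    return G_minus


def fine_gray(
    data: pd.DataFrame, spec: ModelSpec | None = None
) -> CoxFit:
    """Fine-Gray subdistribution-hazard model for an endpoint with
    competing deaths.

    ``data``: survival table whose ``status`` takes values "event",
    "censored", and "competing_death".  Individuals failing from the
    competing cause stay in the risk set past their death with
    inverse-probability-of-censoring weights G(t-)/G(D-), implemented as
    counting-process rows; ties are handled by Breslow weighting.
    Standard errors are the model-based (inverse-information) ones.
    """
    spec = spec or ModelSpec(exposure_form="quartile", ties="breslow")
    status = data["status"].astype(str).to_numpy()
    if not np.any(status == "event"):
        raise EstimationError("no events of interest; Fine-Gray undefined")
    time = data["time_years"].to_numpy(dtype=float)
    X, names = _build_design(data, spec)
    check_design(X, names)

    is_event = status == "event"
    is_cens = status == "censored"
    is_comp = status == "competing_death"
    G_minus = _censoring_survival(time, is_cens)
    tau = np.unique(time[is_event])

    rows_start = [np.zeros(np.count_nonzero(~is_comp))]
    rows_stop = [time[~is_comp]]
    rows_ev = [is_event[~is_comp]]
    rows_w = [np.ones(np.count_nonzero(~is_comp))]
    rows_X = [X[~is_comp]]

    comp_idx = np.flatnonzero(is_comp)
    for i in comp_idx:
        D = time[i]
        later = tau[tau > D]
        if later.size:
            prev = np.concatenate([[D], later[:-1]])
            starts = np.concatenate([[0.0], prev])
            stops = np.concatenate([[D], later])
            gD = max(float(G_minus(np.array([D]))[0]), 1e-12)
            w_i = np.concatenate([[1.0], G_minus(later) / gD])
        else:
            starts, stops, w_i = np.array([0.0]), np.array([D]), np.array([1.0])
        rows_start.append(starts)
        rows_stop.append(stops)
        rows_ev.append(np.zeros(len(stops), dtype=bool))
        rows_w.append(w_i)
        rows_X.append(np.repeat(X[i : i + 1], len(stops), axis=0))

    start = np.concatenate(rows_start)
    stop = np.concatenate(rows_stop)
    ev = np.concatenate(rows_ev)
    w = np.concatenate(rows_w)
    Xe = np.vstack(rows_X)

    pl = PartialLikelihood(Xe, stop, ev, weights=w, entry=start, ties="breslow")
    beta, ll, g, H, path, conv = newton_maximize(pl, np.zeros(Xe.shape[1]))
    cov = np.linalg.inv(-H)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        log_partial_likelihood=ll,
        n_events=int(is_event.sum()),
        converged=conv,
        ties="breslow",
        ll_path=path,
    )
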