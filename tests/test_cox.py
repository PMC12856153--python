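"""Cox model fitting: partial-likelihood oracle equivalence, diagnostics,
competing risks."""

import numpy as np
import pandas as pd
import pytest

import le8surv as L
from le8surv.cox import fine_gray, schoenfeld_residuals, schoenfeld_test
from le8surv.errors import DesignMatrixError, EstimationError
from _helpers import random_survival_frame


# ---------------------------------------------------------------------------
# independent partial-likelihood oracle (explicit risk sets, Efron ties)
# ---------------------------------------------------------------------------

def oracle_log_pl(beta, t, d, x):
    ll = 0.0
    for u in sorted(set(t[d])):
        tied = (t == u) & d
        m = int(tied.sum())
        risk = t >= u
        s0 = np.exp(beta * x[risk]).sum()
        s0_tied = np.exp(beta * x[tied]).sum()
        ll += beta * x[tied].sum()
        for k in range(m):
            ll -= np.log(s0 - (k / m) * s0_tied)
    return ll


def oracle_grid_beta(t, d, x):
    """Two-stage dense grid search of the partial likelihood."""
    grid = np.linspace(-4, 4, 4001)
    lls = [oracle_log_pl(b, t, d, x) for b in grid]
    b0 = grid[int(np.argmax(lls))]
    fine = np.linspace(b0 - 0.005, b0 + 0.005, 2001)
    lls = [oracle_log_pl(b, t, d, x) for b in fine]
    return fine[int(np.argmax(lls))]


def _fit_beta(t, d, x):
    df = pd.DataFrame(
        {"time_years": t, "status": np.where(d, "event", "censored"), "composite": x}
    )
    fit = L.fit_cox(df, L.ModelSpec(adjustment="model1", exposure_form="linear"))
    return fit.coefficients.iloc[0], fit


def test_closed_form_four_row_example():
    """Score equation u^2 - u - 4 = 0 with u = exp(beta)."""
    t = np.array([1.0, 2.0, 3.0, 4.0])
    d = np.ones(4, bool)
    x = np.array([1.0, 0.0, 1.0, 0.0])
    beta, _ = _fit_beta(t, d, x)
    assert beta == pytest.approx(np.log((1 + np.sqrt(17)) / 2), abs=1e-6)


def test_newton_matches_grid_oracle_on_tiny_datasets():
    """Dense grid search of the Efron partial likelihood agrees with the
    Newton solution (|diff| < 1e-4) on random 1-covariate datasets with
    at most 8 rows, including tied event times."""
    rng = np.random.default_rng(12)
    checked = 0
    while checked < 30:
        n = int(rng.integers(3, 9))
        t = rng.integers(1, 6, size=n).astype(float)  # ties likely
        d = rng.random(n) < 0.7
        x = np.round(rng.normal(size=n), 2)
        if d.sum() < 2 or np.std(x[d]) == 0 or np.std(x) == 0:
            continue
        try:
            beta, _ = _fit_beta(t, d, x)
        except (DesignMatrixError, L.errors.ConvergenceError):
            continue
        ref = oracle_grid_beta(t, d, x)
        if abs(ref) > 3.5:  # grid boundary: monotone likelihood, no MLE
            continue
        assert abs(beta - ref) < 1e-4
        checked += 1


def test_constant_covariate_raises_design_error():
    df = pd.DataFrame(
        {"time_years": [1, 2, 3, 4], "status": ["event"] * 4, "composite": 1.0}
    )
    with pytest.raises(DesignMatrixError, match="constant"):
        L.fit_cox(df, L.ModelSpec(adjustment="model1", exposure_form="linear"))


def test_no_events_raises():
    df = pd.DataFrame(
        {"time_years": [1.0, 2.0], "status": ["censored"] * 2, "composite": [0, 1]}
    )
    with pytest.raises(EstimationError):
        L.fit_cox(df, L.ModelSpec(adjustment="model1", exposure_form="linear"))


def test_null_covariate_hr_near_one():
    rng = np.random.default_rng(4)
    df = random_survival_frame(rng, 4000, beta=0.0)
    beta, fit = _fit_beta(
        df["time_years"].to_numpy(),
        (df["status"] == "event").to_numpy(),
        df["composite"].to_numpy(),
    )
    assert abs(beta) < 2.5 * fit.standard_errors.iloc[0]


def test_matches_lifelines_on_random_data():
    """Independent implementation cross-check (coefficients and SEs)."""
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(8)
    df = random_survival_frame(rng, 600, beta=0.4, tie_days=50)
    fit = L.fit_cox(df, L.ModelSpec(adjustment="model1", exposure_form="linear"))
    cph = CoxPHFitter()
    ll_df = df.assign(E=(df["status"] == "event").astype(int))[
        ["time_years", "E", "composite"]
    ]
    cph.fit(ll_df, "time_years", "E")
    assert fit.coefficients.iloc[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
    assert fit.standard_errors.iloc[0] == pytest.approx(
        cph.standard_errors_.iloc[0], abs=1e-6
    )


def test_log_partial_likelihood_nondecreasing(mortality_data):
    fit = L.fit_cox(
        mortality_data, L.ModelSpec(adjustment="model3", exposure_form="quartile")
    )
    path = np.array(fit.ll_path)
    assert np.all(np.diff(path) >= -1e-9)
    assert fit.converged


def test_breslow_equals_efron_without_ties():
    rng = np.random.default_rng(5)
    df = random_survival_frame(rng, 300)
    assert df["time_years"].is_unique
    fe = L.fit_cox(df, L.ModelSpec(adjustment="model1", exposure_form="linear", ties="efron"))
    fb = L.fit_cox(df, L.ModelSpec(adjustment="model1", exposure_form="linear", ties="breslow"))
    assert fe.coefficients.iloc[0] == pytest.approx(fb.coefficients.iloc[0], abs=1e-10)


def test_quartile_hrs_graded_monotone(mortality_data):
    """Higher cardiovascular-health quartiles show graded risk reduction
    (Q2 > Q3 > Q4 hazard ordering versus Q1)."""
    fit = L.fit_cox(
        mortality_data, L.ModelSpec(adjustment="model1", exposure_form="quartile")
    )
    hr = np.exp(fit.coefficients[["Q2", "Q3", "Q4"]].to_numpy())
    assert hr[0] > hr[1] > hr[2]
    assert hr[2] < 1


# ---------------------------------------------------------------------------
# Schoenfeld diagnostics
# ---------------------------------------------------------------------------

def test_schoenfeld_residuals_sum_to_zero(mortality_data):
    fit = L.fit_cox(
        mortality_data, L.ModelSpec(adjustment="model2", exposure_form="linear")
    )
    res = schoenfeld_residuals(mortality_data, fit)
    assert res.sum().abs().max() < 1e-8 * fit.n_events


def test_schoenfeld_test_matches_lifelines():
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    rng = np.random.default_rng(17)
    df = random_survival_frame(rng, 500, beta=0.5)
    fit = L.fit_cox(df, L.ModelSpec(adjustment="model1", exposure_form="linear"))
    zph = schoenfeld_test(df, fit)
    ll_df = df.assign(E=(df["status"] == "event").astype(int))[
        ["time_years", "E", "composite"]
    ]
    cph = CoxPHFitter().fit(ll_df, "time_years", "E")
    ref = proportional_hazard_test(cph, ll_df, time_transform="rank")
    assert zph.loc["composite", "chi2"] == pytest.approx(
        float(np.asarray(ref.test_statistic).ravel()[0]), rel=1e-3
    )


def test_schoenfeld_detects_reversing_effect():
    """A covariate whose effect flips sign mid-follow-up violates
    proportional hazards detectably."""
    rng = np.random.default_rng(23)
    n = 5000
    x = rng.binomial(1, 0.5, n).astype(float)
    # piecewise hazard: HR e^{+0.8x} before t=5, e^{-0.8x} after
    t1 = rng.exponential(1 / (0.08 * np.exp(0.8 * x)))
    t2 = 5 + rng.exponential(1 / (0.08 * np.exp(-0.8 * x)))
    t = np.where(t1 < 5, t1, t2)
    t = np.minimum(t, 15.0)
    d = t < 15.0
    df = pd.DataFrame(
        {"time_years": t, "status": np.where(d, "event", "censored"), "composite": x}
    )
    fit = L.fit_cox(df, L.ModelSpec(adjustment="model1", exposure_form="linear"))
    zph = schoenfeld_test(df, fit)
    assert zph.loc["composite", "p"] < 0.05


# ---------------------------------------------------------------------------
# Fine-Gray
# ---------------------------------------------------------------------------

def test_fine_gray_zero_competing_equals_cause_specific():
    rng = np.random.default_rng(31)
    df = random_survival_frame(rng, 400, beta=0.5)
    fg = fine_gray(df, L.ModelSpec(adjustment="model1", exposure_form="linear", ties="breslow"))
    cs = L.fit_cox(df, L.ModelSpec(adjustment="model1", exposure_form="linear", ties="breslow"))
    assert abs(fg.coefficients.iloc[0] - cs.coefficients.iloc[0]) < 1e-6


def test_fine_gray_requires_events():
    df = pd.DataFrame(
        {
            "time_years": [1.0, 2.0],
            "status": ["competing_death", "censored"],
            "composite": [0.0, 1.0],
        }
    )
    with pytest.raises(EstimationError):
        fine_gray(df, L.ModelSpec(adjustment="model1", exposure_form="linear"))


def test_fine_gray_recovers_subdistribution_hr():
    """Simulated from the subdistribution model with HR 0.6; the
    estimate lands within 2 SE of truth."""
    rng = np.random.default_rng(3)
    n, b, p_mix = 3000, np.log(0.6), 0.5
    x = rng.binomial(1, 0.5, size=n).astype(float)
    u = rng.random(n)
    p1 = 1 - (1 - p_mix) ** np.exp(b * x)
    cause1 = u < p1
    v = rng.random(n)
    t1 = -np.log(1 - (1 - (1 - v * p1) ** (1 / np.exp(b * x))) / p_mix)
    t2 = rng.exponential(1, size=n)
    t = np.where(cause1, t1, t2)
    cens = rng.exponential(5, size=n)
    obs = np.minimum(t, cens)
    status = np.where(
        t <= cens, np.where(cause1, "event", "competing_death"), "censored"
    )
    df = pd.DataFrame({"time_years": obs, "status": status, "composite": x})
    fg = fine_gray(df, L.ModelSpec(adjustment="model1", exposure_form="linear", ties="breslow"))
    assert abs(fg.coefficients.iloc[0] - b) < 2 * fg.standard_errors.iloc[0]


def test_cumulative_incidences_sum_below_one(mace_data):
    """Aalen-Johansen cause-specific cumulative incidences are
    sub-additive to 1 at every time."""
    from lifelines import AalenJohansenFitter

    ev = mace_data["status"].map({"censored": 0, "event": 1, "competing_death": 2})
    t = mace_data["time_years"]
    cif_sum = None
    for cause in (1, 2):
        ajf = AalenJohansenFitter(calculate_variance=False)
        ajf.fit(t, ev, event_of_interest=cause)
        c = ajf.cumulative_density_.iloc[:, 0]
        cif_sum = c if cif_sum is None else cif_sum.add(c, fill_value=0).ffill()
    assert (cif_sum.dropna() <= 1.0 + 1e-9).all()


# ---------------------------------------------------------------------------
# moderation
# ---------------------------------------------------------------------------

def _moderated_frame(rng, n, slope0, slope1):
    x = rng.uniform(30, 95, size=n)
    m = rng.binomial(1, 0.5, size=n).astype(float)
    slope = np.where(m == 1, slope1, slope0)
    t_ev = rng.exponential(1 / (0.05 * np.exp(slope * (x - 60))))
    cens = np.minimum(rng.exponential(10, size=n), 10.0)
    t = np.minimum(t_ev, cens)
    return pd.DataFrame(
        {
            "time_years": t,
            "status": np.where(t_ev <= cens, "event", "censored"),
            "composite": x,
            "mod": m,
        }
    )


def test_lrt_interaction_null_not_significant():
    rng = np.random.default_rng(11)
    res = L.lrt_interaction(_moderated_frame(rng, 4000, -0.02, -0.02), "mod")
    assert res.chi_square >= 0
    assert res.p_value > 0.01


def test_lrt_interaction_detects_slope_difference():
    rng = np.random.default_rng(13)
    res = L.lrt_interaction(_moderated_frame(rng, 8000, -0.01, -0.04), "mod")
    assert res.p_value < 0.05


def test_lrt_interaction_requires_events_in_both_strata():
    rng = np.random.default_rng(5)
    df = _moderated_frame(rng, 500, -0.02, -0.02)
    df.loc[df["mod"] == 1, "status"] = "censored"
    with pytest.raises(EstimationError, match="no events"):
        L.lrt_interaction(df, "mod")
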