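"""Endpoint derivation from ICD-10 coded events, incidence rates, and
Kaplan-Meier machinery.

The two study endpoints are all-cause mortality and MACE (major adverse
cardiovascular events), the latter the first occurrence of ischaemic
heart disease I20-I25, myocardial infarction I21-I23, stroke
I60/I61/I63/I64, or heart failure I50.0/I50.1/I50.9.  Range and bare
three-character patterns include all decimal children; enumerated
patterns with decimals match exactly.  Atrial fibrillation (cohort
inclusion) is ICD-10 I48.

Follow-up is administratively truncated at the 10-year horizon; times
are stored internally in days and analysed in years (365.25 d/y).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import (
    DataConsistencyError,
    EstimationError,
    ParameterError,
    ValidationError,
)

DAYS_PER_YEAR = 365.25

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


@dataclass(frozen=True)
class EndpointDefinition:
    """Named endpoint with its ICD-10 code patterns.

    Patterns are either a (start, stop) three-character range such as
    ("I20", "I25") -- inclusive, covering decimal children -- a bare
    three-character code ("I61", children included), or an exact code
    with decimal ("I50.0").
    """

    name: str
    code_sets: tuple = ()


MACE = EndpointDefinition(
    name="mace",
    code_sets=(
        ("I20", "I25"),  # ischaemic heart disease (includes MI I21-I23)
        "I60",
        "I61",
        "I63",
        "I64",  # stroke
        "I50.0",
        "I50.1",
        "I50.9",  # heart failure
    ),
)

ALL_CAUSE_MORTALITY = EndpointDefinition(name="all_cause_mortality", code_sets=())

AF_INCLUSION = EndpointDefinition(name="atrial_fibrillation", code_sets=("I48",))

ENDPOINTS = {e.name: e for e in (ALL_CAUSE_MORTALITY, MACE, AF_INCLUSION)}


def classify_icd10(code: str, endpoint: EndpointDefinition) -> bool:
    """Whether an ICD-10 code belongs to the endpoint's code sets."""
    code = str(code).strip().upper()
    if not _ICD10_RE.match(code):
        raise ValidationError(f"malformed ICD-10 code: {code!r}")
    stem = code.split(".")[0]
    for pat in endpoint.code_sets:
        if isinstance(pat, tuple):
            lo, hi = pat
            if lo <= stem <= hi:
                return True
        elif "." in pat:
            if code == pat:
                return True
        else:
            if stem == pat:
                return True
    return False


def derive_survival(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    endpoint: EndpointDefinition,
    horizon_years: float = 10.0,
) -> pd.DataFrame:
    """Build per-participant survival records for one endpoint.

    Follow-up runs from baseline (day 0) to the first of: qualifying
    event, death, censoring, horizon.  For MACE, death without a prior
    qualifying event is recorded as ``competing_death``.  Prevalent
    events (day <= 0) exclude the participant; the count is reported in
    ``DataFrame.attrs["n_prevalent_excluded"]``.
    """
    horizon_days = horizon_years * DAYS_PER_YEAR
    censor = cohort["censor_day"].to_numpy(dtype=float)
    if np.any(~np.isfinite(censor)):
        raise ValidationError("censor_day: required for every participant")
    death = cohort["death_day"].to_numpy(dtype=float)  # NaN = alive

    if np.any(death > censor):
        bad = cohort.loc[death > censor, "id"].tolist()[:5]
        raise DataConsistencyError(
            f"death recorded after censoring date for ids {bad}"
        )

    if endpoint.name == "all_cause_mortality":
        event_day = death
        prevalent = np.zeros(len(cohort), dtype=bool)
    else:
        member = diagnoses["icd10"].map(
            lambda c: classify_icd10(c, endpoint)
        )
        qual = diagnoses[member]
        first = qual.groupby("id")["day"].min()
        event_day = (
            cohort["id"].map(first).to_numpy(dtype=float)
        )  # NaN = no qualifying code
        prevalent = np.nan_to_num(event_day, nan=np.inf) <= 0
        ev_after_censor = np.nan_to_num(event_day, nan=-np.inf) > censor
        if np.any(ev_after_censor & ~prevalent):
            bad = cohort.loc[ev_after_censor & ~prevalent, "id"].tolist()[:5]
            raise DataConsistencyError(
                f"event recorded after censoring date for ids {bad}"
            )

    ev = np.nan_to_num(event_day, nan=np.inf)
    de = np.nan_to_num(death, nan=np.inf)
    end_day = np.minimum.reduce([ev, de, censor, np.full_like(censor, horizon_days)])
    status = np.where(
        ev <= end_day,
        "event",
        np.where(
            (endpoint.name != "all_cause_mortality") & (de <= end_day),
            "competing_death",
            "censored",
        ),
    )
    out = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "time_years": np.maximum(end_day, 0.5) / DAYS_PER_YEAR,
            "status": status,
        }
    )
    keep = ~prevalent
    out = out.loc[keep].reset_index(drop=True)
    out.attrs["n_prevalent_excluded"] = int(prevalent.sum())
    out.attrs["endpoint"] = endpoint.name
    return out


def round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def rate_table(
    records: pd.DataFrame,
    group_col: str = "quartile",
    ci_method: str = "log",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Events, person-years, and incidence rates per 1000 person-years by
    group, with 95% Poisson confidence intervals.

    ``ci_method``: "log" (normal approximation on the log-rate scale,
    the default -- this reproduces the published tables), "count"
    (normal approximation on the event count), or "exact" (Garwood
    chi-square).  ``rate_1000py_rounded`` columns apply half-up integer
    rounding as printed.
    """
    from scipy import stats as sps

    z = sps.norm.ppf(1 - alpha / 2)
    rows = []
    for grp, sub in records.groupby(group_col, observed=False):
        events = int((sub["status"].astype(str) == "event").sum())
        py = float(sub["time_years"].sum())
        if py <= 0:
            raise EstimationError(f"zero person-years in group {grp}")
        rate = 1000.0 * events / py
        if events == 0:
            warnings.warn(
                f"group {grp}: no events; degenerate CI (0, 0)", stacklevel=2
            )
            lo = hi = 0.0
        elif ci_method == "log":
            lo = rate * np.exp(-z / np.sqrt(events))
            hi = rate * np.exp(z / np.sqrt(events))
        elif ci_method == "count":
            lo = 1000.0 * (events - z * np.sqrt(events)) / py
            hi = 1000.0 * (events + z * np.sqrt(events)) / py
        elif ci_method == "exact":
            lo = 1000.0 * sps.chi2.ppf(alpha / 2, 2 * events) / 2 / py
            hi = 1000.0 * sps.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2 / py
        else:
            raise ParameterError(f"unknown ci_method {ci_method!r}")
        rows.append(
            {
                "group": grp,
                "events": events,
                "person_years": py,
                "rate_per_1000": rate,
                "ci_low": lo,
                "ci_high": hi,
                "rate_1000py_rounded": int(round_half_up(rate)),
                "ci_low_rounded": int(round_half_up(lo)),
                "ci_high_rounded": int(round_half_up(hi)),
            }
        )
    return pd.DataFrame(rows)


def km_curve(records: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    ``group``: optional value of the ``quartile`` column to subset.
    Returns a step-function table (time, survival, at-risk, events);
    competing deaths are treated as censorings (cause-specific curve).
    """
    sub = records if group is None else records[records["quartile"] == group]
    if len(sub) == 0:
        raise EstimationError("no records for Kaplan-Meier curve")
    kmf = KaplanMeierFitter()
    kmf.fit(
        sub["time_years"],
        event_observed=(sub["status"].astype(str) == "event").astype(int),
    )
    tbl = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": tbl.index.to_numpy(dtype=float),
            "survival": surv.reindex(tbl.index).to_numpy(dtype=float),
            "at_risk": tbl["at_risk"].to_numpy(dtype=int),
            "events": tbl["observed"].to_numpy(dtype=int),
        }
    )
    return out


def landmark_filter(
    records: pd.DataFrame, landmark_years: float = 2.0, horizon_years: float = 10.0
) -> pd.DataFrame:
    """Landmark sensitivity filter: drop participants whose follow-up
    ended (event, competing death, or censoring) by the landmark;
    survivors are retained on the original time scale with delayed entry
    at the landmark (``entry_years`` column)."""
    if not (0 < landmark_years < horizon_years):
        raise ParameterError(
            f"landmark must lie in (0, {horizon_years}) years"
        )
    keep = records["time_years"].to_numpy(dtype=float) > landmark_years
    out = records.loc[keep].copy().reset_index(drop=True)
    out["entry_years"] = landmark_years
    out.attrs["n_landmark_excluded"] = int((~keep).sum())
    return out
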