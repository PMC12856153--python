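"""Life's Essential 8 component scoring, composite score, and quartiles.

Each of the eight cardiovascular-health components (diet, physical
activity, smoking, sleep, BMI, non-HDL cholesterol, HbA1c, blood
pressure) is scored 0-100 from raw measurements via the versioned band
rubric; the composite is the arithmetic mean of the eight component
scores.  The diet component is an adapted score: the number of healthy
food habits met (out of nine) is converted to cohort quartiles, which map
to {0, 100/3, 200/3, 100} points.

All scorers are vectorised: scalars in -> float out, arrays in -> ndarray
out.  Inputs outside the physiologic admissible range raise
:class:`~le8surv.errors.ValidationError` naming the variable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .rubric import Rubric, default_rubric

COMPONENTS = (
    "diet",
    "physical_activity",
    "smoking",
    "sleep",
    "bmi",
    "non_hdl",
    "hba1c",
    "blood_pressure",
)

#: mmol/L -> mg/dL for cholesterol
MGDL_PER_MMOL = 38.67

N_DIET_ITEMS = 9
DIET_ITEM_NAMES = (
    "processed_meat",
    "red_meat",
    "fish",
    "alcohol",
    "spread",
    "cereal",
    "salt",
    "water",
    "fruit_veg",
)
DIET_ITEM_COLUMNS = tuple(f"diet_{name}" for name in DIET_ITEM_NAMES)

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def _asarray(x, name):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: non-finite value encountered")
    return arr


def _check_range(arr, name, lo, hi):
    if np.any((arr < lo) | (arr > hi)):
        raise ValidationError(
            f"{name}: value outside admissible range [{lo}, {hi}]"
        )


def _scalarize(out, *inputs):
    if all(np.ndim(i) == 0 for i in inputs if i is not None):
        return float(out)
    return out


def ifcc_to_ngsp_percent(hba1c_mmol_mol):
    """Convert HbA1c from IFCC mmol/mol to NGSP percent."""
    return 0.09148 * np.asarray(hba1c_mmol_mol, dtype=float) + 2.152


def non_hdl_from_lipids(total_mmol_l, hdl_mmol_l):
    """Non-HDL cholesterol as total minus HDL (mmol/L), for sources that
    do not report non-HDL directly."""
    total = _asarray(total_mmol_l, "total_cholesterol_mmol_L")
    hdl = _asarray(hdl_mmol_l, "hdl_mmol_L")
    out = total - hdl
    if np.any(out <= 0):
        raise ValidationError("non_hdl_mmol_L: total must exceed HDL")
    return _scalarize(out, total_mmol_l, hdl_mmol_l)


# ---------------------------------------------------------------------------
# component scorers
# ---------------------------------------------------------------------------

def score_smoking(status, quit_years=None, rubric: Rubric | None = None):
    """Score smoking exposure: never 100, current 0, former graded by
    years since quitting (>=5y: 75, 1-<5y: 50, <1y: 25)."""
    rub = rubric or default_rubric()
    status_arr = np.asarray(status)
    scalar = status_arr.ndim == 0
    status_arr = np.atleast_1d(status_arr).astype(object)
    valid = {"never", "former", "current"}
    bad = set(np.unique(status_arr.astype(str))) - valid
    if bad:
        raise ValidationError(f"smoking_status: unknown categories {sorted(bad)}")

    qy = np.full(status_arr.shape, np.nan)
    if quit_years is not None:
        qy_in = np.atleast_1d(np.asarray(quit_years, dtype=float))
        qy = np.broadcast_to(qy_in, status_arr.shape).copy()
    former = status_arr == "former"
    if np.any(former & ~np.isfinite(qy)):
        raise ValidationError(
            "quit_years: required for former smokers but missing"
        )
    pts = np.full(status_arr.shape, np.nan)
    pts[status_arr == "never"] = rub.categories[("smoking", "never")]
    pts[status_arr == "current"] = rub.categories[("smoking", "current")]
    if np.any(former):
        qv = np.clip(qy[former], 0.0, np.inf)
        pts[former] = rub.bands[("smoking", "quit_years")].lookup(qv)
    out = pts if not scalar else float(pts[0])
    return out


def score_bmi(bmi, rubric: Rubric | None = None):
    rub = rubric or default_rubric()
    arr = _asarray(bmi, "bmi_kg_m2")
    _check_range(arr, "bmi_kg_m2", 10.0, 80.0)
    return _scalarize(rub.bands[("bmi", "bmi_kg_m2")].lookup(arr), bmi)


def score_physical_activity(met_min_week, rubric: Rubric | None = None):
    rub = rubric or default_rubric()
    arr = _asarray(met_min_week, "met_min_week")
    _check_range(arr, "met_min_week", 0.0, np.inf)
    return _scalarize(
        rub.bands[("physical_activity", "met_min_week")].lookup(arr),
        met_min_week,
    )


def score_sleep(hours, rubric: Rubric | None = None):
    rub = rubric or default_rubric()
    arr = _asarray(hours, "sleep_hours")
    if np.any((arr <= 0) | (arr >= 24)):
        raise ValidationError("sleep_hours: must lie strictly in (0, 24)")
    return _scalarize(rub.bands[("sleep", "sleep_hours")].lookup(arr), hours)


def score_blood_pressure(sbp, dbp, treated=False, rubric: Rubric | None = None):
    """Score blood pressure from the higher-risk of the SBP/DBP bands, with
    the rubric's treatment deduction when on antihypertensives."""
    rub = rubric or default_rubric()
    s = _asarray(sbp, "sbp_mmHg")
    d = _asarray(dbp, "dbp_mmHg")
    _check_range(s, "sbp_mmHg", 60.0, 260.0)
    _check_range(d, "dbp_mmHg", 30.0, 180.0)
    pts = np.minimum(
        rub.bands[("blood_pressure", "sbp_mmHg")].lookup(s),
        rub.bands[("blood_pressure", "dbp_mmHg")].lookup(d),
    )
    tr = np.asarray(treated, dtype=bool)
    pts = np.clip(pts + np.where(tr, rub.deductions["blood_pressure"], 0.0), 0, 100)
    return _scalarize(pts, sbp, dbp)


def score_non_hdl(non_hdl_mmol_l, treated=False, rubric: Rubric | None = None):
    """Score non-HDL cholesterol (input mmol/L; rubric bands in mg/dL),
    with the lipid-lowering treatment deduction."""
    rub = rubric or default_rubric()
    arr = _asarray(non_hdl_mmol_l, "non_hdl_mmol_L")
    _check_range(arr, "non_hdl_mmol_L", 0.3, 20.0)
    pts = rub.bands[("non_hdl", "non_hdl_mg_dl")].lookup(arr * MGDL_PER_MMOL)
    tr = np.asarray(treated, dtype=bool)
    pts = np.clip(pts + np.where(tr, rub.deductions["non_hdl"], 0.0), 0, 100)
    return _scalarize(pts, non_hdl_mmol_l)


def score_hba1c(hba1c_mmol_mol, diabetic=False, rubric: Rubric | None = None):
    """Score glycaemic control from HbA1c (mmol/mol).  Participants with
    diagnosed diabetes (or HbA1c in the diabetic range, >=6.5% NGSP) are
    scored on the diabetes bands."""
    rub = rubric or default_rubric()
    arr = _asarray(hba1c_mmol_mol, "hba1c_mmol_mol")
    _check_range(arr, "hba1c_mmol_mol", 10.0, 200.0)
    pct = ifcc_to_ngsp_percent(arr)
    dia = np.broadcast_to(np.asarray(diabetic, dtype=bool), np.shape(pct)) | (
        pct >= 6.5
    )
    pts = np.where(
        dia,
        rub.bands[("hba1c", "hba1c_pct_diabetes")].lookup(pct),
        rub.bands[("hba1c", "hba1c_pct_no_diabetes")].lookup(np.clip(pct, None, 6.4999)),
    )
    return _scalarize(pts, hba1c_mmol_mol)


def diet_items_met(items) -> np.ndarray:
    """Count healthy habits met from nine binary indicators.

    ``items`` is an (n, 9) array-like (or length-9 vector) of 0/1 flags,
    one per food habit; missing values are rejected (complete-case rule).
    """
    arr = np.asarray(items, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != N_DIET_ITEMS:
        raise ValidationError(
            f"diet_items: expected {N_DIET_ITEMS} indicators, got {arr.shape[1]}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError("diet_items: missing value (complete-case rule)")
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValidationError("diet_items: indicators must be 0/1")
    met = arr.sum(axis=1).astype(int)
    return met[0] if single else met


def score_diet(items, cohort_items_met, rubric: Rubric | None = None):
    """Score the adapted diet component.

    ``items``: nine 0/1 indicators (one participant) or (n, 9) array;
    ``cohort_items_met``: the cohort distribution of items-met counts
    against which quartiles are formed.
    """
    rub = rubric or default_rubric()
    met = np.atleast_1d(diet_items_met(items))
    dist = np.asarray(cohort_items_met, dtype=float)
    if dist.size == 0:
        raise ValidationError("cohort_items_met: empty cohort distribution")
    q = diet_quartile(met, dist)
    pts = np.asarray(rub.diet_quartile_points, dtype=float)[q - 1]
    if np.asarray(items).ndim == 1:
        return float(pts[0])
    return pts


def diet_quartile(items_met, cohort_items_met) -> np.ndarray:
    """Quartile (1..4) of an items-met count within the cohort distribution.

    Boundary ties resolve to the *upper* quartile so that a perfect count
    of nine always lands in the top quartile (scores 100) even when the
    cohort is saturated at nine.
    """
    dist = np.sort(np.asarray(cohort_items_met, dtype=float))
    n = dist.size
    if n < 4:
        raise ValidationError("cohort_items_met: need at least 4 values")
    base, rem = divmod(n, 4)
    sizes = [base + (1 if k < rem else 0) for k in range(4)]
    starts = np.cumsum(sizes)[:3]  # first index of groups 2, 3, 4
    u1, u2, u3 = (float(dist[i]) for i in starts)
    v = np.atleast_1d(np.asarray(items_met, dtype=float))
    return (1 + (v >= u1).astype(int) + (v >= u2) + (v >= u3)).astype(int)


# ---------------------------------------------------------------------------
# composite and quartiles
# ---------------------------------------------------------------------------

def composite_le8(components) -> np.ndarray | float:
    """Arithmetic mean of the eight component scores.

    ``components``: mapping/DataFrame with exactly the eight component
    names as keys/columns (order-invariant), values in [0, 100].
    """
    if isinstance(components, pd.DataFrame):
        comp = {c: components[c].to_numpy(dtype=float) for c in components.columns}
    else:
        comp = {k: np.asarray(v, dtype=float) for k, v in dict(components).items()}
    got = set(comp)
    want = set(COMPONENTS)
    if got != want:
        missing, extra = sorted(want - got), sorted(got - want)
        raise ValidationError(
            f"components: expected the eight domains; missing={missing}, "
            f"unexpected={extra}"
        )
    stack = np.stack([comp[c] for c in COMPONENTS], axis=0)
    if np.any((stack < 0) | (stack > 100)):
        raise ValidationError("components: points must lie in [0, 100]")
    out = stack.mean(axis=0)
    return float(out) if out.ndim == 0 else out


def quartile_cutpoints(values) -> np.ndarray:
    """Value cut-points implied by rank-based quartile allocation.

    Group sizes are ``n//4`` with the remainder allocated to the lowest
    quartiles (so with all-distinct values sizes differ by at most one and
    the lower quartiles are the larger); ties at a boundary fall to the
    lower quartile.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 4:
        raise ValidationError("quartiles: need at least 4 values")
    base, rem = divmod(n, 4)
    sizes = [base + (1 if k < rem else 0) for k in range(4)]
    idx = np.cumsum(sizes)[:3] - 1
    return v[idx]


def value_quartile(values, cuts) -> np.ndarray:
    """Map values to quartile 1..4 given cut-points (<= cut -> lower)."""
    v = np.asarray(values, dtype=float)
    c1, c2, c3 = (float(c) for c in cuts)
    return (1 + (v > c1).astype(int) + (v > c2) + (v > c3)).astype(int)


def assign_quartiles(composites) -> pd.Categorical:
    """Assign cohort quartile labels Q1 (least healthy) .. Q4 (healthiest).

    Degenerate all-tied input collapses to Q1 with a warning.
    """
    v = np.asarray(composites, dtype=float)
    if v.size < 4:
        raise ValidationError("quartiles: need at least 4 values")
    if not np.all(np.isfinite(v)):
        raise ValidationError("composites: non-finite value")
    cuts = quartile_cutpoints(v)
    if cuts[0] == cuts[2] and np.all(v <= cuts[0]):
        warnings.warn(
            "degenerate quartile assignment: all values tied; assigning Q1",
            stacklevel=2,
        )
    q = value_quartile(v, cuts)
    labels = np.array(QUARTILE_LABELS, dtype=object)[q - 1]
    return pd.Categorical(labels, categories=list(QUARTILE_LABELS), ordered=True)


# ---------------------------------------------------------------------------
# cohort-level convenience
# ---------------------------------------------------------------------------

def score_cohort(cohort: pd.DataFrame, rubric: Rubric | None = None) -> pd.DataFrame:
    """Score every participant of a cohort table.

    Expects the cohort CSV schema produced by
    :func:`le8surv.cohort.generate_cohort`.  Returns a DataFrame with the
    participant id, the eight component scores, the composite, and the
    cohort quartile (Q1 least healthy .. Q4 healthiest).
    """
    rub = rubric or default_rubric()
    items = cohort[list(DIET_ITEM_COLUMNS)].to_numpy()
    met = diet_items_met(items)
    diabetic = cohort["comorb_type2_diabetes"].astype(bool) | cohort[
        "on_glucose_lowering"
    ].astype(bool)
    scores = pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "diet": score_diet(items, met, rub),
            "physical_activity": score_physical_activity(
                cohort["met_min_week"].to_numpy(), rub
            ),
            "smoking": score_smoking(
                cohort["smoking_status"].to_numpy(),
                cohort["quit_years"].to_numpy(),
                rub,
            ),
            "sleep": score_sleep(cohort["sleep_hours"].to_numpy(), rub),
            "bmi": score_bmi(cohort["bmi_kg_m2"].to_numpy(), rub),
            "non_hdl": score_non_hdl(
                cohort["non_hdl_mmol_l"].to_numpy(),
                cohort["on_lipid_lowering"].astype(bool).to_numpy(),
                rub,
            ),
            "hba1c": score_hba1c(
                cohort["hba1c_mmol_mol"].to_numpy(), diabetic.to_numpy(), rub
            ),
            "blood_pressure": score_blood_pressure(
                cohort["sbp_mmHg"].to_numpy(),
                cohort["dbp_mmHg"].to_numpy(),
                cohort["on_antihypertensive"].astype(bool).to_numpy(),
                rub,
            ),
        }
    )
    scores["composite"] = composite_le8(scores[list(COMPONENTS)])
    scores["quartile"] = assign_quartiles(scores["composite"].to_numpy())
    return scores
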