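"""Component scoring, composite, and quartile assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import le8surv as L
from le8surv.errors import ValidationError
from le8surv.scoring import diet_quartile, ifcc_to_ngsp_percent

# ---------------------------------------------------------------------------
# independent band-table oracle (coded separately from the rubric CSV)
# ---------------------------------------------------------------------------

def oracle_bmi(b):
    if b < 25: return 100
    if b < 30: return 70
    if b < 35: return 30
    if b < 40: return 15
    return 0

def oracle_pa(m):
    if m >= 600: return 100
    if m >= 480: return 90
    if m >= 360: return 80
    if m >= 240: return 60
    if m >= 120: return 40
    if m >= 4: return 20
    return 0

def oracle_sleep(h):
    if 7 <= h < 9: return 100
    if 9 <= h < 10: return 90
    if 6 <= h < 7: return 70
    if 5 <= h < 6 or h >= 10: return 40
    if 4 <= h < 5: return 20
    return 0

def oracle_bp(s, d, treated):
    if s >= 160 or d >= 100: pts = 0
    elif s >= 140 or d >= 90: pts = 25
    elif s >= 130 or d >= 80: pts = 50
    elif s >= 120: pts = 75
    else: pts = 100
    return max(pts - (20 if treated else 0), 0)

def oracle_nonhdl(mmol, treated):
    mg = mmol * 38.67
    if mg < 130: pts = 100
    elif mg < 160: pts = 60
    elif mg < 190: pts = 40
    elif mg < 220: pts = 20
    else: pts = 0
    return max(pts - (20 if treated else 0), 0)

def oracle_hba1c(mmol_mol, diabetic):
    # published NGSP regression (same convention the package adopts)
    pct = 0.09148 * mmol_mol + 2.152
    if not diabetic and pct < 6.5:
        return 100 if pct < 5.7 else 60
    if pct < 7: return 40
    if pct < 8: return 30
    if pct < 9: return 20
    if pct < 10: return 10
    return 0

def oracle_smoking(status, qy):
    if status == "never": return 100
    if status == "current": return 0
    if qy >= 5: return 75
    if qy >= 1: return 50
    return 25


def test_component_scorers_match_independent_band_oracle():
    """Rubric lookup agrees with a brute-force band table on 10,000
    random physiologic inputs per component."""
    rng = np.random.default_rng(42)
    n = 10_000
    bmi = rng.uniform(10, 79.9, n)
    assert np.array_equal(L.score_bmi(bmi), [oracle_bmi(b) for b in bmi])
    met = rng.uniform(0, 5000, n)
    assert np.array_equal(
        L.score_physical_activity(met), [oracle_pa(m) for m in met]
    )
    hrs = rng.uniform(0.1, 23.9, n)
    assert np.array_equal(L.score_sleep(hrs), [oracle_sleep(h) for h in hrs])
    sbp = rng.uniform(60, 259, n)
    dbp = rng.uniform(30, 179, n)
    tr = rng.random(n) < 0.5
    assert np.array_equal(
        L.score_blood_pressure(sbp, dbp, tr),
        [oracle_bp(s, d, t) for s, d, t in zip(sbp, dbp, tr)],
    )
    chol = rng.uniform(0.5, 10, n)
    assert np.array_equal(
        L.score_non_hdl(chol, tr), [oracle_nonhdl(c, t) for c, t in zip(chol, tr)]
    )
    a1c = rng.uniform(15, 130, n)
    dia = rng.random(n) < 0.2
    mine = L.score_hba1c(a1c, dia)
    ref = np.array([oracle_hba1c(a, d) for a, d in zip(a1c, dia)])
    assert np.array_equal(mine, ref)


@pytest.mark.parametrize(
    "status,qy,expected",
    [("never", None, 100), ("current", None, 0), ("former", 6.0, 75),
     ("former", 2.0, 50), ("former", 0.5, 25)],
)
def test_smoking_bands(status, qy, expected):
    assert L.score_smoking(status, qy) == expected


def test_smoking_former_requires_quit_years():
    with pytest.raises(ValidationError, match="quit_years"):
        L.score_smoking("former", None)


@pytest.mark.parametrize(
    "fn,args,match",
    [
        (L.score_bmi, (9.0,), "bmi"),
        (L.score_bmi, (np.nan,), "bmi"),
        (L.score_sleep, (24.0,), "sleep"),
        (L.score_physical_activity, (-1.0,), "met"),
        (L.score_blood_pressure, (300.0, 80.0), "sbp"),
    ],
)
def test_out_of_range_inputs_name_the_variable(fn, args, match):
    with pytest.raises(ValidationError, match=match):
        fn(*args)


def test_boundary_examples():
    assert L.score_bmi(24.0) == 100 and L.score_bmi(41.0) == 0
    assert L.score_blood_pressure(115, 75, False) == 100
    assert L.score_physical_activity(0.0) == 0


@given(st.floats(10, 79), st.floats(10, 79))
@settings(max_examples=200, derandomize=True)
def test_scorers_monotone_health_protective(a, b):
    """Each scorer is monotone in the health-protective direction."""
    lo, hi = min(a, b), max(a, b)
    assert L.score_bmi(lo) >= L.score_bmi(hi)  # lower BMI never worse
    m_lo, m_hi = 600 * lo / 79, 600 * hi / 79
    assert L.score_physical_activity(m_hi) >= L.score_physical_activity(m_lo)
    assert L.score_smoking("never") >= L.score_smoking("former", hi) >= \
        L.score_smoking("current")


# ---------------------------------------------------------------------------
# diet
# ---------------------------------------------------------------------------

def test_diet_quartile_examples():
    dist = [1, 2, 3, 4, 5, 6, 7, 8]
    assert diet_quartile(5, dist) == 3  # third quartile -> 200/3 points
    items = np.zeros(9); items[:5] = 1
    assert L.score_diet(items, dist) == pytest.approx(200 / 3)
    assert L.score_diet(np.ones(9), dist) == 100
    assert L.score_diet(np.zeros(9), dist) == 0
    # maximum count lands in the top quartile even in a saturated cohort
    assert L.score_diet(np.ones(9), [9] * 20) == 100


def test_diet_missing_item_rejected():
    items = np.ones(9); items[3] = np.nan
    with pytest.raises(ValidationError, match="diet"):
        L.score_diet(items, [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# composite and quartiles
# ---------------------------------------------------------------------------

def test_composite_examples_and_symmetry():
    comp = {c: 100.0 for c in L.COMPONENTS}
    assert L.composite_le8(comp) == 100
    vals = dict(zip(L.COMPONENTS, [80, 80, 80, 80, 60, 60, 60, 60]))
    assert L.composite_le8(vals) == 70
    shuffled = dict(reversed(list(vals.items())))
    assert L.composite_le8(shuffled) == L.composite_le8(vals)


def test_composite_rejects_wrong_domains():
    bad = {c: 50.0 for c in L.COMPONENTS[:-1]}
    with pytest.raises(ValidationError, match="missing"):
        L.composite_le8(bad)
    worse = dict(bad, extra=50.0)
    with pytest.raises(ValidationError):
        L.composite_le8(worse)


def test_quartile_small_example():
    q = L.assign_quartiles(np.arange(1, 9))
    assert list(q) == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]


def test_quartile_bookkeeping_study_size():
    """23,758 distinct values split 5940/5940/5939/5939 (largest
    remainders to the lowest quartiles)."""
    rng = np.random.default_rng(0)
    q = L.assign_quartiles(rng.permutation(23758).astype(float))
    counts = pd.Series(q).value_counts().sort_index()
    assert counts.tolist() == [5940, 5940, 5939, 5939]


def test_quartile_all_tied_degenerates_to_q1_with_warning():
    with pytest.warns(UserWarning, match="degenerate"):
        q = L.assign_quartiles(np.full(10, 5.0))
    assert set(q) == {"Q1"}


def test_quartile_requires_four_values():
    with pytest.raises(ValidationError):
        L.assign_quartiles([1.0, 2.0, 3.0])


@given(st.lists(st.floats(0, 100, allow_nan=False), min_size=8, max_size=60,
                unique=True))
@settings(max_examples=100, derandomize=True)
def test_quartile_sizes_differ_by_at_most_one_for_distinct_values(vals):
    counts = pd.Series(L.assign_quartiles(np.array(vals))).value_counts()
    assert counts.max() - counts.min() <= 1
    # ordering: every Q1 value below every Q4 value
    arr = np.array(vals)
    labels = np.asarray(L.assign_quartiles(arr))
    if "Q4" in labels and "Q1" in labels:
        assert arr[labels == "Q1"].max() < arr[labels == "Q4"].min()


def test_hba1c_unit_conversion_roundtrip():
    # 37.7 mmol/mol (cohort mean) is ~5.6% NGSP, below the prediabetic cut
    assert 5.5 < ifcc_to_ngsp_percent(37.7) < 5.7


def test_score_cohort_schema(scored):
    assert set(L.COMPONENTS) < set(scored.columns)
    assert scored["composite"].between(0, 100).all()
    comp = scored[list(L.COMPONENTS)].mean(axis=1)
    assert np.allclose(comp, scored["composite"])


def test_non_hdl_from_lipids():
    assert L.non_hdl_from_lipids(5.4, 1.4) == pytest.approx(4.0)
    with pytest.raises(ValidationError, match="total must exceed"):
        L.non_hdl_from_lipids(1.0, 1.4)
    arr = L.non_hdl_from_lipids(np.array([5.0, 6.0]), np.array([1.2, 1.5]))
    assert np.allclose(arr, [3.8, 4.5])
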