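"""Cleaning rules, task metrics, filters, screening and ICC."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_trials, reference_rcs

from efbattery.battery import default_battery
from efbattery.engine import NO_RESPONSE
from efbattery.scoring import (
    CleaningConfig,
    clean_trials,
    icc,
    mad_outlier_filter,
    residualize,
    score_task,
    screen_participants,
    transform_rt_metric,
    validity_filter,
)


# ---------------------------------------------------------------------------
# Trial cleaning
# ---------------------------------------------------------------------------


def test_anticipatory_stage_removes_planted_trials(rng):
    rts = list(rng.uniform(300, 600, size=93)) + [50, 100, 120, 150, 180, 190, 199]
    rows = [("a", "a", rt) for rt in rts]
    trials = make_trials(rows)
    cleaned, tally = clean_trials(trials)
    assert len(trials) - len(cleaned) == 7
    assert tally.loc[tally["stage"] == "anticipatory", "count"].sum() == 7


def test_zero_sd_removes_nothing():
    trials = make_trials([("a", "a", 500.0)] * 10)
    cleaned, tally = clean_trials(trials)
    assert len(cleaned) == 10 and tally.empty


def test_cleaning_matches_brute_force_two_pass(rng):
    rts = rng.lognormal(np.log(450), 0.6, size=300)
    trials = make_trials([("a", "a", float(rt)) for rt in rts])
    cleaned, tally = clean_trials(trials)
    # naive reference: anticipatory first, then +/-3 SD on the survivors
    surv = [rt for rt in rts if rt >= 200]
    m, s = np.mean(surv), np.std(surv, ddof=1)
    expected = [rt for rt in surv if abs(rt - m) <= 3 * s]
    assert sorted(cleaned["rt_ms"]) == pytest.approx(sorted(expected))
    # removal tallies conserve the trial count
    assert len(trials) == len(cleaned) + tally["count"].sum()


def test_omissions_pass_through_cleaning():
    trials = make_trials([("a", "a", 500.0)] * 6 + [("a", NO_RESPONSE, None)])
    cleaned, _ = clean_trials(trials)
    assert cleaned["rt_ms"].isna().sum() == 1


# ---------------------------------------------------------------------------
# Task metrics
# ---------------------------------------------------------------------------


def test_rcs_formula_unit_cases():
    # 8 correct of 10, total RT 20 s -> 0.4 correct/s
    rows = [("a", "a", 2000.0)] * 8 + [("a", "b", 2000.0)] * 2
    assert score_task(make_trials(rows), "rcs") == pytest.approx(0.4)
    # all correct at 1 s each -> 1.0
    rows = [("a", "a", 1000.0)] * 12
    assert score_task(make_trials(rows), "rcs") == pytest.approx(1.0)


def test_rcs_matches_spreadsheet_oracle(rng):
    rows = []
    for _ in range(60):
        correct = rng.uniform() < 0.8
        rows.append(("a", "a" if correct else "b",
                     float(rng.uniform(250, 900))))
    trials = make_trials(rows)
    assert score_task(trials, "rcs") == pytest.approx(reference_rcs(rows))


def test_rcs_literal_product_reading():
    rows = [("a", "a", 1000.0)] * 10
    cfg = CleaningConfig(rcs_literal_product=True)
    assert score_task(make_trials(rows), "rcs", cfg) == pytest.approx(0.1)


def test_rcs_excludes_omissions_from_denominator():
    rows = [("a", "a", 1000.0)] * 5 + [("a", NO_RESPONSE, None)] * 5
    assert score_task(make_trials(rows), "rcs") == pytest.approx(1.0)


def test_mean_correct_rt_uses_correct_trials_only():
    rows = [("a", "a", 400.0), ("a", "a", 600.0), ("a", "b", 10_000.0)]
    assert score_task(make_trials(rows), "mean_correct_rt") == pytest.approx(500.0)
    rows = [("a", "b", 400.0)]
    assert np.isnan(score_task(make_trials(rows), "mean_correct_rt"))


def test_object_span_from_trials():
    rows = [("correct", "correct", 1000.0, "len3"),
            ("correct", "correct", 1000.0, "len3"),
            ("correct", "correct", 1000.0, "len4"),
            ("correct", "incorrect", 1000.0, "len4")]
    assert score_task(make_trials(rows, task="span_fwd"), "object_span") == 4


# ---------------------------------------------------------------------------
# Score filters
# ---------------------------------------------------------------------------


def test_validity_filter_rules():
    scores = pd.Series({"p1": 1.0, "p2": 1.0, "p3": 1.0, "p4": 1.0})
    counts = {"p1": {"c": 10}, "p2": {"c": 4}, "p3": {"c": 10}, "p4": {"c": 10}}
    accs = {"p1": 0.9, "p2": 0.9, "p3": 0.20, "p4": 0.25}
    chance = {p: 0.25 for p in scores.index}   # four response options
    out, dropped = validity_filter(scores, counts, accs, chance)
    assert sorted(dropped) == ["p2", "p3"]     # few trials; below chance
    assert not np.isnan(out["p4"])             # exactly at chance retained
    assert np.isnan(out["p2"]) and np.isnan(out["p3"])


def test_mad_filter_drops_gross_outlier():
    col = pd.Series([1.0, 2.0, 3.0, 4.0, 100.0])
    keep = mad_outlier_filter(col)
    assert list(keep) == [True, True, True, True, False]


def test_mad_filter_zero_mad_removes_nothing():
    col = pd.Series([5.0] * 10 + [100.0])
    assert mad_outlier_filter(col).all()


def test_mad_filter_normal_removal_fraction(rng):
    """Removal rate under normality matches the two-sided tail beyond
    3 * 1.4826 * MAD ~ 3 SD (MAD consistency), i.e. ~0.27%."""
    x = pd.Series(rng.standard_normal(10000))
    frac = 1.0 - mad_outlier_filter(x).mean()
    from scipy import stats
    # oracle: P(|Z| > 3 * 1.4826 * MAD(Z)) with MAD estimated from the data
    med = x.median()
    mad = (x - med).abs().median()
    expected = ((x - med).abs() > 3 * 1.4826 * mad).mean()
    assert frac == pytest.approx(expected, abs=1e-12)
    assert frac == pytest.approx(2 * stats.norm.sf(3), abs=0.002)


def test_residualize_properties(rng):
    x = pd.Series(rng.normal(size=200))
    # perfectly linear -> zero residuals
    y = 3.0 * x + 2.0
    assert np.allclose(residualize(y, x), 0.0, atol=1e-12)
    # random data -> residuals orthogonal to covariate
    y2 = pd.Series(rng.normal(size=200))
    r = residualize(y2, x)
    assert abs(np.corrcoef(r, x)[0, 1]) < 1e-10
    # constant covariate -> centred scores
    c = pd.Series(np.ones(200))
    assert np.allclose(residualize(y2, c), y2 - y2.mean())


def test_transform_rt_metric():
    assert transform_rt_metric(500.0) == pytest.approx(-5.0)
    assert transform_rt_metric(0.0) == 0.0
    assert transform_rt_metric(400.0) > transform_rt_metric(600.0)  # faster wins


def test_screening_rules():
    meta = pd.DataFrame({
        "high_risk_location": [True, False, False, False],
        "moderate_risk_a": [False, True, True, False],
        "moderate_risk_b": [False, True, True, False],
        "moderate_risk_c": [False, True, True, False],
        "moderate_risk_d": [False, False, True, False],
    }, index=["p1", "p2", "p3", "p4"])
    out = screen_participants(meta)
    assert not out.loc["p1", "keep"]                     # any high risk
    assert out.loc["p2", "keep"]                         # 3 moderate: retained
    assert not out.loc["p3", "keep"]                     # 4 moderate: excluded
    assert out.loc["p4", "keep"]
    assert out.loc["p1", "reason"] == "high_risk_indicator"


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def test_icc_identical_sessions():
    s = pd.Series(np.arange(10, dtype=float))
    res = icc(s, s)
    assert res.icc == pytest.approx(1.0)
    assert res.quality == "excellent"


def test_icc_null_sessions(rng):
    s1 = pd.Series(rng.normal(size=1000))
    s2 = pd.Series(rng.normal(size=1000))
    assert abs(icc(s1, s2).icc) < 0.07


def test_icc_requires_three_pairs():
    with pytest.raises(ValueError):
        icc(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))


def test_icc_matches_pingouin():
    """Cross-check the ANOVA closed form against pingouin's ICC2."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    truth = rng.standard_normal(40)
    s1 = truth + 0.5 * rng.standard_normal(40)
    s2 = truth + 0.5 * rng.standard_normal(40) + 0.2
    res = icc(pd.Series(s1), pd.Series(s2))
    long = pd.DataFrame({
        "targets": np.r_[np.arange(40), np.arange(40)],
        "raters": ["a"] * 40 + ["b"] * 40,
        "ratings": np.r_[s1, s2],
    })
    ref = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                   ratings="ratings")
    ref2 = ref.loc[ref["Type"] == "ICC(A,1)"].iloc[0]
    assert res.icc == pytest.approx(float(ref2["ICC"]), abs=1e-10)


def test_icc_closed_form_on_balanced_fixture():
    """Hand-computable variance-components fixture."""
    s1 = pd.Series([1.0, 2.0, 3.0, 4.0])
    s2 = pd.Series([1.0, 2.0, 3.0, 4.0]) + 1.0
    res = icc(s1, s2)
    # subjects perfectly ordered, constant session offset of 1:
    # MSR = 2*var(subject means), MSE = 0, MSC = n/ (k-1) * offset^2 / 2 ...
    # with zero error the absolute-agreement ICC is var_r/(var_r + var_c)
    msr = 2 * np.var([1.5, 2.5, 3.5, 4.5], ddof=1)
    msc = 4 * np.var([2.5, 3.5], ddof=1)
    expected = (msr - 0) / (msr + 0 + 2 * (msc - 0) / 4)
    assert res.icc == pytest.approx(expected, abs=1e-12)
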