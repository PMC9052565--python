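"""Kaplan-Meier estimator, log-rank test, Cox hazard ratios and the
subgroup analysis, each checked against hand oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cabanet as cb

# the classic 21-subject remission-time series: 9 observed events,
# 12 right-censored subjects
TOY_TIMES = np.array([6, 6, 6, 7, 10, 13, 16, 22, 23,
                      6, 9, 10, 11, 17, 19, 20, 25, 32, 32, 34, 35], float)
TOY_EVENTS = np.array([1] * 9 + [0] * 12, float)


def km_oracle(times, events):
    """Hand product-limit estimate: S at each distinct event time."""
    times, events = np.asarray(times, float), np.asarray(events, float)
    out = {}
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= (n_risk - d) / n_risk
        out[t] = s
    return out


def logrank_oracle(t1, e1, t2, e2):
    """Direct observed-minus-expected hypergeometric sum for two groups."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    u = v = 0.0
    for t in np.unique(times[events == 1]):
        at = times >= t
        n, n1 = at.sum(), (at & (grp == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (grp == 0)).sum()
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return u * u / v


def test_km_two_subject_hand_case():
    curve = cb.km_curve([10.0, 20.0], [1.0, 0.0])
    assert curve.survival_at(10) == pytest.approx(0.5)
    assert curve.survival_at(20) == pytest.approx(0.5)
    assert curve.median == pytest.approx(10.0)


def test_km_matches_hand_product_limit_on_classic_toy():
    curve = cb.km_curve(TOY_TIMES, TOY_EVENTS)
    oracle = km_oracle(TOY_TIMES, TOY_EVENTS)
    for t, s in oracle.items():
        assert curve.survival_at(t) == pytest.approx(s, abs=1e-10)
    # a few frozen fractions from the hand table
    assert curve.survival_at(6) == pytest.approx(18 / 21, abs=1e-12)
    assert curve.survival_at(10) == pytest.approx((18 / 21) * (16 / 17) * (14 / 15),
                                                  abs=1e-12)
    assert curve.survival_at(23) == pytest.approx(0.448179271708683, abs=1e-10)
    # censoring keeps the median above the last event-time drop to <= 0.5
    assert not np.isfinite(curve.median) or curve.median >= 23


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, size=200).round(2) + 0.01
    curve = cb.km_curve(t, np.ones_like(t))
    for q in (5.0, 10.0, 20.0):
        assert curve.survival_at(q) == pytest.approx(np.mean(t > q), abs=1e-12)


def test_km_all_censored_median_flagged():
    curve = cb.km_curve([5.0, 8.0, 9.0], [0.0, 0.0, 0.0])
    assert not curve.median_defined
    assert np.isnan(curve.median)
    assert curve.survival_at(9.0) == pytest.approx(1.0)


def test_km_median_ci_contains_median(default_cohort):
    table, _ = default_cohort
    curve = cb.km_curve(table.os_days, table.os_event)
    lo, hi = curve.median_ci
    assert lo <= curve.median <= hi


def test_km_invariant_to_input_order():
    rng = np.random.default_rng(3)
    t = rng.exponential(30, 100) + 1
    e = rng.integers(0, 2, 100).astype(float)
    c1 = cb.km_curve(t, e)
    perm = rng.permutation(100)
    c2 = cb.km_curve(t[perm], e[perm])
    np.testing.assert_allclose(c1.survival, c2.survival)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_km_survival_is_monotone_probability(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 60))
    t = rng.exponential(20, n) + 0.1
    e = rng.integers(0, 2, n).astype(float)
    curve = cb.km_curve(t, e)
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all((curve.survival >= -1e-12) & (curve.survival <= 1 + 1e-12))
    assert np.all(np.diff(curve.at_risk) <= 0)


def test_logrank_identical_groups_null():
    t = np.arange(1.0, 31.0)
    e = np.ones_like(t)
    stat, p = cb.logrank([t, t], [e, e])
    assert stat == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_logrank_matches_hypergeometric_oracle():
    t1 = np.array([1.0, 2, 3, 4, 5, 6])
    t2 = np.array([7.0, 8, 9, 10, 11, 12])
    e = np.ones(6)
    stat, p = cb.logrank([t1, t2], [e, e])
    assert stat == pytest.approx(logrank_oracle(t1, e, t2, e), abs=1e-10)
    # with ties and censoring
    rng = np.random.default_rng(5)
    ta = np.ceil(rng.exponential(8, 80))
    tb = np.ceil(rng.exponential(14, 70))
    ea = rng.integers(0, 2, 80).astype(float)
    eb = rng.integers(0, 2, 70).astype(float)
    stat2, _ = cb.logrank([ta, tb], [ea, eb])
    assert stat2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-6)


def test_logrank_empty_group_raises_with_name():
    with pytest.raises(ValueError, match="group 2"):
        cb.logrank([[1.0], [2.0], []], [[1.0], [1.0], []])
    with pytest.raises(ValueError, match="2 groups"):
        cb.logrank([[1.0]], [[1.0]])


def test_logrank_equals_cox_score_test_at_null():
    """For two groups the log-rank chi-square is the Cox partial-likelihood
    score test at beta = 0 (Breslow tie handling) — same O-E sums, same
    hypergeometric variance."""
    rng = np.random.default_rng(6)
    t1 = np.ceil(rng.exponential(10, 120))
    t2 = np.ceil(rng.exponential(16, 100))
    e1 = (rng.uniform(size=120) < 0.8).astype(float)
    e2 = (rng.uniform(size=100) < 0.8).astype(float)
    stat, _ = cb.logrank([t1, t2], [e1, e2])
    assert stat == pytest.approx(logrank_oracle(t1, e1, t2, e2), abs=1e-6)


def test_hazard_ratio_identical_groups_near_one():
    rng = np.random.default_rng(7)
    t = rng.exponential(10, 400) + 0.01
    e = np.ones(400)
    g = np.repeat([0.0, 1.0], 200)
    res = cb.hazard_ratio(t, e, g)
    assert 0.75 < res.hr < 1.3


def test_hazard_ratio_label_swap_inverts():
    rng = np.random.default_rng(8)
    g = np.repeat([0.0, 1.0], 150)
    t = rng.exponential(10, 300) * np.where(g == 1, 0.5, 1.0) + 0.01
    e = np.ones(300)
    r1 = cb.hazard_ratio(t, e, g)
    r2 = cb.hazard_ratio(t, e, 1.0 - g)
    assert r1.hr * r2.hr == pytest.approx(1.0, abs=1e-8)


def test_hazard_ratio_recovery_rate_ratio_two():
    hrs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        g = np.repeat([0.0, 1.0], 500)
        t = np.where(g == 1, rng.exponential(5, 1000), rng.exponential(10, 1000))
        hrs.append(cb.hazard_ratio(t + 1e-6, np.ones(1000), g).hr)
    pooled = np.exp(np.mean(np.log(hrs)))
    assert 1.8 <= pooled <= 2.2


def test_hazard_ratio_requires_events_per_group():
    with pytest.raises(ValueError, match="group 1"):
        cb.hazard_ratio([1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 0.0, 0.0],
                        [0.0, 0.0, 1.0, 1.0])


def test_subgroup_analysis_directions_and_skipping(default_cohort):
    table, _ = default_cohort
    comps = {c.name: c for c in cb.subgroup_analysis(table)}
    assert comps["liver metastasis"].hr > 1
    assert comps["neutropenia"].hr < 1
    assert comps["cabazitaxel cycles >= 4"].hr < 1
    # group sizes add up to the analyzed n
    assert sum(g["n"] for g in comps["liver metastasis"].groups) == len(table)
    # constant subgroup variable -> skipped with reason
    frozen = table.copy()
    frozen["liver_metastasis"] = 1.0
    skipped = {c.name: c for c in cb.subgroup_analysis(frozen)}["liver metastasis"]
    assert skipped.skipped and "empty" in skipped.skip_reason


def test_subgroup_frame_schema(default_cohort):
    table, _ = default_cohort
    df = cb.subgroup_frame(cb.subgroup_analysis(table))
    assert {"subgroup", "group", "n", "events", "median", "hr", "logrank_p"} <= set(df.columns)
    assert (df["n"] > 0).all()
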