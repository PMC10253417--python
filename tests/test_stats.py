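"""Group statistics: closed-form oracles, Levene gate, strata, feature gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aepkit.errors import DataError, InsufficientDataError, ValidationError
from aepkit.stats import (CANONICAL_METRICS, GroupComparison, Stratum,
                          compare_metric, hearing_class,
                          select_time_features, stratify)


def _closed_form_student(a, b):
    """Independent textbook formulas for the pooled t-test and Cohen's d."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return t, n1 + n2 - 2, d


def test_compare_metric_matches_closed_form_example():
    c = compare_metric([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
    assert c.test_used == "student"
    assert c.t_stat == pytest.approx(-1.0, abs=1e-10)
    assert c.df == 8
    assert c.p_value == pytest.approx(0.3466, abs=2e-4)
    assert c.cohens_d == pytest.approx(-1.0 / np.sqrt(2.5), abs=1e-10)


@pytest.mark.parametrize("seed", range(6))
def test_compare_metric_agrees_with_oracle(seed):
    """t, df and d match the closed forms to 1e-10 on random samples."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, rng.integers(5, 40))
    b = rng.normal(0.3, 1, rng.integers(5, 40))
    c = compare_metric(a, b)
    if c.test_used == "student":
        t, df, d = _closed_form_student(a, b)
        assert c.t_stat == pytest.approx(t, abs=1e-10)
        assert c.df == pytest.approx(df, abs=1e-10)
        assert c.cohens_d == pytest.approx(d, abs=1e-10)
    else:  # Welch branch: scipy's Welch t and the RMS-SD effect size
        from scipy import stats as sps
        t, _ = sps.ttest_ind(a, b, equal_var=False)
        assert c.t_stat == pytest.approx(float(t), abs=1e-10)
        d = (a.mean() - b.mean()) / np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert c.cohens_d == pytest.approx(d, abs=1e-10)
    assert c.ci95[0] <= c.ci95[1]
    assert 0 <= c.p_value <= 1


def test_identical_samples_are_null():
    c = compare_metric([1, 2, 3], [1, 2, 3])
    assert c.t_stat == 0.0
    assert c.p_value == 1.0
    assert c.cohens_d == 0.0


def test_welch_chosen_under_gross_variance_inequality():
    """SD ratio 10 at n=50/50: the Levene gate fires almost always."""
    hits = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        c = compare_metric(rng.normal(0, 1, 50), rng.normal(0, 10, 50))
        hits += c.test_used == "welch"
    assert hits >= 190


def test_levene_consistency_invariant():
    for seed in range(30):
        rng = np.random.default_rng(seed)
        c = compare_metric(rng.normal(0, 1, 20), rng.normal(0, 2, 20))
        assert (c.test_used == "welch") == (c.levene_p < 0.05)


def test_insufficient_data_names_metric():
    with pytest.raises(InsufficientDataError, match="wave V"):
        compare_metric([1.0], [1, 2, 3], metric_id=("ABR", "wave V", "latency"))


@pytest.mark.parametrize("pta,expected", [
    (15.0, "normal"), (20.0, "normal"), (20.5, "mild_loss"),
    (45.0, "mild_loss"), (60.0, "mild_loss"), (61.0, "severe_loss"),
    (80.0, "severe_loss"),
])
def test_hearing_class_bins(pta, expected):
    assert hearing_class([pta]) == expected


def test_hearing_class_uses_pure_tone_average():
    assert hearing_class([10, 20, 30]) == "normal"
    with pytest.raises(DataError):
        hearing_class([])


def test_stratify_yields_twelve_disjoint_exhaustive_strata():
    rng = np.random.default_rng(0)
    n = 240
    ears = pd.DataFrame({
        "gender": rng.choice(["female", "male"], n),
        "hearing_class": rng.choice(["normal", "mild_loss", "severe_loss"], n),
        "thi_group": rng.choice(["low", "high"], n),
    }, index=[f"e{i}" for i in range(n)])
    strata = stratify(ears)
    assert len(strata) == 12
    union = set().union(*strata.values())
    assert union == set(ears.index)
    assert sum(len(s) for s in strata.values()) == n  # disjoint


def test_stratify_balanced_cohort_counts():
    rows = []
    for g in ("female", "male"):
        for h in ("normal", "mild_loss", "severe_loss"):
            for t in ("low", "high"):
                for i in range(20):
                    rows.append((f"{g}-{h}-{t}-{i}", g, h, t))
    ears = pd.DataFrame(rows, columns=["ear", "gender", "hearing_class",
                                       "thi_group"]).set_index("ear")
    strata = stratify(ears)
    assert all(len(s) == 20 for s in strata.values())


def test_stratify_single_patient():
    ears = pd.DataFrame({"gender": ["male"], "hearing_class": ["normal"],
                         "thi_group": ["high"]}, index=["e0"])
    strata = stratify(ears)
    assert len(strata) == 12
    assert len(strata[Stratum("male", "normal", "high")]) == 1
    assert sum(len(s) for s in strata.values()) == 1


def test_stratify_rejects_missing_attribute():
    ears = pd.DataFrame({"gender": ["male"], "hearing_class": [np.nan],
                         "thi_group": ["high"]}, index=["e0"])
    with pytest.raises(ValidationError, match="hearing_class"):
        stratify(ears)


def _comparison(metric_id, p):
    return GroupComparison(metric_id=metric_id, n_low=10, n_high=10,
                           mean_low=0, sd_low=1, mean_high=0, sd_high=1,
                           levene_p=0.5, test_used="student", t_stat=0.0,
                           df=18, p_value=p, ci95=(-1, 1), cohens_d=0.0)


def test_select_time_features_reproduces_reported_significance_pattern():
    """With the published significance pattern (ABR III/V latency + I
    amplitude; all AMLR metrics except Na latency), the gate returns those
    11 metrics in canonical order."""
    significant = {
        ("ABR", "III", "latency"), ("ABR", "V", "latency"),
        ("ABR", "I", "amplitude"), ("ABR", "V", "amplitude"),
        ("AMLR", "Pa", "latency"), ("AMLR", "Nb", "latency"),
        ("AMLR", "Pb", "latency"),
        ("AMLR", "Na", "amplitude"), ("AMLR", "Pa", "amplitude"),
        ("AMLR", "Nb", "amplitude"), ("AMLR", "Pb", "amplitude"),
    }
    comps = [_comparison(m, 0.01 if m in significant else 0.5)
             for m in CANONICAL_METRICS]
    selected = select_time_features(comps)
    assert len(selected) == 11
    assert set(selected) == significant
    rank = {m: i for i, m in enumerate(CANONICAL_METRICS)}
    assert [rank[m] for m in selected] == sorted(rank[m] for m in selected)


def test_select_time_features_all_null():
    comps = [_comparison(m, 0.5) for m in CANONICAL_METRICS]
    assert select_time_features(comps) == []


def test_select_time_features_holm_is_stricter():
    comps = [_comparison(m, 0.04) for m in CANONICAL_METRICS]
    assert len(select_time_features(comps)) == len(CANONICAL_METRICS)
    assert len(select_time_features(comps, correction="holm")) == 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_comparison_fields_are_coherent(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=12)
    b = rng.normal(size=15) + rng.normal()
    c = compare_metric(a, b)
    assert 0 <= c.p_value <= 1 and 0 <= c.levene_p <= 1
    # the CI is centred on the point estimate of the mean difference
    assert c.ci95[0] <= (c.mean_low - c.mean_high) <= c.ci95[1]
    assert (c.test_used == "welch") == (c.levene_p < 0.05)
    # significance at 5% coincides with the CI excluding zero
    assert (c.p_value < 0.05) == (c.ci95[0] > 0 or c.ci95[1] < 0)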