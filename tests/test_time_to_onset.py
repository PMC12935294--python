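"""Onset intervals, Weibull shape test, ECDF and subgroup comparison."""

import numpy as np
import pytest

from tetvigil import (
    Hazard,
    PartialDate,
    TTORecord,
    WeibullFit,
    classify_hazard,
    compare_onset,
    compute_tto,
    ecdf_curve,
    fit_weibull,
)
from tetvigil.time_to_onset import Excluded, compare_onset_groups, ecdf_at

from conftest import make_report


def _case_with_dates(start, event):
    return make_report(
        ingredients=("NIVOLUMAB",), event=event,
        therapy_starts=[(0, PartialDate(int(start[:4]), int(start[4:6]),
                                        int(start[6:8])))],
    )


def test_compute_tto_day_arithmetic():
    out = compute_tto(_case_with_dates("20230101", "20230122"))
    assert isinstance(out, TTORecord) and out.days == 21


def test_compute_tto_month_precision_event_excluded():
    out = compute_tto(_case_with_dates("20230101", "202302"))
    assert isinstance(out, Excluded)
    assert "day-precision" in out.reason


def test_compute_tto_negative_interval_excluded():
    out = compute_tto(_case_with_dates("20230110", "20230105"))
    assert out == Excluded(out.primaryid, "negative interval")


def test_compute_tto_missing_event_date():
    out = compute_tto(_case_with_dates("20230110", None))
    assert isinstance(out, Excluded) and "missing event date" in out.reason


def test_compute_tto_uses_earliest_start():
    r = make_report(
        ingredients=("NIVOLUMAB", "PEMBROLIZUMAB"), event="20230201",
        therapy_starts=[(1, PartialDate(2023, 1, 20)),
                        (0, PartialDate(2023, 1, 1))],
    )
    out = compute_tto(r)
    assert out.days == 31


# ---------------------------------------------------------------------------
# Weibull fit
# ---------------------------------------------------------------------------

def test_fit_weibull_floor_and_degenerate():
    with pytest.raises(ValueError, match="at least"):
        fit_weibull([1, 2, 3, 4, 5])
    with pytest.raises(ValueError, match="degenerate"):
        fit_weibull([7.0] * 20)


def test_exponential_sample_classified_random():
    rng = np.random.default_rng(1)
    x = rng.exponential(30, size=2000)
    fit = fit_weibull(x, window_days=None)
    assert fit.shape_ci[0] < 1 < fit.shape_ci[1]
    assert fit.classification is Hazard.RANDOM_FAILURE


def test_weibull_recovery_against_grid_oracle():
    """MLE matches an independent coarse-grid likelihood maximization."""
    rng = np.random.default_rng(7)
    x = rng.weibull(0.7, size=500) * 30
    fit = fit_weibull(x, window_days=None)

    shapes = np.linspace(0.3, 1.5, 241)
    scales = np.linspace(5, 80, 301)
    best = None
    for k in shapes:
        # profile out the scale analytically: lambda_hat = mean(x^k)^(1/k)
        lam = np.mean(x ** k) ** (1 / k)
        ll = np.sum(np.log(k) - k * np.log(lam)
                    + (k - 1) * np.log(x) - (x / lam) ** k)
        if best is None or ll > best[0]:
            best = (ll, k, lam)
    _, k_hat, lam_hat = best
    assert fit.shape == pytest.approx(k_hat, abs=0.01)
    assert fit.scale == pytest.approx(lam_hat, rel=0.02)


def test_window_excludes_late_onsets():
    x = list(np.linspace(5, 300, 40)) + [400, 600, 1250]
    fit = fit_weibull(x, window_days=365)
    assert fit.n == 40


@pytest.mark.parametrize("ci,expected", [
    ((0.4, 0.8), Hazard.EARLY_FAILURE),
    ((0.7, 1.3), Hazard.RANDOM_FAILURE),
    ((1.2, 2.4), Hazard.WEAR_OUT),
    ((0.99, 1.0), Hazard.RANDOM_FAILURE),   # boundary: CI touching 1 includes 1
    ((1.0, 1.4), Hazard.RANDOM_FAILURE),
])
def test_classify_hazard_rules(ci, expected):
    fit = WeibullFit(sum(ci) / 2, ci, 30.0, (20.0, 40.0), 100,
                     Hazard.RANDOM_FAILURE)
    assert classify_hazard(fit) is expected


def test_classify_hazard_exhaustive_over_random_cis():
    rng = np.random.default_rng(2)
    for _ in range(200):
        lo = float(rng.uniform(0.1, 2.0))
        hi = lo + float(rng.uniform(0.0, 1.5))
        fit = WeibullFit((lo + hi) / 2, (lo, hi), 30.0, (20.0, 40.0), 50,
                         Hazard.RANDOM_FAILURE)
        cls = classify_hazard(fit)
        assert cls in set(Hazard)
        assert (cls is Hazard.EARLY_FAILURE) == (hi < 1)
        assert (cls is Hazard.WEAR_OUT) == (lo > 1)


# ---------------------------------------------------------------------------
# ECDF
# ---------------------------------------------------------------------------

def test_ecdf_steps():
    curve = ecdf_curve([7, 21, 60])["all"]
    assert curve == [(7, pytest.approx(1 / 3)), (21, pytest.approx(2 / 3)),
                     (60, pytest.approx(1.0))]


def test_ecdf_ties_collapse_and_end_at_one():
    curve = ecdf_curve([5, 5, 9])["all"]
    assert curve == [(5, pytest.approx(2 / 3)), (9, pytest.approx(1.0))]
    fractions = [f for _, f in curve]
    assert fractions == sorted(fractions)


def test_ecdf_groups():
    recs = [TTORecord(1, 5, fatal=True), TTORecord(2, 9, fatal=False)]
    curves = ecdf_curve(recs, group_by=lambda r: r.fatal)
    assert curves["True"] == [(5, 1.0)] and curves["False"] == [(9, 1.0)]


# ---------------------------------------------------------------------------
# subgroup comparison
# ---------------------------------------------------------------------------

def test_compare_onset_exact_enumeration():
    out = compare_onset([1, 2, 3], [10, 11, 12])
    assert out.p == pytest.approx(0.1)     # 2 / C(6,3)
    assert (out.median_a, out.median_b) == (2.0, 11.0)


def test_compare_onset_identical_groups():
    out = compare_onset([5, 6, 7, 8], [5, 6, 7, 8])
    assert out.p >= 0.99


def test_compare_onset_detects_shift():
    rng = np.random.default_rng(3)
    a = rng.exponential(10, 200)
    b = rng.exponential(30, 200)
    assert compare_onset(a, b).p < 0.01


def test_compare_onset_needs_three_per_group():
    with pytest.raises(ValueError):
        compare_onset([1, 2], [3, 4, 5])


def test_compare_onset_groups_kruskal():
    rng = np.random.default_rng(4)
    groups = {"a": rng.exponential(5, 50), "b": rng.exponential(5, 50),
              "c": rng.exponential(50, 50)}
    stat, p = compare_onset_groups(groups)
    assert p < 0.01
    with pytest.raises(ValueError):
        compare_onset_groups({"a": [1, 2, 3], "b": [4, 5, 6]})


def test_ecdf_at_fraction():
    assert ecdf_at([10, 20, 70, 80], 60) == pytest.approx(0.5)
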