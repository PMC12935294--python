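"""Time-to-onset (TTO) analysis and Weibull hazard classification.

TTO is the number of days from the earliest day-precision ICI therapy start
(THER START_DT) to the event date (EVENT_DT). Records with either date
missing or not at day precision are excluded (the source data's month- and
year-precision dates cannot yield a day count), as are non-positive
intervals. Raw day counts are kept for descriptive medians; the Weibull fit
is restricted to a truncation window (default 365 days after therapy start)
to limit right-truncation bias inherent to spontaneous reports, handled by
exclusion rather than a truncated likelihood.

The Weibull Shape Parameter (WSP) test fits a two-parameter Weibull by
maximum likelihood (no censoring) and classifies the hazard from the 95% CI
of the shape β:

* early failure  — CI upper bound < 1 (decreasing hazard; events cluster
  soon after therapy start),
* random failure — CI includes 1 (constant hazard),
* wear-out       — CI lower bound > 1 (increasing hazard).

Subgroup onset comparisons use the two-sided Mann-Whitney U test (exact
enumeration when both groups have n <= 8, otherwise the normal approximation
with tie correction); Kruskal-Wallis covers more than two groups.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from lifelines import WeibullFitter
from scipy import stats

from .cohort import CaseRecord, Regimen
from .faers_io import Precision, SafetyReport

__all__ = [
    "TTORecord",
    "Excluded",
    "Hazard",
    "WeibullFit",
    "compute_tto",
    "collect_tto",
    "fit_weibull",
    "classify_hazard",
    "ecdf_curve",
    "compare_onset",
    "compare_onset_groups",
]


class Hazard(str, enum.Enum):
    EARLY_FAILURE = "early_failure"
    RANDOM_FAILURE = "random_failure"
    WEAR_OUT = "wear_out"


@dataclass(frozen=True)
class Excluded:
    primaryid: int
    reason: str


@dataclass(frozen=True)
class TTORecord:
    primaryid: int
    days: int
    regimen: Optional[Regimen] = None
    with_chemo_or_targeted: Optional[bool] = None
    sex: Optional[str] = None
    age_band: Optional[str] = None
    fatal: Optional[bool] = None

    def to_row(self) -> dict:
        return {
            "primaryid": self.primaryid, "days": self.days,
            "regimen": self.regimen.value if self.regimen else "",
            "with_chemo_or_targeted": self.with_chemo_or_targeted,
            "sex": self.sex or "", "age_band": self.age_band or "",
            "fatal": self.fatal,
        }


@dataclass
class WeibullFit:
    shape: float
    shape_ci: tuple[float, float]
    scale: float
    scale_ci: tuple[float, float]
    n: int
    classification: Hazard

    def to_row(self) -> dict:
        return {
            "n": self.n, "shape": self.shape,
            "shape_ci_low": self.shape_ci[0], "shape_ci_high": self.shape_ci[1],
            "scale": self.scale,
            "scale_ci_low": self.scale_ci[0], "scale_ci_high": self.scale_ci[1],
            "classification": self.classification.value,
        }


def _age_band(age: Optional[float]) -> Optional[str]:
    if age is None:
        return None
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64"
    if age < 75:
        return "65-74"
    return ">=75"


def compute_tto(case: Union[CaseRecord, SafetyReport]) -> Union[TTORecord, Excluded]:
    """Days from earliest day-precision ICI therapy start to event date.

    Returns an :class:`Excluded` (with a reason) when either date is missing
    or partial, or the interval is non-positive. Day counts above the
    truncation window are *not* excluded here — the window applies to the
    Weibull fit, while descriptive medians use the raw days.
    """
    if isinstance(case, CaseRecord):
        report = case.report
        regimen, with_chemo = case.regimen, case.with_chemo_or_targeted
    else:
        report, regimen, with_chemo = case, None, None

    event = report.event_date
    if event is None:
        return Excluded(report.primaryid, "missing event date")
    if event.precision is not Precision.DAY:
        return Excluded(report.primaryid, "event date not day-precision")

    from .cohort import ICI_CLASSES  # local import to avoid cycle at module load
    starts = []
    for idx, start in report.therapy_starts:
        if start.precision is not Precision.DAY:
            continue
        if idx < len(report.drugs) and report.drugs[idx].drug_class in ICI_CLASSES:
            starts.append(start.to_date())
        elif report.drugs and report.drugs[idx].drug_class is None:
            # unharmonized corpus: accept any therapy episode
            starts.append(start.to_date())
    if not starts:
        return Excluded(report.primaryid, "no day-precision ICI therapy start")

    days = (event.to_date() - min(starts)).days
    if days < 1:
        return Excluded(report.primaryid, "negative interval" if days < 0 else "zero interval")
    return TTORecord(
        primaryid=report.primaryid, days=days, regimen=regimen,
        with_chemo_or_targeted=with_chemo,
        sex=report.sex.value, age_band=_age_band(report.age_years),
        fatal=report.fatal,
    )


def collect_tto(
    cases: Sequence[Union[CaseRecord, SafetyReport]]
) -> tuple[list[TTORecord], list[Excluded]]:
    records, excluded = [], []
    for c in cases:
        out = compute_tto(c)
        (records if isinstance(out, TTORecord) else excluded).append(out)
    return records, excluded


def _days_array(records: Iterable) -> np.ndarray:
    vals = [r.days if isinstance(r, TTORecord) else float(r) for r in records]
    return np.asarray(vals, dtype=float)


def fit_weibull(
    records: Iterable, window_days: Optional[int] = 365,
    min_n: int = 10, z: float = 1.96,
) -> WeibullFit:
    """Maximum-likelihood two-parameter Weibull fit of onset days.

    ``records`` may be TTORecords or plain day counts. Days beyond
    ``window_days`` are excluded (right truncation handled by exclusion).
    95% CIs are normal approximations on the log-parameters, back-transformed
    to the natural scale (hence always positive).
    """
    x = _days_array(records)
    if window_days is not None:
        x = x[x <= window_days]
    n = len(x)
    if n < min_n:
        raise ValueError(f"need at least {min_n} onset records for the Weibull fit, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all onset values identical")

    wf = WeibullFitter().fit(x)
    shape = float(wf.rho_)
    scale = float(wf.lambda_)
    se_shape = float(wf.summary.loc["rho_", "se(coef)"])
    se_scale = float(wf.summary.loc["lambda_", "se(coef)"])
    # delta method: se(log theta) = se(theta) / theta
    shape_ci = (shape * np.exp(-z * se_shape / shape),
                shape * np.exp(z * se_shape / shape))
    scale_ci = (scale * np.exp(-z * se_scale / scale),
                scale * np.exp(z * se_scale / scale))
    fit = WeibullFit(shape, shape_ci, scale, scale_ci, n, Hazard.RANDOM_FAILURE)
    fit.classification = classify_hazard(fit)
    return fit


def classify_hazard(fit: WeibullFit) -> Hazard:
    """WSP three-way rule on the shape CI; exhaustive and mutually exclusive."""
    low, high = fit.shape_ci
    if high < 1.0:
        return Hazard.EARLY_FAILURE
    if low > 1.0:
        return Hazard.WEAR_OUT
    return Hazard.RANDOM_FAILURE


def ecdf_curve(
    records: Iterable, group_by: Optional[Callable] = None
) -> dict[str, list[tuple[float, float]]]:
    """Empirical CDF step points per group: right-continuous, reaching 1 at
    the maximum observed day; tied days collapse into one step."""
    groups: dict[str, list[float]] = {}
    for r in records:
        label = "all" if group_by is None else str(group_by(r))
        days = r.days if isinstance(r, TTORecord) else float(r)
        groups.setdefault(label, []).append(days)
    curves = {}
    for label, vals in groups.items():
        if not vals:
            continue
        x = np.sort(np.asarray(vals, dtype=float))
        uniq, counts = np.unique(x, return_counts=True)
        cum = np.cumsum(counts) / len(x)
        curves[label] = list(zip(uniq.tolist(), cum.tolist()))
    return curves


def ecdf_at(records: Iterable, day: float) -> float:
    """Fraction of records with onset <= day."""
    x = _days_array(records)
    if len(x) == 0:
        raise ValueError("no records")
    return float(np.mean(x <= day))


@dataclass(frozen=True)
class OnsetComparison:
    median_a: float
    median_b: float
    statistic: float
    p: float


def compare_onset(group_a: Iterable, group_b: Iterable) -> OnsetComparison:
    """Two-sided Mann-Whitney U comparison of onset-day distributions.

    Exact enumeration when both groups have n <= 8 (and no ties force the
    asymptotic path inside scipy); otherwise the normal approximation with
    tie correction.
    """
    a, b = _days_array(group_a), _days_array(group_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 onset records")
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return OnsetComparison(
        float(np.median(a)), float(np.median(b)),
        float(res.statistic), float(min(res.pvalue, 1.0)),
    )


def compare_onset_groups(groups: dict[str, Iterable]) -> tuple[float, float]:
    """Kruskal-Wallis H test across more than two onset groups."""
    arrays = [_days_array(v) for v in groups.values()]
    if len(arrays) < 3:
        raise ValueError("use compare_onset for two groups")
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)
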