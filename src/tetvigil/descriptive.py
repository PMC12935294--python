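"""Cohort description and fatal-vs-nonfatal comparison.

Reports whose outcomes include death form the fatal group; everything else
is nonfatal. Categorical variables are tabulated as counts with percentages
over the *column total* (fatal n, nonfatal n, overall N — including missing
levels), rendered half-up to one decimal, which is the convention required
to reproduce published spontaneous-report tables. Group comparisons use the
Pearson chi-square test without continuity correction, switching to the
Fisher exact test when any expected cell count falls below 5 (2x2 via
scipy; larger tables via conditional enumeration over all tables with the
observed margins).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CaseRecord
from .faers_io import Sex, round_half_up
from .time_to_onset import TTORecord

__all__ = [
    "GroupComparison",
    "summarize",
    "group_medians",
    "compare_groups",
    "summarize_cardiotox",
    "load_cardiac_pts",
    "fisher_exact_rxc",
]


# ---------------------------------------------------------------------------
# variable extraction
# ---------------------------------------------------------------------------

_MISSING = "Missing"


def _sex_level(c: CaseRecord) -> str:
    return {Sex.MALE: "Male", Sex.FEMALE: "Female", Sex.UNKNOWN: _MISSING}[c.report.sex]


def _age_level(c: CaseRecord) -> str:
    age = c.report.age_years
    if age is None:
        return _MISSING
    if age < 18:
        return "<18"
    if age < 65:
        return "18-64"
    if age < 75:
        return "65-74"
    return ">=75"


def _weight_level(c: CaseRecord) -> str:
    w = c.report.weight_kg
    if w is None:
        return _MISSING
    return "<70" if w < 70 else ">=70"


def _disease_level(c: CaseRecord) -> str:
    return c.disease.value


def _regimen_level(c: CaseRecord) -> str:
    return c.regimen.value


def _reporter_level(c: CaseRecord) -> str:
    return {"healthcare_professional": "Health care professional",
            "consumer": "Consumer", "unknown": _MISSING}[c.report.reporter.value]


def _country_level(c: CaseRecord) -> str:
    return c.report.country or _MISSING


_VARIABLES = {
    "sex": _sex_level,
    "age_band": _age_level,
    "weight_band": _weight_level,
    "disease": _disease_level,
    "country": _country_level,
    "regimen": _regimen_level,
    "reporter": _reporter_level,
    "with_chemo_or_targeted": lambda c: "ICI + chemo/targeted"
        if c.with_chemo_or_targeted else "ICI only",
}

# display order for fixed-level variables; others sort by total count
_LEVEL_ORDER = {
    "sex": ["Male", "Female", _MISSING],
    "age_band": ["<18", "18-64", "65-74", ">=75", _MISSING],
    "weight_band": ["<70", ">=70", _MISSING],
    "regimen": ["anti_PD1", "anti_PDL1", "anti_CTLA4", "combination_ICI"],
    "reporter": ["Consumer", "Health care professional", _MISSING],
}


def summarize(
    cases: Sequence[CaseRecord],
    variables: Optional[Iterable[str]] = None,
    top_countries: int = 6,
) -> pd.DataFrame:
    """Table-1-style summary: per variable level, fatal / nonfatal / total
    counts and percentages (denominators = group sizes including missing).

    Countries beyond the ``top_countries`` most frequent are pooled into
    "Other country". Returns an empty frame for empty input.
    """
    cols = ["variable", "level", "count_fatal", "count_nonfatal", "count_total",
            "pct_fatal", "pct_nonfatal", "pct_total"]
    if not cases:
        return pd.DataFrame(columns=cols)
    if variables is None:
        variables = list(_VARIABLES)

    n_fatal = sum(1 for c in cases if c.fatal)
    n_nonfatal = len(cases) - n_fatal
    n_total = len(cases)

    rows = []
    for var in variables:
        extractor = _VARIABLES[var]
        levels = [extractor(c) for c in cases]
        if var == "country":
            totals = pd.Series([l for l in levels if l != _MISSING]).value_counts()
            keep = set(totals.index[:top_countries])
            levels = [
                l if l in keep or l == _MISSING else "Other country" for l in levels
            ]
            ordered = list(totals.index[:top_countries]) + ["Other country"]
            if _MISSING in levels:
                ordered.append(_MISSING)
        else:
            order = _LEVEL_ORDER.get(var)
            observed = pd.Series(levels).value_counts()
            if order is not None:
                ordered = [l for l in order if l in observed.index]
            else:
                ordered = [l for l in observed.index if l != _MISSING]
                if _MISSING in observed.index:
                    ordered.append(_MISSING)
        fatal_counts = pd.Series(
            [l for c, l in zip(cases, levels) if c.fatal]).value_counts()
        nonfatal_counts = pd.Series(
            [l for c, l in zip(cases, levels) if not c.fatal]).value_counts()
        for level in ordered:
            cf = int(fatal_counts.get(level, 0))
            cn = int(nonfatal_counts.get(level, 0))
            rows.append({
                "variable": var, "level": level,
                "count_fatal": cf, "count_nonfatal": cn, "count_total": cf + cn,
                "pct_fatal": round_half_up(100 * cf / n_fatal, 1) if n_fatal else 0.0,
                "pct_nonfatal": round_half_up(100 * cn / n_nonfatal, 1) if n_nonfatal else 0.0,
                "pct_total": round_half_up(100 * (cf + cn) / n_total, 1),
            })
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["n_fatal"] = n_fatal
    df.attrs["n_nonfatal"] = n_nonfatal
    df.attrs["n_total"] = n_total
    return df


def group_medians(
    cases: Sequence[CaseRecord],
    tto_records: Optional[Sequence[TTORecord]] = None,
) -> dict:
    """Median age and onset days for the fatal / nonfatal / total groups."""
    def med(vals):
        return float(np.median(vals)) if len(vals) else float("nan")

    ages_f = [c.report.age_years for c in cases if c.fatal and c.report.age_years is not None]
    ages_n = [c.report.age_years for c in cases if not c.fatal and c.report.age_years is not None]
    out = {
        "age_median_fatal": med(ages_f),
        "age_median_nonfatal": med(ages_n),
        "age_median_total": med(ages_f + ages_n),
    }
    if tto_records is not None:
        tf = [r.days for r in tto_records if r.fatal]
        tn = [r.days for r in tto_records if not r.fatal]
        out.update({
            "tto_median_fatal": med(tf),
            "tto_median_nonfatal": med(tn),
            "tto_median_total": med(tf + tn),
            "tto_min": float(min(tf + tn)) if (tf or tn) else float("nan"),
            "tto_max": float(max(tf + tn)) if (tf or tn) else float("nan"),
        })
    return out


# ---------------------------------------------------------------------------
# fatal vs nonfatal tests
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    levels: list  # (label, count_fatal, count_nonfatal, pct_fatal, pct_nonfatal)
    test: str  # "chi_square" | "fisher_exact"
    statistic: float
    p: float


def fisher_exact_rxc(table: np.ndarray) -> float:
    """Fisher exact test for an r x c table of counts (two-sided).

    Conditional on both margins, sums the multivariate hypergeometric
    probability of every table at most as probable as the observed one.
    Enumeration with margin pruning — intended for the small tables of a
    cohort summary, not for large corpora.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r,c >= 2")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    lgam = math.lgamma

    def log_fact(k: int) -> float:
        return lgam(k + 1)

    log_const = (
        sum(log_fact(r) for r in row_sums)
        + sum(log_fact(c) for c in col_sums)
        - log_fact(table.sum())
    )

    def table_logp(cells: np.ndarray) -> float:
        return log_const - sum(log_fact(int(v)) for v in cells.flat)

    obs_logp = table_logp(table)
    cutoff = obs_logp + 1e-7
    r, c = table.shape
    total_p = 0.0

    # enumerate row by row; within a row, cell by cell; last entries forced
    def rec_row(i: int, remaining_cols: np.ndarray, acc_logp: float) -> None:
        nonlocal total_p
        if i == r - 1:
            cells = remaining_cols
            if np.any(cells < 0) or cells.sum() != row_sums[i]:
                return
            lp = acc_logp - sum(log_fact(int(v)) for v in cells)
            if lp <= cutoff:
                total_p += math.exp(lp)
            return

        def rec_cell(j: int, left_in_row: int, cols: np.ndarray, lp: float) -> None:
            if j == c - 1:
                v = left_in_row
                if v < 0 or v > cols[j]:
                    return
                new_cols = cols.copy()
                new_cols[j] -= v
                rec_row(i + 1, new_cols, lp - log_fact(v))
                return
            hi = min(left_in_row, int(cols[j]))
            for v in range(hi + 1):
                new_cols = cols.copy()
                new_cols[j] -= v
                rec_cell(j + 1, left_in_row - v, new_cols, lp - log_fact(v))

        rec_cell(0, int(row_sums[i]), remaining_cols, acc_logp)

    rec_row(0, col_sums.astype(int).copy(), log_const)
    return min(total_p, 1.0)


def compare_groups(
    cases: Sequence[CaseRecord], variable: str, include_missing: bool = False
) -> GroupComparison:
    """Fatal-vs-nonfatal comparison of one categorical variable.

    Pearson chi-square (no continuity correction) by default; Fisher exact
    when any expected cell count is below 5. ``include_missing`` keeps the
    missing level as a category of its own.
    """
    extractor = _VARIABLES[variable]
    pairs = [(extractor(c), c.fatal) for c in cases]
    if not include_missing:
        pairs = [p for p in pairs if p[0] != _MISSING]
    labels = sorted({p[0] for p in pairs})
    counts = {
        lab: [sum(1 for l, f in pairs if l == lab and f),
              sum(1 for l, f in pairs if l == lab and not f)]
        for lab in labels
    }
    labels = [l for l in labels if sum(counts[l]) > 0]
    if len(labels) < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 nonzero levels")
    tab = np.array([counts[l] for l in labels])  # rows = levels, cols = fatal/nonfatal

    n_fatal = tab[:, 0].sum()
    n_nonfatal = tab[:, 1].sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if (expected < 5).any():
        test = "fisher_exact"
        if tab.shape == (2, 2):
            odds, p = stats.fisher_exact(tab, alternative="two-sided")
            statistic = float(odds)
        else:
            p = fisher_exact_rxc(tab)
            statistic = float("nan")
    else:
        test = "chi_square"
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        statistic, p = float(chi2), float(p)

    levels = [
        (lab, int(tab[i, 0]), int(tab[i, 1]),
         round_half_up(100 * tab[i, 0] / n_fatal, 1) if n_fatal else 0.0,
         round_half_up(100 * tab[i, 1] / n_nonfatal, 1) if n_nonfatal else 0.0)
        for i, lab in enumerate(labels)
    ]
    return GroupComparison(variable, levels, test, statistic, float(p))


# ---------------------------------------------------------------------------
# cardiotoxicity
# ---------------------------------------------------------------------------

def load_cardiac_pts(path: str | Path | None = None) -> frozenset:
    """Shipped list of MedDRA cardiac-disorder PTs used for the cardiac
    case series."""
    if path is None:
        with resources.as_file(resources.files("tetvigil.data") / "cardiac_pts.tsv") as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return frozenset(df["pt"])


def summarize_cardiotox(
    cases: Sequence[CaseRecord], cardiac_pts: Optional[frozenset] = None
) -> pd.DataFrame:
    """Per-PT cardiac event counts with shares of all cardiac events.

    attrs carry: n_patients (cases with >=1 cardiac PT), n_events (cardiac
    PT occurrences, report-level), n_multi_event_patients (cases with >1
    distinct cardiac PT). Empty input or no cardiac events -> empty frame.
    """
    if cardiac_pts is None:
        cardiac_pts = load_cardiac_pts()
    counts: dict[str, int] = {}
    n_patients = 0
    n_multi = 0
    for c in cases:
        hits = c.report.reactions & cardiac_pts
        if not hits:
            continue
        n_patients += 1
        if len(hits) > 1:
            n_multi += 1
        for pt in hits:
            counts[pt] = counts.get(pt, 0) + 1
    n_events = sum(counts.values())
    rows = [
        {"pt": pt, "n": n,
         "pct": round_half_up(100 * n / n_events, 1) if n_events else 0.0}
        for pt, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["pt", "n", "pct"])
    df = df.sort_values(["n", "pt"], ascending=[False, True], ignore_index=True)
    df.attrs["n_patients"] = n_patients
    df.attrs["n_events"] = n_events
    df.attrs["n_multi_event_patients"] = n_multi
    return df
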