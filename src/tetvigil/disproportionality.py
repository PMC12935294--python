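"""Reporting-odds-ratio (ROR) disproportionality screening.

For each MedDRA preferred term (PT) observed among the exposed cases, a
report-level 2x2 table is built against a reference corpus:

    a = exposed reports with the PT        b = exposed reports without it
    c = reference reports with the PT      d = reference reports without it

and the ROR with its 95% confidence interval is

    ROR = (a/c) / (b/d) = ad / bc
    CI  = exp( ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.96.

No continuity correction is applied: any zero cell leaves the ROR and CI
undefined (rendered "NA"). A PT is flagged as a signal when it has at least
``min_cases`` exposed reports (default 3) and the CI lower bound exceeds 1.
The ROR is a reporting-disproportionality statistic, not an incidence or
risk measure; no multiple-testing correction is applied, and the number of
PTs tested is carried in the screen output so readers can judge the
screening burden.

The default comparator for a stratum is every deduplicated report *not* in
that stratum (keeping a..d a partition); a ``comparator="whole_database"``
flag instead reuses the full reference pool for every stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

from .cohort import CaseRecord, Regimen
from .faers_io import SafetyReport, round_half_up

__all__ = [
    "ContingencyTable",
    "RORResult",
    "build_contingency",
    "compute_ror",
    "flag_signal",
    "run_screen",
    "pt_summary",
    "load_pt_soc_map",
]


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_reference(self) -> int:
        return self.c + self.d


@dataclass
class RORResult:
    """ROR point estimate, CI and signal flag for one preferred term.

    ``prr`` and ``ebgm`` are reserved hooks for other disproportionality
    statistics; they are not computed here.
    """

    preferred_term: str
    table: ContingencyTable
    ror: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    signal: bool = False
    soc: Optional[str] = None
    prr: Optional[float] = None
    ebgm: Optional[float] = None

    def to_row(self) -> dict:
        t = self.table
        return {
            "pt": self.preferred_term, "soc": self.soc or "",
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": self.ror, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "signal": self.signal,
        }


def build_contingency(
    exposed: Sequence[SafetyReport],
    reference: Sequence[SafetyReport],
    pt: str,
) -> ContingencyTable:
    """Report-level 2x2 counts for one PT (a report lists a PT at most once)."""
    if len(exposed) == 0:
        raise ValueError("exposed report set is empty")
    a = sum(1 for r in exposed if pt in r.reactions)
    c = sum(1 for r in reference if pt in r.reactions)
    return ContingencyTable(a, len(exposed) - a, c, len(reference) - c)


def compute_ror(
    table: ContingencyTable, preferred_term: str = "", z: float = 1.96
) -> RORResult:
    """Evaluate the ROR formula on one table.

    Any zero cell leaves ror/ci undefined (None); that is a value, not an
    error, and such results can never be signals.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return RORResult(preferred_term, table, None, None, None, False)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = z * se
    ln_ror = math.log(ror)
    return RORResult(
        preferred_term, table, ror,
        math.exp(ln_ror - half), math.exp(ln_ror + half), False,
    )


def flag_signal(result: RORResult, min_cases: int = 3) -> bool:
    """Signal rule: at least ``min_cases`` exposed reports with the event and
    a CI lower bound exceeding 1."""
    return (
        result.ci_low is not None
        and result.table.a >= min_cases
        and result.ci_low > 1.0
    )


def load_pt_soc_map(path: str | Path | None = None) -> dict:
    """PT -> System Organ Class map (shipped table, user-replaceable)."""
    if path is None:
        with resources.as_file(resources.files("tetvigil.data") / "pt_soc.tsv") as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["pt"], df["soc"]))


def _default_strata() -> list[tuple[str, Callable[[CaseRecord], bool]]]:
    return [
        ("overall", lambda c: True),
        ("anti_PD1", lambda c: c.regimen is Regimen.ANTI_PD1),
        ("anti_PDL1", lambda c: c.regimen is Regimen.ANTI_PDL1),
        ("combination_ICI", lambda c: c.regimen is Regimen.COMBINATION_ICI),
    ]


def run_screen(
    cases: Sequence[CaseRecord],
    reference: Sequence[SafetyReport],
    strata: Optional[list] = None,
    min_cases: int = 3,
    z: float = 1.96,
    comparator: str = "all_minus_stratum",
    pt_soc: Optional[dict] = None,
    warn: Optional[list] = None,
) -> dict[str, list[RORResult]]:
    """Screen every PT observed in each stratum's exposed set.

    ``reference`` is the pool of deduplicated reports outside the case set.
    With the default ``comparator="all_minus_stratum"``, cases outside the
    stratum are added to its comparator so the four cells always partition
    the deduplicated corpus; ``"whole_database"`` uses the reference pool
    alone for every stratum. Results per stratum are sorted by descending
    exposed count, then descending ROR, then PT name.
    """
    if comparator not in ("all_minus_stratum", "whole_database"):
        raise ValueError(f"unknown comparator: {comparator}")
    if strata is None:
        strata = _default_strata()
    if pt_soc is None:
        pt_soc = load_pt_soc_map()

    out: dict[str, list[RORResult]] = {}
    for name, predicate in strata:
        stratum_cases = [c for c in cases if predicate(c)]
        if not stratum_cases:
            if warn is not None:
                warn.append(f"stratum {name!r} matched no case; empty result")
            out[name] = []
            continue
        exposed = [c.report for c in stratum_cases]
        if comparator == "all_minus_stratum":
            ref = list(reference) + [c.report for c in cases if not predicate(c)]
        else:
            ref = list(reference)

        pts = sorted({pt for r in exposed for pt in r.reactions})
        # count each PT across both pools in one pass
        exp_counts: dict[str, int] = {pt: 0 for pt in pts}
        ref_counts: dict[str, int] = {pt: 0 for pt in pts}
        for r in exposed:
            for pt in r.reactions:
                if pt in exp_counts:
                    exp_counts[pt] += 1
        for r in ref:
            for pt in r.reactions:
                if pt in ref_counts:
                    ref_counts[pt] += 1

        results = []
        n_exp, n_ref = len(exposed), len(ref)
        for pt in pts:
            a, c_ = exp_counts[pt], ref_counts[pt]
            table = ContingencyTable(a, n_exp - a, c_, n_ref - c_)
            res = compute_ror(table, pt, z=z)
            res.signal = flag_signal(res, min_cases=min_cases)
            res.soc = pt_soc.get(pt)
            results.append(res)
        results.sort(key=lambda r: (
            -r.table.a,
            -(r.ror if r.ror is not None else float("-inf")),
            r.preferred_term,
        ))
        out[name] = results
    return out


def pt_summary(
    cases: Sequence[CaseRecord], pt_soc: Optional[dict] = None
) -> pd.DataFrame:
    """Per-PT event counts over the cohort (Table-2 style).

    The denominator is the total number of reported events (sum of reaction
    counts over all cases), and percentages are rendered half-up to two
    decimals, the convention of published top-PT tables. Sorted by
    descending count then PT name.
    """
    if pt_soc is None:
        pt_soc = load_pt_soc_map()
    counts: dict[str, int] = {}
    for c in cases:
        for pt in c.report.reactions:
            counts[pt] = counts.get(pt, 0) + 1
    total_events = sum(counts.values())
    rows = [
        {"pt": pt, "n": n,
         "pct": round_half_up(100.0 * n / total_events, 2) if total_events else 0.0,
         "soc": pt_soc.get(pt, "")}
        for pt, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["pt", "n", "pct", "soc"])
    df = df.sort_values(["n", "pt"], ascending=[False, True], ignore_index=True)
    df.attrs["total_events"] = total_events
    return df
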