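"""End-to-end orchestration: parse -> dedup -> cohort -> screen -> TTO ->
descriptive, with a line-oriented JSON run log recording the stage funnel.

Quarters are parsed independently and concatenated *before* deduplication:
case versions can span quarters, so global deduplication is mandatory and
the stage ordering is fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import descriptive, disproportionality, time_to_onset
from .cohort import DrugDictionary, extract_cohort, load_indication_catalog
from .dedup import dedupe
from .faers_io import parse_quarter, write_json_log, write_table

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run; defaults are the analysis
    parameters used throughout (3-case signal floor, z=1.96, 365-day onset
    window, 60-day "early onset" cut)."""

    quarters: list = field(default_factory=list)
    output_dir: str = "results"
    drug_dictionary: Optional[str] = None
    indication_catalog: Optional[str] = None
    min_cases: int = 3
    z: float = 1.96
    tto_window_days: int = 365
    within_months_days: int = 60
    include_missing: bool = False
    comparator: str = "all_minus_stratum"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Writes per-stratum ROR tables, the PT summary, TTO records and Weibull
    summaries, ECDF points, the cohort summary, fatal-vs-nonfatal
    comparisons, the cardiac-event table, and ``run_log.jsonl`` with the
    stage funnel (reports in -> after dedup -> TET+ICI cases).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, **info) -> None:
        log.append({"stage": name, **info})

    reports = []
    parse_log: list[dict] = []
    for q in config.quarters:
        qr, ql = parse_quarter(q)
        reports.extend(qr)
        parse_log.extend(ql)
        stage("parse_quarter", quarter=str(q), reports=len(qr), skipped=len(ql))
    stage("parsed_total", reports=len(reports))

    audit: list[dict] = []
    deduped = dedupe(reports, audit)
    stage("dedup", reports=len(deduped), removed=len(reports) - len(deduped))

    drug_dict = (DrugDictionary.from_tsv(config.drug_dictionary)
                 if config.drug_dictionary else DrugDictionary.default())
    catalog = load_indication_catalog(config.indication_catalog)
    cohort_audit: list[dict] = []
    cases = extract_cohort(deduped, drug_dict, catalog, cohort_audit)
    stage("cohort", cases=len(cases))

    case_ids = {c.report.primaryid for c in cases}
    reference = [r for r in deduped if r.primaryid not in case_ids]

    if cases:
        screen = disproportionality.run_screen(
            cases, reference, min_cases=config.min_cases, z=config.z,
            comparator=config.comparator,
        )
        for stratum, results in screen.items():
            write_table(results, out / f"ror_{stratum}.tsv")
            stage("screen", stratum=stratum, n_pts=len(results),
                  n_signals=sum(r.signal for r in results))
        pt_df = disproportionality.pt_summary(cases)
        write_table(pt_df, out / "pt_summary.tsv")

        records, excluded = time_to_onset.collect_tto(cases)
        write_table(records, out / "tto_records.tsv")
        stage("tto", records=len(records), excluded=len(excluded))
        weib_rows = []
        groups = {"overall": records}
        for reg in {r.regimen for r in records if r.regimen}:
            groups[reg.value] = [r for r in records if r.regimen is reg]
        for label, recs in groups.items():
            try:
                fit = time_to_onset.fit_weibull(
                    recs, window_days=config.tto_window_days)
            except ValueError as err:
                stage("weibull_skipped", group=label, reason=str(err))
                continue
            row = {"group": label, **fit.to_row()}
            weib_rows.append(row)
            stage("weibull", group=label, shape=fit.shape,
                  classification=fit.classification.value)
        if weib_rows:
            write_table(weib_rows, out / "weibull_summary.tsv")
        curves = time_to_onset.ecdf_curve(records)
        ecdf_rows = [
            {"group": g, "days": d, "cum_fraction": f}
            for g, pts in curves.items() for d, f in pts
        ]
        if ecdf_rows:
            write_table(ecdf_rows, out / "ecdf.tsv")

        summary = descriptive.summarize(cases)
        write_table(summary, out / "cohort_summary.tsv")
        comparisons = {}
        for var in ("sex", "age_band", "weight_band", "disease", "regimen",
                    "reporter"):
            try:
                cmp_ = descriptive.compare_groups(
                    cases, var, include_missing=config.include_missing)
            except ValueError as err:
                stage("comparison_skipped", variable=var, reason=str(err))
                continue
            comparisons[var] = {
                "test": cmp_.test, "statistic": cmp_.statistic, "p": cmp_.p,
            }
        with open(out / "comparisons.json", "w") as fh:
            json.dump(comparisons, fh, indent=1, sort_keys=True)
        cardiac = descriptive.summarize_cardiotox(cases)
        write_table(cardiac, out / "cardiotox.tsv")
        stage("cardiotox", patients=cardiac.attrs["n_patients"],
              events=cardiac.attrs["n_events"])
    else:
        stage("empty_cohort")

    write_json_log(parse_log, out / "parse_log.jsonl")
    write_json_log(audit + cohort_audit, out / "dedup_cohort_audit.jsonl")
    write_json_log(log, out / "run_log.jsonl")
    return out
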