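"""Synthetic FAERS-like corpora with known ground truth, and fixed
published-cohort fixtures.

The generator emulates the structural features of a spontaneous-reporting
database that the pipeline must handle: case/version identifiers, partial
dates, drug role codes, independent per-report preferred-term (PT) draws,
injected duplicates of both kinds (same-CASEID re-versions and
distinct-CASEID field-identical copies), and drug-event pairs spiked at a
configured reporting odds ratio with Weibull-distributed onset times. The
spiked PT probability among exposed reports is chosen on the odds scale,

    odds(p1) = target_ror * odds(p0),

so that the expected report-level 2x2 table reproduces the target ROR
against the background rate p0. A JSON-able manifest records every injected
duplicate and the exact per-spike p0/p1 and realized a/b/c/d counts, giving
downstream stages an exact oracle.

Two deliberate idealizations (documented in the methods note): PTs are drawn
independently per report, and non-injected reports are guaranteed pairwise
distinct on the six-field duplicate key (accidental clashes are resolved by
a deterministic one-day event-date nudge) so duplicate ground truth is
exactly identifiable.

The fixed fixtures reconstruct published cohort tables (cohort
characteristics, top-PT counts, onset subset, cardiac case series) so that
descriptive and time-to-onset stages can be validated against printed
values without any database download. Printed tables give only marginals;
unconstrained joint structure is completed deterministically, and each
fixture re-checks its own marginals at build time.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .faers_io import (
    DrugEntry,
    DrugRole,
    Outcome,
    PartialDate,
    Reporter,
    SafetyReport,
    Sex,
    write_quarter,
)

__all__ = [
    "SpikeSpec",
    "SyntheticSpec",
    "PaperFixture",
    "DEFAULT_PT_CATALOG",
    "generate_reports",
    "generate_corpus",
    "build_paper_fixture",
]


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeSpec:
    """One drug-event association to inject at a target reporting odds ratio."""

    ingredient: str
    preferred_term: str
    target_ror: float
    n_exposed_reports: int
    onset_shape: float = 1.0
    onset_scale_days: float = 45.0

    def __post_init__(self) -> None:
        if not (self.target_ror > 0 and np.isfinite(self.target_ror)):
            raise ValueError("target_ror must be positive and finite")
        if self.n_exposed_reports <= 0:
            raise ValueError("n_exposed_reports must be positive")
        if self.onset_shape <= 0 or self.onset_scale_days <= 0:
            raise ValueError("onset parameters must be positive")


# Background PT catalog: (preferred term, per-report probability). Each PT is
# drawn independently, so a report can carry several. Rates loosely follow
# the mix of common generic AEs (nausea, fatigue, ...) down to rare
# immune-mediated ones (myocarditis, myositis).
DEFAULT_PT_CATALOG: tuple = (
    ("Drug ineffective", 0.050), ("Nausea", 0.045), ("Fatigue", 0.040),
    ("Diarrhoea", 0.030), ("Headache", 0.025), ("Vomiting", 0.025),
    ("Rash", 0.020), ("Dyspnoea", 0.020), ("Pyrexia", 0.018),
    ("Dizziness", 0.018), ("Pruritus", 0.015), ("Asthenia", 0.015),
    ("Anaemia", 0.012), ("Arthralgia", 0.012), ("Insomnia", 0.010),
    ("Cough", 0.010), ("Hypertension", 0.010), ("Decreased appetite", 0.008),
    ("Pneumonia", 0.008), ("Oedema peripheral", 0.006), ("Pneumonitis", 0.005),
    ("Weight decreased", 0.005), ("Neutropenia", 0.004), ("Colitis", 0.003),
    ("Hypothyroidism", 0.003), ("Hepatitis", 0.002), ("Febrile neutropenia", 0.002),
    ("Myocarditis", 0.001), ("Myasthenia gravis", 0.0008), ("Myositis", 0.0005),
)

_FILLER_PT = "Product use issue"

_BACKGROUND_DRUGS = (
    "ASPIRIN", "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE",
    "LEVOTHYROXINE", "AMLODIPINE", "METOPROLOL", "GABAPENTIN", "SERTRALINE",
    "IBUPROFEN", "PARACETAMOL", "WARFARIN", "FUROSEMIDE", "PREDNISONE",
    "INSULIN GLARGINE", "ADALIMUMAB", "INFLIXIMAB", "RITUXIMAB", "METHOTREXATE",
)

_BACKGROUND_INDICATIONS = (
    "Hypertension", "Diabetes mellitus", "Depression", "Rheumatoid arthritis",
    "Pain", "Breast cancer", "Lung neoplasm malignant", "Prostate cancer",
    "Asthma", "Gastrooesophageal reflux disease",
)

_COUNTRIES = ("US", "JP", "FR", "DE", "GB", "CA", "IT", "ES", "CN", "BR")
_COUNTRY_P = (0.45, 0.08, 0.07, 0.07, 0.06, 0.05, 0.05, 0.05, 0.06, 0.06)

_TET_INDICATIONS = ("Thymoma", "Thymic carcinoma")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one generated corpus.

    Same spec + same seed => byte-identical corpus files. Catalog
    probabilities need not sum to 1; each PT is drawn independently.
    Default rates reflect the study conditions the pipeline is meant to
    handle: a few percent duplicate contamination, a majority of reports
    lacking usable onset dates, and roughly a quarter lacking age.
    """

    n_background_reports: int = 100_000
    background_pt_catalog: tuple = DEFAULT_PT_CATALOG
    spikes: tuple = ()
    duplicate_rate: float = 0.02
    versioned_case_rate: float = 0.02
    missing_event_date_rate: float = 0.60
    missing_age_rate: float = 0.26
    death_rate_background: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "versioned_case_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("missing_event_date_rate", "missing_age_rate",
                     "death_rate_background"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        for pt, p in self.background_pt_catalog:
            if not 0 <= p <= 1:
                raise ValueError(f"catalog probability for {pt!r} out of [0, 1]")


def spiked_probability(target_ror: float, p0: float) -> float:
    """p1 with odds(p1) = target_ror * odds(p0); errors if infeasible."""
    if not 0 < p0 < 1:
        raise ValueError(f"background probability must be in (0, 1), got {p0}")
    odds1 = target_ror * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    if p1 >= 1:
        raise ValueError(
            f"target_ror={target_ror} with p0={p0} implies p1 >= 1; "
            "use a smaller p0 or target_ror"
        )
    return p1


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------

_EPOCH = datetime.date(2016, 1, 1)
_N_DAYS = (datetime.date(2024, 12, 31) - _EPOCH).days


def _pdate(day_offset: int) -> PartialDate:
    d = _EPOCH + datetime.timedelta(days=int(day_offset))
    return PartialDate(d.year, d.month, d.day)


def generate_reports(spec: SyntheticSpec) -> tuple[list[SafetyReport], dict]:
    """Generate the corpus in memory. Returns (reports, manifest).

    Reports are ordered by primaryid. The manifest records, per spike, the
    exact p0/p1 and the realized report-level a/b/c/d over *original*
    (non-duplicate) reports, and lists every injected duplicate with the
    primaryid the deduplication stages must remove.
    """
    rng = np.random.default_rng(spec.seed)
    catalog = list(spec.background_pt_catalog)
    cat_pts = [pt for pt, _ in catalog]
    cat_p = np.array([p for _, p in catalog])
    p0_by_pt = dict(catalog)

    n_bg = spec.n_background_reports
    n_exposed_total = sum(s.n_exposed_reports for s in spec.spikes)
    n = n_bg + n_exposed_total

    # --- vectorized field draws for all original reports -------------------
    sex_draw = rng.choice(3, size=n, p=[0.49, 0.49, 0.02])
    ages = rng.integers(18, 91, size=n).astype(float)
    age_missing = rng.random(n) < spec.missing_age_rate
    weights = np.round(rng.uniform(40, 120, size=n), 1)
    weight_missing = rng.random(n) < 0.5
    country_idx = rng.choice(len(_COUNTRIES), size=n, p=_COUNTRY_P)
    fda_offsets = rng.integers(0, _N_DAYS, size=n)
    death = rng.random(n) < spec.death_rate_background
    hosp = rng.random(n) < 0.25
    reporter_draw = rng.choice(3, size=n, p=[0.6, 0.3, 0.1])
    event_missing = rng.random(n) < spec.missing_event_date_rate

    # background PT incidence for every report (spiked PTs overridden below)
    pt_matrix = rng.random((n, len(catalog))) < cat_p

    # spike overrides + onset draws
    spike_of_report = np.full(n, -1)
    spike_meta = []
    pos = n_bg
    for si, s in enumerate(spec.spikes):
        if s.preferred_term not in p0_by_pt:
            raise ValueError(
                f"spiked PT {s.preferred_term!r} not in background catalog"
            )
        p0 = p0_by_pt[s.preferred_term]
        p1 = spiked_probability(s.target_ror, p0)
        rows = slice(pos, pos + s.n_exposed_reports)
        col = cat_pts.index(s.preferred_term)
        pt_matrix[rows, col] = rng.random(s.n_exposed_reports) < p1
        spike_of_report[rows] = si
        spike_meta.append({"spec": s, "p0": p0, "p1": p1})
        pos += s.n_exposed_reports

    onset_days = {}
    for si, s in enumerate(spec.spikes):
        k = s.n_exposed_reports
        draws = rng.weibull(s.onset_shape, size=k) * s.onset_scale_days
        onset_days[si] = np.maximum(1, np.rint(draws)).astype(int)

    bg_drug_idx = rng.integers(0, len(_BACKGROUND_DRUGS), size=n)
    bg_indi_idx = rng.integers(0, len(_BACKGROUND_INDICATIONS), size=n)
    start_offsets = rng.integers(0, _N_DAYS - 400, size=n)

    # group nonzero PT columns by row for fast reaction-set construction
    row_idx, col_idx = np.nonzero(pt_matrix)
    row_pts: dict[int, list[str]] = {}
    for r_i, c_i in zip(row_idx.tolist(), col_idx.tolist()):
        row_pts.setdefault(r_i, []).append(cat_pts[c_i])

    sexes = (Sex.MALE, Sex.FEMALE, Sex.UNKNOWN)
    reporters = (Reporter.HEALTHCARE_PROFESSIONAL, Reporter.CONSUMER, Reporter.UNKNOWN)

    reports: list[SafetyReport] = []
    base_caseid = 10_000_001
    exposed_counter = {si: 0 for si in range(len(spec.spikes))}
    for i in range(n):
        caseid = base_caseid + i
        si = int(spike_of_report[i])
        reactions = frozenset(row_pts.get(i, [_FILLER_PT]))
        outcomes = set()
        if death[i]:
            outcomes.add(Outcome.DEATH)
        if hosp[i]:
            outcomes.add(Outcome.HOSPITALIZATION)

        if si >= 0:
            s = spec.spikes[si]
            j = exposed_counter[si]
            exposed_counter[si] += 1
            drugs = [DrugEntry(s.ingredient, s.ingredient.upper(),
                               DrugRole.PRIMARY_SUSPECT)]
            indication = _TET_INDICATIONS[i % len(_TET_INDICATIONS)]
            start = _pdate(start_offsets[i])
            therapy = [(0, start)]
            if event_missing[i]:
                event = None
            else:
                event = _pdate(start_offsets[i] + onset_days[si][j])
        else:
            name = _BACKGROUND_DRUGS[bg_drug_idx[i]]
            drugs = [DrugEntry(name, name, DrugRole.PRIMARY_SUSPECT)]
            indication = _BACKGROUND_INDICATIONS[bg_indi_idx[i]]
            therapy = []
            event = None if event_missing[i] else _pdate(start_offsets[i])

        reports.append(SafetyReport(
            primaryid=caseid * 10 + 1,
            caseid=caseid,
            fda_date=_pdate(fda_offsets[i]),
            event_date=event,
            sex=sexes[sex_draw[i]],
            age_years=None if age_missing[i] else float(ages[i]),
            weight_kg=None if weight_missing[i] else float(weights[i]),
            country=_COUNTRIES[country_idx[i]],
            reporter=reporters[reporter_draw[i]],
            outcomes=frozenset(outcomes),
            drugs=drugs,
            reactions=reactions,
            indications=frozenset({indication}),
            therapy_starts=therapy,
        ))

    _make_originals_distinct(reports)

    # --- manifest ground truth over originals ------------------------------
    manifest_spikes = []
    for si, meta in enumerate(spike_meta):
        s = meta["spec"]
        exposed = [r for i, r in enumerate(reports) if spike_of_report[i] == si]
        others = [r for i, r in enumerate(reports) if spike_of_report[i] != si]
        a = sum(1 for r in exposed if s.preferred_term in r.reactions)
        c = sum(1 for r in others if s.preferred_term in r.reactions)
        manifest_spikes.append({
            "ingredient": s.ingredient, "preferred_term": s.preferred_term,
            "target_ror": s.target_ror, "n_exposed": s.n_exposed_reports,
            "p0": meta["p0"], "p1": meta["p1"],
            "a": a, "b": len(exposed) - a, "c": c, "d": len(others) - c,
        })

    # --- inject duplicates --------------------------------------------------
    duplicates = []
    n_versions = int(round(spec.versioned_case_rate * n))
    n_copies = int(round(spec.duplicate_rate * n))

    version_targets = rng.choice(n, size=n_versions, replace=False) if n_versions else []
    injected: list[SafetyReport] = []
    for i in sorted(int(x) for x in version_targets):
        orig = reports[i]
        newer = SafetyReport(
            primaryid=orig.caseid * 10 + 2, caseid=orig.caseid,
            fda_date=_pdate(min(_N_DAYS, _to_offset(orig.fda_date) + 30)),
            event_date=orig.event_date, sex=orig.sex, age_years=orig.age_years,
            weight_kg=orig.weight_kg, country=orig.country,
            reporter=orig.reporter, outcomes=orig.outcomes,
            drugs=[DrugEntry(d.reported_name, d.ingredient, d.role) for d in orig.drugs],
            reactions=orig.reactions, indications=orig.indications,
            therapy_starts=list(orig.therapy_starts),
        )
        injected.append(newer)
        # stage 1 keeps the newer version; the original primaryid must go
        duplicates.append({"kind": "version", "caseid": orig.caseid,
                           "kept_primaryid": newer.primaryid,
                           "removed_primaryid": orig.primaryid})

    # field-identical copies need all six stage-2 fields present on the source
    copyable = [
        i for i, r in enumerate(reports)
        if r.sex is not Sex.UNKNOWN and r.age_years is not None and r.country
        and r.event_date is not None and r.reactions and r.drugs
    ]
    n_copies = min(n_copies, len(copyable))
    copy_targets = (
        rng.choice(len(copyable), size=n_copies, replace=False) if n_copies else []
    )
    next_caseid = base_caseid + n
    for k, ci in enumerate(sorted(int(x) for x in copy_targets)):
        orig = reports[copyable[ci]]
        caseid = next_caseid + k
        copy = SafetyReport(
            primaryid=caseid * 10 + 1, caseid=caseid,
            fda_date=orig.fda_date, event_date=orig.event_date, sex=orig.sex,
            age_years=orig.age_years, weight_kg=orig.weight_kg,
            country=orig.country, reporter=orig.reporter, outcomes=orig.outcomes,
            drugs=[DrugEntry(d.reported_name, d.ingredient, d.role) for d in orig.drugs],
            reactions=orig.reactions, indications=orig.indications,
            therapy_starts=list(orig.therapy_starts),
        )
        injected.append(copy)
        # stage 2 keeps the lowest primaryid, i.e. the original
        duplicates.append({"kind": "copy", "caseid": caseid,
                           "kept_primaryid": orig.primaryid,
                           "removed_primaryid": copy.primaryid})

    all_reports = sorted(reports + injected, key=lambda r: r.primaryid)
    manifest = {
        "seed": spec.seed,
        "n_background_reports": n_bg,
        "n_original_reports": n,
        "n_reports_with_duplicates": len(all_reports),
        "spikes": manifest_spikes,
        "duplicates": duplicates,
        "removed_primaryids": sorted(d["removed_primaryid"] for d in duplicates),
    }
    return all_reports, manifest


def _to_offset(pd_: PartialDate) -> int:
    return (pd_.to_date() - _EPOCH).days


def _make_originals_distinct(reports: list[SafetyReport]) -> None:
    """Nudge event dates so no two originals share the six-field dedup key.

    Keeps duplicate ground truth exactly identifiable; deterministic given
    the input order.
    """
    seen: dict[tuple, int] = {}
    for r in reports:
        if (r.sex is Sex.UNKNOWN or r.age_years is None or not r.country
                or r.event_date is None or not r.reactions or not r.drugs):
            continue
        while True:
            key = (r.sex, r.age_years, r.country, r.event_date,
                   r.reactions, r.ingredient_set())
            if key not in seen:
                seen[key] = r.primaryid
                break
            d = r.event_date.to_date() + datetime.timedelta(days=1)
            r.event_date = PartialDate(d.year, d.month, d.day)


def generate_corpus(
    spec: SyntheticSpec, directory: str | Path
) -> tuple[Path, dict]:
    """Generate and write one quarter directory plus manifest.json."""
    reports, manifest = generate_reports(spec)
    directory = Path(directory)
    write_quarter(reports, directory)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return directory, manifest


# ---------------------------------------------------------------------------
# published-cohort fixtures
# ---------------------------------------------------------------------------

@dataclass
class PaperFixture:
    name: str
    reports: Optional[list] = None
    records: Optional[object] = None  # DataFrame or list of TTORecord
    meta: dict = dc_field(default_factory=dict)


def _repeat(pairs: Sequence[tuple]) -> list:
    out = []
    for value, count in pairs:
        out.extend([value] * count)
    return out


_OTHER_COUNTRIES = (
    "DE", "IT", "GB", "CA", "AU", "BR", "IN", "NL", "CH", "BE", "AT",
    "PT", "GR", "PL", "SE", "DK", "NO", "FI", "IE", "IL", "TR", "MX",
)

_PT_CYCLE = (
    "Myositis", "Myocarditis", "Myasthenia gravis", "Febrile neutropenia",
    "Pneumonitis", "Respiratory failure", "Pneumonia", "Adverse event",
    "Transaminases increased", "Dyspnea", "Malignant neoplasm progression",
    "Rash maculopapular", "Hepatitis", "Cardiac failure", "Hypoxia",
    "Myelosuppression", "Myasthenic syndrome", "Diplopia", "Septic shock",
    "Fatigue",
)

# onset-day multisets chosen to satisfy the printed onset statistics:
# overall n=56, median 21.0, 41/56 within 60 days, range 2-1250; fatal
# subset n=7 with median 18.0, range 8-266; and, on the 365-day window,
# a Weibull shape CI entirely below 1 (the published early-failure profile)
_TTO_FATAL_DAYS = (8, 10, 15, 18, 25, 100, 266)
_TTO_ALL_DAYS = tuple(
    [2, 2, 2, 2, 2, 3, 3, 3, 3, 4, 4, 5, 5, 6, 7, 8, 9, 10, 12, 14,
     15, 17, 18, 20] + [21] * 5
    + [22, 25, 28, 30, 33, 36, 40, 45, 50, 55, 58, 60]
    + [65, 75, 90, 100, 130, 160, 200, 250, 266, 320, 350, 360, 400, 600, 1250]
)


def _tto_nonfatal_days() -> list:
    days = list(_TTO_ALL_DAYS)
    for v in _TTO_FATAL_DAYS:
        days.remove(v)
    return days


# per-group age lists: within-band values completing the printed band counts
# and the printed medians (fatal 53, nonfatal 61, overall 58.5)
_FATAL_AGES = (
    [30, 32, 34, 36, 38, 40, 42, 44, 46, 48, 50, 53, 53, 54, 56, 59, 60, 62]  # 18-64
    + [66, 68, 70]      # 65-74
    + [75, 78, 81]      # >=75
    + [None] * 12
)
_NONFATAL_AGES = (
    list(range(18, 61)) + [61, 61] + [62, 62, 62, 63, 63, 63, 64, 64, 64]  # 18-64 (54)
    + [65 + (k % 10) for k in range(28)]   # 65-74
    + [75, 76, 77, 78, 79, 80]             # >=75
    + [None] * 28
)


def _build_table1_reports() -> list[SafetyReport]:
    groups = []
    # (fatal?, n, sex counts (M, F, missing), weights (<70, >=70, missing),
    #  disease (thymoma, carcinoma), country counts, regimen counts
    #  (PD1, PDL1, combo), reporter (consumer, professional), ages)
    groups.append(dict(
        fatal=True, n=36,
        sex=_repeat([(Sex.MALE, 16), (Sex.FEMALE, 20)]),
        ages=list(_FATAL_AGES),
        weights=_repeat([("<70", 8), (">=70", 3), (None, 25)]),
        disease=_repeat([("Thymoma", 15), ("Thymic carcinoma", 21)]),
        country=_repeat([("US", 12), ("CN", 1), ("FR", 2), ("ES", 1),
                         ("KR", 5), ("OTHER", 15)]),
        regimen=_repeat([("PD1", 29), ("PDL1", 3), ("COMBO", 4)]),
        reporter=_repeat([(Reporter.CONSUMER, 10),
                          (Reporter.HEALTHCARE_PROFESSIONAL, 26)]),
        chemo=4, tto_days=list(_TTO_FATAL_DAYS),
    ))
    groups.append(dict(
        fatal=False, n=116,
        sex=_repeat([(Sex.MALE, 64), (Sex.FEMALE, 42), (Sex.UNKNOWN, 10)]),
        ages=list(_NONFATAL_AGES),
        weights=_repeat([("<70", 32), (">=70", 25), (None, 59)]),
        disease=_repeat([("Thymoma", 46), ("Thymic carcinoma", 70)]),
        country=_repeat([("US", 39), ("JP", 16), ("CN", 13), ("FR", 12),
                         ("ES", 6), ("KR", 2), ("OTHER", 28)]),
        regimen=_repeat([("PD1", 72), ("PDL1", 36), ("COMBO", 8)]),
        reporter=_repeat([(Reporter.CONSUMER, 24),
                          (Reporter.HEALTHCARE_PROFESSIONAL, 92)]),
        chemo=18, tto_days=_tto_nonfatal_days(),
    ))

    reports = []
    other_counter = 0
    used_event_dates: set = set()
    gidx = 0
    for g in groups:
        for j in range(g["n"]):
            caseid = 8_000_001 + gidx
            country = g["country"][j]
            if country == "OTHER":
                country = _OTHER_COUNTRIES[other_counter % len(_OTHER_COUNTRIES)]
                other_counter += 1
            wband = g["weights"][j]
            if wband == "<70":
                weight = 50.0 + (j % 20)
            elif wband == ">=70":
                weight = 70.0 + (j % 40)
            else:
                weight = None
            reg = g["regimen"][j]
            if reg == "PD1":
                name = ("NIVOLUMAB", "PEMBROLIZUMAB")[j % 2]
                drugs = [DrugEntry(name, name, DrugRole.PRIMARY_SUSPECT)]
            elif reg == "PDL1":
                name = ("ATEZOLIZUMAB", "AVELUMAB", "DURVALUMAB")[j % 3]
                drugs = [DrugEntry(name, name, DrugRole.PRIMARY_SUSPECT)]
            else:
                drugs = [
                    DrugEntry("NIVOLUMAB", "NIVOLUMAB", DrugRole.PRIMARY_SUSPECT),
                    DrugEntry("IPILIMUMAB", "IPILIMUMAB", DrugRole.PRIMARY_SUSPECT),
                ]
            if j < g["chemo"]:
                drugs.append(DrugEntry("CARBOPLATIN", "CARBOPLATIN",
                                       DrugRole.CONCOMITANT))

            event_date = None
            therapy = []
            if j < len(g["tto_days"]):
                days = g["tto_days"][j]
                start = datetime.date(2019, 6, 1) + datetime.timedelta(days=gidx)
                event = start + datetime.timedelta(days=days)
                while event in used_event_dates:  # keep stage-2 keys distinct
                    start -= datetime.timedelta(days=1)
                    event = start + datetime.timedelta(days=days)
                used_event_dates.add(event)
                therapy = [(0, PartialDate(start.year, start.month, start.day))]
                event_date = PartialDate(event.year, event.month, event.day)

            age = g["ages"][j]
            reports.append(SafetyReport(
                primaryid=caseid * 10 + 1, caseid=caseid,
                fda_date=PartialDate(2024, 12, 1 + (gidx % 28)),
                event_date=event_date,
                sex=g["sex"][j],
                age_years=float(age) if age is not None else None,
                weight_kg=weight,
                country=country,
                reporter=g["reporter"][j],
                outcomes=frozenset({Outcome.DEATH}) if g["fatal"] else
                    frozenset({Outcome.HOSPITALIZATION}),
                drugs=drugs,
                reactions=frozenset({_PT_CYCLE[gidx % len(_PT_CYCLE)]}),
                indications=frozenset({g["disease"][j]}),
                therapy_starts=therapy,
            ))
            gidx += 1
    return reports


_TABLE2_ROWS = (
    ("Myositis", 24, "Musculoskeletal and connective tissue disorders"),
    ("Myocarditis", 20, "Cardiac disorders"),
    ("Myasthenia gravis", 11, "Nervous system disorders"),
    ("Febrile neutropenia", 9, "Blood and lymphatic system disorders"),
    ("Pneumonitis", 7, "Respiratory, thoracic, and mediastinal disorders"),
    ("Respiratory failure", 7, "Respiratory, thoracic, and mediastinal disorders"),
    ("Pneumonia", 7, "Infections and infestations"),
    ("Adverse event", 6, "General disorders and administration-site conditions"),
    ("Transaminases increased", 6, "Investigations"),
    ("Dyspnea", 6, "Respiratory, thoracic, and mediastinal disorders"),
    ("Malignant neoplasm progression", 5,
     "Neoplasms benign, malignant, and unspecified (including cysts and polyps)"),
    ("Rash maculopapular", 5, "Skin and subcutaneous tissue disorders"),
    ("Hepatitis", 4, "Hepatobiliary disorders"),
    ("Cardiac failure", 4, "Cardiac disorders"),
    ("Hypoxia", 4, "Respiratory, thoracic, and mediastinal disorders"),
    ("Myelosuppression", 4, "Blood and lymphatic system disorders"),
    ("Myasthenic syndrome", 3, "Nervous system disorders"),
    ("Diplopia", 3, "Eye disorders"),
    ("Septic shock", 3, "Infections and infestations"),
    ("Fatigue", 3, "General disorders and administration-site conditions"),
)
_TOTAL_EVENTS = 476


def _build_cardiotox_reports() -> list[SafetyReport]:
    # 29 patients, 39 cardiac events: 20 myocarditis, 3 cardiac failure,
    # 7 patients with more than one distinct cardiac event type.
    multi = [
        {"Myocarditis", "Cardiac failure", "Pericarditis"},
        {"Myocarditis", "Cardiac failure", "Atrial fibrillation"},
        {"Myocarditis", "Cardiac failure", "Pericardial effusion"},
        {"Myocarditis", "Cardiac arrest"},
        {"Myocarditis", "Tachycardia"},
        {"Myocarditis", "Pericardial effusion"},
        {"Myocarditis", "Atrial fibrillation"},
    ]
    single_myo = [{"Myocarditis"}] * 13
    single_other = [
        {"Atrial fibrillation"}, {"Cardiac arrest"}, {"Pericardial effusion"},
        {"Tachycardia"}, {"Bradycardia"}, {"Cardiomyopathy"},
        {"Pericarditis"}, {"Palpitations"}, {"Myocardial infarction"},
    ]
    reaction_sets = multi + single_myo + single_other

    # myocarditis sub-series detail (patients 0..19): 11 female, ages with
    # median 58, 15 thymoma / 5 thymic carcinoma, 19 on PD-1 inhibitors,
    # 6 with onset data at median 7 days
    myo_ages = [44, 46, 48, 50, 52, 54, 56, 57, 58, 58,
                58, 59, 60, 62, 64, 66, 68, 70, 72, 74]
    myo_sex = [Sex.FEMALE] * 11 + [Sex.MALE] * 9
    myo_disease = ["Thymoma"] * 15 + ["Thymic carcinoma"] * 5
    myo_drug = ["NIVOLUMAB"] * 10 + ["PEMBROLIZUMAB"] * 9 + ["ATEZOLIZUMAB"]
    myo_tto = {0: 3, 1: 5, 2: 7, 3: 7, 4: 9, 5: 30}

    reports = []
    for i, reactions in enumerate(reaction_sets):
        caseid = 9_000_001 + i
        if i < 20:
            sex, age = myo_sex[i], myo_ages[i]
            disease, drug = myo_disease[i], myo_drug[i]
        else:
            sex = Sex.MALE if i % 2 else Sex.FEMALE
            age = 50 + i
            disease = "Thymoma" if i % 2 else "Thymic carcinoma"
            drug = "PEMBROLIZUMAB"
        event_date = None
        therapy = []
        if i in myo_tto:
            start = datetime.date(2022, 3, 1) + datetime.timedelta(days=40 * i)
            event = start + datetime.timedelta(days=myo_tto[i])
            therapy = [(0, PartialDate(start.year, start.month, start.day))]
            event_date = PartialDate(event.year, event.month, event.day)
        reports.append(SafetyReport(
            primaryid=caseid * 10 + 1, caseid=caseid,
            fda_date=PartialDate(2024, 6, 1 + (i % 28)),
            event_date=event_date, sex=sex, age_years=float(age),
            country="US", reporter=Reporter.HEALTHCARE_PROFESSIONAL,
            outcomes=frozenset(),
            drugs=[DrugEntry(drug, drug, DrugRole.PRIMARY_SUSPECT)],
            reactions=frozenset(reactions),
            indications=frozenset({disease}),
        ))
    return reports


def build_paper_fixture(name: str) -> PaperFixture:
    """Build one published-cohort fixture; marginals re-checked at build.

    Names: ``table1_cohort`` (152 reports with the published cohort-table
    marginals), ``tto_subset`` (56 onset records), ``cardiotox_subset``
    (29 cardiac-event patients), ``pt_counts`` (top-20 PT count rows over a
    476-event denominator).
    """
    import pandas as pd  # local import keeps module import light

    if name == "table1_cohort":
        reports = _build_table1_reports()
        fx = PaperFixture(name, reports=reports,
                          meta={"n": 152, "n_fatal": 36, "n_nonfatal": 116})
        _check(len(reports) == 152, "table1_cohort size")
        _check(sum(1 for r in reports if r.fatal) == 36, "fatal count")
        _self_test_table1(reports)
        return fx

    if name == "tto_subset":
        from .cohort import extract_cohort
        from .dedup import dedupe
        from .time_to_onset import collect_tto
        cases = extract_cohort(dedupe(_build_table1_reports()))
        records, _ = collect_tto(cases)
        _check(len(records) == 56, "tto_subset size")
        days = sorted(r.days for r in records)
        _check(float(np.median(days)) == 21.0, "tto median")
        _check(sum(1 for d in days if d <= 60) == 41, "onset within 60 days")
        return PaperFixture(name, records=records,
                            meta={"n": 56, "median_days": 21.0, "n_within_60": 41})

    if name == "cardiotox_subset":
        reports = _build_cardiotox_reports()
        events = [pt for r in reports for pt in r.reactions]
        _check(len(reports) == 29, "cardiotox patients")
        _check(len(events) == 39, "cardiac events")
        _check(events.count("Myocarditis") == 20, "myocarditis events")
        _check(events.count("Cardiac failure") == 3, "cardiac failure events")
        _check(sum(1 for r in reports if len(r.reactions) > 1) == 7,
               "multi-event patients")
        return PaperFixture(name, reports=reports,
                            meta={"n_patients": 29, "n_events": 39})

    if name == "pt_counts":
        df = pd.DataFrame(_TABLE2_ROWS, columns=["pt", "n", "soc"])
        from .faers_io import round_half_up
        df["pct"] = [round_half_up(100 * v / _TOTAL_EVENTS, 2) for v in df["n"]]
        df.attrs["total_events"] = _TOTAL_EVENTS
        _check(int(df["n"].sum()) == 141, "top-20 event sum")
        _check(df.loc[0, "pt"] == "Myositis" and int(df.loc[0, "n"]) == 24,
               "leading PT row")
        return PaperFixture(name, records=df, meta={"total_events": _TOTAL_EVENTS})

    raise ValueError(f"unknown fixture name: {name!r}")


def _check(condition: bool, what: str) -> None:
    if not condition:
        raise RuntimeError(f"fixture self-test failed: {what}")


def _self_test_table1(reports: list) -> None:
    """Re-derive every published marginal through the analysis chain."""
    from .cohort import Disease, Regimen, extract_cohort
    from .dedup import dedupe
    from .descriptive import summarize

    deduped = dedupe(list(reports))
    _check(len(deduped) == 152, "dedup must not remove fixture reports")
    cases = extract_cohort(deduped)
    _check(len(cases) == 152, "cohort chain must keep all fixture reports")

    expected = {
        ("sex", "Male"): (16, 64), ("sex", "Female"): (20, 42),
        ("sex", "Missing"): (0, 10),
        ("age_band", "18-64"): (18, 54), ("age_band", "65-74"): (3, 28),
        ("age_band", ">=75"): (3, 6), ("age_band", "Missing"): (12, 28),
        ("weight_band", "<70"): (8, 32), ("weight_band", ">=70"): (3, 25),
        ("weight_band", "Missing"): (25, 59),
        ("disease", "thymoma"): (15, 46),
        ("disease", "thymic_carcinoma"): (21, 70),
        ("country", "US"): (12, 39), ("country", "JP"): (0, 16),
        ("country", "CN"): (1, 13), ("country", "FR"): (2, 12),
        ("country", "ES"): (1, 6), ("country", "KR"): (5, 2),
        ("country", "Other country"): (15, 28),
        ("regimen", "anti_PD1"): (29, 72), ("regimen", "anti_PDL1"): (3, 36),
        ("regimen", "combination_ICI"): (4, 8),
        ("reporter", "Consumer"): (10, 24),
        ("reporter", "Health care professional"): (26, 92),
        ("with_chemo_or_targeted", "ICI only"): (32, 98),
        ("with_chemo_or_targeted", "ICI + chemo/targeted"): (4, 18),
    }
    table = summarize(cases)
    got = {
        (row["variable"], row["level"]): (row["count_fatal"], row["count_nonfatal"])
        for _, row in table.iterrows()
    }
    for key, counts in expected.items():
        _check(got.get(key) == counts, f"marginal {key} -> {got.get(key)} != {counts}")
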