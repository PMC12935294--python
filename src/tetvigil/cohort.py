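"""Cohort extraction: indication matching, primary-suspect filtering and
regimen classification.

A report enters the analysis cohort when (a) at least one of its indications
matches the thymic-epithelial-tumor catalog and (b) at least one drug with
role *primary suspect* harmonizes to an immune-checkpoint-inhibitor (ICI)
ingredient. Reported drug names (generic, brand, common variants) are mapped
to active-ingredient names and drug classes through an editable TSV
dictionary; indication matching is exact-string (case-insensitive) against
an editable term catalog — deliberately not substring matching, so that
e.g. "Thymoma" cannot fire inside unrelated terms.

Regimen classification: a case whose suspect drugs span two or more ICI
classes is combination ICI therapy; otherwise the single class. A separate
flag records co-administration of chemotherapy or targeted agents (suspect
or concomitant).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .faers_io import DrugClass, DrugRole, SafetyReport

__all__ = [
    "Disease",
    "Regimen",
    "DrugDictionary",
    "CaseRecord",
    "load_indication_catalog",
    "match_indication",
    "filter_primary_suspect_ici",
    "classify_regimen",
    "extract_cohort",
]


class Disease(str, enum.Enum):
    THYMOMA = "thymoma"
    THYMIC_CARCINOMA = "thymic_carcinoma"
    THYMIC_NET = "thymic_NET"
    UNSPECIFIED_TET = "unspecified_TET"


class Regimen(str, enum.Enum):
    ANTI_PD1 = "anti_PD1"
    ANTI_PDL1 = "anti_PDL1"
    ANTI_CTLA4 = "anti_CTLA4"
    COMBINATION_ICI = "combination_ICI"


ICI_CLASSES = frozenset({DrugClass.ANTI_PD1, DrugClass.ANTI_PDL1, DrugClass.ANTI_CTLA4})

# more specific / more malignant classes win when a report lists indications
# from several disease classes
_DISEASE_PRIORITY = [
    Disease.THYMIC_CARCINOMA,
    Disease.THYMIC_NET,
    Disease.THYMOMA,
    Disease.UNSPECIFIED_TET,
]


def _norm(name: str) -> str:
    return " ".join(name.split()).upper()


@dataclass
class DrugDictionary:
    """Reported-name -> (harmonized ingredient, drug class) lookup.

    Lookup is case-insensitive and whitespace-normalized. Names not in the
    table resolve to themselves with class ``other``.
    """

    entries: dict = field(default_factory=dict)  # norm name -> (ingredient, DrugClass)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugDictionary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries = {
            _norm(row["name"]): (_norm(row["ingredient"]), DrugClass(row["drug_class"]))
            for _, row in df.iterrows()
        }
        return cls(entries)

    @classmethod
    def default(cls) -> "DrugDictionary":
        with resources.as_file(
            resources.files("tetvigil.data") / "drug_dictionary.tsv"
        ) as p:
            return cls.from_tsv(p)

    def lookup(self, name: str) -> Optional[tuple[str, DrugClass]]:
        return self.entries.get(_norm(name))

    def resolve(self, name: str) -> tuple[str, DrugClass]:
        """Like lookup, but unknown names map to themselves with class other."""
        hit = self.lookup(name)
        if hit is not None:
            return hit
        return _norm(name), DrugClass.OTHER

    def ici_ingredients(self) -> frozenset:
        return frozenset(
            ing for ing, cls in self.entries.values() if cls in ICI_CLASSES
        )


def load_indication_catalog(path: str | Path | None = None) -> dict:
    """Map of normalized indication term -> :class:`Disease`."""
    if path is None:
        with resources.as_file(
            resources.files("tetvigil.data") / "indication_catalog.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return {_norm(row["term"]): Disease(row["disease"]) for _, row in df.iterrows()}


@dataclass
class CaseRecord:
    """One analysis-cohort case: a deduplicated report plus its derived
    disease, regimen and co-therapy labels."""

    report: SafetyReport
    disease: Disease
    regimen: Regimen
    with_chemo_or_targeted: bool

    @property
    def fatal(self) -> bool:
        return self.report.fatal


def match_indication(
    report: SafetyReport, term_catalog: dict
) -> Optional[Disease]:
    """Return the disease class of the report's indications, or None.

    Exact-string match (case-insensitive, whitespace-normalized). When
    indications hit several disease classes, the more specific/malignant one
    wins: carcinoma > neuroendocrine > thymoma > unspecified.
    """
    hits = {
        term_catalog[_norm(ind)]
        for ind in report.indications
        if _norm(ind) in term_catalog
    }
    if not hits:
        return None
    for disease in _DISEASE_PRIORITY:
        if disease in hits:
            return disease
    return None  # pragma: no cover — priority list is exhaustive


def _harmonize_drugs(report: SafetyReport, drug_dict: DrugDictionary) -> None:
    """Rewrite each DrugEntry's ingredient/class from the dictionary.

    The reported name is tried first, then the preliminary ingredient (which
    for FAERS rows is PROD_AI).
    """
    for d in report.drugs:
        hit = drug_dict.lookup(d.reported_name) or drug_dict.lookup(d.ingredient)
        if hit is not None:
            d.ingredient, d.drug_class = hit
        else:
            d.ingredient = _norm(d.ingredient)
            d.drug_class = DrugClass.OTHER


def classify_regimen(
    case: SafetyReport | CaseRecord,
) -> tuple[Regimen, bool]:
    """Classify the ICI regimen and the chemo/targeted co-therapy flag.

    Suspect drugs (primary or secondary suspect) define the regimen:
    two or more distinct ICI classes -> combination ICI, else the single
    class. The co-therapy flag is true when any suspect *or concomitant*
    drug maps to chemotherapy or a targeted agent. Pure function of the drug
    set (order-invariant).
    """
    report = case.report if isinstance(case, CaseRecord) else case
    suspect_roles = {DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT}
    ici_classes = {
        d.drug_class for d in report.drugs
        if d.role in suspect_roles and d.drug_class in ICI_CLASSES
    }
    if not ici_classes:
        raise ValueError("classify_regimen requires at least one suspect ICI")
    if len(ici_classes) >= 2:
        regimen = Regimen.COMBINATION_ICI
    else:
        regimen = Regimen((next(iter(ici_classes))).value)
    with_chemo = any(
        d.drug_class in (DrugClass.CHEMOTHERAPY, DrugClass.TARGETED)
        for d in report.drugs
    )
    return regimen, with_chemo


def filter_primary_suspect_ici(
    reports: Sequence[SafetyReport],
    drug_dict: DrugDictionary,
    term_catalog: Optional[dict] = None,
    audit: Optional[list] = None,
) -> list[CaseRecord]:
    """Keep reports with >=1 primary-suspect drug harmonizing to an ICI.

    Drug entries are harmonized in place via the dictionary. If a term
    catalog is given, the report's disease is resolved through
    :func:`match_indication` (no-match reports are dropped); otherwise the
    disease is recorded as unspecified.
    """
    cases: list[CaseRecord] = []
    for r in reports:
        _harmonize_drugs(r, drug_dict)
        if term_catalog is not None:
            disease = match_indication(r, term_catalog)
            if disease is None:
                if audit is not None:
                    audit.append({"stage": "indication", "dropped": r.primaryid,
                                  "reason": "no TET indication"})
                continue
        else:
            disease = Disease.UNSPECIFIED_TET
        has_ps_ici = any(
            d.role is DrugRole.PRIMARY_SUSPECT and d.drug_class in ICI_CLASSES
            for d in r.drugs
        )
        if not has_ps_ici:
            if audit is not None:
                audit.append({"stage": "primary_suspect", "dropped": r.primaryid,
                              "reason": "no primary-suspect ICI"})
            continue
        regimen, with_chemo = classify_regimen(r)
        cases.append(CaseRecord(r, disease, regimen, with_chemo))
    return cases


def extract_cohort(
    reports: Sequence[SafetyReport],
    drug_dict: Optional[DrugDictionary] = None,
    term_catalog: Optional[dict] = None,
    audit: Optional[list] = None,
) -> list[CaseRecord]:
    """Full cohort chain on deduplicated reports: indication filter,
    primary-suspect ICI filter, regimen classification."""
    if drug_dict is None:
        drug_dict = DrugDictionary.default()
    if term_catalog is None:
        term_catalog = load_indication_catalog()
    return filter_primary_suspect_ici(reports, drug_dict, term_catalog, audit)
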