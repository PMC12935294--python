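"""Reading and writing FAERS-style quarterly ASCII extracts.

FAERS quarters are distributed as six '$'-delimited text tables (DEMO, DRUG,
REAC, INDI, THER, OUTC) that cross-reference each other through PRIMARYID.
This module parses one quarter directory into report-level
:class:`SafetyReport` records, and serializes reports and result tables back
out. Dates in FAERS are encoded as bare digit strings of length 4, 6 or 8
(``YYYY``, ``YYYYMM``, ``YYYYMMDD``); :class:`PartialDate` preserves that
precision rather than coercing to a full date.

The '$' delimiter is taken as-is from the FAERS ASCII dialect: fields are not
quoted, and an embedded '$' inside free text is not supported (documented
limitation).
"""

from __future__ import annotations

import datetime
import enum
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Precision",
    "PartialDate",
    "DrugRole",
    "DrugClass",
    "Sex",
    "Reporter",
    "Outcome",
    "DrugEntry",
    "SafetyReport",
    "parse_partial_date",
    "parse_quarter",
    "write_quarter",
    "write_table",
    "round_half_up",
    "AGE_UNIT_YEARS",
]


# ---------------------------------------------------------------------------
# enumerations
# ---------------------------------------------------------------------------

class Precision(str, enum.Enum):
    YEAR = "year"
    MONTH = "month"
    DAY = "day"


class DrugRole(str, enum.Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


class DrugClass(str, enum.Enum):
    ANTI_PD1 = "anti_PD1"
    ANTI_PDL1 = "anti_PDL1"
    ANTI_CTLA4 = "anti_CTLA4"
    CHEMOTHERAPY = "chemotherapy"
    TARGETED = "targeted"
    OTHER = "other"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Reporter(str, enum.Enum):
    HEALTHCARE_PROFESSIONAL = "healthcare_professional"
    CONSUMER = "consumer"
    UNKNOWN = "unknown"


class Outcome(str, enum.Enum):
    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    OTHER = "other"


# FAERS code -> enum maps
_ROLE_CODES = {
    "PS": DrugRole.PRIMARY_SUSPECT,
    "SS": DrugRole.SECONDARY_SUSPECT,
    "C": DrugRole.CONCOMITANT,
    "I": DrugRole.INTERACTING,
}
_ROLE_TO_CODE = {v: k for k, v in _ROLE_CODES.items()}

_SEX_CODES = {"M": Sex.MALE, "F": Sex.FEMALE}
_SEX_TO_CODE = {Sex.MALE: "M", Sex.FEMALE: "F", Sex.UNKNOWN: "UNK"}

# FAERS occupation codes: MD physician, PH pharmacist, HP other health
# professional, OT other, CN consumer, LW lawyer.
_REPORTER_CODES = {
    "MD": Reporter.HEALTHCARE_PROFESSIONAL,
    "PH": Reporter.HEALTHCARE_PROFESSIONAL,
    "HP": Reporter.HEALTHCARE_PROFESSIONAL,
    "OT": Reporter.HEALTHCARE_PROFESSIONAL,
    "CN": Reporter.CONSUMER,
    "LW": Reporter.CONSUMER,
}

_OUTCOME_CODES = {
    "DE": Outcome.DEATH,
    "LT": Outcome.LIFE_THREATENING,
    "HO": Outcome.HOSPITALIZATION,
    "DS": Outcome.DISABILITY,
    "CA": Outcome.OTHER,
    "RI": Outcome.OTHER,
    "OT": Outcome.OTHER,
}
_OUTCOME_TO_CODE = {
    Outcome.DEATH: "DE",
    Outcome.LIFE_THREATENING: "LT",
    Outcome.HOSPITALIZATION: "HO",
    Outcome.DISABILITY: "DS",
    Outcome.OTHER: "OT",
}

# Multiplier from the FAERS AGE_COD unit to years.
AGE_UNIT_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_WEIGHT_UNIT_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.453592, "GMS": 0.001}


# ---------------------------------------------------------------------------
# PartialDate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialDate:
    """A calendar date known to year, month or day precision.

    Ordering between dates of different precision pads the missing month/day
    with 1 (the earliest interpretation); callers that need a total order on
    reports break remaining ties on PRIMARYID.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1000 <= self.year <= 9999:
            raise ValueError(f"year out of range: {self.year}")
        if self.day is not None and self.month is None:
            raise ValueError("day precision requires a month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # raises ValueError for invalid calendar dates (e.g. Feb 30)
            datetime.date(self.year, self.month, self.day)

    @property
    def precision(self) -> Precision:
        if self.day is not None:
            return Precision.DAY
        if self.month is not None:
            return Precision.MONTH
        return Precision.YEAR

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 1, self.day or 1)

    def to_date(self) -> datetime.date:
        """Exact calendar date; only defined at day precision."""
        if self.precision is not Precision.DAY:
            raise ValueError(f"not day-precision: {self}")
        return datetime.date(self.year, self.month, self.day)

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_partial_date(raw: str | None) -> Optional[PartialDate]:
    """Parse a FAERS date string (``YYYY``, ``YYYYMM`` or ``YYYYMMDD``).

    Returns None for empty input, wrong length, non-digits, or invalid
    calendar dates (e.g. ``20230230``).
    """
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    if not raw.isdigit() or len(raw) not in (4, 6, 8):
        return None
    try:
        if len(raw) == 4:
            return PartialDate(int(raw))
        if len(raw) == 6:
            return PartialDate(int(raw[:4]), int(raw[4:6]))
        return PartialDate(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# report-level data model
# ---------------------------------------------------------------------------

@dataclass
class DrugEntry:
    """One drug row of a report.

    ``ingredient`` holds the harmonized active-ingredient name (uppercase);
    straight after parsing it is the normalized reported name, and the cohort
    module's drug dictionary rewrites it (with ``drug_class``) on lookup.
    """

    reported_name: str
    ingredient: str
    role: DrugRole
    drug_class: Optional[DrugClass] = None

    def __post_init__(self) -> None:
        if not self.ingredient:
            raise ValueError("ingredient must be non-empty")


@dataclass
class SafetyReport:
    """One spontaneous adverse-event report (pre- or post-deduplication)."""

    primaryid: int
    caseid: int
    fda_date: PartialDate
    event_date: Optional[PartialDate] = None
    sex: Sex = Sex.UNKNOWN
    age_years: Optional[float] = None
    weight_kg: Optional[float] = None
    country: str = ""
    reporter: Reporter = Reporter.UNKNOWN
    outcomes: frozenset = field(default_factory=frozenset)
    drugs: list = field(default_factory=list)
    reactions: frozenset = field(default_factory=frozenset)
    indications: frozenset = field(default_factory=frozenset)
    therapy_starts: list = field(default_factory=list)  # [(drug index, PartialDate)]

    @property
    def fatal(self) -> bool:
        return Outcome.DEATH in self.outcomes

    def ingredient_set(self) -> frozenset:
        return frozenset(d.ingredient for d in self.drugs)


# ---------------------------------------------------------------------------
# quarter parsing
# ---------------------------------------------------------------------------

_TABLES = ("demo", "drug", "reac", "indi", "ther", "outc")

_REQUIRED_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "reac": ["primaryid", "pt"],
    "indi": ["primaryid", "indi_pt"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt"],
    "outc": ["primaryid", "outc_cod"],
}


def _find_table_file(directory: Path, table: str) -> Path:
    matches = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.name.lower().startswith(table) and p.suffix.lower() == ".txt"
    )
    if not matches:
        raise FileNotFoundError(
            f"mandatory FAERS table file missing: no '{table.upper()}*.txt' in {directory}"
        )
    return matches[0]


def _read_table(path: Path, table: str) -> pd.DataFrame:
    with open(path) as fh:
        header = [c.strip().lower() for c in fh.readline().rstrip("\n").split("$")]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate column names in {path.name}")
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS[table] if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name} lacks required column(s): {missing}")
    return df


def _to_float(raw: str) -> Optional[float]:
    try:
        return float(raw)
    except (TypeError, ValueError):
        return None


def parse_quarter(
    directory_path: str | Path, strict: bool = False
) -> tuple[list[SafetyReport], list[dict]]:
    """Parse one FAERS-style quarter directory into SafetyReports.

    Returns ``(reports, parse_log)`` where the log is a list of JSON-able
    dicts describing skipped rows and coercions. One report is produced per
    DEMO row; DRUG/REAC/INDI/THER/OUTC rows are joined on primaryid. With
    ``strict=True`` any row-level failure aborts with ValueError instead of
    being logged and skipped.
    """
    directory = Path(directory_path)
    frames = {t: _read_table(_find_table_file(directory, t), t) for t in _TABLES}
    log: list[dict] = []

    def note(**entry) -> None:
        if strict and entry.get("level") == "error":
            raise ValueError(f"parse failure in {directory}: {entry}")
        log.append(entry)

    grouped = {
        t: dict(tuple(frames[t].groupby("primaryid", sort=False)))
        for t in _TABLES if t != "demo"
    }

    reports: list[SafetyReport] = []
    for _, row in frames["demo"].iterrows():
        pid_raw = row["primaryid"].strip()
        try:
            primaryid = int(pid_raw)
            caseid = int(row["caseid"].strip())
        except ValueError:
            note(level="error", table="demo", primaryid=pid_raw,
                 reason="non-integer primaryid/caseid")
            continue
        fda_date = parse_partial_date(row.get("fda_dt", ""))
        if fda_date is None:
            note(level="error", table="demo", primaryid=pid_raw,
                 reason="missing or invalid fda_dt")
            continue

        event_date = parse_partial_date(row.get("event_dt", ""))
        sex = _SEX_CODES.get(row.get("sex", "").strip().upper(), Sex.UNKNOWN)

        age_years = None
        age_val = _to_float(row.get("age", ""))
        if age_val is not None:
            unit = row.get("age_cod", "YR").strip().upper() or "YR"
            if unit in AGE_UNIT_YEARS:
                age_years = age_val * AGE_UNIT_YEARS[unit]
                if age_years < 0:
                    note(level="warning", table="demo", primaryid=pid_raw,
                         reason="negative age dropped")
                    age_years = None
            else:
                note(level="warning", table="demo", primaryid=pid_raw,
                     reason=f"unknown age unit {unit!r}; age dropped")

        weight_kg = None
        wt_val = _to_float(row.get("wt", ""))
        if wt_val is not None and wt_val > 0:
            wt_unit = row.get("wt_cod", "KG").strip().upper() or "KG"
            factor = _WEIGHT_UNIT_KG.get(wt_unit)
            if factor is None:
                note(level="warning", table="demo", primaryid=pid_raw,
                     reason=f"unknown weight unit {wt_unit!r}; weight dropped")
            else:
                weight_kg = wt_val * factor

        country = _normalize_country(row.get("reporter_country", ""))
        reporter = _REPORTER_CODES.get(
            row.get("occp_cod", "").strip().upper(), Reporter.UNKNOWN
        )

        key = row["primaryid"]
        drugs: list[DrugEntry] = []
        seq_to_index: dict[str, int] = {}
        drug_rows = grouped["drug"].get(key)
        if drug_rows is not None:
            for _, d in drug_rows.iterrows():
                name = d["drugname"].strip()
                if not name:
                    note(level="warning", table="drug", primaryid=pid_raw,
                         reason="empty drugname skipped")
                    continue
                code = d["role_cod"].strip().upper()
                role = _ROLE_CODES.get(code)
                if role is None:
                    note(level="warning", table="drug", primaryid=pid_raw,
                         reason=f"unknown role code {code!r}; mapped to concomitant")
                    role = DrugRole.CONCOMITANT
                ingredient = (d.get("prod_ai", "") or "").strip().upper() or name.upper()
                seq_to_index[d["drug_seq"].strip()] = len(drugs)
                drugs.append(DrugEntry(name, ingredient, role))

        reac_rows = grouped["reac"].get(key)
        reactions = frozenset(
            p.strip() for p in (reac_rows["pt"] if reac_rows is not None else [])
            if p.strip()
        )
        indi_rows = grouped["indi"].get(key)
        indications = frozenset(
            p.strip() for p in (indi_rows["indi_pt"] if indi_rows is not None else [])
            if p.strip()
        )

        therapy_starts: list[tuple[int, PartialDate]] = []
        ther_rows = grouped["ther"].get(key)
        if ther_rows is not None:
            for _, t in ther_rows.iterrows():
                start = parse_partial_date(t.get("start_dt", ""))
                idx = seq_to_index.get(t["dsg_drug_seq"].strip())
                if start is not None and idx is not None:
                    therapy_starts.append((idx, start))

        outc_rows = grouped["outc"].get(key)
        outcomes = frozenset(
            _OUTCOME_CODES.get(c.strip().upper(), Outcome.OTHER)
            for c in (outc_rows["outc_cod"] if outc_rows is not None else [])
            if c.strip()
        )

        reports.append(SafetyReport(
            primaryid=primaryid, caseid=caseid, fda_date=fda_date,
            event_date=event_date, sex=sex, age_years=age_years,
            weight_kg=weight_kg, country=country, reporter=reporter,
            outcomes=outcomes, drugs=drugs, reactions=reactions,
            indications=indications, therapy_starts=therapy_starts,
        ))

    return reports, log


# A pragmatic reporter_country normalization: recognizable names are mapped
# to uppercase ISO 3166-1 alpha-2 codes, anything else is kept verbatim
# (uppercased). Extend via the cohort config if needed.
_COUNTRY_MAP = {
    "UNITED STATES": "US", "UNITED STATES OF AMERICA": "US", "USA": "US",
    "JAPAN": "JP", "CHINA": "CN", "FRANCE": "FR", "SPAIN": "ES",
    "KOREA, REPUBLIC OF": "KR", "SOUTH KOREA": "KR", "KOREA, SOUTH": "KR",
    "GERMANY": "DE", "ITALY": "IT", "UNITED KINGDOM": "GB", "GREAT BRITAIN": "GB",
    "CANADA": "CA", "AUSTRALIA": "AU", "BRAZIL": "BR", "INDIA": "IN",
    "NETHERLANDS": "NL", "SWITZERLAND": "CH", "BELGIUM": "BE", "AUSTRIA": "AT",
    "PORTUGAL": "PT", "GREECE": "GR", "POLAND": "PL", "SWEDEN": "SE",
    "DENMARK": "DK", "NORWAY": "NO", "FINLAND": "FI", "IRELAND": "IE",
    "ISRAEL": "IL", "TURKEY": "TR", "MEXICO": "MX", "ARGENTINA": "AR",
    "TAIWAN": "TW", "THAILAND": "TH", "SINGAPORE": "SG", "RUSSIA": "RU",
    "CZECH REPUBLIC": "CZ", "HUNGARY": "HU", "ROMANIA": "RO",
}


def _normalize_country(raw: str) -> str:
    s = " ".join(raw.split()).upper()
    return _COUNTRY_MAP.get(s, s)


# ---------------------------------------------------------------------------
# quarter writing (inverse of parse_quarter; used by the synthetic generator)
# ---------------------------------------------------------------------------

def write_quarter(reports: Sequence[SafetyReport], directory: str | Path) -> Path:
    """Serialize reports into the six '$'-delimited quarter files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    demo, drug, reac, indi, ther, outc = [], [], [], [], [], []
    for r in sorted(reports, key=lambda r: r.primaryid):
        demo.append({
            "primaryid": r.primaryid, "caseid": r.caseid,
            "fda_dt": str(r.fda_date),
            "event_dt": str(r.event_date) if r.event_date else "",
            "sex": _SEX_TO_CODE[r.sex] if r.sex is not Sex.UNKNOWN else "",
            "age": _format_age(r.age_years), "age_cod": "YR" if r.age_years is not None else "",
            "wt": f"{r.weight_kg:g}" if r.weight_kg is not None else "",
            "wt_cod": "KG" if r.weight_kg is not None else "",
            "reporter_country": r.country,
            "occp_cod": {"healthcare_professional": "MD", "consumer": "CN"}.get(
                r.reporter.value, ""),
        })
        for i, d in enumerate(r.drugs, start=1):
            drug.append({
                "primaryid": r.primaryid, "drug_seq": i,
                "role_cod": _ROLE_TO_CODE[d.role],
                "drugname": d.reported_name, "prod_ai": d.ingredient,
            })
        for pt in sorted(r.reactions):
            reac.append({"primaryid": r.primaryid, "pt": pt})
        for pt in sorted(r.indications):
            indi.append({"primaryid": r.primaryid, "indi_pt": pt})
        for idx, start in r.therapy_starts:
            ther.append({
                "primaryid": r.primaryid, "dsg_drug_seq": idx + 1,
                "start_dt": str(start),
            })
        for o in sorted(r.outcomes, key=lambda o: o.value):
            outc.append({"primaryid": r.primaryid, "outc_cod": _OUTCOME_TO_CODE[o]})

    tables = {"demo": demo, "drug": drug, "reac": reac, "indi": indi,
              "ther": ther, "outc": outc}
    columns = {
        "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
                 "age_cod", "wt", "wt_cod", "reporter_country", "occp_cod"],
        "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
        "reac": ["primaryid", "pt"],
        "indi": ["primaryid", "indi_pt"],
        "ther": ["primaryid", "dsg_drug_seq", "start_dt"],
        "outc": ["primaryid", "outc_cod"],
    }
    for name, rows in tables.items():
        df = pd.DataFrame(rows, columns=columns[name])
        df.to_csv(directory / f"{name}.txt", sep="$", index=False, lineterminator="\n")
    return directory


def _format_age(age_years: Optional[float]) -> str:
    if age_years is None:
        return ""
    if float(age_years).is_integer():
        return str(int(age_years))
    return repr(float(age_years))


# ---------------------------------------------------------------------------
# result-table writing
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (the convention used for printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# column-name driven rendering precision: RORs and CI bounds to 2 decimals,
# percentages to 1 decimal
_TWO_DP = {"ror", "ci_low", "ci_high", "statistic", "shape", "scale",
           "shape_ci_low", "shape_ci_high", "scale_ci_low", "scale_ci_high"}


def _render(col: str, value) -> object:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if value != value:  # NaN
            return "NA"
        low = col.lower()
        if low in _TWO_DP:
            return f"{value:.2f}"
        if "pct" in low or low.endswith("_percent"):
            return f"{round_half_up(value, 1):.1f}"
    if isinstance(value, (frozenset, set)):
        return ";".join(sorted(map(str, value)))
    return value


def write_table(rows: Iterable, path: str | Path, format: str = "tsv") -> Path:
    """Write homogeneous records (dataclasses, dicts, or a DataFrame) to
    TSV/CSV with a deterministic column order and fixed numeric rendering."""
    if format not in ("tsv", "csv"):
        raise ValueError(f"unsupported format: {format}")
    path = Path(path)
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        dicts = []
        for r in rows:
            if hasattr(r, "to_row"):
                dicts.append(r.to_row())
            elif hasattr(r, "__dataclass_fields__"):
                dicts.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            else:
                dicts.append(dict(r))
        cols = list(dicts[0].keys()) if dicts else []
        df = pd.DataFrame(dicts, columns=cols)
    for col in df.columns:
        df[col] = [_render(col, v) for v in df[col]]
    df.to_csv(path, sep="\t" if format == "tsv" else ",", index=False,
              lineterminator="\n")
    return path


def write_json_log(entries: list[dict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for e in entries:
            fh.write(json.dumps(e, default=str) + "\n")
    return path
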