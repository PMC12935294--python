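"""Quarter parsing, partial dates, and table writing."""

import pytest
from hypothesis import given, settings, strategies as st

from tetvigil import (
    ContingencyTable,
    DrugEntry,
    PartialDate,
    RORResult,
    SafetyReport,
    parse_partial_date,
    parse_quarter,
    write_quarter,
    write_table,
)
from tetvigil.faers_io import (
    DrugRole,
    Outcome,
    Precision,
    Reporter,
    Sex,
    round_half_up,
)

# ---------------------------------------------------------------------------
# partial dates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw,expected", [
    ("20230115", PartialDate(2023, 1, 15)),
    ("202302", PartialDate(2023, 2)),
    ("1999", PartialDate(1999)),
    ("20230230", None),      # invalid calendar day
    ("20231315", None),      # invalid month
    ("2023011", None),       # bad length
    ("2023ab15", None),
    ("", None),
    (None, None),
])
def test_parse_partial_date(raw, expected):
    assert parse_partial_date(raw) == expected


def test_partial_date_precision_and_ordering():
    assert PartialDate(2023, 1, 15).precision is Precision.DAY
    assert PartialDate(2023, 2).precision is Precision.MONTH
    assert PartialDate(2023).precision is Precision.YEAR
    # missing components pad to 1 (earliest interpretation)
    assert PartialDate(2023).sort_key() == (2023, 1, 1)
    assert PartialDate(2023, 2).sort_key() < PartialDate(2023, 2, 2).sort_key()


# ---------------------------------------------------------------------------
# quarter parsing from handwritten files
# ---------------------------------------------------------------------------

def _write_toy_quarter(d, demo_rows):
    (d / "demo.txt").write_text(
        "primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$wt$wt_cod$"
        "reporter_country$occp_cod\n" + "\n".join(demo_rows) + "\n")
    (d / "drug.txt").write_text(
        "primaryid$drug_seq$role_cod$drugname$prod_ai\n"
        "101$1$PS$KEYTRUDA$PEMBROLIZUMAB\n"
        "101$2$XX$CARBOPLATIN$CARBOPLATIN\n"
        "102$1$PS$OPDIVO$NIVOLUMAB\n")
    (d / "reac.txt").write_text(
        "primaryid$pt\n101$Myositis\n101$Myocarditis\n102$Nausea\n")
    (d / "indi.txt").write_text("primaryid$indi_pt\n101$Thymoma\n")
    (d / "ther.txt").write_text(
        "primaryid$dsg_drug_seq$start_dt\n101$1$20230101\n")
    (d / "outc.txt").write_text("primaryid$outc_cod\n101$DE\n")


def test_parse_quarter_joins_tables(tmp_path):
    _write_toy_quarter(tmp_path, [
        "101$11$20230301$20230122$F$62$YR$70$KG$JAPAN$MD",
        "102$12$20230302$$M$18$MON$$$UNITED STATES$CN",
    ])
    reports, log = parse_quarter(tmp_path)
    assert len(reports) == 2
    r = {x.primaryid: x for x in reports}
    assert r[101].reactions == frozenset({"Myositis", "Myocarditis"})
    assert r[101].age_years == 62.0
    assert r[101].country == "JP"
    assert r[101].fatal and not r[102].fatal
    assert r[101].indications == frozenset({"Thymoma"})
    assert r[101].therapy_starts == [(0, PartialDate(2023, 1, 1))]
    assert r[101].reporter is Reporter.HEALTHCARE_PROFESSIONAL
    assert r[102].reporter is Reporter.CONSUMER
    # 18 months -> 1.5 years
    assert r[102].age_years == pytest.approx(1.5)
    # unknown role code logged and mapped to concomitant
    assert r[101].drugs[1].role is DrugRole.CONCOMITANT
    assert any("unknown role code" in e.get("reason", "") for e in log)


def test_parse_quarter_bad_row_skipped_or_strict(tmp_path):
    _write_toy_quarter(tmp_path, [
        "101$11$20230301$$F$62$YR$$$JAPAN$MD",
        "bogus$12$20230302$$M$$$$$US$",
    ])
    reports, log = parse_quarter(tmp_path, strict=False)
    assert len(reports) == 1
    errors = [e for e in log if e.get("level") == "error"]
    assert len(errors) == 1  # report count == DEMO rows - logged failures
    with pytest.raises(ValueError):
        parse_quarter(tmp_path, strict=True)


def test_parse_quarter_missing_file_is_named(tmp_path):
    _write_toy_quarter(tmp_path, ["101$11$20230301$$F$62$YR$$$JAPAN$MD"])
    (tmp_path / "outc.txt").unlink()
    with pytest.raises(FileNotFoundError, match="OUTC"):
        parse_quarter(tmp_path)


def test_parse_quarter_duplicate_columns_rejected(tmp_path):
    _write_toy_quarter(tmp_path, ["101$11$20230301$$F$62$YR$$$JAPAN$MD"])
    (tmp_path / "reac.txt").write_text("primaryid$pt$pt\n101$Nausea$Nausea\n")
    with pytest.raises(ValueError, match="duplicate column"):
        parse_quarter(tmp_path)


def test_unknown_age_unit_drops_age(tmp_path):
    _write_toy_quarter(tmp_path, ["101$11$20230301$$F$62$ZZ$$$JAPAN$MD"])
    reports, log = parse_quarter(tmp_path)
    assert reports[0].age_years is None
    assert any("unknown age unit" in e.get("reason", "") for e in log)


# ---------------------------------------------------------------------------
# write-then-parse round trip (property test)
# ---------------------------------------------------------------------------

_words = st.sampled_from(
    ["Myositis", "Myocarditis", "Nausea", "Fatigue", "Rash", "Pneumonitis"])
_dates = st.one_of(
    st.builds(PartialDate, st.integers(2016, 2024)),
    st.builds(PartialDate, st.integers(2016, 2024), st.integers(1, 12)),
    st.builds(PartialDate, st.integers(2016, 2024), st.integers(1, 12),
              st.integers(1, 28)),
)


@st.composite
def _reports(draw):
    n_drugs = draw(st.integers(1, 3))
    drugs = [
        DrugEntry(f"DRUG{i}", draw(st.sampled_from(
            ["NIVOLUMAB", "ASPIRIN", "CARBOPLATIN"])),
            draw(st.sampled_from(list(DrugRole))))
        for i in range(n_drugs)
    ]
    therapy = [
        (i, draw(_dates)) for i in range(n_drugs) if draw(st.booleans())
    ]
    return SafetyReport(
        primaryid=draw(st.integers(1, 10**8)),
        caseid=draw(st.integers(1, 10**7)),
        fda_date=draw(_dates),
        event_date=draw(st.none() | _dates),
        sex=draw(st.sampled_from(list(Sex))),
        age_years=draw(st.none() | st.sampled_from([18.0, 62.0, 1.5, 80.25])),
        weight_kg=draw(st.none() | st.sampled_from([50.0, 70.5, 102.0])),
        country=draw(st.sampled_from(["US", "JP", "FR", "ZZ"])),
        reporter=draw(st.sampled_from(list(Reporter))),
        outcomes=frozenset(draw(st.sets(st.sampled_from(list(Outcome))))),
        drugs=drugs,
        reactions=frozenset(draw(st.sets(_words, min_size=1, max_size=3))),
        indications=frozenset(draw(st.sets(_words, max_size=2))),
        therapy_starts=therapy,
    )


@given(st.lists(_reports(), min_size=1, max_size=5,
                unique_by=lambda r: r.primaryid))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_write_then_parse_roundtrip(tmp_path_factory, reports):
    d = tmp_path_factory.mktemp("quarter")
    write_quarter(reports, d)
    parsed, log = parse_quarter(d)
    assert not [e for e in log if e.get("level") == "error"]
    parsed_by_id = {r.primaryid: r for r in parsed}
    assert set(parsed_by_id) == {r.primaryid for r in reports}
    for orig in reports:
        got = parsed_by_id[orig.primaryid]
        for attr in ("caseid", "fda_date", "event_date", "sex", "age_years",
                     "weight_kg", "country", "reporter", "outcomes",
                     "reactions", "indications"):
            assert getattr(got, attr) == getattr(orig, attr), attr
        assert [(d.ingredient, d.role) for d in got.drugs] == \
               [(d.ingredient, d.role) for d in orig.drugs]
        assert sorted(got.therapy_starts) == sorted(orig.therapy_starts)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def test_write_table_renders_ror_to_two_decimals(tmp_path):
    res = RORResult("Myositis", ContingencyTable(24, 128, 20000, 10**7),
                    113.152, 26.649, 480.338, True)
    path = write_table([res], tmp_path / "out.tsv")
    lines = path.read_text().splitlines()
    assert "113.15" in lines[1] and "26.65" in lines[1] and "480.34" in lines[1]


def test_write_table_empty_gives_header_only(tmp_path):
    path = write_table([], tmp_path / "empty.tsv")
    assert path.read_text().strip() == ""


def test_write_table_roundtrip(tmp_path):
    import pandas as pd
    rows = [{"pt": "Myositis", "n": 24}, {"pt": "Myocarditis", "n": 20}]
    path = write_table(rows, tmp_path / "t.csv", format="csv")
    back = pd.read_csv(path)
    assert back.to_dict("records") == rows


def test_round_half_up_matches_printed_convention():
    assert round_half_up(23.68421, 1) == 23.7
    assert round_half_up(5.0420, 2) == 5.04
    assert round_half_up(0.25, 1) == 0.3  # half goes up, not to even
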