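"""Synthetic corpus generator: determinism, manifest oracle, fixtures."""

import json

import numpy as np
import pytest

from tetvigil import (
    SpikeSpec,
    SyntheticSpec,
    build_paper_fixture,
    dedupe,
    generate_corpus,
    generate_reports,
)
from tetvigil.synthetic import spiked_probability


def test_same_seed_byte_identical(tmp_path):
    spec = SyntheticSpec(n_background_reports=300, seed=5,
                         spikes=(SpikeSpec("NIVOLUMAB", "Myositis", 20.0, 40),))
    d1, _ = generate_corpus(spec, tmp_path / "a")
    d2, _ = generate_corpus(spec, tmp_path / "b")
    for name in ("demo", "drug", "reac", "indi", "ther", "outc"):
        assert (d1 / f"{name}.txt").read_bytes() == (d2 / f"{name}.txt").read_bytes()
    assert (d1 / "manifest.json").read_bytes() == (d2 / "manifest.json").read_bytes()


def test_different_seed_differs(tmp_path):
    d1, _ = generate_corpus(SyntheticSpec(n_background_reports=300, seed=5),
                            tmp_path / "a")
    d2, _ = generate_corpus(SyntheticSpec(n_background_reports=300, seed=6),
                            tmp_path / "b")
    assert (d1 / "demo.txt").read_bytes() != (d2 / "demo.txt").read_bytes()


def test_no_duplicate_rates_means_dedup_removes_nothing():
    spec = SyntheticSpec(n_background_reports=500, duplicate_rate=0.0,
                         versioned_case_rate=0.0, seed=9)
    reports, manifest = generate_reports(spec)
    assert manifest["removed_primaryids"] == []
    assert len(dedupe(reports)) == len(reports)


def test_manifest_counts_match_direct_recount(small_spiked_spec):
    """Oracle: recount the 2x2 cells directly from the generated reports."""
    reports, manifest = generate_reports(small_spiked_spec)
    spike = manifest["spikes"][0]
    originals = [r for r in reports
                 if r.primaryid not in set(manifest["removed_primaryids"])]
    # identify exposed originals by their primary-suspect ingredient
    exposed = [r for r in originals
               if any(d.ingredient == "NIVOLUMAB" for d in r.drugs)]
    others = [r for r in originals
              if not any(d.ingredient == "NIVOLUMAB" for d in r.drugs)]
    # dedup keeps the newer version of re-versioned cases, which is field-
    # identical to the original, so recounting on survivors is equivalent
    a = sum(1 for r in exposed if "Pneumonitis" in r.reactions)
    c = sum(1 for r in others if "Pneumonitis" in r.reactions)
    assert (spike["a"], spike["c"]) == (a, c)
    assert spike["a"] + spike["b"] == len(exposed)
    assert spike["c"] + spike["d"] == len(others)


def test_spiked_probability_odds_transform():
    p0 = 0.005
    p1 = spiked_probability(10.0, p0)
    odds0, odds1 = p0 / (1 - p0), p1 / (1 - p1)
    assert odds1 / odds0 == pytest.approx(10.0)
    with pytest.raises(ValueError):
        spiked_probability(10.0, 0.0)
    with pytest.raises(ValueError):
        spiked_probability(10.0, 1.0)


def test_spike_pt_must_be_in_catalog():
    spec = SyntheticSpec(
        n_background_reports=50,
        spikes=(SpikeSpec("NIVOLUMAB", "No such PT", 10.0, 5),))
    with pytest.raises(ValueError, match="not in background catalog"):
        generate_reports(spec)


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(duplicate_rate=1.0)
    with pytest.raises(ValueError):
        SpikeSpec("X", "Nausea", -1.0, 10)
    with pytest.raises(ValueError):
        SpikeSpec("X", "Nausea", 2.0, 10, onset_shape=0.0)


def test_originals_distinct_on_dedup_key(small_spiked_spec):
    from tetvigil.dedup import _field_key
    reports, manifest = generate_reports(small_spiked_spec)
    removed = set(manifest["removed_primaryids"])
    dup_caseids = {d["caseid"] for d in manifest["duplicates"]
                   if d["kind"] == "copy"}
    keys = [
        k for r in reports
        if r.primaryid not in removed and r.caseid not in dup_caseids
        and (k := _field_key(r)) is not None
    ]
    assert len(keys) == len(set(keys))


def test_exposed_reports_carry_tet_indication_and_onsets(small_spiked_spec):
    reports, _ = generate_reports(small_spiked_spec)
    exposed = [r for r in reports
               if any(d.ingredient == "NIVOLUMAB" for d in r.drugs)]
    assert all(r.indications <= {"Thymoma", "Thymic carcinoma"} for r in exposed)
    with_dates = [r for r in exposed if r.event_date is not None]
    assert with_dates and all(r.therapy_starts for r in exposed)


# ---------------------------------------------------------------------------
# fixed published-cohort fixtures
# ---------------------------------------------------------------------------

def test_fixture_unknown_name():
    with pytest.raises(ValueError):
        build_paper_fixture("nope")


def test_table1_fixture_marginals(table1_fixture):
    reports = table1_fixture.reports
    assert len(reports) == 152
    assert sum(1 for r in reports if r.fatal) == 36
    # self-test already enforces the full marginal set at build time; spot-
    # check two published cells here
    from tetvigil import extract_cohort
    from tetvigil.cohort import Regimen
    cases = extract_cohort(dedupe(list(reports)))
    assert sum(1 for c in cases if c.regimen is Regimen.ANTI_PD1) == 101
    assert sum(1 for c in cases if c.report.country == "US") == 51


def test_tto_fixture_statistics(tto_fixture):
    days = sorted(r.days for r in tto_fixture.records)
    assert len(days) == 56
    assert float(np.median(days)) == 21.0
    assert sum(1 for d in days if d <= 60) == 41
    assert (days[0], days[-1]) == (2, 1250)
    fatal_days = sorted(r.days for r in tto_fixture.records if r.fatal)
    assert len(fatal_days) == 7
    assert float(np.median(fatal_days)) == 18.0
    assert (fatal_days[0], fatal_days[-1]) == (8, 266)


def test_cardiotox_fixture_composition(cardiotox_fixture):
    reports = cardiotox_fixture.reports
    events = [pt for r in reports for pt in r.reactions]
    assert (len(reports), len(events)) == (29, 39)
    assert events.count("Myocarditis") == 20
    assert events.count("Cardiac failure") == 3
    assert sum(1 for r in reports if len(r.reactions) > 1) == 7
    myo = [r for r in reports if "Myocarditis" in r.reactions]
    assert sum(1 for r in myo if r.sex.value == "female") == 11
    assert float(np.median([r.age_years for r in myo])) == 58.0


def test_pt_counts_fixture_rows(pt_counts_fixture):
    df = pt_counts_fixture.records
    assert df.attrs["total_events"] == 476
    top = df.iloc[0]
    assert (top.pt, int(top.n), top.soc) == (
        "Myositis", 24, "Musculoskeletal and connective tissue disorders")
    assert top.pct == 5.04
    assert int(df.n.sum()) == 141
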