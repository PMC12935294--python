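import pytest

from tetvigil import (
    DrugEntry,
    PartialDate,
    SafetyReport,
    SpikeSpec,
    SyntheticSpec,
    build_paper_fixture,
)
from tetvigil.faers_io import DrugRole, Outcome, Reporter, Sex


@pytest.fixture(scope="session")
def table1_fixture():
    return build_paper_fixture("table1_cohort")


@pytest.fixture(scope="session")
def tto_fixture():
    return build_paper_fixture("tto_subset")


@pytest.fixture(scope="session")
def cardiotox_fixture():
    return build_paper_fixture("cardiotox_subset")


@pytest.fixture(scope="session")
def pt_counts_fixture():
    return build_paper_fixture("pt_counts")


@pytest.fixture(scope="session")
def small_spiked_spec():
    """A corpus small enough for unit tests but with every structural
    feature switched on."""
    return SyntheticSpec(
        n_background_reports=3000,
        spikes=(SpikeSpec("NIVOLUMAB", "Pneumonitis", 10.0, 200),),
        duplicate_rate=0.05,
        versioned_case_rate=0.05,
        seed=11,
    )


def make_report(
    primaryid=1,
    caseid=1,
    fda="20230101",
    event=None,
    sex=Sex.MALE,
    age=60.0,
    country="US",
    reactions=("Nausea",),
    ingredients=("ASPIRIN",),
    fatal=False,
    role=DrugRole.PRIMARY_SUSPECT,
    indications=(),
    therapy_starts=(),
    reporter=Reporter.HEALTHCARE_PROFESSIONAL,
):
    """Compact SafetyReport builder for handcrafted test cases."""
    def pd_of(s):
        if s is None or isinstance(s, PartialDate):
            return s
        return PartialDate(int(s[:4]), int(s[4:6]) if len(s) > 4 else None,
                           int(s[6:8]) if len(s) > 6 else None)

    return SafetyReport(
        primaryid=primaryid,
        caseid=caseid,
        fda_date=pd_of(fda),
        event_date=pd_of(event),
        sex=sex,
        age_years=age,
        country=country,
        reporter=reporter,
        outcomes=frozenset({Outcome.DEATH}) if fatal else frozenset(),
        drugs=[DrugEntry(name, name, role) for name in ingredients],
        reactions=frozenset(reactions),
        indications=frozenset(indications),
        therapy_starts=list(therapy_starts),
    )
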