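import datetime as dt

import pytest

from pvsignal.reports import (
    ICSR,
    ChallengeResult,
    DrugRecord,
    DrugRole,
    Outcome,
    ReactionRecord,
    ReporterType,
    ReportType,
    Route,
    Sex,
)
from pvsignal.terms import TermDictionary


def make_report(
    report_id="R1",
    report_date=dt.date(2014, 6, 1),
    age=70.0,
    sex=Sex.male,
    drug="ranibizumab",
    role=DrugRole.suspected,
    route=Route.intravitreal,
    pts=("Parkinson's disease",),
    **kw,
) -> ICSR:
    """Fully-documented single-drug report; keyword overrides for variants."""
    defaults = dict(
        report_id=report_id,
        report_date=report_date,
        age_years=age,
        sex=sex,
        country="IT",
        reporter_type=ReporterType.physician,
        report_type=ReportType.spontaneous,
        outcome=Outcome.not_recovered,
        comment_present=True,
        drugs=(
            DrugRecord(
                drug_name=drug,
                role=role,
                route=route,
                indication="macular degeneration",
                start_date="2012-06-01",
                dose_documented=True,
            ),
        ),
        reactions=tuple(
            ReactionRecord(pt_name=pt, onset_date="2014-05-15") for pt in pts
        ),
        dechallenge=ChallengeResult.unknown,
        rechallenge=ChallengeResult.unknown,
    )
    defaults.update(kw)
    return ICSR(**defaults)


@pytest.fixture
def demo_dictionary() -> TermDictionary:
    d = TermDictionary()
    d.add("Parkinson's disease", "Parkinson-like events", "narrow")
    d.add("Parkinsonism", "Parkinson-like events", "narrow")
    d.add("Hypertonia", "Parkinson-like events", "broad")
    d.add("Dementia", "Dementia", "narrow")
    d.add("Dementia Alzheimer's type", "Dementia", "narrow")
    d.add("Memory impairment", "Dementia", "broad")
    return d


@pytest.fixture
def small_cohort() -> list[ICSR]:
    """10 reports: 4 exposed (intravitreal ranibizumab), event planted on
    2 exposed and 1 unexposed -> hand-counted table (2, 2, 1, 5)."""
    reports = []
    for i in range(4):
        pts = ("Parkinson's disease",) if i < 2 else ("Headache",)
        reports.append(make_report(report_id=f"E{i}", pts=pts))
    reports.append(make_report(report_id="U0", drug="aspirin", route=Route.oral,
                               pts=("Parkinson's disease",)))
    for i in range(5):
        reports.append(make_report(report_id=f"N{i}", drug="aspirin",
                                   route=Route.oral, pts=("Headache",)))
    return reports
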