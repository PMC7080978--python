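import itertools
import math

import pytest

from pvsignal.grading import (
    DEFAULT_PENALTIES,
    CausalityCategory,
    CausalityInput,
    OtherExplanations,
    Temporal,
    classify_causality,
    derive_causality_input,
    time_to_onset_summary,
    vigigrade,
)
from pvsignal.reports import ChallengeResult, DrugRecord, ReactionRecord
from pvsignal.terms import EventDefinition

from conftest import make_report


class TestVigigrade:
    def test_fully_documented_scores_one(self):
        s = vigigrade(make_report())
        assert s.score == 1.0
        assert s.penalties_applied == ()
        assert s.well_documented

    def test_missing_time_to_onset_only(self):
        r = make_report(reactions=(ReactionRecord(pt_name="X"),))
        s = vigigrade(r)
        assert s.score == pytest.approx(0.5)
        assert dict(s.penalties_applied) == {"time_to_onset": 0.5}

    def test_imprecise_onset_counts_as_missing(self):
        r = make_report(reactions=(
            ReactionRecord(pt_name="X", onset_date="2014"),))
        assert vigigrade(r).score == pytest.approx(0.5)

    def test_three_missing_fields(self):
        r = make_report(
            sex=None,
            reactions=(ReactionRecord(pt_name="X"),),
            drugs=(DrugRecord(drug_name="ranibizumab", role="suspected",
                              route="intravitreal", indication=None,
                              start_date="2012-06-01", dose_documented=True),),
        )
        s = vigigrade(r)
        assert s.score == pytest.approx(0.5 * 0.7 * 0.9)
        assert s.score == pytest.approx(0.315)
        assert not s.well_documented

    def test_penalty_product_on_masked_reports(self):
        import random

        rng = random.Random(9)
        maskable = {
            "outcome": ("outcome", 0.3),
            "sex": ("sex", 0.1),
            "age": ("age", 0.1),
            "country": ("country", 0.1),
            "reporter_type": ("reporter", 0.1),
            "report_type": ("report_type", 0.1),
        }
        for _ in range(50):
            masked = [f for f in maskable if rng.random() < 0.5]
            r = make_report(**{f: None for f in masked})
            expected = 1.0
            for f in masked:
                expected *= 1.0 - maskable[f][1]
            s = vigigrade(r)
            assert s.score == pytest.approx(expected)
            assert {f for f, _ in s.penalties_applied} == \
                {maskable[f][0] for f in masked}

    def test_strictly_decreasing_with_each_penalty(self):
        base = make_report()
        r1 = make_report(sex=None)
        r2 = make_report(sex=None, country=None)
        assert vigigrade(base).score > vigigrade(r1).score > vigigrade(r2).score

    def test_custom_penalties(self):
        r = make_report(sex=None)
        s = vigigrade(r, {**DEFAULT_PENALTIES, "sex": 0.4})
        assert s.score == pytest.approx(0.6)


def oracle_category(inp: CausalityInput) -> CausalityCategory:
    """Independent rule table: evaluate every category's defining predicate
    and return the first in fixed priority order."""
    t, o = inp.temporal_relationship, inp.other_explanations
    de, re = inp.dechallenge, inp.rechallenge
    rules = [
        (CausalityCategory.unassessable,
         (not inp.information_sufficient) or inp.information_contradictory),
        (CausalityCategory.certain,
         t == Temporal.plausible and o == OtherExplanations.excluded
         and de == ChallengeResult.positive and re == ChallengeResult.positive),
        (CausalityCategory.probable,
         t == Temporal.plausible and o == OtherExplanations.excluded
         and de == ChallengeResult.positive and re != ChallengeResult.positive),
        (CausalityCategory.possible,
         t == Temporal.plausible
         and o in (OtherExplanations.possible, OtherExplanations.unknown)),
        (CausalityCategory.unlikely,
         t == Temporal.implausible or o == OtherExplanations.likely),
        (CausalityCategory.conditional, True),
    ]
    for cat, hit in rules:
        if hit:
            return cat
    raise AssertionError("unreachable")


class TestCausality:
    def test_modal_possible_case(self):
        inp = CausalityInput(Temporal.plausible, OtherExplanations.possible,
                             ChallengeResult.unknown, ChallengeResult.unknown)
        assert classify_causality(inp) is CausalityCategory.possible

    def test_implausible_is_unlikely(self):
        inp = CausalityInput(Temporal.implausible, OtherExplanations.unknown,
                             ChallengeResult.unknown, ChallengeResult.unknown)
        assert classify_causality(inp) is CausalityCategory.unlikely

    def test_insufficient_information_unassessable(self):
        inp = CausalityInput(Temporal.plausible, OtherExplanations.excluded,
                             ChallengeResult.positive, ChallengeResult.positive,
                             information_sufficient=False)
        assert classify_causality(inp) is CausalityCategory.unassessable

    def test_full_challenge_chain_is_certain(self):
        inp = CausalityInput(Temporal.plausible, OtherExplanations.excluded,
                             ChallengeResult.positive, ChallengeResult.positive)
        assert classify_causality(inp) is CausalityCategory.certain

    def test_exhaustive_768_inputs_against_oracle(self):
        combos = itertools.product(
            Temporal, OtherExplanations, ChallengeResult, ChallengeResult,
            (True, False), (True, False))
        n = 0
        for t, o, de, re, suff, contra in combos:
            inp = CausalityInput(t, o, de, re, suff, contra)
            assert classify_causality(inp) is oracle_category(inp), inp
            n += 1
        assert n == 3 * 4 * 4 * 4 * 2 * 2 == 768

    def test_derive_input_from_structured_report(self, demo_dictionary):
        ev = EventDefinition("pt", "Parkinson's disease")
        r = make_report()
        inp = derive_causality_input(r, "ranibizumab", ev, demo_dictionary)
        assert inp.temporal_relationship is Temporal.plausible
        assert classify_causality(inp) is CausalityCategory.possible


class TestTimeToOnset:
    def test_exactly_two_years(self):
        r = make_report(
            drugs=(DrugRecord(drug_name="d", role="suspected",
                              route="intravitreal", start_date="2012-05-15"),),
            reactions=(ReactionRecord(pt_name="X", onset_date="2014-05-15"),),
        )
        s = time_to_onset_summary([r], "d", EventDefinition("pt", "X"))
        assert s.n_estimable == 1
        assert s.mean_years == pytest.approx(730 / 365.25, abs=1e-9)
        assert round(s.mean_years, 2) == 2.0
        assert s.sd_years is None

    def test_four_point_fixture(self):
        import datetime as dt

        onsets = [0.5, 1.5, 2.5, 4.7]
        start = dt.date(2010, 1, 1)
        cases = []
        for i, y in enumerate(onsets):
            onset = start + dt.timedelta(days=round(y * 365.25))
            cases.append(make_report(
                report_id=f"C{i}", report_date=dt.date(2016, 1, 1),
                drugs=(DrugRecord(drug_name="d", role="suspected",
                                  route="intravitreal",
                                  start_date=start.isoformat()),),
                reactions=(ReactionRecord(pt_name="X",
                                          onset_date=onset.isoformat()),),
            ))
        # a fifth case with no start date is not estimable
        cases.append(make_report(
            report_id="C4", report_date=dt.date(2016, 1, 1),
            drugs=(DrugRecord(drug_name="d", role="suspected",
                              route="intravitreal"),),
            reactions=(ReactionRecord(pt_name="X", onset_date="2015-01-01"),),
        ))
        s = time_to_onset_summary(cases, "d", EventDefinition("pt", "X"))
        assert s.n_cases == 5 and s.n_estimable == 4
        # hand-computed oracle: mean 2.3; sample SD sqrt(9.68/3) ~ 1.7963
        assert s.mean_years == pytest.approx(2.3, abs=2e-3)
        assert s.sd_years == pytest.approx(math.sqrt(9.68 / 3), abs=2e-3)

    def test_two_point_sd_closed_form(self):
        import datetime as dt

        start = dt.date(2010, 1, 1)
        cases = []
        for i, days in enumerate((365, 731)):
            cases.append(make_report(
                report_id=f"B{i}", report_date=dt.date(2016, 1, 1),
                drugs=(DrugRecord(drug_name="d", role="suspected",
                                  route="intravitreal",
                                  start_date=start.isoformat()),),
                reactions=(ReactionRecord(
                    pt_name="X",
                    onset_date=(start + dt.timedelta(days=days)).isoformat()),),
            ))
        s = time_to_onset_summary(cases, "d", EventDefinition("pt", "X"))
        x1, x2 = 365 / 365.25, 731 / 365.25
        assert s.sd_years == pytest.approx(abs(x1 - x2) / math.sqrt(2))

    def test_imprecise_dates_not_estimable(self):
        r = make_report(
            drugs=(DrugRecord(drug_name="d", role="suspected",
                              route="intravitreal", start_date="2012"),),
            reactions=(ReactionRecord(pt_name="X", onset_date="2014-05-15"),),
        )
        s = time_to_onset_summary([r], "d", EventDefinition("pt", "X"))
        assert s.n_estimable == 0
        assert s.mean_years is None and s.sd_years is None

    def test_smq_level_event_requires_dictionary(self, demo_dictionary):
        r = make_report()
        ev = EventDefinition("smq", "Parkinson-like events")
        with pytest.raises(ValueError):
            time_to_onset_summary([r], "ranibizumab", ev)
        s = time_to_onset_summary([r], "ranibizumab", ev, demo_dictionary)
        assert s.n_estimable == 1
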