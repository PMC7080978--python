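import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.dates import FuzzyDate
from pvsignal.errors import RecordValidationError
from pvsignal.reports import (
    DrugRecord,
    ReactionRecord,
    Route,
    Sex,
    filter_age,
    filter_period,
    read_reports,
    select_exposed,
    write_reports,
)

from conftest import make_report


class TestModel:
    def test_valid_report(self):
        r = make_report()
        assert r.report_id == "R1"
        assert r.drugs[0].route is Route.intravitreal

    def test_age_out_of_range_rejected(self):
        with pytest.raises(Exception, match="120"):
            make_report(age_years=150, age=None)

    def test_age_150_named_in_jsonl_error(self, tmp_path):
        good = make_report().model_dump_json(exclude_none=True)
        bad = good.replace('"age_years":70.0', '"age_years":150.0').replace(
            '"report_id":"R1"', '"report_id":"RBAD"')
        p = tmp_path / "r.jsonl"
        p.write_text(good + "\n" + bad + "\n")
        with pytest.raises(RecordValidationError) as exc:
            read_reports(p, "jsonl")
        assert "RBAD" in str(exc.value)
        errors: list = []
        reports = read_reports(p, "jsonl", errors=errors)
        assert len(reports) == 1 and errors[0][0] == 2

    def test_onset_after_report_date_rejected(self):
        with pytest.raises(Exception, match="onset_date"):
            make_report(reactions=(
                ReactionRecord(pt_name="X", onset_date="2015-01-01"),))

    def test_duplicate_report_id_rejected(self, tmp_path):
        p = tmp_path / "r.jsonl"
        line = make_report().model_dump_json(exclude_none=True)
        p.write_text(line + "\n" + line + "\n")
        with pytest.raises(RecordValidationError, match="R1"):
            read_reports(p, "jsonl")


class TestFuzzyDates:
    @pytest.mark.parametrize("raw,precision,iso", [
        ("2014-03-05", "day", "2014-03-05"),
        ("2014-03", "month", "2014-03"),
        ("2014", "year", "2014"),
    ])
    def test_parse_roundtrip(self, raw, precision, iso):
        d = FuzzyDate.parse(raw)
        assert d.precision == precision
        assert d.isoformat() == iso
        assert d.precise == (precision == "day")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            FuzzyDate.parse("last tuesday")


class TestRoundTrip:
    def test_jsonl_three_records(self, tmp_path):
        reports = [make_report(report_id=f"R{i}") for i in range(3)]
        p = tmp_path / "r.jsonl"
        write_reports(reports, p, "jsonl")
        assert read_reports(p, "jsonl") == reports

    def test_empty_collection(self, tmp_path):
        for dialect in ("jsonl", "flat_csv"):
            p = tmp_path / f"empty.{dialect}"
            write_reports([], p, dialect)
            assert read_reports(p, dialect) == []

    @pytest.mark.parametrize("dialect", ["jsonl", "flat_csv"])
    def test_100_reports_field_wise(self, dialect, tmp_path):
        from pvsignal.simulate import GeneratorConfig, generate

        cfg = GeneratorConfig(
            n_reports=100, seed=7,
            drugs=[{"name": "ranibizumab", "marginal_prob": 0.3,
                    "route_dist": {"intravitreal": 0.8, "unreported": 0.2}}],
            events=[{"pt_name": "Tremor", "baseline_prob": 0.2}],
            missingness={"imprecise_date_prob": 0.2},
        )
        reports = generate(cfg)
        p = tmp_path / f"r.{dialect}"
        write_reports(reports, p, dialect)
        back = read_reports(p, dialect)
        assert len(back) == len(reports)
        # field-wise diff oracle: every model field must survive the trip
        for orig, rt in zip(reports, back):
            assert orig.model_dump() == rt.model_dump(), orig.report_id

    def test_flat_csv_nesting_two_drug_rows(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "report_id,report_date,age_years,sex,country,reporter_type,"
            "report_type,outcome,comment_present,dechallenge,rechallenge,"
            "drug_name,drug_role,drug_route,drug_indication,drug_start_date,"
            "dose_documented,pt_name,onset_date\n"
            "A1,2014-06-01,70,male,IT,,,,"
            "false,,,ranibizumab,suspected,intravitreal,,,false,Tremor,\n"
            "A1,2014-06-01,70,male,IT,,,,"
            "false,,,aspirin,concomitant,oral,,,false,Tremor,\n"
        )
        reports = read_reports(p, "flat_csv")
        assert len(reports) == 1
        # hand-nested fixture: one report, two distinct drug records, one PT
        r = reports[0]
        assert [d.drug_name for d in r.drugs] == ["ranibizumab", "aspirin"]
        assert [rx.pt_name for rx in r.reactions] == ["Tremor"]

    def test_flat_csv_conflicting_demographics(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "report_id,report_date,age_years,sex,country,reporter_type,"
            "report_type,outcome,comment_present,dechallenge,rechallenge,"
            "drug_name,drug_role,drug_route,drug_indication,drug_start_date,"
            "dose_documented,pt_name,onset_date\n"
            "A1,2014-06-01,70,male,,,,,false,,,x,suspected,oral,,,false,T,\n"
            "A1,2014-06-01,71,male,,,,,false,,,y,suspected,oral,,,false,T,\n"
        )
        with pytest.raises(RecordValidationError, match="A1"):
            read_reports(p, "flat_csv")


class TestSelectExposed:
    def test_intravitreal_retained(self):
        r = make_report()
        assert select_exposed([r], {"ranibizumab"}, Route.intravitreal) == [r]

    def test_unreported_route_excluded(self):
        r = make_report(route=Route.unreported)
        assert select_exposed([r], {"ranibizumab"}, Route.intravitreal) == []

    def test_concomitant_only_excluded(self):
        from pvsignal.reports import DrugRole

        r = make_report(role=DrugRole.concomitant)
        assert select_exposed([r], {"ranibizumab"}, Route.intravitreal) == []
        # configurable: allowing concomitant role retains it
        assert select_exposed([r], {"ranibizumab"}, Route.intravitreal,
                              require_suspected=False) == [r]

    def test_case_insensitive_name(self):
        r = make_report()
        assert select_exposed([r], {"RANIBIZUMAB"}, "intravitreal") == [r]

    def test_empty_drug_set_rejected(self):
        with pytest.raises(ValueError):
            select_exposed([], set(), Route.intravitreal)


class TestFilterPeriod:
    def test_boundaries(self):
        win = (dt.date(2010, 1, 1), dt.date(2016, 12, 31))
        inside = make_report(report_date=dt.date(2010, 1, 1),
                             drugs=(DrugRecord(drug_name="x", role="suspected"),),
                             reactions=(ReactionRecord(pt_name="T"),))
        outside = make_report(report_id="R2", report_date=dt.date(2009, 12, 31),
                              drugs=(DrugRecord(drug_name="x", role="suspected"),),
                              reactions=(ReactionRecord(pt_name="T"),))
        assert filter_period([inside, outside], *win) == [inside]

    def test_reversed_window_rejected(self):
        with pytest.raises(ValueError):
            filter_period([], dt.date(2016, 1, 1), dt.date(2010, 1, 1))

    def test_50_reports_linear_scan_oracle(self):
        reports = [
            make_report(report_id=f"R{i}",
                        report_date=dt.date(2008 + i % 10, 1 + i % 12, 1),
                        drugs=(DrugRecord(drug_name="x", role="suspected"),),
                        reactions=(ReactionRecord(pt_name="T"),))
            for i in range(50)
        ]
        start, end = dt.date(2010, 1, 1), dt.date(2016, 12, 31)
        expected = [r for r in reports if start <= r.report_date <= end]
        assert filter_period(reports, start, end) == expected


class TestFilterAge:
    def test_boundary_inclusive(self):
        assert filter_age([make_report(age=65.0)], 65) != []

    def test_missing_age_excluded(self):
        reports = [make_report(age=None), make_report(report_id="R2", age=80.0)]
        kept = filter_age(reports, 65)
        assert [r.report_id for r in kept] == ["R2"]

    def test_band_65_74_closed_open(self):
        r74 = make_report(report_id="A", age=74.0)
        r75 = make_report(report_id="B", age=75.0)
        band = filter_age([r74, r75], 65, 75, max_exclusive=True)
        assert [r.report_id for r in band] == ["A"]
        ge75 = filter_age([r74, r75], 75)
        assert [r.report_id for r in ge75] == ["B"]

    def test_negative_min_age_rejected(self):
        with pytest.raises(ValueError):
            filter_age([], -1)


class TestFilterProperties:
    @given(st.lists(st.tuples(st.integers(0, 99),
                              st.one_of(st.none(), st.floats(0, 120)),
                              st.booleans(), st.booleans()),
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_filters_commute_and_shrink(self, rows):
        reports = []
        for i, (uid, age, exposed_drug, ivt) in enumerate(rows):
            reports.append(make_report(
                report_id=f"H{i}",
                age=age,
                drug="ranibizumab" if exposed_drug else "aspirin",
                route=Route.intravitreal if ivt else Route.oral,
            ))
        names = {"ranibizumab"}
        ab = filter_age(select_exposed(reports, names, "intravitreal"), 65)
        ba = select_exposed(filter_age(reports, 65), names, "intravitreal")
        assert ab == ba
        assert set(r.report_id for r in ab) <= set(r.report_id for r in reports)
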